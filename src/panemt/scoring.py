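"""Single-sample enrichment scoring and scalar activity statistics.

The enrichment score follows the single-sample GSEA running-sum definition:
per sample, genes are ranked by expression; walking down the ranking, the
weighted fraction of set genes encountered (rank value raised to ``alpha`` as
weight) is compared to the fraction of non-set genes, and the differences are
summed over all positions.  Scores depend on within-sample ranks only, so any
strictly increasing transform of a sample's expression leaves them unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass
class ScoreMatrix:
    """Set-by-sample enrichment scores."""

    data: pd.DataFrame  # sets x samples

    def __post_init__(self) -> None:
        if not np.isfinite(self.data.to_numpy()).all():
            raise ValueError("score matrix contains non-finite values")

    @property
    def set_names(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


def ssgsea_scores(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    alpha: float = 0.25,
    normalize: bool = True,
) -> ScoreMatrix:
    """Single-sample enrichment scores for every set against every sample.

    Per sample: genes are ranked (ascending rank values, ties averaged) and
    ordered descending by expression.  For a set S of size m among N genes,

        ES = sum_i [ cum_in(i) / sum_{j in S} r_j^alpha  -  cum_out(i) / (N - m) ]

    where cum_in accumulates r_j^alpha over set genes seen up to position i
    and cum_out counts non-set genes.  With ``normalize`` the whole matrix is
    divided by its (max - min), mirroring the usual tool default; ordering is
    preserved.  Sets with no gene in the matrix are dropped with a warning.
    """
    genes = pd.Index(expr.gene_ids)
    X = expr.values  # genes x samples
    n_genes, n_samples = X.shape

    # ascending rank values per sample (ties -> average rank)
    ranks = np.apply_along_axis(rankdata, 0, X)
    weights = np.abs(ranks) ** alpha

    # descending-expression order per sample
    order = np.argsort(-X, axis=0, kind="stable")

    rows = {}
    for name, members in sets.sets.items():
        in_set = np.asarray(genes.isin(members))
        m = int(in_set.sum())
        if m == 0:
            logger.warning("gene set %r has no gene in the expression matrix; skipped", name)
            continue
        if m == n_genes:
            raise ValueError(
                f"gene set {name!r} covers every gene in the matrix; "
                "the non-set denominator is zero"
            )
        scores = np.empty(n_samples)
        for s in range(n_samples):
            o = order[:, s]
            hit = in_set[o]
            w = np.where(hit, weights[o, s], 0.0)
            denom_in = w.sum()
            p_in = np.cumsum(w) / denom_in
            p_out = np.cumsum(~hit) / (n_genes - m)
            scores[s] = float(np.sum(p_in - p_out))
        rows[name] = scores

    if not rows:
        raise ValueError("no gene set overlaps the expression matrix")
    df = pd.DataFrame(rows, index=expr.sample_ids).T
    df.columns = expr.sample_ids
    if normalize:
        spread = df.to_numpy().max() - df.to_numpy().min()
        if spread > 0:
            df = df / spread
    return ScoreMatrix(df)


def geometric_mean_activity(
    expr: ExpressionMatrix,
    genes: list[str],
    pseudocount: float = 1e-3,
    input_scale: str = "linear",
) -> pd.Series:
    """Per-sample geometric mean of the listed marker genes.

    ``input_scale='log2'`` exponentiates the matrix first, so the mean is
    taken on the linear scale; the default assumes linear-scale input.
    """
    present = [g for g in genes if g in expr.data.index]
    if not present:
        raise ValueError("none of the listed genes is present in the expression matrix")
    if len(present) < len(genes):
        logger.info("%d of %d marker genes absent; ignored", len(genes) - len(present), len(genes))
    sub = expr.data.loc[present]
    if input_scale == "log2":
        sub = np.power(2.0, sub)
    elif input_scale != "linear":
        raise ValueError(f"unknown input_scale {input_scale!r}")
    if (sub + pseudocount <= 0).any().any():
        raise ValueError("non-positive values after pseudocount; geometric mean undefined")
    return np.exp(np.log(sub + pseudocount).mean(axis=0))


@dataclass
class ActivityGroupStats:
    """Per-group mean, sd and coefficient of variation of an activity score."""

    table: pd.DataFrame  # columns: group, n, mean, sd, cv_percent, flag


def activity_cv(
    scores: pd.Series,
    groups: pd.Series,
    high_threshold: float = 50.0,
    low_threshold: float = 20.0,
    shift_to_positive: bool = False,
) -> ActivityGroupStats:
    """Coefficient of variation (100*sd/mean) of ``scores`` within each group.

    Singleton groups are excluded with a warning.  Groups with mean <= 0 get
    an undefined CV (the statistic is scale-dependent and signed enrichment
    scores can straddle zero) unless ``shift_to_positive`` min-shifts the
    scores first.  Groups are flagged ``high`` (CV > high_threshold), ``low``
    (CV < low_threshold) or ``mid``.
    """
    scores = scores.astype(float)
    if shift_to_positive:
        scores = scores - scores.min() + scores.std(ddof=1) * 1e-6
    rows = []
    for g, vals in scores.groupby(groups):
        if len(vals) < 2:
            logger.warning("group %r has a single sample; excluded from CV report", g)
            continue
        mean, sd = vals.mean(), vals.std(ddof=1)
        if mean <= 0:
            rows.append({"group": g, "n": len(vals), "mean": mean, "sd": sd,
                         "cv_percent": np.nan, "flag": "undefined"})
            continue
        cv = 100.0 * sd / mean
        flag = "high" if cv > high_threshold else ("low" if cv < low_threshold else "mid")
        rows.append({"group": g, "n": len(vals), "mean": mean, "sd": sd,
                     "cv_percent": cv, "flag": flag})
    return ActivityGroupStats(pd.DataFrame(rows))


def compare_paired_activity(
    tumor_scores: pd.Series,
    normal_scores: pd.Series,
    pairs: list[tuple[str, str]],
    groups: pd.Series | None = None,
) -> pd.DataFrame:
    """Tumor-vs-matched-normal activity comparison.

    ``pairs`` lists (tumor_id, normal_id).  A pair is ``enhanced`` iff the
    tumor score strictly exceeds the normal score, ``inhibited`` iff strictly
    lower; equal scores are a tie (neither).  Returns one row per pair plus
    attrs ``fraction_enhanced`` (overall) and, when ``groups`` maps tumor ids
    to e.g. cancer types, ``fraction_enhanced_by_group``.
    """
    rows = []
    for t, nrm in pairs:
        if t not in tumor_scores.index:
            raise KeyError(f"tumor sample {t!r} not in tumor score vector")
        if nrm not in normal_scores.index:
            raise KeyError(f"normal sample {nrm!r} not in normal score vector")
        ts, ns = float(tumor_scores[t]), float(normal_scores[nrm])
        rows.append(
            {
                "tumor_id": t,
                "normal_id": nrm,
                "tumor_score": ts,
                "normal_score": ns,
                "enhanced": ts > ns,
                "inhibited": ts < ns,
                "tie": ts == ns,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["fraction_enhanced"] = float(out["enhanced"].mean()) if len(out) else np.nan
    if groups is not None and len(out):
        grp = out.assign(group=out["tumor_id"].map(groups)).groupby("group")["enhanced"].mean()
        out.attrs["fraction_enhanced_by_group"] = grp.to_dict()
    return out
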