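"""Cohort-level statistics: balanced resampling validation, category-count
normalization, univariate Cox regression, Kaplan-Meier summaries and the
cosine tumor-purity transform.

The balanced resampling scheme draws an equal number of patients per
(cancer type, cluster) cell, merges them, and evaluates a caller-supplied
comparison on the merged subsample; repeating this removes the bias that
uneven cancer-type sizes would otherwise impose on any cross-cluster
comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps

logger = logging.getLogger(__name__)

# cosine transform of the combined stromal+immune score into tumor purity
PURITY_INTERCEPT = 0.6049872018
PURITY_SLOPE = 0.0001467884


# ---------------------------------------------------------------------------
# balanced resampling validation

Comparison = Callable[[pd.DataFrame, pd.Series], bool]


def score_enhanced_in(
    high_clusters: list,
    low_clusters: list,
    column: str = "score",
    alpha: float = 0.05,
) -> Comparison:
    """Verdict: every high cluster beats every low cluster.

    One-sided Welch t-test (high > low) for each (high, low) pair on the
    given column; the verdict is true iff all pairs reach p < alpha.
    """

    def verdict(df: pd.DataFrame, clusters: pd.Series) -> bool:
        for h in high_clusters:
            hv = df.loc[clusters == h, column]
            for lo in low_clusters:
                lv = df.loc[clusters == lo, column]
                if len(hv) < 2 or len(lv) < 2:
                    return False
                p = sps.ttest_ind(hv, lv, equal_var=False, alternative="greater").pvalue
                if not p < alpha:
                    return False
        return True

    verdict.__name__ = f"enhanced_{'_'.join(map(str, high_clusters))}_over_{'_'.join(map(str, low_clusters))}"
    return verdict


def shortest_median_survival(
    target_cluster,
    time_column: str = "survival_time",
    event_column: str = "event",
) -> Comparison:
    """Verdict: the target cluster has the strictly shortest KM median."""

    def verdict(df: pd.DataFrame, clusters: pd.Series) -> bool:
        medians = {}
        for c, idx in clusters.groupby(clusters).groups.items():
            sub = df.loc[idx]
            if sub[event_column].sum() == 0:
                medians[c] = np.inf
                continue
            kmf = KaplanMeierFitter()
            kmf.fit(sub[time_column], sub[event_column])
            medians[c] = float(kmf.median_survival_time_)
        if target_cluster not in medians:
            return False
        target = medians.pop(target_cluster)
        return all(target < m for m in medians.values())

    verdict.__name__ = f"shortest_median_{target_cluster}"
    return verdict


@dataclass
class SamplingReport:
    """Outcome of the cancer-type-balanced resampling validation."""

    statistic: str
    n_iterations: int
    n_per: int
    verdicts: list[bool]
    seed: int | None

    @property
    def n_consistent(self) -> int:
        return int(sum(self.verdicts))

    @property
    def fraction_consistent(self) -> float:
        return self.n_consistent / self.n_iterations


def balanced_sampling_validation(
    values: pd.Series | pd.DataFrame,
    cluster_labels: pd.Series,
    cancer_labels: pd.Series,
    comparison: Comparison,
    n_per: int = 10,
    iterations: int = 100,
    seed: int | None = None,
) -> SamplingReport:
    """Repeatedly draw ``n_per`` samples per (cancer, cluster) cell and test.

    Cells with fewer than ``n_per`` members contribute all their samples
    (empty cells are skipped with a log message).  Sampling is without
    replacement within each iteration, reproducible under ``seed`` and
    invariant to input row order (samples are processed in sorted-id order).
    """
    if isinstance(values, pd.Series):
        values = values.to_frame(name=values.name or "score")
    ids = sorted(values.index)
    values = values.loc[ids]
    clusters = cluster_labels.reindex(ids)
    cancers = cancer_labels.reindex(ids)
    if clusters.isna().any() or cancers.isna().any():
        raise ValueError("every sample needs a cluster and a cancer label")

    cells: list[np.ndarray] = []
    for (_, _), grp in values.groupby([cancers, clusters], sort=True):
        cells.append(np.asarray(sorted(grp.index), dtype=object))

    rng = np.random.default_rng(seed)
    verdicts = []
    for _ in range(iterations):
        chosen: list = []
        for cell in cells:
            if len(cell) == 0:
                continue
            take = min(n_per, len(cell))
            pick = rng.choice(len(cell), size=take, replace=False)
            chosen.extend(cell[np.sort(pick)])
        sub = values.loc[chosen]
        verdicts.append(bool(comparison(sub, clusters.loc[chosen])))
    return SamplingReport(
        statistic=getattr(comparison, "__name__", "comparison"),
        n_iterations=iterations,
        n_per=n_per,
        verdicts=verdicts,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# category-count normalization


def normalize_category_counts(counts: pd.DataFrame, target: float = 100.0) -> pd.DataFrame:
    """Rescale each row (cancer type) of a contingency table to sum to ``target``.

    Preserves within-cancer proportions exactly; zero-total rows are dropped
    with a warning.  Aggregating the normalized table across cancers then
    weighs every cancer type equally.
    """
    totals = counts.sum(axis=1)
    zero = totals == 0
    if zero.any():
        logger.warning("dropping zero-total rows: %s", list(counts.index[zero]))
        counts = counts.loc[~zero]
        totals = totals[~zero]
    return counts.mul(target / totals, axis=0)


def category_composition(normalized: pd.DataFrame) -> pd.Series:
    """Percent composition per category after per-cancer normalization."""
    col = normalized.sum(axis=0)
    return 100.0 * col / col.sum()


# ---------------------------------------------------------------------------
# univariate Cox proportional hazards


@dataclass
class CoxResult:
    """Univariate Cox fit: log-hazard per unit covariate and Wald inference."""

    beta: float
    hr: float
    se: float
    wald_z: float
    p_value: float
    n: int
    n_events: int


def _breslow_loglik(beta: float, t, e, x):
    """Breslow partial log-likelihood and its first two derivatives."""
    order = np.argsort(-t, kind="stable")  # descending time
    t, e, x = t[order], e[order], x[order]
    eta = beta * x
    w = np.exp(eta)
    # running sums over the risk set (all with time >= current event time)
    cw = np.cumsum(w)
    cwx = np.cumsum(w * x)
    cwx2 = np.cumsum(w * x * x)
    ll = dll = d2ll = 0.0
    i = 0
    n = len(t)
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        # risk set = samples 0..j-1 (times >= t[i]); events in this tie block
        block = slice(i, j)
        d = int(e[block].sum())
        if d > 0:
            s0, s1, s2 = cw[j - 1], cwx[j - 1], cwx2[j - 1]
            ll += float((eta[block] * e[block]).sum()) - d * np.log(s0)
            dll += float((x[block] * e[block]).sum()) - d * s1 / s0
            d2ll -= d * (s2 / s0 - (s1 / s0) ** 2)
        i = j
    return ll, dll, d2ll


def cox_univariate(time, event, covariate, max_iter: int = 50, tol: float = 1e-9) -> CoxResult:
    """Newton-Raphson fit of a one-covariate Cox model with Breslow ties.

    Raises on zero events, a constant covariate, or non-convergence within
    ``max_iter`` iterations.  The Wald z and two-sided p come from the
    observed information at the maximum.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=float)
    x = np.asarray(covariate, dtype=float)
    if t.shape != e.shape or t.shape != x.shape:
        raise ValueError("time, event and covariate must have equal length")
    if (t < 0).any():
        raise ValueError("negative survival times")
    if e.sum() == 0:
        raise ValueError("no events observed; Cox model undefined")
    if np.std(x) == 0:
        raise ValueError("constant covariate")
    x_center = x - x.mean()  # improves conditioning; beta is unchanged

    beta = 0.0
    ll, dll, d2ll = _breslow_loglik(beta, t, e, x_center)
    for it in range(max_iter):
        if d2ll >= 0:
            raise RuntimeError("non-concave point encountered in Cox fit")
        step = -dll / d2ll
        # step-halving to guarantee ascent
        new_beta = beta + step
        new_ll, new_dll, new_d2ll = _breslow_loglik(new_beta, t, e, x_center)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_dll, new_d2ll = _breslow_loglik(new_beta, t, e, x_center)
            halvings += 1
        converged = abs(new_beta - beta) < tol or abs(new_dll) < tol
        beta, ll, dll, d2ll = new_beta, new_ll, new_dll, new_d2ll
        if converged:
            break
    else:
        raise RuntimeError(
            f"Cox fit did not converge in {max_iter} iterations "
            f"(beta={beta:.4g}, score={dll:.3g})"
        )
    se = float(np.sqrt(-1.0 / d2ll))
    z = beta / se
    p = 2.0 * sps.norm.sf(abs(z))
    return CoxResult(
        beta=float(beta),
        hr=float(np.exp(beta)),
        se=se,
        wald_z=float(z),
        p_value=float(p),
        n=len(t),
        n_events=int(e.sum()),
    )


# ---------------------------------------------------------------------------
# Kaplan-Meier summaries


@dataclass
class KMSummary:
    """Per-group KM curves, median survival and the log-rank p across groups."""

    table: pd.DataFrame  # group, n, n_events, median
    curves: dict  # group -> DataFrame(time, survival)
    logrank_p: float


def km_summary(time, event, group_labels) -> KMSummary:
    """Product-limit survival per group with median and a log-rank test.

    The median is the smallest time at which the estimated survival drops to
    0.5 or below; groups that never reach it report NaN (not reached).
    Groups with zero events are dropped from the log-rank comparison with a
    warning but still summarized.
    """
    df = pd.DataFrame({"time": np.asarray(time, dtype=float),
                       "event": np.asarray(event, dtype=float),
                       "group": np.asarray(group_labels)})
    if df.empty:
        raise ValueError("empty survival input")
    rows = []
    curves = {}
    usable = []
    for g, sub in df.groupby("group"):
        if len(sub) == 0:
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"], label=str(g))
        med = float(kmf.median_survival_time_)
        rows.append(
            {
                "group": g,
                "n": len(sub),
                "n_events": int(sub["event"].sum()),
                "median": med if np.isfinite(med) else np.nan,
            }
        )
        curves[g] = kmf.survival_function_.reset_index().set_axis(["time", "survival"], axis=1)
        if sub["event"].sum() > 0:
            usable.append(g)
        else:
            logger.warning("group %r has no events; excluded from log-rank test", g)
    if len(usable) >= 2:
        sub = df[df["group"].isin(usable)]
        lr = multivariate_logrank_test(sub["time"], sub["group"], sub["event"])
        p = float(lr.p_value)
    else:
        p = np.nan
    return KMSummary(table=pd.DataFrame(rows), curves=curves, logrank_p=p)


def median_split_groups(scores: pd.Series) -> pd.Series:
    """Label samples 'high'/'low' relative to the median score (helper for KM)."""
    med = scores.median()
    return pd.Series(np.where(scores > med, "high", "low"), index=scores.index)


# ---------------------------------------------------------------------------
# tumor purity


def estimate_purity(estimate_score) -> pd.DataFrame:
    """Cosine transform of the combined stromal+immune score into purity.

    purity = cos(0.6049872018 + 0.0001467884 * estimate_score).  Scores whose
    cosine argument falls outside [0, pi] (where the transform is monotone)
    are flagged out-of-range rather than rejected.
    """
    s = pd.Series(estimate_score, dtype=float)
    arg = PURITY_INTERCEPT + PURITY_SLOPE * s
    out = pd.DataFrame(
        {
            "estimate_score": s,
            "purity": np.cos(arg),
            "in_range": (arg >= 0) & (arg <= np.pi),
        }
    )
    if (~out["in_range"]).any():
        logger.warning(
            "%d estimate scores give a cosine argument outside [0, pi]",
            int((~out["in_range"]).sum()),
        )
    return out
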