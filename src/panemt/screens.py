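"""Multi-omics regulator screens and per-cluster driver-event enrichment.

Three screens ask whether a signature gene's expression is plausibly driven
by somatic mutation (frequency against a genome-wide baseline), copy number
(Pearson correlation of expression with GISTIC-style values plus an altered
fraction) or DNA methylation (anti-correlation with the most methylated
probe).  A separate enrichment test flags events over-represented in one
cluster versus the rest.  Multiple testing uses Benjamini-Hochberg FDR,
applied per mechanism within each cancer type (or per cluster comparison).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, OmicsMatrix

logger = logging.getLogger(__name__)

HIT_COLUMNS = [
    "gene", "cancer_type", "mechanism", "statistic",
    "altered_fraction", "p_value", "fdr", "is_hit",
]


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _iter_cancers(sample_ids, cancer_labels):
    if cancer_labels is None:
        yield "all", list(sample_ids)
        return
    lab = cancer_labels.reindex(sample_ids)
    for cancer, grp in lab.groupby(lab):
        yield cancer, list(grp.index)


def mutation_frequency_screen(
    mut: OmicsMatrix,
    genes: list[str],
    cancer_labels: pd.Series | None = None,
    freq_threshold: float = 0.03,
    fc_threshold: float = 1.5,
) -> pd.DataFrame:
    """Flag genes mutated above a frequency floor and a fold over baseline.

    Baseline per cancer type = total positive events / total observed events
    over the whole matrix (the genome-wide mutation rate proxy); fold = gene
    frequency / baseline.  Hit iff frequency > ``freq_threshold`` and fold >
    ``fc_threshold``.  The frequency screen carries no p-value.
    """
    if mut.kind != "mutation":
        raise ValueError("mutation_frequency_screen requires a mutation matrix")
    rows = []
    for cancer, samples in _iter_cancers(mut.sample_ids, cancer_labels):
        sub = mut.data[samples]
        baseline = float(sub.to_numpy().sum()) / sub.size
        if baseline == 0:
            logger.warning("cancer %r has no mutations at all; skipped", cancer)
            continue
        for g in genes:
            if g not in sub.index:
                continue
            freq = float(sub.loc[g].mean())
            fold = freq / baseline
            rows.append(
                {
                    "gene": g,
                    "cancer_type": cancer,
                    "mechanism": "mutation",
                    "statistic": fold,
                    "altered_fraction": freq,
                    "p_value": np.nan,
                    "fdr": np.nan,
                    "is_hit": freq > freq_threshold and fold > fc_threshold,
                }
            )
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def cnv_expression_screen(
    cnv: OmicsMatrix,
    expr: ExpressionMatrix,
    genes: list[str],
    cancer_labels: pd.Series | None = None,
    r_threshold: float = 0.3,
    frac_threshold: float = 0.3,
    fdr_threshold: float = 0.05,
    call_threshold: float = 0.3,
) -> pd.DataFrame:
    """Dosage screen: expression-vs-copy-number Pearson correlation.

    Per (gene, cancer): r with two-sided p; altered fraction = share of
    samples with |copy-number value| >= ``call_threshold``.  Hit iff
    r > ``r_threshold``, fraction > ``frac_threshold`` and BH FDR (within
    the cancer type) < ``fdr_threshold``.  The mechanism label follows the
    sign of the mean called value (amplification vs deletion).
    """
    if cnv.kind != "cnv":
        raise ValueError("cnv_expression_screen requires a cnv matrix")
    shared = [s for s in cnv.sample_ids if s in set(expr.sample_ids)]
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} shared samples; need >= 10")
    rows = []
    for cancer, samples in _iter_cancers(shared, cancer_labels):
        sub_rows = []
        for g in genes:
            if g not in cnv.data.index or g not in expr.data.index:
                continue
            c = cnv.data.loc[g, samples].to_numpy(dtype=float)
            e = expr.data.loc[g, samples].to_numpy(dtype=float)
            if np.std(c) == 0:
                logger.info("gene %r: zero-variance copy number in %r; skipped", g, cancer)
                continue
            r, p = stats.pearsonr(e, c)
            altered = np.abs(c) >= call_threshold
            frac = float(altered.mean())
            direction = "cnv_amplification" if (altered.any() and c[altered].mean() > 0) else "cnv_deletion"
            sub_rows.append(
                {
                    "gene": g,
                    "cancer_type": cancer,
                    "mechanism": direction,
                    "statistic": float(r),
                    "altered_fraction": frac,
                    "p_value": float(p),
                }
            )
        if not sub_rows:
            continue
        df = pd.DataFrame(sub_rows)
        df["fdr"] = bh_fdr(df["p_value"])
        df["is_hit"] = (
            (df["statistic"] > r_threshold)
            & (df["altered_fraction"] > frac_threshold)
            & (df["fdr"] < fdr_threshold)
        )
        rows.append(df)
    if not rows:
        return pd.DataFrame(columns=HIT_COLUMNS)
    return pd.concat(rows, ignore_index=True)[HIT_COLUMNS]


def methylation_expression_screen(
    meth: OmicsMatrix,
    expr: ExpressionMatrix,
    genes: list[str],
    cancer_labels: pd.Series | None = None,
    r_threshold: float = -0.3,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Methylation screen on the most-methylated probe per gene.

    For each gene the probe with the largest mean beta is tested; hit iff
    Pearson r(expression, beta) < ``r_threshold`` (anti-correlation) and BH
    FDR < ``fdr_threshold`` within the cancer type.
    """
    if meth.kind != "methylation":
        raise ValueError("methylation_expression_screen requires a methylation matrix")
    if meth.probe_to_gene is None:
        raise ValueError("methylation matrix needs a probe_to_gene mapping")
    gene_probes: dict[str, list[str]] = {}
    for probe, gene in meth.probe_to_gene.items():
        gene_probes.setdefault(gene, []).append(probe)

    shared = [s for s in meth.sample_ids if s in set(expr.sample_ids)]
    rows = []
    for cancer, samples in _iter_cancers(shared, cancer_labels):
        sub_rows = []
        for g in genes:
            probes = [p for p in gene_probes.get(g, []) if p in meth.data.index]
            if not probes or g not in expr.data.index:
                logger.info("gene %r has no mapped probe; skipped", g)
                continue
            means = meth.data.loc[probes, samples].mean(axis=1)
            probe = means.idxmax()
            beta = meth.data.loc[probe, samples].to_numpy(dtype=float)
            e = expr.data.loc[g, samples].to_numpy(dtype=float)
            if np.std(beta) == 0 or np.std(e) == 0:
                continue
            r, p = stats.pearsonr(e, beta)
            sub_rows.append(
                {
                    "gene": g,
                    "cancer_type": cancer,
                    "mechanism": "hypomethylation" if r < 0 else "hypermethylation",
                    "statistic": float(r),
                    "altered_fraction": np.nan,
                    "p_value": float(p),
                    "probe": probe,
                }
            )
        if not sub_rows:
            continue
        df = pd.DataFrame(sub_rows)
        df["fdr"] = bh_fdr(df["p_value"])
        df["is_hit"] = (df["statistic"] < r_threshold) & (df["fdr"] < fdr_threshold)
        rows.append(df)
    if not rows:
        return pd.DataFrame(columns=HIT_COLUMNS + ["probe"])
    return pd.concat(rows, ignore_index=True)[HIT_COLUMNS + ["probe"]]


def cluster_event_enrichment(
    events: OmicsMatrix,
    labels: pd.Series,
    test: str = "fisher",
    alpha: float = 0.05,
    fc_threshold: float = 1.5,
) -> pd.DataFrame:
    """Per-(event, cluster) enrichment of binary events in-cluster vs rest.

    Builds the 2x2 table (altered/unaltered x in/out), tests with Fisher's
    exact test (mutations) or chi-square (copy-number events), reports the
    sample odds ratio and fold change (freq_in / freq_out), BH-adjusts across
    events within each cluster comparison, and flags drivers by
    adj_p < ``alpha`` and fold change > ``fc_threshold``.
    """
    if test not in ("fisher", "chisq"):
        raise ValueError("test must be 'fisher' or 'chisq'")
    labels = labels.reindex(events.sample_ids)
    if labels.isna().any():
        raise ValueError("every event sample needs a cluster label")
    mat = events.data.to_numpy() > 0
    out_frames = []
    for cluster in sorted(labels.unique()):
        inside = (labels == cluster).to_numpy()
        n_in, n_out = int(inside.sum()), int((~inside).sum())
        if n_in == 0 or n_out == 0:
            raise ValueError(f"cluster {cluster!r} is empty or covers the whole cohort")
        rows = []
        for gi, event in enumerate(events.data.index):
            v = mat[gi]
            if not v.any():
                continue
            a = int(v[inside].sum())
            b = n_in - a
            c = int(v[~inside].sum())
            d = n_out - c
            table = np.array([[a, b], [c, d]])
            if test == "fisher":
                _, p = stats.fisher_exact(table, alternative="two-sided")
            else:
                if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
                    p = 1.0
                else:
                    _, p, _, _ = stats.chi2_contingency(table, correction=True)
            freq_in = a / n_in
            freq_out = c / n_out
            odds = (a * d) / (b * c) if b * c > 0 else np.inf
            fold = freq_in / freq_out if freq_out > 0 else np.inf
            rows.append(
                {
                    "event": event,
                    "cluster": cluster,
                    "freq_in": freq_in,
                    "freq_out": freq_out,
                    "odds_ratio": odds,
                    "fold_change": fold,
                    "p_value": float(p),
                }
            )
        if not rows:
            continue
        df = pd.DataFrame(rows)
        df["adj_p"] = bh_fdr(df["p_value"])
        df["is_driver"] = (df["adj_p"] < alpha) & (df["fold_change"] > fc_threshold)
        out_frames.append(df)
    if not out_frames:
        return pd.DataFrame(
            columns=["event", "cluster", "freq_in", "freq_out", "odds_ratio",
                     "fold_change", "p_value", "adj_p", "is_driver"]
        )
    return pd.concat(out_frames, ignore_index=True)
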