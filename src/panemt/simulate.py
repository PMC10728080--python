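"""Synthetic pan-cancer cohorts with planted EMT structure.

The generator emulates the statistical shape the analysis assumes: a
gene-by-sample log2-scale expression matrix over many cancer types with
additive cancer-type batch shifts, four planted EMT subtypes expressed as
mean shifts on a signature gene set, omics events (mutation / copy number /
methylation) coupled to expression for designated regulator genes, and
survival times whose hazard depends on the planted EMT score.

The two high-EMT subtypes share the magnitude of their signature shift but
express it on partly disjoint gene blocks, so they cannot be told apart by
the mean signature score alone — clustering has to use the full
signature-gene covariance, as in real mesenchymal-like tumors where an
AKT-driven and a genomically-driven subtype score alike.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ClinicalTable, ExpressionMatrix, GeneSetCollection, OmicsMatrix

SIGNATURE_SET_NAME = "EMTCG"
SUBTYPE_ORDER = ("EMTlow", "EMTmid", "EMThigh-NOS", "EMThigh-AKT")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults are the study conditions.

    Expression is simulated on a log2-like Gaussian scale.  ``subtype_effect``
    gives the per-subtype mean shift applied to the shared signature block
    (log2 units, quoted relative to a unit-variance reference scale); each
    high subtype additionally shifts its own disjoint 5-gene block by
    ``secondary_effect``.  ``survival_beta`` is the log-hazard per standard
    deviation of the planted EMT score.
    """

    n_cancer_types: int = 24
    samples_per_cancer: int = 40
    n_genes: int = 1000
    n_signature_genes: int = 35
    n_shared_signature: int = 25
    subtype_proportions: tuple = (0.20, 0.33, 0.16, 0.31)
    subtype_effect: tuple = (0.0, 0.5, 2.0, 2.0)
    secondary_effect: float = 2.0
    batch_sd: float = 0.25
    noise_sd: float = 0.7
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    # omics
    n_regulator_genes: int = 5  # per mechanism (cnv, methylation, mutation)
    cnv_dosage: float = 1.0
    cnv_altered_fraction: float = 0.45
    meth_coupling: float = 0.15  # beta decrease per sd of expression
    mut_regulator_rate: float = 0.20  # recurrently mutated regulator genes
    driver_rate_in: float = 0.65  # TP53-like event, NOS-subtype rate
    driver_rate_out: float = 0.27
    background_mutation_rate: float = 0.01
    n_mutation_background: int = 30  # extra quiet genes setting the baseline
    # survival
    survival_beta: float = 0.5
    baseline_hazard: float = 0.01  # events per month at score 0
    censoring_rate: float = 0.3
    seed: int | None = 0

    def __post_init__(self) -> None:
        if abs(sum(self.subtype_proportions) - 1.0) > 1e-9:
            raise ValueError("subtype_proportions must sum to 1")
        for name in ("batch_sd", "noise_sd", "baseline_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must lie in [0, 1)")
        needed = 5 * self.n_regulator_genes + self.n_mutation_background
        if needed > self.n_genes - self.n_signature_genes:
            raise ValueError("regulator genes exceed the available background genes")
        if self.n_shared_signature + 10 > self.n_signature_genes:
            # two disjoint 5-gene blocks must fit after the shared block
            raise ValueError("signature must leave room for two 5-gene subtype blocks")


@dataclass
class SyntheticCohort:
    """Planted-truth bundle: data for every pipeline stage plus the answers."""

    expression: ExpressionMatrix
    clinical: ClinicalTable
    mutation: OmicsMatrix
    cnv: OmicsMatrix
    methylation: OmicsMatrix
    true_labels: pd.Series  # sample -> subtype name
    true_regulators: dict  # gene -> mechanism
    signature: GeneSetCollection
    config: SimulationConfig = field(repr=False, default=None)

    def __post_init__(self) -> None:
        sids = set(self.expression.sample_ids)
        for name, ids in (
            ("clinical", self.clinical.sample_ids),
            ("mutation", self.mutation.sample_ids),
            ("cnv", self.cnv.sample_ids),
            ("methylation", self.methylation.sample_ids),
            ("true_labels", list(self.true_labels.index)),
        ):
            if set(ids) != sids:
                raise ValueError(f"{name} sample ids do not match the expression matrix")


def _planted_score(expr: ExpressionMatrix, signature_genes: list[str]) -> pd.Series:
    """Standardized mean scaled-expression over the signature genes."""
    sub = expr.data.loc[signature_genes]
    z = sub.sub(sub.mean(axis=1), axis=0).div(sub.std(axis=1, ddof=1), axis=0)
    score = z.mean(axis=0)
    return (score - score.mean()) / score.std(ddof=1)


def simulate_expression(config: SimulationConfig):
    """Expression matrix, true subtype labels and cancer-type labels."""
    rng = np.random.default_rng(None if config.seed is None else [config.seed, 0])
    n = config.n_cancer_types * config.samples_per_cancer
    n_sig = config.n_signature_genes
    sample_ids = [f"S{i + 1:05d}" for i in range(n)]
    sig_genes = [f"SG{i + 1:03d}" for i in range(n_sig)]
    bg_genes = [f"BG{i + 1:05d}" for i in range(config.n_genes - n_sig)]
    genes = sig_genes + bg_genes
    cancers = pd.Series(
        [f"CT{i + 1:02d}" for i in np.repeat(np.arange(config.n_cancer_types),
                                             config.samples_per_cancer)],
        index=sample_ids,
        name="cancer_type",
    )

    subtype_idx = rng.choice(4, size=n, p=np.asarray(config.subtype_proportions))
    counts = np.bincount(subtype_idx, minlength=4)
    if (counts < 4).any():
        raise ValueError(f"fewer than 4 samples in some subtype: {dict(zip(SUBTYPE_ORDER, counts))}")
    labels = pd.Series([SUBTYPE_ORDER[i] for i in subtype_idx], index=sample_ids, name="subtype")

    # subtype mean-shift matrix on the signature genes
    shared = config.n_shared_signature
    shift = np.zeros((4, n_sig))
    eff = np.asarray(config.subtype_effect, dtype=float)
    shift[:, :shared] = eff[:, None]
    shift[1, shared:] = eff[1]  # the mid subtype shifts the whole signature
    shift[2, shared:shared + 5] = config.secondary_effect  # NOS block
    shift[3, shared + 5:shared + 10] = config.secondary_effect  # AKT block

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)
    batch = rng.normal(0.0, config.batch_sd, size=(config.n_cancer_types, config.n_genes))
    cancer_idx = np.repeat(np.arange(config.n_cancer_types), config.samples_per_cancer)
    X = (
        baseline[None, :]
        + batch[cancer_idx]
        + rng.normal(0.0, config.noise_sd, size=(n, config.n_genes))
    )
    X[:, :n_sig] += shift[subtype_idx]
    expr = ExpressionMatrix(pd.DataFrame(X.T, index=genes, columns=sample_ids))
    return expr, labels, cancers, sig_genes


def simulate_omics(expr: ExpressionMatrix, labels: pd.Series, config: SimulationConfig):
    """Mutation, CNV and methylation matrices coupled to designated genes.

    Returns (mutation, cnv, methylation, expression) — the expression comes
    back modified because copy-number dosage feeds into it.  CNV regulators
    get ``cnv_dosage * value`` added to their expression (>= the configured
    altered fraction); methylation regulators get a high-mean probe whose
    beta is anti-correlated with expression; one TP53-like driver event is
    mutated at ``driver_rate_in`` inside the NOS-like subtype and
    ``driver_rate_out`` elsewhere.
    """
    rng = np.random.default_rng(None if config.seed is None else [config.seed, 1])
    n_reg = config.n_regulator_genes
    samples = expr.sample_ids
    n = len(samples)
    bg = [g for g in expr.gene_ids if g.startswith("BG")]
    if len(bg) < 3 * n_reg:
        raise ValueError("not enough background genes for the requested regulators")
    cnv_reg = bg[:n_reg]
    meth_reg = bg[n_reg:2 * n_reg]
    mut_reg = bg[2 * n_reg:3 * n_reg]
    null_panel = bg[3 * n_reg:5 * n_reg]
    mut_background = bg[5 * n_reg:5 * n_reg + config.n_mutation_background]
    true_regulators = {
        **{g: "cnv_amplification" for g in cnv_reg},
        **{g: "hypomethylation" for g in meth_reg},
        **{g: "mutation" for g in mut_reg},
    }

    data = expr.data.copy()

    # --- copy number: amplification events feeding expression dosage
    cnv_rows = {}
    for g in cnv_reg + null_panel:
        altered = rng.random(n) < config.cnv_altered_fraction
        value = np.where(altered, rng.normal(1.2, 0.3, size=n), rng.normal(0.0, 0.1, size=n))
        cnv_rows[g] = value
        if g in cnv_reg:
            data.loc[g] = data.loc[g].to_numpy() + config.cnv_dosage * value
    cnv = OmicsMatrix("cnv", pd.DataFrame(cnv_rows, index=samples).T)

    # --- methylation: two probes per gene; the high-mean probe is the coupled one
    meth_rows = {}
    probe_map = {}
    for g in meth_reg + null_panel:
        e = data.loc[g].to_numpy()
        z = (e - e.mean()) / e.std(ddof=1)
        if g in meth_reg:
            beta_hi = np.clip(
                0.55 - config.meth_coupling * z + rng.normal(0, 0.08, size=n), 0.02, 0.98
            )
        else:
            beta_hi = np.clip(rng.normal(0.55, 0.1, size=n), 0.02, 0.98)
        beta_lo = np.clip(rng.normal(0.2, 0.05, size=n), 0.02, 0.98)
        meth_rows[f"{g}_p1"] = beta_hi
        meth_rows[f"{g}_p2"] = beta_lo
        probe_map[f"{g}_p1"] = g
        probe_map[f"{g}_p2"] = g
    meth = OmicsMatrix("methylation", pd.DataFrame(meth_rows, index=samples).T,
                       probe_to_gene=probe_map)

    # --- mutation: elevated-frequency regulators, one subtype-driver event,
    #     and a genome-wide background that sets the baseline rate
    nos = (labels == "EMThigh-NOS").to_numpy()
    mut_rows = {}
    for g in mut_reg:
        mut_rows[g] = (rng.random(n) < config.mut_regulator_rate).astype(float)
    driver_p = np.where(nos, config.driver_rate_in, config.driver_rate_out)
    mut_rows["MUT_DRIVER"] = (rng.random(n) < driver_p).astype(float)
    for g in null_panel + mut_background:
        mut_rows[g] = (rng.random(n) < config.background_mutation_rate).astype(float)
    mut = OmicsMatrix("mutation", pd.DataFrame(mut_rows, index=samples).T)

    return mut, cnv, meth, ExpressionMatrix(data), true_regulators


def simulate_survival(
    expr: ExpressionMatrix,
    labels: pd.Series,
    cancers: pd.Series,
    signature_genes: list[str],
    config: SimulationConfig,
) -> ClinicalTable:
    """Clinical table with score-dependent exponential survival.

    Event times are exponential with hazard h0 * exp(beta * score), score
    being the standardized planted EMT score; a ``censoring_rate`` fraction
    of samples is censored uniformly before its event.  The combined
    stromal+immune score is drawn per subtype with the AKT-like subtype
    highest (lowest purity).
    """
    rng = np.random.default_rng(None if config.seed is None else [config.seed, 2])
    samples = expr.sample_ids
    n = len(samples)
    score = _planted_score(expr, signature_genes)

    hazard = config.baseline_hazard * np.exp(config.survival_beta * score.to_numpy())
    event_time = rng.exponential(1.0 / hazard)
    if config.censoring_rate > 0:
        # independent exponential censoring, calibrated so that a baseline-risk
        # sample is censored with the configured probability
        censor_rate = config.baseline_hazard * config.censoring_rate / (1 - config.censoring_rate)
        censor_time = rng.exponential(1.0 / censor_rate, size=n)
    else:
        censor_time = np.full(n, np.inf)
    obs_time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    est_mean = {"EMTlow": 600.0, "EMTmid": 1200.0, "EMThigh-NOS": 2200.0,
                "EMThigh-AKT": 3600.0}
    estimate = np.array([rng.normal(est_mean[labels[s]], 400.0) for s in samples])

    grade = rng.choice(["G1", "G2", "G3", "G4"], size=n)
    gender = rng.choice(["female", "male"], size=n)
    return ClinicalTable(
        pd.DataFrame(
            {
                "sample_id": samples,
                "survival_time": obs_time,
                "event": event,
                "cancer_type": cancers.loc[samples].to_numpy(),
                "grade": grade,
                "gender": gender,
                "estimate_score": estimate,
                "emt_score": score.loc[samples].to_numpy(),
            }
        )
    )


def simulate_cohort(config: SimulationConfig | None = None) -> SyntheticCohort:
    """Full planted cohort: expression, omics, clinical and truth labels."""
    config = config or SimulationConfig()
    expr, labels, cancers, sig_genes = simulate_expression(config)
    mut, cnv, meth, expr, true_regulators = simulate_omics(expr, labels, config)
    clinical = simulate_survival(expr, labels, cancers, sig_genes, config)
    shared = config.n_shared_signature
    signature = GeneSetCollection(
        sets={
            SIGNATURE_SET_NAME: sig_genes,
            "EMTCG_shared": sig_genes[:shared],
            "EMTCG_NOS_block": sig_genes[shared:shared + 5],
            "EMTCG_AKT_block": sig_genes[shared + 5:shared + 10],
        },
        descriptions={
            SIGNATURE_SET_NAME: "planted EMT core signature",
            "EMTCG_shared": "signature block shifted in every activated subtype",
            "EMTCG_NOS_block": "block private to the NOS-like high subtype",
            "EMTCG_AKT_block": "block private to the AKT-like high subtype",
        },
    )
    return SyntheticCohort(
        expression=expr,
        clinical=clinical,
        mutation=mut,
        cnv=cnv,
        methylation=meth,
        true_labels=labels,
        true_regulators=true_regulators,
        signature=signature,
        config=config,
    )
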