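import numpy as np
import pandas as pd
import pytest

import panemt


@pytest.fixture
def tiny_expr():
    """3-gene x 4-sample matrix with known values."""
    return panemt.ExpressionMatrix(
        pd.DataFrame(
            [[4.0, 3.0, 2.0, 1.0], [1.0, 2.0, 3.0, 4.0], [2.0, 2.0, 2.0, 2.0]],
            index=["g1", "g2", "g3"],
            columns=["s1", "s2", "s3", "s4"],
        )
    )


@pytest.fixture(scope="session")
def planted_cohort():
    """Default synthetic pan-cancer cohort (24 cancer types, 4 planted subtypes)."""
    return panemt.simulate_cohort(panemt.SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def planted_pipeline(planted_cohort):
    """Score + consensus-cluster the planted cohort once for the whole session."""
    cohort = planted_cohort
    scores = panemt.ssgsea_scores(
        cohort.expression,
        panemt.GeneSetCollection({"EMTCG": cohort.signature["EMTCG"]}),
    )
    sig_expr = cohort.expression.subset_genes(cohort.signature["EMTCG"])
    scaled = panemt.scale_genes(sig_expr)
    run = panemt.run_consensus(scaled, range(2, 7), reps=100, item_fraction=0.8, seed=12)
    metrics = panemt.consensus_metrics(run)
    model = panemt.final_clusters(run, 4)
    return {
        "cohort": cohort,
        "scores": scores.data.loc["EMTCG"],
        "scaled": scaled,
        "run": run,
        "metrics": metrics,
        "model": model,
    }


def rand_expression(rng, n_genes=20, n_samples=5):
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"s{i}" for i in range(n_samples)]
    return panemt.ExpressionMatrix(
        pd.DataFrame(
            rng.normal(5, 2, size=(n_genes, n_samples)), index=genes, columns=samples
        )
    )
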