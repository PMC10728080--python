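"""Consensus k-means clustering with CDF / delta-area model-selection metrics.

For each candidate K, samples are repeatedly subsampled without replacement,
k-means (Euclidean) is run on each subsample, and the consensus matrix records
how often each pair of samples co-clusters among the resamples in which both
were drawn.  Final labels come from average-linkage hierarchical clustering of
1 - consensus.  The area under the consensus CDF and its relative increase
across K are the usual diagnostics for picking the number of clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class GeneScaler:
    """Per-gene standardization statistics (mean, sample sd)."""

    means: pd.Series
    sds: pd.Series

    @classmethod
    def fit(cls, expr: ExpressionMatrix) -> "GeneScaler":
        return cls(expr.data.mean(axis=1), expr.data.std(axis=1, ddof=1))

    def transform(self, expr: ExpressionMatrix) -> ExpressionMatrix:
        keep = self.sds.index[self.sds > 0]
        dropped = self.sds.index.difference(keep)
        if len(dropped):
            logger.warning("dropping %d constant genes before scaling", len(dropped))
        genes = [g for g in expr.gene_ids if g in set(keep)]
        sub = expr.data.loc[genes]
        return ExpressionMatrix(sub.sub(self.means[genes], axis=0).div(self.sds[genes], axis=0))


def scale_genes(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Standardize each gene to zero mean and unit sample sd across samples.

    Constant genes (sd = 0) are dropped with a warning.
    """
    return GeneScaler.fit(expr).transform(expr)


@dataclass
class ConsensusRun:
    """Output of the resampled-k-means consensus procedure."""

    sample_ids: list[str]
    k_range: list[int]
    consensus: dict[int, np.ndarray]  # K -> samples x samples, in sample_ids order
    reps: int
    item_fraction: float
    seed: int | None
    scaled: ExpressionMatrix | None = field(default=None, repr=False)


@dataclass
class ClusterModel:
    """Final partition plus centroids on the scaled-expression space."""

    chosen_k: int
    labels: pd.Series  # sample_id -> cluster in 1..K
    centroids: pd.DataFrame  # cluster x gene
    gene_means: pd.Series | None = None
    gene_sds: pd.Series | None = None


def run_consensus(
    expr_scaled: ExpressionMatrix,
    k_range: range | list[int] = range(2, 11),
    reps: int = 100,
    item_fraction: float = 0.8,
    seed: int | None = None,
    n_init: int = 10,
) -> ConsensusRun:
    """Resampled k-means consensus over ``k_range``.

    Each rep draws ceil(item_fraction * n) samples without replacement and
    clusters them with k-means (k-means++ init, ``n_init`` restarts, 300
    iteration cap, tol 1e-6).  consensus(i, j) = co-cluster count / co-sample
    count; pairs never co-sampled get 0 with a warning.  Samples are processed
    in lexicographic id order internally, so the result is reproducible under
    a fixed seed and invariant to input column order.
    """
    k_range = sorted(int(k) for k in k_range)
    if min(k_range) < 2:
        raise ValueError("k_range must start at 2 or above")
    order = np.argsort(np.asarray(expr_scaled.sample_ids, dtype=object))
    ids = [expr_scaled.sample_ids[i] for i in order]
    X = expr_scaled.values[:, order].T  # samples x genes, id-sorted
    n = X.shape[0]
    if n < max(k_range) * 2:
        raise ValueError(f"need at least {max(k_range) * 2} samples for K={max(k_range)}")
    m = int(np.ceil(item_fraction * n))

    rng = np.random.default_rng(seed)
    consensus: dict[int, np.ndarray] = {}
    for k in k_range:
        co_cluster = np.zeros((n, n))
        co_sample = np.zeros((n, n))
        for _ in range(reps):
            sub = np.sort(rng.choice(n, size=m, replace=False))
            km_seed = int(rng.integers(0, 2**31 - 1))
            labels = KMeans(
                n_clusters=k,
                init="k-means++",
                n_init=n_init,
                max_iter=300,
                tol=1e-6,
                random_state=km_seed,
            ).fit_predict(X[sub])
            co_sample[np.ix_(sub, sub)] += 1.0
            same = labels[:, None] == labels[None, :]
            co_cluster[np.ix_(sub, sub)] += same
        never = co_sample == 0
        if never.any():
            logger.warning(
                "K=%d: %d sample pairs never co-sampled; consensus set to 0",
                k,
                int(np.triu(never, 1).sum()),
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            cons = np.where(co_sample > 0, co_cluster / np.maximum(co_sample, 1), 0.0)
        consensus[k] = cons
    return ConsensusRun(
        sample_ids=ids,
        k_range=k_range,
        consensus=consensus,
        reps=reps,
        item_fraction=item_fraction,
        seed=seed,
        scaled=expr_scaled,
    )


def _cdf_area(consensus: np.ndarray) -> float:
    """Area under the empirical CDF of the upper-triangle consensus values."""
    vals = np.sort(consensus[np.triu_indices_from(consensus, k=1)])
    if vals.size == 0:
        return 0.0
    uniq = np.unique(vals)
    cdf = np.searchsorted(vals, uniq, side="right") / vals.size
    # left Riemann over [0, 1] value range, the conventional consensus diagnostic
    area = 0.0
    prev_v = uniq[0]
    prev_c = cdf[0]
    for v, c in zip(uniq[1:], cdf[1:]):
        area += (v - prev_v) * prev_c
        prev_v, prev_c = v, c
    area += (1.0 - prev_v) * prev_c
    return float(area)


def consensus_metrics(run: ConsensusRun) -> pd.DataFrame:
    """Table of (K, area under consensus CDF, relative delta area).

    delta_area(K) is the area itself at the smallest K and the relative
    increase (area(K) - area(K-1)) / area(K-1) afterwards.
    """
    rows = []
    prev_area = None
    for k in run.k_range:
        area = _cdf_area(run.consensus[k])
        if prev_area is None:
            delta = area
        else:
            delta = (area - prev_area) / prev_area if prev_area > 0 else np.nan
        rows.append({"K": k, "area": area, "delta_area": delta})
        prev_area = area
    return pd.DataFrame(rows)


def suggest_k(metrics: pd.DataFrame, min_delta: float = 0.1) -> int:
    """Largest K whose relative delta-area still reaches ``min_delta``.

    Encodes the usual elbow reading of the delta-area curve: beyond the true
    cluster number the area gain collapses.  Purely advisory — the final K is
    the caller's decision.
    """
    eligible = metrics[metrics["delta_area"] >= min_delta]
    if eligible.empty:
        return int(metrics["K"].iloc[0])
    return int(eligible["K"].max())


def final_clusters(run: ConsensusRun, k: int) -> ClusterModel:
    """Cut average-linkage clustering of (1 - consensus) into ``k`` groups.

    Centroids are the mean scaled-expression profiles of each cluster's
    members.  Cluster numbers are assigned in order of first appearance of
    the consensus-tree groups; an empty group raises.
    """
    if k not in run.k_range:
        raise ValueError(f"K={k} was not part of the consensus run {run.k_range}")
    cons = run.consensus[k]
    dist = 1.0 - cons
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    Z = linkage(squareform(dist, checks=False), method="average")
    raw = fcluster(Z, t=k, criterion="maxclust")
    if len(np.unique(raw)) != k:
        raise ValueError(f"consensus tree does not yield {k} non-empty clusters")
    # relabel deterministically by sorted sample id of each cluster's first member
    remap: dict[int, int] = {}
    for lab in raw:
        if lab not in remap:
            remap[lab] = len(remap) + 1
    labels = pd.Series([remap[v] for v in raw], index=run.sample_ids, name="cluster")

    centroids = pd.DataFrame()
    if run.scaled is not None:
        scaled = run.scaled.data[run.sample_ids]  # columns in consensus order
        centroids = pd.DataFrame(
            {c: scaled.loc[:, labels.index[labels == c]].mean(axis=1) for c in sorted(labels.unique())}
        ).T
        centroids.index.name = "cluster"
    return ClusterModel(chosen_k=k, labels=labels, centroids=centroids)
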