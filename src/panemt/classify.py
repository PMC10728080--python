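"""Assign external samples to the four EMT subtypes.

A frozen ReferenceModel carries the signature genes, the four cluster
centroids on the scaled-expression space and the per-gene reference mean/sd.
External samples are standardized with the *reference* statistics (the only
reading under which a single external sample can be classified) and assigned
to the nearest centroid in Euclidean distance; a k-nearest-neighbour vote
against the scaled reference cohort is the alternative used for cross-species
queries.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cluster import ClusterModel, GeneScaler
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

SUBTYPE_NAMES = ("EMTlow", "EMTmid", "EMThigh-NOS", "EMThigh-AKT")


class TieWarning(UserWarning):
    """Emitted when a sample is equidistant from two or more centroids."""


class MissingGeneWarning(UserWarning):
    """Emitted when signature genes are absent from a query cohort."""


@dataclass
class ReferenceModel:
    """Frozen centroids and scaling statistics of the reference cohort."""

    genes: list[str]
    centroids: pd.DataFrame  # subtype x gene, scaled space
    gene_means: pd.Series
    gene_sds: pd.Series
    subtype_names: list[str] = field(default_factory=lambda: list(SUBTYPE_NAMES))
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.centroids.shape[0] != len(self.subtype_names):
            raise ValueError("one centroid per subtype name is required")
        if list(self.centroids.columns) != list(self.genes):
            raise ValueError("centroid genes do not match the model gene list")
        if not (set(self.genes) <= set(self.gene_means.index)
                and set(self.genes) <= set(self.gene_sds.index)):
            raise ValueError("scaling statistics missing for some model genes")
        self.centroids.index = pd.Index(self.subtype_names, name="subtype")

    # -- construction -------------------------------------------------------

    @classmethod
    def from_clustering(
        cls,
        expr: ExpressionMatrix,
        model: ClusterModel,
        signature_genes: list[str],
        emt_scores: pd.Series,
        secondary_scores: pd.Series | None = None,
        provenance: dict | None = None,
    ) -> "ReferenceModel":
        """Freeze a reference model from a clustered reference cohort.

        Subtype names attach to clusters by ranking the mean signature score
        (low -> mid -> two high); when ``secondary_scores`` (e.g. an AKT
        pathway activity) are given, the higher-scoring of the two top
        clusters takes the AKT label, otherwise the tie is broken by cluster
        number.
        """
        genes = [g for g in signature_genes if g in expr.data.index]
        if len(genes) < len(signature_genes):
            warnings.warn(
                f"{len(signature_genes) - len(genes)} signature genes absent from "
                "the reference cohort",
                MissingGeneWarning,
            )
        sub = ExpressionMatrix(expr.data.loc[genes])
        scaler = GeneScaler.fit(sub)
        scaled = scaler.transform(sub).data

        labels = model.labels
        clusters = sorted(labels.unique())
        if len(clusters) != 4:
            raise ValueError("reference model requires exactly 4 clusters")
        mean_score = {c: float(emt_scores[labels.index[labels == c]].mean()) for c in clusters}
        by_score = sorted(clusters, key=lambda c: mean_score[c])
        low, mid, hi_a, hi_b = by_score
        if secondary_scores is not None:
            sec = {c: float(secondary_scores[labels.index[labels == c]].mean()) for c in (hi_a, hi_b)}
            nos, akt = (hi_a, hi_b) if sec[hi_b] >= sec[hi_a] else (hi_b, hi_a)
        else:
            nos, akt = sorted((hi_a, hi_b))
        name_of = {low: "EMTlow", mid: "EMTmid", nos: "EMThigh-NOS", akt: "EMThigh-AKT"}

        centroids = pd.DataFrame(
            {name_of[c]: scaled.loc[:, labels.index[labels == c]].mean(axis=1) for c in clusters}
        ).T.loc[list(SUBTYPE_NAMES), genes]
        return cls(
            genes=genes,
            centroids=centroids,
            gene_means=scaler.means[genes],
            gene_sds=scaler.sds[genes],
            provenance=provenance or {},
        )

    def cluster_to_subtype(self, model: ClusterModel, emt_scores: pd.Series,
                           secondary_scores: pd.Series | None = None) -> dict[int, str]:
        """Map raw cluster numbers to subtype names by the same ranking rule."""
        labels = model.labels
        clusters = sorted(labels.unique())
        mean_score = {c: float(emt_scores[labels.index[labels == c]].mean()) for c in clusters}
        by_score = sorted(clusters, key=lambda c: mean_score[c])
        low, mid, hi_a, hi_b = by_score
        if secondary_scores is not None:
            sec = {c: float(secondary_scores[labels.index[labels == c]].mean()) for c in (hi_a, hi_b)}
            nos, akt = (hi_a, hi_b) if sec[hi_b] >= sec[hi_a] else (hi_b, hi_a)
        else:
            nos, akt = sorted((hi_a, hi_b))
        return {low: "EMTlow", mid: "EMTmid", nos: "EMThigh-NOS", akt: "EMThigh-AKT"}

    # -- serialization ------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.centroids.to_csv(d / "centroids.tsv", sep="\t")
        pd.DataFrame({"mean": self.gene_means, "sd": self.gene_sds}).loc[self.genes].to_csv(
            d / "scaling.tsv", sep="\t", index_label="gene"
        )
        manifest = {
            "genes": self.genes,
            "subtype_names": self.subtype_names,
            "provenance": self.provenance,
        }
        (d / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "ReferenceModel":
        d = Path(directory)
        manifest = json.loads((d / "manifest.json").read_text())
        centroids = pd.read_csv(d / "centroids.tsv", sep="\t", index_col=0)
        scaling = pd.read_csv(d / "scaling.tsv", sep="\t", index_col=0)
        return cls(
            genes=manifest["genes"],
            centroids=centroids[manifest["genes"]],
            gene_means=scaling["mean"],
            gene_sds=scaling["sd"],
            subtype_names=manifest["subtype_names"],
            provenance=manifest.get("provenance", {}),
        )


def reference_scale(
    expr: ExpressionMatrix,
    model: ReferenceModel,
    min_gene_coverage: float = 0.8,
) -> pd.DataFrame:
    """Standardize a query cohort on the model's signature genes.

    Each gene is transformed with the *reference* per-gene mean and sd.
    Genes absent from the query are dropped (warned); coverage below
    ``min_gene_coverage`` raises, listing the missing genes.
    """
    present = [g for g in model.genes if g in expr.data.index]
    missing = [g for g in model.genes if g not in expr.data.index]
    coverage = len(present) / len(model.genes)
    if coverage < min_gene_coverage:
        raise ValueError(
            f"only {len(present)}/{len(model.genes)} signature genes present "
            f"({coverage:.0%} < {min_gene_coverage:.0%}); missing: {missing}"
        )
    if missing:
        warnings.warn(
            f"{len(missing)} signature genes absent from query cohort: {missing}",
            MissingGeneWarning,
        )
    sub = expr.data.loc[present]
    return sub.sub(model.gene_means[present], axis=0).div(model.gene_sds[present], axis=0)


def assign_by_centroid(
    scaled: pd.DataFrame,
    model: ReferenceModel,
    rescale_missing: bool = True,
) -> pd.DataFrame:
    """Nearest-centroid assignment of scaled query samples.

    Distance to each centroid is the Euclidean distance over the genes the
    query provides; with ``rescale_missing`` it is multiplied by
    sqrt(n_model_genes / n_used) so samples with different coverage remain
    comparable.  Ties go to the earlier subtype in the fixed order with a
    warning.  Returns one row per sample: distances, assigned subtype,
    margin (second-best minus best distance) and genes used.
    """
    genes = [g for g in model.genes if g in scaled.index]
    if not genes:
        raise ValueError("no model gene present in the scaled query matrix")
    C = model.centroids[genes].to_numpy()  # 4 x g
    Q = scaled.loc[genes].to_numpy().T  # samples x g
    if np.isnan(Q).all(axis=1).any():
        raise ValueError("some samples have no usable gene values")

    n_total = len(model.genes)
    rows = []
    for i, sid in enumerate(scaled.columns):
        q = Q[i]
        used = np.isfinite(q)
        n_used = int(used.sum())
        if n_used == 0:
            raise ValueError(f"sample {sid!r}: all distances undefined (no finite values)")
        d = np.sqrt(((q[used] - C[:, used]) ** 2).sum(axis=1))
        if rescale_missing and n_used < n_total:
            d = d * np.sqrt(n_total / n_used)
        best = int(np.argmin(d))
        ties = np.flatnonzero(d == d[best])
        if len(ties) > 1:
            warnings.warn(
                f"sample {sid!r} equidistant from subtypes "
                f"{[model.subtype_names[t] for t in ties]}; keeping the first",
                TieWarning,
            )
        d_sorted = np.sort(d)
        rows.append(
            {
                "sample_id": sid,
                **{f"d_{name}": d[j] for j, name in enumerate(model.subtype_names)},
                "subtype": model.subtype_names[best],
                "margin": float(d_sorted[1] - d_sorted[0]),
                "n_genes_used": n_used,
            }
        )
    return pd.DataFrame(rows)


def assign_by_knn(
    scaled_query: pd.DataFrame,
    reference_scaled: pd.DataFrame,
    reference_labels: pd.Series,
    k: int = 5,
) -> pd.DataFrame:
    """Majority vote among the k Euclidean-nearest reference samples.

    A tied vote goes to the tied label with the smaller mean distance.
    Both matrices are gene-by-sample on a common scaled space.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > reference_scaled.shape[1]:
        raise ValueError(f"k={k} exceeds the {reference_scaled.shape[1]} reference samples")
    genes = reference_scaled.index.intersection(scaled_query.index)
    if genes.empty:
        raise ValueError("query and reference share no genes")
    R = reference_scaled.loc[genes].to_numpy().T  # n_ref x g
    Q = scaled_query.loc[genes].to_numpy().T
    ref_labels = reference_labels.reindex(reference_scaled.columns).to_numpy()

    rows = []
    for i, sid in enumerate(scaled_query.columns):
        dist = np.sqrt(((R - Q[i]) ** 2).sum(axis=1))
        nearest = np.argsort(dist, kind="stable")[:k]
        votes = pd.Series(ref_labels[nearest])
        counts = votes.value_counts()
        top = counts[counts == counts.iloc[0]].index
        if len(top) > 1:
            mean_d = {
                lab: dist[nearest][votes.to_numpy() == lab].mean() for lab in top
            }
            label = min(mean_d, key=mean_d.get)
        else:
            label = top[0]
        rows.append(
            {
                "sample_id": sid,
                "subtype": label,
                "mean_neighbor_distance": float(dist[nearest].mean()),
                "vote_fraction": float(counts.iloc[0] / k),
            }
        )
    return pd.DataFrame(rows)
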