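"""Core-signature derivation.

A positive gene set (e.g. the epithelial-to-mesenchymal transition GO term)
is pruned of genes that also appear in negatively-oriented sets, then filtered
twice — by protein-interaction degree and by co-expression score, keeping the
top fraction of each ranking — and the two filtered lists are intersected to
give the core signature.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_KEEP_FRACTION = 2.0 / 3.0


@dataclass
class NetworkEdges:
    """Undirected interaction edges with a combined confidence score in [0, 1].

    Self-loops are dropped; each unordered pair is stored once (the maximum
    score wins if a pair appears twice).
    """

    edges: list[tuple[str, str, float]]

    def __post_init__(self) -> None:
        seen: dict[tuple[str, str], float] = {}
        for a, b, s in self.edges:
            if a == b:
                continue
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"combined score {s} outside [0, 1] for edge ({a}, {b})")
            key = (a, b) if a < b else (b, a)
            seen[key] = max(seen.get(key, 0.0), s)
        self.edges = [(a, b, s) for (a, b), s in seen.items()]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "NetworkEdges":
        df = pd.read_csv(path, sep="\t")
        cols = list(df.columns[:3])
        return cls([(str(a), str(b), float(s)) for a, b, s in df[cols].itertuples(index=False)])

    def degrees(self, genes: Sequence[str], min_score: float = 0.0) -> dict[str, int]:
        """Node degree on the subgraph induced by ``genes``."""
        gene_set = set(genes)
        deg = {g: 0 for g in genes}
        for a, b, s in self.edges:
            if s < min_score:
                continue
            if a in gene_set and b in gene_set:
                deg[a] += 1
                deg[b] += 1
        return deg


@dataclass
class CoexpressionTable:
    """Per-gene non-negative co-expression scores."""

    scores: dict[str, float]

    def __post_init__(self) -> None:
        bad = {g: s for g, s in self.scores.items() if s < 0}
        if bad:
            raise ValueError(f"negative co-expression scores: {bad}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CoexpressionTable":
        df = pd.read_csv(path, sep="\t")
        return cls({str(g): float(s) for g, s in df.iloc[:, :2].itertuples(index=False)})


@dataclass
class SignatureReport:
    """Per-stage provenance of a derived core signature."""

    positive_only: list[str]
    ppi_filtered: list[str]
    coexp_filtered: list[str]
    core: list[str]
    keep_fraction_ppi: float
    keep_fraction_coexp: float
    log: list[str] = field(default_factory=list)

    def stage_counts(self) -> dict[str, int]:
        return {
            "positive_only": len(self.positive_only),
            "ppi_filtered": len(self.ppi_filtered),
            "coexp_filtered": len(self.coexp_filtered),
            "core": len(self.core),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.positive_only:
            rows.append(
                {
                    "gene": g,
                    "in_ppi_filtered": g in self.ppi_filtered,
                    "in_coexp_filtered": g in self.coexp_filtered,
                    "in_core": g in self.core,
                }
            )
        return pd.DataFrame(rows)


def derive_positive_set(
    positive: Iterable[str], negatives: Sequence[Iterable[str]]
) -> list[str]:
    """Genes of ``positive`` not present in any negative set, order preserved."""
    exclude = set()
    for neg in negatives:
        exclude.update(neg)
    out = [g for g in positive if g not in exclude]
    if not out:
        logger.warning("positive set is empty after subtracting negative sets")
    return out


def _keep_count(n: int, fraction: float) -> int:
    if not 0 < fraction <= 1:
        raise ValueError(f"keep_fraction must be in (0, 1], got {fraction}")
    return math.ceil(fraction * n)


def filter_by_degree(
    network: NetworkEdges,
    genes: Sequence[str],
    keep_fraction: float = DEFAULT_KEEP_FRACTION,
    denominator: str = "nonzero",
    min_score: float = 0.0,
) -> list[str]:
    """Keep the top ``keep_fraction`` of ``genes`` ranked by induced-subgraph degree.

    ``denominator`` chooses the count base for the fraction: ``nonzero``
    (genes with degree > 0, the default) or ``all``.  Ties at the cutoff are
    broken lexicographically; result is in descending-degree order.
    """
    deg = network.degrees(genes, min_score=min_score)
    connected = [g for g in genes if deg[g] > 0]
    if not connected:
        logger.warning("no gene of the input list has any network edge")
        return []
    n = len(connected) if denominator == "nonzero" else len(genes)
    k = min(_keep_count(n, keep_fraction), len(connected))
    ranked = sorted(connected, key=lambda g: (-deg[g], g))
    return ranked[:k]


def filter_by_coexpression(
    scores: CoexpressionTable,
    genes: Sequence[str],
    keep_fraction: float = DEFAULT_KEEP_FRACTION,
    denominator: str = "nonzero",
) -> list[str]:
    """Keep the top ``keep_fraction`` of ``genes`` ranked by co-expression score.

    Genes absent from the score table score 0 (logged) and, under the default
    ``nonzero`` denominator, do not count toward the fraction base.
    """
    missing = [g for g in genes if g not in scores.scores]
    if missing:
        logger.info("%d genes absent from co-expression table, scored 0", len(missing))
    present = [g for g in genes if g in scores.scores]
    if not present:
        logger.warning("no gene of the input list has a co-expression score")
        return []
    n = len(present) if denominator == "nonzero" else len(genes)
    k = min(_keep_count(n, keep_fraction), len(present))
    ranked = sorted(present, key=lambda g: (-scores.scores[g], g))
    return ranked[:k]


def build_signature(
    positive: Iterable[str],
    negatives: Sequence[Iterable[str]],
    network: NetworkEdges,
    coexp: CoexpressionTable,
    keep_fraction_ppi: float = DEFAULT_KEEP_FRACTION,
    keep_fraction_coexp: float = DEFAULT_KEEP_FRACTION,
    denominator: str = "nonzero",
    min_score: float = 0.0,
) -> SignatureReport:
    """Compose set subtraction, degree filter and co-expression filter.

    The core signature is the intersection of the two filtered lists (in
    positive-set order).  An empty core raises, advising larger fractions.
    """
    positive_only = derive_positive_set(positive, negatives)
    ppi = filter_by_degree(
        network, positive_only, keep_fraction_ppi, denominator=denominator, min_score=min_score
    )
    coe = filter_by_coexpression(coexp, positive_only, keep_fraction_coexp, denominator=denominator)
    core = [g for g in positive_only if g in set(ppi) and g in set(coe)]
    if not core:
        raise ValueError(
            "signature core is empty: the degree- and co-expression-filtered lists "
            "are disjoint; consider larger keep fractions"
        )
    report = SignatureReport(
        positive_only=positive_only,
        ppi_filtered=ppi,
        coexp_filtered=coe,
        core=core,
        keep_fraction_ppi=keep_fraction_ppi,
        keep_fraction_coexp=keep_fraction_coexp,
        log=[
            f"positive_only: {len(positive_only)}",
            f"ppi_filtered: {len(ppi)} (fraction {keep_fraction_ppi:.4f}, {denominator})",
            f"coexp_filtered: {len(coe)} (fraction {keep_fraction_coexp:.4f}, {denominator})",
            f"core: {len(core)}",
        ],
    )
    return report
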