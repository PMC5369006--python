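"""Core domain containers shared across the inference pipeline.

The central objects are species-scoped reference interactomes, BLAST-style
homology tables linking target-species proteins to reference proteins, and
the scored interolog network produced from them.  All containers are plain
dataclasses; graphs are materialised as :mod:`networkx` objects only where
topology is actually computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Iterator, List, Optional, Tuple

__all__ = [
    "AnnotatedProteinSet",
    "ReferenceInteraction",
    "ReferenceInteractome",
    "HomologyHit",
    "HomologyTable",
    "Y2HRecord",
    "GoldNetwork",
    "PredictionParameters",
    "Support",
    "PredictedEdge",
    "PredictedNetwork",
    "CoverageReport",
    "FisherResult",
    "unordered",
]


def unordered(a: str, b: str) -> Tuple[str, str]:
    """Canonical (sorted) orientation of an undirected protein pair."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class AnnotatedProteinSet:
    """A set of protein accessions for one species under one annotation tag.

    Parameters
    ----------
    species_taxid:
        NCBI taxon identifier of the species the accessions belong to.
    accessions:
        Unique, non-empty set of accession strings.  Accession namespaces
        are treated as opaque; species are distinguished only by taxid.
    annotation:
        Free-text tag describing how the set was assembled
        (default ``"autophagy"``).
    """

    species_taxid: int
    accessions: FrozenSet[str]
    annotation: str = "autophagy"

    def __post_init__(self) -> None:
        if not self.accessions:
            raise ValueError("protein set must be non-empty")
        object.__setattr__(self, "accessions", frozenset(self.accessions))

    def __len__(self) -> int:
        return len(self.accessions)

    def __contains__(self, accession: str) -> bool:
        return accession in self.accessions


@dataclass(frozen=True)
class ReferenceInteraction:
    """One typed, undirected interaction between two reference proteins."""

    a: str
    b: str
    species_taxid: int
    interaction_type: str = "physical"
    provenance: str = ""

    def __post_init__(self) -> None:
        pa, pb = unordered(self.a, self.b)
        object.__setattr__(self, "a", pa)
        object.__setattr__(self, "b", pb)

    @property
    def pair(self) -> Tuple[str, str]:
        return (self.a, self.b)

    @property
    def is_self(self) -> bool:
        return self.a == self.b


@dataclass
class ReferenceInteractome:
    """A species-scoped annotated protein set plus its interactions."""

    protein_set: AnnotatedProteinSet
    interactions: List[ReferenceInteraction]

    def __post_init__(self) -> None:
        for ia in self.interactions:
            if ia.species_taxid != self.species_taxid:
                raise ValueError(
                    f"interaction taxid {ia.species_taxid} does not match "
                    f"interactome taxid {self.species_taxid}"
                )
            if ia.a not in self.protein_set or ia.b not in self.protein_set:
                raise ValueError(
                    f"interaction {ia.pair} has an endpoint outside the "
                    "protein universe"
                )

    @property
    def species_taxid(self) -> int:
        return self.protein_set.species_taxid

    @property
    def edge_pairs(self) -> List[Tuple[str, str]]:
        return [ia.pair for ia in self.interactions]

    def __len__(self) -> int:
        return len(self.interactions)


@dataclass(frozen=True)
class HomologyHit:
    """One query (target species) → subject (reference species) BLAST hit."""

    query: str
    subject: str
    evalue: float
    subject_taxid: int

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative E-value: {self.evalue!r}")


class HomologyTable:
    """Collapsed query→subject homology hits with per-subject indexing.

    Duplicate ``(query, subject)`` pairs are collapsed to the minimum
    E-value on construction.  The table answers the two questions the
    interolog transfer needs: which target proteins are homologous to a
    given reference protein (and how strongly), and how many homologs a
    reference protein has in total.
    """

    def __init__(self, hits: Iterable[HomologyHit]):
        best: Dict[Tuple[str, str], HomologyHit] = {}
        for hit in hits:
            key = (hit.query, hit.subject)
            prev = best.get(key)
            if prev is None or hit.evalue < prev.evalue:
                best[key] = hit
        self._hits: List[HomologyHit] = sorted(
            best.values(), key=lambda h: (h.subject, h.query, h.evalue)
        )
        self._by_subject: Dict[str, Dict[str, float]] = {}
        self._subject_taxid: Dict[str, int] = {}
        for hit in self._hits:
            self._by_subject.setdefault(hit.subject, {})[hit.query] = hit.evalue
            self._subject_taxid[hit.subject] = hit.subject_taxid

    def __len__(self) -> int:
        return len(self._hits)

    def __iter__(self) -> Iterator[HomologyHit]:
        return iter(self._hits)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HomologyTable):
            return NotImplemented
        return self._hits == other._hits

    @property
    def hits(self) -> List[HomologyHit]:
        return list(self._hits)

    @property
    def queries(self) -> FrozenSet[str]:
        return frozenset(h.query for h in self._hits)

    def homologs_of(self, subject: str) -> Dict[str, float]:
        """Target-species homologs of a reference protein → E-value map."""
        return dict(self._by_subject.get(subject, {}))

    def n_homologs(self, subject: str) -> int:
        """Number of distinct target-species homologs of ``subject``."""
        return len(self._by_subject.get(subject, {}))

    def evalue(self, query: str, subject: str) -> Optional[float]:
        return self._by_subject.get(subject, {}).get(query)

    def filter(self, e_cutoff: float) -> "HomologyTable":
        """Retain hits with E-value at or below ``e_cutoff``."""
        return HomologyTable(h for h in self._hits if h.evalue <= e_cutoff)

    @classmethod
    def merge(cls, *tables: "HomologyTable") -> "HomologyTable":
        hits: List[HomologyHit] = []
        for t in tables:
            hits.extend(t._hits)
        return cls(hits)


@dataclass(frozen=True)
class Y2HRecord:
    """Aggregated yeast-two-hybrid evidence for one prey protein."""

    prey_accession: str
    clone_count: int = 1
    in_frame: bool = True
    excluded_reason: Optional[str] = None

    def __post_init__(self) -> None:
        if self.clone_count < 1:
            raise ValueError("clone_count must be >= 1")

    @property
    def retained(self) -> bool:
        return self.in_frame and not self.excluded_reason


@dataclass(frozen=True)
class GoldNetwork:
    """Small curated reference network used for parameter fitting."""

    proteins: FrozenSet[str]
    interactions: FrozenSet[Tuple[str, str]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "proteins", frozenset(self.proteins))
        object.__setattr__(
            self,
            "interactions",
            frozenset(unordered(a, b) for a, b in self.interactions),
        )
        for a, b in self.interactions:
            if a not in self.proteins or b not in self.proteins:
                raise ValueError(f"gold pair ({a}, {b}) has an endpoint "
                                 "outside the gold protein set")

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    @property
    def n_interactions(self) -> int:
        return len(self.interactions)


@dataclass(frozen=True)
class PredictionParameters:
    """Homology range and score-combination settings for interolog transfer.

    The homology range ``[h_l, h_u]`` maps BLAST E-values to a [0, 1]
    similarity score: E-values at or below ``h_l`` score 1, at or above
    ``h_u`` score 0, with log10-linear interpolation in between.  A
    reference protein with exactly one homolog whose E-value is at most
    ``single_homolog_evalue`` scores 1 regardless of the range.

    ``support_rule`` combines the two endpoint scores of one supporting
    reference interaction (``mean``, ``min`` or ``max``); ``edge_rule``
    combines scores across multiple supports of the same predicted edge
    (``max`` or ``mean``).
    """

    h_u: float = 1e-20
    h_l: float = 1e-200
    single_homolog_evalue: float = 1e-5
    support_rule: str = "mean"
    edge_rule: str = "max"

    def __post_init__(self) -> None:
        if not (0 <= self.h_l < self.h_u):
            raise ValueError(f"need 0 <= h_l < h_u, got h_l={self.h_l}, "
                             f"h_u={self.h_u}")
        if self.support_rule not in ("mean", "min", "max"):
            raise ValueError(f"unknown support_rule {self.support_rule!r}")
        if self.edge_rule not in ("max", "mean"):
            raise ValueError(f"unknown edge_rule {self.edge_rule!r}")

    @property
    def log_span(self) -> float:
        """Width of the homology range in log10 units."""
        lo = self.h_l if self.h_l > 0 else 1e-300
        return math.log10(self.h_u) - math.log10(lo)


@dataclass(frozen=True)
class Support:
    """Provenance of one predicted edge: the reference interaction that was
    transferred and the homology scores of the two endpoint matchings."""

    species_taxid: int
    ref_pair: Tuple[str, str]
    score_a: float  # homology score of target endpoint matched to ref_pair[0]
    score_b: float  # homology score of target endpoint matched to ref_pair[1]

    def score(self, rule: str = "mean") -> float:
        if rule == "mean":
            return 0.5 * (self.score_a + self.score_b)
        if rule == "min":
            return min(self.score_a, self.score_b)
        if rule == "max":
            return max(self.score_a, self.score_b)
        raise ValueError(f"unknown support rule {rule!r}")


@dataclass
class PredictedEdge:
    """A scored target-species edge with its full reference provenance."""

    pair: Tuple[str, str]
    score: float
    supports: List[Support] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pair = unordered(*self.pair)
        if not self.supports:
            raise ValueError("predicted edge must carry at least one support")
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"edge score {self.score} outside [0, 1]")

    @property
    def species(self) -> FrozenSet[int]:
        """Reference species taxids that contributed evidence."""
        return frozenset(s.species_taxid for s in self.supports)


@dataclass
class PredictedNetwork:
    """Simple undirected target-species network of scored interolog edges."""

    edges: Dict[Tuple[str, str], PredictedEdge]
    parameters: PredictionParameters

    @property
    def proteins(self) -> FrozenSet[str]:
        nodes = set()
        for a, b in self.edges:
            nodes.add(a)
            nodes.add(b)
        return frozenset(nodes)

    @property
    def pairs(self) -> FrozenSet[Tuple[str, str]]:
        return frozenset(self.edges)

    def __len__(self) -> int:
        return len(self.edges)

    def __contains__(self, pair: Tuple[str, str]) -> bool:
        return unordered(*pair) in self.edges

    def to_graph(self):
        """Materialise as a :class:`networkx.Graph` with score attributes."""
        import networkx as nx

        g = nx.Graph()
        for (a, b), edge in self.edges.items():
            g.add_edge(a, b, score=edge.score,
                       species=sorted(edge.species),
                       n_supports=len(edge.supports))
        return g


@dataclass(frozen=True)
class CoverageReport:
    """How much of a gold network one parameterisation recovered."""

    params: PredictionParameters
    proteins_covered: int
    proteins_total: int
    interactions_covered: int
    interactions_total: int
    predicted_proteins: int
    predicted_interactions: int

    def __post_init__(self) -> None:
        if self.proteins_covered > self.proteins_total:
            raise ValueError("covered proteins exceed total")
        if self.interactions_covered > self.interactions_total:
            raise ValueError("covered interactions exceed total")

    @property
    def protein_fraction(self) -> float:
        return self.proteins_covered / self.proteins_total

    @property
    def interaction_fraction(self) -> float:
        return self.interactions_covered / self.interactions_total


@dataclass(frozen=True)
class FisherResult:
    """2x2 contingency table with one-sided Fisher's exact test output.

    ``table`` is ((a, b), (c, d)) where the first row is the group of
    interest (e.g. pathway pairs) and the first column the property of
    interest (e.g. co-expressed).  ``expected`` is the expectation of cell
    (1,1) under the hypergeometric null, row1_total * col1_total / total.
    """

    table: Tuple[Tuple[int, int], Tuple[int, int]]
    odds_ratio: float
    p_value: float
    expected: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        (a, b), (c, d) = self.table
        if min(a, b, c, d) < 0:
            raise ValueError("contingency cells must be non-negative")
        if not self.degenerate and not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")

    @property
    def universe(self) -> int:
        (a, b), (c, d) = self.table
        return a + b + c + d
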