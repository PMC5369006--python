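"""Synthetic study-condition generator for the whole pipeline.

Every input the inference pipeline consumes can be generated here with
*planted* structure whose recovery is verifiable downstream: two reference
interactomes with autophagy-tagged protein sets, a homology table with
planted conserved interologs and out-of-range decoy hits, a small gold
subnetwork drawn from the planted truth, a yeast-two-hybrid-like prey
table, and an age-resolved expression matrix with planted trends and
co-expression clusters.

Default scales mirror the study conditions the generator emulates:
259/108 reference proteins with 487/313 interactions, seven age points,
~10,000 expression profiles with roughly three times more decreasing
than increasing trends, and a 15-protein / 12-interaction gold network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .types import (
    AnnotatedProteinSet,
    GoldNetwork,
    HomologyHit,
    HomologyTable,
    ReferenceInteraction,
    ReferenceInteractome,
    unordered,
)

__all__ = [
    "SynthConfig",
    "InterologTruth",
    "gen_reference_interactomes",
    "gen_homology_table",
    "gen_gold_network",
    "gen_expression_matrix",
    "gen_y2h_table",
]

#: interaction-type labels with their default sampling proportions
#: (physical 61%, direct 27%, association 2%, colocalization 2%,
#: covalent 1%; normalised before sampling)
DEFAULT_TYPE_PROBS: Dict[str, float] = {
    "physical": 0.61,
    "direct": 0.27,
    "association": 0.02,
    "colocalization": 0.02,
    "covalent": 0.01,
}


@dataclass
class SynthConfig:
    """All knobs of the synthetic study, in one place.

    The defaults define the emulated study conditions; tests vary them
    only where an operation's contract explicitly depends on a parameter.
    """

    seed: int = 0
    # reference interactomes
    n_proteins_ref_a: int = 259
    n_proteins_ref_b: int = 108
    n_autophagy_a: int = 259
    n_autophagy_b: int = 108
    n_interactions_a: int = 487
    n_interactions_b: int = 313
    taxid_a: int = 9606
    taxid_b: int = 559292
    interaction_type_probs: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_PROBS))
    preferential_attachment: bool = False
    # homology table
    n_target_proteins: int = 150
    n_conserved_interologs: int = 60
    homology_evalue_range: Tuple[float, float] = (1e-180, 1e-30)
    decoy_fraction: float = 0.3
    decoy_evalue_range: Tuple[float, float] = (2e-5, 1e-4)
    # expression matrix
    n_age_points: int = 7
    n_genes: int = 10059
    frac_up: float = 418 / 10059
    frac_down: float = 1202 / 10059
    coexpr_cluster_sizes: List[int] = field(
        default_factory=lambda: [12, 8, 5])
    noise_sd: float = 0.2

    def __post_init__(self) -> None:
        if self.n_autophagy_a > self.n_proteins_ref_a:
            raise ValueError("n_autophagy_a exceeds n_proteins_ref_a")
        if self.n_autophagy_b > self.n_proteins_ref_b:
            raise ValueError("n_autophagy_b exceeds n_proteins_ref_b")
        if self.n_conserved_interologs > min(self.n_interactions_a,
                                             self.n_interactions_b):
            raise ValueError("n_conserved_interologs exceeds the smaller "
                             "reference interaction count")
        if not (0.0 <= self.decoy_fraction < 1.0):
            raise ValueError("decoy_fraction must be in [0, 1)")
        if self.frac_up + self.frac_down > 1.0:
            raise ValueError("frac_up + frac_down must be <= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        lo, hi = self.homology_evalue_range
        if not (0 < lo <= hi):
            raise ValueError("homology_evalue_range must be positive and "
                             "ordered (low, high)")


def _rng(config_seed: int, stream: int) -> np.random.Generator:
    """Independent, reproducible substream per generator."""
    return np.random.default_rng([stream, config_seed])


def _loguniform(rng: np.random.Generator, lo: float, hi: float,
                size=None) -> np.ndarray:
    """Sample log10-uniformly from [lo, hi] (E-values span magnitudes)."""
    return 10.0 ** rng.uniform(math.log10(lo), math.log10(hi), size=size)


def _sample_simple_edges(rng: np.random.Generator, nodes: Sequence[str],
                         m: int) -> List[Tuple[str, str]]:
    """Uniform simple graph with exactly m edges over the given nodes."""
    k = len(nodes)
    max_edges = k * (k - 1) // 2
    if m > max_edges:
        raise ValueError(
            f"requested {m} interactions but a simple graph over "
            f"{k} proteins holds at most {max_edges}")
    iu, ju = np.triu_indices(k, k=1)
    chosen = rng.choice(max_edges, size=m, replace=False)
    return [(nodes[iu[c]], nodes[ju[c]]) for c in chosen]


def _sample_pa_edges(rng: np.random.Generator, nodes: Sequence[str],
                     m: int) -> List[Tuple[str, str]]:
    """Preferential-attachment edge sampling (degree-heterogeneous option)."""
    k = len(nodes)
    if m > k * (k - 1) // 2:
        raise ValueError("requested interaction count exceeds the "
                         "simple-graph maximum")
    degree = np.ones(k)
    edges: Set[Tuple[int, int]] = set()
    while len(edges) < m:
        probs = degree / degree.sum()
        i = int(rng.choice(k, p=probs))
        j = int(rng.choice(k, p=probs))
        if i == j:
            continue
        e = (i, j) if i < j else (j, i)
        if e in edges:
            continue
        edges.add(e)
        degree[i] += 1
        degree[j] += 1
    return [(nodes[i], nodes[j]) for i, j in sorted(edges)]


def gen_reference_interactomes(
    config: SynthConfig,
) -> Tuple[ReferenceInteractome, ReferenceInteractome]:
    """Generate the two reference interactomes.

    Each species gets exactly the configured number of proteins, of which
    the first ``n_autophagy_*`` form the annotated (autophagy-tagged)
    subset; interactions are sampled as a uniform simple graph over that
    subset (or with preferential attachment when configured) and typed by
    the configured label proportions.
    """
    rng = _rng(config.seed, 1)
    out = []
    specs = [
        ("HSA", config.taxid_a, config.n_proteins_ref_a,
         config.n_autophagy_a, config.n_interactions_a),
        ("SCE", config.taxid_b, config.n_proteins_ref_b,
         config.n_autophagy_b, config.n_interactions_b),
    ]
    labels = list(config.interaction_type_probs)
    probs = np.array([config.interaction_type_probs[t] for t in labels])
    probs = probs / probs.sum()
    for prefix, taxid, n_prot, n_auto, n_int in specs:
        accessions = [f"{prefix}{i:04d}" for i in range(n_prot)]
        autophagy = accessions[:n_auto]
        sampler = (_sample_pa_edges if config.preferential_attachment
                   else _sample_simple_edges)
        pairs = sampler(rng, autophagy, n_int)
        types = rng.choice(labels, size=n_int, p=probs)
        interactions = [
            ReferenceInteraction(a, b, taxid, interaction_type=str(t),
                                 provenance="synthetic")
            for (a, b), t in zip(pairs, types)
        ]
        pset = AnnotatedProteinSet(species_taxid=taxid,
                                   accessions=frozenset(accessions))
        out.append(ReferenceInteractome(protein_set=pset,
                                        interactions=interactions))
    return out[0], out[1]


def _connected_edge_sample(
    graph: nx.Graph, k: int, rng: np.random.Generator
) -> List[Tuple[str, str]]:
    """k edges forming a connected subgraph, grown breadth-first from a
    random start inside the largest component."""
    if graph.number_of_edges() < k:
        raise ValueError("graph has fewer edges than requested")
    comp = max(nx.connected_components(graph), key=len)
    sub = graph.subgraph(comp)
    if sub.number_of_edges() < k:
        raise ValueError(
            f"largest component holds {sub.number_of_edges()} edges, "
            f"{k} requested")
    start = sorted(comp)[int(rng.integers(len(comp)))]
    visited = {start}
    queue = [start]
    collected: List[Tuple[str, str]] = []
    seen: Set[Tuple[str, str]] = set()
    while queue and len(collected) < k:
        u = queue.pop(0)
        neighbours = sorted(sub.neighbors(u))
        rng.shuffle(neighbours)
        for v in neighbours:
            e = unordered(u, v)
            if e not in seen:
                seen.add(e)
                collected.append(e)
                if v not in visited:
                    visited.add(v)
                    queue.append(v)
                if len(collected) == k:
                    break
    return collected


@dataclass
class InterologTruth:
    """Ground truth planted into a synthetic homology table.

    ``core_pairs`` are the target pairs derived from the sampled
    ("designated") conserved reference edges.  ``planted_pairs`` is the
    full induced truth: every reference interaction whose two endpoints
    both received a target ortholog, projected onto target pairs — this
    is exactly the edge set a perfect prediction recovers.
    """

    core_pairs: FrozenSet[Tuple[str, str]]
    planted_pairs: FrozenSet[Tuple[str, str]]
    ortholog_map_a: Dict[str, str]  # reference accession -> target accession
    ortholog_map_b: Dict[str, str]
    decoy_queries: FrozenSet[str]
    evalue_range: Tuple[float, float]

    @property
    def planted_proteins(self) -> FrozenSet[str]:
        return frozenset(p for pair in self.planted_pairs for p in pair)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"target_a": a, "target_b": b,
                 "core": (a, b) in self.core_pairs}
                for a, b in sorted(self.planted_pairs)]
        return pd.DataFrame(rows, columns=["target_a", "target_b", "core"])


def gen_homology_table(
    ref_a: ReferenceInteractome,
    ref_b: ReferenceInteractome,
    config: SynthConfig,
) -> Tuple[HomologyTable, InterologTruth]:
    """Generate homology hits with planted conserved interologs and decoys.

    ``n_conserved_interologs`` reference edges (split between the two
    species, sampled as connected subgraphs so that a gold network can be
    carved out downstream) have both endpoints mapped to fresh
    target-species proteins with E-values drawn log-uniformly inside
    ``homology_evalue_range``.  Decoy hits attach previously unused
    target proteins to random reference proteins with E-values inside
    ``decoy_evalue_range`` — outside the planted range, so a prediction
    run whose homology range contains the planted E-values recovers
    every planted pair and no decoy pair.
    """
    if not ref_a.interactions or not ref_b.interactions:
        raise ValueError("reference interactomes must be non-empty")
    rng = _rng(config.seed, 2)
    n_c = config.n_conserved_interologs
    n_from_a = (n_c + 1) // 2
    n_from_b = n_c - n_from_a

    pool = [f"PA{i:04d}" for i in range(config.n_target_proteins)]
    rng.shuffle(pool)
    pool_iter = iter(pool)

    hits: List[HomologyHit] = []
    core: Set[Tuple[str, str]] = set()
    maps: Dict[int, Dict[str, str]] = {}

    for ref, n_edges in ((ref_a, n_from_a), (ref_b, n_from_b)):
        ortho: Dict[str, str] = {}
        if n_edges > 0:
            g = nx.Graph(ref.edge_pairs)
            sampled = _connected_edge_sample(g, n_edges, rng)
            for p, q in sampled:
                for prot in (p, q):
                    if prot not in ortho:
                        try:
                            ortho[prot] = next(pool_iter)
                        except StopIteration:
                            raise ValueError(
                                "n_target_proteins too small for the "
                                "requested planted structure") from None
                core.add(unordered(ortho[p], ortho[q]))
        maps[ref.species_taxid] = ortho
        for prot, target in ortho.items():
            ev = float(_loguniform(rng, *config.homology_evalue_range))
            hits.append(HomologyHit(query=target, subject=prot,
                                    evalue=ev,
                                    subject_taxid=ref.species_taxid))

    # induced truth: any reference edge whose endpoints are both mapped
    planted: Set[Tuple[str, str]] = set()
    for ref in (ref_a, ref_b):
        ortho = maps[ref.species_taxid]
        for p, q in ref.edge_pairs:
            if p in ortho and q in ortho and ortho[p] != ortho[q]:
                planted.add(unordered(ortho[p], ortho[q]))

    n_planted_hits = len(hits)
    decoy_queries: Set[str] = set()
    if config.decoy_fraction > 0:
        n_decoys = round(config.decoy_fraction * n_planted_hits
                         / (1.0 - config.decoy_fraction))
        subjects = (sorted(ref_a.protein_set.accessions),
                    sorted(ref_b.protein_set.accessions))
        taxids = (ref_a.species_taxid, ref_b.species_taxid)
        for _ in range(n_decoys):
            try:
                query = next(pool_iter)
            except StopIteration:
                raise ValueError("n_target_proteins too small to host the "
                                 "requested decoy hits") from None
            side = int(rng.integers(2))
            subject = subjects[side][int(rng.integers(len(subjects[side])))]
            ev = float(_loguniform(rng, *config.decoy_evalue_range))
            hits.append(HomologyHit(query=query, subject=subject,
                                    evalue=ev, subject_taxid=taxids[side]))
            decoy_queries.add(query)

    truth = InterologTruth(
        core_pairs=frozenset(core),
        planted_pairs=frozenset(planted),
        ortholog_map_a=maps[ref_a.species_taxid],
        ortholog_map_b=maps[ref_b.species_taxid],
        decoy_queries=frozenset(decoy_queries),
        evalue_range=config.homology_evalue_range,
    )
    return HomologyTable(hits), truth


def gen_gold_network(
    truth: InterologTruth,
    size_proteins: int = 15,
    size_interactions: int = 12,
    seed: int = 0,
) -> GoldNetwork:
    """Carve a small gold-standard network out of the planted truth.

    The gold network is a connected subset of ``size_interactions`` true
    planted target pairs, padded with further planted proteins up to
    ``size_proteins`` (a curated pathway map may list proteins without
    interactions).  Defaults mirror a 15-protein / 12-interaction curated
    reference map.
    """
    rng = np.random.default_rng([3, seed])
    planted_graph = nx.Graph(list(truth.planted_pairs))
    all_proteins = sorted(truth.planted_proteins)
    if size_proteins > len(all_proteins) and size_proteins > 0:
        raise ValueError("size_proteins exceeds the planted protein count")

    if size_interactions == 0:
        proteins = [all_proteins[i] for i in
                    rng.choice(len(all_proteins), size=size_proteins,
                               replace=False)]
        return GoldNetwork(proteins=frozenset(proteins),
                           interactions=frozenset())

    edges = _connected_edge_sample(planted_graph, size_interactions, rng)
    proteins = {p for e in edges for p in e}
    if len(proteins) > size_proteins:
        raise ValueError(
            f"{size_interactions} connected planted interactions span "
            f"{len(proteins)} proteins > size_proteins={size_proteins}")
    spare = [p for p in all_proteins if p not in proteins]
    rng.shuffle(spare)
    while len(proteins) < size_proteins:
        if not spare:
            raise ValueError("not enough planted proteins to pad the gold "
                             "network")
        proteins.add(spare.pop())
    return GoldNetwork(proteins=frozenset(proteins),
                       interactions=frozenset(edges))


def gen_expression_matrix(
    config: SynthConfig,
    network_genes: Optional[Sequence[str]] = None,
    network_up_enrichment: float = 1.0,
) -> Tuple[ExpressionMatrix, pd.DataFrame]:
    """Generate an age-resolved expression matrix with planted structure.

    ``frac_up`` of the genes receive a monotone-increasing linear mean
    trend over the age index, ``frac_down`` a decreasing one (defaults
    keep roughly three decreasing trends per increasing one), the rest
    stay flat; configured co-expression clusters share one non-linear
    template each, so within-cluster Pearson correlations are exactly 1
    in the noise-free limit.  Multiplicative log-normal noise of width
    ``noise_sd`` keeps all abundances strictly positive.

    ``network_genes`` names the first rows of the matrix (so a predicted
    network can be annotated directly); ``network_up_enrichment``
    multiplies the up-trend rate inside that set, planting a controlled
    enrichment for power studies while the genome-wide up-count stays at
    ``round(frac_up * n_genes)``.

    Returns the matrix and a truth table with columns ``trend``
    (up/down/flat/cluster), ``cluster`` (id or -1) and ``in_network``.
    """
    if config.n_age_points < 3:
        raise ValueError("need at least 3 age points")
    if config.noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = _rng(config.seed, 4)
    n = config.n_genes
    n_time = config.n_age_points

    network_genes = list(network_genes or [])
    if len(set(network_genes)) != len(network_genes):
        raise ValueError("network_genes must be unique")
    if len(network_genes) > n:
        raise ValueError("more network genes than genes")
    genes = network_genes + [f"G{i:05d}"
                             for i in range(n - len(network_genes))]

    n_up = round(config.frac_up * n)
    n_down = round(config.frac_down * n)
    n_net = len(network_genes)
    n_up_net = min(n_net, round(network_up_enrichment * config.frac_up
                                * n_net))
    n_up_net = min(n_up_net, n_up)

    net_idx = np.arange(n_net)
    rest_idx = np.arange(n_net, n)
    up_idx = set(rng.choice(net_idx, size=n_up_net, replace=False).tolist()
                 if n_up_net else [])
    remaining_up = n_up - len(up_idx)
    if remaining_up > len(rest_idx):
        raise ValueError("frac_up too large for the non-network pool")
    up_idx |= set(rng.choice(rest_idx, size=remaining_up,
                             replace=False).tolist())
    free = np.array([i for i in range(n) if i not in up_idx])
    down_idx = set(rng.choice(free, size=n_down, replace=False).tolist())

    trend = np.full(n, "flat", dtype=object)
    trend[list(up_idx)] = "up"
    trend[list(down_idx)] = "down"

    cluster_id = np.full(n, -1, dtype=int)
    flat_pool = [i for i in range(n) if trend[i] == "flat"]
    rng.shuffle(flat_pool)
    if sum(config.coexpr_cluster_sizes) > len(flat_pool):
        raise ValueError("cluster sizes exceed the flat gene pool")
    cursor = 0
    cluster_templates = {}
    for cid, size in enumerate(config.coexpr_cluster_sizes):
        members = flat_pool[cursor:cursor + size]
        cursor += size
        cluster_id[members] = cid
        trend[members] = "cluster"
        # shared non-linear positive template (smoothed random walk)
        walk = np.cumsum(rng.normal(0.0, 0.5, size=n_time))
        cluster_templates[cid] = np.exp(walk - walk.mean())

    t = np.arange(n_time, dtype=float)
    base = _loguniform(rng, 50.0, 5000.0, size=n)
    slope = rng.uniform(0.5, 3.0, size=n)
    shapes = np.ones((n, n_time))
    for i in range(n):
        if trend[i] == "up":
            shapes[i] = 1.0 + slope[i] * t / (n_time - 1)
        elif trend[i] == "down":
            shapes[i] = 1.0 + slope[i] * (n_time - 1 - t) / (n_time - 1)
        elif trend[i] == "cluster":
            shapes[i] = cluster_templates[cluster_id[i]]
    values = base[:, None] * shapes
    if config.noise_sd > 0:
        values = values * np.exp(
            rng.normal(0.0, config.noise_sd, size=values.shape))

    frame = pd.DataFrame(values, index=pd.Index(genes, name="gene"),
                         columns=[f"age_{j + 1}" for j in range(n_time)])
    truth = pd.DataFrame(
        {
            "trend": trend,
            "cluster": cluster_id,
            "in_network": [i < n_net for i in range(n)],
        },
        index=frame.index,
    )
    return ExpressionMatrix(values=frame), truth


def gen_y2h_table(
    bait: str,
    candidate_preys: Sequence[str],
    seed: int = 0,
    n_preys: int = 21,
    n_clones: int = 62,
    n_discarded: int = 6,
    novel_fraction: float = 0.3,
) -> pd.DataFrame:
    """Generate a clone-level yeast-two-hybrid prey table for one bait.

    One row per sequenced clone: prey accession, clone count (1), an
    in-frame flag, and an optional exclusion reason.  Retained clones
    cover ``n_preys`` distinct preys with a skewed clone-count
    distribution (a few preys are found many times); ``n_discarded``
    extra rows are out-of-frame or flagged with an exclusion reason, as
    a screening pipeline would discard them.  ``novel_fraction`` of the
    preys are proteins absent from ``candidate_preys`` (experimental hits
    not predicted computationally).
    """
    if n_clones < n_preys:
        raise ValueError("n_clones must be at least n_preys")
    rng = np.random.default_rng([5, seed])
    candidates = [p for p in candidate_preys if p != bait]
    n_novel = min(n_preys, max(0, round(novel_fraction * n_preys)))
    n_known = n_preys - n_novel
    if n_known > len(candidates):
        raise ValueError("not enough candidate preys")
    known = [candidates[i] for i in
             rng.choice(len(candidates), size=n_known, replace=False)]
    novel = [f"PAY2H{i:02d}" for i in range(n_novel)]
    preys = known + novel
    # skewed clone allocation: each prey >= 1 clone, surplus ~ geometric
    weights = rng.geometric(0.3, size=n_preys).astype(float)
    surplus = rng.multinomial(n_clones - n_preys, weights / weights.sum())
    counts = 1 + surplus
    rows = []
    for prey, count in zip(preys, counts):
        for _ in range(int(count)):
            rows.append({"prey_accession": prey, "clone_count": 1,
                         "in_frame": True, "excluded_reason": ""})
    for i in range(n_discarded):
        reason = "" if i % 2 == 0 else "false_positive"
        rows.append({
            "prey_accession": f"PADISC{i:02d}",
            "clone_count": 1,
            "in_frame": i % 2 != 0,  # out-of-frame or excluded-by-reason
            "excluded_reason": reason,
        })
    frame = pd.DataFrame(rows, columns=["prey_accession", "clone_count",
                                        "in_frame", "excluded_reason"])
    return frame
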