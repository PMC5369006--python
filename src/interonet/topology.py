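"""Topological validation of a predicted network against random ensembles.

Five features are computed on the prediction-only network: diameter,
modularity (with random-walk community detection), transitivity, node
degree, and node betweenness.  Two null ensembles provide the comparison:

* **set 1** — degree-preserving randomisation by double-edge swaps
  (every node keeps its degree; only the partners change);
* **set 2** — uniform simple graphs with the same node and edge counts.

Diameter, modularity, and transitivity are tested against set 1 (empirical
relative frequency for the discrete diameter; Shapiro-Wilk gate plus a
normal fit for modularity/transitivity).  The degree and betweenness
distributions are tested against the pooled set-2 node values with a
two-sample Kolmogorov-Smirnov test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "compute_diameter",
    "compute_transitivity",
    "compute_centralities",
    "detect_modules",
    "compute_modularity",
    "generate_null_ensemble",
    "null_model_tests",
    "rank_hubs",
    "fit_degree_loglog",
    "NullEnsemble",
    "TopologyReport",
    "FeatureTest",
    "StatsReport",
    "topology_report",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# single-graph features
# ---------------------------------------------------------------------------

def compute_diameter(graph: nx.Graph) -> int:
    """Longest of all shortest paths (unweighted).

    On a disconnected graph the diameter of the largest connected
    component is returned.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if nx.is_connected(graph):
        return nx.diameter(graph)
    largest = max(nx.connected_components(graph), key=len)
    return nx.diameter(graph.subgraph(largest))


def compute_transitivity(graph: nx.Graph) -> float:
    """Global clustering coefficient c = 3n / t.

    n is the number of triangles and t the number of connected triples
    (paths of length two).  Undefined (raises ``ValueError``) when the
    graph has no connected triple.
    """
    degrees = [d for _, d in graph.degree()]
    triples = sum(d * (d - 1) // 2 for d in degrees)
    if triples == 0:
        raise ValueError("undefined: graph has no connected triple")
    triangles = sum(nx.triangles(graph).values()) // 3
    return 3.0 * triangles / triples


def compute_centralities(
    graph: nx.Graph,
) -> Tuple[Dict[str, int], Dict[str, float]]:
    """Node degrees and unnormalised shortest-path betweenness.

    Betweenness counts, for every node pair, the fraction of equal-length
    shortest paths passing through a node (each unordered pair counted
    once); a 5-star's centre therefore scores C(4,2) = 6.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    degrees = dict(graph.degree())
    betweenness = nx.betweenness_centrality(graph, normalized=False)
    return degrees, betweenness


def detect_modules(graph: nx.Graph, steps: int = 4) -> Dict[str, int]:
    """Random-walk (walktrap) community detection, cut at max modularity.

    Returns a complete partition mapping every node to a module id
    (0-based).  The agglomeration is deterministic for a given graph.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    import igraph as ig

    nodes = list(graph.nodes())
    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[a], index[b]) for a, b in graph.edges()]
    g = ig.Graph(n=len(nodes), edges=edges, directed=False)
    dendrogram = g.community_walktrap(steps=steps)
    clustering = dendrogram.as_clustering()  # cut maximising modularity
    membership = clustering.membership
    return {n: membership[index[n]] for n in nodes}


def compute_modularity(graph: nx.Graph, partition: Dict[str, int]) -> float:
    """Newman-Girvan modularity Q = sum_i (e_ii - a_i^2).

    ``e_ii`` is the fraction of edges with both endpoints in module i and
    ``a_i`` the fraction of edge endpoints attached to module i.  This is
    an independent implementation (it does not delegate to a graph
    library) so it can verify partitions produced elsewhere.
    """
    nodes = set(graph.nodes())
    if set(partition) < nodes:
        missing = nodes - set(partition)
        raise ValueError(f"incomplete partition: {sorted(missing)[:5]}")
    m = graph.number_of_edges()
    if m == 0:
        raise ValueError("modularity undefined for an edgeless graph")
    modules = set(partition[n] for n in nodes)
    e_within = {mod: 0 for mod in modules}
    endpoints = {mod: 0 for mod in modules}
    for a, b in graph.edges():
        ma, mb = partition[a], partition[b]
        if ma == mb:
            e_within[ma] += 1
        endpoints[ma] += 1
        endpoints[mb] += 1
    q = 0.0
    for mod in modules:
        e_ii = e_within[mod] / m
        a_i = endpoints[mod] / (2 * m)
        q += e_ii - a_i * a_i
    return q


# ---------------------------------------------------------------------------
# null ensembles
# ---------------------------------------------------------------------------

@dataclass
class NullEnsemble:
    """A seeded collection of randomised graphs of one kind.

    ``kind`` is ``"rewired"`` (set 1: degree-preserving double-edge
    swaps) or ``"same_size_random"`` (set 2: uniform simple graph with
    identical node and edge counts).
    """

    kind: str
    graphs: List[nx.Graph]
    seed: int
    n: int

    def __post_init__(self) -> None:
        if self.kind not in ("rewired", "same_size_random"):
            raise ValueError(f"unknown ensemble kind {self.kind!r}")
        if len(self.graphs) != self.n:
            raise ValueError("ensemble size mismatch")


def _rewire_once(
    edges: List[Tuple[str, str]],
    rng: np.random.Generator,
    swaps_target: int,
    max_attempts: int,
) -> Tuple[List[Tuple[str, str]], int]:
    """Degree-preserving double-edge swaps on an edge list.

    Picks two edges (u,v), (x,y), rewires to (u,x), (v,y) (with a random
    orientation flip), rejecting swaps that would create a self-loop or a
    multi-edge.  Returns the new edge list and the number of accepted
    swaps.
    """
    edge_list = list(edges)
    edge_set = set(frozenset(e) for e in edge_list)
    m = len(edge_list)
    accepted = 0
    attempts = 0
    while accepted < swaps_target and attempts < max_attempts:
        attempts += 1
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        u, v = edge_list[i]
        x, y = edge_list[j]
        if rng.random() < 0.5:
            x, y = y, x
        # proposed: (u, x), (v, y)
        if u == x or v == y:
            continue
        new1, new2 = frozenset((u, x)), frozenset((v, y))
        if new1 in edge_set or new2 in edge_set or new1 == new2:
            continue
        edge_set.discard(frozenset((u, v)))
        edge_set.discard(frozenset((x, y)))
        edge_set.add(new1)
        edge_set.add(new2)
        edge_list[i] = (u, x)
        edge_list[j] = (v, y)
        accepted += 1
    return edge_list, accepted


def generate_null_ensemble(
    graph: nx.Graph,
    kind: str,
    n: int = 1000,
    seed: int = 0,
    swaps_per_edge: int = 10,
) -> NullEnsemble:
    """Build one of the two random-network ensembles.

    set 1 (``kind="rewired"``): each sample applies ``swaps_per_edge * |E|``
    accepted degree-preserving double-edge swaps (self-loops and
    multi-edges rejected).  Graphs admitting no swap (e.g. a star) are
    returned as copies with a warning.

    set 2 (``kind="same_size_random"``): each sample is a uniform simple
    graph on the same node set with exactly |E| edges.
    """
    if kind not in ("rewired", "same_size_random"):
        raise ValueError(f"unknown ensemble kind {kind!r}")
    rng = np.random.default_rng(seed)
    nodes = list(graph.nodes())
    edges = list(graph.edges())
    m = len(edges)
    graphs: List[nx.Graph] = []

    if kind == "rewired":
        swaps_target = swaps_per_edge * m
        max_attempts = max(100 * m, 1000)
        warned = False
        for _ in range(n):
            new_edges, accepted = _rewire_once(edges, rng, swaps_target,
                                               max_attempts)
            if accepted == 0 and not warned:
                warnings.warn("no degree-preserving swap possible: "
                              "ensemble contains copies of the input")
                warned = True
            g = nx.Graph()
            g.add_nodes_from(nodes)
            g.add_edges_from(new_edges)
            graphs.append(g)
    else:
        n_nodes = len(nodes)
        n_pairs = n_nodes * (n_nodes - 1) // 2
        if m > n_pairs:
            raise ValueError("more edges than simple-graph maximum")
        iu, ju = np.triu_indices(n_nodes, k=1)
        for _ in range(n):
            chosen = rng.choice(n_pairs, size=m, replace=False)
            g = nx.Graph()
            g.add_nodes_from(nodes)
            g.add_edges_from(
                (nodes[iu[c]], nodes[ju[c]]) for c in chosen)
            graphs.append(g)
    return NullEnsemble(kind=kind, graphs=graphs, seed=seed, n=n)


# ---------------------------------------------------------------------------
# reports and significance tests
# ---------------------------------------------------------------------------

@dataclass
class TopologyReport:
    """Observed topological features of one network."""

    diameter: int
    transitivity: float
    modularity: float
    n_modules: int
    partition: Dict[str, int]
    degrees: Dict[str, int]
    betweenness: Dict[str, float]

    def __post_init__(self) -> None:
        if not (0.0 <= self.transitivity <= 1.0):
            raise ValueError("transitivity outside [0, 1]")
        if not (-0.5 <= self.modularity <= 1.0):
            raise ValueError("modularity outside [-0.5, 1]")


def topology_report(graph: nx.Graph, steps: int = 4) -> TopologyReport:
    """Compute all five features plus the module partition for a graph."""
    partition = detect_modules(graph, steps=steps)
    degrees, betweenness = compute_centralities(graph)
    return TopologyReport(
        diameter=compute_diameter(graph),
        transitivity=compute_transitivity(graph),
        modularity=compute_modularity(graph, partition),
        n_modules=len(set(partition.values())),
        partition=partition,
        degrees=degrees,
        betweenness=betweenness,
    )


@dataclass(frozen=True)
class FeatureTest:
    """Outcome of one per-feature significance test."""

    feature: str
    observed: float
    random_median: float
    test: str
    p_value: float
    normal: Optional[bool] = None  # Shapiro-Wilk gate, where applicable
    p_upper_tail: Optional[float] = None  # for the discrete diameter

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


@dataclass
class StatsReport:
    """Per-feature tests of an observed network against the null ensembles."""

    tests: Dict[str, FeatureTest] = field(default_factory=dict)

    def __getitem__(self, feature: str) -> FeatureTest:
        return self.tests[feature]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "feature": t.feature,
                "observed": t.observed,
                "random_median": t.random_median,
                "test": t.test,
                "p_value": t.p_value,
            }
            for t in self.tests.values()
        ]
        return pd.DataFrame(rows)


def _normal_fit_p(observed: float, samples: np.ndarray,
                  alpha: float) -> Tuple[float, bool]:
    """Shapiro-Wilk gate, then a one-sided normal-fit p in the direction
    of the observed deviation (0.5 when the observed equals the mean)."""
    if np.ptp(samples) == 0:
        # degenerate ensemble (e.g. a graph with a unique realisation)
        mean = samples.mean()
        return (0.5 if observed == mean else 0.0), False
    _, shapiro_p = stats.shapiro(samples)
    normal = bool(shapiro_p > alpha)
    if not normal:
        warnings.warn("random feature values failed the Shapiro-Wilk "
                      "normality gate; the normal-fit p-value is flagged")
    mean = samples.mean()
    sd = samples.std(ddof=1)
    if sd == 0:
        return (1.0 if observed == mean else 0.0), normal
    z = (observed - mean) / sd
    if z >= 0:
        p = float(stats.norm.sf(z))
    else:
        p = float(stats.norm.cdf(z))
    return p, normal


def null_model_tests(
    observed: TopologyReport,
    set1: NullEnsemble,
    set2: NullEnsemble,
    alpha: float = 0.05,
    steps: int = 4,
) -> StatsReport:
    """Test each observed feature against its designated null ensemble.

    * diameter vs set 1: empirical p = relative frequency of the observed
      diameter among the random diameters (the upper-tail frequency of
      values >= observed is reported alongside);
    * modularity and transitivity vs set 1: Shapiro-Wilk gate at
      ``alpha``, then a one-sided p from a normal fitted to the random
      mean and standard deviation, in the direction of the deviation;
    * degree and betweenness vs set 2: two-sample Kolmogorov-Smirnov p
      comparing the observed per-node values with the pooled per-node
      values of all random graphs.
    """
    if set1.kind != "rewired" or set2.kind != "same_size_random":
        raise ValueError("set1 must be the rewired ensemble and set2 the "
                         "same-size random ensemble")
    if not set1.graphs or not set2.graphs:
        raise ValueError("ensembles must be non-empty")

    report = StatsReport()

    diam = np.array([compute_diameter(g) for g in set1.graphs], dtype=float)
    p_exact = float(np.mean(diam == observed.diameter))
    p_tail = float(np.mean(diam >= observed.diameter))
    report.tests["diameter"] = FeatureTest(
        feature="diameter", observed=float(observed.diameter),
        random_median=float(np.median(diam)),
        test="relative frequency", p_value=p_exact, p_upper_tail=p_tail)

    mods = []
    trans = []
    for g in set1.graphs:
        part = detect_modules(g, steps=steps)
        mods.append(compute_modularity(g, part))
        try:
            trans.append(compute_transitivity(g))
        except ValueError:
            trans.append(0.0)
    mods = np.asarray(mods)
    trans = np.asarray(trans)
    p_mod, norm_mod = _normal_fit_p(observed.modularity, mods, alpha)
    report.tests["modularity"] = FeatureTest(
        feature="modularity", observed=observed.modularity,
        random_median=float(np.median(mods)),
        test="Shapiro-Wilk + normal fit", p_value=p_mod, normal=norm_mod)
    p_tr, norm_tr = _normal_fit_p(observed.transitivity, trans, alpha)
    report.tests["transitivity"] = FeatureTest(
        feature="transitivity", observed=observed.transitivity,
        random_median=float(np.median(trans)),
        test="Shapiro-Wilk + normal fit", p_value=p_tr, normal=norm_tr)

    obs_deg = np.array(sorted(observed.degrees.values()), dtype=float)
    obs_bet = np.array(sorted(observed.betweenness.values()), dtype=float)
    pooled_deg: List[float] = []
    pooled_bet: List[float] = []
    for g in set2.graphs:
        deg, bet = compute_centralities(g)
        pooled_deg.extend(deg.values())
        pooled_bet.extend(bet.values())
    ks_deg = stats.ks_2samp(obs_deg, np.asarray(pooled_deg))
    ks_bet = stats.ks_2samp(obs_bet, np.asarray(pooled_bet))
    report.tests["degree"] = FeatureTest(
        feature="degree", observed=float(np.median(obs_deg)),
        random_median=float(np.median(pooled_deg)),
        test="Kolmogorov-Smirnov", p_value=float(ks_deg.pvalue))
    report.tests["betweenness"] = FeatureTest(
        feature="betweenness", observed=float(np.median(obs_bet)),
        random_median=float(np.median(pooled_bet)),
        test="Kolmogorov-Smirnov", p_value=float(ks_bet.pvalue))
    return report


# ---------------------------------------------------------------------------
# hubs and degree-distribution shape
# ---------------------------------------------------------------------------

def rank_hubs(
    degrees: Dict[str, int], betweennesses: Dict[str, float]
) -> pd.DataFrame:
    """Rank nodes by degree and betweenness, summed to a total rank.

    Both features are ranked descending with competition ("min") ranking
    for ties; the total rank is the sum and the table is sorted ascending
    by total (best first).
    """
    if set(degrees) != set(betweennesses):
        raise ValueError("degree and betweenness vectors must cover the "
                         "same node set")
    nodes = sorted(degrees)
    deg = np.array([degrees[n] for n in nodes], dtype=float)
    bet = np.array([betweennesses[n] for n in nodes], dtype=float)
    deg_rank = stats.rankdata(-deg, method="min")
    bet_rank = stats.rankdata(-bet, method="min")
    frame = pd.DataFrame({
        "node": nodes,
        "degree": deg,
        "betweenness": bet,
        "degree_rank": deg_rank.astype(int),
        "betweenness_rank": bet_rank.astype(int),
    })
    frame["total_rank"] = frame["degree_rank"] + frame["betweenness_rank"]
    frame = frame.sort_values(
        ["total_rank", "degree_rank", "node"]).reset_index(drop=True)
    return frame


def fit_degree_loglog(degrees: Sequence[int]) -> Tuple[float, float]:
    """Least-squares line on the log10-log10 degree distribution.

    Fits log10(count_k) against log10(k) over the observed degrees k >= 1
    with count_k > 0; returns (slope, intercept).  A power-law
    ("scale-free") degree distribution shows up as a straight line with a
    negative slope.  Raises ``ValueError("degenerate")`` with fewer than
    two distinct positive degrees.
    """
    vals, counts = np.unique(
        [d for d in degrees if d >= 1], return_counts=True)
    if len(vals) < 2:
        raise ValueError("degenerate: fewer than two distinct degrees")
    x = np.log10(vals.astype(float))
    y = np.log10(counts.astype(float))
    slope, intercept = np.polyfit(x, y, deg=1)
    return float(slope), float(intercept)
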