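"""Interolog transfer: score homology and project reference interactions.

An *interolog* is an interaction inferred in a target species because both
partners are homologous to an interacting protein pair in a reference
species.  BLAST E-values are interpreted as degrees of similarity and
mapped onto a [0, 1] homology score over a configurable E-value range
``[h_l, h_u]``; reference interactions are then transferred to every
target-species pair whose endpoints both score above zero.
"""

from __future__ import annotations

import logging
import math
import warnings
from typing import Dict, List, Tuple

import networkx as nx

from .types import (
    HomologyTable,
    PredictedEdge,
    PredictedNetwork,
    PredictionParameters,
    ReferenceInteractome,
    Support,
    unordered,
)

__all__ = ["homology_score", "predict_network", "build_hybrid_network"]

logger = logging.getLogger(__name__)

# floor used for log10 when an E-value underflows to exactly 0
_LOG_FLOOR = 1e-300


def homology_score(
    evalue: float,
    n_homologs: int,
    params: PredictionParameters,
) -> float:
    """Map a BLAST E-value to a [0, 1] homology ("similarity") score.

    The score is 0 for E-values at or above the upper bound ``h_u``, 1 for
    E-values at or below the lower bound ``h_l``, and interpolates linearly
    in log10(E) between the bounds::

        score = (log10 h_u - log10 E) / (log10 h_u - log10 h_l)

    Independently of the range, a reference protein with exactly one
    homolog scores 1 whenever its E-value is at most
    ``params.single_homolog_evalue`` (default 1e-5); this override takes
    precedence over the range mapping.  An E-value of exactly 0 (BLAST
    underflow) is treated as the strongest possible hit.

    Parameters
    ----------
    evalue:
        Non-negative BLAST E-value of the query→subject hit.
    n_homologs:
        Total number of distinct target-species homologs of the reference
        (subject) protein.
    params:
        Homology-range bounds.
    """
    if evalue < 0:
        raise ValueError(f"negative E-value: {evalue!r}")
    if n_homologs == 1 and evalue <= params.single_homolog_evalue:
        return 1.0
    if evalue <= params.h_l:
        return 1.0
    if evalue >= params.h_u:
        return 0.0
    log_u = math.log10(params.h_u)
    log_l = math.log10(max(params.h_l, _LOG_FLOOR))
    log_e = math.log10(max(evalue, _LOG_FLOOR))
    return (log_u - log_e) / (log_u - log_l)


def _combine_edge(scores: List[float], rule: str) -> float:
    if rule == "max":
        return max(scores)
    if rule == "mean":
        return sum(scores) / len(scores)
    raise ValueError(f"unknown edge rule {rule!r}")


def predict_network(
    ref_a: ReferenceInteractome,
    ref_b: ReferenceInteractome,
    homology: HomologyTable,
    params: PredictionParameters,
) -> PredictedNetwork:
    """Transfer reference interactions to the target species.

    For every reference interaction (p, q) in either reference interactome
    and every target pair (x, y) with x homologous to p and y to q where
    both homology scores are strictly positive, an edge {x, y} is emitted
    (or extended with an additional support).  The per-support score
    combines the two endpoint scores (``params.support_rule``, default
    mean); the edge score combines across supports (``params.edge_rule``,
    default max).  Pairs collapsing onto a single target protein (x == y)
    are dropped.  Provenance retains every support from both species.

    The output is invariant to the ordering of the input rows and to the
    orientation of reference pairs.
    """
    if len(homology) == 0:
        warnings.warn("empty homology table: predicted network is empty")
        return PredictedNetwork(edges={}, parameters=params)

    supports: Dict[Tuple[str, str], List[Support]] = {}
    for ref in (ref_a, ref_b):
        taxid = ref.species_taxid
        seen_pairs = set()
        for ia in ref.interactions:
            p, q = ia.pair
            if (p, q) in seen_pairs:
                continue
            seen_pairs.add((p, q))
            hom_p = homology.homologs_of(p)
            hom_q = homology.homologs_of(q)
            if not hom_p or not hom_q:
                continue
            n_p = len(hom_p)
            n_q = len(hom_q)
            for x, e_xp in hom_p.items():
                s_x = homology_score(e_xp, n_p, params)
                if s_x <= 0.0:
                    continue
                for y, e_yq in hom_q.items():
                    if x == y:
                        continue
                    s_y = homology_score(e_yq, n_q, params)
                    if s_y <= 0.0:
                        continue
                    pair = unordered(x, y)
                    # keep the endpoint scores aligned with ref_pair order
                    if pair == (x, y):
                        sup = Support(taxid, (p, q), s_x, s_y)
                    else:
                        sup = Support(taxid, (q, p), s_y, s_x)
                    supports.setdefault(pair, []).append(sup)

    edges: Dict[Tuple[str, str], PredictedEdge] = {}
    for pair, sups in supports.items():
        # deduplicate identical supports (e.g. duplicated reference rows)
        uniq = sorted(set(sups), key=lambda s: (s.species_taxid, s.ref_pair))
        score = _combine_edge(
            [s.score(params.support_rule) for s in uniq], params.edge_rule
        )
        edges[pair] = PredictedEdge(pair=pair, score=min(score, 1.0),
                                    supports=uniq)
    logger.info("predicted %d interactions over %d proteins",
                len(edges), len({n for p in edges for n in p}))
    return PredictedNetwork(edges=edges, parameters=params)


def build_hybrid_network(
    ref_a: ReferenceInteractome,
    ref_b: ReferenceInteractome,
    predicted: PredictedNetwork,
    homology: HomologyTable,
) -> nx.Graph:
    """Assemble the reference/predicted/homology union ("hybrid") graph.

    The hybrid graph contains (i) the subsets of both reference networks
    whose interactions supported at least one predicted edge, (ii) the
    predicted target-species network, and (iii) one homology edge for
    every target↔reference protein relation used by at least one support.

    Nodes carry ``species_taxid`` and ``kind`` ("reference"/"target");
    interaction edges carry ``kind="interaction"`` plus species, homology
    edges carry ``kind="homology"`` plus the E-value.  Per-species usage
    counts are stored in ``graph.graph["summary"]``.
    """
    g = nx.Graph()
    target_taxid = -1  # synthetic marker; target species carries no taxid here
    used_ref_edges: Dict[int, set] = {ref_a.species_taxid: set(),
                                      ref_b.species_taxid: set()}
    used_homology: set = set()

    for (x, y), edge in predicted.edges.items():
        g.add_node(x, species_taxid=target_taxid, kind="target")
        g.add_node(y, species_taxid=target_taxid, kind="target")
        g.add_edge(x, y, kind="interaction", species=sorted(edge.species),
                   score=edge.score)
        for sup in edge.supports:
            p, q = sup.ref_pair
            used_ref_edges.setdefault(sup.species_taxid, set()).add(
                unordered(p, q))
            used_homology.add((x, p))
            used_homology.add((y, q))

    for ref in (ref_a, ref_b):
        taxid = ref.species_taxid
        for p, q in used_ref_edges.get(taxid, ()):  # used subset only
            g.add_node(p, species_taxid=taxid, kind="reference")
            g.add_node(q, species_taxid=taxid, kind="reference")
            g.add_edge(p, q, kind="interaction", species=[taxid])

    for x, p in used_homology:
        if p not in g:
            continue
        ev = homology.evalue(x, p)
        g.add_edge(x, p, kind="homology", evalue=ev)

    summary = {}
    for ref in (ref_a, ref_b):
        taxid = ref.species_taxid
        nodes = {n for n, d in g.nodes(data=True)
                 if d.get("species_taxid") == taxid}
        summary[taxid] = {
            "proteins": len(nodes),
            "interactions": len(used_ref_edges.get(taxid, ())),
        }
    summary["target"] = {
        "proteins": len(predicted.proteins),
        "interactions": len(predicted),
    }
    summary["homology_edges"] = sum(
        1 for _, _, d in g.edges(data=True) if d["kind"] == "homology")
    g.graph["summary"] = summary
    logger.info("hybrid network: %s", summary)
    return g
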