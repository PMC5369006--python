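"""Combine the predicted interolog network with experimental evidence.

The combined network is an undirected :class:`networkx.Graph` over
target-species accessions.  Edges carry an ``evidence`` set (reference
species taxids as strings, plus ``"y2h"``), the interolog ``score`` where
predicted, a ``clone_count`` where seen in the yeast-two-hybrid screen,
and an ``is_prediction`` flag so that downstream topology can run on the
prediction-only subnetwork.  Nodes can be annotated with age-resolved
expression statistics and optional aliases.
"""

from __future__ import annotations

import csv
import logging
import warnings
from pathlib import Path
from typing import Dict, Iterable, Optional, Union

import networkx as nx
import numpy as np

from .expression import ExpressionMatrix, pearson_correlation
from .types import PredictedNetwork, Y2HRecord

__all__ = [
    "merge_networks",
    "annotate_expression",
    "prediction_subnetwork",
    "export_network",
    "load_network",
]

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

Y2H_TAG = "y2h"

_EDGE_COLUMNS = ["source", "target", "evidence", "score", "clone_count",
                 "is_prediction"]
_NODE_COLUMNS = ["accession", "alias", "module", "age_pcc", "ratio",
                 "profile"]


def merge_networks(
    predicted: PredictedNetwork,
    bait: str,
    y2h: Iterable[Y2HRecord],
    aliases: Optional[Dict[str, str]] = None,
) -> nx.Graph:
    """Merge a predicted network with bait-prey yeast-two-hybrid edges.

    Every retained yeast-two-hybrid record becomes an edge
    ``{bait, prey}`` with evidence ``"y2h"`` and its clone count; if that
    pair was already predicted, the existing edge gains the evidence tag
    instead of being duplicated.  Merging the same record list twice
    changes nothing.  Preys equal to the bait are skipped with a warning.
    """
    g = nx.Graph()
    for (a, b), edge in predicted.edges.items():
        g.add_edge(a, b,
                   evidence=frozenset(str(t) for t in edge.species),
                   score=edge.score,
                   clone_count=0,
                   is_prediction=True)
    for record in y2h:
        if not record.retained:
            continue
        prey = record.prey_accession
        if prey == bait:
            warnings.warn(f"skipping self-interaction of bait {bait}")
            continue
        if g.has_edge(bait, prey):
            data = g.edges[bait, prey]
            data["evidence"] = data["evidence"] | {Y2H_TAG}
            data["clone_count"] = record.clone_count
        else:
            g.add_edge(bait, prey, evidence=frozenset({Y2H_TAG}),
                       score=float("nan"), clone_count=record.clone_count,
                       is_prediction=False)
    for n in g.nodes:
        g.nodes[n].setdefault("alias", (aliases or {}).get(n, ""))
    logger.info("combined network: %d proteins, %d interactions",
                g.number_of_nodes(), g.number_of_edges())
    return g


def prediction_subnetwork(combined: nx.Graph) -> nx.Graph:
    """The prediction-only subgraph (yeast-two-hybrid-only material
    excluded), as used for the topological validation."""
    g = nx.Graph()
    for a, b, data in combined.edges(data=True):
        if data.get("is_prediction"):
            g.add_edge(a, b, **data)
    return g


def annotate_expression(
    net: nx.Graph,
    expr: ExpressionMatrix,
    age_points=None,
) -> nx.Graph:
    """Attach expression statistics to every node with a matching gene.

    Each matched node receives its abundance profile, the Pearson
    correlation of the profile with the age vector (``age_pcc``), and the
    last-to-first abundance ratio (``ratio``, > 1 for genes that gain
    expression with age).  Unmatched nodes are flagged
    ``expression_matched=False``.  Modifies and returns ``net``.
    """
    if age_points is not None:
        age = np.asarray(age_points, dtype=float)
        if len(age) != expr.n_age_points:
            raise ValueError("age_points length does not match the matrix")
    else:
        age = expr.age_points
    genes = set(expr.genes)
    n_matched = 0
    for node in net.nodes:
        if node in genes:
            profile = expr.profile(node)
            try:
                pcc = pearson_correlation(profile, age)
            except ValueError:
                pcc = float("nan")
            net.nodes[node]["profile"] = profile.tolist()
            net.nodes[node]["age_pcc"] = pcc
            net.nodes[node]["ratio"] = float(profile[-1] / profile[0])
            net.nodes[node]["expression_matched"] = True
            n_matched += 1
        else:
            net.nodes[node]["expression_matched"] = False
    logger.info("expression annotation: %d of %d nodes matched",
                n_matched, net.number_of_nodes())
    return net


def _edge_sort_key(edge):
    a, b, _ = edge
    return (a, b) if a <= b else (b, a)


def export_network(net: nx.Graph, path: PathLike, fmt: str = "tsv") -> None:
    """Write the combined network to ``tsv``, ``graphml`` or ``sif``.

    ``tsv`` writes two files, ``<path>.edges.tsv`` and
    ``<path>.nodes.tsv``, with deterministic row ordering; ``graphml``
    serialises set/list attributes as strings; ``sif`` writes one
    ``source <evidence> target`` line per edge.  ``tsv`` and ``graphml``
    round-trip losslessly through :func:`load_network`.
    """
    path = Path(path)
    if fmt == "tsv":
        _export_tsv(net, path)
    elif fmt == "graphml":
        _export_graphml(net, path)
    elif fmt == "sif":
        with open(path, "w") as handle:
            for a, b, data in sorted(net.edges(data=True),
                                     key=_edge_sort_key):
                ev = "|".join(sorted(data.get("evidence", ())))
                handle.write(f"{a}\t{ev or 'interacts'}\t{b}\n")
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def _fmt_edge_row(a, b, data):
    if b < a:
        a, b = b, a
    score = data.get("score", float("nan"))
    return [
        a, b,
        "|".join(sorted(data.get("evidence", ()))),
        "" if score != score else f"{score:.17g}",  # NaN -> empty
        str(data.get("clone_count", 0)),
        str(bool(data.get("is_prediction", False))),
    ]


def _fmt_node_row(n, data):
    profile = data.get("profile")
    pcc = data.get("age_pcc")
    ratio = data.get("ratio")
    module = data.get("module")
    return [
        n,
        data.get("alias", ""),
        "" if module is None else str(module),
        "" if pcc is None or pcc != pcc else f"{pcc:.17g}",
        "" if ratio is None else f"{ratio:.17g}",
        "" if not profile else ",".join(f"{v:.17g}" for v in profile),
    ]


def _export_tsv(net: nx.Graph, path: Path) -> None:
    with open(f"{path}.edges.tsv", "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(_EDGE_COLUMNS)
        for a, b, data in sorted(net.edges(data=True), key=_edge_sort_key):
            writer.writerow(_fmt_edge_row(a, b, data))
    with open(f"{path}.nodes.tsv", "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(_NODE_COLUMNS)
        for n in sorted(net.nodes):
            writer.writerow(_fmt_node_row(n, net.nodes[n]))


def _export_graphml(net: nx.Graph, path: Path) -> None:
    g = nx.Graph()
    for n in sorted(net.nodes):
        row = _fmt_node_row(n, net.nodes[n])
        g.add_node(n, alias=row[1], module=row[2], age_pcc=row[3],
                   ratio=row[4], profile=row[5])
    for a, b, data in sorted(net.edges(data=True), key=_edge_sort_key):
        row = _fmt_edge_row(a, b, data)
        g.add_edge(row[0], row[1], evidence=row[2], score=row[3],
                   clone_count=row[4], is_prediction=row[5])
    nx.write_graphml(g, str(path))


def _parse_edge_attrs(evidence, score, clone_count, is_prediction):
    return {
        "evidence": frozenset(evidence.split("|")) if evidence
        else frozenset(),
        "score": float(score) if score else float("nan"),
        "clone_count": int(clone_count or 0),
        "is_prediction": str(is_prediction).lower() == "true",
    }


def _parse_node_attrs(alias, module, age_pcc, ratio, profile):
    attrs = {"alias": alias or ""}
    if module not in (None, ""):
        attrs["module"] = int(module)
    if age_pcc not in (None, ""):
        attrs["age_pcc"] = float(age_pcc)
    if ratio not in (None, ""):
        attrs["ratio"] = float(ratio)
    if profile not in (None, ""):
        attrs["profile"] = [float(v) for v in profile.split(",")]
        attrs["expression_matched"] = True
    return attrs


def load_network(path: PathLike, fmt: str = "tsv") -> nx.Graph:
    """Read a network written by :func:`export_network` (tsv or graphml)."""
    path = Path(path)
    g = nx.Graph()
    if fmt == "tsv":
        with open(f"{path}.nodes.tsv", newline="") as handle:
            for row in csv.DictReader(handle, delimiter="\t"):
                g.add_node(row["accession"],
                           **_parse_node_attrs(row["alias"], row["module"],
                                               row["age_pcc"], row["ratio"],
                                               row["profile"]))
        with open(f"{path}.edges.tsv", newline="") as handle:
            for row in csv.DictReader(handle, delimiter="\t"):
                g.add_edge(row["source"], row["target"],
                           **_parse_edge_attrs(row["evidence"], row["score"],
                                               row["clone_count"],
                                               row["is_prediction"]))
    elif fmt == "graphml":
        raw = nx.read_graphml(str(path))
        for n, d in raw.nodes(data=True):
            g.add_node(n, **_parse_node_attrs(d.get("alias"),
                                              d.get("module"),
                                              d.get("age_pcc"),
                                              d.get("ratio"),
                                              d.get("profile")))
        for a, b, d in raw.edges(data=True):
            g.add_edge(a, b, **_parse_edge_attrs(d.get("evidence", ""),
                                                 d.get("score", ""),
                                                 d.get("clone_count", 0),
                                                 d.get("is_prediction")))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return g
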