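"""Homology scoring and interolog transfer, against a brute-force oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from interonet import (
    AnnotatedProteinSet,
    HomologyHit,
    HomologyTable,
    PredictionParameters,
    ReferenceInteraction,
    ReferenceInteractome,
    build_hybrid_network,
    homology_score,
    predict_network,
)

DEFAULT = PredictionParameters()


class TestHomologyScore:
    def test_at_upper_bound_scores_zero(self):
        assert homology_score(1e-20, 5, DEFAULT) == 0.0

    def test_below_lower_bound_scores_one(self):
        assert homology_score(1e-250, 5, DEFAULT) == 1.0
        assert homology_score(1e-200, 5, DEFAULT) == 1.0

    def test_log_midpoint_scores_half(self):
        assert homology_score(1e-110, 5, DEFAULT) == pytest.approx(0.5)

    def test_single_homolog_override(self):
        # a sole homolog at 1e-6 scores 1 even though 1e-6 >= h_u
        assert homology_score(1e-6, 1, DEFAULT) == 1.0
        assert homology_score(1e-6, 2, DEFAULT) == 0.0
        assert homology_score(1e-4, 1, DEFAULT) == 0.0  # above the override

    def test_zero_evalue_is_strongest_hit(self):
        assert homology_score(0.0, 5, DEFAULT) == 1.0

    def test_negative_evalue_errors(self):
        with pytest.raises(ValueError, match="negative"):
            homology_score(-1.0, 5, DEFAULT)

    def test_interpolation_matches_oracle(self):
        # independent linear interpolation over log10(E)
        rng = np.random.default_rng(0)
        for exp in rng.uniform(-200, -20, size=50):
            e = 10.0 ** exp
            expected = np.interp(exp, [-200, -20], [1.0, 0.0])
            assert homology_score(e, 5, DEFAULT) == pytest.approx(expected)

    @given(st.floats(min_value=1e-220, max_value=1e-2),
           st.floats(min_value=1e-220, max_value=1e-2))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_monotone_non_increasing_in_evalue(self, e1, e2):
        lo, hi = sorted((e1, e2))
        assert homology_score(lo, 5, DEFAULT) >= homology_score(hi, 5, DEFAULT)

    def test_continuity_at_bounds(self):
        eps = 1e-12
        for bound, val in ((1e-20, 0.0), (1e-200, 1.0)):
            near = homology_score(bound * (1 - eps), 5, DEFAULT)
            assert abs(near - homology_score(bound, 5, DEFAULT)) < 1e-9 or \
                abs(near - val) < 1e-9


def _ref(taxid, prefix, pairs):
    proteins = sorted({p for pair in pairs for p in pair})
    pset = AnnotatedProteinSet(species_taxid=taxid,
                               accessions=frozenset(proteins))
    return ReferenceInteractome(
        protein_set=pset,
        interactions=[ReferenceInteraction(a, b, taxid) for a, b in pairs])


def oracle_predict(refs, hits, params):
    """Independent brute-force enumeration over every reference edge x
    homolog pair, with the score rules written from scratch."""
    best = {}
    for q, s, e in hits:
        key = (q, s)
        best[key] = min(best.get(key, math.inf), e)
    n_hom = {}
    for (q, s) in best:
        n_hom[s] = n_hom.get(s, 0) + 1

    def score(e, s):
        if n_hom[s] == 1 and e <= params.single_homolog_evalue:
            return 1.0
        if e <= params.h_l:
            return 1.0
        if e >= params.h_u:
            return 0.0
        return ((math.log10(params.h_u) - math.log10(e))
                / (math.log10(params.h_u) - math.log10(params.h_l)))

    per_edge = {}
    for ref in refs:
        ref_pairs = {(min(i.a, i.b), max(i.a, i.b)) for i in ref.interactions}
        for p, q in ref_pairs:
            for (x, s1), e1 in best.items():
                if s1 != p:
                    continue
                for (y, s2), e2 in best.items():
                    if s2 != q or x == y:
                        continue
                    sx, sy = score(e1, p), score(e2, q)
                    if sx <= 0 or sy <= 0:
                        continue
                    pair = (min(x, y), max(x, y))
                    sup_score = {"mean": (sx + sy) / 2,
                                 "min": min(sx, sy),
                                 "max": max(sx, sy)}[params.support_rule]
                    per_edge.setdefault(pair, set()).add(
                        (ref.species_taxid, p, q, sup_score))
    result = {}
    for pair, sups in per_edge.items():
        scores = [s for (_, _, _, s) in sups]
        result[pair] = (max(scores) if params.edge_rule == "max"
                        else sum(scores) / len(scores))
    return result


def _random_instance(seed):
    rng = np.random.default_rng(seed)
    prot_a = [f"A{i}" for i in range(8)]
    prot_b = [f"B{i}" for i in range(6)]
    targets = [f"T{i}" for i in range(10)]

    def pairs(prots, k):
        out = set()
        while len(out) < k:
            i, j = rng.choice(len(prots), size=2, replace=False)
            out.add((min(prots[i], prots[j]), max(prots[i], prots[j])))
        return sorted(out)

    ref_a = _ref(9606, "A", pairs(prot_a, int(rng.integers(3, 11))))
    ref_b = _ref(559292, "B", pairs(prot_b, int(rng.integers(3, 10))))
    hits = []
    for _ in range(int(rng.integers(10, 30))):
        q = targets[rng.integers(len(targets))]
        side = prot_a if rng.random() < 0.5 else prot_b
        s = side[rng.integers(len(side))]
        e = 10.0 ** rng.uniform(-210, -1)
        hits.append((q, s, e))
    return ref_a, ref_b, hits


@pytest.mark.parametrize("seed", range(8))
@pytest.mark.parametrize("support_rule,edge_rule",
                         [("mean", "max"), ("min", "mean")])
def test_predict_matches_brute_force_oracle(seed, support_rule, edge_rule):
    ref_a, ref_b, hits = _random_instance(seed)
    params = PredictionParameters(support_rule=support_rule,
                                  edge_rule=edge_rule)
    table = HomologyTable(
        HomologyHit(q, s, e, 9606 if s.startswith("A") else 559292)
        for q, s, e in hits)
    predicted = predict_network(ref_a, ref_b, table, params)
    expected = oracle_predict([ref_a, ref_b], hits, params)
    assert predicted.pairs == set(expected)
    for pair, edge in predicted.edges.items():
        assert edge.score == pytest.approx(expected[pair])


def test_single_reference_edge_perfect_homologs():
    ref_a = _ref(9606, "A", [("Ap", "Aq")])
    ref_b = _ref(559292, "B", [("Bp", "Bq")])
    table = HomologyTable([
        HomologyHit("T1", "Ap", 1e-250, 9606),
        HomologyHit("T2", "Aq", 1e-250, 9606),
    ])
    net = predict_network(ref_a, ref_b, table, DEFAULT)
    assert len(net) == 1
    edge = net.edges[("T1", "T2")]
    assert edge.score == 1.0
    assert len(edge.supports) == 1


def test_both_species_support_merges_to_one_edge():
    ref_a = _ref(9606, "A", [("Ap", "Aq")])
    ref_b = _ref(559292, "B", [("Bp", "Bq")])
    table = HomologyTable([
        HomologyHit("T1", "Ap", 1e-250, 9606),
        HomologyHit("T2", "Aq", 1e-250, 9606),
        HomologyHit("T1", "Bp", 1e-250, 559292),
        HomologyHit("T2", "Bq", 1e-250, 559292),
    ])
    net = predict_network(ref_a, ref_b, table, DEFAULT)
    assert len(net) == 1
    edge = net.edges[("T1", "T2")]
    assert len(edge.supports) == 2
    assert edge.species == {9606, 559292}


def test_all_evalues_at_upper_bound_gives_empty_network():
    ref_a = _ref(9606, "A", [("Ap", "Aq")])
    ref_b = _ref(559292, "B", [("Bp", "Bq")])
    table = HomologyTable([
        HomologyHit("T1", "Ap", 1e-20, 9606),
        HomologyHit("T2", "Aq", 1e-20, 9606),
        HomologyHit("T3", "Aq", 1e-20, 9606),  # two homologs: no override
        HomologyHit("T4", "Ap", 1e-20, 9606),
    ])
    net = predict_network(ref_a, ref_b, table, DEFAULT)
    assert len(net) == 0


def test_empty_homology_table_warns():
    ref_a = _ref(9606, "A", [("Ap", "Aq")])
    ref_b = _ref(559292, "B", [("Bp", "Bq")])
    with pytest.warns(UserWarning, match="empty homology"):
        net = predict_network(ref_a, ref_b, HomologyTable([]), DEFAULT)
    assert len(net) == 0


def test_prediction_invariant_to_row_order_and_orientation():
    ref_a = _ref(9606, "A", [("Ap", "Aq"), ("Aq", "Ar")])
    ref_a_flipped = ReferenceInteractome(
        protein_set=ref_a.protein_set,
        interactions=[ReferenceInteraction("Ar", "Aq", 9606),
                      ReferenceInteraction("Aq", "Ap", 9606)])
    ref_b = _ref(559292, "B", [("Bp", "Bq")])
    hits = [
        HomologyHit("T1", "Ap", 1e-100, 9606),
        HomologyHit("T2", "Aq", 1e-120, 9606),
        HomologyHit("T3", "Ar", 1e-140, 9606),
    ]
    net1 = predict_network(ref_a, ref_b, HomologyTable(hits), DEFAULT)
    net2 = predict_network(ref_a_flipped, ref_b,
                           HomologyTable(reversed(hits)), DEFAULT)
    assert net1.pairs == net2.pairs
    for pair in net1.pairs:
        assert net1.edges[pair].score == pytest.approx(net2.edges[pair].score)


def test_edge_score_reproducible_from_supports(small_pipeline):
    net = small_pipeline["predicted"]
    params = net.parameters
    for edge in net.edges.values():
        combined = max(s.score(params.support_rule) for s in edge.supports)
        assert edge.score == pytest.approx(combined)


class TestHybridNetwork:
    def test_minimal_construction(self):
        ref_a = _ref(9606, "A", [("Ap", "Aq")])
        ref_b = _ref(559292, "B", [("Bp", "Bq")])
        table = HomologyTable([
            HomologyHit("T1", "Ap", 1e-250, 9606),
            HomologyHit("T2", "Aq", 1e-250, 9606),
        ])
        net = predict_network(ref_a, ref_b, table, DEFAULT)
        hybrid = build_hybrid_network(ref_a, ref_b, net, table)
        kinds = [d["kind"] for _, _, d in hybrid.edges(data=True)]
        assert sorted(kinds) == ["homology", "homology",
                                 "interaction", "interaction"]
        assert hybrid.graph["summary"][9606] == {"proteins": 2,
                                                 "interactions": 1}
        assert hybrid.graph["summary"][559292] == {"proteins": 0,
                                                   "interactions": 0}

    def test_empty_prediction_no_homology_edges(self):
        ref_a = _ref(9606, "A", [("Ap", "Aq")])
        ref_b = _ref(559292, "B", [("Bp", "Bq")])
        table = HomologyTable([HomologyHit("T1", "Ap", 1e-250, 9606)])
        net = predict_network(ref_a, ref_b, table, DEFAULT)
        hybrid = build_hybrid_network(ref_a, ref_b, net, table)
        assert hybrid.graph["summary"]["homology_edges"] == 0

    def test_pipeline_scale_summary(self, small_pipeline):
        hybrid = build_hybrid_network(
            small_pipeline["ref_a"], small_pipeline["ref_b"],
            small_pipeline["predicted"], small_pipeline["homology"])
        summary = hybrid.graph["summary"]
        n_planted = len(small_pipeline["truth"].planted_pairs)
        assert summary["target"]["interactions"] == n_planted
        # every planted ortholog relation appears as one homology edge
        truth = small_pipeline["truth"]
        assert summary["homology_edges"] == (
            len(truth.ortholog_map_a) + len(truth.ortholog_map_b))
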