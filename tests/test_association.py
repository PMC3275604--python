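"""Association indices, focal-male filtering, ranks, networks, features."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import raidnet.association as assoc
from raidnet.association import (
    MaleRecord,
    UndefinedPairError,
    age_class,
    build_association_matrix,
    build_top_k_network,
    compute_ai,
    filter_focal_males,
    make_features,
    rank_associates,
)

from conftest import toy_attributes, toy_sightings


@pytest.mark.parametrize(
    "n_ab,n_a,n_b,expected",
    [(0, 5, 7, 0.0), (5, 0, 0, 1.0), (10, 5, 5, 0.5), (2, 1, 0, 2 / 3)],
)
def test_ai_formula(n_ab, n_a, n_b, expected):
    assert compute_ai(n_ab, n_a, n_b) == pytest.approx(expected)


def test_ai_undefined_and_invalid():
    with pytest.raises(UndefinedPairError):
        compute_ai(0, 0, 0)
    with pytest.raises(ValueError):
        compute_ai(-1, 2, 3)


def test_male_record_validation():
    with pytest.raises(ValueError):
        MaleRecord("A", 20, 2)
    with pytest.raises(ValueError):
        MaleRecord("A", 8, 0)


def test_matrix_hand_count():
    # {A,B}, {A,B}, {A,C}: AI(A,B) = 2/(1+0+2) = 2/3, AI(B,C) = 0
    s = toy_sightings([["A", "B"], ["A", "B"], ["A", "C"]])
    a = toy_attributes(["A", "B", "C"])
    m = build_association_matrix(s, a)
    assert m.ai("A", "B") == pytest.approx(2 / 3)
    assert m.ai("B", "C") == 0.0
    assert m.ai("A", "C") == pytest.approx(1 / 3)


def test_single_group_all_pairs_ai_one():
    s = toy_sightings([["A", "B", "C"]])
    m = build_association_matrix(s, toy_attributes(["A", "B", "C"]))
    for x, y in [("A", "B"), ("A", "C"), ("B", "C")]:
        assert m.ai(x, y) == 1.0


def test_never_cosighted_male_has_zero_ai():
    s = toy_sightings([["A", "B"], ["A", "B"], ["C", "D"]])
    m = build_association_matrix(s, toy_attributes(list("ABCD")))
    assert m.ai("A", "C") == 0.0
    assert m.ai("A", "D") == 0.0


def test_duplicate_member_rows_collapse_with_warning():
    s = toy_sightings([["A", "B", "B"]])
    with pytest.warns(UserWarning, match="duplicate"):
        m = build_association_matrix(s, toy_attributes(["A", "B"]))
    assert m.totals.tolist() == [1, 1]
    assert m.n_together[0, 1] == 1


def test_lone_male_sighting_rejected_unless_allowed():
    s = toy_sightings([["A"], ["A", "B"]])
    with pytest.warns(UserWarning, match="single member"):
        m = build_association_matrix(s, toy_attributes(["A", "B"]))
    assert m.totals.tolist() == [1, 1]
    m2 = build_association_matrix(s, toy_attributes(["A", "B"]), allow_singletons=True)
    assert m2.totals.tolist() == [2, 1]
    assert m2.ai("A", "B") == pytest.approx(1 / 2)


def test_unknown_id_is_input_error():
    s = toy_sightings([["A", "Z"]])
    with pytest.raises(ValueError, match="Z"):
        build_association_matrix(s, toy_attributes(["A", "B"]))


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_ai_symmetry_bounds_and_conservation(seed):
    """On random sightings: AI symmetric in [0,1]; N_AB + N_A = totals[A]."""
    rng = np.random.default_rng(seed)
    ids = [f"m{i}" for i in range(6)]
    groups = []
    for _ in range(rng.integers(1, 15)):
        size = int(rng.integers(2, 5))
        groups.append(list(rng.choice(ids, size=size, replace=False)))
    m = build_association_matrix(toy_sightings(groups), toy_attributes(ids))
    ai = m.ai_matrix()
    off = ~np.eye(len(ids), dtype=bool)
    finite = off & np.isfinite(ai)
    assert np.allclose(ai[finite], ai.T[finite])
    assert ((ai[finite] >= 0) & (ai[finite] <= 1)).all()
    for a in range(len(ids)):
        for b in range(len(ids)):
            if a == b:
                continue
            n_ab = m.n_together[a, b]
            assert n_ab + (m.totals[a] - n_ab) == m.totals[a]


def test_filter_identity_when_everyone_well_sampled():
    groups = [["A", "B"]] * 20 + [["B", "C"]] * 20 + [["A", "C"]] * 20
    m = build_association_matrix(toy_sightings(groups), toy_attributes(list("ABC")))
    assert filter_focal_males(m, min_sightings=15) == ["A", "B", "C"]


def test_filter_drops_undersighted_male_and_his_dependents():
    # C has 10 sightings -> dropped; B's top-2 frequent associates include C
    # -> B dropped too; A's frequent associate B was well sighted -> A stays
    groups = [["A", "B"]] * 20 + [["B", "C"]] * 10
    m = build_association_matrix(toy_sightings(groups), toy_attributes(list("ABC")))
    assert filter_focal_males(m, min_sightings=15) == ["A"]


def test_filter_drops_male_whose_sole_associate_is_undersighted():
    # X well sighted (20) but his associates are Y2 (15 sightings, fine) and
    # Y (5 sightings): Y undersighted -> X dropped; Y dropped on count;
    # Y2's only frequent associate X was well sighted, so Y2 stays.
    groups = [["X", "Y"]] * 5 + [["A", "B"]] * 20 + [["X", "Y2"]] * 15
    m = build_association_matrix(
        toy_sightings(groups), toy_attributes(["X", "Y", "Y2", "A", "B"])
    )
    kept = filter_focal_males(m, min_sightings=15, top_m=2)
    assert kept == ["Y2", "A", "B"]


def test_rank_rows_are_permutations_with_deterministic_ties(focal_features):
    _, _, matrix, ranks, _ = focal_features
    n = matrix.n
    for focal in matrix.ids:
        row = ranks.order[focal]
        assert len(row) == n - 1
        assert set(row) == set(matrix.ids) - {focal}
    # re-ranking is bit-identical
    again = rank_associates(matrix)
    assert again.order == ranks.order


def test_rank_ordering_follows_ai_then_tiebreak():
    groups = [["F", "B"]] * 5 + [["F", "C"]] * 2 + [["B", "C", "D"]] * 3
    m = build_association_matrix(toy_sightings(groups), toy_attributes(list("FBCD")))
    r = rank_associates(m)
    assert r.order["F"][:2] == ["B", "C"]
    assert r.rank_of("F", "D") == 3  # zero AI, last


def test_top_k_network_out_degree_and_positive_ai(focal_features):
    _, _, matrix, ranks, network = focal_features
    n = matrix.n
    assert network.number_of_edges() <= 2 * n
    for node in network.nodes:
        assert network.out_degree(node) <= 2
        for _, j in network.out_edges(node):
            assert matrix.ai(node, j) > 0


def test_top_k_network_respects_sparse_partners():
    groups = [["A", "B"]] * 20 + [["C", "D"]] * 20
    m = build_association_matrix(toy_sightings(groups), toy_attributes(list("ABCD")))
    r = rank_associates(m)
    g = build_top_k_network(r, m, k=2)
    # each male has a single positive-AI partner -> out-degree 1, reciprocal
    assert all(g.out_degree(v) == 1 for v in g.nodes)
    assert g.has_edge("A", "B") and g.has_edge("B", "A")


@pytest.mark.parametrize(
    "age,expected",
    [(12, "10-14"), (17, "15-19"), (25, "20-30"), (40, "31-44"), (50, "45+")],
)
def test_age_classes(age, expected):
    assert age_class(age) == expected


def test_features_relative_age_and_interactions():
    groups = [["F", "B"]] * 20 + [["F", "C"]] * 10 + [["B", "C"]] * 8 + [["F", "D"]] * 5 + [["B", "D"]] * 4 + [["C", "D"]] * 2
    ids = ["F", "B", "C", "D"]
    att = toy_attributes(ids, ages=[30, 37, 25, 45], raiders=[0, 1, 0, 1])
    m = build_association_matrix(toy_sightings(groups), att)
    r = rank_associates(m)
    f = make_features(r, att, k=3).set_index("male_id")
    # F's closest associate is B (37y raider): relage +7, status 1, interaction +7
    assert f.loc["F", "status_1"] == 1
    assert f.loc["F", "relage_1"] == 7
    assert f.loc["F", "status_1_x_relage_1"] == 7
    # second closest is C (25y non-raider): relage -5
    assert f.loc["F", "relage_2"] == -5
    assert f.loc["F", "status_2"] == 0
    assert f.loc["F", "age_class"] == "20-30"


def test_features_require_enough_associates():
    groups = [["A", "B"]] * 16
    att = toy_attributes(["A", "B"])
    m = build_association_matrix(toy_sightings(groups), att)
    r = rank_associates(m)
    with pytest.raises(ValueError, match="ranked associates"):
        make_features(r, att, k=5)
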