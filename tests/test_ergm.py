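"""ERGM statistics, change statistics, sampler and Robbins-Monro fitting."""

import networkx as nx
import numpy as np
import pytest

from raidnet.ergm import (
    ErgmSpec,
    change_statistics,
    evaluate_statistics,
    fit_robbins_monro,
    gof_tratios,
    sample_networks,
)
from raidnet.logistic import fit_logistic

ALL_STATS = (
    "arc",
    "reciprocity",
    "AinS",
    "AT_T",
    "AinAoutS",
    "OneInAoutS",
    "AinOneOutS",
    "source",
    "abs_diff:age",
    "match:raider",
    "reciprocal_match:raider",
)


def rand_attrs(rng, n):
    return {
        "age": rng.integers(10, 50, n).astype(float),
        "raider": rng.integers(0, 2, n).astype(float),
    }


def test_spec_validation():
    with pytest.raises(ValueError, match="lam"):
        ErgmSpec(("arc",), lam=0.5)
    with pytest.raises(ValueError, match="unknown"):
        ErgmSpec(("arcs",))
    with pytest.raises(ValueError, match="attribute binding"):
        ErgmSpec(("match",))


def test_statistics_on_empty_graph_are_zero(rng):
    spec = ErgmSpec(ALL_STATS)
    z = evaluate_statistics(np.zeros((6, 6), dtype=int), spec, rand_attrs(rng, 6))
    assert np.allclose(z, 0.0)


def test_statistics_single_arc():
    spec = ErgmSpec(("arc", "reciprocity", "abs_diff:age", "source"))
    a = np.zeros((3, 3), dtype=int)
    a[0, 1] = 1
    z = evaluate_statistics(a, spec, {"age": np.array([30.0, 37.0, 20.0])})
    assert z.tolist() == [1.0, 0.0, 7.0, 1.0]


def test_transitive_triangle_statistic_with_damping_two():
    # arcs 0->1, 1->2 and the closing arc 0->2: L2(0,2)=1, so the closing
    # arc contributes lam * (1 - (1-1/lam)^1) = 1 at lam=2
    a = np.zeros((3, 3), dtype=int)
    a[0, 1] = a[1, 2] = 1
    spec = ErgmSpec(("AT_T",), lam=2.0)
    base = evaluate_statistics(a, spec)
    a2 = a.copy()
    a2[0, 2] = 1
    closed = evaluate_statistics(a2, spec)
    assert base[0] == 0.0
    assert closed[0] - base[0] == pytest.approx(1.0)


def test_reciprocity_counts_unordered_dyads():
    a = np.zeros((3, 3), dtype=int)
    a[0, 1] = a[1, 0] = a[1, 2] = 1
    z = evaluate_statistics(a, ErgmSpec(("reciprocity",)))
    assert z[0] == 1.0


def test_alternating_in_star_form():
    # one node with in-degree 3: AinS = lam^2 [(1-1/lam)^3 - 1 + 3/lam]
    a = np.zeros((4, 4), dtype=int)
    a[1, 0] = a[2, 0] = a[3, 0] = 1
    z = evaluate_statistics(a, ErgmSpec(("AinS",), lam=2.0))
    assert z[0] == pytest.approx(4 * ((0.5) ** 3 - 1 + 1.5))


@pytest.mark.parametrize("trial", range(12))
def test_change_statistics_match_full_recomputation(trial):
    """Incremental delta z equals z(after) - z(before) for every statistic."""
    rng = np.random.default_rng(1000 + trial)
    n = int(rng.integers(5, 12))
    a = (rng.random((n, n)) < 0.35).astype(np.int8)
    np.fill_diagonal(a, 0)
    attrs = rand_attrs(rng, n)
    spec = ErgmSpec(ALL_STATS)
    i, j = rng.integers(0, n, 2)
    while i == j:
        i, j = rng.integers(0, n, 2)
    dz = change_statistics(a, spec, (int(i), int(j)), attrs)
    a2 = a.copy()
    a2[i, j] ^= 1
    full = evaluate_statistics(a2, spec, attrs) - evaluate_statistics(a, spec, attrs)
    assert np.allclose(dz, full)


def test_change_statistics_trivial_cases():
    a = np.zeros((4, 4), dtype=int)
    a[1, 0] = 1
    spec = ErgmSpec(("arc", "reciprocity"))
    dz = change_statistics(a, spec, (0, 1))
    assert dz.tolist() == [1.0, 1.0]  # adding 0->1 reciprocates 1->0
    with pytest.raises(ValueError, match="self-loops"):
        change_statistics(a, spec, (1, 1))


def test_sampler_bernoulli_half_at_theta_zero():
    out = sample_networks(ErgmSpec(("arc",)), np.array([0.0]), 12, n_samples=80, seed=0)
    dens = out["z"].mean() / (12 * 11)
    assert dens == pytest.approx(0.5, abs=0.03)


def test_sampler_matches_closed_form_bernoulli_ergm():
    # arc-only theta: density = logit^-1(theta), independent arcs
    theta = -2.0
    out = sample_networks(ErgmSpec(("arc",)), np.array([theta]), 14, n_samples=100, seed=1)
    dens = out["z"].mean() / (14 * 13)
    assert dens == pytest.approx(1 / (1 + np.exp(2.0)), abs=0.015)


def test_positive_reciprocity_parameter_raises_mutuality():
    spec = ErgmSpec(("arc", "reciprocity"))
    base = sample_networks(spec, np.array([-1.5, 0.0]), 14, n_samples=60, seed=2)
    recip = sample_networks(spec, np.array([-1.5, 2.0]), 14, n_samples=60, seed=2)
    assert recip["z"][:, 1].mean() > base["z"][:, 1].mean() * 1.5


def test_sampler_deterministic_under_seed():
    spec = ErgmSpec(("arc", "AT_T"))
    a = sample_networks(spec, np.array([-1.0, 0.3]), 10, n_samples=20, seed=5)
    b = sample_networks(spec, np.array([-1.0, 0.3]), 10, n_samples=20, seed=5)
    c = sample_networks(spec, np.array([-1.0, 0.3]), 10, n_samples=20, seed=6)
    assert np.array_equal(a["z"], b["z"])
    assert not np.array_equal(a["z"], c["z"])


def test_arc_only_fit_recovers_logit_of_density(rng):
    n = 20
    a = (rng.random((n, n)) < 0.18).astype(np.int8)
    np.fill_diagonal(a, 0)
    dens = a.sum() / (n * (n - 1))
    fit = fit_robbins_monro(
        a, ErgmSpec(("arc",)), seed=3, phase3_samples=400, return_graphs=False
    )
    target = np.log(dens / (1 - dens))
    assert fit.converged
    assert abs(fit.theta[0] - target) <= 2 * fit.se[0]


def test_dyad_independent_fit_matches_logistic_oracle(rng):
    """With arc + dyadic covariate only, the ERGM MLE is the logistic
    regression of arc indicators on the covariate; the stochastic fit must
    agree within its own simulation error."""
    n = 18
    ages = rng.integers(10, 50, n).astype(float)
    diff = np.abs(ages[:, None] - ages[None, :])
    beta = np.array([0.5, -0.08])
    p = 1 / (1 + np.exp(-(beta[0] + beta[1] * diff)))
    a = (rng.random((n, n)) < p).astype(np.int8)
    np.fill_diagonal(a, 0)
    mask = ~np.eye(n, dtype=bool)
    oracle = fit_logistic(
        np.column_stack([np.ones(mask.sum()), diff[mask]]), a[mask].astype(float)
    )
    spec = ErgmSpec(("arc", "abs_diff:age"))
    fit = fit_robbins_monro(
        a, spec, attributes={"age": ages}, seed=4,
        phase2_subphases=5, phase3_samples=600, return_graphs=False,
    )
    assert np.all(np.abs(fit.theta - oracle.params) <= 2.5 * fit.se)


def test_degenerate_saturated_graph_flagged():
    """A complete graph pins the sampler to a zero-variance corner of the
    statistic space, the classic ERGM degeneracy; the fit must be flagged."""
    n = 12
    a = np.ones((n, n), dtype=np.int8)
    np.fill_diagonal(a, 0)
    spec = ErgmSpec(("arc", "AT_T"))
    fit = fit_robbins_monro(
        a, spec, seed=5, phase1_samples=30, phase3_samples=100,
        max_restarts=0, return_graphs=False,
    )
    assert not fit.converged


def test_gof_tratios_fitted_and_alias(rng):
    n = 16
    a = (rng.random((n, n)) < 0.15).astype(np.int8)
    np.fill_diagonal(a, 0)
    attrs = rand_attrs(rng, n)
    fit = fit_robbins_monro(
        a, ErgmSpec(("arc",)), attributes=attrs, seed=6, phase3_samples=300
    )
    assert fit.converged
    gof = gof_tratios(fit, ErgmSpec(("arc", "reciprocity", "match:raider")))
    # the fitted statistic keeps its small t-ratio under the alias
    assert abs(gof["t_ratios"][0]) == pytest.approx(abs(fit.tratios[0]), abs=1e-9)
    # a well-specified Bernoulli graph: un-modelled statistics also close
    assert np.all(np.abs(gof["t_ratios"]) < 3)


def test_homophily_statistics_have_interpretable_signs(rng):
    """Planted status homophily gives theta_match > 0; planted age mixing
    by proximity gives theta_absdiff < 0."""
    n = 24
    attrs = rand_attrs(rng, n)
    spec = ErgmSpec(("arc", "match:raider", "abs_diff:age"))
    theta_true = np.array([-1.2, 1.2, -0.06])
    sim = sample_networks(spec, theta_true, n, attributes=attrs,
                          n_samples=1, burn_in=50 * n * n, seed=7)
    fit = fit_robbins_monro(
        sim["final"], spec, attributes=attrs, seed=8,
        phase3_samples=400, return_graphs=False,
    )
    assert fit.theta[1] > 0
    assert fit.theta[2] < 0
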