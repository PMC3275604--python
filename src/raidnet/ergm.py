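"""Directed binary exponential random graph models (ERGMs).

The model places probability  Pr(X = x) = (1/kappa) exp(theta . z(x))  on
directed simple graphs x over a fixed node set, where z(x) is a vector of
configuration counts.  Supported statistics (lambda is the geometric damping
of the alternating forms, default 2):

=================  ========================================================
``arc``            number of arcs, sum x_ij
``reciprocity``    mutual dyads, sum_{i<j} x_ij x_ji
``AinS``           alternating in-star: sum_i lam^2 [(1-1/lam)^din_i - 1
                   + din_i/lam]
``AT_T``           alternating transitive triangle: sum over arcs (i,j) of
                   lam [1 - (1-1/lam)^L2(i,j)], L2(i,j) = #two-paths i->k->j
``AinAoutS``       sum_i g(din_i) g(dout_i),  g(d) = lam [1-(1-1/lam)^d]
``OneInAoutS``     sum_i 1{din_i >= 1} g(dout_i)
``AinOneOutS``     sum_i g(din_i) 1{dout_i >= 1}
``source``         nodes with out-arcs but no in-arcs
``abs_diff:attr``  sum over arcs of |a_i - a_j| (age proximity when fitted
                   negative)
``match:attr``     sum over arcs of 1{a_i == a_j} (trait homophily)
``reciprocal_match:attr``  mutual dyads with matching trait
=================  ========================================================

Estimation is MCMC maximum likelihood by stochastic approximation
(Robbins-Monro): networks are simulated from the current parameters by
Metropolis single-arc toggles and the parameters are nudged against the
difference between simulated and observed statistics.  Convergence is
declared when every fitted statistic's t-ratio — (mean simulated minus
observed) over the simulated standard deviation — is below 0.1 in absolute
value; standard errors come from the inverse covariance of the statistics
over the final simulated sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "ErgmSpec",
    "ErgmFit",
    "ErgmState",
    "graph_to_adjacency",
    "evaluate_statistics",
    "change_statistics",
    "sample_networks",
    "fit_robbins_monro",
    "gof_tratios",
]

_KNOWN = {
    "arc",
    "reciprocity",
    "AinS",
    "AT_T",
    "AinAoutS",
    "OneInAoutS",
    "AinOneOutS",
    "source",
    "abs_diff",
    "match",
    "reciprocal_match",
}


@dataclass(frozen=True)
class ErgmSpec:
    """Ordered statistic list, e.g. ('arc', 'reciprocity', 'match:raider').

    Covariate statistics carry their node attribute after a colon.  ``lam``
    is the damping of the alternating statistics and must be >= 1.
    """

    stats: tuple
    lam: float = 2.0

    def __post_init__(self) -> None:
        if self.lam < 1:
            raise ValueError("lam must be >= 1")
        for s in self.stats:
            base = s.split(":")[0]
            if base not in _KNOWN:
                raise ValueError(f"unknown statistic {s!r}")
            if base in ("abs_diff", "match", "reciprocal_match") and ":" not in s:
                raise ValueError(f"{s!r} needs an attribute binding, e.g. '{s}:age'")

    @property
    def p(self) -> int:
        return len(self.stats)


def graph_to_adjacency(g: nx.DiGraph, attr_names: tuple = ()) -> tuple:
    """(adjacency int8 array, node order, {attr: float array}) from a DiGraph."""
    nodes = sorted(g.nodes, key=str)
    a = nx.to_numpy_array(g, nodelist=nodes, dtype=np.int8)
    np.fill_diagonal(a, 0)
    attrs = {}
    for name in attr_names:
        attrs[name] = np.array([g.nodes[v][name] for v in nodes], dtype=float)
    return a, nodes, attrs


def _required_attrs(spec: ErgmSpec) -> list:
    out = []
    for s in spec.stats:
        if ":" in s:
            out.append(s.split(":", 1)[1])
    return out


def _g_table(lam: float, n: int) -> np.ndarray:
    d = np.arange(n + 2)
    return lam * (1.0 - (1.0 - 1.0 / lam) ** d)


def _h_table(lam: float, n: int) -> np.ndarray:
    d = np.arange(n + 2)
    return lam**2 * ((1.0 - 1.0 / lam) ** d - 1.0 + d / lam)


def evaluate_statistics(
    graph, spec: ErgmSpec, attributes: dict | None = None
) -> np.ndarray:
    """Full (non-incremental) statistic vector z(x) of a directed graph.

    ``graph`` is a DiGraph or a 0/1 adjacency array; ``attributes`` maps
    attribute names to node-aligned arrays (read off the DiGraph's node
    attributes when omitted).
    """
    if isinstance(graph, nx.DiGraph):
        a, _, attrs = graph_to_adjacency(graph, tuple(_required_attrs(spec)))
        attributes = attributes or attrs
    else:
        a = np.asarray(graph)
        attributes = attributes or {}
    for name in _required_attrs(spec):
        if name not in attributes:
            raise KeyError(f"missing node attribute {name!r}")
    a = a.astype(np.int64)
    n = a.shape[0]
    din = a.sum(axis=0)
    dout = a.sum(axis=1)
    gt = _g_table(spec.lam, n)
    ht = _h_table(spec.lam, n)
    l2 = a @ a  # l2[i, j] = number of two-paths i -> k -> j

    z = np.empty(spec.p)
    for idx, s in enumerate(spec.stats):
        base, _, attr = s.partition(":")
        if base == "arc":
            z[idx] = a.sum()
        elif base == "reciprocity":
            z[idx] = (a * a.T).sum() / 2
        elif base == "AinS":
            z[idx] = ht[din].sum()
        elif base == "AT_T":
            z[idx] = (a * gt[l2]).sum()
        elif base == "AinAoutS":
            z[idx] = (gt[din] * gt[dout]).sum()
        elif base == "OneInAoutS":
            z[idx] = ((din >= 1) * gt[dout]).sum()
        elif base == "AinOneOutS":
            z[idx] = (gt[din] * (dout >= 1)).sum()
        elif base == "source":
            z[idx] = int(np.sum((dout >= 1) & (din == 0)))
        elif base == "abs_diff":
            v = attributes[attr]
            z[idx] = (a * np.abs(v[:, None] - v[None, :])).sum()
        elif base == "match":
            v = attributes[attr]
            z[idx] = (a * (v[:, None] == v[None, :])).sum()
        elif base == "reciprocal_match":
            v = attributes[attr]
            z[idx] = ((a * a.T) * (v[:, None] == v[None, :])).sum() / 2
    return z


class ErgmState:
    """Mutable sampler state: adjacency, degrees, two-path counts, z(x).

    Change statistics for a single-arc toggle are O(n); applying a toggle
    updates the two-path matrix incrementally so the statistic vector is
    always current.
    """

    def __init__(self, a: np.ndarray, spec: ErgmSpec, attributes: dict | None = None):
        self.spec = spec
        self.a = np.array(a, dtype=np.int8)
        np.fill_diagonal(self.a, 0)
        self.n = self.a.shape[0]
        self.din = self.a.sum(axis=0).astype(np.int64)
        self.dout = self.a.sum(axis=1).astype(np.int64)
        self.l2 = (self.a.astype(np.int64) @ self.a.astype(np.int64)).astype(np.int64)
        self.attributes = attributes or {}
        self.gt = _g_table(spec.lam, self.n)
        self.ht = _h_table(spec.lam, self.n)
        self.z = evaluate_statistics(self.a, spec, self.attributes)
        # pre-split spec for the hot loop
        self._parsed = [s.partition(":")[::2] for s in spec.stats]

    def delta(self, i: int, j: int) -> np.ndarray:
        """Change in z from toggling arc i->j (without applying it)."""
        a, gt, ht = self.a, self.gt, self.ht
        d = 1 - 2 * int(a[i, j])
        din_j, dout_i = int(self.din[j]), int(self.dout[i])
        out = np.empty(self.spec.p)
        for idx, (base, attr) in enumerate(self._parsed):
            if base == "arc":
                out[idx] = d
            elif base == "reciprocity":
                out[idx] = d * int(a[j, i])
            elif base == "AinS":
                out[idx] = ht[din_j + d] - ht[din_j]
            elif base == "AT_T":
                own = d * gt[self.l2[i, j]]
                # arcs (i, k) gaining/losing the two-path i->j->k
                mask_ik = (a[i, :] & a[j, :]).astype(bool)
                l2ik = self.l2[i, mask_ik]
                side1 = (gt[l2ik + d] - gt[l2ik]).sum()
                # arcs (k, j) gaining/losing the two-path k->i->j
                mask_kj = (a[:, j] & a[:, i]).astype(bool)
                l2kj = self.l2[mask_kj, j]
                side2 = (gt[l2kj + d] - gt[l2kj]).sum()
                out[idx] = own + side1 + side2
            elif base == "AinAoutS":
                out[idx] = (gt[dout_i + d] - gt[dout_i]) * gt[self.din[i]] + (
                    gt[din_j + d] - gt[din_j]
                ) * gt[self.dout[j]]
            elif base == "OneInAoutS":
                out[idx] = (self.din[i] >= 1) * (gt[dout_i + d] - gt[dout_i]) + (
                    float(din_j + d >= 1) - float(din_j >= 1)
                ) * gt[self.dout[j]]
            elif base == "AinOneOutS":
                out[idx] = (gt[din_j + d] - gt[din_j]) * float(self.dout[j] >= 1) + gt[
                    self.din[i]
                ] * (float(dout_i + d >= 1) - float(dout_i >= 1))
            elif base == "source":
                before_i = (dout_i >= 1) and (self.din[i] == 0)
                after_i = (dout_i + d >= 1) and (self.din[i] == 0)
                before_j = (self.dout[j] >= 1) and (din_j == 0)
                after_j = (self.dout[j] >= 1) and (din_j + d == 0)
                out[idx] = (int(after_i) - int(before_i)) + (int(after_j) - int(before_j))
            elif base == "abs_diff":
                v = self.attributes[attr]
                out[idx] = d * abs(v[i] - v[j])
            elif base == "match":
                v = self.attributes[attr]
                out[idx] = d * float(v[i] == v[j])
            elif base == "reciprocal_match":
                v = self.attributes[attr]
                out[idx] = d * int(a[j, i]) * float(v[i] == v[j])
        return out

    def apply(self, i: int, j: int, dz: np.ndarray) -> None:
        """Commit a toggle whose change vector ``dz`` was already computed."""
        d = 1 - 2 * int(self.a[i, j])
        self.a[i, j] ^= 1
        self.dout[i] += d
        self.din[j] += d
        # two-paths through the toggled arc
        self.l2[i, :] += d * self.a[j, :]
        self.l2[:, j] += d * self.a[:, i]
        self.z = self.z + dz

    def density(self) -> float:
        return float(self.a.sum()) / (self.n * (self.n - 1))


def change_statistics(
    graph, spec: ErgmSpec, toggle: tuple, attributes: dict | None = None
) -> np.ndarray:
    """Delta z for flipping one arc: z(x with x_ij toggled) - z(x)."""
    i, j = toggle
    if i == j:
        raise ValueError("self-loops are not modelled")
    if isinstance(graph, nx.DiGraph):
        a, nodes, attrs = graph_to_adjacency(graph, tuple(_required_attrs(spec)))
        attributes = attributes or attrs
        i, j = nodes.index(i), nodes.index(j)
    else:
        a = np.asarray(graph)
    return ErgmState(a, spec, attributes).delta(i, j)


def _metropolis(
    state: ErgmState, theta: np.ndarray, n_steps: int, rng: np.random.Generator
) -> None:
    """Advance the chain by ``n_steps`` uniform single-arc toggle proposals."""
    n = state.n
    ii = rng.integers(0, n, size=n_steps)
    jj = rng.integers(0, n - 1, size=n_steps)
    jj = jj + (jj >= ii)  # uniform over ordered pairs i != j
    logu = np.log(rng.random(n_steps))
    for t in range(n_steps):
        i, j = int(ii[t]), int(jj[t])
        dz = state.delta(i, j)
        if float(theta @ dz) >= logu[t]:
            state.apply(i, j, dz)


def sample_networks(
    spec: ErgmSpec,
    theta: np.ndarray,
    n_nodes: int,
    attributes: dict | None = None,
    n_samples: int = 100,
    burn_in: int | None = None,
    thin: int | None = None,
    seed: int = 0,
    init: np.ndarray | None = None,
    return_graphs: bool = False,
) -> dict:
    """Simulate networks from an ERGM by Metropolis single-arc toggles.

    Acceptance probability for toggling x_ij is min(1, exp(theta . dz)).
    Defaults: burn-in 20 n^2 proposals, thinning 5 n^2 between samples.
    Returns {'z': (n_samples, p) statistics, 'graphs': list of adjacency
    arrays (if requested), 'final': final adjacency}.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (spec.p,):
        raise ValueError("theta must align with spec.stats")
    burn_in = 20 * n_nodes**2 if burn_in is None else burn_in
    thin = 5 * n_nodes**2 if thin is None else thin
    rng = np.random.default_rng(seed)
    a0 = np.zeros((n_nodes, n_nodes), dtype=np.int8) if init is None else init
    state = ErgmState(a0, spec, attributes)
    _metropolis(state, theta, burn_in, rng)
    zs = np.empty((n_samples, spec.p))
    graphs = []
    for s in range(n_samples):
        _metropolis(state, theta, thin, rng)
        zs[s] = state.z
        if return_graphs:
            graphs.append(state.a.copy())
    return {"z": zs, "graphs": graphs, "final": state.a.copy()}


@dataclass
class ErgmFit:
    """Robbins-Monro fit: estimates, SEs, convergence t-ratios, diagnostics."""

    spec: ErgmSpec
    theta: np.ndarray
    se: np.ndarray
    tratios: np.ndarray
    z_obs: np.ndarray
    z_sim: np.ndarray           # phase-3 statistic sample
    converged: bool
    n_restarts: int
    observed_adjacency: np.ndarray = field(repr=False, default=None)
    attributes: dict = field(repr=False, default=None)
    sim_graphs: list = field(repr=False, default=None)

    @property
    def pvalues(self) -> np.ndarray:
        """Two-sided normal-approximation p-values from the simulated SEs."""
        from scipy import stats

        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(self.se > 0, self.theta / self.se, np.inf)
        return 2 * stats.norm.sf(np.abs(z))

    def summary(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "estimate": self.theta,
                "se": self.se,
                "t_ratio": self.tratios,
                "p": self.pvalues,
            },
            index=list(self.spec.stats),
        )


def fit_robbins_monro(
    graph,
    spec: ErgmSpec,
    attributes: dict | None = None,
    seed: int = 0,
    phase1_samples: int = 100,
    phase2_subphases: int = 4,
    phase2_base_gain: float = 0.25,
    phase2_steps: int | None = None,
    phase3_samples: int = 1000,
    burn_in: int | None = None,
    thin: int | None = None,
    max_restarts: int = 3,
    return_graphs: bool = True,
) -> ErgmFit:
    """MCMC maximum likelihood by the Robbins-Monro stochastic approximation.

    Phase 1 simulates at the starting values (arc parameter at the logit of
    the observed density, all others zero) to estimate the statistic
    covariance D used as a scaling matrix.  Phase 2 runs ``phase2_subphases``
    sub-phases of (7 + 2^k) p iterations each, updating

        theta <- theta - a_k D^-1 (z(X_t) - z_obs)

    with the gain a_k halved between sub-phases and the chain advanced
    between updates.  Phase 3 simulates ``phase3_samples`` networks at the
    final estimate for the convergence t-ratios and the standard errors
    (square roots of the diagonal of the inverse statistic covariance).
    The whole schedule restarts from the current estimate, up to
    ``max_restarts`` times, if any fitted |t-ratio| is >= 0.1.
    """
    if isinstance(graph, nx.DiGraph):
        a_obs, _, attrs = graph_to_adjacency(graph, tuple(_required_attrs(spec)))
        attributes = attributes or attrs
    else:
        a_obs = np.asarray(graph, dtype=np.int8)
        attributes = attributes or {}
    n = a_obs.shape[0]
    p = spec.p
    burn_in = 10 * n * n if burn_in is None else burn_in
    thin = n * n if thin is None else thin
    phase2_steps = max(n * n // 2, 50) if phase2_steps is None else phase2_steps

    z_obs = evaluate_statistics(a_obs, spec, attributes)
    theta = np.zeros(p)
    if "arc" in spec.stats:
        dens = np.clip(a_obs.sum() / (n * (n - 1)), 1e-6, 1 - 1e-6)
        theta[list(spec.stats).index("arc")] = np.log(dens / (1 - dens))

    rng = np.random.default_rng(seed)
    fit = None
    for attempt in range(max_restarts + 1):
        # ---- phase 1: scaling matrix at the current theta
        state = ErgmState(a_obs, spec, attributes)
        _metropolis(state, theta, burn_in, rng)
        z1 = np.empty((phase1_samples, p))
        for s in range(phase1_samples):
            _metropolis(state, theta, thin, rng)
            z1[s] = state.z
        d_mat = np.cov(z1.T) if p > 1 else np.atleast_2d(np.var(z1.T))
        d_inv = np.linalg.pinv(d_mat + 1e-8 * np.eye(p) * max(np.trace(d_mat) / p, 1.0))

        # ---- phase 2: stochastic approximation
        gain = phase2_base_gain
        for k in range(phase2_subphases):
            # sub-phase length grows geometrically; the floor keeps short
            # parameter vectors from under-iterating
            n_iter = (7 + 2 ** (k + 1)) * max(p, 4)
            for _ in range(n_iter):
                _metropolis(state, theta, phase2_steps, rng)
                step = gain * (d_inv @ (state.z - z_obs))
                norm = np.linalg.norm(step)
                if norm > 1.0:  # guard against early-phase blowups
                    step *= 1.0 / norm
                theta = theta - step
            gain *= 0.5

        # ---- phase 3: convergence check and standard errors
        state = ErgmState(a_obs, spec, attributes)
        _metropolis(state, theta, burn_in, rng)
        z3 = np.empty((phase3_samples, p))
        graphs = [] if return_graphs else None
        for s in range(phase3_samples):
            _metropolis(state, theta, thin, rng)
            z3[s] = state.z
            if return_graphs:
                graphs.append(state.a.copy())
        sd = z3.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            tratios = np.where(sd > 0, (z3.mean(axis=0) - z_obs) / sd, np.inf)
        cov = np.cov(z3.T) if p > 1 else np.atleast_2d(np.var(z3.T))
        theta_cov = np.linalg.pinv(cov + 1e-10 * np.eye(p))
        se = np.sqrt(np.clip(np.diag(theta_cov), 0, None))
        converged = bool(np.all(np.abs(tratios) < 0.1))
        fit = ErgmFit(
            spec=spec,
            theta=theta.copy(),
            se=se,
            tratios=tratios,
            z_obs=z_obs,
            z_sim=z3,
            converged=converged,
            n_restarts=attempt,
            observed_adjacency=a_obs,
            attributes=attributes,
            sim_graphs=graphs,
        )
        if converged:
            break
    return fit


def gof_tratios(fit: ErgmFit, extra_spec: ErgmSpec) -> dict:
    """Goodness-of-fit t-ratios for statistics not used in fitting.

    Evaluates ``extra_spec``'s statistics on the phase-3 simulated networks
    and compares with the observed graph: t = (mean sim - obs) / sd(sim).
    Absolute values below 1 indicate the fitted model also reproduces these
    un-modelled features.
    """
    if fit.sim_graphs is None:
        raise ValueError("fit was run with return_graphs=False")
    z_obs = evaluate_statistics(fit.observed_adjacency, extra_spec, fit.attributes)
    zs = np.array(
        [evaluate_statistics(a, extra_spec, fit.attributes) for a in fit.sim_graphs]
    )
    sd = zs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, (zs.mean(axis=0) - z_obs) / sd, np.inf)
    return {
        "stats": list(extra_spec.stats),
        "t_ratios": t,
        "z_obs": z_obs,
        "z_sim_mean": zs.mean(axis=0),
    }
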