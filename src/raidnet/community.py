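"""Community structure: Girvan-Newman detection, modularity nulls, and
cluster-composition permutation tests.

The directed closest-associate network is symmetrized (an arc in either
direction becomes an undirected edge; reciprocal arcs collapse to one edge)
before community detection, since Newman's modularity

    Q = sum_c [ m_c / m  -  (d_c / 2m)^2 ]

is defined for undirected graphs (m edges, m_c intra-cluster edges, d_c the
total degree of cluster c).  Girvan-Newman repeatedly removes the edge with
the highest betweenness; among the nested component partitions produced
along the way, the one maximizing Q is returned.

Whether the detected clusters are enriched or depleted in a node attribute
(proportion of raiders, mean age) is assessed by permuting attribute values
across individuals while holding cluster sizes constant; two-sided
"at least as extreme" is operationalized as absolute deviation from the
null mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Partition",
    "CompositionTestResult",
    "symmetrize",
    "modularity",
    "girvan_newman",
    "modularity_null",
    "cluster_composition_test",
]


@dataclass
class Partition:
    """Cluster label per node (labels contiguous 0..K-1) and its modularity."""

    labels: dict
    q: float

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))

    def communities(self) -> list:
        out: dict = {}
        for node, lab in self.labels.items():
            out.setdefault(lab, set()).add(node)
        return [out[k] for k in sorted(out)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.labels.items()), columns=["male_id", "cluster"]
        )


def symmetrize(g: nx.DiGraph) -> nx.Graph:
    """Undirected view: edge {i, j} iff i->j or j->i (multiplicity dropped)."""
    u = nx.Graph()
    u.add_nodes_from(g.nodes(data=True))
    u.add_edges_from((i, j) for i, j in g.edges if i != j)
    return u


def _as_undirected(g) -> nx.Graph:
    return symmetrize(g) if g.is_directed() else g


def modularity(g, labels: dict) -> float:
    """Newman modularity Q of a labelled partition of an undirected graph."""
    u = _as_undirected(g)
    if u.number_of_edges() == 0:
        raise ValueError("modularity undefined on a graph with no edges")
    comms: dict = {}
    for node, lab in labels.items():
        comms.setdefault(lab, set()).add(node)
    return float(nx.community.modularity(u, comms.values()))


def _components_partition(u: nx.Graph) -> dict:
    labels = {}
    for k, comp in enumerate(
        sorted(nx.connected_components(u), key=lambda c: sorted(c)[0] if c else "")
    ):
        for node in comp:
            labels[node] = k
    return labels


def girvan_newman(g) -> Partition:
    """Girvan-Newman divisive clustering, returning the max-Q partition.

    Edges are removed one at a time in order of highest edge betweenness,
    ties broken by lexicographic edge id for determinism; every intermediate
    connected-component partition (including the starting one) is scored by
    Q and the best is returned.
    """
    u = _as_undirected(g).copy()
    if u.number_of_edges() == 0:
        raise ValueError("Girvan-Newman needs at least one edge")
    full = u.copy()
    best_labels = _components_partition(u)
    best_q = modularity(full, best_labels)
    while u.number_of_edges() > 0:
        eb = nx.edge_betweenness_centrality(u)
        # deterministic: highest betweenness, then lexicographically first edge
        edge = min(eb, key=lambda e: (-eb[e], tuple(sorted(map(str, e)))))
        u.remove_edge(*edge)
        labels = _components_partition(u)
        q = modularity(full, labels)
        if q > best_q + 1e-12:
            best_q, best_labels = q, labels
    return Partition(labels=best_labels, q=best_q)


def modularity_null(
    g,
    n_reps: int = 1000,
    seed: int = 0,
    degree_preserving: bool = False,
) -> dict:
    """Null distribution of max-Q under random graphs with the same n and m.

    Each replicate draws a uniform simple graph with the observed node and
    edge counts (or, with ``degree_preserving``, rewires the observed graph
    by double-edge swaps), runs Girvan-Newman, and records its Q.  The
    p-value is the proportion of replicate Q at least as large as observed.
    """
    u = _as_undirected(g)
    n, m = u.number_of_nodes(), u.number_of_edges()
    obs = girvan_newman(u)
    rng = np.random.default_rng(seed)
    qs = np.empty(n_reps)
    for r in range(n_reps):
        if degree_preserving:
            rep = u.copy()
            rep = nx.relabel_nodes(rep, {v: i for i, v in enumerate(sorted(rep.nodes, key=str))})
            nx.double_edge_swap(
                rep, nswap=4 * m, max_tries=100 * m,
                seed=int(rng.integers(2**31 - 1)),
            )
        else:
            rep = nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31 - 1)))
        qs[r] = girvan_newman(rep).q
    return {
        "q_obs": obs.q,
        "null_q": qs,
        "null_mean": float(qs.mean()),
        "null_sd": float(qs.std(ddof=1)),
        "p": float(np.mean(qs >= obs.q)),
        "partition": obs,
    }


@dataclass
class CompositionTestResult:
    """Per-cluster observed statistic vs its shuffle-across-clusters null."""

    statistic: str
    n_reps: int
    seed: int
    table: pd.DataFrame  # columns: cluster, size, observed, null_mean, null_se, p

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def cluster_composition_test(
    labels: dict | np.ndarray,
    values: dict | np.ndarray,
    statistic: str = "proportion",
    n_reps: int = 1000,
    seed: int = 0,
) -> CompositionTestResult:
    """Permutation test of cluster composition with cluster sizes held fixed.

    Parameters
    ----------
    labels : cluster label per individual (dict keyed like ``values`` or an
        array aligned with it).
    values : the node attribute (binary for ``statistic='proportion'``, any
        numeric for ``'mean'``).
    statistic : 'proportion' (of ones) or 'mean' per cluster.

    Each of ``n_reps`` replicates permutes the attribute values across all
    individuals (cluster sizes constant by construction) and recomputes the
    per-cluster statistic.  The two-sided p-value for cluster c is the
    proportion of replicates with |stat_rep - null_mean| >= |stat_obs -
    null_mean|.
    """
    if isinstance(labels, dict):
        keys = sorted(labels, key=str)
        lab = np.array([labels[k] for k in keys])
        vals = np.array([values[k] for k in keys], dtype=float)
    else:
        lab = np.asarray(labels)
        vals = np.asarray(values, dtype=float)
    if len(lab) != len(vals):
        raise ValueError("labels and values must align")
    clusters, inverse = np.unique(lab, return_inverse=True)
    sizes = np.bincount(inverse)
    if (sizes == 0).any():
        raise ValueError("empty cluster")
    if statistic == "proportion" and not np.isin(vals, (0.0, 1.0)).all():
        raise ValueError("'proportion' statistic requires a binary attribute")
    if statistic not in ("proportion", "mean"):
        raise ValueError(f"unknown statistic {statistic!r}")

    k = len(clusters)
    # one-hot divided by size: stat vector = M @ values
    M = np.zeros((k, len(vals)))
    M[inverse, np.arange(len(vals))] = 1.0
    M /= sizes[:, None]
    observed = M @ vals

    rng = np.random.default_rng(seed)
    reps = np.empty((n_reps, k))
    for r in range(n_reps):
        reps[r] = M @ vals[rng.permutation(len(vals))]

    null_mean = reps.mean(axis=0)
    null_se = reps.std(axis=0, ddof=1) / np.sqrt(n_reps)
    dev_obs = np.abs(observed - null_mean)
    p = (np.abs(reps - null_mean) >= dev_obs[None, :] - 1e-12).mean(axis=0)

    table = pd.DataFrame(
        {
            "cluster": clusters,
            "size": sizes,
            "observed": observed,
            "null_mean": null_mean,
            "null_se": null_se,
            "p": p,
        }
    )
    return CompositionTestResult(
        statistic=statistic, n_reps=n_reps, seed=seed, table=table
    )
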