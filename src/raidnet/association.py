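"""Association indices, associate ranks, and top-k networks from group sightings.

The workflow follows the "gambit of the group": every pair of individuals
recorded in the same sighting is taken to be associating.  Pairwise
association strength is the simple association ratio

    AI(A, B) = N_AB / (N_A + N_B + N_AB)

where ``N_AB`` is the number of sightings containing both A and B, and
``N_A`` (``N_B``) the number of sightings containing A without B (B without
A).  Each individual's associates are then rank-ordered by descending AI,
and a directed "closest associates" network is built by drawing an arc from
each focal male to his top-k ranked associates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "MaleRecord",
    "AssociationMatrix",
    "RankTable",
    "UndefinedPairError",
    "compute_ai",
    "build_association_matrix",
    "filter_focal_males",
    "rank_associates",
    "build_top_k_network",
    "make_features",
    "age_class",
    "AGE_CLASS_LABELS",
]

#: Life-history age classes (years): early dispersal, late dispersal,
#: first musth, ascent to reproductive prime, reproductive peak.
AGE_CLASS_BINS = [(10, 14), (15, 19), (20, 30), (31, 44), (45, np.inf)]
AGE_CLASS_LABELS = ["10-14", "15-19", "20-30", "31-44", "45+"]


class UndefinedPairError(ValueError):
    """Raised when an association index is requested for a never-sighted pair."""


@dataclass(frozen=True)
class MaleRecord:
    """One individual: identifier, age in whole years, binary raider status."""

    id: str
    age_years: int
    raider: int

    def __post_init__(self) -> None:
        if self.raider not in (0, 1):
            raise ValueError(f"raider must be 0 or 1, got {self.raider!r}")
        if self.age_years < 10:
            raise ValueError(f"age_years must be >= 10, got {self.age_years}")


def compute_ai(n_ab: int, n_a: int, n_b: int) -> float:
    """Simple association ratio AI = N_AB / (N_A + N_B + N_AB).

    ``n_ab`` counts sightings with both individuals present; ``n_a`` and
    ``n_b`` count sightings with exactly one of them.  All three zero means
    the pair was never observed at all, for which the index is undefined.
    """
    if min(n_ab, n_a, n_b) < 0:
        raise ValueError("sighting counts must be non-negative")
    denom = n_a + n_b + n_ab
    if denom == 0:
        raise UndefinedPairError("AI undefined: pair has no sightings at all")
    return n_ab / denom


@dataclass
class AssociationMatrix:
    """Pairwise co-sighting counts and association indices.

    Attributes
    ----------
    ids : list of str
        Individual identifiers, fixing the row/column order.
    n_together : (n, n) int array
        ``n_together[a, b]`` = number of sightings containing both a and b.
    totals : (n,) int array
        Total group sightings per individual; ``N_A`` for pair (A, B) is
        ``totals[a] - n_together[a, b]``.
    """

    ids: list
    n_together: np.ndarray
    totals: np.ndarray
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {m: i for i, m in enumerate(self.ids)}

    @property
    def n(self) -> int:
        return len(self.ids)

    def ai_matrix(self) -> np.ndarray:
        """Symmetric AI matrix with NaN on the diagonal.

        Pairs with no sightings at all (both totals zero) are NaN.
        """
        tot = self.totals.astype(float)
        denom = tot[:, None] + tot[None, :] - self.n_together
        with np.errstate(invalid="ignore", divide="ignore"):
            ai = np.where(denom > 0, self.n_together / denom, np.nan)
        np.fill_diagonal(ai, np.nan)
        return ai

    def ai(self, a: str, b: str) -> float:
        ia, ib = self._index[a], self._index[b]
        if ia == ib:
            raise UndefinedPairError("AI undefined on the diagonal")
        nab = int(self.n_together[ia, ib])
        return compute_ai(nab, int(self.totals[ia]) - nab, int(self.totals[ib]) - nab)

    def subset(self, keep: list) -> "AssociationMatrix":
        """Restrict the matrix to the given individuals (order preserved)."""
        idx = [self._index[m] for m in keep]
        return AssociationMatrix(
            ids=list(keep),
            n_together=self.n_together[np.ix_(idx, idx)].copy(),
            totals=self.totals[idx].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ai_matrix(), index=self.ids, columns=self.ids)


def _sighting_sets(sightings: pd.DataFrame) -> dict:
    """Collapse the long-format sightings table to {sighting_id: set of males}."""
    groups: dict = {}
    dup = sightings.duplicated(subset=["sighting_id", "male_id"])
    if dup.any():
        warnings.warn(
            f"collapsed {int(dup.sum())} duplicate (sighting_id, male_id) rows",
            stacklevel=3,
        )
    for sid, grp in sightings.groupby("sighting_id", sort=True):
        groups[sid] = set(grp["male_id"])
    return groups


def build_association_matrix(
    sightings: pd.DataFrame,
    attributes: pd.DataFrame,
    allow_singletons: bool = False,
) -> AssociationMatrix:
    """Count pairwise co-sightings from a long-format sightings table.

    Parameters
    ----------
    sightings : DataFrame with columns sighting_id, male_id (date optional).
    attributes : DataFrame with column male_id; defines the universe of ids.
    allow_singletons : if True, single-member sightings count toward the
        lone male's total (his ``N_A``) instead of being rejected.

    A group is a set: duplicate member rows are collapsed with a warning.
    Sightings of a single individual are dropped (groups are defined as two
    or more individuals) unless ``allow_singletons``.
    """
    ids = list(attributes["male_id"])
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate male_id in attributes")
    index = {m: i for i, m in enumerate(ids)}
    unknown = set(sightings["male_id"]) - set(ids)
    if unknown:
        raise ValueError(f"sightings contain male_ids absent from attributes: {sorted(unknown)}")

    n = len(ids)
    n_together = np.zeros((n, n), dtype=np.int64)
    totals = np.zeros(n, dtype=np.int64)
    for sid, members in _sighting_sets(sightings).items():
        if len(members) < 2 and not allow_singletons:
            warnings.warn(f"sighting {sid!r} has a single member; dropped", stacklevel=2)
            continue
        idx = np.fromiter((index[m] for m in members), dtype=np.int64)
        totals[idx] += 1
        if len(idx) >= 2:
            n_together[np.ix_(idx, idx)] += 1
    np.fill_diagonal(n_together, 0)
    return AssociationMatrix(ids=ids, n_together=n_together, totals=totals)


@dataclass
class RankTable:
    """Per-focal ordering of all other individuals by descending AI.

    ``order[f]`` is the full list of the other ids, rank 1 first.  Ties are
    broken by larger N_AB, then lexicographic id, so ranks are deterministic.
    """

    ids: list
    order: dict

    def rank_of(self, focal: str, other: str) -> int:
        return self.order[focal].index(other) + 1

    def top(self, focal: str, k: int) -> list:
        return self.order[focal][:k]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.ids:
            for r, other in enumerate(self.order[f], start=1):
                rows.append((f, r, other))
        return pd.DataFrame(rows, columns=["male_id", "rank", "associate_id"])


def rank_associates(matrix: AssociationMatrix) -> RankTable:
    """Rank every individual's associates 1..n-1 by descending AI."""
    if matrix.n < 2:
        raise ValueError("need at least two individuals to rank associates")
    ai = matrix.ai_matrix()
    ai = np.nan_to_num(ai, nan=0.0)
    order = {}
    for i, focal in enumerate(matrix.ids):
        others = [j for j in range(matrix.n) if j != i]
        others.sort(
            key=lambda j: (-ai[i, j], -matrix.n_together[i, j], matrix.ids[j])
        )
        order[focal] = [matrix.ids[j] for j in others]
    return RankTable(ids=list(matrix.ids), order=order)


def _top_positive(matrix: AssociationMatrix, ranks: RankTable, focal: str, m: int) -> list:
    """Focal's top-m associates restricted to positive AI (may be < m)."""
    out = []
    for other in ranks.order[focal]:
        ia, ib = matrix._index[focal], matrix._index[other]
        if matrix.n_together[ia, ib] > 0:
            out.append(other)
            if len(out) == m:
                break
        else:
            break  # ordering is by descending AI; zeros follow
    return out


def filter_focal_males(
    matrix: AssociationMatrix, min_sightings: int = 15, top_m: int = 2
) -> list:
    """Select focal males with reliable association estimates.

    An individual is retained only if (a) he has at least ``min_sightings``
    group sightings and (b) each of his ``top_m`` positive-AI associates
    (his "frequent associates") was himself sighted at least
    ``min_sightings`` times — otherwise his strongest associations involve
    under-sampled males and his own rank ordering is unreliable.  The rule
    is applied repeatedly until the retained set is stable (a single extra
    pass in practice, since condition (b) depends on raw sighting counts).
    Returns the retained ids in the matrix's order.
    """
    totals = dict(zip(matrix.ids, matrix.totals))
    ranks = rank_associates(matrix) if matrix.n >= 2 else None
    retained = {m for m in matrix.ids if totals[m] >= min_sightings}
    if ranks is not None:
        while True:
            dropped = set()
            for f in retained:
                top = _top_positive(matrix, ranks, f, top_m)
                if any(totals[a] < min_sightings for a in top):
                    dropped.add(f)
            if not dropped:
                break
            retained -= dropped
    if not retained:
        warnings.warn("focal-male filter retained no individuals", stacklevel=2)
    return [m for m in matrix.ids if m in retained]


def build_top_k_network(
    ranks: RankTable,
    matrix: AssociationMatrix | None = None,
    k: int = 2,
    require_positive_ai: bool = True,
    attributes: pd.DataFrame | None = None,
) -> nx.DiGraph:
    """Directed closest-associate network: arc i -> j iff rank(j) <= k for i.

    With ``require_positive_ai`` (default) an arc is drawn only when the pair
    was actually co-sighted, so out-degree can fall below k.  Node attributes
    ``age_years`` and ``raider`` are attached when ``attributes`` is given.
    """
    g = nx.DiGraph()
    g.add_nodes_from(ranks.ids)
    for focal in ranks.ids:
        if require_positive_ai:
            if matrix is None:
                raise ValueError("matrix required when require_positive_ai=True")
            targets = _top_positive(matrix, ranks, focal, k)
        else:
            targets = ranks.top(focal, k)
        g.add_edges_from((focal, t) for t in targets)
    if attributes is not None:
        attr = attributes.set_index("male_id")
        for node in g.nodes:
            g.nodes[node]["age_years"] = int(attr.loc[node, "age_years"])
            g.nodes[node]["raider"] = int(attr.loc[node, "raider"])
    return g


def age_class(age: float) -> str:
    """Map an age in years to its life-history class label."""
    for (lo, hi), lab in zip(AGE_CLASS_BINS, AGE_CLASS_LABELS):
        if lo <= age <= hi:
            return lab
    raise ValueError(f"age {age} outside the defined classes (>= 10)")


def make_features(
    ranks: RankTable, attributes: pd.DataFrame, k: int = 5
) -> pd.DataFrame:
    """Per-focal feature table for the raiding-status models.

    Columns: own age and class, and for each associate rank r = 1..k the
    associate's raiding status ``status_r`` and relative age ``relage_r``
    (associate age minus focal age; negative means a younger associate),
    the count of raiders among the top five, and the status x relative-age
    interactions for the two closest associates.
    """
    attr = attributes.set_index("male_id")
    rows = []
    for focal in ranks.ids:
        top = ranks.top(focal, k)
        if len(top) < k:
            raise ValueError(f"{focal} has only {len(top)} ranked associates; need {k}")
        age_f = float(attr.loc[focal, "age_years"])
        row = {
            "male_id": focal,
            "raider": int(attr.loc[focal, "raider"]),
            "age": age_f,
            "age_class": age_class(age_f),
        }
        for r, assoc in enumerate(top, start=1):
            row[f"status_{r}"] = int(attr.loc[assoc, "raider"])
            row[f"relage_{r}"] = float(attr.loc[assoc, "age_years"]) - age_f
        row["n_raiders_top5"] = sum(row[f"status_{r}"] for r in range(1, min(k, 5) + 1))
        for r in (1, 2):
            row[f"status_{r}_x_relage_{r}"] = row[f"status_{r}"] * row[f"relage_{r}"]
        rows.append(row)
    return pd.DataFrame(rows)
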