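"""Synthetic populations, group sightings and trait assignments.

The generator emulates the design of a field study of a wild all-male
population: ~58 focal males aged 10+ with a right-skewed age distribution,
roughly a third of them carrying a binary behavioral trait ("raider") whose
baseline probability rises with age on the logit scale, six social
communities of unequal size, group sightings biased toward own community and
similar ages, per-male sighting counts with a long right tail (mean ~36,
median ~18, max ~107, minimum 15 for inclusion), and a social-transmission
overlay: a non-raider whose two closest associates include an older raider
may convert, emulating acquisition of the behavior from older associates.

Every stage is deterministic under (config, seed); per-stage random streams
are derived from the master seed by fixed offsets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .association import MaleRecord, build_association_matrix, build_top_k_network, rank_associates

__all__ = [
    "PopulationConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "calibrate_intercept",
    "generate_population",
    "generate_sightings",
    "apply_transmission_overlay",
    "generate_dataset",
]

# fixed offsets deriving per-stage streams from the master seed
_POP_OFFSET = 0
_SIGHT_OFFSET = 1
_OVERLAY_OFFSET = 2


@dataclass
class PopulationConfig:
    """Generative parameters for one synthetic study population.

    Defaults reproduce the reference study design: 58 males, communities of
    sizes 8/10/12/12/9/7, baseline raiding log-odds rising 0.074 per year of
    age with the intercept calibrated so the expected raider fraction is
    21/58, sighting counts with mean 36 / median 18 capped at 107, and a
    moderate transmission overlay.
    """

    n_males: int = 58
    age_min: int = 10
    age_max: int = 60
    age_shape: float = 1.7          # gamma shape; smaller = more right-skew
    age_mean: float = 25.2          # target mean age in years
    n_communities: int = 6
    community_sizes: tuple = (8, 10, 12, 12, 9, 7)
    beta0: float | None = None      # None: calibrate to target_raider_fraction
    beta_age: float = 0.074         # per-year log-odds slope of raiding
    target_raider_fraction: float = 21 / 58
    tau_transmit: float = 0.3       # conversion prob. given an older raider in top 2
    sigma_age_homophily: float = 8.0  # years; grouping weight exp(-|d age|/sigma)
    eps_between: float = 0.05       # prob. a group member is drawn outside the community
    sightings_mean: float = 36.0
    sightings_median: float = 18.0
    sightings_max: int = 107
    min_sightings: int = 15
    sightings_nb_r: float = 0.55    # negative-binomial dispersion of count targets
    group_size_p: float = 0.35      # truncated geometric on [2, group_size_max]
    group_size_max: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = tuple(int(s) for s in self.community_sizes)
        if len(sizes) != self.n_communities:
            raise ValueError("community_sizes must have n_communities entries")
        if sum(sizes) != self.n_males:
            raise ValueError(
                f"community sizes sum to {sum(sizes)}, expected n_males={self.n_males}"
            )
        if any(s < 2 for s in sizes):
            raise ValueError("every community needs at least 2 males")
        if not (0 <= self.tau_transmit <= 1 and 0 <= self.eps_between <= 1):
            raise ValueError("tau_transmit and eps_between must lie in [0, 1]")
        if self.age_min < 10:
            raise ValueError("age_min must be >= 10")
        if self.min_sightings > self.sightings_max:
            raise ValueError("infeasible sighting-count targets: min > max")
        if self.sightings_mean > self.sightings_max or self.sightings_mean < self.min_sightings:
            raise ValueError("infeasible sighting-count targets: mean outside [min, max]")
        self.community_sizes = sizes


@dataclass
class SyntheticTruth:
    """Ground truth behind one synthetic dataset."""

    community: dict                  # male_id -> community label 0..K-1
    params: dict                     # the generative parameter values used
    pathway: dict                    # male_id -> 'age' | 'transmitted' | 'none'

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {"community": self.community, "params": self.params, "pathway": self.pathway},
                indent=2,
                default=float,
            )
        )


def _age_pmf(config: PopulationConfig) -> tuple:
    """Discretized gamma age distribution on [age_min, age_max]."""
    scale = (config.age_mean - config.age_min) / config.age_shape
    ages = np.arange(config.age_min, config.age_max + 1)
    upper = ages + 1 - config.age_min
    lower = ages - config.age_min
    cdf = stats.gamma.cdf(upper, config.age_shape, scale=scale) - stats.gamma.cdf(
        lower, config.age_shape, scale=scale
    )
    pmf = cdf / cdf.sum()
    return ages, pmf


def calibrate_intercept(config: PopulationConfig) -> float:
    """Intercept giving E[raider fraction] = target under the age mix.

    Solves  sum_a pmf(a) logit^-1(b0 + beta_age a) = target_raider_fraction
    by numeric root finding over the discretized age distribution.
    """
    ages, pmf = _age_pmf(config)

    def expected(b0):
        return float(pmf @ (1.0 / (1.0 + np.exp(-(b0 + config.beta_age * ages))))) - (
            config.target_raider_fraction
        )

    return float(optimize.brentq(expected, -50.0, 50.0))


def _male_ids(n: int) -> list:
    return [f"M{i + 1:03d}" for i in range(n)]


def generate_population(config: PopulationConfig) -> tuple:
    """Draw males with ages, community labels, and baseline raider status.

    Ages come from the discretized gamma; raider ~ Bernoulli of the logistic
    in age.  Communities are age-assortative: males are sorted on age plus
    Gaussian noise (sd = sigma_age_homophily) and sliced into the configured
    sizes, so communities differ in mean age as real social clusters do.
    Returns (list of MaleRecord, SyntheticTruth).
    """
    rng = np.random.default_rng(config.seed + _POP_OFFSET)
    ids = _male_ids(config.n_males)
    ages_support, pmf = _age_pmf(config)
    ages = rng.choice(ages_support, size=config.n_males, p=pmf)

    beta0 = config.beta0 if config.beta0 is not None else calibrate_intercept(config)
    p_raid = 1.0 / (1.0 + np.exp(-(beta0 + config.beta_age * ages)))
    raider = (rng.random(config.n_males) < p_raid).astype(int)

    noisy = ages + rng.normal(0.0, config.sigma_age_homophily, size=config.n_males)
    order = np.argsort(noisy, kind="stable")
    labels = np.empty(config.n_males, dtype=int)
    start = 0
    for c, size in enumerate(config.community_sizes):
        labels[order[start : start + size]] = c
        start += size

    records = [
        MaleRecord(id=i, age_years=int(a), raider=int(r))
        for i, a, r in zip(ids, ages, raider)
    ]
    truth = SyntheticTruth(
        community={i: int(c) for i, c in zip(ids, labels)},
        params={**asdict(config), "beta0": beta0},
        pathway={i: ("age" if r else "none") for i, r in zip(ids, raider)},
    )
    return records, truth


def _count_targets(config: PopulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-male sighting-count targets: clipped negative binomial."""
    r = config.sightings_nb_r
    mu = config.sightings_mean
    p = r / (r + mu)
    draws = rng.negative_binomial(r, p, size=config.n_males)
    return np.clip(draws, config.min_sightings, config.sightings_max)


def _sighting_dates(n_groups: int) -> list:
    """Synthetic field-season dates (June-December, three years), cycling."""
    days = pd.date_range("2005-06-01", "2007-12-31", freq="3D")
    days = days[(days.month >= 6)]
    return [days[k % len(days)].strftime("%Y-%m-%d") for k in range(n_groups)]


def generate_sightings(
    population: list, truth: SyntheticTruth, config: PopulationConfig
) -> pd.DataFrame:
    """Simulate group sightings until every male reaches his count target.

    Groups are seeded by a focal male chosen in proportion to his remaining
    count deficit; each further member slot draws from the focal's own
    community with probability 1 - eps_between (else from outside), weighted
    by the age-homophily kernel exp(-|delta age| / sigma) and by remaining
    deficit, without replacement within the group.  Group sizes follow a
    truncated geometric on [2, group_size_max].
    """
    rng = np.random.default_rng(config.seed + _SIGHT_OFFSET)
    ids = [m.id for m in population]
    ages = np.array([m.age_years for m in population], dtype=float)
    comm = np.array([truth.community[i] for i in ids])
    n = len(ids)
    targets = _count_targets(config, rng)
    counts = np.zeros(n, dtype=int)

    if np.isfinite(config.sigma_age_homophily) and config.sigma_age_homophily > 0:
        age_w = np.exp(-np.abs(ages[:, None] - ages[None, :]) / config.sigma_age_homophily)
    else:
        age_w = np.ones((n, n))

    # truncated geometric pmf over group sizes 2..group_size_max
    sizes = np.arange(2, max(3, min(config.group_size_max, n)) + 1)
    gp = config.group_size_p * (1 - config.group_size_p) ** (sizes - 2)
    gp /= gp.sum()

    rows = []
    gid = 0
    budget = int(2 * targets.sum())  # hard stop; never reached in practice
    while (counts < targets).any() and gid < budget:
        deficit = np.clip(targets - counts, 0, None).astype(float)
        focal = int(rng.choice(n, p=deficit / deficit.sum()))
        size = int(rng.choice(sizes, p=gp))
        members = [focal]
        member_set = {focal}
        for _ in range(size - 1):
            use_out = rng.random() < config.eps_between
            # candidate pools in preference order; with eps strictly inside
            # (0, 1) the other pool is a fallback, otherwise it is forbidden
            pool_order = [use_out, not use_out] if 0 < config.eps_between < 1 else [use_out]
            pools = []
            for pool_is_out in pool_order:
                if pool_is_out:
                    pools.append(np.array(
                        [j for j in range(n) if comm[j] != comm[focal] and j not in member_set]
                    ))
                else:
                    pools.append(np.array(
                        [j for j in range(n) if comm[j] == comm[focal] and j not in member_set]
                    ))
            # prefer males still short of their count target (searching both
            # allowed pools) so final counts track the configured mean/median/max
            cand = None
            for pool in pools:
                if pool.size:
                    short = pool[(targets[pool] - counts[pool]) > 0]
                    if short.size:
                        cand = short
                        break
            if cand is None:
                nonempty = [p for p in pools if p.size]
                if not nonempty:
                    break
                cand = nonempty[0]
            w = age_w[focal, cand] * (np.clip(targets[cand] - counts[cand], 0, None) + 0.25)
            w = w / w.sum()
            pick = int(rng.choice(cand, p=w))
            members.append(pick)
            member_set.add(pick)
        if len(members) < 2:
            continue
        gid += 1
        counts[members] += 1
        for m in members:
            rows.append((f"S{gid:05d}", ids[m]))

    dates = _sighting_dates(gid)
    df = pd.DataFrame(rows, columns=["sighting_id", "male_id"])
    date_map = {f"S{k + 1:05d}": dates[k] for k in range(gid)}
    df.insert(1, "date", df["sighting_id"].map(date_map))
    return df


def apply_transmission_overlay(
    population: list,
    network,
    tau_transmit: float,
    seed: int = 0,
) -> tuple:
    """One-pass social transmission of raider status along top-2 arcs.

    Each non-raider whose top-2 associates (out-neighbours in ``network``)
    include a raider strictly older than him converts with probability
    ``tau_transmit``.  Eligibility is judged against the pre-overlay
    statuses, so the overlay is a single synchronous pass.  Returns
    (updated records, list of converted ids).
    """
    rng = np.random.default_rng(seed)
    by_id = {m.id: m for m in population}
    converted = []
    for m in population:
        if m.raider:
            continue
        eligible = any(
            by_id[a].raider == 1 and by_id[a].age_years > m.age_years
            for a in network.successors(m.id)
        )
        if eligible and rng.random() < tau_transmit:
            converted.append(m.id)
    updated = [
        MaleRecord(id=m.id, age_years=m.age_years, raider=1)
        if m.id in set(converted)
        else m
        for m in population
    ]
    return updated, converted


@dataclass
class SyntheticDataset:
    """A complete synthetic study: sightings, final attributes, ground truth."""

    sightings: pd.DataFrame
    attributes: pd.DataFrame
    truth: SyntheticTruth
    converted: list = field(default_factory=list)

    def write(self, outdir) -> dict:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "sightings": outdir / "sightings.csv",
            "attributes": outdir / "attributes.csv",
            "truth": outdir / "truth.json",
        }
        self.sightings.to_csv(paths["sightings"], index=False)
        self.attributes.to_csv(paths["attributes"], index=False)
        self.truth.to_json(paths["truth"])
        return {k: str(v) for k, v in paths.items()}


def generate_dataset(config: PopulationConfig) -> SyntheticDataset:
    """Population -> sightings -> top-2 network -> transmission overlay."""
    population, truth = generate_population(config)
    sightings = generate_sightings(population, truth, config)
    attributes = pd.DataFrame(
        {
            "male_id": [m.id for m in population],
            "age_years": [m.age_years for m in population],
            "raider": [m.raider for m in population],
        }
    )
    matrix = build_association_matrix(sightings, attributes)
    ranks = rank_associates(matrix)
    net = build_top_k_network(ranks, matrix, k=2)
    population, converted = apply_transmission_overlay(
        population, net, config.tau_transmit, seed=config.seed + _OVERLAY_OFFSET
    )
    for mid in converted:
        truth.pathway[mid] = "transmitted"
    attributes["raider"] = [m.raider for m in population]
    return SyntheticDataset(
        sightings=sightings, attributes=attributes, truth=truth, converted=converted
    )
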