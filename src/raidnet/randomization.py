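"""Monte-Carlo randomization nulls for logistic coefficients.

Because the associations of one individual are not independent of the
associations of his associates, Wald p-values for associate-derived
predictors are biased.  Two null schemes address this:

* ``shuffle_predictors_null`` — jointly permutes the predictor rows against
  the fixed response and refits, breaking any focal-predictor link while
  preserving the joint predictor distribution.
* ``associate_pool_null`` — keeps each focal's response and own-age fixed
  but replaces the attributes of his tested associates with those of a male
  drawn uniformly from his pool of potential associates (all other focal
  males); status and relative age come from the *same* sampled male so their
  pairing survives, unless ``independent_draws`` is set.

Empirical p-values are the plain proportion of null replicates whose
coefficient is at least as extreme (in absolute value) as the observed one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .logistic import LogisticFit, build_design, fit_logistic

__all__ = [
    "NullEnsemble",
    "shuffle_predictors_null",
    "associate_pool_null",
    "resample_associates",
    "empirical_p",
]


@dataclass
class NullEnsemble:
    """Replicate coefficient vectors under a stated randomization scheme."""

    scheme: str
    n_reps: int
    seed: int
    names: list
    observed: np.ndarray
    replicates: np.ndarray          # (n_reps, p); NaN rows never fit
    rep_separated: np.ndarray       # (n_reps,) bool
    observed_fit: LogisticFit | None = None

    def summary(self) -> pd.DataFrame:
        """Observed coefficient, null mean +/- SE, and empirical p per term."""
        ok = ~self.rep_separated
        reps = self.replicates[ok]
        null_mean = reps.mean(axis=0)
        null_se = reps.std(axis=0, ddof=1) / np.sqrt(len(reps))
        return pd.DataFrame(
            {
                "observed": self.observed,
                "null_mean": null_mean,
                "null_se": null_se,
                "p": [empirical_p(self, nm) for nm in self.names],
            },
            index=self.names,
        )


def _fit_observed(X: np.ndarray, y: np.ndarray, names: list) -> LogisticFit:
    """Observed-data fit; a rank-deficient design (e.g. a constant associate
    status) is flagged inestimable rather than raised, so the ensemble still
    carries the metadata."""
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn(
            "observed design is rank deficient; coefficients are inestimable "
            "and flagged",
            stacklevel=3,
        )
        fit = fit_logistic(X, y, names=names, check_rank=False)
        fit.separated = True
        fit.converged = False
        return fit
    return fit_logistic(X, y, names=names)


def _fit_replicates(
    scheme: str,
    make_design,
    n_reps: int,
    seed: int,
    observed_fit: LogisticFit,
    names: list,
) -> NullEnsemble:
    rng = np.random.default_rng(seed)
    p = len(names)
    reps = np.full((n_reps, p), np.nan)
    separated = np.zeros(n_reps, dtype=bool)
    for r in range(n_reps):
        X, y = make_design(rng)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            # e.g. a degenerate pool producing a constant predictor: the
            # coefficient is inestimable in this replicate
            separated[r] = True
            continue
        try:
            fit = fit_logistic(X, y, names=names, check_rank=False)
        except np.linalg.LinAlgError:
            separated[r] = True
            continue
        reps[r] = fit.params
        separated[r] = fit.separated or not fit.converged
    ens = NullEnsemble(
        scheme=scheme,
        n_reps=n_reps,
        seed=seed,
        names=list(names),
        observed=observed_fit.params.copy(),
        replicates=reps,
        rep_separated=separated,
        observed_fit=observed_fit,
    )
    frac_bad = separated.mean()
    if frac_bad > 0.10:
        warnings.warn(
            f"{scheme}: {frac_bad:.0%} of null replicates were separated or "
            "failed to converge; empirical p-values exclude them",
            stacklevel=3,
        )
    return ens


def shuffle_predictors_null(
    features: pd.DataFrame,
    terms: list,
    n_reps: int = 1000,
    seed: int = 0,
    response: str = "raider",
) -> NullEnsemble:
    """Null by jointly permuting predictor rows against the fixed response."""
    X_obs, y, names = build_design(features, terms, response=response)
    obs_fit = _fit_observed(X_obs, y, names)
    n = len(y)

    def make_design(rng):
        perm = rng.permutation(n)
        X = X_obs.copy()
        X[:, 1:] = X_obs[perm, 1:]  # keep the intercept column fixed
        return X, y

    return _fit_replicates("shuffle_predictors", make_design, n_reps, seed, obs_fit, names)


def associate_pool_null(
    features: pd.DataFrame,
    attributes: pd.DataFrame,
    terms: list,
    ranks_to_randomize: tuple = (1,),
    n_reps: int = 1000,
    seed: int = 0,
    response: str = "raider",
    independent_draws: bool = False,
) -> NullEnsemble:
    """Null by resampling each focal's tested associates from his pool.

    For every focal male and every rank slot in ``ranks_to_randomize``, a
    male is drawn uniformly (with replacement across replicates) from the
    focal's n-1 potential associates; his raiding status and relative age
    replace the slot's ``status_r`` / ``relage_r`` columns (and any
    interactions built from them).  With ``independent_draws`` the status
    and relative age come from two independent draws.
    """
    X_obs, y, names = build_design(features, terms, response=response)
    obs_fit = _fit_observed(X_obs, y, names)

    def make_design(rng):
        feat = resample_associates(
            features, attributes, ranks_to_randomize, rng, independent_draws
        )
        X, y_r, _ = build_design(feat, terms, response=response)
        return X, y_r

    return _fit_replicates("associate_pool", make_design, n_reps, seed, obs_fit, names)


def resample_associates(
    features: pd.DataFrame,
    attributes: pd.DataFrame,
    ranks_to_randomize: tuple,
    rng: np.random.Generator,
    independent_draws: bool = False,
) -> pd.DataFrame:
    """One null replicate of the associate-pool scheme.

    For each focal and each slot in ``ranks_to_randomize``, draws one male
    uniformly from the focal's n-1 potential associates and writes that
    male's raiding status and relative age into ``status_r`` / ``relage_r``
    (plus any prebuilt interaction column).  With coupled draws (default)
    both attributes come from the same sampled male.
    """
    attr = attributes.set_index("male_id")
    ids = list(features["male_id"])
    n = len(ids)
    ages = attr.loc[ids, "age_years"].to_numpy(dtype=float)
    status = attr.loc[ids, "raider"].to_numpy(dtype=float)
    # pools[i] = indices of the n-1 potential associates of focal i
    pools = np.array([[j for j in range(n) if j != i] for i in range(n)])
    feat = features.copy()
    for r in ranks_to_randomize:
        draw = pools[np.arange(n), rng.integers(0, n - 1, size=n)]
        feat[f"status_{r}"] = status[draw]
        if independent_draws:
            draw = pools[np.arange(n), rng.integers(0, n - 1, size=n)]
        feat[f"relage_{r}"] = ages[draw] - ages[np.arange(n)]
        col = f"status_{r}_x_relage_{r}"
        if col in feat.columns:
            feat[col] = feat[f"status_{r}"] * feat[f"relage_{r}"]
    return feat


def empirical_p(
    ensemble: NullEnsemble, name: str, smoothed: bool = False
) -> float:
    """Proportion of null |coefficients| at least as extreme as observed.

    Separated or non-converged replicates are excluded (their truncated
    coefficients would distort the null tail); the count excluded is
    ``ensemble.rep_separated.sum()``.  ``smoothed`` applies the (r+1)/(n+1)
    correction instead of the plain proportion.
    """
    j = ensemble.names.index(name)
    ok = ~ensemble.rep_separated
    reps = ensemble.replicates[ok, j]
    reps = reps[~np.isnan(reps)]
    if reps.size == 0:
        raise ValueError("no usable null replicates for empirical p-value")
    extreme = int(np.sum(np.abs(reps) >= np.abs(ensemble.observed[j])))
    if smoothed:
        return (extreme + 1) / (reps.size + 1)
    return extreme / reps.size
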