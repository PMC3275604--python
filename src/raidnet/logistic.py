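"""Binary logistic regression by Newton-Raphson, Wald tests, AIC comparison.

The fitter is written from scratch because downstream randomization nulls
refit the same model thousands of times on permuted designs and need tight
control over convergence, step-halving and separation detection.  The model
is the standard logit:  P(y=1 | x) = exp(b0 + sum_i b_i x_i) / (1 + exp(.)).

Complete or quasi-complete separation makes the MLE non-existent (some
coefficient diverges while the likelihood keeps improving).  Rather than
erroring, the fitter flags it and returns the last iterate: flagged fits are
excluded from randomization null ensembles and their Wald output is marked
unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LogisticFit",
    "RankDeficientError",
    "fit_logistic",
    "wald_test",
    "compare_aic",
    "build_design",
    "run_model_suite",
    "MODEL_SUITE",
]

#: Any |coefficient| beyond this during iteration is treated as divergence
#: to +/- infinity, i.e. separation.
SEPARATION_BOUND = 15.0


class RankDeficientError(np.linalg.LinAlgError):
    """Design matrix is not full column rank."""


@dataclass
class LogisticFit:
    """Result of a logistic fit.

    ``params`` includes the intercept first.  ``cov`` is the inverse observed
    information at the estimate (unreliable under separation).  AIC is
    2p - 2 loglik.
    """

    names: list
    params: np.ndarray
    cov: np.ndarray
    loglik: float
    n_obs: int
    n_iter: int
    converged: bool
    separated: bool
    n_events: int = 0

    @property
    def aic(self) -> float:
        return 2 * len(self.params) - 2 * self.loglik

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0, None))

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.params)

    def coef(self, name: str) -> float:
        return float(self.params[self.names.index(name)])

    def summary(self) -> pd.DataFrame:
        w = wald_test(self)
        w.insert(len(w.columns), "odds_ratio", self.odds_ratios)
        return w


def _loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    # log(1 + e^eta) computed stably
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def _check_rank(X: np.ndarray, names: list) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify a minimal set of columns involved in the collinearity
        bad = []
        for j in range(X.shape[1]):
            keep = [c for c in range(X.shape[1]) if c != j]
            if np.linalg.matrix_rank(X[:, keep]) == rank:
                bad.append(names[j])
        raise RankDeficientError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear columns involve: {bad}"
        )


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    names: list | None = None,
    max_iter: int = 25,
    tol: float = 1e-8,
    check_rank: bool = True,
) -> LogisticFit:
    """Maximum-likelihood logistic fit by Newton-Raphson with step-halving.

    Parameters
    ----------
    X : (n, p) design matrix including the intercept column.
    y : (n,) binary response.
    tol : convergence when the largest absolute score component < tol.

    The Newton step is ``(X'WX)^-1 X'(y - p)`` with W = diag(p(1-p)); the
    step is halved until the log-likelihood does not decrease, which makes
    the log-likelihood monotone across iterations.  Separation is flagged
    when any coefficient passes ``SEPARATION_BOUND`` in absolute value.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n, p) aligned with y")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("response must be binary 0/1")
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    if check_rank:
        _check_rank(X, names)

    beta = np.zeros(p)
    ll = _loglik(X, y, beta)
    converged = False
    separated = False
    it = 0
    cov = np.full((p, p), np.nan)
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        score = X.T @ (y - mu)
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, score, rcond=None)[0]
        # step-halving: never let the log-likelihood decrease
        t = 1.0
        for _ in range(30):
            cand = beta + t * step
            ll_new = _loglik(X, y, cand)
            if ll_new >= ll - 1e-12:
                break
            t *= 0.5
        beta = beta + t * step
        ll = _loglik(X, y, cand)
        if np.max(np.abs(beta)) > SEPARATION_BOUND:
            separated = True
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    info = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    return LogisticFit(
        names=list(names),
        params=beta,
        cov=cov,
        loglik=_loglik(X, y, beta),
        n_obs=n,
        n_iter=it,
        converged=converged and not separated,
        separated=separated,
        n_events=int(y.sum()),
    )


def wald_test(fit: LogisticFit) -> pd.DataFrame:
    """Per-coefficient Wald chi-square (1 df) and two-sided p-values.

    chi2_j = (beta_j / se_j)^2; under separation the statistics are computed
    but flagged unreliable (the information matrix is nearly singular there).
    """
    se = fit.se
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, fit.params / se, 0.0)
    chi2 = z**2
    pvals = stats.chi2.sf(chi2, df=1)
    pvals = np.where(se > 0, pvals, 1.0)
    return pd.DataFrame(
        {
            "coef": fit.params,
            "se": se,
            "chi2": chi2,
            "p": pvals,
            "reliable": not fit.separated,
        },
        index=fit.names,
    )


def compare_aic(fits: dict) -> pd.DataFrame:
    """Rank fits of the same response by AIC, best first, with delta-AIC."""
    n_set = {f.n_obs for f in fits.values()}
    ev_set = {f.n_events for f in fits.values()}
    if len(n_set) > 1 or len(ev_set) > 1:
        raise ValueError("AIC comparison requires fits on the identical response")
    tab = pd.DataFrame(
        {
            "aic": {name: f.aic for name, f in fits.items()},
            "loglik": {name: f.loglik for name, f in fits.items()},
            "n_params": {name: len(f.params) for name, f in fits.items()},
        }
    ).sort_values("aic")
    tab["delta_aic"] = tab["aic"] - tab["aic"].iloc[0]
    return tab


# --------------------------------------------------------------------------
# model suite on the associate-feature table

def build_design(
    features: pd.DataFrame, terms: list, response: str = "raider"
) -> tuple[np.ndarray, np.ndarray, list]:
    """Assemble (X, y, names) from a feature table.

    Terms are column names; ``a:b`` denotes a product column and
    ``C(age_class)`` expands to treatment-coded dummies with the youngest
    class (10-14) as baseline.  An intercept is always prepended.
    """
    from .association import AGE_CLASS_LABELS

    y = features[response].to_numpy(dtype=float)
    cols = [np.ones(len(features))]
    names = ["intercept"]
    for term in terms:
        if term == "C(age_class)":
            present = set(features["age_class"])
            for lab in AGE_CLASS_LABELS[1:]:  # baseline = first class
                if lab in present:
                    cols.append((features["age_class"] == lab).to_numpy(dtype=float))
                    names.append(f"age_class[{lab}]")
        elif ":" in term:
            a, b = term.split(":")
            cols.append((features[a] * features[b]).to_numpy(dtype=float))
            names.append(term)
        else:
            cols.append(features[term].to_numpy(dtype=float))
            names.append(term)
    return np.column_stack(cols), y, names


#: The candidate models for predicting raider status from age and associates.
MODEL_SUITE: dict = {
    "M1_age": ["age"],
    "M2_age_class": ["C(age_class)"],
    "M3_status_1": ["status_1"],
    "M3_status_2": ["status_2"],
    "M3_status_3": ["status_3"],
    "M3_status_4": ["status_4"],
    "M3_status_5": ["status_5"],
    "M4_n_raiders_top5": ["n_raiders_top5"],
    "M5_status_1_2": ["status_1", "status_2"],
    "M6_full": [
        "age",
        "relage_1",
        "relage_2",
        "status_1",
        "status_2",
        "status_1:relage_1",
        "status_2:relage_2",
    ],
}


def run_model_suite(
    features: pd.DataFrame, models: dict | None = None
) -> dict:
    """Fit the full candidate-model suite on one feature table.

    Returns {model name: LogisticFit}.  Model M2 uses life-history age
    classes with the 10-14 baseline coefficient fixed at zero by treatment
    coding; separation there (e.g. a class with no raiders) is flagged, not
    an error.
    """
    models = MODEL_SUITE if models is None else models
    fits = {}
    for name, terms in models.items():
        X, y, colnames = build_design(features, terms)
        fits[name] = fit_logistic(X, y, names=colnames)
    return fits
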