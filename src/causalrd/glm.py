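"""Binary logistic regression by Newton/IRLS with explicit failure signals.

This fitter underlies propensity-score models, the stratified outcome
models of the doubly-robust estimator, and odds-ratio estimation.  It is
written in-house rather than delegating to a host GLM routine because the
bootstrap needs machine-readable singularity signals: a resample with too
few exposed participants must raise a typed error that the resampling loop
can skip and count, not converge silently to garbage.  No penalisation is
applied; small-sample instability is surfaced, never patched.

Convergence follows fixed, platform-independent criteria: the fit stops
when the largest score (gradient) component falls below 1e-8 or the
relative log-likelihood change falls below 1e-10, with a cap of 50
iterations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats
from scipy.optimize import brentq
from scipy.special import expit

from .cohort import CohortTable, DesignMatrix, build_design
from .errors import (
    AlignmentError,
    ConvergenceError,
    DegenerateResponseError,
    DimensionError,
    ProfilingError,
    SeparationError,
    SingularError,
)

__all__ = [
    "LogisticFit",
    "GroupOutcomeModels",
    "fit_logistic",
    "predict_probability",
    "fit_group_outcome_models",
    "profile_likelihood_ci",
]

SCORE_TOL = 1e-8
LL_RELTOL = 1e-10
MAX_ITER = 50
# Fitted probabilities this close to 0/1 together with a diverging
# coefficient indicate (quasi-)complete separation.
SEPARATION_PROB_TOL = 1e-10
SEPARATION_BETA = 30.0


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit aligned to a design matrix."""

    beta: np.ndarray
    labels: tuple[str, ...]
    log_likelihood: float
    converged: bool
    n_iter: int
    fitted: np.ndarray
    weights: np.ndarray | None = None

    @property
    def p(self) -> int:
        return len(self.beta)

    def covariance(self, design: DesignMatrix) -> np.ndarray:
        """Inverse observed information at the optimum."""
        w = self.fitted * (1.0 - self.fitted)
        if self.weights is not None:
            w = w * self.weights
        H = design.matrix.T @ (design.matrix * w[:, None])
        return linalg.inv(H)


def _log_likelihood(eta: np.ndarray, y: np.ndarray, w: np.ndarray | None) -> float:
    # log L = sum y*eta - log(1+exp(eta)), computed stably
    ll = y * eta - np.logaddexp(0.0, eta)
    if w is not None:
        ll = ll * w
    return float(ll.sum())


def fit_logistic(
    design: DesignMatrix,
    response: np.ndarray,
    offset: np.ndarray | None = None,
    freq_weights: np.ndarray | None = None,
    beta0: np.ndarray | None = None,
) -> LogisticFit:
    """Fit P(Y=1) = logit^-1(X beta + offset) by Newton-Raphson.

    Parameters
    ----------
    design
        Design matrix; its first column is normally an intercept.
    response
        0/1 response vector, same length as the design.
    offset
        Optional fixed additive term on the linear-predictor scale (used by
        the profile-likelihood machinery to hold one coefficient fixed).
    freq_weights
        Optional non-negative frequency weights.
    beta0
        Optional starting values (e.g. a full-data fit warm-starting a
        bootstrap replicate); the converged MLE does not depend on them.

    Raises
    ------
    DegenerateResponseError
        If the response takes a single value.
    SeparationError
        If the MLE diverges (fitted probabilities pinned at 0/1).
    SingularError
        If the information matrix is singular (collinear/constant columns).
    ConvergenceError
        If the iteration cap is reached without convergence.
    """
    X = design.matrix
    y = np.asarray(response, dtype=float)
    if len(y) != X.shape[0]:
        raise DimensionError("response length does not match design rows")
    w = None if freq_weights is None else np.asarray(freq_weights, dtype=float)
    ybar = np.average(y, weights=w)
    if ybar <= 0.0 or ybar >= 1.0:
        raise DegenerateResponseError(
            "response is constant; the logistic MLE does not exist"
        )
    off = np.zeros(len(y)) if offset is None else np.asarray(offset, dtype=float)

    if beta0 is None:
        beta = np.zeros(X.shape[1])
        eta = off if offset is not None else np.zeros(len(y))
    else:
        beta = np.asarray(beta0, dtype=float).copy()
        if len(beta) != X.shape[1]:
            raise DimensionError("beta0 length does not match design columns")
        eta = X @ beta + off
    ll = _log_likelihood(eta, y, w)
    converged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        p = expit(eta)
        resid = y - p
        if w is not None:
            score = X.T @ (w * resid)
            wdiag = w * p * (1.0 - p)
        else:
            score = X.T @ resid
            wdiag = p * (1.0 - p)
        if np.max(np.abs(score)) < SCORE_TOL:
            converged = True
            break
        H = X.T @ (X * wdiag[:, None])
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            raise SingularError(
                "singular information matrix (collinear or constant columns)"
            ) from None
        if not np.all(np.isfinite(step)):
            raise SingularError("non-finite Newton step")
        # step-halving keeps the likelihood monotone on hard resamples;
        # the acceptance slack scales with |ll| because the summed
        # log-likelihood carries rounding noise of that order
        new_ll = -np.inf
        eta_cand = eta
        slack = 1e-12 + 4e-14 * abs(ll)
        for _ in range(30):
            cand = beta + step
            eta_cand = X @ cand + off
            new_ll = _log_likelihood(eta_cand, y, w)
            if new_ll >= ll - slack:
                break
            step = step / 2.0
        beta = beta + step
        eta = eta_cand
        prev_ll, ll = ll, new_ll
        _check_separation(beta, expit(eta), design)
        if abs(ll - prev_ll) < LL_RELTOL * (abs(prev_ll) + LL_RELTOL):
            # the likelihood has flattened to float resolution; declare
            # convergence if the Newton decrement shows beta is resolved
            p = expit(eta)
            resid = y - p
            score = X.T @ ((w * resid) if w is not None else resid)
            converged = bool(np.max(np.abs(score)) < 1e-4)
            if not converged:
                wdiag = (w * p * (1.0 - p)) if w is not None else p * (1.0 - p)
                H = X.T @ (X * wdiag[:, None])
                try:
                    delta = np.linalg.solve(H, score)
                    converged = bool(np.max(np.abs(delta)) < 1e-8)
                except np.linalg.LinAlgError:
                    pass
            break
    if converged:
        # polishing Newton steps: quadratic convergence takes the score to
        # machine precision, so closed-form identities (saturated-model
        # cell means, 2x2 odds ratios) hold essentially exactly
        for _ in range(2):
            p = expit(eta)
            wdiag = (w * p * (1.0 - p)) if w is not None else p * (1.0 - p)
            score = X.T @ ((w * (y - p)) if w is not None else (y - p))
            H = X.T @ (X * wdiag[:, None])
            try:
                step = np.linalg.solve(H, score)
            except np.linalg.LinAlgError:
                break
            if not np.all(np.isfinite(step)) or np.max(np.abs(step)) >= 1.0:
                break
            beta = beta + step
            eta = X @ beta + off
        ll = _log_likelihood(eta, y, w)
    fitted = expit(eta)
    _check_separation(beta, fitted, design)
    if not converged:
        raise ConvergenceError(f"no convergence after {it} iterations")
    return LogisticFit(
        beta=beta,
        labels=design.labels,
        log_likelihood=ll,
        converged=converged,
        n_iter=it,
        fitted=fitted,
        weights=w,
    )


def _check_separation(beta: np.ndarray, fitted: np.ndarray, design: DesignMatrix):
    if np.max(np.abs(beta)) < SEPARATION_BETA:
        return
    pinned = (fitted < SEPARATION_PROB_TOL) | (fitted > 1.0 - SEPARATION_PROB_TOL)
    if pinned.any():
        j = int(np.argmax(np.abs(beta)))
        raise SeparationError(
            f"perfect separation along column {design.labels[j]!r}",
            column=design.labels[j],
        )


def predict_probability(fit: LogisticFit, design: DesignMatrix) -> np.ndarray:
    """Inverse-logit of the linear predictor X beta for new rows."""
    if design.labels != tuple(fit.labels):
        raise AlignmentError(
            "design columns do not match the fitted coefficient vector"
        )
    return expit(design.matrix @ fit.beta)


@dataclass
class GroupOutcomeModels:
    """Outcome models fit separately in each exposure stratum.

    ``m0`` is fit on employed participants only, ``m1`` on unemployed only;
    both use the same covariate set as the propensity model, and both are
    evaluated at every participant's covariates regardless of stratum.
    """

    m0_fit: LogisticFit
    m1_fit: LogisticFit
    m0: np.ndarray
    m1: np.ndarray


def fit_group_outcome_models(
    cohort: CohortTable, covariates: list[str]
) -> GroupOutcomeModels:
    """Fit m0/m1 on the exposure strata; predict for the full cohort.

    Raises any :class:`EstimationError` subclass from the stratum fits —
    with few unemployed, resamples routinely produce constant-outcome or
    separated strata, which is the singularity condition the bootstrap
    skip-and-count logic consumes.
    """
    x = cohort.x
    full_design = build_design(cohort, covariates)
    models = {}
    preds = {}
    for group, mask in ((0, x == 0), (1, x == 1)):
        rows = np.flatnonzero(mask)
        if rows.size == 0:
            raise DegenerateResponseError(f"no participants with exposure={group}")
        sub = DesignMatrix(full_design.matrix[rows], full_design.labels)
        fit = fit_logistic(sub, cohort.y[rows])
        models[group] = fit
        preds[group] = predict_probability(fit, full_design)
    return GroupOutcomeModels(
        m0_fit=models[0], m1_fit=models[1], m0=preds[0], m1=preds[1]
    )


def _profile_ll(
    design: DesignMatrix,
    response: np.ndarray,
    j: int,
    beta_j: float,
) -> float:
    """Log-likelihood maximised over all coefficients except beta_j."""
    X = design.matrix
    keep = [k for k in range(X.shape[1]) if k != j]
    offset = X[:, j] * beta_j
    if not keep:  # single-parameter model: nothing left to profile over
        return _log_likelihood(offset, np.asarray(response, dtype=float), None)
    sub = DesignMatrix(X[:, keep], tuple(design.labels[k] for k in keep))
    try:
        fit = fit_logistic(sub, response, offset=offset)
    except ConvergenceError as err:
        raise ProfilingError(f"profile refit failed at beta={beta_j:g}") from err
    except SeparationError:
        # nuisance parameters diverging means the profile is effectively
        # unbounded at this beta_j; treat as -inf so the bracket widens
        return -np.inf
    return fit.log_likelihood


def profile_likelihood_ci(
    fit: LogisticFit,
    design: DesignMatrix,
    response: np.ndarray,
    index: int,
    level: float = 0.95,
) -> tuple[float, float]:
    """Profile-likelihood confidence bounds for one coefficient, OR scale.

    The bounds are the beta values where twice the drop in profile
    log-likelihood from its maximum equals the chi-square(1) quantile
    (3.841 at the 95% level), located by monotone root bracketing to an
    absolute tolerance better than 1e-6 on the beta scale.  A side where
    the profile never drops far enough (a separation direction) is reported
    as an open bound (0 or +inf on the odds-ratio scale).
    """
    if not fit.converged:
        raise ProfilingError("profile interval requires a converged fit")
    q = stats.chi2.ppf(level, df=1)
    ll_max = fit.log_likelihood
    b_hat = fit.beta[index]
    se = float(np.sqrt(fit.covariance(design)[index, index]))

    def deficit(b: float) -> float:
        # positive once beyond the interval boundary; capped so the root
        # finder sees finite values even where the profile is degenerate
        d = 2.0 * (ll_max - _profile_ll(design, response, index, b)) - q
        return min(d, 1e6) if np.isfinite(d) or d > 0 else d

    bounds = []
    for sign in (-1.0, 1.0):
        step = max(se, 1e-3)
        lo_b, hi_b = b_hat, b_hat + sign * step
        f_hi = deficit(hi_b)
        n_expand = 0
        while f_hi < 0.0 and n_expand < 60:
            lo_b = hi_b
            step *= 1.6
            hi_b = hi_b + sign * step
            f_hi = deficit(hi_b)
            n_expand += 1
        if f_hi < 0.0 or not np.isfinite(f_hi):
            bounds.append(-np.inf if sign < 0 else np.inf)
            continue
        a, b = (hi_b, lo_b) if sign < 0 else (lo_b, hi_b)
        root = brentq(deficit, a, b, xtol=1e-8)
        bounds.append(root)
    return float(np.exp(bounds[0])), float(np.exp(bounds[1]))
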