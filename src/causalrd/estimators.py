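"""Marginal risk-difference and odds-ratio estimators.

All risk-difference estimators target E[Y(1)] - E[Y(0)]: the change in the
probability of poor health if every participant were unemployed versus
every participant employed.  Three reweighting estimators use the
propensity score PS_i = P(X_i = 1 | covariates):

* ``rd_ipw`` — the plain inverse-probability-weighting estimator,
  (1/n) sum_i [ Y_i X_i / PS_i  -  Y_i (1 - X_i) / (1 - PS_i) ];

* ``rd_aug`` — the augmented (normalised-weights) estimator, which
  replaces the 1/n normaliser by the within-arm sums of weights, bounding
  the estimate in [-1, 1];

* ``rd_dr`` — the doubly-robust estimator, which corrects each weighted
  arm with stratum-specific outcome-model predictions m1 (fit on
  unemployed) and m0 (fit on employed) and remains consistent if either
  the propensity model or the outcome models are correctly specified:
  (1/n) sum_i [ (Y_i X_i - (X_i - PS_i) m1_i) / PS_i
                - (Y_i (1 - X_i) + (X_i - PS_i) m0_i) / (1 - PS_i) ].
  The 1/n normaliser is part of the estimator: without it the sum scales
  with n and could not be a risk difference.  m1_i and m0_i denote the
  stratum models evaluated at participant i's covariates.

``rd_gcomp`` is G-computation (standardisation): fit a logistic outcome
model with exposure among the covariates, then average predictions with
exposure forced to 1 and to 0 for everyone.  ``or_logistic`` reports the
conditional odds ratio for exposure with a profile-likelihood interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import CohortTable, DesignMatrix, build_design
from .errors import (
    ContractError,
    DegenerateResponseError,
    DimensionError,
    DivisionGuardError,
)
from .glm import (
    fit_logistic,
    fit_group_outcome_models,
    predict_probability,
    profile_likelihood_ci,
)

__all__ = [
    "RiskDifferenceInput",
    "EffectEstimate",
    "RD_ESTIMATORS",
    "rd_ipw",
    "rd_aug",
    "rd_dr",
    "rd_gcomp",
    "or_logistic",
    "crude_risk_difference",
    "estimate_propensity_scores",
    "rd_point_estimates",
]

PS_GUARD = 1e-12


@dataclass(frozen=True)
class RiskDifferenceInput:
    """Aligned vectors entering the weighting estimators."""

    y: np.ndarray
    x: np.ndarray
    ps: np.ndarray
    m0: np.ndarray | None = None
    m1: np.ndarray | None = None

    def __post_init__(self):
        n = len(self.y)
        if len(self.x) != n or len(self.ps) != n:
            raise DimensionError("Y, X and PS must have equal length")
        for m in (self.m0, self.m1):
            if m is not None and len(m) != n:
                raise DimensionError("m0/m1 predictions must match cohort length")
        if np.any(self.ps <= PS_GUARD) or np.any(self.ps >= 1.0 - PS_GUARD):
            raise DivisionGuardError(
                "propensity scores must be strictly inside (0, 1)"
            )


@dataclass
class EffectEstimate:
    """One estimator's result in a reportable form."""

    estimator: str
    scale: str  # "risk_difference" | "odds_ratio"
    point: float
    ci_low: float | None = None
    ci_high: float | None = None
    effective_b: int | None = None
    requested_b: int | None = None
    mse: float | None = None
    reliable: bool = True
    extra: dict = field(default_factory=dict)

    @property
    def null_value(self) -> float:
        return 1.0 if self.scale == "odds_ratio" else 0.0


def rd_ipw(inp: RiskDifferenceInput) -> float:
    """Plain inverse-probability-weighting risk difference."""
    y, x, ps = inp.y, inp.x, inp.ps
    n = len(y)
    return float(np.sum(y * x / ps - y * (1.0 - x) / (1.0 - ps)) / n)


def rd_aug(inp: RiskDifferenceInput) -> float:
    """Normalised-weights (augmented) risk difference; bounded in [-1, 1]."""
    y, x, ps = inp.y, inp.x, inp.ps
    w1 = np.sum(x / ps)
    w0 = np.sum((1.0 - x) / (1.0 - ps))
    if w1 <= 0.0 or w0 <= 0.0:
        raise DegenerateResponseError("an exposure group is empty")
    return float(np.sum(y * x / ps) / w1 - np.sum(y * (1.0 - x) / (1.0 - ps)) / w0)


def rd_dr(inp: RiskDifferenceInput) -> float:
    """Doubly-robust risk difference with stratum outcome-model augmentation."""
    if inp.m0 is None or inp.m1 is None:
        raise ContractError("rd_dr requires m0 and m1 predictions for all rows")
    y, x, ps, m0, m1 = inp.y, inp.x, inp.ps, inp.m0, inp.m1
    n = len(y)
    arm1 = (y * x - (x - ps) * m1) / ps
    arm0 = (y * (1.0 - x) + (x - ps) * m0) / (1.0 - ps)
    return float(np.sum(arm1 - arm0) / n)


def estimate_propensity_scores(
    cohort: CohortTable, covariates: list[str]
) -> np.ndarray:
    """Fitted P(unemployed | covariates) from a logistic propensity model."""
    design = build_design(cohort, covariates)
    fit = fit_logistic(design, cohort.x)
    return fit.fitted


def rd_gcomp(
    cohort: CohortTable,
    covariates: list[str],
    exposure_interactions: bool = False,
) -> float:
    """G-computation risk difference from a logistic outcome model.

    The default is a main-effects model (exposure enters additively on the
    log-odds scale alongside the covariates).  With
    ``exposure_interactions`` the model additionally carries
    exposure-by-covariate product terms; with a single binary covariate
    this saturates the 2x2x2 table and G-computation reduces to direct
    standardisation over the covariate distribution.
    """
    design = build_design(cohort, covariates, include_exposure=True)
    j = design.column_index("exposure")
    M = design.matrix
    labels = list(design.labels)
    if exposure_interactions:
        cov_cols = [k for k, lab in enumerate(labels) if lab not in ("intercept", "exposure")]
        inter = M[:, cov_cols] * M[:, [j]]
        M = np.column_stack([M, inter])
        labels += [f"exposure:{design.labels[k]}" for k in cov_cols]
        design = DesignMatrix(M, tuple(labels))
    fit = fit_logistic(design, cohort.y)

    def forced(value: float) -> np.ndarray:
        Xf = M.copy()
        Xf[:, j] = value
        if exposure_interactions:
            for offset, k in enumerate(cov_cols):
                Xf[:, len(design.labels) - len(cov_cols) + offset] = value * M[:, k]
        return predict_probability(fit, DesignMatrix(Xf, design.labels))

    p1 = forced(1.0)
    p0 = forced(0.0)
    return float(np.mean(p1 - p0))


def or_logistic(
    cohort: CohortTable, covariates: list[str], level: float = 0.95
) -> EffectEstimate:
    """Conditional odds ratio for exposure with a profile-likelihood CI."""
    design = build_design(cohort, covariates, include_exposure=True)
    fit = fit_logistic(design, cohort.y)
    j = design.column_index("exposure")
    lo, hi = profile_likelihood_ci(fit, design, cohort.y, j, level=level)
    return EffectEstimate(
        estimator="logistic_or",
        scale="odds_ratio",
        point=float(np.exp(fit.beta[j])),
        ci_low=lo,
        ci_high=hi,
    )


def crude_risk_difference(y: np.ndarray, x: np.ndarray) -> float:
    """mean(Y | X=1) - mean(Y | X=0)."""
    x = np.asarray(x, dtype=bool)
    if not x.any() or x.all():
        raise DegenerateResponseError("an exposure group is empty")
    y = np.asarray(y, dtype=float)
    return float(y[x].mean() - y[~x].mean())


RD_ESTIMATORS = ("gcomp", "ipw_standard", "ipw_augmented", "ipw_doubly_robust")


def rd_point_estimates(
    cohort: CohortTable,
    ps_covariates: list[str],
    outcome_covariates: list[str] | None = None,
    estimators: tuple[str, ...] = RD_ESTIMATORS,
) -> dict[str, float]:
    """All requested risk-difference point estimates on one cohort.

    The propensity model adjusts for ``ps_covariates``; G-computation and
    the m0/m1 augmentation models adjust for ``outcome_covariates``
    (defaulting to the same set).  Separate sets are what
    model-misspecification studies vary.
    """
    unknown = set(estimators) - set(RD_ESTIMATORS)
    if unknown:
        raise ContractError(f"unknown estimators: {sorted(unknown)}")
    out_covs = list(ps_covariates) if outcome_covariates is None else list(
        outcome_covariates
    )
    out: dict[str, float] = {}
    if "gcomp" in estimators:
        out["gcomp"] = rd_gcomp(cohort, out_covs)
    if any(e.startswith("ipw") for e in estimators):
        ps = estimate_propensity_scores(cohort, list(ps_covariates))
        if "ipw_standard" in estimators:
            out["ipw_standard"] = rd_ipw(RiskDifferenceInput(cohort.y, cohort.x, ps))
        if "ipw_augmented" in estimators:
            out["ipw_augmented"] = rd_aug(RiskDifferenceInput(cohort.y, cohort.x, ps))
        if "ipw_doubly_robust" in estimators:
            gm = fit_group_outcome_models(cohort, out_covs)
            out["ipw_doubly_robust"] = rd_dr(
                RiskDifferenceInput(cohort.y, cohort.x, ps, gm.m0, gm.m1)
            )
    return out
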