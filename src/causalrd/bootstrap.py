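"""Percentile-bootstrap inference with singular-replicate accounting.

Participants are resampled with replacement, unstratified; each replicate
re-runs the whole estimation chain (propensity fit, outcome fits,
estimator).  Replicates on which estimation fails — typically a resample
with too few unemployed, producing a constant-outcome or separated
stratum — are skipped and counted rather than patched, since that failure
mode is informative in its own right.  Confidence intervals are the
empirical 2.5% and 97.5% percentiles of the successful replicates
(linear-interpolation / type-7 quantiles, for cross-platform
determinism); the bootstrap MSE is the mean squared deviation of the
replicate estimates from the full-data point estimate.

The default replicate count is 10,000; simulation studies in the test
suite scale it down.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import CohortTable, DesignMatrix, build_design
from .errors import (
    DomainError,
    EstimationError,
    ReliabilityError,
)
from .estimators import (
    EffectEstimate,
    RD_ESTIMATORS,
    RiskDifferenceInput,
    rd_aug,
    rd_dr,
    rd_ipw,
)
from .glm import LogisticFit, fit_logistic, predict_probability

__all__ = [
    "BootstrapPlan",
    "BootstrapResult",
    "bootstrap",
    "bootstrap_many",
    "percentile_ci",
    "significance_flag",
]

DEFAULT_B = 10_000
# below this fraction of successful replicates the interval is flagged
# (or refused, in strict mode) as unreliable
RELIABILITY_FRACTION = 0.5


@dataclass(frozen=True)
class BootstrapPlan:
    """Resampling configuration; the seed is recorded in every result."""

    b: int = DEFAULT_B
    seed: int = 0
    level: float = 0.95
    strict: bool = False  # raise ReliabilityError instead of flagging

    def __post_init__(self):
        if self.b < 1:
            raise DomainError("replicate count must be >= 1")
        if not 0.0 < self.level < 1.0:
            raise DomainError("confidence level must be in (0, 1)")


@dataclass
class BootstrapResult:
    """Full-data point estimate plus percentile interval and MSE."""

    estimator: str
    point: float
    replicates: np.ndarray
    requested_b: int
    effective_b: int
    ci_low: float
    ci_high: float
    mse: float
    seed: int
    level: float
    reliable: bool
    failures: dict[str, int] = field(default_factory=dict)

    def to_effect_estimate(self) -> EffectEstimate:
        return EffectEstimate(
            estimator=self.estimator,
            scale="risk_difference",
            point=self.point,
            ci_low=self.ci_low,
            ci_high=self.ci_high,
            effective_b=self.effective_b,
            requested_b=self.requested_b,
            mse=self.mse,
            reliable=self.reliable,
        )


def percentile_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Empirical percentile interval (type-7 linear interpolation)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise DomainError("cannot take percentiles of an empty vector")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(values, [alpha, 1.0 - alpha], method="linear")
    return float(lo), float(hi)


def significance_flag(
    interval: tuple[float, float], scale: str = "risk_difference"
) -> bool:
    """True iff the null value lies outside the closed interval.

    The null is 0 on the risk-difference scale and 1 on the odds-ratio
    scale; an interval whose closed endpoints include the null is read as
    non-significant at the corresponding level.
    """
    null = 1.0 if scale == "odds_ratio" else 0.0
    lo, hi = interval
    return not (lo <= null <= hi)


class _ReplicateEngine:
    """Shared per-replicate estimation over precomputed design matrices.

    Builds the covariate design once on the full cohort; each replicate
    subsets rows by index, so resampling costs no re-coding of categorical
    variables.  All requested estimators are evaluated on the *same*
    resample, which keeps between-estimator (and, in ledger runs,
    between-model) contrasts free of resampling noise.
    """

    def __init__(self, cohort: CohortTable, covariates: list[str], estimators):
        unknown = set(estimators) - set(RD_ESTIMATORS)
        if unknown:
            raise DomainError(f"unknown estimators: {sorted(unknown)}")
        self.estimators = tuple(estimators)
        self.y = cohort.y
        self.x = cohort.x
        Z = build_design(cohort, covariates)
        self.Z = Z.matrix
        self.z_labels = Z.labels
        ZX = build_design(cohort, covariates, include_exposure=True)
        self.ZX = ZX.matrix
        self.zx_labels = ZX.labels
        self.exposure_col = ZX.column_index("exposure")
        # full-data coefficient vectors warm-start replicate fits; the MLE
        # is unchanged, convergence just takes fewer Newton steps
        self._warm: dict[str, np.ndarray] = {}

    def estimate(
        self, rows: np.ndarray | None = None, collect_failures: bool = False
    ) -> tuple[dict[str, float], dict[str, str]]:
        """Evaluate every requested estimator on one (re)sample.

        Returns ``(values, failures)`` where ``failures`` maps an
        estimator name to the class name of the error that invalidated it.
        With ``collect_failures`` false the first failure propagates —
        full-data point estimation must not swallow errors.
        """
        if rows is None:
            y, x, Z, ZX = self.y, self.x, self.Z, self.ZX
        else:
            y, x = self.y[rows], self.x[rows]
            Z, ZX = self.Z[rows], self.ZX[rows]
        out: dict[str, float] = {}
        failed: dict[str, str] = {}

        def attempt(name, func):
            try:
                out[name] = func()
            except EstimationError as err:
                if not collect_failures:
                    raise
                failed[name] = type(err).__name__

        inp = None
        need_ps = any(e.startswith("ipw") for e in self.estimators)
        if need_ps:
            try:
                ps_fit = fit_logistic(
                    DesignMatrix(Z, self.z_labels), x,
                    beta0=self._warm.get("ps"),
                )
                if rows is None:
                    self._warm["ps"] = ps_fit.beta
                inp = RiskDifferenceInput(y, x, ps_fit.fitted)
            except EstimationError as err:
                if not collect_failures:
                    raise
                for e in self.estimators:
                    if e.startswith("ipw"):
                        failed[e] = type(err).__name__
        if "gcomp" in self.estimators:
            attempt("gcomp", lambda: self._gcomp(ZX, y, full_data=rows is None))
        if inp is not None:
            if "ipw_standard" in self.estimators:
                attempt("ipw_standard", lambda: rd_ipw(inp))
            if "ipw_augmented" in self.estimators:
                attempt("ipw_augmented", lambda: rd_aug(inp))
            if "ipw_doubly_robust" in self.estimators:

                def _dr():
                    m0, m1 = self._group_models(Z, x, y, full_data=rows is None)
                    return rd_dr(RiskDifferenceInput(y, x, inp.ps, m0, m1))

                attempt("ipw_doubly_robust", _dr)
        return out, failed

    def _gcomp(self, ZX: np.ndarray, y: np.ndarray, full_data: bool = False) -> float:
        des = DesignMatrix(ZX, self.zx_labels)
        fit = fit_logistic(des, y, beta0=self._warm.get("gcomp"))
        if full_data:
            self._warm["gcomp"] = fit.beta
        j = self.exposure_col
        X1 = ZX.copy()
        X1[:, j] = 1.0
        X0 = ZX.copy()
        X0[:, j] = 0.0
        p1 = predict_probability(fit, DesignMatrix(X1, self.zx_labels))
        p0 = predict_probability(fit, DesignMatrix(X0, self.zx_labels))
        return float(np.mean(p1 - p0))

    def _group_models(self, Z, x, y, full_data: bool = False):
        preds = {}
        full = DesignMatrix(Z, self.z_labels)
        for group in (0, 1):
            mask = x == group
            sub = DesignMatrix(Z[mask], self.z_labels)
            fit = fit_logistic(sub, y[mask], beta0=self._warm.get(f"m{group}"))
            if full_data:
                self._warm[f"m{group}"] = fit.beta
            preds[group] = predict_probability(fit, full)
        return preds[0], preds[1]


def bootstrap_many(
    cohort: CohortTable,
    covariates: list[str],
    estimators: tuple[str, ...],
    plan: BootstrapPlan,
    resample_indices: list[np.ndarray] | None = None,
) -> dict[str, BootstrapResult]:
    """Bootstrap several estimators on identical resamples.

    ``resample_indices`` lets a caller (the model ledger) share one set of
    resamples across several model specifications; when omitted, indices
    are drawn from ``plan.seed``.
    """
    engine = _ReplicateEngine(cohort, covariates, estimators)
    points, _ = engine.estimate(None)
    n = len(cohort)
    if resample_indices is None:
        rng = np.random.default_rng(plan.seed)
        resample_indices = [rng.integers(0, n, n) for _ in range(plan.b)]
    elif len(resample_indices) != plan.b:
        raise DomainError("resample_indices length must equal plan.b")

    reps: dict[str, list[float]] = {e: [] for e in estimators}
    failures: dict[str, dict[str, int]] = {e: {} for e in estimators}
    for rows in resample_indices:
        est, failed = engine.estimate(rows, collect_failures=True)
        for e, value in est.items():
            reps[e].append(value)
        for e, reason in failed.items():
            failures[e][reason] = failures[e].get(reason, 0) + 1

    out = {}
    for e in estimators:
        values = np.asarray(reps[e])
        eff = values.size
        if eff == 0:
            raise ReliabilityError(
                f"{e}: no successful bootstrap replicates out of {plan.b}"
            )
        reliable = eff >= RELIABILITY_FRACTION * plan.b
        if not reliable and plan.strict:
            raise ReliabilityError(
                f"{e}: only {eff}/{plan.b} replicates succeeded"
            )
        lo, hi = percentile_ci(values, plan.level)
        mse = float(np.mean((values - points[e]) ** 2))
        out[e] = BootstrapResult(
            estimator=e,
            point=points[e],
            replicates=values,
            requested_b=plan.b,
            effective_b=eff,
            ci_low=lo,
            ci_high=hi,
            mse=mse,
            seed=plan.seed,
            level=plan.level,
            reliable=reliable,
            failures=failures[e],
        )
    return out


def bootstrap(
    cohort: CohortTable,
    covariates: list[str],
    estimator: str,
    plan: BootstrapPlan,
) -> BootstrapResult:
    """Percentile bootstrap of a single risk-difference estimator."""
    return bootstrap_many(cohort, covariates, (estimator,), plan)[estimator]
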