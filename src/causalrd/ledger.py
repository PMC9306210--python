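"""The 24-model confounder-sensitivity grid and full-to-reduced selection.

The sensitivity analysis asks how much the exposure effect moves when the
adjustment set changes.  Model 1 is the full model with all 11
confounders; models 2-12 remove each confounder in turn; model 13 is the
reduced model keeping only the confounders significant in the full
logistic fit; models 14-17 remove each reduced-set member in turn; models
18-24 add back each excluded variable.  A crude (unadjusted)
specification is appended.  Categorical variables enter and leave
atomically — all of a variable's indicator columns move together.

Significance for the full-to-reduced step is judged at the variable
level: a confounder is retained if any of its non-reference levels has a
profile-likelihood interval excluding an odds ratio of 1 (5% level by
default).  Bootstrap resamples are shared across models within a ledger
run so that between-model deviations reflect the adjustment sets, not
resampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bootstrap import BootstrapPlan, bootstrap_many, significance_flag
from .cohort import CONFOUNDER_ORDER, CohortTable, VariableCodebook, build_design
from .errors import ContractError, EstimationError, SchemaError
from .estimators import or_logistic
from .glm import fit_logistic, profile_likelihood_ci

__all__ = [
    "ModelSpec",
    "LedgerReport",
    "full_model_spec",
    "select_significant",
    "build_ledger",
    "run_ledger",
    "coefficient_report",
]


@dataclass(frozen=True)
class ModelSpec:
    """A named confounder set defining one analysis."""

    model_id: str
    variables: tuple[str, ...]
    lineage: str  # full | full-minus-v | reduced | reduced-minus-v |
    #               reduced-plus-v | crude
    alias_of: str | None = None


@dataclass
class LedgerReport:
    """Long-format results of a ledger run plus between-model deviations."""

    table: pd.DataFrame
    specs: tuple[ModelSpec, ...]
    max_deviation_vs_full: dict[str, float] = field(default_factory=dict)
    max_deviation_vs_reduced: dict[str, float] = field(default_factory=dict)


def full_model_spec(codebook: VariableCodebook) -> ModelSpec:
    """Model 1: all 11 confounders in their declared order."""
    missing = [v for v in CONFOUNDER_ORDER if v not in codebook]
    if missing:
        raise SchemaError(f"codebook lacks confounders: {missing}")
    return ModelSpec("1", tuple(CONFOUNDER_ORDER), "full")


def select_significant(
    cohort: CohortTable, full: ModelSpec, alpha: float = 0.05
) -> ModelSpec:
    """Reduced model: confounders significant in the full logistic fit.

    Fits outcome ~ exposure + all confounders and keeps a confounder iff
    any of its non-reference levels has a profile-likelihood interval
    excluding OR = 1 at ``alpha``.  Exposure itself is always retained (it
    is not part of the adjustment set).
    """
    if alpha >= 1.0:
        return ModelSpec("13", full.variables, "reduced")
    design = build_design(cohort, list(full.variables), include_exposure=True)
    fit = fit_logistic(design, cohort.y)
    keep = []
    for name in full.variables:
        var = cohort.codebook[name]
        significant = False
        for level in var.non_reference_levels:
            j = design.column_index(f"{name}[{level}]")
            lo, hi = profile_likelihood_ci(
                fit, design, cohort.y, j, level=1.0 - alpha
            )
            if significance_flag((lo, hi), scale="odds_ratio"):
                significant = True
                break
        if significant:
            keep.append(name)
    return ModelSpec("13", tuple(keep), "reduced")


def build_ledger(full: ModelSpec, reduced: ModelSpec) -> list[ModelSpec]:
    """All 24 model specifications plus the crude model.

    1 = full; 2..12 = full minus each confounder; 13 = reduced;
    then reduced minus each member; then reduced plus each excluded
    variable; finally the crude (empty) adjustment set.  Specs whose
    variable set duplicates an earlier spec carry ``alias_of``.
    """
    if not set(reduced.variables) <= set(full.variables):
        raise ContractError("reduced model must be a subset of the full model")
    specs: list[ModelSpec] = [ModelSpec("1", full.variables, "full")]
    mid = 2
    for v in full.variables:
        specs.append(
            ModelSpec(
                str(mid),
                tuple(w for w in full.variables if w != v),
                f"full-minus-{v}",
            )
        )
        mid += 1
    specs.append(ModelSpec(str(mid), reduced.variables, "reduced"))
    mid += 1
    for v in reduced.variables:
        specs.append(
            ModelSpec(
                str(mid),
                tuple(w for w in reduced.variables if w != v),
                f"reduced-minus-{v}",
            )
        )
        mid += 1
    for v in full.variables:
        if v in reduced.variables:
            continue
        specs.append(
            ModelSpec(
                str(mid),
                tuple(reduced.variables) + (v,),
                f"reduced-plus-{v}",
            )
        )
        mid += 1
    specs.append(ModelSpec("crude", (), "crude"))

    seen: dict[frozenset, str] = {}
    out: list[ModelSpec] = []
    for spec in specs:
        key = frozenset(spec.variables)
        if key in seen:
            out.append(
                ModelSpec(spec.model_id, spec.variables, spec.lineage, seen[key])
            )
        else:
            seen[key] = spec.model_id
            out.append(spec)
    return out


def run_ledger(
    cohort: CohortTable,
    specs: list[ModelSpec],
    estimators: tuple[str, ...],
    plan: BootstrapPlan,
    shared_resamples: bool = True,
    include_or: bool = False,
) -> LedgerReport:
    """Bootstrap every (model, estimator) cell of the ledger.

    With ``shared_resamples`` (default), one set of resample indices drawn
    from ``plan.seed`` is reused for every model; per-model independent
    resampling is available by switching it off.  Per-cell failures are
    recorded and the run continues.
    """
    n = len(cohort)
    indices = None
    if shared_resamples:
        rng = np.random.default_rng(plan.seed)
        indices = [rng.integers(0, n, n) for _ in range(plan.b)]

    rows = []
    cache: dict[str, dict] = {}
    for spec in specs:
        source = spec.alias_of or spec.model_id
        if source in cache:
            results = cache[source]
        else:
            try:
                results = bootstrap_many(
                    cohort, list(spec.variables), estimators, plan, indices
                )
            except Exception as err:  # per-cell failure: record, keep going
                results = {"__error__": f"{type(err).__name__}: {err}"}
            cache[source] = results
        if "__error__" in results:
            for e in estimators:
                rows.append(
                    {
                        "model_id": spec.model_id,
                        "lineage": spec.lineage,
                        "estimator": e,
                        "point": np.nan,
                        "ci_low": np.nan,
                        "ci_high": np.nan,
                        "significant": False,
                        "effective_b": 0,
                        "mse": np.nan,
                        "reliable": False,
                        "failure": results["__error__"],
                    }
                )
            continue
        for e in estimators:
            r = results[e]
            rows.append(
                {
                    "model_id": spec.model_id,
                    "lineage": spec.lineage,
                    "estimator": e,
                    "point": r.point,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "significant": significance_flag((r.ci_low, r.ci_high)),
                    "effective_b": r.effective_b,
                    "mse": r.mse,
                    "reliable": r.reliable,
                    "failure": "",
                }
            )
        if include_or:
            try:
                orr = or_logistic(cohort, list(spec.variables))
                rows.append(
                    {
                        "model_id": spec.model_id,
                        "lineage": spec.lineage,
                        "estimator": "logistic_or",
                        "point": orr.point,
                        "ci_low": orr.ci_low,
                        "ci_high": orr.ci_high,
                        "significant": significance_flag(
                            (orr.ci_low, orr.ci_high), scale="odds_ratio"
                        ),
                        "effective_b": None,
                        "mse": None,
                        "reliable": True,
                        "failure": "",
                    }
                )
            except EstimationError as err:
                rows.append(
                    {
                        "model_id": spec.model_id,
                        "lineage": spec.lineage,
                        "estimator": "logistic_or",
                        "point": np.nan,
                        "ci_low": np.nan,
                        "ci_high": np.nan,
                        "significant": False,
                        "effective_b": None,
                        "mse": None,
                        "reliable": False,
                        "failure": type(err).__name__,
                    }
                )

    table = pd.DataFrame(rows)
    report = LedgerReport(table=table, specs=tuple(specs))
    for anchor, store in (("full", report.max_deviation_vs_full),
                          ("reduced", report.max_deviation_vs_reduced)):
        base = table[table["lineage"] == anchor]
        for e in estimators:
            ref = base[base["estimator"] == e]["point"]
            if ref.empty or not np.isfinite(ref.iloc[0]):
                continue
            pts = table[table["estimator"] == e]["point"]
            store[e] = float(np.nanmax(np.abs(pts - ref.iloc[0])))
    return report


def coefficient_report(
    cohort: CohortTable,
    specs: list[ModelSpec],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-model odds ratios and significance for every coefficient.

    One row per (model, coefficient); coefficients of variables excluded
    from a model are absent, mirroring the blank cells of a wide
    sensitivity table.
    """
    rows = []
    for spec in specs:
        design = build_design(cohort, list(spec.variables), include_exposure=True)
        try:
            fit = fit_logistic(design, cohort.y)
        except EstimationError as err:
            rows.append(
                {
                    "model_id": spec.model_id,
                    "term": "<failed>",
                    "odds_ratio": np.nan,
                    "significant": False,
                    "failure": type(err).__name__,
                }
            )
            continue
        for j, label in enumerate(design.labels):
            if label == "intercept":
                continue
            lo, hi = profile_likelihood_ci(
                fit, design, cohort.y, j, level=1.0 - alpha
            )
            rows.append(
                {
                    "model_id": spec.model_id,
                    "term": label,
                    "odds_ratio": float(np.exp(fit.beta[j])),
                    "ci_low": lo,
                    "ci_high": hi,
                    "significant": significance_flag((lo, hi), "odds_ratio"),
                    "failure": "",
                }
            )
    return pd.DataFrame(rows)
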