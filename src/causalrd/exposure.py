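"""Derive employed/unemployed/excluded status from labour-history records.

Three measurement modes for unemployment around the 1995 baseline:

* ``self_reported`` — at least half a year (6 months) of self-reported
  unemployment accumulated over the last three years (1993-1995);
* ``register`` — at least 6 months (taken as 182 days, the ceiling of
  365/2, since the register stores day counts) of registered unemployment
  over 1992-1994;
* ``current`` — a tick at "unemployed" on the current-situation question.

In every mode, "employed" requires labour-market attachment — full-time
work, part-time work of 20-39 hours, or a labour-market measure — for at
least 1.5 years (18 months) over the window, with no unemployment under
that mode's measure.  Participants who are neither unemployed nor
attached-and-unemployment-free are excluded with a reason code.

The optional censor policy additionally excludes participants with any
unemployment, or fewer than 18 months of labour-market attachment, during
the 1995-2007 follow-up.  Censoring only removes participants; it never
changes an employed/unemployed call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .errors import CodingError, DomainError

__all__ = [
    "LabourHistoryRecord",
    "ExposureAssignment",
    "EMPLOYMENT_STATUSES",
    "STATUS_VOCABULARY",
    "derive_self_reported_longterm",
    "derive_register_longterm",
    "derive_current",
    "apply_censor_policy",
    "derive_exposure",
    "assignments_to_frame",
    "records_to_frame",
    "frame_to_records",
]

# statuses counting as labour-market attachment
EMPLOYMENT_STATUSES = frozenset(
    {"full_time", "part_time_20_39h", "labour_market_measure"}
)
# current-situation alternatives not counted as being in the labour market
OUT_OF_LABOUR_STATUSES = frozenset(
    {"studies", "other_education", "casual_job", "sick_leave",
     "parental_leave", "other"}
)
STATUS_VOCABULARY = EMPLOYMENT_STATUSES | OUT_OF_LABOUR_STATUSES | {"unemployed"}

UNEMPLOYMENT_MONTHS_MIN = 6
UNEMPLOYMENT_DAYS_MIN = 182  # 6 months of register days: ceil(365 / 2)
ATTACHMENT_MONTHS_MIN = 18  # 1.5 years


@dataclass
class LabourHistoryRecord:
    """Raw survey and register labour-market information for one participant.

    ``retrospective`` and ``followup`` are (status, months) episode lists
    drawn from ``STATUS_VOCABULARY``; ``register_days`` holds registered
    unemployment days for 1992, 1993 and 1994; ``followup_unemployed``
    flags any unemployment during the 1995-2007 follow-up.
    """

    participant_id: int
    current_status: str | None = None
    retrospective: list[tuple[str, float]] = field(default_factory=list)
    register_days: tuple[int, int, int] | None = None
    followup: list[tuple[str, float]] = field(default_factory=list)
    followup_unemployed: bool = False

    def __post_init__(self):
        for status, months in list(self.retrospective) + list(self.followup):
            if status not in STATUS_VOCABULARY:
                raise CodingError(f"unknown episode status {status!r}")
            if months < 0:
                raise DomainError("episode months must be non-negative")
        if self.register_days is not None:
            for d in self.register_days:
                if d < 0:
                    raise DomainError("register day counts must be non-negative")
                if d > 366:
                    raise DomainError("register day count exceeds a calendar year")

    def months(self, statuses: Iterable[str] | str, followup: bool = False) -> float:
        if isinstance(statuses, str):
            statuses = {statuses}
        episodes = self.followup if followup else self.retrospective
        return sum(m for s, m in episodes if s in statuses)


@dataclass
class ExposureAssignment:
    """Mode-specific employed/unemployed/excluded call for one participant."""

    participant_id: int
    mode: str
    status: str  # employed | unemployed | excluded
    censored: bool = False
    reason: str | None = None

    def __post_init__(self):
        if self.status == "excluded" and self.reason is None:
            raise DomainError("excluded assignments must carry a reason")

    @property
    def in_analysis(self) -> bool:
        return self.status != "excluded" and not self.censored


def _attachment_call(
    rec: LabourHistoryRecord, pid: int, mode: str, unemployment_free: bool
) -> ExposureAssignment:
    attachment = rec.months(EMPLOYMENT_STATUSES)
    if unemployment_free and attachment >= ATTACHMENT_MONTHS_MIN:
        return ExposureAssignment(pid, mode, "employed")
    reason = (
        "unemployment_below_threshold"
        if not unemployment_free
        else "insufficient_attachment"
    )
    return ExposureAssignment(pid, mode, "excluded", reason=reason)


def derive_self_reported_longterm(rec: LabourHistoryRecord) -> ExposureAssignment:
    """Accumulated self-reported unemployment 1993-1995, 6-month threshold."""
    mode = "self_reported"
    unemp = rec.months("unemployed")
    if unemp >= UNEMPLOYMENT_MONTHS_MIN:
        return ExposureAssignment(rec.participant_id, mode, "unemployed")
    return _attachment_call(rec, rec.participant_id, mode, unemp == 0)


def derive_register_longterm(rec: LabourHistoryRecord) -> ExposureAssignment:
    """Registered unemployment days 1992-1994, 182-day threshold."""
    mode = "register"
    if rec.register_days is None:
        return ExposureAssignment(
            rec.participant_id, mode, "excluded", reason="no_register_data"
        )
    days = sum(rec.register_days)
    if days >= UNEMPLOYMENT_DAYS_MIN:
        return ExposureAssignment(rec.participant_id, mode, "unemployed")
    return _attachment_call(rec, rec.participant_id, mode, days == 0)


def derive_current(rec: LabourHistoryRecord) -> ExposureAssignment:
    """Current-situation tick: unemployed / in-work / out of labour market."""
    mode = "current"
    tick = rec.current_status
    if tick is None:
        return ExposureAssignment(
            rec.participant_id, mode, "excluded", reason="no_current_status"
        )
    if tick not in STATUS_VOCABULARY:
        raise CodingError(f"unknown current-status tick {tick!r}")
    if tick == "unemployed":
        return ExposureAssignment(rec.participant_id, mode, "unemployed")
    if tick in EMPLOYMENT_STATUSES:
        return ExposureAssignment(rec.participant_id, mode, "employed")
    return ExposureAssignment(
        rec.participant_id, mode, "excluded", reason="out_of_labour_market"
    )


def apply_censor_policy(
    assign: ExposureAssignment,
    rec: LabourHistoryRecord,
    policy: str = "none",
) -> ExposureAssignment:
    """Exclude participants with follow-up unemployment or weak attachment.

    Under ``policy="censor"`` a participant is flagged censored (and so
    excluded from estimation) if they report any unemployment during
    follow-up or accumulate fewer than 18 months of labour-market
    attachment over it.  ``policy="none"`` returns the assignment
    unchanged.
    """
    if policy not in ("none", "censor"):
        raise DomainError(f"unknown censor policy {policy!r}")
    if policy == "none" or assign.status == "excluded":
        return assign
    followup_unemp = rec.followup_unemployed or rec.months(
        "unemployed", followup=True
    ) > 0
    followup_attach = rec.months(EMPLOYMENT_STATUSES, followup=True)
    if followup_unemp:
        return ExposureAssignment(
            assign.participant_id, assign.mode, assign.status,
            censored=True, reason="followup_unemployment",
        )
    if followup_attach < ATTACHMENT_MONTHS_MIN:
        return ExposureAssignment(
            assign.participant_id, assign.mode, assign.status,
            censored=True, reason="followup_insufficient_attachment",
        )
    return assign


_DERIVERS = {
    "self_reported": derive_self_reported_longterm,
    "register": derive_register_longterm,
    "current": derive_current,
}


def derive_exposure(
    records: Iterable[LabourHistoryRecord],
    mode: str,
    policy: str = "none",
) -> list[ExposureAssignment]:
    """Run one mode plus censor policy over a batch of records."""
    if mode not in _DERIVERS:
        raise DomainError(f"unknown unemployment mode {mode!r}")
    derive = _DERIVERS[mode]
    return [apply_censor_policy(derive(rec), rec, policy) for rec in records]


def records_to_frame(records: Iterable[LabourHistoryRecord]) -> pd.DataFrame:
    """One row per participant; episode lists encoded as ``status:months;...``."""

    def enc(episodes):
        return ";".join(f"{s}:{m:g}" for s, m in episodes)

    rows = []
    for r in records:
        d1992, d1993, d1994 = r.register_days or (None, None, None)
        rows.append(
            {
                "participant_id": r.participant_id,
                "current_status": r.current_status or "",
                "retrospective": enc(r.retrospective),
                "register_days_1992": d1992,
                "register_days_1993": d1993,
                "register_days_1994": d1994,
                "followup": enc(r.followup),
                "followup_unemployed": int(r.followup_unemployed),
            }
        )
    return pd.DataFrame(rows)


def frame_to_records(df: pd.DataFrame) -> list[LabourHistoryRecord]:
    """Inverse of :func:`records_to_frame`."""

    def dec(cell) -> list[tuple[str, float]]:
        if not isinstance(cell, str) or not cell:
            return []
        out = []
        for item in cell.split(";"):
            status, months = item.rsplit(":", 1)
            out.append((status, float(months)))
        return out

    records = []
    for _, row in df.iterrows():
        days = (
            row.get("register_days_1992"),
            row.get("register_days_1993"),
            row.get("register_days_1994"),
        )
        register = (
            None
            if any(pd.isna(d) for d in days)
            else tuple(int(d) for d in days)
        )
        current = row.get("current_status")
        records.append(
            LabourHistoryRecord(
                participant_id=int(row["participant_id"]),
                current_status=current if isinstance(current, str) and current else None,
                retrospective=dec(row.get("retrospective")),
                register_days=register,
                followup=dec(row.get("followup")),
                followup_unemployed=bool(int(row.get("followup_unemployed", 0))),
            )
        )
    return records


def assignments_to_frame(assignments: Iterable[ExposureAssignment]) -> pd.DataFrame:
    """Tabulate assignments (one row per participant) for CSV export."""
    return pd.DataFrame(
        [
            {
                "participant_id": a.participant_id,
                "mode": a.mode,
                "status": a.status,
                "censored": a.censored,
                "reason": a.reason or "",
            }
            for a in assignments
        ]
    )
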