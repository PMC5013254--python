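"""Treatment-window construction and cohort inclusion/exclusion filters.

For a chosen primary medication, each subject's evaluation interval
starts at the first in-trial monthly record of the medication.  The
pre-treatment phenotype is the latest measurement at or within a
lookback window (default 30 days) before that start; the post-treatment
phenotype is the first measurement between ``min_days`` and ``max_days``
(default 90–270) after it.  Subjects are excluded — with every
applicable reason recorded — when records are internally inconsistent,
when they never started the medication in-trial or were already on it
at randomization, when the medication was held for too short a span,
stopped and restarted, when per-visit compliance (after NOCB
imputation) fails the 80%-of-visits full-compliance rule or contains
any 0%-compliance record, or when a qualifying phenotype pair is
missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .trial_data import (
    FULL_COMPLIANCE_CODES,
    ZERO_COMPLIANCE_CODE,
    TrialDataset,
    check_record_consistency,
)


@dataclass(frozen=True)
class WindowParams:
    """Timing and compliance thresholds for the treatment window."""

    min_days: int = 90
    max_days: int = 270
    pre_lookback_days: int = 30
    full_compliance_visit_fraction: float = 0.8

    def __post_init__(self) -> None:
        if not (0 < self.min_days < self.max_days):
            raise ValueError("require 0 < min_days < max_days")
        if not (0 < self.full_compliance_visit_fraction <= 1):
            raise ValueError("full_compliance_visit_fraction must be in (0, 1]")


@dataclass(frozen=True)
class PhenotypeObs:
    subject_id: str
    day: int
    phenotype: str
    value: float


@dataclass(frozen=True)
class TreatmentWindow:
    """One subject's primary-medication evaluation interval."""

    subject_id: str
    medication: str
    start_day: int
    pre_obs: PhenotypeObs
    post_obs: PhenotypeObs

    @property
    def response(self) -> float:
        """Phenotype change: post minus pre (e.g. change in %HbA1c)."""
        return self.post_obs.value - self.pre_obs.value


class ExclusionReason(str, Enum):
    inconsistent_records = "inconsistent_records"
    never_on = "never_on"
    on_at_baseline = "on_at_baseline"
    insufficient_duration = "insufficient_duration"
    stop_restart = "stop_restart"
    zero_compliance = "zero_compliance"
    low_compliance = "low_compliance"
    missing_phenotype = "missing_phenotype"


#: Documented evaluation order; membership is order-insensitive but the
#: tally attribution follows this order.
REASON_ORDER: tuple[ExclusionReason, ...] = (
    ExclusionReason.inconsistent_records,
    ExclusionReason.never_on,
    ExclusionReason.on_at_baseline,
    ExclusionReason.insufficient_duration,
    ExclusionReason.stop_restart,
    ExclusionReason.zero_compliance,
    ExclusionReason.low_compliance,
    ExclusionReason.missing_phenotype,
)


@dataclass
class CohortSelectionResult:
    included: list[TreatmentWindow]
    excluded: dict[str, set[ExclusionReason]]
    tally: dict[ExclusionReason, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        inc = {w.subject_id for w in self.included}
        if inc & set(self.excluded):
            raise ValueError("a subject cannot be both included and excluded")
        if not self.tally:
            self.tally = {r: 0 for r in REASON_ORDER}
            for reasons in self.excluded.values():
                for r in reasons:
                    self.tally[r] += 1

    @property
    def included_ids(self) -> list[str]:
        return [w.subject_id for w in self.included]

    def responses(self) -> pd.Series:
        return pd.Series(
            {w.subject_id: w.response for w in self.included}, name="response", dtype=float
        )

    def tally_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.value, self.tally.get(r, 0)) for r in REASON_ORDER],
            columns=["reason", "count"],
        )


def nocb_impute(seq: Sequence[float | int | None]) -> tuple[list[float | int | None], bool]:
    """Next-observation-carried-backward imputation of compliance codes.

    Each missing entry takes the value of the next non-missing entry
    (compliance at a visit describes the interval since the previous
    visit, so the later record is the informative one).  Trailing
    missing entries, which have no next observation, fall back to the
    last preceding value (LOCF).  Returns the imputed sequence and a
    flag that is True when the sequence was entirely missing (returned
    unchanged).
    """
    vals = [None if _is_missing(v) else v for v in seq]
    if all(v is None for v in vals):
        return list(vals), True
    out: list = list(vals)
    nxt = None
    for i in range(len(out) - 1, -1, -1):
        if out[i] is None:
            out[i] = nxt
        else:
            nxt = out[i]
    prev = None
    for i, v in enumerate(out):
        if v is None:
            out[i] = prev
        else:
            prev = v
    return out, False


def _is_missing(v) -> bool:
    if v is None:
        return True
    try:
        return bool(pd.isna(v))
    except (TypeError, ValueError):
        return False


def find_start_day(ds: TrialDataset, subject_id: str, medication: str) -> int | None:
    """First monthly-log day for the medication or any of its class members."""
    names = ds.medication_names(medication)
    sub = ds.subject_med_logs(subject_id)
    rows = sub.loc[sub["medication"].isin(names), "day"]
    return int(rows.min()) if len(rows) else None


def subject_visit_days(ds: TrialDataset, subject_id: str) -> list[int]:
    """All distinct monthly-visit days for a subject (any medication)."""
    return sorted(set(ds.subject_med_logs(subject_id)["day"].tolist()))


def detect_stop_restart(
    ds: TrialDataset,
    subject_id: str,
    medication: str,
    start_day: int,
    params: WindowParams = WindowParams(),
    gap_tolerance_visits: int = 0,
) -> bool:
    """Gap-and-resume detection at visit granularity.

    True iff, within ``[start_day, start_day + max_days]``, the subject
    attended more than ``gap_tolerance_visits`` consecutive visits with
    no record of the medication and then a later visit with a record of
    it.  Stopping without resuming is not a stop–restart.
    """
    names = ds.medication_names(medication)
    sub = ds.subject_med_logs(subject_id)
    window_end = start_day + params.max_days
    visits = sorted(set(sub.loc[(sub["day"] >= start_day) & (sub["day"] <= window_end), "day"]))
    on_days = set(sub.loc[sub["medication"].isin(names), "day"])
    gap = 0
    for v in visits:
        if v in on_days:
            if gap > gap_tolerance_visits:
                return True
            gap = 0
        else:
            gap += 1
    return False


def evaluate_compliance(
    codes: Sequence[float | int | None], params: WindowParams = WindowParams()
) -> tuple[float, bool]:
    """Fraction of records at full compliance, and any-0%-record flag.

    ``codes`` are the NOCB-imputed compliance codes of the medication's
    records inside the window.  Codes 1 and 4 count as full compliance;
    code 3 is 0% compliance.
    """
    vals = [v for v in codes if not _is_missing(v)]
    if not vals:
        raise ValueError("no compliance records in window")
    full = sum(1 for v in vals if int(v) in FULL_COMPLIANCE_CODES)
    any_zero = any(int(v) == ZERO_COMPLIANCE_CODE for v in vals)
    return full / len(vals), any_zero


def window_compliance_codes(
    ds: TrialDataset,
    subject_id: str,
    medication: str,
    start_day: int,
    params: WindowParams = WindowParams(),
) -> list:
    """NOCB-imputed compliance codes for the medication's in-window records."""
    names = ds.medication_names(medication)
    logs = ds.subject_med_logs(subject_id)
    sub = logs.loc[
        logs["medication"].isin(names)
        & (logs["day"] >= start_day)
        & (logs["day"] <= start_day + params.max_days)
    ].sort_values("day")
    if sub["day"].duplicated().any():
        # class members recorded on the same visit: keep the most
        # compliant code for that visit
        def _best(group: pd.Series):
            obs = [c for c in group if not _is_missing(c)]
            if not obs:
                return np.nan
            return min(obs, key=lambda c: {1: 0, 4: 0, 2: 1, 3: 2}[int(c)])

        codes = sub.groupby("day")["compliance"].agg(_best).tolist()
    else:
        codes = sub["compliance"].tolist()
    imputed, _ = nocb_impute(codes)
    return imputed


def extract_window_phenotypes(
    ds: TrialDataset,
    subject_id: str,
    start_day: int,
    phenotype: str,
    params: WindowParams = WindowParams(),
) -> tuple[PhenotypeObs, PhenotypeObs] | ExclusionReason:
    """Pre/post phenotype pair for a window, or ``missing_phenotype``.

    Pre = latest observation with ``start − lookback ≤ day ≤ start``
    (a same-day draw counts as pre-treatment); post = earliest
    observation with ``min_days ≤ day − start ≤ max_days``.
    """
    p = ds.subject_phenotypes(subject_id)
    sub = p.loc[p["phenotype"] == phenotype]
    pre = sub.loc[
        (sub["day"] >= start_day - params.pre_lookback_days) & (sub["day"] <= start_day)
    ].sort_values("day")
    post = sub.loc[
        (sub["day"] >= start_day + params.min_days) & (sub["day"] <= start_day + params.max_days)
    ].sort_values("day")
    if pre.empty or post.empty:
        return ExclusionReason.missing_phenotype
    pr, po = pre.iloc[-1], post.iloc[0]
    return (
        PhenotypeObs(subject_id, int(pr["day"]), phenotype, float(pr["value"])),
        PhenotypeObs(subject_id, int(po["day"]), phenotype, float(po["value"])),
    )


def _on_at_baseline(ds: TrialDataset, subject_id: str, medication: str, start_day: int) -> bool:
    if start_day == 0:
        return True
    class_name = ds.medication_class_map.get(medication, medication)
    a = ds.subject_annual_logs(subject_id)
    rows = a.loc[(a["medication_class"] == class_name) & (a["day"] <= 0) & a["on_flag"]]
    return bool(len(rows))


def select_primary_cohort(
    ds: TrialDataset,
    medication: str,
    phenotype: str,
    params: WindowParams = WindowParams(),
    subjects: Iterable[str] | None = None,
) -> CohortSelectionResult:
    """Apply all inclusion filters; survivors become TreatmentWindows.

    Every applicable exclusion reason is recorded per subject (a subject
    may carry several); an empty cohort is a valid outcome.
    """
    inconsistent = check_record_consistency(ds, medication)
    names = ds.medication_names(medication)
    included: list[TreatmentWindow] = []
    excluded: dict[str, set[ExclusionReason]] = {}
    ids = list(subjects) if subjects is not None else ds.subject_ids
    for sid in ids:
        reasons: set[ExclusionReason] = set()
        if bool(inconsistent.get(sid, False)):
            reasons.add(ExclusionReason.inconsistent_records)
        start = find_start_day(ds, sid, medication)
        if start is None:
            reasons.add(ExclusionReason.never_on)
            excluded[sid] = reasons
            continue
        if _on_at_baseline(ds, sid, medication, start):
            reasons.add(ExclusionReason.on_at_baseline)
        logs = ds.subject_med_logs(sid)
        sub = logs.loc[logs["medication"].isin(names)]
        last_day = int(sub["day"].max())
        if last_day < start + params.min_days:
            reasons.add(ExclusionReason.insufficient_duration)
        if detect_stop_restart(ds, sid, medication, start, params):
            reasons.add(ExclusionReason.stop_restart)
        codes = window_compliance_codes(ds, sid, medication, start, params)
        observed = [c for c in codes if not _is_missing(c)]
        if observed:
            frac, any_zero = evaluate_compliance(observed, params)
            if any_zero:
                reasons.add(ExclusionReason.zero_compliance)
            if frac < params.full_compliance_visit_fraction:
                reasons.add(ExclusionReason.low_compliance)
        obs = extract_window_phenotypes(ds, sid, start, phenotype, params)
        if isinstance(obs, ExclusionReason):
            reasons.add(obs)
        if reasons:
            excluded[sid] = reasons
        else:
            pre, post = obs
            included.append(TreatmentWindow(sid, medication, start, pre, post))
    return CohortSelectionResult(included=included, excluded=excluded)
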