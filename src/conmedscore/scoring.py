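"""Trajectory scoring of concomitant medications against a subject's
primary-medication treatment window.

The five-level score summarizes when a concomitant medication was
started and whether it was maintained, relative to the window already
fixed by the subject's primary medication:

====  =========================================================
score meaning
====  =========================================================
0     no record of ever taking the medication
1     already on at window start, stopped before the window end
2     started at/after window start, stopped before the end
3     started at/after window start, compliant to the end
4     already on at window start, compliant to the end
====  =========================================================

Scores 3 and 4 additionally require the medication's own compliance
records (NOCB-imputed) to pass the 80%-of-visits full-compliance rule
with no 0%-compliance record; a medication carried to the window end
with failing compliance is downgraded to the corresponding "stopped"
score (1 or 2).  Medications with only annual records get a binary
score: 1 if the most recent annual record before the window start shows
the subject on the medication, else 0 (0 with a ``not_scorable`` flag
when no annual record exists at all).  Insulin, recorded as a
continuous dose, is not scored but summarized as the change in units
per day between the window and the last pre-start record.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import (
    TreatmentWindow,
    WindowParams,
    evaluate_compliance,
    window_compliance_codes,
    _is_missing,
)
from .trial_data import TrialDataset

INSULIN_NAME = "insulin"


@dataclass(frozen=True)
class ScoringParams:
    """Window timing plus the persistence-to-end convention.

    ``persistence_grace_days`` — a medication counts as carried to the
    window end if its last in-window record is no more than this many
    days before ``start + max_days``; defaults to one monthly visit
    interval.
    """

    window: WindowParams = WindowParams()
    persistence_grace_days: int = 30


@dataclass(frozen=True)
class ConmedScore:
    subject_id: str
    medication_or_class: str
    value: int
    encoding: str  # "five_level" | "binary_annual"
    not_scorable: bool = False

    def __post_init__(self) -> None:
        if self.encoding == "binary_annual" and self.value not in (0, 1):
            raise ValueError("binary_annual scores must be 0 or 1")
        if self.value not in (0, 1, 2, 3, 4):
            raise ValueError("score must be in 0..4")


@dataclass(frozen=True)
class InsulinDelta:
    subject_id: str
    delta_units_per_day: float


def _annual_on_at_start(
    ds: TrialDataset, subject_id: str, class_name: str, start_day: int
) -> bool | None:
    """on_flag of the most recent annual class record at/before start.

    None when the subject has no annual record for the class at all.
    """
    a = ds.subject_annual_logs(subject_id)
    sub = a.loc[a["medication_class"] == class_name]
    if sub.empty:
        return None
    prior = sub.loc[sub["day"] <= start_day].sort_values("day")
    if prior.empty:
        return False
    return bool(prior.iloc[-1]["on_flag"])


def score_monthly_conmed(
    ds: TrialDataset,
    subject_id: str,
    conmed: str,
    window: TreatmentWindow,
    params: ScoringParams = ScoringParams(),
) -> ConmedScore:
    """Five-level trajectory score for a monthly-logged conmed.

    The conmed is evaluated strictly against the subject's existing
    primary-medication window; class members of ``conmed`` are pooled
    into one pseudo-medication trajectory, and annual class records at
    or before the start can establish that the subject was already on
    the medication.
    """
    if window is None:
        raise ValueError("subject has no treatment window")
    names = ds.medication_names(conmed)
    class_name = ds.medication_class_map.get(conmed, conmed)
    logs = ds.subject_med_logs(subject_id)
    recs = logs.loc[logs["medication"].isin(names)]
    annual_on = _annual_on_at_start(ds, subject_id, class_name, window.start_day)
    if recs.empty and not annual_on:
        return ConmedScore(subject_id, conmed, 0, "five_level")

    start = window.start_day
    window_end = start + params.window.max_days
    on_at_start = bool(annual_on) or bool((recs["day"] <= start).any())

    in_window = recs.loc[(recs["day"] >= start) & (recs["day"] <= window_end)]
    if in_window.empty:
        persisted = False
    else:
        reaches_end = int(in_window["day"].max()) >= window_end - params.persistence_grace_days
        codes = window_compliance_codes(ds, subject_id, conmed, start, params.window)
        observed = [c for c in codes if not _is_missing(c)]
        if observed:
            frac, any_zero = evaluate_compliance(observed, params.window)
            compliant = (
                frac >= params.window.full_compliance_visit_fraction and not any_zero
            )
        else:
            # no compliance recorded for any in-window visit: presence alone
            # cannot establish scores 3/4
            compliant = False
        persisted = reaches_end and compliant

    if on_at_start:
        value = 4 if persisted else 1
    else:
        value = 3 if persisted else 2
    return ConmedScore(subject_id, conmed, value, "five_level")


def score_annual_conmed(
    ds: TrialDataset, subject_id: str, conmed_class: str, window: TreatmentWindow
) -> ConmedScore:
    """Binary score for a conmed class with only yearly records."""
    annual_on = _annual_on_at_start(ds, subject_id, conmed_class, window.start_day)
    if annual_on is None:
        return ConmedScore(subject_id, conmed_class, 0, "binary_annual", not_scorable=True)
    return ConmedScore(subject_id, conmed_class, int(annual_on), "binary_annual")


def combine_class_scores(
    ds: TrialDataset,
    subject_id: str,
    class_name: str,
    window: TreatmentWindow,
    params: ScoringParams = ScoringParams(),
) -> ConmedScore:
    """Score a drug class as the union of its members' trajectories."""
    if not ds.class_members(class_name) and class_name not in set(
        ds.medication_class_map.values()
    ):
        raise ValueError(f"unknown medication class: {class_name}")
    score = score_monthly_conmed(ds, subject_id, class_name, window, params)
    return ConmedScore(subject_id, class_name, score.value, "five_level", score.not_scorable)


def insulin_change(
    ds: TrialDataset,
    subject_id: str,
    window: TreatmentWindow,
    params: ScoringParams = ScoringParams(),
    insulin_name: str = INSULIN_NAME,
) -> InsulinDelta:
    """Change in total insulin units/day between window and pre-start.

    Delta = mean dose over records in ``[start+min_days, start+max_days]``
    minus the most recent dose at/before the start (0 when never on
    insulin before the start).  A subject with no insulin records at all
    scores 0; a pre-start user with no in-window records scores minus
    the pre-start dose (discontinuation).
    """
    logs = ds.subject_med_logs(subject_id)
    recs = logs.loc[
        (logs["medication"] == insulin_name) & logs["insulin_units_per_day"].notna()
    ]
    if recs.empty:
        return InsulinDelta(subject_id, 0.0)
    start = window.start_day
    pre = recs.loc[recs["day"] <= start].sort_values("day")
    pre_dose = float(pre.iloc[-1]["insulin_units_per_day"]) if len(pre) else 0.0
    w = recs.loc[
        (recs["day"] >= start + params.window.min_days)
        & (recs["day"] <= start + params.window.max_days)
    ]
    window_dose = float(w["insulin_units_per_day"].mean()) if len(w) else 0.0
    return InsulinDelta(subject_id, window_dose - pre_dose)


def score_table(
    ds: TrialDataset,
    windows: dict[str, TreatmentWindow],
    monthly_conmeds: list[str],
    annual_conmeds: list[str] | None = None,
    params: ScoringParams = ScoringParams(),
    include_insulin: bool = False,
) -> pd.DataFrame:
    """Raw score matrix: one row per subject, one column per conmed."""
    annual_conmeds = annual_conmeds or []
    rows = {}
    for sid, window in windows.items():
        row: dict[str, float] = {}
        for med in monthly_conmeds:
            row[med] = score_monthly_conmed(ds, sid, med, window, params).value
        for med in annual_conmeds:
            s = score_annual_conmed(ds, sid, med, window)
            row[med] = s.value
            row[f"{med}__not_scorable"] = int(s.not_scorable)
        if include_insulin:
            row["insulin_delta"] = insulin_change(ds, sid, window, params).delta_units_per_day
        rows[sid] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "subject_id"
    return out


def score_distribution(scores: pd.DataFrame, conmeds: list[str]) -> pd.DataFrame:
    """Per-conmed counts of scores 0–4 and not-scorable subjects."""
    rows = []
    for med in conmeds:
        counts = scores[med].value_counts()
        ns_col = f"{med}__not_scorable"
        n_ns = int(scores[ns_col].sum()) if ns_col in scores else 0
        rows.append(
            [med] + [int(counts.get(v, 0)) for v in range(5)] + [n_ns]
        )
    return pd.DataFrame(rows, columns=["medication", "0", "1", "2", "3", "4", "not_scorable"])


def encode_dummies(
    scores: pd.DataFrame, conmeds: list[str], encodings: dict[str, str] | None = None
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Indicator columns versus referent score 0, plus group metadata.

    Five-level scores expand to up to four indicators (``med_score_1``
    .. ``med_score_4``); binary annual scores to one (``med_score_1``).
    Levels absent from the data are omitted and simply missing from the
    group's member list.  The returned metadata maps each medication to
    the columns that must enter or leave a model together.
    """
    encodings = encodings or {}
    cols: dict[str, np.ndarray] = {}
    groups: dict[str, list[str]] = {}
    for med in conmeds:
        enc = encodings.get(med, "five_level")
        levels = [1] if enc == "binary_annual" else [1, 2, 3, 4]
        members = []
        for lvl in levels:
            ind = (scores[med] == lvl).astype(float)
            if ind.sum() == 0:
                continue  # level unobserved: degenerate column omitted
            name = f"{med}_score_{lvl}"
            cols[name] = ind.values
            members.append(name)
        groups[med] = members
    out = pd.DataFrame(cols, index=scores.index)
    return out, groups
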