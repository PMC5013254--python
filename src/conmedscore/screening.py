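"""Concomitant-medication screening: time-on-drug vs phenotype change.

Candidate concomitant medications are screened one at a time with a
Wilcoxon rank-sum test comparing the phenotype change of subjects who
were ever on the medication (days on > 0, computed over the full trial
record) against subjects never on it, followed by Benjamini–Hochberg
FDR control over the screened set.  The screen is deliberately
univariate and permissive: it exists to limit how many medications must
be trajectory-scored, and false positives are later removed by model
selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import CohortSelectionResult
from .trial_data import TrialDataset


@dataclass(frozen=True)
class ScreeningResult:
    medication: str
    statistic: float | None
    p_value: float | None
    q_value: float | None
    n_on: int
    n_off: int
    selected: bool


def days_on_medication(ds: TrialDataset, subject_id: str, medication: str) -> int:
    """Total days on a medication by the inter-visit-interval convention.

    Each consecutive pair of the subject's visits contributes the
    interval length when the earlier visit carries a record of the
    medication (or any class member); a record at the final visit adds
    nothing because no later visit bounds the interval.
    """
    names = ds.medication_names(medication)
    sub = ds.subject_med_logs(subject_id)
    visits = sorted(set(sub["day"]))
    if len(visits) < 2:
        return 0
    on = set(sub.loc[sub["medication"].isin(names), "day"])
    total = 0
    for a, b in zip(visits[:-1], visits[1:]):
        if a in on:
            total += b - a
    return total


def wilcoxon_rank_sum(
    x, y, exact_max_n: int = 8
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns the rank-sum statistic W for the first sample and its
    two-sided p-value: an exact permutation p when the smaller group has
    at most ``exact_max_n`` observations and there are no ties, and a
    normal approximation with tie and continuity correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (min(x.size, y.size) <= exact_max_n and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    w = float(res.statistic) + x.size * (x.size + 1) / 2.0  # U -> rank-sum W
    return w, float(min(res.pvalue, 1.0))


def bh_fdr(p) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def screen_conmeds(
    cohort: CohortSelectionResult,
    ds: TrialDataset,
    conmed_list: list[str],
    q_threshold: float = 0.05,
    exact_max_n: int = 8,
) -> pd.DataFrame:
    """Rank-sum screen of each candidate conmed against phenotype change.

    For each medication, subjects in the cohort are split into ever-on
    (days on > 0 over the whole trial record) versus never-on, and the
    response difference is tested.  Medications with an empty group are
    reported untested (p absent) and never selected.  Returns one row
    per conmed with columns medication, statistic, p_value, q_value,
    n_on, n_off, selected.
    """
    if not cohort.included:
        raise ValueError("cohort is empty")
    resp = cohort.responses()
    ids = list(resp.index)
    rows = []
    for med in conmed_list:
        days = np.array([days_on_medication(ds, sid, med) for sid in ids])
        on = resp.values[days > 0]
        off = resp.values[days == 0]
        if on.size == 0 or off.size == 0:
            rows.append((med, np.nan, np.nan, on.size, off.size))
        else:
            w, p = wilcoxon_rank_sum(on, off, exact_max_n=exact_max_n)
            rows.append((med, w, p, on.size, off.size))
    table = pd.DataFrame(rows, columns=["medication", "statistic", "p_value", "n_on", "n_off"])
    table["q_value"] = np.nan
    tested = table["p_value"].notna()
    if tested.any():
        table.loc[tested, "q_value"] = bh_fdr(table.loc[tested, "p_value"].values)
    table["selected"] = tested & (table["q_value"] < q_threshold)
    return table
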