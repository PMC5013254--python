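import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conmedscore.cohort import (
    ExclusionReason,
    WindowParams,
    detect_stop_restart,
    evaluate_compliance,
    extract_window_phenotypes,
    find_start_day,
    nocb_impute,
    select_primary_cohort,
)

from conftest import make_dataset

M = None  # missing marker for readability


class TestNocb:
    @pytest.mark.parametrize(
        "seq, expected",
        [
            ([1, M, 1], [1, 1, 1]),
            ([M, 2, 1], [2, 2, 1]),
            ([1, M], [1, 1]),          # trailing gap falls back to LOCF
            ([M, M, 3], [3, 3, 3]),
            ([2, M, M, 1, M], [2, 1, 1, 1, 1]),
            ([4], [4]),
        ],
    )
    def test_backfill(self, seq, expected):
        out, all_missing = nocb_impute(seq)
        assert out == expected
        assert not all_missing

    def test_all_missing_flagged_unchanged(self):
        out, all_missing = nocb_impute([M, M])
        assert all_missing and out == [M, M]

    def test_nan_treated_as_missing(self):
        out, _ = nocb_impute([1.0, np.nan, 2.0])
        assert out == [1.0, 2.0, 2.0]

    @given(st.lists(st.one_of(st.none(), st.integers(1, 4)), max_size=20))
    @settings(max_examples=200, deadline=None)
    def test_idempotent_and_preserves_observed(self, seq):
        once, _ = nocb_impute(seq)
        twice, _ = nocb_impute(once)
        assert once == twice
        for orig, imp in zip(seq, once):
            if orig is not None:
                assert imp == orig


class TestFindStartDay:
    def test_minimum_day(self):
        ds = make_dataset([("S1", 60, "m", 1), ("S1", 90, "m", 1), ("S1", 120, "m", 1)])
        assert find_start_day(ds, "S1", "m") == 60

    def test_no_entries(self):
        ds = make_dataset([("S1", 60, "m", 1)])
        assert find_start_day(ds, "S1", "other") is None

    def test_class_union(self):
        ds = make_dataset(
            [("S1", 200, "a", 1), ("S1", 100, "b", 1)],
            class_map={"a": "tzd", "b": "tzd"},
        )
        assert find_start_day(ds, "S1", "tzd") == 100


class TestStopRestart:
    def test_gap_and_resume(self):
        # visit at day 60 exists (other med) but lacks the medication
        ds = make_dataset(
            [("S1", 0, "m", 1), ("S1", 30, "m", 1), ("S1", 60, "other", 1),
             ("S1", 90, "m", 1), ("S1", 120, "m", 1)]
        )
        assert detect_stop_restart(ds, "S1", "m", 0)

    def test_continuous_records(self):
        ds = make_dataset([("S1", d, "m", 1) for d in range(0, 271, 30)])
        assert not detect_stop_restart(ds, "S1", "m", 0)

    def test_stop_without_resume(self):
        ds = make_dataset(
            [("S1", 0, "m", 1), ("S1", 30, "m", 1)]
            + [("S1", d, "other", 1) for d in range(60, 271, 30)]
        )
        assert not detect_stop_restart(ds, "S1", "m", 0)

    def test_gap_tolerance(self):
        ds = make_dataset(
            [("S1", 0, "m", 1), ("S1", 30, "other", 1), ("S1", 60, "m", 1)]
        )
        assert detect_stop_restart(ds, "S1", "m", 0, gap_tolerance_visits=0)
        assert not detect_stop_restart(ds, "S1", "m", 0, gap_tolerance_visits=1)


class TestEvaluateCompliance:
    @pytest.mark.parametrize(
        "codes, frac, any_zero",
        [
            ([1, 1, 1, 1, 2], 0.8, False),
            ([1, 4, 1], 1.0, False),    # over-use code counts as full compliance
            ([1, 3, 1], 2 / 3, True),
        ],
    )
    def test_fraction_and_zero_flag(self, codes, frac, any_zero):
        f, z = evaluate_compliance(codes)
        assert f == pytest.approx(frac)
        assert z is any_zero

    def test_empty_errors(self):
        with pytest.raises(ValueError, match="no compliance records"):
            evaluate_compliance([])


class TestExtractWindowPhenotypes:
    def _ds(self, days, sid="S1"):
        return make_dataset(
            med_rows=[(sid, 0, "m", 1)],
            pheno_rows=[(sid, d, "hba1c_pct", 8.0 + i) for i, d in enumerate(days)],
        )

    def test_latest_pre_earliest_post(self):
        ds = self._ds([-40, -10, 100, 200])
        pre, post = extract_window_phenotypes(ds, "S1", 0, "hba1c_pct")
        assert pre.day == -10 and post.day == 100

    def test_pre_too_old(self):
        ds = self._ds([-40, 100])
        assert extract_window_phenotypes(ds, "S1", 0, "hba1c_pct") is ExclusionReason.missing_phenotype

    def test_post_too_early(self):
        ds = self._ds([0, 80])
        assert extract_window_phenotypes(ds, "S1", 0, "hba1c_pct") is ExclusionReason.missing_phenotype

    def test_same_day_pre_allowed(self):
        ds = self._ds([0, 120])
        pre, post = extract_window_phenotypes(ds, "S1", 0, "hba1c_pct")
        assert pre.day == 0

    def test_ldl_style_window(self):
        """A 90–120 day post window (lipid phenotype) rejects day-200 obs."""
        params = WindowParams(min_days=90, max_days=120)
        ds = self._ds([-5, 200])
        assert (
            extract_window_phenotypes(ds, "S1", 0, "hba1c_pct", params)
            is ExclusionReason.missing_phenotype
        )
        ds2 = self._ds([-5, 110])
        pre, post = extract_window_phenotypes(ds2, "S1", 0, "hba1c_pct", params)
        assert post.day == 110


def _clean_subject(sid, start=100):
    """Rows for a subject passing every filter."""
    med = [(sid, d, "m", 1) for d in range(start, start + 271, 30)]
    ph = [(sid, start - 5, "hba1c_pct", 8.0), (sid, start + 100, "hba1c_pct", 7.0)]
    return med, [], ph


class TestSelectPrimaryCohort:
    def test_clean_subject_included(self):
        med, ann, ph = _clean_subject("S1")
        ds = make_dataset(med, ann, ph)
        res = select_primary_cohort(ds, "m", "hba1c_pct")
        assert res.included_ids == ["S1"]
        assert res.included[0].response == pytest.approx(-1.0)
        assert res.included[0].start_day == 100

    def test_on_at_baseline_excluded(self):
        med = [("S1", d, "m", 1) for d in range(0, 271, 30)]
        ph = [("S1", 0, "hba1c_pct", 8.0), ("S1", 100, "hba1c_pct", 7.0)]
        ds = make_dataset(med, [], ph)
        res = select_primary_cohort(ds, "m", "hba1c_pct")
        assert ExclusionReason.on_at_baseline in res.excluded["S1"]

    def test_annual_baseline_flag_excludes(self):
        """Annual on-record at day <= 0 marks the subject as already on."""
        med, _, ph = _clean_subject("S1")
        ds = make_dataset(med, [("S1", 0, "m", True)], ph)
        res = select_primary_cohort(ds, "m", "hba1c_pct")
        assert ExclusionReason.on_at_baseline in res.excluded["S1"]

    def test_every_reason_triggered_once(self):
        """Eight subjects, each constructed to fail exactly one filter."""
        rows, ann, ph = [], [], []
        # S1 inconsistent: annual on, no monthly record of m
        ann += [("S1", 365, "m", True)]
        rows += [("S1", 100, "other", 1)]
        # S2 never on
        rows += [("S2", 100, "other", 1)]
        ph += [("S2", 95, "hba1c_pct", 8.0)]
        # S3 on at baseline
        rows += [("S3", d, "m", 1) for d in range(0, 271, 30)]
        ph += [("S3", 0, "hba1c_pct", 8.0), ("S3", 100, "hba1c_pct", 7.0)]
        # S4 insufficient duration (records span < 90 d from start)
        rows += [("S4", 100, "m", 1), ("S4", 130, "m", 1)]
        ph += [("S4", 95, "hba1c_pct", 8.0), ("S4", 200, "hba1c_pct", 7.0)]
        # S5 stop-restart
        rows += [("S5", d, "m", 1) for d in (100, 130, 190, 220, 250, 280, 310, 340, 370)]
        rows += [("S5", 160, "other", 1)]
        ph += [("S5", 95, "hba1c_pct", 8.0), ("S5", 200, "hba1c_pct", 7.0)]
        # S6 zero compliance record
        rows += [("S6", d, "m", 3 if d == 160 else 1) for d in range(100, 371, 30)]
        ph += [("S6", 95, "hba1c_pct", 8.0), ("S6", 200, "hba1c_pct", 7.0)]
        # S7 low compliance (codes 2 at most visits)
        rows += [("S7", d, "m", 2 if d > 130 else 1) for d in range(100, 371, 30)]
        ph += [("S7", 95, "hba1c_pct", 8.0), ("S7", 200, "hba1c_pct", 7.0)]
        # S8 missing phenotype
        rows += [("S8", d, "m", 1) for d in range(100, 371, 30)]
        ph += [("S8", 95, "hba1c_pct", 8.0)]
        ds = make_dataset(rows, ann, ph)
        res = select_primary_cohort(ds, "m", "hba1c_pct")
        assert not res.included
        expected = {
            "S1": ExclusionReason.inconsistent_records,
            "S2": ExclusionReason.never_on,
            "S3": ExclusionReason.on_at_baseline,
            "S4": ExclusionReason.insufficient_duration,
            "S5": ExclusionReason.stop_restart,
            "S6": ExclusionReason.zero_compliance,
            "S7": ExclusionReason.low_compliance,
            "S8": ExclusionReason.missing_phenotype,
        }
        for sid, reason in expected.items():
            assert reason in res.excluded[sid], (sid, res.excluded[sid])
        for reason in expected.values():
            assert res.tally[reason] >= 1

    def test_included_windows_satisfy_invariants(self):
        med1, _, ph1 = _clean_subject("S1", start=100)
        med2, _, ph2 = _clean_subject("S2", start=400)
        ds = make_dataset(med1 + med2, [], ph1 + ph2)
        params = WindowParams()
        res = select_primary_cohort(ds, "m", "hba1c_pct", params)
        assert len(res.included) == 2
        for w in res.included:
            assert 0 <= w.start_day - w.pre_obs.day <= params.pre_lookback_days
            assert params.min_days <= w.post_obs.day - w.start_day <= params.max_days

    def test_nocb_rescues_missing_interior_compliance(self):
        """A missing code surrounded by full-compliance codes is imputed full."""
        med = [("S1", d, "m", np.nan if d == 160 else 1) for d in range(100, 371, 30)]
        ph = [("S1", 95, "hba1c_pct", 8.0), ("S1", 200, "hba1c_pct", 7.0)]
        ds = make_dataset(med, [], ph)
        res = select_primary_cohort(ds, "m", "hba1c_pct")
        assert res.included_ids == ["S1"]
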