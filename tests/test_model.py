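import numpy as np
import pandas as pd
import pytest

from conmedscore.model import (
    CovariateSpec,
    RankDeficientError,
    backward_select,
    build_covariate_table,
    compute_bic,
    fit_linear,
    prune_collinear,
)


def qr_ols(y, X):
    """Independent QR-based OLS oracle (intercept prepended)."""
    A = np.column_stack([np.ones(len(y)), X])
    Q, R = np.linalg.qr(A)
    return np.linalg.solve(R, Q.T @ np.asarray(y, float))


class TestFitLinear:
    def test_hand_case(self):
        fit = fit_linear([1, 2, 3, 4.1], pd.DataFrame({"x": [0, 1, 2, 3]}))
        beta = fit.coefficients.set_index("name")["beta"]
        ref = qr_ols([1, 2, 3, 4.1], np.array([[0.0], [1], [2], [3]]))
        assert beta["Intercept"] == pytest.approx(ref[0])
        assert beta["x"] == pytest.approx(ref[1])

    def test_intercept_only_is_mean(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=20)
        fit = fit_linear(y, pd.DataFrame(index=range(20)))
        assert fit.beta("Intercept") == pytest.approx(y.mean())

    def test_duplicated_column_raises_named_error(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=10)
        X = pd.DataFrame({"a": x, "b": x})
        with pytest.raises(RankDeficientError, match="b"):
            fit_linear(rng.normal(size=10), X)

    def test_perfect_fit_errors(self):
        with pytest.raises(ValueError, match="rss"):
            fit_linear([1, 2, 3, 4], pd.DataFrame({"x": [1.0, 2, 3, 4]}))

    def test_matches_qr_oracle_random_instances(self):
        """Coefficients agree with an independent QR solver to 1e-8."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(10, 60))
            k = int(rng.integers(1, 6))
            X = rng.normal(size=(n, k))
            y = rng.normal(size=n)
            fit = fit_linear(y, pd.DataFrame(X, columns=[f"x{j}" for j in range(k)]))
            np.testing.assert_allclose(
                fit.coefficients["beta"].values, qr_ols(y, X), atol=1e-8
            )

    def test_se_and_p_match_statsmodels(self):
        """Standard errors and p-values cross-checked against statsmodels OLS."""
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 3))
        y = X @ [0.5, 0.0, -1.0] + rng.normal(size=50)
        fit = fit_linear(y, pd.DataFrame(X, columns=list("abc")))
        ref = sm.OLS(y, sm.add_constant(X)).fit()
        np.testing.assert_allclose(fit.coefficients["se"].values, ref.bse, rtol=1e-8)
        np.testing.assert_allclose(fit.coefficients["p"].values, ref.pvalues, rtol=1e-8)


class TestBic:
    def test_closed_form(self):
        assert compute_bic(100, 100.0, 1) == pytest.approx(2 * np.log(100))

    def test_rss_nonpositive_errors(self):
        with pytest.raises(ValueError):
            compute_bic(100, 0.0, 1)

    def test_noise_column_increases_bic_in_expectation(self):
        rng = np.random.default_rng(3)
        diffs = []
        for _ in range(200):
            n = 80
            x = rng.normal(size=n)
            y = x + rng.normal(size=n)
            base = fit_linear(y, pd.DataFrame({"x": x}))
            noisy = fit_linear(y, pd.DataFrame({"x": x, "z": rng.normal(size=n)}))
            diffs.append(noisy.bic - base.bic)
        assert np.mean(diffs) > 0


class TestBuildCovariateTable:
    def _inputs(self, n=10):
        rng = np.random.default_rng(4)
        ids = [f"S{i}" for i in range(n)]
        resp = pd.Series(rng.normal(size=n), index=ids)
        cov = pd.DataFrame(
            {"age": rng.normal(60, 5, n), "bmi": rng.normal(30, 4, n),
             "arm": rng.integers(0, 2, n).astype(float)},
            index=ids,
        )
        return resp, cov

    def test_complete_case_drop(self):
        resp, cov = self._inputs()
        cov.loc["S3", "bmi"] = np.nan
        y, tab, specs = build_covariate_table(resp, cov, forced=["arm"])
        assert len(tab) == 9 and "S3" not in tab.index

    def test_standardization(self):
        resp, cov = self._inputs()
        _, tab, _ = build_covariate_table(resp, cov, forced=[])
        assert tab["age"].mean() == pytest.approx(0, abs=1e-9)
        assert tab["age"].std(ddof=1) == pytest.approx(1, abs=1e-9)
        # indicators are left alone
        assert set(tab["arm"].unique()) <= {0.0, 1.0}

    def test_forced_flags_and_groups(self):
        resp, cov = self._inputs()
        cov["m_score_1"] = 0.0
        cov.loc["S1", "m_score_1"] = 1.0
        y, tab, specs = build_covariate_table(
            resp, cov, forced=["arm"], dummy_groups={"m": ["m_score_1"]}
        )
        by = {s.name: s for s in specs}
        assert by["arm"].forced and not by["age"].forced
        assert by["m"].kind == "dummy_group" and by["m"].group_members == ("m_score_1",)

    def test_consent_filter(self):
        resp, cov = self._inputs()
        consent = pd.Series(1, index=resp.index)
        consent["S0"] = 0
        y, tab, _ = build_covariate_table(resp, cov, forced=[], consent=consent)
        assert "S0" not in tab.index

    def test_all_missing_column_errors(self):
        resp, cov = self._inputs()
        cov["ghost"] = np.nan
        with pytest.raises(ValueError, match="ghost"):
            build_covariate_table(resp, cov, forced=[])


def _specs(table, forced=()):
    return [CovariateSpec(c, "continuous", forced=c in forced) for c in table.columns]


class TestPruneCollinear:
    def test_duplicate_column_drops_exactly_one(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=50)
        tab = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=50)})
        y = pd.Series(x + rng.normal(size=50, scale=0.1))
        pruned, specs, log = prune_collinear(tab, _specs(tab), y)
        assert len(pruned.columns) == 2 and len(log) == 1

    def test_forced_protected(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=50)
        tab = pd.DataFrame({"x1": x, "x2": x + rng.normal(size=50, scale=0.1)})
        y = pd.Series(rng.normal(size=50))
        pruned, specs, log = prune_collinear(tab, _specs(tab, forced=("x1",)), y)
        assert list(pruned.columns) == ["x1"]
        assert log.iloc[0]["dropped"] == "x2"

    def test_iterative_removal_terminates_clean(self):
        rng = np.random.default_rng(7)
        base = rng.normal(size=100)
        tab = pd.DataFrame(
            {f"v{i}": base + rng.normal(size=100, scale=0.3) for i in range(3)}
        )
        tab["indep"] = rng.normal(size=100)
        y = pd.Series(base + rng.normal(size=100))
        pruned, specs, _ = prune_collinear(tab, _specs(tab), y)
        corr = pruned.corr().abs().values
        np.fill_diagonal(corr, 0)
        assert corr.max() <= 0.5

    def test_weaker_outcome_correlation_dropped(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=200)
        y = pd.Series(x + rng.normal(size=200, scale=0.5))
        tab = pd.DataFrame({"strong": x, "weak": x + rng.normal(size=200, scale=0.2)})
        pruned, _, _ = prune_collinear(tab, _specs(tab), y)
        assert list(pruned.columns) == ["strong"]

    def test_bad_threshold_errors(self):
        tab = pd.DataFrame({"a": [1.0, 2, 3]})
        with pytest.raises(ValueError):
            prune_collinear(tab, _specs(tab), pd.Series([1.0, 2, 3]), threshold=0)


class TestBackwardSelect:
    def _simulated(self, rng, n=500, beta=1.0):
        x_true = rng.normal(size=n)
        pre = rng.normal(size=n)
        noise_cols = {f"noise{j}": rng.normal(size=n) for j in range(5)}
        y = pd.Series(beta * x_true + 0.3 * pre + rng.normal(size=n))
        tab = pd.DataFrame({"x_true": x_true, "pre_phenotype": pre, **noise_cols})
        specs = [
            CovariateSpec("x_true", "continuous"),
            CovariateSpec("pre_phenotype", "continuous", forced=True),
        ] + [CovariateSpec(f"noise{j}", "continuous") for j in range(5)]
        return y, tab, specs

    def test_recovers_true_covariate(self):
        """True signal retained, most noise discarded, across replicates."""
        rng = np.random.default_rng(9)
        good = 0
        for _ in range(20):
            y, tab, specs = self._simulated(rng)
            fit, trace, kept = backward_select(y, tab, specs)
            names = {s.name for s in kept}
            if "x_true" in names and len(names - {"x_true", "pre_phenotype"}) <= 1:
                good += 1
        assert good >= 19

    def test_all_noise_leaves_forced_only(self):
        rng = np.random.default_rng(10)
        hits = 0
        for _ in range(10):
            y, tab, specs = self._simulated(rng, beta=0.0)
            specs = [s for s in specs if s.name != "x_true"]
            tab = tab.drop(columns="x_true")
            fit, trace, kept = backward_select(y, tab, specs)
            if {s.name for s in kept} == {"pre_phenotype"}:
                hits += 1
        assert hits >= 6

    def test_trace_strictly_decreasing(self):
        rng = np.random.default_rng(11)
        y, tab, specs = self._simulated(rng)
        _, trace, _ = backward_select(y, tab, specs)
        bics = [s.bic_before for s in trace.steps] + [trace.steps[-1].bic_after]
        assert all(b2 < b1 for b1, b2 in zip(bics[:-1], bics[1:]))

    def test_forced_present_in_every_step(self):
        rng = np.random.default_rng(12)
        y, tab, specs = self._simulated(rng)
        _, trace, kept = backward_select(y, tab, specs)
        assert "pre_phenotype" in {s.name for s in kept}
        assert all(s.removed != "pre_phenotype" for s in trace.steps)

    def test_dummy_group_removed_en_bloc(self):
        rng = np.random.default_rng(13)
        n = 300
        g1 = (rng.random(n) < 0.3).astype(float)
        g2 = (rng.random(n) < 0.2).astype(float) * (1 - g1)
        x = rng.normal(size=n)
        y = pd.Series(x + rng.normal(size=n))
        tab = pd.DataFrame({"x": x, "med_score_1": g1, "med_score_2": g2})
        specs = [
            CovariateSpec("x", "continuous"),
            CovariateSpec("med", "dummy_group", group_members=("med_score_1", "med_score_2")),
        ]
        fit, trace, kept = backward_select(y, tab, specs)
        names = {s.name for s in kept}
        cols = {c for s in kept for c in s.columns}
        # either both med columns or neither
        assert cols & {"med_score_1", "med_score_2"} in (set(), {"med_score_1", "med_score_2"})
        assert "x" in names

    def test_deterministic(self):
        rng = np.random.default_rng(14)
        y, tab, specs = self._simulated(rng)
        r1 = backward_select(y, tab, specs)
        r2 = backward_select(y, tab, specs)
        assert [s.removed for s in r1[1].steps] == [s.removed for s in r2[1].steps]
        assert r1[0].bic == r2[0].bic
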