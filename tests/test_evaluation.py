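"""The statistical battery: unit behavior of each analysis."""

import numpy as np
import pytest

import tvdtsim as tv
from tvdtsim import evaluation as ev


class TestNormality:
    def test_skewed_data_rejected(self, canonical_fit):
        x = tv.sample_tvdt(canonical_fit, 500, seed=1)
        _, p = ev.normality(x)
        assert p < 0.05

    def test_normal_data_accepted(self, rng):
        _, p = ev.normality(rng.normal(300, 40, 500))
        assert p > 0.01

    def test_degenerate_input(self):
        with pytest.raises(ValueError):
            ev.normality([5.0] * 10)
        with pytest.raises(ValueError):
            ev.normality([1.0, 2.0])


class TestReproducibility:
    def test_identical_sessions_no_discrimination(self):
        s = [1.0, 2.0, 3.0, 4.0]
        assert ev.reproducibility([s, s, s]) == (0.0, 1.0)

    def test_shifted_session_detected(self, rng):
        base = rng.normal(10, 1, 30)
        sessions = [base + rng.normal(0, 0.1, 30) for _ in range(2)]
        sessions.append(base + 5.0)
        _, p = ev.reproducibility(sessions)
        assert p < 0.05

    def test_ragged_input(self):
        with pytest.raises(ValueError):
            ev.reproducibility([[1, 2, 3], [1, 2]])


class TestComparePair:
    def test_identical_samples(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        comp = ev.compare_pair(x, x, paired=True)
        assert comp.ks_statistic == 0.0
        assert comp.degenerate and comp.wilcoxon_pvalue == 1.0
        assert comp.n_zero_diff == 5

    def test_sentinel_exclusion_accounting(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0, 6.0, 7.0]
        y = [1.1, 2.2, 3.0, np.nan, 5.5, 6.6, 7.7]
        comp = ev.compare_pair(x, y, paired=True)
        assert comp.n_excluded == 2
        assert comp.n_x == comp.n_y == 5  # analyzed + excluded = input

    def test_same_distribution_not_rejected(self, canonical_fit):
        x = tv.sample_tvdt(canonical_fit, 30, seed=1)
        y = tv.sample_tvdt(canonical_fit, 30, seed=2)
        comp = ev.compare_pair(x, y)
        assert comp.ks_pvalue > 0.05
        assert comp.wilcoxon_pvalue is None  # unpaired

    def test_shift_detected_by_wilcoxon_not_ks(self, canonical_fit, rng):
        # a small systematic shift in paired data: the signed-rank test sees
        # it, the two-sample KS on n=30 does not
        x = tv.sample_tvdt(canonical_fit, 30, seed=3)
        y = x + 15 + rng.normal(0, 25, 30)
        comp = ev.compare_pair(x, y, paired=True)
        assert comp.wilcoxon_pvalue < 0.05
        assert comp.ks_pvalue > 0.05

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            ev.compare_pair([1.0, 2.0], [1.0, 2.0])


class TestMedianDifference:
    def test_identical(self):
        med, iqr, n_excl = ev.median_difference([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (med, iqr, n_excl) == (0.0, 0.0, 0)

    def test_quantile_oracle(self):
        # differences {-5, 0, 5, 10, 30}: median 5, IQR by linear
        # interpolation = percentile(75) - percentile(25) = 10 - 0
        diffs = np.array([-5.0, 0.0, 5.0, 10.0, 30.0])
        med, iqr, _ = ev.median_difference(diffs, np.zeros(5))
        assert med == 5.0
        assert iqr == 10.0

    def test_sentinels_excluded(self):
        med, iqr, n_excl = ev.median_difference([1, 2, np.nan], [0, 0, 0])
        assert n_excl == 1
        assert med == 1.5
        with pytest.raises(ValueError):
            ev.median_difference([np.nan], [1.0])


class TestRegressSizes:
    def test_perfect_agreement(self):
        slope, intercept, r2 = ev.regress_sizes([3.0, 5.0, 8.0], [3.0, 5.0, 8.0])
        assert (slope, intercept, r2) == pytest.approx((1.0, 0.0, 1.0))

    def test_unbiased_noise(self, rng):
        x = rng.uniform(3.5, 13, 300)
        y = x + rng.normal(0, 0.5, 300)
        slope, intercept, r2 = ev.regress_sizes(x, y)
        assert slope == pytest.approx(1.0, abs=0.05)
        assert r2 < 1.0

    def test_second_round_regression_tighter(self, rng):
        # equal absolute noise on bigger tumors gives higher R^2
        d1 = rng.uniform(3.5, 13, 200)
        d2 = 2 * d1
        noise = rng.normal(0, 0.5, 200)
        _, _, r2_first = ev.regress_sizes(d1, d1 + noise)
        _, _, r2_second = ev.regress_sizes(d2, d2 + noise)
        assert r2_second > r2_first

    def test_zero_variance(self):
        with pytest.raises(ValueError):
            ev.regress_sizes([5.0, 5.0, 5.0], [4.0, 5.0, 6.0])


class TestGrowthClassAnalysis:
    def test_quartile_counting(self):
        assigned = np.arange(1, 9, dtype=float) * 100
        estimated = assigned * 1.1
        gc = ev.growth_class_analysis(assigned, estimated)
        assert len(gc.fast_ids) == len(gc.slow_ids) == 2
        assert set(gc.fast_ids) == {1, 2}  # shortest TVDTs grow fastest
        assert set(gc.slow_ids) == {7, 8}

    def test_identical_estimates_degenerate(self):
        assigned = np.arange(1, 13, dtype=float) * 50
        gc = ev.growth_class_analysis(assigned, assigned)
        assert gc.degenerate and gc.p_value == 1.0
        assert all(e == 0 for e in gc.fast_errors + gc.slow_errors)

    def test_classes_disjoint(self, canonical_fit, rng):
        assigned = tv.sample_tvdt(canonical_fit, 30, seed=5)
        estimated = assigned * (1 + rng.normal(0, 0.15, 30))
        gc = ev.growth_class_analysis(assigned, estimated)
        assert not set(gc.fast_ids) & set(gc.slow_ids)
        assert len(gc.fast_ids) == len(gc.slow_ids) == 30 // 4
        assert 0 <= gc.p_value <= 1

    def test_too_few_patients(self):
        with pytest.raises(ValueError):
            ev.growth_class_analysis([1.0] * 7, [1.0] * 7)


class TestBuildReport:
    def test_full_report(self, cohort30, noisy_estimates, noisy_records, canonical_fit):
        report = ev.build_report(
            cohort30,
            noisy_estimates,
            measurements=noisy_records,
            fit=canonical_fit,
            family_bootstrap=50,
            seed=3,
        )
        d = report.to_dict()
        for section in ("normality", "reproducibility", "pairwise", "median_diff",
                        "regression", "growth_class"):
            assert d[section], f"section {section} empty"
        # every p-value in [0, 1]
        for sec in (report.normality.values(), report.reproducibility.values(),
                    report.median_diff.values()):
            for entry in sec:
                for k, v in entry.items():
                    if k == "pvalue":
                        assert 0 <= v <= 1
        for comp in report.pairwise.values():
            assert 0 <= comp["ks_pvalue"] <= 1
        assert 0 <= report.growth_class["pvalue"] <= 1
        for rnd in ("round_1", "round_2"):
            assert 0 <= report.regression[rnd]["r_squared"] <= 1

    def test_report_deterministic(self, cohort30, noisy_estimates, canonical_fit):
        kwargs = dict(fit=canonical_fit, family_bootstrap=20, seed=11)
        a = ev.build_report(cohort30, noisy_estimates, **kwargs).to_json()
        b = ev.build_report(cohort30, noisy_estimates, **kwargs).to_json()
        assert a == b

    def test_json_round_trip(self, cohort30, noisy_estimates, canonical_fit, tmp_path):
        import json

        report = ev.build_report(cohort30, noisy_estimates, fit=canonical_fit,
                                 family_bootstrap=20, seed=2)
        path = tmp_path / "report.json"
        report.to_json(path)
        loaded = json.loads(path.read_text())
        assert loaded["alpha"] == 0.05
        assert loaded["meta"]["n_patients"] == 30
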