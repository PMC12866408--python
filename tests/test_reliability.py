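import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import petquant as pq
from petquant.errors import UndefinedMetricError, UnderDeterminedError, ValidationError
from petquant.reliability import TrtCohort, anova_icc, bland_altman, icc_reml
from petquant.synthetic_data import TrtCohortSpec, simulate_trt_cohort


def make_cohort(test_values, retest_values, genotypes=None, region="s", metric="VT"):
    n = len(test_values)
    genotypes = genotypes or ["WT"] * (n // 2) + ["HET"] * (n - n // 2)
    rows = []
    for i, (t, r) in enumerate(zip(test_values, retest_values)):
        for session, value in (("test", t), ("retest", r)):
            rows.append((f"a{i:03d}", genotypes[i], session, region, metric, value))
    return TrtCohort(pd.DataFrame(
        rows, columns=["animal", "genotype", "session", "region", "metric", "value"]
    ))


class TestTrv:
    def test_identical_pair_is_zero(self):
        assert pq.rtrv(1.0, 1.0) == 0.0

    def test_arithmetic_case(self):
        assert pq.rtrv(2.2, 1.8) == pytest.approx(20.0, abs=1e-12)
        assert pq.atrv(2.2, 1.8) == pytest.approx(20.0, abs=1e-12)

    def test_antisymmetry_and_symmetry(self):
        assert pq.rtrv(1.8, 2.2) == pytest.approx(-20.0, abs=1e-12)
        assert pq.atrv(1.8, 2.2) == pytest.approx(20.0, abs=1e-12)

    def test_zero_mean_rejected(self):
        with pytest.raises(UndefinedMetricError):
            pq.rtrv(1.0, -1.0)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        st.floats(0.1, 50.0), st.floats(0.1, 50.0), st.floats(0.01, 100.0)
    )
    def test_scale_invariance_and_abs_identity(self, test, retest, c):
        base = pq.rtrv(test, retest)
        assert pq.rtrv(c * test, c * retest) == pytest.approx(base, rel=1e-9)
        assert pq.atrv(test, retest) == pytest.approx(abs(base), rel=1e-12)


class TestBlandAltman:
    def test_identical_pairs_collapse_limits(self):
        res = bland_altman(make_cohort([2.0, 3.0, 4.0, 5.0], [2.0, 3.0, 4.0, 5.0]), "s", "VT")
        assert res.bias == 0.0
        assert res.limits == (0.0, 0.0)

    def test_hand_computed_two_pair_case(self):
        # rTRVs are exactly {+10, -10}: sd (n-1) = sqrt(200) = 14.1421...
        cohort = make_cohort([2.1, 1.9], [1.9, 2.1])
        res = bland_altman(cohort, "s", "VT")
        assert res.bias == pytest.approx(0.0, abs=1e-9)
        assert res.sd == pytest.approx(np.sqrt(200.0), abs=1e-9)
        assert res.limits[1] == pytest.approx(1.96 * np.sqrt(200.0), abs=1e-6)

    def test_limits_cover_about_95pct_of_differences(self):
        spec = TrtCohortSpec(
            n_per_genotype=250, means={"WT": {"s": 5.0}, "HET": {"s": 5.0}},
            sigma_between=0.5, sigma_within=0.25, seed=31,
        )
        cohort = simulate_trt_cohort(spec)
        res = bland_altman(cohort, "s", "VT")
        pairs = cohort.pairs("s", "VT")
        diffs = pq.rtrv(pairs["test"].to_numpy(), pairs["retest"].to_numpy())
        inside = np.mean((diffs >= res.limits[0]) & (diffs <= res.limits[1]))
        assert 0.93 <= inside <= 0.97

    def test_single_pair_rejected(self):
        with pytest.raises(UnderDeterminedError):
            bland_altman(make_cohort([2.0], [2.1], genotypes=["WT"]), "s", "VT")


class TestIccReml:
    def test_no_within_noise_gives_icc_one(self):
        spec = TrtCohortSpec(n_per_genotype=10, sigma_between=0.5, sigma_within=0.0, seed=3)
        cohort = simulate_trt_cohort(spec)
        res = icc_reml(cohort, "striatum", "VT")
        assert res.icc == pytest.approx(1.0, abs=1e-6)

    def test_no_between_variance_gives_icc_near_zero(self):
        spec = TrtCohortSpec(
            n_per_genotype=100, means={"WT": {"s": 3.0}, "HET": {"s": 3.0}},
            sigma_between=0.0, sigma_within=1.0, seed=5,
        )
        res = icc_reml(simulate_trt_cohort(spec), "s", "VT")
        assert res.icc <= 0.05

    def test_reml_equals_anova_closed_form_on_balanced_data(self):
        """Exact identity between profiled REML and the one-way ANOVA
        method-of-moments estimator on structure-free balanced data."""
        for seed in (1, 2, 3, 4):
            spec = TrtCohortSpec(
                n_per_genotype=20, means={"WT": {"s": 3.0}, "HET": {"s": 3.0}},
                sigma_between=np.sqrt(3.0), sigma_within=1.0, seed=seed,
            )
            cohort = simulate_trt_cohort(spec)
            res = icc_reml(cohort, "s", "VT", fixed="intercept")
            sub = cohort.subset("s", "VT")
            icc_mom, vb, vw = anova_icc(sub["value"].to_numpy(), sub["animal"].to_numpy())
            assert res.icc == pytest.approx(icc_mom, abs=1e-8)
            assert res.variance_components["animal"] == pytest.approx(vb, abs=1e-8)
            assert res.variance_components["residual"] == pytest.approx(vw, abs=1e-8)

    def test_cross_check_against_statsmodels_mixedlm(self):
        import statsmodels.formula.api as smf

        spec = TrtCohortSpec(
            n_per_genotype=30, means={"WT": {"s": 3.0}, "HET": {"s": 6.0}},
            sigma_between=0.8, sigma_within=0.4, seed=13,
        )
        cohort = simulate_trt_cohort(spec)
        res = icc_reml(cohort, "s", "VT")
        sub = cohort.subset("s", "VT")
        fit = smf.mixedlm(
            "value ~ genotype * session", sub, groups=sub["animal"]
        ).fit(reml=True)
        icc_sm = float(fit.cov_re.iloc[0, 0]) / (float(fit.cov_re.iloc[0, 0]) + float(fit.scale))
        assert res.icc == pytest.approx(icc_sm, abs=1e-4)

    def test_recovery_across_variance_ratios(self):
        """Median ICC estimate is within 0.05 of the generative value for
        variance ratios 0.25, 1, 3, 9."""
        for ratio in (0.25, 1.0, 3.0, 9.0):
            estimates = []
            for rep in range(21):
                spec = TrtCohortSpec(
                    n_per_genotype=100, means={"WT": {"s": 3.0}, "HET": {"s": 6.0}},
                    sigma_between=np.sqrt(ratio), sigma_within=1.0, seed=700 + rep,
                )
                estimates.append(icc_reml(simulate_trt_cohort(spec), "s", "VT").icc)
            assert np.median(estimates) == pytest.approx(ratio / (1 + ratio), abs=0.05)

    def test_invariance_to_shift_and_positive_scaling(self):
        spec = TrtCohortSpec(n_per_genotype=15, sigma_between=0.5, sigma_within=0.3, seed=8)
        cohort = simulate_trt_cohort(spec)
        base = icc_reml(cohort, "striatum", "VT").icc
        shifted = cohort.frame.copy()
        shifted["value"] = 3.7 * shifted["value"] + 11.0
        assert icc_reml(TrtCohort(shifted), "striatum", "VT").icc == pytest.approx(
            base, abs=1e-9
        )

    def test_extra_random_terms_do_not_change_icc(self):
        spec = TrtCohortSpec(n_per_genotype=20, sigma_between=0.6, sigma_within=0.3, seed=21)
        cohort = simulate_trt_cohort(spec)
        plain = icc_reml(cohort, "striatum", "VT")
        extra = icc_reml(cohort, "striatum", "VT", extra_random_terms=True)
        assert extra.icc == pytest.approx(plain.icc, abs=0.02)

    def test_too_few_animals_rejected(self):
        cohort = make_cohort([2.0, 3.0, 4.0], [2.1, 2.9, 4.2])
        with pytest.raises(UnderDeterminedError):
            icc_reml(cohort, "s", "VT")


class TestCohortValidation:
    def test_incomplete_pair_rejected(self):
        rows = [
            ("a1", "WT", "test", "s", "VT", 1.0),
            ("a1", "WT", "retest", "s", "VT", 1.1),
            ("a2", "WT", "test", "s", "VT", 2.0),
        ]
        with pytest.raises(ValidationError):
            TrtCohort(pd.DataFrame(
                rows, columns=["animal", "genotype", "session", "region", "metric", "value"]
            ))

    def test_report_shape(self):
        spec = TrtCohortSpec(n_per_genotype=6, sigma_between=0.4, sigma_within=0.2, seed=2)
        cohort = simulate_trt_cohort(spec)
        report = pq.trt_report(cohort)
        assert set(report["region"]) == {"striatum"}
        assert {"ICC", "rTRV_mean_WT", "aTRV_sd_HET", "BA_lower"} <= set(report.columns)
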