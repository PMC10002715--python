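import numpy as np
import pandas as pd
import pytest
from helpers_oracles import mannwhitney_enumerate

from mcmm.stats import (
    ClinicalAssociationModel,
    DegenerateGroupError,
    FitError,
    clinical_scan,
    endpoint_flux,
    group_test,
    pearson_assoc,
    zscore_within,
)
from mcmm.synthetic import simulate_clinical


class TestEndpointFlux:
    def test_rate_of_change(self):
        assert endpoint_flux(0.0, 14.0, 7.0) == pytest.approx(2.0)

    def test_od_normalization(self):
        assert endpoint_flux(0.0, 12.0, 24.0, od=0.6) == pytest.approx(
            12.0 / 24.0 / 0.6
        )

    def test_net_consumption_is_negative_not_error(self):
        assert endpoint_flux(5.0, 2.0, 3.0) == pytest.approx(-1.0)

    def test_bad_arguments(self):
        with pytest.raises(ValueError):
            endpoint_flux(0, 1, 0)
        with pytest.raises(ValueError):
            endpoint_flux(0, 1, 1, od=0)


def make_table(values_by_study):
    rows = []
    for study, values in values_by_study.items():
        for i, v in enumerate(values):
            rows.append({"sample_id": f"{study}_{i}", "study_id": study,
                         "treatment": "control", "dilution_factor": 5,
                         "metabolite": "butyrate",
                         "measured_flux": v, "predicted_flux": 2 * v + 1})
    return pd.DataFrame(rows)


class TestZScore:
    def test_simple_values(self):
        table = make_table({"A": [1.0, 2.0, 3.0]})
        out = zscore_within(table)
        assert list(out["measured_flux"]) == pytest.approx([-1.0, 0.0, 1.0])

    def test_groups_scored_independently(self):
        table = make_table({"A": [1.0, 2.0, 3.0], "B": [10.0, 30.0]})
        out = zscore_within(table)
        for _, grp in out.groupby("study_id"):
            assert grp["measured_flux"].mean() == pytest.approx(0.0, abs=1e-12)
            assert grp["measured_flux"].std(ddof=1) == pytest.approx(1.0)

    def test_singleton_group_rejected(self):
        table = make_table({"A": [1.0]})
        with pytest.raises(DegenerateGroupError, match="A"):
            zscore_within(table)

    def test_constant_column_rejected(self):
        table = make_table({"A": [2.0, 2.0, 2.0]})
        with pytest.raises(DegenerateGroupError):
            zscore_within(table)

    def test_idempotent(self):
        table = make_table({"A": [1.0, 5.0, 2.0, 8.0]})
        once = zscore_within(table)
        twice = zscore_within(once)
        assert np.allclose(once["measured_flux"], twice["measured_flux"],
                           atol=1e-12)


class TestPearson:
    def test_perfect_lines(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_assoc(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert pearson_assoc(x, -x)[0] == pytest.approx(-1.0)

    def test_hand_formula_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 3.0, 2.0, 4.0])
        r, _ = pearson_assoc(x, y)
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        expected = cov / (x.std() * y.std())
        assert r == pytest.approx(expected, rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson_assoc([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestMannWhitney:
    def test_complete_separation_exact(self):
        u, p = group_test([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1)  # 2/20 rank assignments as extreme

    def test_identical_groups(self):
        _, p = group_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_two_singletons(self):
        u, p = group_test([1.0], [2.0])
        assert u == 0 and p == pytest.approx(1.0)

    @pytest.mark.parametrize("n_a, n_b", [(1, 3), (2, 2), (3, 4), (4, 4)])
    def test_matches_enumeration_oracle(self, n_a, n_b):
        rng = np.random.default_rng(n_a * 10 + n_b)
        for _ in range(5):
            pooled = rng.permutation(np.arange(1.0, n_a + n_b + 1))
            a, b = pooled[:n_a], pooled[n_a:]
            u, p = group_test(a, b)
            u_ref, p_ref = mannwhitney_enumerate(a, b)
            assert u == pytest.approx(u_ref)
            assert p == pytest.approx(p_ref, rel=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(size=5), rng.normal(size=8)
        u_ab, p_ab = group_test(a, b)
        u_ba, p_ba = group_test(b, a)
        assert u_ab + u_ba == pytest.approx(len(a) * len(b))
        assert p_ab == pytest.approx(p_ba, rel=1e-12)


def cohort_with_planted_effect(beta, n, n_null, seed):
    rng = np.random.default_rng(seed)
    flux = rng.lognormal(1.0, 0.5, n)
    betas = np.zeros(n_null + 1)
    betas[0] = beta
    markers, covariates = simulate_clinical(flux, n_null + 1, betas, seed + 1)
    return flux, markers, covariates


class TestClinicalScan:
    def test_recovers_planted_beta(self):
        """Mean recovered standardized beta lies within 3 SE of the planted
        0.3 across replicates."""
        betas, ses = [], []
        for seed in range(5):
            flux, markers, cov = cohort_with_planted_effect(0.3, 500, 0, seed)
            res = clinical_scan(flux, markers, cov)[0]
            betas.append(res.beta)
        # marker z-scoring shrinks the coefficient by 1/sd(marker)
        expected = 0.3 / np.sqrt(0.3**2 + 0.2**2 + 0.1**2 * 0.25
                                 + 0.15**2 * 0.25 + 1.0)
        se = np.std(betas, ddof=1) / np.sqrt(len(betas))
        assert abs(np.mean(betas) - expected) < 3 * max(se, 0.01)

    def test_marker_equal_to_covariate_is_fit_error(self):
        flux, markers, cov = cohort_with_planted_effect(0.0, 100, 0, 1)
        markers["marker_000"] = cov["age"]
        with pytest.raises(FitError):
            clinical_scan(flux, markers, cov)

    def test_collinear_design_is_fit_error(self):
        flux, markers, cov = cohort_with_planted_effect(0.0, 100, 0, 2)
        cov = cov.copy()
        cov["vendor"] = cov["sex"].map({0: "V1", 1: "V2"})  # duplicates sex
        with pytest.raises(FitError, match="collinear"):
            clinical_scan(flux, markers, cov)

    def test_too_few_complete_cases_skipped(self):
        flux, markers, cov = cohort_with_planted_effect(0.0, 30, 1, 3)
        markers.loc[markers.index[5:], "marker_000"] = np.nan
        fitted = ClinicalAssociationModel(markers, flux, cov).fit()
        assert "marker_000" in fitted.skipped
        assert len(fitted.results) == 1

    def test_by_adjustment_monotone_and_dominating(self):
        flux, markers, cov = cohort_with_planted_effect(0.2, 200, 30, 4)
        results = clinical_scan(flux, markers, cov)
        assert all(r.p_fdr >= r.p_raw - 1e-15 for r in results)
        by_raw = sorted(results, key=lambda r: r.p_raw)
        fdrs = [r.p_fdr for r in by_raw]
        assert all(a <= b + 1e-15 for a, b in zip(fdrs, fdrs[1:]))

    def test_beta_invariant_to_affine_rescaling(self):
        flux, markers, cov = cohort_with_planted_effect(0.3, 300, 0, 5)
        base = clinical_scan(flux, markers, cov)[0].beta
        scaled = clinical_scan(10 * flux + 7, markers * 3.5 - 2, cov)[0].beta
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_null_false_positive_rate_small_batch(self):
        """BY control on 128 null markers, a few replicates (the full
        calibration lives in the acceptance suite)."""
        rates = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            flux = rng.lognormal(1.0, 0.5, 200)
            markers, cov = simulate_clinical(flux, 32, np.zeros(32), seed)
            results = clinical_scan(flux, markers, cov)
            rates.append(np.mean([r.p_fdr < 0.05 for r in results]))
        assert np.mean(rates) <= 0.05 + 0.05
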