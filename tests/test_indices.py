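"""Fit-index arithmetic: GFI, AGFI, CGFI, CFI/TLI, RMSEA, SRMR, AIC/BIC."""

import math

import numpy as np
import pytest

from cgfiboot import synthetic
from cgfiboot.estimator import fit, fit_baseline
from cgfiboot.indices import (
    compute_agfi,
    compute_aic_bic,
    compute_cfi_tli,
    compute_cgfi,
    compute_fit_indices,
    compute_gfi,
    compute_rmsea,
    compute_srmr,
)
from cgfiboot.model import parse_model
from cgfiboot.moments import sample_covariance


class TestGfi:
    def test_perfect_reproduction(self):
        S = np.array([[1.0, 0.3], [0.3, 1.0]])
        assert compute_gfi(S, S, "ML") == pytest.approx(1.0)
        assert compute_gfi(S, S, "ULS") == pytest.approx(1.0)

    def test_uls_hand_example(self):
        S = np.eye(2)
        Sigma = np.array([[1.0, 0.1], [0.1, 1.0]])
        assert compute_gfi(S, Sigma, "ULS") == pytest.approx(0.99)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(4, 4))
        S = a @ a.T + 4 * np.eye(4)
        b = rng.normal(size=(4, 4))
        Sigma = b @ b.T + 4 * np.eye(4)
        perm = rng.permutation(4)
        for est in ("ML", "ULS"):
            assert compute_gfi(S, Sigma, est) == pytest.approx(
                compute_gfi(S[np.ix_(perm, perm)],
                            Sigma[np.ix_(perm, perm)], est),
                rel=1e-12,
            )


class TestAgfiCgfi:
    def test_agfi_perfect_fit(self):
        assert compute_agfi(1.0, 7, 14) == pytest.approx(1.0)

    def test_agfi_hand_example(self):
        assert compute_agfi(0.9, 4, 2) == pytest.approx(0.5)

    def test_agfi_penalty_direction(self):
        assert compute_agfi(0.95, 7, 14) <= 0.95

    def test_agfi_saturated_absent(self):
        assert compute_agfi(0.9, 4, 0) is None

    def test_cgfi_small_sample_worked_example(self):
        # GFI 0.945, 7 indicators, df 14, N 193 -> 0.950 at 3 decimals
        val = compute_cgfi(0.945, 7, 14, 193)
        assert val == pytest.approx(0.945 + 1 / 193, abs=1e-12)
        assert round(val, 3) == 0.950

    def test_cgfi_large_sample_worked_example(self):
        val = compute_cgfi(0.997, 14, 77, 4540)
        assert round(val, 3) == 0.997

    def test_cgfi_vanishes_for_large_n(self):
        assert compute_cgfi(0.9, 7, 14, 10**9) == pytest.approx(0.9, abs=1e-8)

    def test_cgfi_cap_at_one(self):
        assert compute_cgfi(0.9999, 3, 1, 5) == 1.0

    def test_cgfi_positive_correction(self):
        # CGFI > GFI whenever df < k(k+1)/2
        assert compute_cgfi(0.8, 5, 5, 100) > 0.8


class TestCfiTli:
    def test_zero_noncentrality(self):
        cfi, tli = compute_cfi_tli(14.0, 14, 500.0, 21)
        assert cfi == 1.0

    def test_hand_example(self):
        cfi, tli = compute_cfi_tli(30.0, 14, 500.0, 21)
        assert cfi == pytest.approx(1 - 16 / 479, abs=1e-10)
        expected_tli = (500 / 21 - 30 / 14) / (500 / 21 - 1)
        assert tli == pytest.approx(expected_tli, abs=1e-10)

    def test_no_improvement(self):
        cfi, _ = compute_cfi_tli(100.0, 21, 100.0, 21)
        assert cfi == 0.0

    def test_fitting_baseline_returns_cfi_one_tli_absent(self):
        cfi, tli = compute_cfi_tli(10.0, 5, 20.0, 21)
        assert cfi == 1.0 and tli is None


class TestRmseaSrmr:
    def test_rmsea_clamped_at_zero(self):
        assert compute_rmsea(10.0, 14, 200) == 0.0

    def test_rmsea_hand_example(self):
        assert compute_rmsea(28.0, 14, 192) == pytest.approx(
            math.sqrt(14 / 2688), abs=1e-10
        )

    def test_rmsea_decreasing_in_n(self):
        vals = [compute_rmsea(50.0, 14, n) for n in (100, 200, 400)]
        assert vals[0] > vals[1] > vals[2]

    def test_srmr_zero_residuals(self):
        S = np.array([[2.0, 0.6], [0.6, 1.0]])
        assert compute_srmr(S, S) == 0.0

    def test_srmr_hand_example(self):
        S = np.eye(2)
        Sigma = np.array([[1.0, 0.06], [0.06, 1.0]])
        assert compute_srmr(S, Sigma) == pytest.approx(
            math.sqrt(0.0036 / 3), abs=1e-12
        )

    def test_srmr_scale_invariance(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(3, 3))
        S = a @ a.T + 3 * np.eye(3)
        b = rng.normal(size=(3, 3))
        Sigma = b @ b.T + 3 * np.eye(3)
        d = np.diag([2.0, 0.5, 3.0])
        assert compute_srmr(S, Sigma) == pytest.approx(
            compute_srmr(d @ S @ d, d @ Sigma @ d), rel=1e-12
        )


class TestAicBic:
    def test_difference_identity(self):
        aic, bic = compute_aic_bic(-1500.0, 14, 193)
        assert bic - aic == pytest.approx(14 * (np.log(193) - 2))

    def test_zero_loglik_forms(self):
        aic, bic = compute_aic_bic(0.0, 3, 100)
        assert aic == 6.0
        assert bic == pytest.approx(3 * np.log(100), abs=1e-12)

    def test_absent_for_non_ml(self):
        assert compute_aic_bic(None, 10, 100) == (None, None)


class TestAssembledBattery:
    def test_perfect_fit_identity_suite(
        self, one_factor_spec7, exact_one_factor_moments
    ):
        """When sample equals implied moments, every index is at its ideal."""
        f = fit(one_factor_spec7, exact_one_factor_moments)
        b = fit_baseline(one_factor_spec7, exact_one_factor_moments)
        ix = compute_fit_indices(f, b)
        assert ix.chi_square == pytest.approx(0.0, abs=1e-5)
        assert ix.gfi == pytest.approx(1.0, abs=1e-7)
        assert ix.srmr == pytest.approx(0.0, abs=1e-5)
        assert ix.rmsea == pytest.approx(0.0, abs=1e-6)
        assert ix.cfi == pytest.approx(1.0, abs=1e-7)

    def test_eq3_identity_on_fitted_models(self, small_continuous):
        """CGFI == GFI + 4p/(k(k+1)N) to 1e-12 on a real fit."""
        pop, data = small_continuous
        mo = sample_covariance(data)
        spec = parse_model(pop.model_syntax())
        f = fit(spec, mo)
        b = fit_baseline(spec, mo)
        ix = compute_fit_indices(f, b)
        alt = ix.gfi + 4 * ix.p_free / (ix.k * (ix.k + 1) * ix.n)
        assert ix.cgfi == pytest.approx(alt, abs=1e-12)
        assert ix.cgfi > ix.gfi

    def test_aic_absent_under_dwls(self):
        pop = synthetic.one_factor_model(
            k=4, loading=0.7, n=600, seed=17, thresholds=(-0.4, 0.6),
        )
        from cgfiboot.moments import polychoric_moments

        mo = polychoric_moments(synthetic.generate_ordinal(pop))
        spec = parse_model(
            pop.model_syntax(), data_kind="ordinal",
            n_categories={i: 3 for i in pop.indicators},
        )
        f = fit(spec, mo, estimator="DWLS")
        b = fit_baseline(spec, mo, estimator="DWLS")
        ix = compute_fit_indices(f, b)
        assert ix.aic is None and ix.bic is None
        assert math.isnan(ix.as_dict()["aic"])
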