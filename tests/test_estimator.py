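"""Discrepancy functions, model fitting and the baseline model."""

import numpy as np
import pytest

from cgfiboot import synthetic
from cgfiboot.estimator import (
    EstimationError,
    fit,
    fit_baseline,
    gls_discrepancy,
    ls_discrepancy,
    ml_discrepancy,
)
from cgfiboot.model import parse_model
from cgfiboot.moments import (
    SampleMoments,
    polychoric_moments,
    sample_covariance,
)


class TestMlDiscrepancy:
    def test_zero_at_identity(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(4, 4))
        S = a @ a.T + 4 * np.eye(4)
        assert ml_discrepancy(S, S) == pytest.approx(0.0, abs=1e-12)

    def test_hand_example(self):
        S = np.eye(2)
        Sigma = np.diag([2.0, 2.0])
        expected = 2 * np.log(2) + 1 - 2
        assert ml_discrepancy(S, Sigma) == pytest.approx(expected, abs=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(5, 5))
        S = a @ a.T + 5 * np.eye(5)
        b = rng.normal(size=(5, 5))
        Sigma = b @ b.T + 5 * np.eye(5)
        perm = rng.permutation(5)
        f1 = ml_discrepancy(S, Sigma)
        f2 = ml_discrepancy(S[np.ix_(perm, perm)], Sigma[np.ix_(perm, perm)])
        assert f1 == pytest.approx(f2, rel=1e-12)

    def test_gls_zero_at_identity(self):
        S = np.array([[2.0, 0.5], [0.5, 1.5]])
        assert gls_discrepancy(S, S) == pytest.approx(0.0, abs=1e-12)


class TestLsDiscrepancy:
    def test_identity_residual(self):
        v = np.array([0.3, -0.2, 0.1])
        assert ls_discrepancy(v, v) == 0.0

    def test_uls_sum_of_squares(self):
        assert ls_discrepancy(
            np.array([0.1, -0.1]), np.zeros(2), "ULS"
        ) == pytest.approx(0.02)

    def test_dwls_equals_wls_for_diagonal_weight(self):
        r = np.array([0.2, -0.1, 0.05])
        d = np.array([0.5, 0.25, 1.0])
        f_dwls = ls_discrepancy(r, np.zeros(3), "DWLS", gamma_diag=d)
        f_wls = ls_discrepancy(r, np.zeros(3), "WLS", gamma_full=np.diag(d))
        assert f_dwls == pytest.approx(f_wls, rel=1e-12)


class TestFit:
    def test_zero_discrepancy_recovers_parameters(
        self, one_factor_spec7, exact_one_factor_moments
    ):
        f = fit(one_factor_spec7, exact_one_factor_moments)
        assert f.converged
        assert f.F_min == pytest.approx(0.0, abs=1e-8)
        assert f.chi_square == pytest.approx(0.0, abs=1e-5)
        np.testing.assert_allclose(f.lam[:, 0], 0.7, atol=1e-4)

    def test_parameter_recovery_large_n(self):
        pop = synthetic.one_factor_model(k=7, loading=0.7, n=100_000, seed=7)
        mo = sample_covariance(synthetic.generate_continuous(pop))
        f = fit(parse_model(pop.model_syntax()), mo)
        np.testing.assert_allclose(f.lam[:, 0], 0.7, atol=0.01)

    def test_identifications_fit_equivalent(self, small_moments):
        text = "L =~ q1 + q2 + q3 + q4 + q5 + q6 + q7"
        f_uv = fit(parse_model(text), small_moments)
        f_fl = fit(
            parse_model(text, identification="first_loading_fixed"),
            small_moments,
        )
        assert f_uv.F_min == pytest.approx(f_fl.F_min, abs=1e-8)

    def test_variable_order_invariance(self, small_moments):
        f1 = fit(parse_model("L =~ q1 + q2 + q3 + q4 + q5 + q6 + q7"),
                 small_moments)
        f2 = fit(parse_model("L =~ q7 + q3 + q1 + q2 + q5 + q6 + q4"),
                 small_moments)
        assert f1.F_min == pytest.approx(f2.F_min, abs=1e-8)

    def test_two_factor_fit(self):
        lam = {"F1": {"x1": 0.8, "x2": 0.7, "x3": 0.6},
               "F2": {"y1": 0.7, "y2": 0.6, "y3": 0.8}}
        phi = np.array([[1.0, 0.4], [0.4, 1.0]])
        uniq = 1 - np.array([0.8, 0.7, 0.6, 0.7, 0.6, 0.8]) ** 2
        pop = synthetic.PopulationModel(
            loadings=lam, uniquenesses=uniq, factor_correlations=phi,
            n=50_000, seed=12,
        )
        mo = sample_covariance(synthetic.generate_continuous(pop))
        spec = parse_model("F1 =~ x1 + x2 + x3\nF2 =~ y1 + y2 + y3")
        f = fit(spec, mo)
        assert f.converged
        assert f.phi[0, 1] == pytest.approx(0.4, abs=0.02)

    def test_saturated_model_chi_zero_p_one(self):
        pop = synthetic.one_factor_model(k=3, loading=0.7, n=500, seed=5)
        mo = sample_covariance(synthetic.generate_continuous(pop))
        f = fit(parse_model("F =~ x1 + x2 + x3"), mo)
        assert f.df == 0 and f.chi_square == 0.0 and f.p_value == 1.0

    def test_chi_multiplier_convention(self, one_factor_spec7, small_moments):
        f_n = fit(one_factor_spec7, small_moments, chi_multiplier="N")
        f_n1 = fit(one_factor_spec7, small_moments, chi_multiplier="N-1")
        n = small_moments.n_effective
        assert f_n1.chi_square == pytest.approx(
            f_n.chi_square * (n - 1) / n, rel=1e-9
        )

    def test_estimator_moments_compatibility(self, small_moments):
        spec = parse_model("L =~ q1 + q2 + q3 + q4 + q5 + q6 + q7")
        with pytest.raises(EstimationError, match="polychoric"):
            fit(spec, small_moments, estimator="ULS")

    def test_ordinal_dwls_recovery(self):
        pop = synthetic.one_factor_model(
            k=5, loading=0.7, n=2000, seed=21, thresholds=(-0.5, 0.5),
        )
        data = synthetic.generate_ordinal(pop)
        mo = polychoric_moments(data)
        spec = parse_model(
            pop.model_syntax(), data_kind="ordinal",
            n_categories={i: 3 for i in pop.indicators},
        )
        f = fit(spec, mo, estimator="DWLS")
        assert f.converged
        np.testing.assert_allclose(f.lam[:, 0], 0.7, atol=0.06)
        np.testing.assert_allclose(np.diag(f.implied), 1.0, atol=1e-10)

    def test_uls_matches_dwls_direction(self):
        pop = synthetic.one_factor_model(
            k=4, loading=0.6, n=800, seed=31, thresholds=(0.0,),
        )
        mo = polychoric_moments(synthetic.generate_ordinal(pop))
        spec = parse_model(
            pop.model_syntax(), data_kind="ordinal",
            n_categories={i: 2 for i in pop.indicators},
        )
        for est in ("ULS", "DWLS", "WLS"):
            f = fit(spec, mo, estimator=est)
            assert f.converged and f.F_min >= 0


class TestBaseline:
    def test_diagonal_sample_gives_zero(self):
        S = np.diag([1.0, 2.0, 3.0])
        mo = SampleMoments(matrix=S, names=["a", "b", "c"], n_effective=100,
                           kind="covariance")
        spec = parse_model("F =~ a + b + c")
        b = fit_baseline(spec, mo)
        assert b.chi_square == pytest.approx(0.0, abs=1e-10)

    def test_closed_form_hand_example(self):
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        mo = SampleMoments(matrix=S, names=["a", "b"], n_effective=101,
                           kind="covariance")
        spec = parse_model("F =~ a + b")
        b = fit_baseline(spec, mo)
        assert b.chi_square == pytest.approx(-101 * np.log(0.75), rel=1e-10)
        assert b.df == 1

    def test_baseline_df_k7(self, one_factor_spec7, small_moments):
        assert fit_baseline(one_factor_spec7, small_moments).df == 21

    def test_gls_baseline_is_stationary(self, small_moments):
        spec = parse_model("L =~ q1 + q2 + q3 + q4 + q5 + q6 + q7")
        b = fit_baseline(spec, small_moments, estimator="GLS")
        # perturbing any implied variance should not lower F
        d0 = np.diag(b.implied).copy()
        f0 = b.F_min
        for j in range(7):
            for eps in (-1e-4, 1e-4):
                d = d0.copy()
                d[j] += eps
                f = gls_discrepancy(small_moments.matrix, np.diag(d))
                assert f >= f0 - 1e-10
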