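"""Sample moments: CSV loading, covariance, thresholds, polychorics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cgfiboot.moments import (
    DataError,
    DegenerateDataError,
    InsufficientDataError,
    dataset_from_frame,
    estimate_thresholds,
    load_csv,
    polychoric_correlation,
    polychoric_moments,
    sample_covariance,
)
from cgfiboot import synthetic


def _write_csv(tmp_path, text, name="d.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestLoadCsv:
    def test_complete_file(self, tmp_path):
        p = _write_csv(tmp_path, "a,b,c\n1,2,3\n4,5,6\n7,8,9\n1,1,1\n2,2,3\n")
        d = load_csv(p)
        assert d.n_rows_raw == 5 and d.n_rows_complete == 5

    def test_listwise_deletion(self, tmp_path):
        p = _write_csv(tmp_path, "a,b,c\n1,2,3\n4,NA,6\n7,8,9\n1,1,1\n2,2,3\n")
        d = load_csv(p)
        assert d.n_rows_complete == 4
        assert not d.values.isna().any().any()

    def test_unmodeled_column_missing_kept(self, tmp_path):
        p = _write_csv(
            tmp_path, "a,b,junk\n1,2,NA\n4,5,6\n7,8,9\n0,1,2\n"
        )
        d = load_csv(p, indicators=["a", "b"])
        assert d.n_rows_complete == 4

    def test_non_numeric_cell_reports_location(self, tmp_path):
        p = _write_csv(tmp_path, "a,b\n1,2\n4,oops\n")
        with pytest.raises(DataError, match="'oops'.*column 'b'"):
            load_csv(p)

    def test_custom_missing_token(self, tmp_path):
        p = _write_csv(tmp_path, "a,b\n1,2\n4,.\n5,6\n7,8\n")
        d = load_csv(p, missing_token=".")
        assert d.n_rows_complete == 3

    def test_insufficient_data(self, tmp_path):
        p = _write_csv(tmp_path, "a,b,c\n1,2,3\n4,5,6\n")
        with pytest.raises(InsufficientDataError):
            load_csv(p)


class TestSampleCovariance:
    def test_hand_example_divisor_n(self):
        frame = pd.DataFrame(
            {"x": [0, 1, 0, 1], "y": [0, 1, 1, 0]}, dtype=float
        )
        mo = sample_covariance(dataset_from_frame(frame, min_rows=0))
        np.testing.assert_allclose(mo.matrix, [[0.25, 0], [0, 0.25]],
                                   atol=1e-12)

    def test_identical_columns_share_variance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        frame = pd.DataFrame({"a": x, "b": x})
        mo = sample_covariance(dataset_from_frame(frame))
        assert mo.matrix[0, 1] == pytest.approx(mo.matrix[0, 0])

    def test_divisor_choice(self):
        rng = np.random.default_rng(1)
        frame = pd.DataFrame(rng.normal(size=(20, 2)), columns=["a", "b"])
        d = dataset_from_frame(frame)
        m_n = sample_covariance(d, divisor="N").matrix
        m_n1 = sample_covariance(d, divisor="N-1").matrix
        np.testing.assert_allclose(m_n * 20 / 19, m_n1)

    def test_constant_column_raises(self):
        frame = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [5.0, 5, 5, 5]})
        with pytest.raises(DegenerateDataError, match="'b'"):
            sample_covariance(dataset_from_frame(frame))


class TestThresholds:
    def test_even_binary_split(self):
        col = np.array([1] * 50 + [2] * 50, float)
        np.testing.assert_allclose(estimate_thresholds(col), [0.0], atol=1e-12)

    def test_8413_percent_split(self):
        col = np.array([1] * 8413 + [2] * 1587, float)
        assert estimate_thresholds(col)[0] == pytest.approx(1.0, abs=1e-3)

    def test_equal_quartiles(self):
        col = np.repeat([1, 2, 3, 4], 25).astype(float)
        tau = estimate_thresholds(col)
        expected = stats.norm.ppf([0.25, 0.5, 0.75])
        np.testing.assert_allclose(tau, expected, atol=1e-12)

    def test_single_category_raises(self):
        with pytest.raises(DegenerateDataError):
            estimate_thresholds(np.ones(10))


class TestPolychoric:
    def test_orthant_table_gives_half(self):
        # P(both below zero thresholds) = 1/4 + asin(rho)/(2 pi) = 1/3
        # exactly at rho = 0.5
        n = 600
        x = np.array([1] * 200 + [1] * 100 + [2] * 100 + [2] * 200, float)
        y = np.array([1] * 200 + [2] * 100 + [1] * 100 + [2] * 200, float)
        rho, conv = polychoric_correlation(x, y)
        assert conv
        assert rho == pytest.approx(0.5, abs=1e-3)

    def test_independent_margins_give_zero(self):
        # an exactly independent 2x2 table: cells 30,30,20,20
        x = np.array([1] * 60 + [2] * 40, float)
        y = np.array([1] * 30 + [2] * 30 + [1] * 20 + [2] * 20, float)
        rho, _ = polychoric_correlation(x, y)
        assert rho == pytest.approx(0.0, abs=1e-3)

    def test_monte_carlo_recovery(self):
        pop = synthetic.one_factor_model(
            k=2, loading=np.sqrt(0.7), n=2000, seed=99,
            thresholds=(-0.8, 0.0, 0.8),
        )
        data = synthetic.generate_ordinal(pop)
        x = data.values.to_numpy()
        rho, _ = polychoric_correlation(x[:, 0], x[:, 1])
        assert rho == pytest.approx(0.7, abs=0.03)

    def test_matrix_symmetric_unit_diagonal(self):
        pop = synthetic.one_factor_model(
            k=4, loading=0.6, n=300, seed=3, thresholds=(0.0,),
        )
        mo = polychoric_moments(synthetic.generate_ordinal(pop))
        np.testing.assert_allclose(mo.matrix, mo.matrix.T)
        np.testing.assert_allclose(np.diag(mo.matrix), 1.0)
        assert np.linalg.eigvalsh(mo.matrix).min() > 0

    def test_gamma_diag_scales_inversely_with_n(self):
        # asymptotic variances are per sqrt(n), so the diagonal should be
        # roughly n-invariant while the moment SD shrinks
        rhos = []
        for n in (400, 1600):
            pop = synthetic.one_factor_model(
                k=2, loading=0.7, n=n, seed=11, thresholds=(0.0, 1.0),
            )
            mo = polychoric_moments(synthetic.generate_ordinal(pop))
            rhos.append(mo.gamma_diag[0])
        assert rhos[0] == pytest.approx(rhos[1], rel=0.5)
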