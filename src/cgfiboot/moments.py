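"""Observed sample moments: covariances, thresholds, polychoric correlations.

Continuous data are summarized by the sample covariance matrix (ML
divisor N by default). Ordered-categorical data are summarized by the
standard two-step polychoric moments: thresholds from the inverse-normal
cumulative margins, then each pairwise correlation by maximizing the
bivariate-normal likelihood of the two-way table with thresholds fixed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

__all__ = [
    "Dataset",
    "SampleMoments",
    "DataError",
    "InsufficientDataError",
    "DegenerateDataError",
    "load_csv",
    "dataset_from_frame",
    "sample_covariance",
    "estimate_thresholds",
    "polychoric_correlation",
    "polychoric_moments",
    "compute_moments",
]

RHO_BOUND = 1.0 - 1e-4  # |rho| kept away from +/-1
PSD_EIG_FLOOR = 1e-8


class DataError(ValueError):
    """Base class for raw-data problems."""


class InsufficientDataError(DataError):
    """Too few complete cases to estimate the moments."""


class DegenerateDataError(DataError):
    """A column carries no information (constant, single category, ...)."""


@dataclass
class Dataset:
    """Complete-case rectangular data for the modeled indicators.

    ``values`` holds only the modeled columns, with listwise deletion
    already applied; ``n_rows_raw`` is the case count before deletion
    (the bootstrap resamples raw cases, so the raw table is retained).
    """

    values: pd.DataFrame
    variable_names: list[str]
    n_rows_raw: int
    n_rows_complete: int
    raw: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.n_rows_complete > self.n_rows_raw:
            raise DataError("complete cases exceed raw cases")
        if self.values.isna().any().any():
            raise DataError("Dataset still contains missing cells")


def dataset_from_frame(
    frame: pd.DataFrame,
    indicators: list[str] | None = None,
    min_rows: int | None = None,
) -> Dataset:
    """Build a Dataset from an in-memory frame (NaN marks missing)."""
    if indicators is None:
        indicators = list(frame.columns)
    missing_cols = [c for c in indicators if c not in frame.columns]
    if missing_cols:
        raise DataError(f"columns not found in data: {missing_cols}")
    sub = frame[indicators]
    complete = sub.dropna(axis=0, how="any")
    n_raw, n_complete = len(sub), len(complete)
    if n_raw != n_complete:
        logger.info(
            "listwise deletion dropped %d of %d rows", n_raw - n_complete, n_raw
        )
    floor = (len(indicators) + 1) if min_rows is None else min_rows
    if n_complete < floor:
        raise InsufficientDataError(
            f"only {n_complete} complete cases for {len(indicators)} "
            f"indicators (need >= {floor})"
        )
    return Dataset(
        values=complete.reset_index(drop=True).astype(float),
        variable_names=list(indicators),
        n_rows_raw=n_raw,
        n_rows_complete=n_complete,
        raw=sub.reset_index(drop=True),
    )


def load_csv(
    path,
    indicators: list[str] | None = None,
    missing_token: str = "NA",
) -> Dataset:
    """Read comma-delimited case data with a header row.

    Rows with the missing token in any *modeled* column are dropped
    (listwise deletion); missingness in unmodeled columns is ignored.
    Non-numeric cells other than the missing token raise a parse error
    naming the row and column.
    """
    frame = pd.read_csv(
        path, na_values=[missing_token], keep_default_na=False, comment=None
    )
    if frame.shape[1] < 2:
        raise DataError(f"{path}: expected >= 2 columns")
    cols = indicators if indicators is not None else list(frame.columns)
    missing_cols = [c for c in cols if c not in frame.columns]
    if missing_cols:
        raise DataError(f"{path}: columns not found: {missing_cols}")
    sub = frame[cols].copy()
    for c in cols:
        converted = pd.to_numeric(sub[c], errors="coerce")
        bad = converted.isna() & sub[c].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise DataError(
                f"{path}: non-numeric value {sub[c].iloc[row]!r} at data row "
                f"{row + 1}, column {c!r}"
            )
        sub[c] = converted
    return dataset_from_frame(sub, cols)


@dataclass
class SampleMoments:
    """Observed moments consumed by the fit engine.

    ``matrix`` is either a covariance matrix (continuous data) or a
    polychoric correlation matrix (ordinal data, unit diagonal);
    ``thresholds`` maps each ordinal indicator to its ascending
    threshold vector.
    """

    matrix: np.ndarray
    names: list[str]
    n_effective: int
    kind: Literal["covariance", "polychoric"]
    thresholds: dict[str, np.ndarray] | None = None
    smoothed: bool = False
    # Gamma: asymptotic covariance of sqrt(n) * (correlations, thresholds)
    gamma_diag: np.ndarray | None = None
    gamma_full: np.ndarray | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("moment matrix is not symmetric")
        self.matrix = 0.5 * (m + m.T)
        if self.kind == "polychoric":
            if not np.allclose(np.diag(self.matrix), 1.0):
                raise ValueError("polychoric matrix must have unit diagonal")
            if self.thresholds is not None:
                for name, tau in self.thresholds.items():
                    if np.any(np.diff(tau) <= 0):
                        raise ValueError(
                            f"thresholds for {name!r} not strictly increasing"
                        )

    @property
    def k(self) -> int:
        return self.matrix.shape[0]


def sample_covariance(
    data: Dataset, divisor: Literal["N", "N-1"] = "N"
) -> SampleMoments:
    """Sample covariance matrix of the complete cases.

    The default divisor N is the biased maximum-likelihood form that
    normal-theory covariance-structure fitting assumes; N-1 is offered
    for compatibility with descriptive conventions.
    """
    x = data.values.to_numpy(dtype=float)
    n = x.shape[0]
    if n < 2:
        raise InsufficientDataError("need >= 2 complete cases")
    xc = x - x.mean(axis=0)
    s = xc.T @ xc / (n if divisor == "N" else n - 1)
    variances = np.diag(s)
    if np.any(variances <= 0):
        col = data.variable_names[int(np.argmin(variances))]
        raise DegenerateDataError(f"column {col!r} has zero variance")
    return SampleMoments(
        matrix=s, names=list(data.variable_names), n_effective=n,
        kind="covariance",
    )


def estimate_thresholds(column: np.ndarray) -> np.ndarray:
    """Thresholds from the inverse-normal cumulative category proportions.

    For categories c = 1..C the threshold vector has C-1 entries,
    tau_c = Phi^{-1}(P(X <= c)).
    """
    col = np.asarray(column, dtype=float)
    col = col[~np.isnan(col)]
    cats, counts = np.unique(col, return_counts=True)
    if len(cats) < 2:
        raise DegenerateDataError("column has a single observed category")
    cum = np.cumsum(counts)[:-1] / col.size
    return stats.norm.ppf(cum)


def _cell_probabilities(
    rho: float, tau_x: np.ndarray, tau_y: np.ndarray
) -> np.ndarray:
    """Bivariate-normal rectangle probabilities for every table cell."""
    tx = np.concatenate(([-np.inf], tau_x, [np.inf]))
    ty = np.concatenate(([-np.inf], tau_y, [np.inf]))
    nx, ny = len(tx), len(ty)
    cdf = np.zeros((nx, ny))
    fx = np.isfinite(tx)
    fy = np.isfinite(ty)
    # interior: true bivariate cdf; edges reduce to univariate marginals
    if fx[:-1].any() and fy[:-1].any():
        bv = stats.multivariate_normal(
            mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]],
            allow_singular=True,
        )
        xi, yi = np.meshgrid(np.where(fx)[0], np.where(fy)[0], indexing="ij")
        pts = np.column_stack([tx[xi.ravel()], ty[yi.ravel()]])
        cdf[xi.ravel(), yi.ravel()] = np.atleast_1d(bv.cdf(pts))
    # edges: +inf in one coordinate -> univariate marginal of the other
    cdf[-1, fy] = stats.norm.cdf(ty[fy])
    cdf[fx, -1] = stats.norm.cdf(tx[fx])
    cdf[-1, -1] = 1.0
    # -inf rows/columns are exactly 0 (already zeros)
    probs = (
        cdf[1:, 1:] - cdf[:-1, 1:] - cdf[1:, :-1] + cdf[:-1, :-1]
    )
    return np.clip(probs, 1e-12, None)


def _cell_prob_drho(
    rho: float, tau_x: np.ndarray, tau_y: np.ndarray
) -> np.ndarray:
    """d(cell probability)/d(rho) via the bivariate-normal density identity."""
    tx = np.concatenate(([-np.inf], tau_x, [np.inf]))
    ty = np.concatenate(([-np.inf], tau_y, [np.inf]))
    det = 1.0 - rho * rho

    def phi2(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        out = np.zeros(np.broadcast(a, b).shape)
        fin = np.isfinite(a) & np.isfinite(b)
        aa, bb = np.broadcast_arrays(a, b)
        z = (aa[fin] ** 2 - 2 * rho * aa[fin] * bb[fin] + bb[fin] ** 2) / det
        out[fin] = np.exp(-0.5 * z) / (2 * np.pi * np.sqrt(det))
        return out

    ax, by = np.meshgrid(tx, ty, indexing="ij")
    d = phi2(ax, by)
    return d[1:, 1:] - d[:-1, 1:] - d[1:, :-1] + d[:-1, :-1]


def polychoric_correlation(
    col_x: np.ndarray,
    col_y: np.ndarray,
    tau_x: np.ndarray | None = None,
    tau_y: np.ndarray | None = None,
) -> tuple[float, bool]:
    """Two-step polychoric correlation of a pair of ordinal columns.

    With thresholds held at their margin-based estimates, the
    correlation maximizes the multinomial likelihood of the two-way
    contingency table under the underlying bivariate-normal model.
    Returns ``(rho_hat, converged)``; the estimate is clamped inside
    (-1, 1) by 1e-4.
    """
    x = np.asarray(col_x, dtype=float)
    y = np.asarray(col_y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size == 0:
        raise DataError("empty contingency table")
    if tau_x is None:
        tau_x = estimate_thresholds(x)
    if tau_y is None:
        tau_y = estimate_thresholds(y)
    cats_x = np.unique(x)
    cats_y = np.unique(y)
    if len(cats_x) < 2 or len(cats_y) < 2:
        raise DegenerateDataError("both columns need >= 2 observed categories")
    ix = np.searchsorted(cats_x, x)
    iy = np.searchsorted(cats_y, y)
    table = np.zeros((len(cats_x), len(cats_y)))
    np.add.at(table, (ix, iy), 1.0)

    def negloglik(rho: float) -> float:
        probs = _cell_probabilities(rho, tau_x, tau_y)
        return -float(np.sum(table * np.log(probs)))

    res = optimize.minimize_scalar(
        negloglik, bounds=(-RHO_BOUND, RHO_BOUND), method="bounded",
        options={"xatol": 1e-6},
    )
    rho = float(np.clip(res.x, -RHO_BOUND, RHO_BOUND))
    converged = bool(res.success)
    if not converged:
        warnings.warn("polychoric optimizer did not converge; estimate flagged")
    return rho, converged


def _influence_acov(
    codes: np.ndarray,
    taus: list[np.ndarray],
    rho: np.ndarray,
    pairs: list[tuple[int, int]],
) -> np.ndarray:
    """Asymptotic covariance of (correlations, thresholds) moment estimates.

    Each two-step estimate solves an estimating equation; its per-case
    influence function is computed in closed form (delta method on the
    cumulative margins for thresholds; score over information, with
    thresholds fixed, for each polychoric correlation). The empirical
    covariance of the stacked influence functions estimates Gamma, the
    asymptotic covariance of sqrt(n) times the moment vector; the
    sampling covariance of the moments themselves is Gamma / n.
    """
    n, k = codes.shape
    cols: list[np.ndarray] = []
    for (i, j) in pairs:
        probs = _cell_probabilities(rho[i, j], taus[i], taus[j])
        dprob = _cell_prob_drho(rho[i, j], taus[i], taus[j])
        score_cell = dprob / probs
        s = score_cell[codes[:, i], codes[:, j]]
        info = float(np.mean(s * s))
        cols.append(s / max(info, 1e-12))
    for j in range(k):
        tau = taus[j]
        dens = stats.norm.pdf(tau)
        cum = stats.norm.cdf(tau)
        for c, (t, d, p) in enumerate(zip(tau, dens, cum)):
            ind = (codes[:, j] <= c).astype(float)
            cols.append((ind - p) / max(d, 1e-12))
    inf_mat = np.column_stack(cols)
    return np.cov(inf_mat, rowvar=False, bias=True)


def polychoric_moments(
    data: Dataset, compute_acov: bool = True
) -> SampleMoments:
    """Thresholds plus pairwise polychoric correlation matrix.

    The assembled matrix is smoothed to the nearest positive
    semidefinite matrix (eigenvalues clipped at 1e-8) when necessary;
    smoothing is logged and flagged on the result.
    """
    x = data.values.to_numpy(dtype=float)
    n, k = x.shape
    names = data.variable_names
    taus = []
    codes = np.zeros_like(x, dtype=int)
    for j in range(k):
        cats = np.unique(x[:, j])
        if len(cats) < 2:
            raise DegenerateDataError(
                f"column {names[j]!r} has a single observed category"
            )
        taus.append(estimate_thresholds(x[:, j]))
        codes[:, j] = np.searchsorted(cats, x[:, j])
    rho = np.eye(k)
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    for (i, j) in pairs:
        r, _ = polychoric_correlation(x[:, i], x[:, j], taus[i], taus[j])
        rho[i, j] = rho[j, i] = r
    smoothed = False
    eigval, eigvec = np.linalg.eigh(rho)
    if eigval.min() < PSD_EIG_FLOOR:
        smoothed = True
        logger.warning(
            "polychoric matrix not PSD (min eigenvalue %.3e); smoothing",
            eigval.min(),
        )
        eigval = np.clip(eigval, PSD_EIG_FLOOR, None)
        rho = eigvec @ np.diag(eigval) @ eigvec.T
        d = np.sqrt(np.diag(rho))
        rho = rho / np.outer(d, d)
        np.fill_diagonal(rho, 1.0)
    gamma = None
    if compute_acov:
        gamma = _influence_acov(codes, taus, rho, pairs)
    return SampleMoments(
        matrix=rho,
        names=list(names),
        n_effective=n,
        kind="polychoric",
        thresholds={names[j]: taus[j] for j in range(k)},
        smoothed=smoothed,
        gamma_diag=None if gamma is None else np.diag(gamma).copy(),
        gamma_full=gamma,
    )


def compute_moments(
    data: Dataset,
    ordered: bool,
    divisor: Literal["N", "N-1"] = "N",
    compute_acov: bool = True,
) -> SampleMoments:
    """Dispatch to covariance or polychoric moments per the ordered flag."""
    if ordered:
        return polychoric_moments(data, compute_acov=compute_acov)
    return sample_covariance(data, divisor=divisor)
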