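"""Descriptive fit indices and the corrected goodness-of-fit index (CGFI).

The CGFI adds a small-sample / model-complexity correction to the GFI:

    CGFI = GFI + 2 * (1 - 2*df / (k*(k+1))) / N

where ``k`` is the number of observed variables, ``df`` the test-model
degrees of freedom and ``N`` the sample size. Because
``df = k(k+1)/2 - p`` for covariance-metric models, the correction
equals ``4p / (k(k+1) N)``: it grows with the number of free parameters
``p`` and vanishes as N grows, offsetting the downward bias that small
samples impose on the GFI.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .estimator import FittedModel

logger = logging.getLogger(__name__)

__all__ = [
    "FitIndexSet",
    "INDEX_ORDER",
    "compute_gfi",
    "compute_agfi",
    "compute_cgfi",
    "compute_cfi_tli",
    "compute_rmsea",
    "compute_srmr",
    "compute_aic_bic",
    "compute_fit_indices",
]

# report row order, matching the published table layout
INDEX_ORDER = [
    "chi_square", "df", "p_value", "cfi", "tli", "gfi", "agfi",
    "rmsea", "srmr", "aic", "bic", "cgfi",
]


@dataclass
class FitIndexSet:
    """One value per fit index for a single fitted model.

    ``aic``/``bic`` are None for non-ML estimators, ``tli`` is None when
    the baseline model already fits, ``agfi``/``rmsea`` are None for
    saturated models (df = 0).
    """

    chi_square: float
    df: int
    p_value: float
    cfi: float
    tli: float | None
    gfi: float
    agfi: float | None
    rmsea: float | None
    srmr: float
    aic: float | None
    bic: float | None
    cgfi: float
    k: int
    p_free: int
    n: int
    notes: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        out = {}
        for name in INDEX_ORDER:
            v = getattr(self, name)
            out[name] = math.nan if v is None else float(v)
        return out


def compute_gfi(S: np.ndarray, Sigma: np.ndarray, estimator: str = "ML") -> float:
    """Goodness-of-fit index: share of observed moment information reproduced.

    ML/GLS (covariance metric): ``1 - tr[(Sigma^-1 S - I)^2] / tr[(Sigma^-1 S)^2]``.
    Least-squares estimators on correlations: ``1 - tr[(S-Sigma)^2] / tr[S^2]``.
    """
    S = np.asarray(S, float)
    Sigma = np.asarray(Sigma, float)
    if estimator in ("ML", "GLS"):
        try:
            W = np.linalg.solve(Sigma, S)
        except np.linalg.LinAlgError as exc:
            raise ValueError("implied matrix is singular") from exc
        resid = W - np.eye(S.shape[0])
        return float(1.0 - np.trace(resid @ resid) / np.trace(W @ W))
    diff = S - Sigma
    return float(1.0 - np.trace(diff @ diff) / np.trace(S @ S))


def compute_agfi(gfi: float, k: int, df: int) -> float | None:
    """df-penalized GFI; undefined (None) for saturated models."""
    if df == 0:
        return None
    return float(1.0 - (k * (k + 1) / (2.0 * df)) * (1.0 - gfi))


def compute_cgfi(gfi: float, k: int, df: int, n: int) -> float:
    """Corrected GFI: ``GFI + 2*(1 - 2*df/(k*(k+1))) / n``, capped at 1.

    The correction term equals ``4p/(k(k+1)n)`` by the df identity, so
    it rewards parsimony (small p) and disappears for large samples.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    kk1 = k * (k + 1)
    if not (0 <= df <= kk1 / 2):
        raise ValueError(f"df={df} outside [0, k(k+1)/2]")
    raw = gfi + 2.0 * (1.0 - 2.0 * df / kk1) / n
    if raw > 1.0:
        logger.warning("CGFI %.6f exceeds 1; capped at 1.0", raw)
        return 1.0
    return float(raw)


def compute_cfi_tli(
    chi_t: float, df_t: int, chi_b: float, df_b: int
) -> tuple[float, float | None]:
    """Incremental fit against the independence baseline.

    CFI uses noncentrality with max-protection; TLI is the relative
    chi-square reduction and is undefined when the baseline fits
    (chi_b <= df_b), in which case CFI is 1 and TLI is None.
    """
    if df_b <= 0:
        raise ValueError("baseline df must be positive")
    nc_t = chi_t - df_t
    nc_b = chi_b - df_b
    if nc_b <= 0:
        return 1.0, None
    cfi = 1.0 - max(nc_t, 0.0) / max(nc_b, nc_t, 0.0)
    if df_t == 0:
        return float(cfi), None
    ratio_b = chi_b / df_b
    tli = (ratio_b - chi_t / df_t) / (ratio_b - 1.0)
    return float(cfi), float(tli)


def compute_rmsea(chi: float, df: int, n: int) -> float | None:
    """Root mean squared error of approximation, per-df noncentrality."""
    if df == 0:
        return None
    return float(np.sqrt(max(chi - df, 0.0) / (df * n)))


def compute_srmr(S: np.ndarray, Sigma: np.ndarray) -> float:
    """Standardized root mean squared residual.

    Both matrices are standardized by the sample standard deviations;
    the root mean square runs over the k(k+1)/2 lower-triangle cells
    including the diagonal (whose residuals are exactly zero in the
    correlation metric).
    """
    S = np.asarray(S, float)
    Sigma = np.asarray(Sigma, float)
    d = np.sqrt(np.diag(S))
    scale = np.outer(d, d)
    resid = (S - Sigma) / scale
    il = np.tril_indices(S.shape[0])
    return float(np.sqrt(np.mean(resid[il] ** 2)))


def compute_aic_bic(
    loglik: float | None, p_free: int, n: int
) -> tuple[float | None, float | None]:
    """Information criteria from the ML log-likelihood; absent for non-ML."""
    if loglik is None:
        return None, None
    aic = -2.0 * loglik + 2.0 * p_free
    bic = -2.0 * loglik + p_free * np.log(n)
    return float(aic), float(bic)


def compute_fit_indices(
    target: FittedModel, baseline: FittedModel
) -> FitIndexSet:
    """Assemble the full index battery for a fitted model."""
    S = target.sample_matrix
    Sigma = target.implied
    k = target.k
    n = target.n_effective
    df = target.df
    notes = list(target.warnings)
    gfi = compute_gfi(S, Sigma, target.estimator)
    agfi = compute_agfi(gfi, k, df)
    raw_cgfi = gfi + 2.0 * (1.0 - 2.0 * df / (k * (k + 1))) / n
    cgfi = compute_cgfi(gfi, k, df, n)
    if raw_cgfi > 1.0:
        notes.append(f"CGFI capped at 1.0 (raw {raw_cgfi:.6f})")
    cfi, tli = compute_cfi_tli(
        target.chi_square, df, baseline.chi_square, baseline.df
    )
    if tli is None:
        notes.append("TLI undefined (baseline model fits or df = 0)")
    rmsea = compute_rmsea(target.chi_square, df, n)
    srmr = compute_srmr(S, Sigma)
    aic, bic = compute_aic_bic(target.loglik, target.p_free, n)
    return FitIndexSet(
        chi_square=target.chi_square, df=df, p_value=target.p_value,
        cfi=cfi, tli=tli, gfi=gfi, agfi=agfi, rmsea=rmsea, srmr=srmr,
        aic=aic, bic=bic, cgfi=cgfi, k=k, p_free=target.p_free, n=n,
        notes=notes,
    )
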