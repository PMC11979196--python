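"""Covariance- and correlation-structure estimation.

The target model ``Sigma(theta) = Lambda Phi Lambda' + Theta`` is fitted
to sample moments by minimizing a discrepancy function:

* ``ML`` (covariance metric): normal-theory maximum likelihood,
  ``F = log|Sigma| + tr(S Sigma^-1) - log|S| - k``.
* ``GLS`` (covariance metric): ``F = 1/2 tr[(I - Sigma S^-1)^2]``.
* ``ULS`` / ``DWLS`` / ``WLS`` (polychoric metric): weighted least
  squares over the non-redundant moment vector (lower-triangle
  correlations followed by thresholds), with identity, diagonal or full
  weight matrix respectively.

The chi-square statistic is ``multiplier * F_min`` with multiplier
``n_effective`` by default (``n_effective - 1`` optionally).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import optimize, stats

from .model import (
    ModelSpec,
    ModelValidationError,
    ParameterTemplate,
    build_template,
    model_df,
)
from .moments import SampleMoments

logger = logging.getLogger(__name__)

__all__ = [
    "FittedModel",
    "EstimationError",
    "ml_discrepancy",
    "gls_discrepancy",
    "ls_discrepancy",
    "fit",
    "fit_baseline",
    "ESTIMATORS",
]

Estimator = Literal["ML", "GLS", "ULS", "DWLS", "WLS"]
ESTIMATORS = ("ML", "GLS", "ULS", "DWLS", "WLS")
COVARIANCE_ESTIMATORS = ("ML", "GLS")
POLYCHORIC_ESTIMATORS = ("ULS", "DWLS", "WLS")

UNIQUENESS_FLOOR = 1e-4  # Heywood protection, relative to sample variance
_PENALTY = 1e10


class EstimationError(RuntimeError):
    pass


class SingularMatrixError(EstimationError):
    pass


def ml_discrepancy(S: np.ndarray, Sigma: np.ndarray) -> float:
    """Normal-theory ML discrepancy between sample and implied covariance.

    Zero iff ``Sigma == S``. Raises on a singular sample matrix; a
    singular implied matrix raises ``SingularMatrixError`` (the
    optimizer path catches it and substitutes a penalty).
    """
    S = np.asarray(S, float)
    Sigma = np.asarray(Sigma, float)
    k = S.shape[0]
    sign_s, logdet_s = np.linalg.slogdet(S)
    if sign_s <= 0:
        raise EstimationError("sample covariance matrix is singular")
    try:
        c = np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError as exc:
        raise SingularMatrixError("implied matrix not positive-definite") from exc
    logdet_sigma = 2.0 * np.sum(np.log(np.diag(c)))
    trace = float(np.trace(np.linalg.solve(Sigma, S)))
    return float(logdet_sigma + trace - logdet_s - k)


def gls_discrepancy(S: np.ndarray, Sigma: np.ndarray) -> float:
    """Normal-theory generalized least squares, F = 1/2 tr[(I - Sigma S^-1)^2]."""
    S = np.asarray(S, float)
    Sigma = np.asarray(Sigma, float)
    A = np.eye(S.shape[0]) - np.linalg.solve(S, Sigma)
    return float(0.5 * np.trace(A @ A))


def ls_discrepancy(
    sample_vec: np.ndarray,
    implied_vec: np.ndarray,
    weights: Literal["ULS", "DWLS", "WLS"] = "ULS",
    gamma_diag: np.ndarray | None = None,
    gamma_full: np.ndarray | None = None,
) -> float:
    """(Weighted) least-squares discrepancy over a moment vector."""
    r = np.asarray(sample_vec, float) - np.asarray(implied_vec, float)
    if weights == "ULS":
        return float(r @ r)
    if weights == "DWLS":
        if gamma_diag is None:
            raise EstimationError("DWLS requires diagonal moment variances")
        return float(np.sum(r * r / gamma_diag))
    if gamma_full is None:
        raise EstimationError("WLS requires the full moment covariance")
    try:
        sol = np.linalg.solve(gamma_full, r)
    except np.linalg.LinAlgError as exc:
        raise EstimationError(
            "full weight matrix is not invertible; try DWLS"
        ) from exc
    return float(r @ sol)


@dataclass
class FittedModel:
    """A fitted covariance/correlation-structure model."""

    spec: ModelSpec
    template: ParameterTemplate
    estimator: str
    lam: np.ndarray            # k x m loading matrix
    phi: np.ndarray            # m x m factor covariance matrix
    theta_diag: np.ndarray     # k uniquenesses (derived under ordinal)
    thresholds: dict[str, np.ndarray] | None
    implied: np.ndarray
    F_min: float
    chi_square: float
    df: int
    p_value: float
    converged: bool
    n_effective: int
    loglik: float | None = None
    heywood: bool = False
    warnings: list[str] = field(default_factory=list)
    sample_matrix: np.ndarray | None = None

    @property
    def k(self) -> int:
        return self.implied.shape[0]

    @property
    def p_free(self) -> int:
        return self.template.p_free

    def loadings_dict(self) -> dict[str, float]:
        out = {}
        for fi, f in enumerate(self.spec.factors):
            for ind in self.spec.loadings_pattern[f]:
                j = self.spec.indicators.index(ind)
                out[f"{f}=~{ind}"] = float(self.lam[j, fi])
        return out


class _ParamMap:
    """Maps the free-parameter vector to (Lambda, Phi, Theta, thresholds)."""

    def __init__(self, spec: ModelSpec, moments: SampleMoments):
        self.spec = spec
        self.k = spec.k
        self.m = spec.n_factors
        self.indicators = spec.indicators
        self.idx = {v: i for i, v in enumerate(self.indicators)}
        self.flf = spec.identification == "first_loading_fixed"
        self.ordinal = spec.data_kind == "ordinal"
        order = [moments.names.index(v) for v in self.indicators]
        svar = np.diag(moments.matrix)[order]
        # slices of the free vector, in template order
        self.free_loadings: list[tuple[int, int]] = []   # (row, factor)
        self.fixed_loadings: list[tuple[int, int, float]] = []
        for fi, f in enumerate(spec.factors):
            for j, ind in enumerate(spec.loadings_pattern[f]):
                row = self.idx[ind]
                if self.flf and j == 0:
                    self.fixed_loadings.append((row, fi, 1.0))
                else:
                    self.free_loadings.append((row, fi))
        self.n_lam = len(self.free_loadings)
        self.n_fvar = self.m if self.flf else 0
        self.pairs_phi = [
            (a, b) for a in range(self.m) for b in range(a + 1, self.m)
        ]
        self.n_fcov = len(self.pairs_phi)
        self.n_theta = 0 if self.ordinal else self.k
        if self.ordinal:
            assert spec.n_categories is not None
            self.n_thresh = [spec.n_categories[i] - 1 for i in self.indicators]
        else:
            self.n_thresh = []
        self.n_free = (
            self.n_lam + self.n_fvar + self.n_fcov + self.n_theta
            + sum(self.n_thresh)
        )
        # bounds
        lo = np.full(self.n_free, -np.inf)
        hi = np.full(self.n_free, np.inf)
        pos = self.n_lam
        if self.ordinal and not self.flf:
            # unit factor variances + no cross-loadings: |lambda| caps the
            # implied variance, keeping uniquenesses >= the floor
            cap = np.sqrt(1.0 - UNIQUENESS_FLOOR)
            lo[: self.n_lam] = -cap
            hi[: self.n_lam] = cap
        if self.flf:
            lo[pos: pos + self.m] = 1e-6
            pos += self.m
        lo[pos: pos + self.n_fcov] = -0.999
        hi[pos: pos + self.n_fcov] = 0.999
        pos += self.n_fcov
        if not self.ordinal:
            lo[pos: pos + self.k] = UNIQUENESS_FLOOR * svar
            pos += self.k
        self.bounds = list(zip(lo, hi))
        self.svar = svar

    # --- layout helpers -------------------------------------------------
    def _split(self, theta: np.ndarray):
        pos = 0
        lam_free = theta[pos: pos + self.n_lam]; pos += self.n_lam
        fvar = theta[pos: pos + self.n_fvar]; pos += self.n_fvar
        fcov = theta[pos: pos + self.n_fcov]; pos += self.n_fcov
        th = theta[pos: pos + self.n_theta]; pos += self.n_theta
        taus = []
        for nt in self.n_thresh:
            taus.append(theta[pos: pos + nt]); pos += nt
        return lam_free, fvar, fcov, th, taus

    def matrices(self, theta: np.ndarray):
        lam_free, fvar, fcov, th, taus = self._split(theta)
        lam = np.zeros((self.k, self.m))
        for (row, fi, val) in self.fixed_loadings:
            lam[row, fi] = val
        for val, (row, fi) in zip(lam_free, self.free_loadings):
            lam[row, fi] = val
        phi = np.eye(self.m)
        if self.flf:
            np.fill_diagonal(phi, fvar)
        for val, (a, b) in zip(fcov, self.pairs_phi):
            phi[a, b] = phi[b, a] = val
        common = lam @ phi @ lam.T
        if self.ordinal:
            theta_d = 1.0 - np.diag(common)
        else:
            theta_d = np.asarray(th, float)
        sigma = common + np.diag(theta_d)
        return lam, phi, theta_d, taus, sigma

    def grad_from_gmat(self, G: np.ndarray, lam: np.ndarray, phi: np.ndarray,
                       include_theta: bool = True) -> np.ndarray:
        """Chain rule from dF/dSigma (symmetric G) to the free vector.

        Threshold entries (which do not enter Sigma) get zeros.
        """
        g = np.zeros(self.n_free)
        GLP = G @ lam @ phi          # k x m
        LGL = lam.T @ G @ lam        # m x m
        pos = 0
        for i, (row, fi) in enumerate(self.free_loadings):
            g[i] = 2.0 * GLP[row, fi]
        pos = self.n_lam
        if self.flf:
            for fi in range(self.m):
                g[pos + fi] = LGL[fi, fi]
            pos += self.m
        for i, (a, b) in enumerate(self.pairs_phi):
            g[pos + i] = 2.0 * LGL[a, b]
        pos += self.n_fcov
        if not self.ordinal and include_theta:
            g[pos: pos + self.k] = np.diag(G)
        return g

    def start(self, moments: SampleMoments, rng: np.random.Generator | None,
              scale: float = 0.0) -> np.ndarray:
        sd = np.sqrt(self.svar)
        theta0 = np.zeros(self.n_free)
        for i, (row, _fi) in enumerate(self.free_loadings):
            theta0[i] = 0.7 * sd[row]
        pos = self.n_lam
        if self.flf:
            theta0[pos: pos + self.m] = 0.5 * float(np.mean(self.svar))
            pos += self.m
        pos += self.n_fcov  # factor covariances start at 0
        if not self.ordinal:
            theta0[pos: pos + self.k] = 0.51 * self.svar
            pos += self.k
        if self.ordinal and moments.thresholds is not None:
            for ind, nt in zip(self.indicators, self.n_thresh):
                theta0[pos: pos + nt] = moments.thresholds[ind]
                pos += nt
        if rng is not None and scale > 0:
            theta0 = theta0 * (1.0 + scale * rng.standard_normal(self.n_free))
        lo = np.array([b[0] for b in self.bounds])
        hi = np.array([b[1] for b in self.bounds])
        return np.clip(theta0, lo + 1e-8, hi - 1e-8)


def _moment_vector(moments: SampleMoments, spec: ModelSpec):
    """Stack lower-triangle correlations then thresholds, model order."""
    order = [moments.names.index(v) for v in spec.indicators]
    R = moments.matrix[np.ix_(order, order)]
    k = len(order)
    iu = [(i, j) for i in range(k) for j in range(i + 1, k)]
    corr = np.array([R[i, j] for (i, j) in iu])
    taus = np.concatenate(
        [moments.thresholds[v] for v in spec.indicators]
    ) if moments.thresholds else np.array([])
    return np.concatenate([corr, taus]), iu, R


def _reorder_gamma(moments: SampleMoments, spec: ModelSpec):
    """Gamma blocks follow moments.names order; permute to model order."""
    if moments.gamma_full is None:
        return None, None
    names = moments.names
    k = len(names)
    pair_index = {}
    pos = 0
    for i in range(k):
        for j in range(i + 1, k):
            pair_index[frozenset((names[i], names[j]))] = pos
            pos += 1
    thresh_index = {}
    for name in names:
        thresh_index[name] = (pos, pos + len(moments.thresholds[name]))
        pos += len(moments.thresholds[name])
    perm: list[int] = []
    inds = spec.indicators
    for a in range(len(inds)):
        for b in range(a + 1, len(inds)):
            perm.append(pair_index[frozenset((inds[a], inds[b]))])
    for name in inds:
        lo, hi = thresh_index[name]
        perm.extend(range(lo, hi))
    perm_arr = np.array(perm)
    full = moments.gamma_full[np.ix_(perm_arr, perm_arr)]
    return np.diag(full).copy(), full


def _check_compat(estimator: str, moments: SampleMoments) -> None:
    if estimator not in ESTIMATORS:
        raise EstimationError(f"unknown estimator {estimator!r}")
    if estimator in COVARIANCE_ESTIMATORS and moments.kind != "covariance":
        raise EstimationError(
            f"{estimator} requires covariance moments (continuous data)"
        )
    if estimator in POLYCHORIC_ESTIMATORS and moments.kind != "polychoric":
        raise EstimationError(
            f"{estimator} requires polychoric moments (ordered data)"
        )


def fit(
    spec: ModelSpec,
    moments: SampleMoments,
    estimator: Estimator = "ML",
    start: np.ndarray | None = None,
    seed: int = 0,
    chi_multiplier: Literal["N", "N-1"] = "N",
    max_restarts: int = 5,
) -> FittedModel:
    """Fit the measurement model to sample moments.

    Minimizes the estimator's discrepancy with an analytic-gradient
    L-BFGS-B search; on non-convergence the start values are perturbed
    (seeded) up to ``max_restarts`` times. Heywood protection bounds
    uniquenesses below at ``1e-4`` times the sample variance; a binding
    bound is flagged.
    """
    _check_compat(estimator, moments)
    df = model_df(spec)
    pm = _ParamMap(spec, moments)
    order = [moments.names.index(v) for v in spec.indicators]
    S = moments.matrix[np.ix_(order, order)]
    n = moments.n_effective
    warns: list[str] = []

    if estimator in COVARIANCE_ESTIMATORS:
        sign_s, logdet_s = np.linalg.slogdet(S)
        if sign_s <= 0:
            raise EstimationError("sample covariance matrix is singular")
        S_inv = np.linalg.inv(S)

        if estimator == "ML":
            def objective(theta):
                lam, phi, theta_d, _, sigma = pm.matrices(theta)
                try:
                    c = np.linalg.cholesky(sigma)
                except np.linalg.LinAlgError:
                    return _PENALTY + float(theta @ theta), 2.0 * theta
                sigma_inv = np.linalg.inv(sigma)
                f = (2.0 * np.sum(np.log(np.diag(c)))
                     + float(np.sum(sigma_inv * S)) - logdet_s - pm.k)
                G = sigma_inv @ (sigma - S) @ sigma_inv
                return f, pm.grad_from_gmat(G, lam, phi)
        else:  # GLS
            def objective(theta):
                lam, phi, theta_d, _, sigma = pm.matrices(theta)
                A = np.eye(pm.k) - S_inv @ sigma
                f = 0.5 * float(np.trace(A @ A))
                G = S_inv @ (sigma - S) @ S_inv
                return f, pm.grad_from_gmat(G, lam, phi)
    else:
        s_vec, iu, R = _moment_vector(moments, spec)
        gamma_diag, gamma_full = _reorder_gamma(moments, spec)
        n_corr = len(iu)
        if estimator == "DWLS":
            if gamma_diag is None:
                raise EstimationError(
                    "DWLS requires moment asymptotic variances"
                )
            w_diag_inv = 1.0 / gamma_diag
        elif estimator == "WLS":
            if gamma_full is None:
                raise EstimationError(
                    "WLS requires the full moment covariance"
                )
            if spec.k > 25:
                raise EstimationError(
                    "WLS full weight matrix limited to k <= 25; use DWLS"
                )
            try:
                w_chol = np.linalg.cholesky(gamma_full)
            except np.linalg.LinAlgError as exc:
                raise EstimationError(
                    "full weight matrix not positive-definite; try DWLS"
                ) from exc

        def implied_vec_and_jac(theta):
            lam, phi, theta_d, taus, sigma = pm.matrices(theta)
            corr = np.array([sigma[i, j] for (i, j) in iu])
            tau_vec = (np.concatenate(taus) if taus else np.array([]))
            vec = np.concatenate([corr, tau_vec])
            return lam, phi, vec

        def residual_backprop(theta, wr):
            """Map weighted residual back to parameter gradient."""
            lam, phi, _, _, _ = pm.matrices(theta)
            G = np.zeros((pm.k, pm.k))
            for w, (i, j) in zip(wr[:n_corr], iu):
                G[i, j] += 0.5 * w
                G[j, i] += 0.5 * w
            g = pm.grad_from_gmat(G, lam, phi, include_theta=False)
            # thresholds enter the moment vector directly (identity block)
            g[pm.n_free - sum(pm.n_thresh):] = wr[n_corr:]
            return g

        def objective(theta):
            lam, phi, vec = implied_vec_and_jac(theta)
            r = s_vec - vec
            if estimator == "ULS":
                f = float(r @ r)
                wr = 2.0 * r
            elif estimator == "DWLS":
                f = float(np.sum(r * r * w_diag_inv))
                wr = 2.0 * r * w_diag_inv
            else:
                sol = np.linalg.solve(gamma_full, r)
                f = float(r @ sol)
                wr = 2.0 * sol
            return f, -residual_backprop(theta, wr)

    rng = np.random.default_rng(seed)
    best = None
    for attempt in range(max_restarts + 1):
        theta0 = (
            np.asarray(start, float)
            if (start is not None and attempt == 0)
            else pm.start(moments, rng, scale=0.0 if attempt == 0 else 0.3)
        )
        res = optimize.minimize(
            objective, theta0, jac=True, method="L-BFGS-B",
            bounds=pm.bounds,
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
        )
        ok = bool(res.success)
        if best is None or res.fun < best[0].fun:
            best = (res, ok)
        if ok:
            break
        logger.debug("restart %d after non-convergence", attempt + 1)
    res, converged = best
    theta_hat = res.x
    lam, phi, theta_d, taus, sigma = pm.matrices(theta_hat)
    F_min = max(float(res.fun), 0.0)
    if F_min >= _PENALTY / 2:
        converged = False
        warns.append("optimizer trapped in a non-positive-definite region")

    heywood = False
    if spec.data_kind == "continuous":
        floor = UNIQUENESS_FLOOR * pm.svar
        if np.any(theta_d <= floor * (1 + 1e-6)):
            heywood = True
    else:
        if np.any(theta_d <= UNIQUENESS_FLOOR * (1 + 1e-6)):
            heywood = True
    if heywood:
        warns.append("Heywood protection active: uniqueness at lower bound")
        logger.warning("Heywood protection active")

    mult = n if chi_multiplier == "N" else n - 1
    if df == 0:
        chi_square = 0.0
        p_value = 1.0
    else:
        chi_square = mult * F_min
        p_value = float(stats.chi2.sf(chi_square, df))
    loglik = None
    if estimator == "ML":
        sign, logdet_sigma = np.linalg.slogdet(sigma)
        if sign > 0:
            trace = float(np.trace(np.linalg.solve(sigma, S)))
            loglik = -0.5 * n * (
                pm.k * np.log(2 * np.pi) + logdet_sigma + trace
            )
    thresholds = None
    if spec.data_kind == "ordinal":
        thresholds = {
            ind: np.asarray(t, float)
            for ind, t in zip(spec.indicators, taus)
        }
    return FittedModel(
        spec=spec, template=build_template(spec), estimator=estimator,
        lam=lam, phi=phi, theta_diag=theta_d, thresholds=thresholds,
        implied=sigma, F_min=F_min, chi_square=float(chi_square), df=df,
        p_value=p_value, converged=converged, n_effective=n, loglik=loglik,
        heywood=heywood, warnings=warns, sample_matrix=S,
    )


def fit_baseline(
    spec: ModelSpec,
    moments: SampleMoments,
    estimator: Estimator = "ML",
    chi_multiplier: Literal["N", "N-1"] = "N",
) -> FittedModel:
    """Fit the independence (baseline) model that anchors CFI and TLI.

    Continuous metric: implied matrix is the diagonal of S, with the ML
    closed form ``F_B = sum(log s_ii) - log|S|``. Polychoric metric: all
    correlations zero with thresholds at their sample values, so the
    residual vector is the correlation vector itself. ``df_B = k(k-1)/2``.
    """
    _check_compat(estimator, moments)
    order = [moments.names.index(v) for v in spec.indicators]
    S = moments.matrix[np.ix_(order, order)]
    k = len(order)
    n = moments.n_effective
    mult = n if chi_multiplier == "N" else n - 1
    df_b = k * (k - 1) // 2
    loglik = None
    if estimator == "ML":
        sign, logdet_s = np.linalg.slogdet(S)
        if sign <= 0:
            raise EstimationError("sample covariance matrix is singular")
        F_b = float(np.sum(np.log(np.diag(S))) - logdet_s)
        implied = np.diag(np.diag(S)).astype(float)
        loglik = -0.5 * n * (
            k * np.log(2 * np.pi) + np.sum(np.log(np.diag(S))) + k
        )
    elif estimator == "GLS":
        # independence GLS: stationarity gives the linear system
        # (S^-1 o S^-1) d = diag(S^-1), o = Hadamard product
        B = np.linalg.inv(S)
        d = np.linalg.solve(B * B, np.diag(B))
        implied = np.diag(d)
        F_b = gls_discrepancy(S, implied)
    else:
        s_vec, iu, R = _moment_vector(moments, spec)
        gamma_diag, gamma_full = _reorder_gamma(moments, spec)
        n_corr = len(iu)
        r = np.zeros_like(s_vec)
        r[:n_corr] = s_vec[:n_corr]  # residuals: correlations vs zero
        if estimator == "ULS":
            F_b = float(r @ r)
        elif estimator == "DWLS":
            if gamma_diag is None:
                raise EstimationError("DWLS requires moment variances")
            F_b = float(np.sum(r * r / gamma_diag))
        else:
            if gamma_full is None:
                raise EstimationError("WLS requires full moment covariance")
            F_b = float(r @ np.linalg.solve(gamma_full, r))
        implied = np.eye(k)
    F_b = max(F_b, 0.0)
    chi_b = mult * F_b
    template = build_template(spec)
    return FittedModel(
        spec=spec, template=template, estimator=estimator,
        lam=np.zeros((k, spec.n_factors)), phi=np.eye(spec.n_factors),
        theta_diag=np.diag(implied).copy(), thresholds=None, implied=implied,
        F_min=F_b, chi_square=float(chi_b), df=df_b,
        p_value=float(stats.chi2.sf(chi_b, df_b)) if df_b > 0 else 1.0,
        converged=True, n_effective=n, loglik=loglik, sample_matrix=S,
    )
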