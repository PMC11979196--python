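"""Synthetic factor-model data with known population structure.

Generates multivariate-normal indicator data from a population
measurement model (``Sigma0 = Lambda Phi Lambda' + Theta``) and, for
ordered-categorical designs, discretizes the latent responses at fixed
thresholds. Two ready-made scenarios mirror the shapes of the package's
motivating applications: a 7-item one-factor scale rated by ~200
respondents, and a 14-item 4-category scale with a large sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import json
import numpy as np
import pandas as pd

from .moments import Dataset, dataset_from_frame

__all__ = [
    "PopulationModel",
    "implied_population_cov",
    "generate_continuous",
    "generate_ordinal",
    "inject_missing",
    "one_factor_model",
    "small_scale_scenario",
    "large_ordinal_scenario",
]


@dataclass
class PopulationModel:
    """Population measurement model driving the generator.

    ``loadings`` maps each factor to {indicator: loading};
    ``uniquenesses`` follow the indicator order implied by the loadings
    map. For ordinal designs, ``thresholds`` gives each indicator's
    ascending cut points on the latent-response scale.
    """

    loadings: dict[str, dict[str, float]]
    uniquenesses: np.ndarray
    factor_correlations: np.ndarray | None = None
    thresholds: dict[str, np.ndarray] | None = None
    n: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        self.uniquenesses = np.asarray(self.uniquenesses, float)
        if np.any(self.uniquenesses < 0):
            raise ValueError("uniquenesses must be >= 0")
        m = len(self.loadings)
        if self.factor_correlations is None:
            self.factor_correlations = np.eye(m)
        self.factor_correlations = np.asarray(self.factor_correlations, float)
        if self.factor_correlations.shape != (m, m):
            raise ValueError("factor_correlations shape mismatch")
        if self.thresholds is not None:
            for name, tau in self.thresholds.items():
                tau = np.asarray(tau, float)
                if np.any(np.diff(tau) <= 0):
                    raise ValueError(f"thresholds for {name!r} not ascending")
                self.thresholds[name] = tau

    @property
    def indicators(self) -> list[str]:
        out: list[str] = []
        for f in self.loadings:
            out.extend(self.loadings[f])
        return out

    @property
    def lambda_matrix(self) -> np.ndarray:
        inds = self.indicators
        lam = np.zeros((len(inds), len(self.loadings)))
        for fi, f in enumerate(self.loadings):
            for ind, val in self.loadings[f].items():
                lam[inds.index(ind), fi] = val
        return lam

    def model_syntax(self) -> str:
        return "\n".join(
            f"{f} =~ " + " + ".join(self.loadings[f]) for f in self.loadings
        )

    def to_json(self) -> str:
        payload = {
            "loadings": self.loadings,
            "uniquenesses": self.uniquenesses.tolist(),
            "factor_correlations": self.factor_correlations.tolist(),
            "thresholds": None if self.thresholds is None else {
                k: v.tolist() for k, v in self.thresholds.items()
            },
            "n": self.n,
            "seed": self.seed,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PopulationModel":
        d = json.loads(text)
        return cls(
            loadings=d["loadings"],
            uniquenesses=np.asarray(d["uniquenesses"], float),
            factor_correlations=np.asarray(d["factor_correlations"], float),
            thresholds=None if d["thresholds"] is None else {
                k: np.asarray(v, float) for k, v in d["thresholds"].items()
            },
            n=d["n"],
            seed=d["seed"],
        )


def implied_population_cov(model: PopulationModel) -> np.ndarray:
    """Population covariance ``Sigma0 = Lambda Phi Lambda' + Theta``."""
    lam = model.lambda_matrix
    sigma = lam @ model.factor_correlations @ lam.T + np.diag(
        model.uniquenesses
    )
    eig = np.linalg.eigvalsh(sigma)
    if eig.min() <= 0:
        raise ValueError(
            f"implied population covariance not positive-definite "
            f"(min eigenvalue {eig.min():.3e})"
        )
    return sigma


def _draw_latent(
    model: PopulationModel, rng: np.random.Generator
) -> np.ndarray:
    sigma = implied_population_cov(model)
    chol = np.linalg.cholesky(sigma)
    z = rng.standard_normal((model.n, sigma.shape[0]))
    return z @ chol.T


def generate_continuous(
    model: PopulationModel, seed: int | None = None
) -> Dataset:
    """Multivariate-normal indicator data with covariance ``Sigma0``."""
    rng = np.random.default_rng(model.seed if seed is None else seed)
    x = _draw_latent(model, rng)
    frame = pd.DataFrame(x, columns=model.indicators)
    return dataset_from_frame(frame)


def generate_ordinal(
    model: PopulationModel, seed: int | None = None
) -> Dataset:
    """Latent responses discretized at the model thresholds (categories 1..C)."""
    if model.thresholds is None:
        raise ValueError("ordinal generation requires thresholds")
    rng = np.random.default_rng(model.seed if seed is None else seed)
    x = _draw_latent(model, rng)
    out = np.empty_like(x)
    for j, ind in enumerate(model.indicators):
        tau = model.thresholds[ind]
        out[:, j] = np.searchsorted(tau, x[:, j]) + 1.0
    frame = pd.DataFrame(out, columns=model.indicators)
    return dataset_from_frame(frame)


def inject_missing(
    data: Dataset, rate: float, seed: int = 0
) -> pd.DataFrame:
    """Return the raw frame with MCAR missingness at the given cell rate.

    The result still carries NaN (not yet listwise-deleted); feed it to
    :func:`cgfiboot.moments.dataset_from_frame` or write it to CSV with
    ``na_rep="NA"`` to exercise the missing-data path.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    frame = data.values.copy()
    mask = rng.random(frame.shape) < rate
    frame = frame.mask(mask)
    return frame


def one_factor_model(
    k: int = 7,
    loading: float | Sequence[float] = 0.7,
    n: int = 200,
    seed: int = 0,
    thresholds: Sequence[float] | None = None,
    factor: str = "F1",
    prefix: str = "x",
) -> PopulationModel:
    """Convenience constructor for a standardized one-factor population."""
    lam = np.full(k, loading, float) if np.isscalar(loading) else np.asarray(
        loading, float
    )
    if lam.size != k:
        raise ValueError("loading vector length must equal k")
    names = [f"{prefix}{j + 1}" for j in range(k)]
    thr = None
    if thresholds is not None:
        thr = {name: np.asarray(thresholds, float) for name in names}
    return PopulationModel(
        loadings={factor: dict(zip(names, lam))},
        uniquenesses=1.0 - lam**2,
        thresholds=thr,
        n=n,
        seed=seed,
    )


def small_scale_scenario(seed: int = 0, n: int = 193) -> PopulationModel:
    """A 7-item one-factor scale at a small sample size.

    Mirrors the shape of a short principal-rated leadership scale:
    standardized loadings 0.7, unit indicator variances.
    """
    return one_factor_model(k=7, loading=0.7, n=n, seed=seed, prefix="q")


def large_ordinal_scenario(seed: int = 0, n: int = 4540) -> PopulationModel:
    """A 14-item, 4-category one-factor scale at a large sample size.

    Mirrors frequency-of-occurrence items ("never" ... "at least once a
    week"): right-skewed margins via thresholds (-0.25, 0.6, 1.2).
    """
    return one_factor_model(
        k=14, loading=0.65, n=n, seed=seed,
        thresholds=(-0.25, 0.6, 1.2), prefix="b",
    )
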