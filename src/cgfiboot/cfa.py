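"""Scikit-learn-style front end for confirmatory factor analysis fit
evaluation.

``CFA`` is a ``BaseEstimator``: construct it with a measurement-model
string and hyperparameters, call :meth:`fit` on case-by-indicator data,
then read the fitted attributes (``fit_indices_``, ``loadings_``, ...)
or call :meth:`bootstrap` for percentile confidence intervals of every
index. It composes with sklearn tooling (``get_params``/``set_params``,
``clone``).
"""

from __future__ import annotations

from typing import Literal

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .bootstrap import BootstrapResult, bootstrap_indices
from .estimator import fit as _fit
from .estimator import fit_baseline as _fit_baseline
from .indices import FitIndexSet, compute_fit_indices
from .model import ModelSpec, build_template, model_df, parse_model
from .moments import Dataset, compute_moments, dataset_from_frame

__all__ = ["CFA"]


class CFA(BaseEstimator):
    """Confirmatory factor analysis with a descriptive fit-index battery.

    Parameters
    ----------
    model : str
        Measurement model in ``Factor =~ ind1 + ind2 + ...`` syntax.
    estimator : {"ML", "GLS", "ULS", "DWLS", "WLS"}
        Discrepancy function. ML/GLS operate on the covariance matrix of
        continuous indicators; ULS/DWLS/WLS on the polychoric
        correlation matrix of ordered indicators.
    ordered : bool
        Treat indicators as ordered-categorical. The flag, not the data,
        decides the metric.
    identification : {"unit_factor_variance", "first_loading_fixed"}
        Factor scale-setting convention (fit-equivalent).
    chi_multiplier : {"N", "N-1"}
        Multiplier turning the minimized discrepancy into chi-square.
    cov_divisor : {"N", "N-1"}
        Divisor of the sample covariance (continuous data).
    random_state : int
        Seeds optimizer restarts (and nothing else during fit).

    Attributes
    ----------
    spec_ : ModelSpec
    moments_ : SampleMoments
    fitted_ : FittedModel
    baseline_ : FittedModel
    fit_indices_ : FitIndexSet
    loadings_ : pandas.Series  (parameter name -> estimate)
    uniquenesses_ : numpy.ndarray
    chi_square_, df_, p_value_, n_effective_, converged_ : scalars

    Examples
    --------
    >>> from cgfiboot import CFA, synthetic
    >>> pop = synthetic.small_scale_scenario(seed=1)
    >>> data = synthetic.generate_continuous(pop)
    >>> cfa = CFA(model=pop.model_syntax()).fit(data.values)
    >>> round(cfa.fit_indices_.cgfi, 3) >= round(cfa.fit_indices_.gfi, 3)
    True
    """

    def __init__(
        self,
        model: str = "",
        estimator: str = "ML",
        ordered: bool = False,
        n_categories: dict[str, int] | None = None,
        identification: str = "unit_factor_variance",
        chi_multiplier: Literal["N", "N-1"] = "N",
        cov_divisor: Literal["N", "N-1"] = "N",
        random_state: int = 0,
    ) -> None:
        self.model = model
        self.estimator = estimator
        self.ordered = ordered
        self.n_categories = n_categories
        self.identification = identification
        self.chi_multiplier = chi_multiplier
        self.cov_divisor = cov_divisor
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _build_spec(self, X: pd.DataFrame) -> ModelSpec:
        n_cats = self.n_categories
        if self.ordered and n_cats is None:
            n_cats = {
                c: int(X[c].dropna().nunique()) for c in X.columns
            }
        spec = parse_model(
            self.model,
            data_kind="ordinal" if self.ordered else "continuous",
            n_categories={k: n_cats[k] for k in n_cats} if n_cats else None,
            identification=self.identification,  # type: ignore[arg-type]
        )
        return spec

    def _as_frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X, float)
        # positional naming: indicators in model order
        tmp_spec = parse_model(self.model)
        if X.shape[1] != tmp_spec.k:
            raise ValueError(
                f"X has {X.shape[1]} columns but the model names "
                f"{tmp_spec.k} indicators"
            )
        return pd.DataFrame(X, columns=tmp_spec.indicators)

    def fit(self, X, y=None) -> "CFA":
        """Fit the measurement model to case-by-indicator data.

        ``X`` is a DataFrame whose columns include the model's
        indicators, or an array whose columns follow model order. NaN
        cells are handled by listwise deletion.
        """
        frame = self._as_frame(X)
        spec = self._build_spec(frame)
        data = dataset_from_frame(frame, spec.indicators)
        self.spec_ = self._build_spec(data.values)
        self.data_ = data
        self.template_ = build_template(self.spec_)
        self.moments_ = compute_moments(
            data, ordered=self.ordered, divisor=self.cov_divisor,
            compute_acov=self.estimator in ("DWLS", "WLS"),
        )
        self.fitted_ = _fit(
            self.spec_, self.moments_, estimator=self.estimator,
            seed=self.random_state, chi_multiplier=self.chi_multiplier,
        )
        self.baseline_ = _fit_baseline(
            self.spec_, self.moments_, estimator=self.estimator,
            chi_multiplier=self.chi_multiplier,
        )
        self.fit_indices_ = compute_fit_indices(self.fitted_, self.baseline_)
        self.loadings_ = pd.Series(self.fitted_.loadings_dict())
        self.uniquenesses_ = self.fitted_.theta_diag.copy()
        self.chi_square_ = self.fitted_.chi_square
        self.df_ = self.fitted_.df
        self.p_value_ = self.fitted_.p_value
        self.n_effective_ = self.fitted_.n_effective
        self.converged_ = self.fitted_.converged
        self.n_features_in_ = self.spec_.k
        return self

    def score(self, X, y=None) -> float:
        """Negative ML discrepancy of the fitted structure on new data.

        Higher is better; useful with sklearn model-selection helpers.
        """
        from .estimator import ml_discrepancy

        frame = self._as_frame(X)
        data = dataset_from_frame(frame, self.spec_.indicators)
        moments = compute_moments(
            data, ordered=self.ordered, divisor=self.cov_divisor,
            compute_acov=False,
        )
        order = [moments.names.index(v) for v in self.spec_.indicators]
        S = moments.matrix[np.ix_(order, order)]
        return -ml_discrepancy(S, self.fitted_.implied)

    def bootstrap(
        self, B: int = 1000, seed: int | None = None
    ) -> BootstrapResult:
        """Case-resampling bootstrap of the index battery on the fit data."""
        if not hasattr(self, "fitted_"):
            raise RuntimeError("call fit() before bootstrap()")
        if not self.fitted_.converged:
            raise RuntimeError(
                "original-sample fit did not converge; bootstrap aborted"
            )
        return bootstrap_indices(
            self.data_, self.spec_, estimator=self.estimator, B=B,
            seed=self.random_state if seed is None else seed,
            chi_multiplier=self.chi_multiplier,
            cov_divisor=self.cov_divisor,
        )

    @property
    def model_df_(self) -> int:
        return model_df(self.spec_)
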