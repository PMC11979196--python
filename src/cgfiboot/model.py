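"""Measurement-model specification, parameter templates and model df.

A model is written in the compact ``=~`` measurement dialect, one factor
per line::

    Leadership =~ q1 + q2 + q3 + q4 + q5 + q6 + q7

Only measurement statements are supported: regressions (``~``) and
residual covariances (``~~``) are rejected, as are cross-loadings.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Literal

__all__ = [
    "ModelSpec",
    "ParameterTemplate",
    "TemplateEntry",
    "ModelSyntaxError",
    "ModelValidationError",
    "parse_model",
    "serialize_model",
    "build_template",
    "model_df",
]

DataKind = Literal["continuous", "ordinal"]
Identification = Literal["unit_factor_variance", "first_loading_fixed"]

_NAME_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_.]*$")


class ModelSyntaxError(ValueError):
    """Raised when the model text cannot be parsed."""


class ModelValidationError(ValueError):
    """Raised when a parsed model violates a structural constraint."""


@dataclass(frozen=True)
class ModelSpec:
    """A confirmatory measurement model.

    Parameters
    ----------
    factors : list of str
        Latent factor names, in declaration order.
    loadings_pattern : dict
        Map factor name -> ordered list of indicator names.
    data_kind : {"continuous", "ordinal"}
        Whether indicators are treated as continuous (covariance metric)
        or ordered-categorical (latent-response / polychoric metric).
    n_categories : dict or None
        Map indicator -> number of categories (>= 2); required iff
        ``data_kind == "ordinal"``.
    identification : {"unit_factor_variance", "first_loading_fixed"}
        Scale-setting convention for each factor. The two are
        fit-equivalent; the default frees every loading and fixes factor
        variances at 1.
    """

    factors: list[str]
    loadings_pattern: dict[str, list[str]]
    data_kind: DataKind = "continuous"
    n_categories: dict[str, int] | None = None
    identification: Identification = "unit_factor_variance"

    def __post_init__(self) -> None:
        if not self.factors:
            raise ModelValidationError("model has no factors")
        if set(self.factors) != set(self.loadings_pattern):
            raise ModelValidationError("factors and loadings_pattern disagree")
        seen_global: dict[str, str] = {}
        for f in self.factors:
            inds = self.loadings_pattern[f]
            if not inds:
                raise ModelValidationError(f"factor {f!r} has no indicators")
            if len(set(inds)) != len(inds):
                raise ModelValidationError(
                    f"duplicate indicator within factor {f!r}"
                )
            for ind in inds:
                if ind in seen_global:
                    raise ModelValidationError(
                        f"cross-loading not supported: {ind!r} appears under "
                        f"both {seen_global[ind]!r} and {f!r}"
                    )
                seen_global[ind] = f
        if self.k < 2:
            raise ModelValidationError("model needs at least 2 indicators")
        if self.data_kind == "ordinal":
            if self.n_categories is None:
                raise ModelValidationError(
                    "n_categories is required for ordinal data"
                )
            missing = [i for i in self.indicators if i not in self.n_categories]
            if missing:
                raise ModelValidationError(
                    f"n_categories missing for indicators: {missing}"
                )
            bad = {i: c for i, c in self.n_categories.items() if c < 2}
            if bad:
                raise ModelValidationError(f"n_categories must be >= 2: {bad}")
        elif self.n_categories is not None:
            raise ModelValidationError(
                "n_categories only applies to ordinal data"
            )

    @property
    def indicators(self) -> list[str]:
        """All observed variables, in factor-then-declaration order."""
        out: list[str] = []
        for f in self.factors:
            out.extend(self.loadings_pattern[f])
        return out

    @property
    def k(self) -> int:
        """Number of observed variables."""
        return sum(len(v) for v in self.loadings_pattern.values())

    @property
    def n_factors(self) -> int:
        return len(self.factors)

    @property
    def total_thresholds(self) -> int:
        if self.data_kind != "ordinal":
            return 0
        assert self.n_categories is not None
        return sum(self.n_categories[i] - 1 for i in self.indicators)


@dataclass(frozen=True)
class TemplateEntry:
    name: str
    role: Literal[
        "loading", "factor_variance", "factor_covariance", "uniqueness",
        "threshold",
    ]
    free: bool
    value: float | None = None  # fixed value; None for free or derived


@dataclass(frozen=True)
class ParameterTemplate:
    """Ordered list of model parameters with free/fixed status."""

    entries: tuple[TemplateEntry, ...]
    p_free: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "p_free", sum(1 for e in self.entries if e.free)
        )
        if self.p_free < 1:
            raise ModelValidationError("model has no free parameters")

    def free_entries(self) -> list[TemplateEntry]:
        return [e for e in self.entries if e.free]


def parse_model(
    text: str,
    data_kind: DataKind = "continuous",
    n_categories: dict[str, int] | None = None,
    identification: Identification = "unit_factor_variance",
) -> ModelSpec:
    """Parse ``Factor =~ ind1 + ind2 + ...`` lines into a :class:`ModelSpec`.

    ``#`` starts a comment; blank lines are ignored. Raises
    :class:`ModelSyntaxError` naming the offending line on bad syntax.
    """
    if not text or not text.strip():
        raise ModelSyntaxError("empty model description")
    factors: list[str] = []
    pattern: dict[str, list[str]] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "~~" in line:
            raise ModelSyntaxError(
                f"line {lineno}: residual covariances ('~~') are not "
                f"supported: {raw.strip()!r}"
            )
        if "=~" not in line:
            raise ModelSyntaxError(
                f"line {lineno}: expected a measurement statement "
                f"'Factor =~ ind1 + ind2': {raw.strip()!r}"
            )
        lhs, rhs = line.split("=~", 1)
        factor = lhs.strip()
        if not _NAME_RE.match(factor):
            raise ModelSyntaxError(
                f"line {lineno}: invalid factor name {factor!r}"
            )
        inds = [tok.strip() for tok in rhs.split("+")]
        if any(not tok for tok in inds):
            raise ModelSyntaxError(
                f"line {lineno}: empty indicator in {raw.strip()!r}"
            )
        for tok in inds:
            if not _NAME_RE.match(tok):
                raise ModelSyntaxError(
                    f"line {lineno}: invalid indicator name {tok!r}"
                )
        if factor in pattern:
            raise ModelSyntaxError(
                f"line {lineno}: factor {factor!r} defined twice"
            )
        factors.append(factor)
        pattern[factor] = inds
    return ModelSpec(
        factors=factors,
        loadings_pattern=pattern,
        data_kind=data_kind,
        n_categories=n_categories,
        identification=identification,
    )


def serialize_model(spec: ModelSpec) -> str:
    """Render a ModelSpec back to model-syntax text (parse round-trips)."""
    return "\n".join(
        f"{f} =~ " + " + ".join(spec.loadings_pattern[f]) for f in spec.factors
    )


def build_template(spec: ModelSpec) -> ParameterTemplate:
    """Expand a ModelSpec into the explicit parameter list.

    Continuous data, unit-factor-variance identification: every loading
    and every uniqueness is free; factor variances fixed at 1; one free
    covariance per factor pair. Ordinal data use the delta
    parameterization: loadings, thresholds (C-1 per indicator) and
    factor covariances are free, while uniquenesses are derived so the
    implied latent-response variances equal 1.
    """
    entries: list[TemplateEntry] = []
    flf = spec.identification == "first_loading_fixed"
    for f in spec.factors:
        for j, ind in enumerate(spec.loadings_pattern[f]):
            if flf and j == 0:
                entries.append(
                    TemplateEntry(f"{f}=~{ind}", "loading", False, 1.0)
                )
            else:
                entries.append(TemplateEntry(f"{f}=~{ind}", "loading", True))
    for f in spec.factors:
        if flf:
            entries.append(TemplateEntry(f"var({f})", "factor_variance", True))
        else:
            entries.append(
                TemplateEntry(f"var({f})", "factor_variance", False, 1.0)
            )
    for a in range(spec.n_factors):
        for b in range(a + 1, spec.n_factors):
            fa, fb = spec.factors[a], spec.factors[b]
            entries.append(
                TemplateEntry(f"cov({fa},{fb})", "factor_covariance", True)
            )
    if spec.data_kind == "continuous":
        for ind in spec.indicators:
            entries.append(TemplateEntry(f"theta({ind})", "uniqueness", True))
    else:
        assert spec.n_categories is not None
        # delta parameterization: uniqueness derived, implied diagonal = 1
        for ind in spec.indicators:
            entries.append(
                TemplateEntry(f"theta({ind})", "uniqueness", False, None)
            )
        for ind in spec.indicators:
            for c in range(1, spec.n_categories[ind]):
                entries.append(
                    TemplateEntry(f"tau({ind},{c})", "threshold", True)
                )
    return ParameterTemplate(entries=tuple(entries))


def n_sample_moments(spec: ModelSpec) -> int:
    """Number of non-redundant observed moments the model is fitted to."""
    k = spec.k
    if spec.data_kind == "continuous":
        return k * (k + 1) // 2
    return k * (k - 1) // 2 + spec.total_thresholds


def model_df(spec: ModelSpec) -> int:
    """Test-model degrees of freedom: sample moments minus free parameters.

    Continuous: ``k(k+1)/2 - p``. Ordinal (polychoric metric):
    ``k(k-1)/2 + (total thresholds) - p``. Raises on df < 0.
    """
    p = build_template(spec).p_free
    df = n_sample_moments(spec) - p
    if df < 0:
        raise ModelValidationError(
            f"model is under-identified: {p} free parameters for "
            f"{n_sample_moments(spec)} sample moments (df = {df})"
        )
    return df
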