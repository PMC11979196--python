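"""Non-parametric case-resampling bootstrap of the fit-index battery.

Each replicate draws ``n_rows_raw`` cases with replacement from the raw
data, applies listwise deletion within the replicate, recomputes the
sample moments, refits the target and baseline models and evaluates all
fit indices. Replicates that fail (non-convergence, degenerate moments)
are dropped from the summaries but counted. Summaries are the mean,
sample standard deviation and the empirical 2.5/97.5 percentiles
(median-unbiased quantile definition) of each index's bootstrap
distribution.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .estimator import fit, fit_baseline
from .indices import INDEX_ORDER, compute_fit_indices
from .model import ModelSpec
from .moments import (
    DataError,
    Dataset,
    compute_moments,
    dataset_from_frame,
)

logger = logging.getLogger(__name__)

__all__ = [
    "BootstrapResult",
    "bootstrap_indices",
    "percentile_interval",
    "export_draws",
]


@dataclass
class BootstrapResult:
    """Per-replicate fit-index draws plus summary statistics."""

    draws: pd.DataFrame          # successes x indices
    n_requested: int
    n_success: int
    n_failed: int
    seed: int
    summary: pd.DataFrame        # indices x (mean, sd, q2.5, q97.5)
    failure_reasons: list[str] = field(default_factory=list)
    unstable: bool = False

    def summary_dict(self) -> dict[str, dict[str, float]]:
        return {
            idx: {c: float(self.summary.loc[idx, c]) for c in
                  self.summary.columns}
            for idx in self.summary.index
        }


def percentile_interval(
    draws: np.ndarray, lower: float = 0.025, upper: float = 0.975
) -> tuple[float, float]:
    """Empirical percentile interval, median-unbiased quantile definition."""
    x = np.asarray(draws, float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("need at least 2 finite draws")
    lo, hi = np.quantile(x, [lower, upper], method="median_unbiased")
    return float(lo), float(hi)


def _summarize(draws: pd.DataFrame) -> pd.DataFrame:
    rows = {}
    for col in draws.columns:
        x = draws[col].to_numpy(float)
        finite = x[np.isfinite(x)]
        if finite.size == x.size and finite.size >= 2:
            lo, hi = percentile_interval(x)
            rows[col] = {
                "mean": float(np.mean(x)),
                "sd": float(np.std(x, ddof=1)),
                "q2.5": lo,
                "q97.5": hi,
            }
        else:
            # an index absent (NaN) in any replicate is summarized as NaN,
            # mirroring the "AIC NA NaN" rendering for categorical fits
            rows[col] = {
                "mean": float(np.mean(x)), "sd": float(np.nan),
                "q2.5": float(np.nan), "q97.5": float(np.nan),
            }
    return pd.DataFrame(rows).T[["mean", "sd", "q2.5", "q97.5"]]


def bootstrap_indices(
    data: Dataset,
    spec: ModelSpec,
    estimator: str = "ML",
    B: int = 1000,
    seed: int = 0,
    chi_multiplier: Literal["N", "N-1"] = "N",
    cov_divisor: Literal["N", "N-1"] = "N",
    warm_start: np.ndarray | None = None,
) -> BootstrapResult:
    """Bootstrap the full index battery over ``B`` case resamples.

    The master seed spawns one independent substream per replicate, so
    results do not depend on execution order. Exactly ``B`` attempts
    are made; failures are excluded from summaries and counted. If more
    than half the replicates fail, the result is flagged unstable.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    raw = data.raw if data.raw is not None else data.values
    n_raw = len(raw)
    raw_values = raw.to_numpy(float)
    columns = list(raw.columns)
    streams = np.random.SeedSequence(seed).spawn(B)
    ordered = spec.data_kind == "ordinal"
    records: list[dict[str, float]] = []
    failures: list[str] = []
    for b in range(B):
        rng = np.random.default_rng(streams[b])
        idx = rng.integers(0, n_raw, size=n_raw)
        frame = pd.DataFrame(raw_values[idx], columns=columns)
        try:
            rep_data = dataset_from_frame(frame, spec.indicators)
            moments = compute_moments(
                rep_data, ordered=ordered, divisor=cov_divisor,
                compute_acov=estimator in ("DWLS", "WLS"),
            )
            fitted = fit(
                spec, moments, estimator=estimator, start=warm_start,
                seed=int(rng.integers(2**31)),
                chi_multiplier=chi_multiplier, max_restarts=2,
            )
            if not fitted.converged:
                raise RuntimeError("replicate fit did not converge")
            base = fit_baseline(
                spec, moments, estimator=estimator,
                chi_multiplier=chi_multiplier,
            )
            ix = compute_fit_indices(fitted, base)
            records.append(ix.as_dict())
        except (DataError, RuntimeError, np.linalg.LinAlgError) as exc:
            failures.append(f"replicate {b}: {exc}")
    n_success = len(records)
    if n_success == 0:
        raise RuntimeError("all bootstrap replicates failed")
    draws = pd.DataFrame.from_records(records, columns=INDEX_ORDER)
    draws.insert(0, "replicate_id", range(n_success))
    summary = _summarize(draws[INDEX_ORDER])
    unstable = n_success < 0.5 * B
    if unstable:
        logger.warning(
            "bootstrap unstable: only %d of %d replicates succeeded",
            n_success, B,
        )
    if failures:
        logger.info("%d bootstrap replicates failed", len(failures))
    return BootstrapResult(
        draws=draws,
        n_requested=B,
        n_success=n_success,
        n_failed=B - n_success,
        seed=seed,
        summary=summary,
        failure_reasons=failures,
        unstable=unstable,
    )


def export_draws(result: BootstrapResult, path) -> tuple[Path, Path]:
    """Write long-format draws CSV and a summary JSON alongside.

    The CSV has columns (replicate_id, index, value), one row per
    successful replicate and index; failed replicates appear only in
    the JSON metadata counts.
    """
    path = Path(path)
    long = result.draws.melt(
        id_vars="replicate_id", var_name="index", value_name="value"
    ).sort_values(["replicate_id", "index"], kind="stable")
    long.to_csv(path, index=False)
    meta = {
        "n_requested": result.n_requested,
        "n_success": result.n_success,
        "n_failed": result.n_failed,
        "seed": result.seed,
        "unstable": result.unstable,
        "summary": result.summary_dict(),
    }
    json_path = path.with_suffix(".summary.json")
    json_path.write_text(json.dumps(meta, indent=2))
    return path, json_path
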