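"""Run configuration, validation and report assembly.

A run reads a CSV and a model file, fits the model, bootstraps the fit
indices and writes: a report table (rows = the 12 measures, columns =
Original / Boot Mean / Boot SD / CI_2.5 / CI_97.5) as CSV and pretty
text, the long-format bootstrap draws, and a metadata JSON from which
the run is fully reproducible.
"""

from __future__ import annotations

import json
import logging
import math
import secrets
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bootstrap import BootstrapResult, bootstrap_indices, export_draws
from .estimator import (
    COVARIANCE_ESTIMATORS,
    ESTIMATORS,
    POLYCHORIC_ESTIMATORS,
    fit,
    fit_baseline,
)
from .indices import INDEX_ORDER, compute_fit_indices
from .model import parse_model
from .moments import compute_moments, load_csv

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ConfigError", "validate_config", "run",
           "REPORT_ROWS"]

REPORT_ROWS = {
    "chi_square": "Chi-Square",
    "df": "DF",
    "p_value": "P-Value",
    "cfi": "CFI",
    "tli": "TLI",
    "gfi": "GFI",
    "agfi": "AGFI",
    "rmsea": "RMSEA",
    "srmr": "SRMR",
    "aic": "AIC",
    "bic": "BIC",
    "cgfi": "CGFI",
}
# "CI_95" is accepted as an alias of the 97.5th-percentile column when
# parsing existing reports: the label names the interval, not the quantile.
REPORT_COLUMNS = ["Original", "Boot Mean", "Boot SD", "CI_2.5", "CI_97.5"]


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    data_path: str
    model_path: str
    estimator: str = "ML"
    ordered: bool = False
    n_boot: int = 1000
    seed: int | None = None
    missing_token: str = "NA"
    output_dir: str = "cgfiboot_out"
    chi_multiplier: str = "N"
    cov_divisor: str = "N"
    report_precision: int = 3
    identification: str = "unit_factor_variance"


def validate_config(config: RunConfig) -> RunConfig:
    """Check the configuration, collecting every violation, and fill defaults.

    An omitted seed is drawn from entropy and recorded, so any run can
    be reproduced from its metadata.
    """
    errors: list[str] = []
    if config.estimator not in ESTIMATORS:
        errors.append(
            f"unknown estimator {config.estimator!r}; choose from "
            f"{', '.join(ESTIMATORS)}"
        )
    elif config.ordered and config.estimator in COVARIANCE_ESTIMATORS:
        errors.append(
            f"estimator {config.estimator} requires continuous data; for "
            f"ordered data use one of {', '.join(POLYCHORIC_ESTIMATORS)}"
        )
    elif not config.ordered and config.estimator in POLYCHORIC_ESTIMATORS:
        errors.append(
            f"estimator {config.estimator} requires ordered data "
            f"(pass ordered=True); for continuous data use ML or GLS"
        )
    if config.n_boot < 0:
        errors.append(f"n_boot must be >= 0, got {config.n_boot}")
    if config.chi_multiplier not in ("N", "N-1"):
        errors.append(f"chi_multiplier must be 'N' or 'N-1'")
    if config.cov_divisor not in ("N", "N-1"):
        errors.append(f"cov_divisor must be 'N' or 'N-1'")
    if config.report_precision < 0:
        errors.append("report_precision must be >= 0")
    if config.identification not in (
        "unit_factor_variance", "first_loading_fixed"
    ):
        errors.append(f"unknown identification {config.identification!r}")
    if errors:
        raise ConfigError("; ".join(errors))
    if config.seed is None:
        config.seed = secrets.randbelow(2**31)
        logger.info("seed drawn from entropy: %d", config.seed)
    return config


def _fmt(value: float | None, precision: int) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "NA"
    return f"{value:.{precision}f}"


def _report_frame(
    original: dict[str, float],
    boot: BootstrapResult | None,
) -> pd.DataFrame:
    rows = {}
    for key, label in REPORT_ROWS.items():
        row = {"Original": original.get(key, math.nan)}
        if boot is not None and key in boot.summary.index:
            row["Boot Mean"] = boot.summary.loc[key, "mean"]
            row["Boot SD"] = boot.summary.loc[key, "sd"]
            row["CI_2.5"] = boot.summary.loc[key, "q2.5"]
            row["CI_97.5"] = boot.summary.loc[key, "q97.5"]
        else:
            row.update({c: math.nan for c in REPORT_COLUMNS[1:]})
        rows[label] = row
    return pd.DataFrame(rows).T[REPORT_COLUMNS]


def _pretty(report: pd.DataFrame, precision: int) -> str:
    width = max(len(i) for i in report.index) + 2
    cols = report.columns
    header = "Measure".ljust(width) + "".join(c.rjust(12) for c in cols)
    lines = [header, "-" * len(header)]
    for label, row in report.iterrows():
        cells = "".join(_fmt(row[c], precision).rjust(12) for c in cols)
        lines.append(label.ljust(width) + cells)
    return "\n".join(lines) + "\n"


def run(config: RunConfig) -> dict[str, Path]:
    """Execute a full fit + bootstrap run and write the report files."""
    config = validate_config(config)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model_text = Path(config.model_path).read_text()
    base_spec = parse_model(model_text, identification=config.identification)
    data = load_csv(
        config.data_path, indicators=base_spec.indicators,
        missing_token=config.missing_token,
    )
    n_cats = None
    if config.ordered:
        n_cats = {
            c: int(data.values[c].nunique()) for c in base_spec.indicators
        }
    spec = parse_model(
        model_text,
        data_kind="ordinal" if config.ordered else "continuous",
        n_categories=n_cats,
        identification=config.identification,
    )
    moments = compute_moments(
        data, ordered=config.ordered, divisor=config.cov_divisor,
        compute_acov=config.estimator in ("DWLS", "WLS"),
    )
    fitted = fit(
        spec, moments, estimator=config.estimator, seed=config.seed,
        chi_multiplier=config.chi_multiplier,
    )
    if not fitted.converged:
        raise RuntimeError(
            "original-sample fit did not converge; no report written"
        )
    baseline = fit_baseline(
        spec, moments, estimator=config.estimator,
        chi_multiplier=config.chi_multiplier,
    )
    index_set = compute_fit_indices(fitted, baseline)
    original = index_set.as_dict()

    boot = None
    paths: dict[str, Path] = {}
    if config.n_boot > 0:
        boot = bootstrap_indices(
            data, spec, estimator=config.estimator, B=config.n_boot,
            seed=config.seed, chi_multiplier=config.chi_multiplier,
            cov_divisor=config.cov_divisor,
        )
        draws_path, _ = export_draws(boot, out_dir / "bootstrap_draws.csv")
        paths["draws"] = draws_path
        paths["boot_summary"] = draws_path.with_suffix(".summary.json")

    report = _report_frame(original, boot)
    csv_path = out_dir / "report.csv"
    report.round(12).to_csv(csv_path, index_label="Measure", na_rep="NA")
    txt_path = out_dir / "report.txt"
    txt_path.write_text(_pretty(report, config.report_precision))
    paths["report_csv"] = csv_path
    paths["report_txt"] = txt_path

    warnings_log = list(index_set.notes)
    if moments.smoothed:
        warnings_log.append("polychoric matrix smoothed to nearest PSD")
    if boot is not None and boot.unstable:
        warnings_log.append(
            f"bootstrap unstable: {boot.n_failed} of {boot.n_requested} "
            f"replicates failed"
        )
    meta = {
        "data_path": str(config.data_path),
        "model_path": str(config.model_path),
        "model": model_text,
        "estimator": config.estimator,
        "ordered": config.ordered,
        "identification": config.identification,
        "seed": config.seed,
        "n_boot": config.n_boot,
        "missing_token": config.missing_token,
        "chi_multiplier": config.chi_multiplier,
        "cov_divisor": config.cov_divisor,
        "n_rows_raw": data.n_rows_raw,
        "n_rows_complete": data.n_rows_complete,
        "n_deleted": data.n_rows_raw - data.n_rows_complete,
        "converged": fitted.converged,
        "heywood": fitted.heywood,
        "n_boot_failed": 0 if boot is None else boot.n_failed,
        "warnings": warnings_log,
        "original_indices": {
            k: (None if math.isnan(v) else v) for k, v in original.items()
        },
    }
    meta_path = out_dir / "run_metadata.json"
    meta_path.write_text(json.dumps(meta, indent=2))
    paths["metadata"] = meta_path
    for w in warnings_log:
        logger.warning(w)
    return paths
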