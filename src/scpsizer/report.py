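"""Cross-method comparison arithmetic and study-style summary tables.

Covers the bookkeeping used to compare sizing/counting methods on the
same samples: dilution-consistency ratios (a dilution-corrected
quantity measured at two dilutions should give a ratio of 1),
replicate-error estimation (largest deviation from the mean of repeat
measurements), within-error agreement between two Rh estimates, and
emission of the four summary tables in delimited-text form.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RatioReport",
    "ReplicateError",
    "dilution_ratio",
    "round_display",
    "replicate_error",
    "agreement_within_error",
    "agreement_tally",
    "emit_summary_tables",
]


def round_display(x: float, decimals: int = 2) -> float:
    """Half-up rounding for display (so 0.885 -> 0.89, unlike banker's rounding)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class RatioReport:
    """Dilution-consistency ratio of one quantity for one sample and method."""

    sample: str
    method: str
    value_high_dilution: float
    value_low_dilution: float

    def __post_init__(self) -> None:
        if self.value_high_dilution <= 0 or self.value_low_dilution <= 0:
            raise ValueError("dilution-corrected values must be positive")

    @property
    def ratio(self) -> float:
        return self.value_high_dilution / self.value_low_dilution

    @property
    def ratio_display(self) -> float:
        return round_display(self.ratio)


def dilution_ratio(value_high: float, value_low: float) -> float:
    """Ratio of dilution-corrected quantities (higher dilution / lower dilution).

    Both inputs must already be corrected for their dilution factors;
    ideally the ratio is 1.  Use :func:`round_display` for the 2-decimal
    presentation.
    """
    if value_high <= 0 or value_low <= 0:
        raise ValueError("dilution-corrected values must be positive")
    return value_high / value_low


@dataclass(frozen=True)
class ReplicateError:
    """Mean of replicate measurements with the largest deviation as the error."""

    mean: float
    max_abs_deviation: float

    @property
    def percent(self) -> float:
        """100 x max deviation / mean; NaN (flagged undefined) when the mean is 0."""
        if self.mean == 0:
            return float("nan")
        return 100.0 * self.max_abs_deviation / self.mean


def replicate_error(values: Sequence[float]) -> ReplicateError:
    """Largest-difference-from-the-mean error of >= 2 replicate measurements."""
    arr = np.asarray(list(values), dtype=float)
    if len(arr) < 2:
        raise ValueError("replicate_error needs at least 2 measurements")
    if not np.all(np.isfinite(arr)):
        raise ValueError("replicate measurements must be finite")
    mean = float(arr.mean())
    return ReplicateError(mean=mean, max_abs_deviation=float(np.max(np.abs(arr - mean))))


def agreement_within_error(rh_a: float, err_a: float, rh_b: float, err_b: float) -> bool:
    """True when two estimates agree within their combined measurement errors."""
    if err_a < 0 or err_b < 0:
        raise ValueError("errors must be >= 0")
    return abs(rh_a - rh_b) <= err_a + err_b

def agreement_tally(pairs: Iterable[tuple[float, float, float, float]]) -> tuple[int, int]:
    """Count of (rh_a, err_a, rh_b, err_b) pairs agreeing within error, and total."""
    agree = total = 0
    for rh_a, err_a, rh_b, err_b in pairs:
        total += 1
        if agreement_within_error(rh_a, err_a, rh_b, err_b):
            agree += 1
    return agree, total


ILM_COLUMNS = ["sample", "dilution", "n_tracked", "mean_rh_nm", "sd_rh_nm", "density_per_ml", "flags"]
DLS_COLUMNS = ["sample", "rh1_nm", "frac1", "rh2_nm", "frac2", "rh3_nm", "frac3", "lp_flag"]
RATIO_COLUMNS = ["sample", "method", "value_high_dilution", "value_low_dilution", "ratio", "ratio_display"]
REPLICATE_COLUMNS = ["sample", "mean", "max_abs_deviation", "percent"]


def _as_frame(rows, columns: list[str]) -> pd.DataFrame:
    if rows is None:
        return pd.DataFrame(columns=columns)
    df = pd.DataFrame(rows)
    for col in columns:
        if col not in df.columns:
            df[col] = pd.NA
    return df[columns]


def emit_summary_tables(
    ilm_rows=None,
    dls_rows=None,
    ratio_rows=None,
    replicate_rows=None,
    out_dir: str | Path = ".",
    log_params: Optional[dict] = None,
) -> dict[str, Path]:
    """Write the four study-style summary tables as TSV files.

    Row collections may be DataFrames or lists of dicts keyed by the
    documented column names; missing cells are emitted empty.  Sample
    labels appearing in some tables but not others produce a warning
    (rows are still written with gaps).  Returns the written paths.
    Idempotent: re-emitting the same inputs reproduces identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames = {
        "ilm_results.tsv": _as_frame(ilm_rows, ILM_COLUMNS),
        "dls_peaks.tsv": _as_frame(dls_rows, DLS_COLUMNS),
        "dilution_ratios.tsv": _as_frame(ratio_rows, RATIO_COLUMNS),
        "replicate_errors.tsv": _as_frame(replicate_rows, REPLICATE_COLUMNS),
    }
    labelled = {
        name: set(df["sample"].dropna()) for name, df in frames.items() if len(df)
    }
    if len(labelled) > 1:
        universe = set.union(*labelled.values())
        for name, labels in labelled.items():
            missing = universe - labels
            if missing:
                warnings.warn(
                    f"{name}: no rows for sample(s) {sorted(missing)}", stacklevel=2
                )
    paths: dict[str, Path] = {}
    for name, df in frames.items():
        path = out / name
        df.to_csv(path, sep="\t", index=False, na_rep="")
        paths[name] = path
    if log_params is not None:
        with open(out / "run_log.jsonl", "a") as fh:
            fh.write(json.dumps(log_params, default=str) + "\n")
    return paths
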