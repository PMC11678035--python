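"""Readers and writers for the package's plain-text formats.

Trace CSV contract: header ``time_s,c_donor_mg_per_dm3,c_acceptor_mg_per_dm3``,
strictly increasing times, non-negative concentrations.  Sorption CSV:
``c0,c_eq_ads,c_leach,volume_dm3,mass_g``.  Absorbance series convert to
concentration through a linear (Beer-Lambert) calibration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .simulate import ConcentrationTrace, SorptionRecord

__all__ = [
    "TRACE_COLUMNS",
    "SORPTION_COLUMNS",
    "CalibrationLine",
    "absorbance_to_concentration",
    "read_trace",
    "write_trace",
    "read_sorption_records",
    "write_sorption_records",
]

logger = logging.getLogger("gelcell")

TRACE_COLUMNS = ["time_s", "c_donor_mg_per_dm3", "c_acceptor_mg_per_dm3"]
SORPTION_COLUMNS = ["c0", "c_eq_ads", "c_leach", "volume_dm3", "mass_g"]


@dataclass(frozen=True)
class CalibrationLine:
    """Linear absorbance calibration ``A = slope * c + intercept``."""

    slope: float
    intercept: float = 0.0
    wavelength_nm: float | None = None

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValidationError("CalibrationLine.slope must be > 0")


def absorbance_to_concentration(
    absorbance: Sequence[float], calibration: CalibrationLine
) -> tuple[np.ndarray, int]:
    """Invert the calibration, clipping negatives to zero.

    Returns the concentration series (mg/dm3) and the number of readings
    that had to be clipped.
    """
    a = np.asarray(absorbance, dtype=float)
    c = (a - calibration.intercept) / calibration.slope
    n_clipped = int(np.sum(c < 0))
    if n_clipped:
        logger.warning("calibration produced %d negative concentrations; clipped to 0", n_clipped)
    return np.clip(c, 0.0, None), n_clipped


def _read_csv(path: str | Path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"file not found: {path}")
    try:
        # round_trip: the default float parser is not correctly rounded
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValidationError(f"empty input file: {path}") from None
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}; expected header {columns}")
    if len(df) == 0:
        raise ValidationError(f"{path}: no data rows")
    return df


def read_trace(path: str | Path, label: str | None = None) -> ConcentrationTrace:
    """Read and validate a trace CSV; errors name the first offending row."""
    df = _read_csv(path, TRACE_COLUMNS)
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) > 1:
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if bad.size:
            # +2: one for the header, one for diff offset (1-based data rows)
            raise ValidationError(
                f"{path}: time_s not strictly increasing at data row {bad[0] + 2}"
            )
    for col in TRACE_COLUMNS:
        vals = df[col].to_numpy(dtype=float)
        neg = np.nonzero(vals < 0)[0]
        if neg.size:
            raise ValidationError(f"{path}: negative {col} at data row {neg[0] + 1}")
        nan = np.nonzero(~np.isfinite(vals))[0]
        if nan.size:
            raise ValidationError(f"{path}: non-finite {col} at data row {nan[0] + 1}")
    return ConcentrationTrace(
        t,
        df["c_donor_mg_per_dm3"].to_numpy(dtype=float),
        df["c_acceptor_mg_per_dm3"].to_numpy(dtype=float),
        {"label": label or str(path)},
    )


def write_trace(trace: ConcentrationTrace, path: str | Path) -> None:
    """Write a trace CSV at full float precision (lossless round trip)."""
    df = pd.DataFrame(
        {
            "time_s": trace.times,
            "c_donor_mg_per_dm3": trace.c_donor,
            "c_acceptor_mg_per_dm3": trace.c_acceptor,
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_sorption_records(path: str | Path) -> list[SorptionRecord]:
    """Read a sorption CSV; record invariants are enforced per row."""
    df = _read_csv(path, SORPTION_COLUMNS)
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                SorptionRecord(
                    c0=float(row["c0"]),
                    c_eq_ads=float(row["c_eq_ads"]),
                    c_leach=float(row["c_leach"]),
                    solution_volume=float(row["volume_dm3"]),
                    sorbent_mass=float(row["mass_g"]),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: data row {i + 1}: {exc}") from None
    return records


def write_sorption_records(records: Sequence[SorptionRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "c0": [r.c0 for r in records],
            "c_eq_ads": [r.c_eq_ads for r in records],
            "c_leach": [r.c_leach for r in records],
            "volume_dm3": [r.solution_volume for r in records],
            "mass_g": [r.sorbent_mass for r in records],
        }
    ).to_csv(path, index=False, float_format="%.17g")
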