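"""Curve-table file handling.

The on-disk format is plain CSV, one sample per row: ec_label,
concentration, replicate_id, f_0001 .. f_NNNN (fluorescence columns, 4-digit
zero-padded).  Floats are written with Python's shortest round-trip
representation, so a write -> read cycle is lossless at full float64
precision.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import CurveDataset, TimeGrid

__all__ = ["CurveTableError", "write_curve_table", "read_curve_table"]

META_COLUMNS = ("ec_label", "concentration", "replicate_id")


class CurveTableError(ValueError):
    """Malformed curve-table file."""


def _fluor_columns(n_points: int) -> list[str]:
    return [f"f_{i + 1:04d}" for i in range(n_points)]


def write_curve_table(dataset: CurveDataset, path) -> None:
    """Write one CSV row per sample; header row mandatory."""
    cols = _fluor_columns(dataset.time.n_points)
    frame = pd.DataFrame(dataset.values, columns=cols)
    for c in reversed(META_COLUMNS):
        frame.insert(0, c, dataset.meta[c].to_numpy())
    frame.to_csv(path, index=False)


def read_curve_table(path, dt: float = 0.010) -> CurveDataset:
    """Read and validate a curve table; malformed rows are reported by line.

    The number of fluorescence columns defines the grid length; ``dt`` sets
    the sample spacing (the file does not store times).
    """
    path = Path(path)
    try:
        # round_trip parsing keeps the read bit-identical to what was written
        frame = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise CurveTableError(f"{path}: cannot parse CSV: {exc}") from exc
    if list(frame.columns[:3]) != list(META_COLUMNS):
        raise CurveTableError(
            f"{path}: header must start with {', '.join(META_COLUMNS)}"
        )
    fluor_cols = list(frame.columns[3:])
    expected = _fluor_columns(len(fluor_cols))
    if fluor_cols != expected:
        raise CurveTableError(
            f"{path}: fluorescence columns must be {expected[0]}..{expected[-1]} "
            "in order"
        )
    if len(fluor_cols) < 2:
        raise CurveTableError(f"{path}: need at least 2 fluorescence columns")
    # pandas pads short rows with NaN; coerce catches non-numeric cells too
    values = frame[fluor_cols].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.flatnonzero(np.isnan(values).any(axis=1))
    if bad.size:
        line = int(bad[0]) + 2  # +1 header, +1 one-based
        raise CurveTableError(
            f"{path}: row at line {line} has missing or non-numeric fluorescence"
        )
    if np.any(values <= 0):
        bad = int(np.argmax(np.any(values <= 0, axis=1)))
        raise CurveTableError(
            f"{path}: row at line {bad + 2} has non-positive fluorescence"
        )
    conc = pd.to_numeric(frame["concentration"], errors="coerce").to_numpy()
    if np.isnan(conc).any():
        line = int(np.flatnonzero(np.isnan(conc))[0]) + 2
        raise CurveTableError(f"{path}: non-numeric concentration at line {line}")
    if (conc < 0).any():
        line = int(np.flatnonzero(conc < 0)[0]) + 2
        raise CurveTableError(f"{path}: negative concentration at line {line}")
    meta = pd.DataFrame(
        {
            "ec_label": frame["ec_label"].astype(str),
            "concentration": conc,
            "replicate_id": frame["replicate_id"].astype(int),
        }
    )
    grid = TimeGrid(n_points=len(fluor_cols), dt=dt)
    return CurveDataset(time=grid, values=values, meta=meta)
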