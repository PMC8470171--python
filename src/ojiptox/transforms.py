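"""Relative variable fluorescence normalizations of OJIP transients.

Vt rescales a transient between its origin Fo (first sample) and peak FP
(grid maximum): Vt = (Ft - Fo) / (FP - Fo).  WK uses the K-band sample
instead of the peak: WK = (Ft - Fo) / (FK - Fo).  The Delta forms subtract
the corresponding control transform, exposing treatment-induced shape change:
dVt = Vt,treatment - Vt,control and dWK likewise.  A per-sample min-max
rescaling to [0, 1] is provided for the concentration task, where absolute
intensity is removed so classifiers see shape only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import CurveDataset, InductionCurve, TimeGrid

__all__ = [
    "DegenerateCurveError",
    "NormalizedCurve",
    "fo_fp",
    "vt",
    "delta_vt",
    "wk",
    "delta_wk",
    "minmax_normalize",
    "vt_matrix",
    "wk_matrix",
    "minmax_matrix",
    "control_mean_vt",
]

# Default K-band index: the second grid sample (20 ms on the default grid).
# The K band is conventionally at ~300 us, which precedes a 10 ms-spaced
# grid entirely; the earliest post-origin sample is the closest available.
DEFAULT_K_INDEX = 1


class DegenerateCurveError(ValueError):
    """Flat or otherwise non-normalizable transient."""


@dataclass(frozen=True)
class NormalizedCurve:
    """A transformed transient; metadata travels with the values."""

    values: np.ndarray
    kind: str  # one of {"Vt", "dVt", "WK", "dWK", "minmax"}
    time: TimeGrid
    ec_label: str = "control"
    concentration: float = 0.0
    replicate_id: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


def _values(curve) -> np.ndarray:
    if isinstance(curve, InductionCurve):
        return curve.fluorescence
    if isinstance(curve, NormalizedCurve):
        return curve.values
    return np.asarray(curve, dtype=float)


def _meta(curve) -> dict:
    if isinstance(curve, (InductionCurve, NormalizedCurve)):
        return {
            "time": curve.time,
            "ec_label": curve.ec_label,
            "concentration": curve.concentration,
            "replicate_id": curve.replicate_id,
        }
    return {"time": TimeGrid(n_points=len(_values(curve)))}


def fo_fp(curve) -> tuple[float, float]:
    """Origin and peak fluorescence: Fo = first sample, FP = grid maximum."""
    f = _values(curve)
    fo = float(f[0])
    fp = float(np.max(f))
    if fp <= fo:
        raise DegenerateCurveError("flat transient: FP <= Fo, Vt undefined")
    return fo, fp


def vt(curve) -> NormalizedCurve:
    """Relative variable fluorescence Vt = (Ft - Fo) / (FP - Fo).

    Maps the origin sample to 0 and the peak sample to 1; invariant under
    positive affine transforms of the raw fluorescence.
    """
    f = _values(curve)
    fo, fp = fo_fp(curve)
    return NormalizedCurve(values=(f - fo) / (fp - fo), kind="Vt", **_meta(curve))


def _check_pair(a: NormalizedCurve, b: NormalizedCurve, kind: str) -> None:
    if a.kind != kind or b.kind != kind:
        raise ValueError(f"both inputs must be {kind} curves, got {a.kind}/{b.kind}")
    if a.values.shape != b.values.shape:
        raise ValueError(
            f"length mismatch: {a.values.shape} vs {b.values.shape}"
        )


def delta_vt(treatment: NormalizedCurve, control: NormalizedCurve) -> NormalizedCurve:
    """dVt = Vt,treatment - Vt,control, element-wise."""
    _check_pair(treatment, control, "Vt")
    return NormalizedCurve(
        values=treatment.values - control.values,
        kind="dVt",
        time=treatment.time,
        ec_label=treatment.ec_label,
        concentration=treatment.concentration,
        replicate_id=treatment.replicate_id,
    )


def wk(curve, k_index: int = DEFAULT_K_INDEX) -> NormalizedCurve:
    """WK = (Ft - Fo) / (FK - Fo) with FK the sample at ``k_index``."""
    f = _values(curve)
    if not 0 <= k_index < len(f):
        raise ValueError(f"k_index {k_index} outside grid of {len(f)} points")
    fo = float(f[0])
    fk = float(f[k_index])
    if fk <= fo:
        raise DegenerateCurveError("F at the K index does not exceed Fo")
    return NormalizedCurve(values=(f - fo) / (fk - fo), kind="WK", **_meta(curve))


def delta_wk(treatment: NormalizedCurve, control: NormalizedCurve) -> NormalizedCurve:
    """dWK = WK,treatment - WK,control, element-wise."""
    _check_pair(treatment, control, "WK")
    return NormalizedCurve(
        values=treatment.values - control.values,
        kind="dWK",
        time=treatment.time,
        ec_label=treatment.ec_label,
        concentration=treatment.concentration,
        replicate_id=treatment.replicate_id,
    )


def minmax_normalize(curve) -> NormalizedCurve:
    """Per-sample min-max rescaling to [0, 1] exactly."""
    f = _values(curve)
    lo, hi = float(np.min(f)), float(np.max(f))
    if hi <= lo:
        raise DegenerateCurveError("flat transient: min-max normalization undefined")
    return NormalizedCurve(values=(f - lo) / (hi - lo), kind="minmax", **_meta(curve))


# ---------------------------------------------------------------------------
# Matrix forms, used by the pipeline on whole datasets.
# ---------------------------------------------------------------------------

def vt_matrix(values: np.ndarray) -> np.ndarray:
    """Row-wise Vt of a (n_samples, n_points) matrix."""
    values = np.asarray(values, dtype=float)
    fo = values[:, [0]]
    fp = values.max(axis=1, keepdims=True)
    span = fp - fo
    if np.any(span <= 0):
        bad = int(np.argmax(span.ravel() <= 0))
        raise DegenerateCurveError(f"flat transient at row {bad}")
    return (values - fo) / span


def wk_matrix(values: np.ndarray, k_index: int = DEFAULT_K_INDEX) -> np.ndarray:
    """Row-wise WK of a matrix."""
    values = np.asarray(values, dtype=float)
    fo = values[:, [0]]
    fk = values[:, [k_index]]
    span = fk - fo
    if np.any(span <= 0):
        bad = int(np.argmax(span.ravel() <= 0))
        raise DegenerateCurveError(f"F at K index <= Fo at row {bad}")
    return (values - fo) / span


def minmax_matrix(values: np.ndarray) -> np.ndarray:
    """Row-wise min-max rescaling of a matrix to [0, 1]."""
    values = np.asarray(values, dtype=float)
    lo = values.min(axis=1, keepdims=True)
    hi = values.max(axis=1, keepdims=True)
    span = hi - lo
    if np.any(span <= 0):
        bad = int(np.argmax(span.ravel() <= 0))
        raise DegenerateCurveError(f"flat transient at row {bad}")
    return (values - lo) / span


def control_mean_vt(
    dataset: CurveDataset, indices: np.ndarray | None = None
) -> pd.DataFrame:
    """Per-EC mean Vt of the concentration-0 replicates.

    The control reference used for dVt/dWK; ``indices`` restricts the
    averaging pool (pass the training split to avoid test leakage).  Returns
    a DataFrame indexed by ec_label whose rows are mean Vt curves.
    """
    sub = dataset if indices is None else dataset.subset(indices)
    mask = sub.meta["concentration"].to_numpy() == 0.0
    if not mask.any():
        raise ValueError("no concentration-0 replicates in the reference pool")
    ctrl_vt = vt_matrix(sub.values[mask])
    labels = sub.meta.loc[mask, "ec_label"].to_numpy()
    frame = pd.DataFrame(ctrl_vt)
    frame["ec_label"] = labels
    return frame.groupby("ec_label").mean()
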