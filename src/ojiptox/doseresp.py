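"""Growth inhibition and IC50 summaries from cell-density endpoints.

Endpoint cell densities of exposed cultures are compared with their control:
growth inhibition (%) is 100 * (treatment - control) / control, negative when
growth is inhibited.  The half-maximal inhibitory concentration (IC50) is
estimated by least-squares fit of a two-parameter log-logistic curve to the
inhibition magnitude:

    M(d) = 100 * d^h / (d^h + IC50^h)

with IC50 the dose at which the fitted magnitude crosses 50% and h the Hill
slope.  The upper asymptote is fixed at 100% (complete inhibition).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["DoseResponseSeries", "IC50Fit", "growth_inhibition", "fit_ic50",
           "interpolate_ic50"]


def growth_inhibition(density_treatment, density_control):
    """Percent change in endpoint cell density versus control.

    Negative values indicate growth inhibition (treatment below control).
    Accepts scalars or arrays; densities must be positive.
    """
    t = np.asarray(density_treatment, dtype=float)
    c = np.asarray(density_control, dtype=float)
    if np.any(t <= 0) or np.any(c <= 0):
        raise ValueError("cell densities must be positive")
    out = 100.0 * (t - c) / c
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class DoseResponseSeries:
    """One EC's exposure trial set: doses with their inhibition percentages."""

    ec_label: str
    concentrations: tuple[float, ...]
    inhibition: tuple[float, ...]  # percent; negative = growth inhibition

    def __post_init__(self) -> None:
        c = tuple(float(x) for x in self.concentrations)
        i = tuple(float(x) for x in self.inhibition)
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "inhibition", i)
        if len(c) != len(i):
            raise ValueError("concentrations and inhibition must align")
        if any(b <= a for a, b in zip(c, c[1:])):
            raise ValueError("concentrations must be strictly increasing")
        if any(x < 0 for x in c):
            raise ValueError("concentrations must be >= 0")

    @classmethod
    def from_densities(
        cls, ec_label, concentrations, density_treatment, density_control
    ) -> "DoseResponseSeries":
        inh = growth_inhibition(density_treatment, density_control)
        return cls(ec_label, tuple(concentrations), tuple(np.atleast_1d(inh)))


@dataclass(frozen=True)
class IC50Fit:
    ic50: float
    hill: float
    converged: bool
    extrapolated: bool
    residual_rms: float


def _loglogistic_magnitude(d, ic50, hill):
    d = np.asarray(d, dtype=float)
    out = np.zeros_like(d)
    pos = d > 0
    r = (d[pos] / ic50) ** hill
    out[pos] = 100.0 * r / (1.0 + r)
    return out


def fit_ic50(series: DoseResponseSeries, p0: tuple[float, float] | None = None) -> IC50Fit:
    """Least-squares two-parameter log-logistic fit of inhibition magnitude.

    Requires at least 3 non-control doses with non-constant inhibition.  The
    extrapolated flag is set when the fitted magnitude stays below 50% up to
    10x the largest tested dose, i.e. the IC50 lies outside the supported
    dose range.
    """
    conc = np.asarray(series.concentrations, dtype=float)
    inh = np.asarray(series.inhibition, dtype=float)
    pos = conc > 0
    if pos.sum() < 3:
        raise ValueError("need at least 3 non-control doses")
    d = conc[pos]
    m = -inh[pos]  # magnitude: positive = inhibition
    if np.allclose(m, m[0]):
        raise ValueError("inhibition magnitudes are all equal; IC50 undefined")
    if p0 is None:
        # start at the dose whose magnitude is closest to 50%
        ic0 = float(d[np.argmin(np.abs(m - 50.0))])
        p0 = (max(ic0, 1e-6), 1.5)
    try:
        popt, _ = curve_fit(
            _loglogistic_magnitude, d, m, p0=p0,
            bounds=([1e-9, 1e-3], [np.inf, 50.0]), maxfev=20_000,
        )
        converged = True
    except RuntimeError:
        popt = p0
        converged = False
    ic50, hill = float(popt[0]), float(popt[1])
    resid = m - _loglogistic_magnitude(d, ic50, hill)
    extrapolated = bool(_loglogistic_magnitude(10.0 * d.max(), ic50, hill) < 50.0)
    return IC50Fit(
        ic50=ic50,
        hill=hill,
        converged=converged,
        extrapolated=extrapolated,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def interpolate_ic50(series: DoseResponseSeries) -> float:
    """Model-free fallback: log-linear interpolation of the 50% crossing.

    Requires two tested doses whose inhibition magnitudes bracket 50%.
    """
    conc = np.asarray(series.concentrations, dtype=float)
    inh = np.asarray(series.inhibition, dtype=float)
    pos = conc > 0
    d, m = conc[pos], -inh[pos]
    below = np.flatnonzero(m < 50.0)
    above = np.flatnonzero(m >= 50.0)
    if below.size == 0 or above.size == 0:
        raise ValueError("no pair of doses brackets 50% inhibition")
    i = below[m[below].argmax()]
    j = above[m[above].argmin()]
    ld = np.log(d[[i, j]])
    frac = (50.0 - m[i]) / (m[j] - m[i])
    return float(np.exp(ld[0] + frac * (ld[1] - ld[0])))
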