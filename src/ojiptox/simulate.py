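"""Synthetic OJIP chlorophyll-a fluorescence transients with contaminant structure.

A dark-adapted phototroph exposed to saturating light shows the Kautsky fast
fluorescence rise: from the origin level Fo through the J and I inflections up
to the peak FP (= FM).  This module emulates that transient with a parametric
curve — a basal level plus three logistic steps in log-time — and derives a
labelled dataset in which each emerging contaminant (EC) perturbs the curve
parameters in a characteristic direction, scaled by a Hill dose-effect at the
applied concentration.  The default roster reproduces the design of a 13-EC
exposure trial on the marine diatom *Phaeodactylum tricornutum*: per EC, a
dose list including the control (0 µg/L), 30 replicates per dose, 1950
samples in total, each a 458-point transient sampled every 10 ms.

The model is a phenomenological stand-in for measured curves, not a
photosystem-II kinetic model; see the methods note for what it does and does
not emulate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "TimeGrid",
    "InductionCurve",
    "CurveDataset",
    "ControlTemplate",
    "ContaminantProfile",
    "DatasetConfig",
    "control_curve",
    "dose_effect",
    "generate_curve",
    "generate_dataset",
    "table1_profiles",
    "well_separated_profiles",
    "well_separated_config",
    "scaled_profiles",
    "curve_space_gain",
    "TABLE1_CONCENTRATIONS",
    "TABLE2_IC50",
]


class SimulationError(ValueError):
    """Invalid simulator configuration or parameter set."""


@dataclass(frozen=True)
class TimeGrid:
    """Uniform acquisition grid: t_i = (i+1)*dt, i = 0..n_points-1.

    Defaults follow the instrument protocol being emulated: 458 fluorescence
    readings at 10 ms spacing (first sample at 10 ms).
    """

    n_points: int = 458
    dt: float = 0.010

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise SimulationError(f"n_points must be >= 2, got {self.n_points}")
        if not self.dt > 0:
            raise SimulationError(f"dt must be > 0, got {self.dt}")

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, strictly increasing."""
        return (np.arange(self.n_points) + 1.0) * self.dt

    @property
    def t_max(self) -> float:
        return self.n_points * self.dt


@dataclass(frozen=True)
class InductionCurve:
    """One sample: a fluorescence transient plus its exposure metadata."""

    time: TimeGrid
    fluorescence: np.ndarray
    ec_label: str = "control"
    concentration: float = 0.0
    replicate_id: int = 0

    def __post_init__(self) -> None:
        f = np.asarray(self.fluorescence, dtype=float)
        object.__setattr__(self, "fluorescence", f)
        if f.ndim != 1 or f.shape[0] != self.time.n_points:
            raise SimulationError(
                f"fluorescence length {f.shape} does not match grid "
                f"({self.time.n_points} points)"
            )
        if not np.all(f > 0):
            raise SimulationError("fluorescence values must be positive")
        if self.concentration < 0:
            raise SimulationError("concentration must be >= 0")


@dataclass
class CurveDataset:
    """A labelled collection of transients stored as a dense matrix.

    ``values`` has one row per sample (n_samples x n_points); ``meta`` carries
    the columns ec_label, concentration, replicate_id aligned with the rows.
    """

    time: TimeGrid
    values: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != self.time.n_points:
            raise SimulationError("values must be (n_samples, n_points)")
        if len(self.meta) != self.values.shape[0]:
            raise SimulationError("meta rows must align with value rows")
        required = {"ec_label", "concentration", "replicate_id"}
        missing = required - set(self.meta.columns)
        if missing:
            raise SimulationError(f"meta missing columns: {sorted(missing)}")
        self.meta = self.meta.reset_index(drop=True)

    def __len__(self) -> int:
        return self.values.shape[0]

    def curve(self, i: int) -> InductionCurve:
        row = self.meta.iloc[i]
        return InductionCurve(
            time=self.time,
            fluorescence=self.values[i],
            ec_label=str(row["ec_label"]),
            concentration=float(row["concentration"]),
            replicate_id=int(row["replicate_id"]),
        )

    def subset(self, indices) -> "CurveDataset":
        indices = np.asarray(indices)
        return CurveDataset(
            time=self.time,
            values=self.values[indices],
            meta=self.meta.iloc[indices].reset_index(drop=True),
        )

    # --- label views -----------------------------------------------------
    def contaminant_labels(self) -> np.ndarray:
        """Task-1 view: the EC code of each sample, dose pooled per class."""
        return self.meta["ec_label"].to_numpy(dtype=object)

    def concentration_labels(self, ec_label: str) -> tuple[np.ndarray, np.ndarray]:
        """Task-2 view for one EC: (row indices, concentration class labels)."""
        mask = (self.meta["ec_label"] == ec_label).to_numpy()
        if not mask.any():
            raise SimulationError(f"no samples for ec_label {ec_label!r}")
        idx = np.flatnonzero(mask)
        labels = self.meta.loc[mask, "concentration"].to_numpy(dtype=float)
        return idx, labels


# Template parameter order used by perturbation directions.
PARAM_NAMES = ("f0", "A_J", "A_I", "A_P", "tau_J", "tau_I", "tau_P")


@dataclass(frozen=True)
class ControlTemplate:
    """Noise-free Kautsky stand-in: F(t) = f0 * (1 + sum_s A_s * sigma((log10 t - log10 tau_s)/w_s)).

    Amplitudes are dimensionless step heights relative to the basal level f0;
    step times tau (seconds) locate the J, I and P rises; widths are in
    log10-seconds.  Defaults give FP/Fo ~ 4, i.e. Fv/Fm ~ 0.75, typical of a
    healthy diatom culture.
    """

    f0: float = 1200.0
    amplitudes: tuple[float, float, float] = (1.5, 1.0, 0.5)
    step_times: tuple[float, float, float] = (0.03, 0.3, 1.5)
    step_widths: tuple[float, float, float] = (0.28, 0.25, 0.22)

    def __post_init__(self) -> None:
        if not self.f0 > 0:
            raise SimulationError("f0 must be > 0")
        if len(self.amplitudes) != 3 or any(a <= 0 for a in self.amplitudes):
            raise SimulationError("amplitudes must be three positive values")
        tj, ti, tp = self.step_times
        if not (0 < tj < ti < tp):
            raise SimulationError("step times must satisfy 0 < tau_J < tau_I < tau_P")
        if any(w <= 0 for w in self.step_widths):
            raise SimulationError("step widths must be > 0")

    def as_vector(self) -> np.ndarray:
        return np.array([self.f0, *self.amplitudes, *self.step_times], dtype=float)

    @staticmethod
    def from_vector(v: np.ndarray, widths: tuple[float, float, float]) -> "ControlTemplate":
        return ControlTemplate(
            f0=float(v[0]),
            amplitudes=(float(v[1]), float(v[2]), float(v[3])),
            step_times=(float(v[4]), float(v[5]), float(v[6])),
            step_widths=widths,
        )


def control_curve(
    template: ControlTemplate | None = None,
    grid: TimeGrid | None = None,
) -> InductionCurve:
    """Evaluate the noise-free control transient on ``grid``.

    The curve is a nondecreasing sum of logistic steps in log-time, bounded by
    f0 below (asymptotically) and f0*(1 + A_J + A_I + A_P) above.
    """
    template = template if template is not None else ControlTemplate()
    grid = grid if grid is not None else TimeGrid()
    for tau in template.step_times:
        if not (0 < tau <= grid.t_max):
            raise SimulationError(
                f"step time {tau} s outside the sampled window (0, {grid.t_max}]"
            )
    t = grid.times
    log_t = np.log10(t)
    f = np.ones_like(t)
    for a, tau, w in zip(template.amplitudes, template.step_times, template.step_widths):
        f = f + a * expit((log_t - math.log10(tau)) / w)
    return InductionCurve(
        time=grid,
        fluorescence=template.f0 * f,
        ec_label="control",
        concentration=0.0,
        replicate_id=0,
    )


def dose_effect(concentration: float, ec50: float, hill: float) -> float:
    """Hill saturation e(d) = d^h / (d^h + ec50^h), in [0, 1).

    e(0) = 0, e(ec50) = 1/2, strictly increasing in dose.
    """
    if ec50 <= 0:
        raise SimulationError("ec50 must be > 0")
    if hill <= 0:
        raise SimulationError("hill must be > 0")
    if concentration < 0:
        raise SimulationError("concentration must be >= 0")
    if concentration == 0:
        return 0.0
    # log-space ratio form is robust to large dose/ec50 ratios
    r = (concentration / ec50) ** hill
    return float(r / (1.0 + r))


@dataclass(frozen=True)
class ContaminantProfile:
    """How one EC deforms the control transient.

    ``direction`` holds signed relative effects on (f0, A_J, A_I, A_P, tau_J,
    tau_I, tau_P), applied in proportion to the Hill dose effect;
    ``batch_direction`` is a dose-independent offset emulating trial-set batch
    variability (each EC's exposure set is a separate culture batch), applied
    to every sample of the EC including its controls.
    """

    ec_label: str
    direction: np.ndarray
    ec50: float
    concentrations: tuple[float, ...]
    hill: float = 1.5
    batch_direction: np.ndarray = field(default_factory=lambda: np.zeros(len(PARAM_NAMES)))

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        b = np.asarray(self.batch_direction, dtype=float)
        object.__setattr__(self, "direction", d)
        object.__setattr__(self, "batch_direction", b)
        if d.shape != (len(PARAM_NAMES),) or b.shape != (len(PARAM_NAMES),):
            raise SimulationError(
                f"direction vectors must have shape ({len(PARAM_NAMES)},)"
            )
        if np.max(np.abs(d) + np.abs(b)) >= 1.0:
            raise SimulationError(
                "direction too large: perturbed parameters could become non-positive"
            )
        c = tuple(float(x) for x in self.concentrations)
        object.__setattr__(self, "concentrations", c)
        if len(c) < 1 or any(b >= a for a, b in zip(c[1:], c[:-1])):
            raise SimulationError("concentrations must be strictly increasing")
        if c[0] != 0.0:
            raise SimulationError("first concentration must be 0 (control)")
        if self.ec50 <= 0 or self.hill <= 0:
            raise SimulationError("ec50 and hill must be > 0")


def perturbed_template(
    profile: ContaminantProfile,
    template: ControlTemplate,
    concentration: float,
) -> ControlTemplate:
    """Shift template parameters by batch + dose-scaled relative effects."""
    e = dose_effect(concentration, profile.ec50, profile.hill)
    shift = profile.batch_direction + profile.direction * e
    v = template.as_vector() * (1.0 + shift)
    if np.any(v[:4] <= 0):
        raise SimulationError(
            f"perturbation for {profile.ec_label!r} at {concentration} ug/L "
            "drives an amplitude non-positive"
        )
    if not (0 < v[4] < v[5] < v[6]):
        raise SimulationError(
            f"perturbation for {profile.ec_label!r} breaks step-time ordering"
        )
    return ControlTemplate.from_vector(v, template.step_widths)


def generate_curve(
    profile: ContaminantProfile,
    template: ControlTemplate,
    grid: TimeGrid,
    concentration: float,
    rng_seed,
    noise_cv: float = 0.02,
    rep_cv: float = 0.0,
    replicate_id: int = 0,
) -> InductionCurve:
    """One replicate transient: perturbed template + replicate variability + noise.

    Two noise sources, both multiplicative because fluorescence is positive
    and variability scales with signal: ``rep_cv`` jitters the template
    parameters once per replicate (independent cultures differ smoothly in
    their whole transient, not pointwise), and ``noise_cv`` applies
    mean-preserving lognormal measurement noise per point.  Deterministic
    given ``rng_seed`` (an int or ``numpy.random.SeedSequence``).
    """
    if concentration not in profile.concentrations:
        raise SimulationError(
            f"{concentration} not in the dose list of {profile.ec_label!r}"
        )
    if noise_cv < 0 or rep_cv < 0:
        raise SimulationError("noise_cv and rep_cv must be >= 0")
    rng = np.random.default_rng(rng_seed) if (noise_cv > 0 or rep_cv > 0) else None
    tpl = perturbed_template(profile, template, concentration)
    if rep_cv > 0:
        jitter = rng.normal(0.0, rep_cv, size=len(PARAM_NAMES))
        v = tpl.as_vector() * (1.0 + jitter)
        if np.any(v[:4] <= 0) or not (0 < v[4] < v[5] < v[6]):
            raise SimulationError(
                "replicate jitter produced an invalid template; lower rep_cv"
            )
        tpl = ControlTemplate.from_vector(v, tpl.step_widths)
    clean = control_curve(tpl, grid).fluorescence
    if noise_cv > 0:
        sigma = math.sqrt(math.log1p(noise_cv**2))
        factors = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=clean.shape)
        clean = clean * factors
    return InductionCurve(
        time=grid,
        fluorescence=clean,
        ec_label=profile.ec_label,
        concentration=concentration,
        replicate_id=replicate_id,
    )


@dataclass(frozen=True)
class DatasetConfig:
    """Full factorial design: every profile x dose x replicate."""

    profiles: tuple[ContaminantProfile, ...]
    replicates_per_cell: int = 30
    noise_cv: float = 0.02
    rep_cv: float = 0.01
    master_seed: int = 1
    template: ControlTemplate = field(default_factory=ControlTemplate)
    grid: TimeGrid = field(default_factory=TimeGrid)

    def __post_init__(self) -> None:
        object.__setattr__(self, "profiles", tuple(self.profiles))
        if self.replicates_per_cell < 1:
            raise SimulationError("replicates_per_cell must be >= 1")
        if self.noise_cv < 0 or self.rep_cv < 0:
            raise SimulationError("noise_cv and rep_cv must be >= 0")
        labels = [p.ec_label for p in self.profiles]
        if len(set(labels)) != len(labels):
            raise SimulationError("duplicate ec_labels in config")

    @property
    def n_samples(self) -> int:
        return sum(len(p.concentrations) for p in self.profiles) * self.replicates_per_cell


def generate_dataset(config: DatasetConfig) -> CurveDataset:
    """Generate the full design deterministically from ``master_seed``.

    Per-replicate generators are seeded counter-style from
    SeedSequence([master_seed, profile_index, dose_index, replicate]), so any
    subset of the design is reproducible independently of generation order.
    """
    n = config.n_samples
    values = np.empty((n, config.grid.n_points), dtype=float)
    labels, concs, reps = [], [], []
    row = 0
    for pi, profile in enumerate(config.profiles):
        for ci, conc in enumerate(profile.concentrations):
            for r in range(config.replicates_per_cell):
                seed = np.random.SeedSequence([config.master_seed, pi, ci, r])
                curve = generate_curve(
                    profile,
                    config.template,
                    config.grid,
                    conc,
                    rng_seed=seed,
                    noise_cv=config.noise_cv,
                    rep_cv=config.rep_cv,
                    replicate_id=r,
                )
                values[row] = curve.fluorescence
                labels.append(profile.ec_label)
                concs.append(conc)
                reps.append(r)
                row += 1
    meta = pd.DataFrame(
        {"ec_label": labels, "concentration": concs, "replicate_id": reps}
    )
    return CurveDataset(time=config.grid, values=values, meta=meta)


# ---------------------------------------------------------------------------
# The emulated 13-EC trial design: dose lists and growth-inhibition IC50 anchors.
# ---------------------------------------------------------------------------

TABLE1_CONCENTRATIONS: dict[str, tuple[float, ...]] = {
    "dcf": (0, 0.8, 3, 40, 100, 300),      # diclofenac
    "fx": (0, 0.3, 0.6, 20, 40, 80),       # fluoxetine
    "gliph": (0, 10, 50, 100, 250, 500),   # glyphosate
    "ibu": (0, 0.3, 3, 40, 100, 300),      # ibuprofen
    "prop": (0, 0.3, 8, 80, 150, 300),     # propranolol
    "sds": (0, 0.1, 1, 3, 10),             # sodium dodecyl sulphate
    "tri": (0, 0.1, 1, 10, 50, 100),       # triclosan
    "Cu_d": (0, 1, 5, 10),                 # dissolved ionic copper
    "Cu_np": (0, 1, 5, 10),                # CuO engineered nanoparticles
    "Ti_d": (0, 10, 50, 200),              # dissolved ionic titanium
    "Ti_np": (0, 10, 50, 200),             # TiO engineered nanoparticles
    "Zn_d": (0, 1, 5, 10),                 # dissolved ionic zinc
    "Zn_np": (0, 1, 5, 10),                # ZnO engineered nanoparticles
}

# Growth-inhibition IC50 (ug/L) per EC from the exposure trials; used to
# anchor the dose-effect midpoint of the default profiles.
TABLE2_IC50: dict[str, float] = {
    "dcf": 318.9,
    "fx": 47.3,
    "gliph": 225.9,
    "ibu": 350.6,
    "prop": 194.6,
    "sds": 11.4,
    "tri": 691.7,
    "Cu_d": 14.6,
    "Cu_np": 8.31,
    "Ti_d": 577.5,
    "Ti_np": 634.3,
    "Zn_d": 73.9,
    "Zn_np": 88.4,
}

_DIRECTION_SEED = 20210918  # fixed: class directions are part of the study design

# Componentwise cap on |direction| + |batch_direction|.  At 0.4 the perturbed
# parameters stay positive and the J < I < P step-time ordering is preserved
# (the default step-time ratios are 10x and 5x).
_DIRECTION_CAP = 0.4


def _unit_directions(n: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((n, len(PARAM_NAMES)))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def curve_space_gain(
    direction: np.ndarray,
    template: ControlTemplate | None = None,
    grid: TimeGrid | None = None,
    eps: float = 1e-4,
) -> float:
    """Relative curve displacement per unit of relative parameter shift.

    A unit vector in parameter space moves the curve by wildly different
    amounts depending on which parameters it loads (basal level and
    amplitudes act strongly, step times weakly), so class separations are
    normalized in curve space: ``||c(theta*(1+a*d)) - c(theta)|| / (a*||c||)``
    evaluated at small ``a``.
    """
    template = template if template is not None else ControlTemplate()
    grid = grid if grid is not None else TimeGrid()
    c0 = control_curve(template, grid).fluorescence
    v = template.as_vector() * (1.0 + eps * np.asarray(direction, dtype=float))
    c1 = control_curve(
        ControlTemplate.from_vector(v, template.step_widths), grid
    ).fluorescence
    return float(np.linalg.norm(c1 - c0) / (eps * np.linalg.norm(c0)))


def _scaled_direction_pair(
    raw_dir: np.ndarray,
    raw_batch: np.ndarray,
    effect_scale: float,
    batch_scale: float,
    template: ControlTemplate,
    grid: TimeGrid,
) -> tuple[np.ndarray, np.ndarray]:
    d = raw_dir / curve_space_gain(raw_dir, template, grid) * effect_scale
    b = raw_batch / curve_space_gain(raw_batch, template, grid) * batch_scale
    cap = _DIRECTION_CAP / max(float(np.max(np.abs(d) + np.abs(b))), 1e-12)
    if cap < 1.0:
        d, b = d * cap, b * cap
    return d, b


def _build_profiles(
    effect_scale: float,
    batch_scale: float,
    hill: float,
    direction_seed: int,
    ec50_map: dict[str, float],
    template: ControlTemplate,
    grid: TimeGrid,
    shape_only: bool = False,
) -> tuple[ContaminantProfile, ...]:
    labels = list(TABLE1_CONCENTRATIONS)
    dirs = _unit_directions(len(labels), direction_seed)
    batch = _unit_directions(len(labels), direction_seed + 1)
    if shape_only:
        # zero the basal-level (f0) component: pure-scale differences are
        # invisible to scale-free representations (per-image y scaling, Vt)
        dirs = dirs.copy(); batch = batch.copy()
        dirs[:, 0] = 0.0; batch[:, 0] = 0.0
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        batch /= np.linalg.norm(batch, axis=1, keepdims=True)
    profiles = []
    for i, lab in enumerate(labels):
        d, b = _scaled_direction_pair(
            dirs[i], batch[i], effect_scale, batch_scale, template, grid
        )
        profiles.append(
            ContaminantProfile(
                ec_label=lab,
                direction=d,
                batch_direction=b,
                ec50=ec50_map[lab],
                hill=hill,
                concentrations=TABLE1_CONCENTRATIONS[lab],
            )
        )
    return tuple(profiles)


def table1_profiles(
    effect_scale: float = 0.25,
    batch_scale: float = 0.05,
    hill: float = 1.5,
    direction_seed: int = _DIRECTION_SEED,
    template: ControlTemplate | None = None,
    grid: TimeGrid | None = None,
) -> tuple[ContaminantProfile, ...]:
    """The 13-EC design with dose-effect midpoints at the measured IC50s.

    Each EC gets a distinct random direction (fixed seed: the directions are
    part of the study design, not per-dataset randomness) normalized so that
    the full-dose effect displaces the control transient by ``effect_scale``
    of its norm, plus an independent batch direction worth ``batch_scale``
    emulating trial-set culture-batch variability.  With the IC50 anchors,
    ECs whose tested doses sit far below their IC50 (e.g. triclosan) remain
    nearly indistinguishable from control — realistic difficulty, by design.
    """
    template = template if template is not None else ControlTemplate()
    grid = grid if grid is not None else TimeGrid()
    return _build_profiles(
        effect_scale, batch_scale, hill, direction_seed, TABLE2_IC50, template, grid
    )


def well_separated_profiles(
    effect_scale: float = 0.25,
    batch_scale: float = 0.18,
    hill: float = 1.5,
    direction_seed: int = _DIRECTION_SEED,
    template: ControlTemplate | None = None,
    grid: TimeGrid | None = None,
) -> tuple[ContaminantProfile, ...]:
    """A benchmark configuration in which every EC is identifiable.

    Same design as :func:`table1_profiles` but with three changes that make
    every EC identifiable under every representation: each EC's dose-effect
    midpoint sits at the geometric mean of its non-zero doses (so every dose
    list spans the dynamic range of its Hill curve); the batch offset is
    large enough that control replicates of different trial sets separate;
    and class directions load on shape parameters only (f0 zeroed), since
    scale-free representations such as the image encoding cannot see pure
    basal-level differences.  Used for parameter-recovery benchmarks.
    """
    template = template if template is not None else ControlTemplate()
    grid = grid if grid is not None else TimeGrid()
    ec50s = {
        lab: float(np.exp(np.mean(np.log(np.asarray(doses[1:], dtype=float)))))
        for lab, doses in TABLE1_CONCENTRATIONS.items()
    }
    return _build_profiles(
        effect_scale, batch_scale, hill, direction_seed, ec50s, template, grid,
        shape_only=True,
    )


def well_separated_config(
    master_seed: int = 1,
    replicates_per_cell: int = 30,
    separation: float = 1.0,
) -> "DatasetConfig":
    """The full benchmark dataset: well-separated profiles, low point noise.

    Replicate-to-replicate variability is dominated by smooth biological
    parameter jitter (1%) rather than white measurement noise (0.5%): a
    well-averaged fluorometer reading varies far less pointwise than two
    sister cultures differ, and white noise at the 2% level would mask the
    class structure for convolution-feature methods at any separation.
    ``separation`` scales all class-distinguishing directions (0 = chance).
    """
    return DatasetConfig(
        profiles=scaled_profiles(well_separated_profiles(), separation),
        replicates_per_cell=replicates_per_cell,
        noise_cv=0.005,
        rep_cv=0.01,
        master_seed=master_seed,
    )


def scaled_profiles(
    profiles: tuple[ContaminantProfile, ...], separation: float
) -> tuple[ContaminantProfile, ...]:
    """Scale every class-distinguishing direction by ``separation`` in [0, 1].

    At 0 all ECs share the control distribution, so classifier accuracy drops
    to chance (1/n_classes); at 1 the input configuration is returned.
    """
    if not 0 <= separation <= 1:
        raise SimulationError("separation must be in [0, 1]")
    return tuple(
        replace(
            p,
            direction=p.direction * separation,
            batch_direction=p.batch_direction * separation,
        )
        for p in profiles
    )
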