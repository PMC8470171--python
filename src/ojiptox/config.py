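"""Pipeline configuration: a YAML/JSON-mirrorable description of a full run."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .models.base import FAMILIES, REPRESENTATIONS
from .simulate import TABLE1_CONCENTRATIONS


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class DatasetSection:
    """Either a path to an existing curve table or generator settings.

    ``n_points``/``dt`` override the acquisition grid and ``ec_subset``
    keeps only the first k contaminants — both meant for quick smoke
    configurations; the trial design itself uses the defaults.
    """

    path: str | None = None
    profiles: str = "table1"  # "table1" | "well_separated"
    replicates_per_cell: int = 30
    noise_cv: float = 0.02
    rep_cv: float | None = None
    effect_scale: float | None = None
    batch_scale: float | None = None
    n_points: int | None = None
    dt: float | None = None
    ec_subset: int | None = None

    def __post_init__(self) -> None:
        if self.path is None and self.profiles not in ("table1", "well_separated"):
            raise ConfigError(f"unknown profile set {self.profiles!r}")
        if self.path is not None and not Path(self.path).exists():
            raise ConfigError(f"dataset path {self.path!r} does not exist")
        if self.ec_subset is not None and self.ec_subset < 2:
            raise ConfigError("ec_subset must keep at least 2 contaminants")


@dataclass
class MethodSection:
    family: str
    hyperparameters: dict = field(default_factory=dict)
    epochs: int | None = None
    representation: str | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigError(f"unknown method family {self.family!r}")
        if self.representation is not None and self.representation not in REPRESENTATIONS:
            raise ConfigError(f"unknown representation {self.representation!r}")


@dataclass
class PipelineConfig:
    dataset: DatasetSection = field(default_factory=DatasetSection)
    tasks: list[str] = field(default_factory=lambda: ["ec"])  # "ec" | "conc:<ec>" | "conc:all"
    methods: list[MethodSection] = field(
        default_factory=lambda: [MethodSection("rf"), MethodSection("rocket")]
    )
    n_runs: int = 30
    seed: int = 1
    test_fraction: float = 0.2
    stratify: bool = True
    image_height: int = 128
    image_width: int = 128
    include_control: bool = True

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ConfigError("n_runs must be >= 1")
        if not 0 < self.test_fraction < 1:
            raise ConfigError("test_fraction must be in (0, 1)")
        for t in self.tasks:
            if t == "ec" or t == "conc:all":
                continue
            if t.startswith("conc:") and t[5:] in TABLE1_CONCENTRATIONS:
                continue
            if t.startswith("conc:"):
                # custom EC labels are validated against the dataset later
                continue
            raise ConfigError(f"unknown task {t!r}; use 'ec', 'conc:<ec>' or 'conc:all'")

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        try:
            dataset = DatasetSection(**raw.pop("dataset", {}))
            methods = [
                MethodSection(**m) if isinstance(m, dict) else MethodSection(m)
                for m in raw.pop("methods", ["rf", "rocket"])
            ]
            return cls(dataset=dataset, methods=methods, **raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text)  # YAML superset also parses JSON
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def content_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
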