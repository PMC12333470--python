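"""Experiment configuration: one YAML document drives a full analysis run."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

__all__ = ["CohortSpec", "ExperimentConfig"]


@dataclass
class CohortSpec:
    """One experimental group: condition + size."""

    condition: str = "control"  # control | lesion | lesion+treatment
    n_animals: int = 6
    severity: float = 0.8

    def validate(self) -> None:
        if self.condition not in ("control", "lesion", "lesion+treatment"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce a control-vs-lesion(-vs-treatment) run.

    A config plus the package version determines every output bit-exactly;
    all randomness flows from ``seed``.
    """

    cohorts: dict = field(default_factory=lambda: {
        "control": CohortSpec("control", 6),
        "lesion": CohortSpec("lesion", 7, 0.8),
    })
    # generator
    n_syllables: int = 12
    speed_range: tuple = (0.0, 172.0)
    target_mean_duration_s: float = 0.4
    baseline_speed: float = 30.0  # mm/s motionless baseline from tracking jitter
    session_duration_s: float = 300.0
    fps: float = 30.0
    arena_size: float = 400.0
    # preprocessing
    likelihood_threshold: float = 0.5
    n_pcs: int = 5
    # segmentation
    labels_source: str = "arhmm"  # arhmm | ground_truth
    kappa_grid: tuple = (1e3, 1e4, 1e5)
    target_duration_ms: float = 400.0
    K_max: int = 20
    ar_order: int = 1
    alpha: float = 5.7
    gamma: float = 1e3
    n_iter: int = 50
    burn_in: int = 25
    # metrics / stats
    usage_threshold: float = 0.005
    entropy_base: float = 2.0
    entropy_mode: str = "rate"
    fdr_q: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if len(self.cohorts) < 1:
            raise ValueError("at least one cohort required")
        for spec in self.cohorts.values():
            spec.validate()
        if self.labels_source not in ("arhmm", "ground_truth"):
            raise ValueError(f"unknown labels_source {self.labels_source!r}")
        if self.session_duration_s <= 0 or self.fps <= 0:
            raise ValueError("session duration and fps must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohorts"] = {k: dataclasses.asdict(v) for k, v in self.cohorts.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        cohorts = {
            name: CohortSpec(**spec) if isinstance(spec, dict) else spec
            for name, spec in d.pop("cohorts", {}).items()
        }
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        if cohorts:
            cfg.cohorts = cohorts
        for key in ("speed_range", "kappa_grid"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=False)
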