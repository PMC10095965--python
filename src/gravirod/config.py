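"""Run configuration: a flat, human-editable YAML mapping to typed blocks.

Unknown keys are rejected with an error naming the block and key, and a
loaded configuration serializes back to an identical mapping (lossless
round-trip).  A stable hash of the canonical serialization is logged with
every run for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields

import yaml

from gravirod.growth import GrowthParams
from gravirod.mechanics import MechanicalParams
from gravirod.synthetic import CohortSpec

__all__ = ["AnalysisConfig", "FitBlock", "RunConfig", "config_hash"]


def _build(cls, data: dict, block: str):
    """Construct a dataclass from a mapping, rejecting unknown keys."""
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config block {block!r} must be a mapping")
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in config block {block!r}; "
            f"known keys: {sorted(known)}"
        )
    return cls(**data)


@dataclass
class AnalysisConfig:
    """Centerline-analysis settings."""

    ds: float = 0.5  # arc-length grid spacing, mm
    window: int = 3  # curvature moving-average window, samples
    smoothing: str | float | None = "gcv"
    t_end: float = 140.0
    extension_as_strain: bool = False


@dataclass
class FitBlock:
    """Grid-search settings (scalar form of :class:`gravirod.fitting.FitConfig`)."""

    s_min: float = 10**-0.5
    s_max: float = 10**0.5
    s_num: int = 10
    g_min: float = 10**-0.5
    g_max: float = 10**0.5
    g_num: int = 10
    gamma: float = 5.0e-2
    w_kmax: float = 1.0
    w_extension: float = 1.0
    initial_length: float = 40.0
    n_vertices: int = 41
    n_points: int = 220
    block: int = 5
    smoothing_lam: float = 3.0
    window: int = 3
    n_avg_frames: int = 20
    calibration_sigma: float = 0.0
    calibration_reps: int = 5
    calibration_seed: int = 2024

    def to_fit_config(self, mechanical: MechanicalParams, growth: GrowthParams):
        import numpy as np

        from gravirod.fitting import FitConfig

        return FitConfig(
            s_grid=np.geomspace(self.s_min, self.s_max, self.s_num),
            g_grid=np.geomspace(self.g_min, self.g_max, self.g_num),
            gamma=self.gamma,
            weights=(self.w_kmax, self.w_extension),
            initial_length=self.initial_length,
            n_vertices=self.n_vertices,
            mechanical=mechanical,
            growth=growth,
            n_points=self.n_points,
            block=self.block,
            smoothing_lam=self.smoothing_lam,
            window=self.window,
            n_avg_frames=self.n_avg_frames,
            calibration_sigma=self.calibration_sigma,
            calibration_reps=self.calibration_reps,
            calibration_seed=self.calibration_seed,
        )


@dataclass
class RunConfig:
    """Top-level configuration for the command-line pipeline."""

    seed: int = 0
    log_level: str = "INFO"
    mechanical: MechanicalParams = field(default_factory=MechanicalParams)
    growth: GrowthParams = field(default_factory=GrowthParams)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    fit: FitBlock = field(default_factory=FitBlock)
    synth_wt: CohortSpec = field(default_factory=lambda: CohortSpec())
    synth_mut: CohortSpec = field(
        default_factory=lambda: CohortSpec(
            n_individuals=15, genotype="mut", beta_mean=1.0e-3, beta_sd=1.0e-4
        )
    )

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        if data is None:
            data = {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(
                f"unknown top-level config key(s) {sorted(unknown)}; "
                f"known keys: {sorted(known)}"
            )
        kwargs = {}
        blocks = {
            "mechanical": MechanicalParams,
            "growth": GrowthParams,
            "analysis": AnalysisConfig,
            "fit": FitBlock,
            "synth_wt": CohortSpec,
            "synth_mut": CohortSpec,
        }
        for key, value in data.items():
            if key in blocks:
                kwargs[key] = _build(blocks[key], value, key)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of the canonical configuration serialization."""
    text = json.dumps(cfg.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:16]
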