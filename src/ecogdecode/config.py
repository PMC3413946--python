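"""Configuration containers for simulation and the decoding pipeline.

All numeric defaults are the constants the decoding stack is built around:
300 ms analysis windows advanced every 100 ms, autoregressive order 25,
mu/beta/high-gamma band edges, a 1 s (10-step) FIFO buffer, an onset
probability threshold of 0.3, and eight targets at 45 degree spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import yaml


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class SimConfig:
    """Parameters of the synthetic center-out ECoG session generator.

    Effect sizes are dimensionless multipliers applied to designated "motor"
    channels: ``gamma_gain`` scales the movement-locked high-gamma amplitude
    increase (1.0 means the envelope doubles), ``mu_beta_suppression`` is the
    fractional mu/beta decrease, ``lmp_shift`` is an additive slow-potential
    offset in signal units, and ``direction_coupling_strength`` scales the
    direction-specific linear-Gaussian coupling coefficients that tie channel
    band-features together in the second before movement onset.
    """

    n_channels: int = 8
    n_trials: int = 40
    sampling_rate: float = 1200.0
    n_directions: int = 8
    target_radius: float = 1.0
    onset_latency_mean: float = 0.5
    onset_latency_sd: float = 0.15
    gamma_gain: float = 1.0
    mu_beta_suppression: float = 0.5
    lmp_shift: float = 1.0
    direction_coupling_strength: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ConfigurationError("n_channels must be >= 2 (CAR needs it)")
        if self.n_trials < 1:
            raise ConfigurationError("n_trials must be positive")
        if self.n_directions < 2:
            raise ConfigurationError("n_directions must be >= 2")
        if self.sampling_rate <= 400.0:
            raise ConfigurationError(
                "sampling_rate must exceed 400 Hz so 0-200 Hz spectra exist"
            )
        if self.target_radius <= 0:
            raise ConfigurationError("target_radius must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if self.onset_latency_sd < 0:
            raise ConfigurationError("onset_latency_sd must be non-negative")

    @classmethod
    def null_effect(cls, **overrides) -> "SimConfig":
        """A configuration in which no channel carries task information."""
        params = dict(
            gamma_gain=0.0,
            mu_beta_suppression=0.0,
            lmp_shift=0.0,
            direction_coupling_strength=0.0,
        )
        params.update(overrides)
        return cls(**params)


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration.

    Defaults mirror the decoding stack's published constants; anything set
    here is logged with the fitted hyperparameters in the pipeline report.
    """

    # data
    session_path: str | None = None
    sim: SimConfig = field(default_factory=SimConfig)
    exclude_channels: tuple[int, ...] = ()

    # feature extraction
    window_s: float = 0.3
    step_s: float = 0.1
    ar_order: int = 25
    n_selected_features: int = 20

    # onset detection
    buffer_len: int = 10
    onset_threshold: float = 0.3
    svm_C_grid: tuple[float, ...] = (1.0, 10.0, 100.0)
    svm_gamma_grid: tuple[float | str, ...] = ("scale",)

    # direction classification
    T: int = 10
    lambda_grid: tuple[float, ...] = (0.001, 0.01, 0.1, 0.3, 1.0, 3.0, 10.0)
    direction_feature_set: str = "all"  # "all" or "selected"

    # targeting simulation
    alpha_grid: tuple[float, ...] = tuple(round(0.05 * i, 2) for i in range(21))

    n_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.onset_threshold < 1.0):
            raise ConfigurationError("onset_threshold must lie in (0, 1)")
        if abs(self.buffer_len * self.step_s - 1.0) > 1e-9:
            raise ConfigurationError("buffer must span exactly 1 s")
        if self.direction_feature_set not in ("selected", "all"):
            raise ConfigurationError(
                "direction_feature_set must be 'selected' or 'all'"
            )
        if any(a < 0 or a > 1 for a in self.alpha_grid):
            raise ConfigurationError("alpha grid must lie within [0, 1]")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if "sim" in data and isinstance(data["sim"], dict):
            data["sim"] = SimConfig(**data["sim"])
        for key in ("exclude_channels", "svm_C_grid", "svm_gamma_grid",
                    "lambda_grid", "alpha_grid"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
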