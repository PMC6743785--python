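"""Simulation configuration with YAML round-tripping.

Every knob of the simulator lives here so that a run is fully
reproducible from ``(config, seed)``: control step, noise levels, UKF
settings, feedback gating, null-space attractor, perturbation schedules
and the divergence bound.  ``SimConfig.to_yaml`` echoes *all* defaults,
so the sidecar written next to results is a complete provenance record.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from .kinematics import NullSpaceConfig
from .plant import ChannelNorms, NoiseConfig


@dataclass
class UKFConfig:
    """Observer settings; internal noise estimates default to the true
    noise levels (``None`` means 'copy from the plant noise config')."""

    alpha: float = 1e-3
    kappa: float = 0.0
    beta: float = 2.0
    state_cov_init: float = 1e-2
    covariance_update: str = "static"
    process_noise_est: float | None = None
    aud_noise_est: float | None = None
    somat_noise_est: float | None = None


@dataclass
class PerturbationConfig:
    """External perturbation schedule.

    ``jaw_clamp_onset``: time (s) from which the jaw angle is frozen in
    place (``None`` = never).  ``jaw_mode`` selects the clamp (default,
    matching 'fixing the jaw in place') or a constant downward bias
    acceleration variant.  ``f1_shift_hz`` is added to the *perceived* F1
    from ``f1_shift_onset`` onward.
    """

    jaw_clamp_onset: float | None = None
    jaw_mode: str = "clamp"          # "clamp" | "bias"
    jaw_bias_accel: float = -2.0     # rad/s^2, used when jaw_mode == "bias"
    f1_shift_hz: float = 0.0
    f1_shift_onset: float = 0.2


@dataclass
class SimConfig:
    dt: float = 0.005
    feedback: str = "both"
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    ukf: UKFConfig = field(default_factory=UKFConfig)
    null_space: NullSpaceConfig = field(default_factory=NullSpaceConfig)
    perturbation: PerturbationConfig = field(default_factory=PerturbationConfig)
    divergence_factor: float = 5.0

    # -- derived ------------------------------------------------------------
    def internal_noise_levels(self) -> tuple[float, float, float]:
        """(process, auditory, somatosensory) levels the observer assumes."""
        u = self.ukf
        return (
            u.process_noise_est if u.process_noise_est is not None else self.noise.motor_level,
            u.aud_noise_est if u.aud_noise_est is not None else self.noise.aud_level,
            u.somat_noise_est if u.somat_noise_est is not None else self.noise.somat_level,
        )

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return _asdict_plain(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_dict(cls, doc: dict) -> "SimConfig":
        doc = dict(doc)
        noise = doc.pop("noise", {})
        norms = noise.pop("channel_norms", {}) if isinstance(noise, dict) else {}
        kwargs: dict = {}
        if noise:
            kwargs["noise"] = NoiseConfig(channel_norms=ChannelNorms(**norms), **noise)
        if "ukf" in doc:
            kwargs["ukf"] = UKFConfig(**doc.pop("ukf"))
        if "null_space" in doc:
            kwargs["null_space"] = NullSpaceConfig(**doc.pop("null_space"))
        if "perturbation" in doc:
            kwargs["perturbation"] = PerturbationConfig(**doc.pop("perturbation"))
        doc.pop("noise", None)
        return cls(**doc, **kwargs)

    @classmethod
    def from_yaml(cls, text: str) -> "SimConfig":
        return cls.from_dict(yaml.safe_load(text) or {})


def _asdict_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _asdict_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
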