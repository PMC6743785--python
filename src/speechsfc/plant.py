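"""The simulated vocal tract (plant).

The plant integrates motor commands (articulator accelerations plus motor
noise) with classical 4th-order Runge–Kutta, enforces the articulator
range box, computes constriction task variables through the surrogate
geometry, and converts them to the first three formants with a smooth
closed-form map.  It emits noisy somatosensory (positions + velocities,
20-dim) and auditory (F1–F3, 3-dim) observations and applies external
perturbations: a jaw clamp (mechanical) and a perceived-F1 shift
(auditory).

Noise convention: every channel's noise is zero-mean Gaussian with
standard deviation ``level × channel norm``, where the channel norms are
the RMS per channel group (positions, velocities, formants, motor
commands) measured once from a noiseless, unperturbed calibration run of
the same gestural score.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .kinematics import (
    DEFAULT_GEOMETRY,
    ARTIC_INDEX,
    Geometry,
    ArticulatoryState,
    MotorCommand,
    N_ARTIC,
    RANGE_HIGH,
    RANGE_LOW,
    forward_kinematics,
)

JA = ARTIC_INDEX["JA"]


@dataclass
class FormantMap:
    """Closed-form articulatory-to-acoustic map.

    Formants depend on the articulators only through the tongue-body
    constriction (degree ``d`` and location ``l``) and lip protrusion,
    making the full 10-dim map smooth and many-to-one.  A tight palatal
    constriction (l = pi/2, d -> 0) gives (F1, F2) -> (310, 2200) Hz; a
    wide neutral tract (d >> 0.5 cm) relaxes to (500, 1500, 2500) Hz.
    """

    d_scale: float = 0.5  # cm; constriction-coupling length scale

    def __call__(self, tbcd, tbcl, pro):
        d = np.maximum(np.asarray(tbcd, dtype=float), 0.0)  # contact at 0
        l = np.asarray(tbcl, dtype=float)
        c = np.exp(-d / self.d_scale)
        f1 = 500.0 + 180.0 * np.cos(l) * c - 190.0 * np.sin(l) * c
        f2 = 1500.0 + 700.0 * np.sin(l) * c - 570.0 * np.cos(l) * c
        f3 = 2500.0 + 200.0 * np.sin(l) * c - 150.0 * np.asarray(pro, dtype=float)
        return np.stack([f1, f2, f3], axis=-1)


DEFAULT_FORMANT_MAP = FormantMap()


def synthesize(
    a: np.ndarray,
    geometry: Geometry = DEFAULT_GEOMETRY,
    formant_map: FormantMap = DEFAULT_FORMANT_MAP,
) -> np.ndarray:
    """Formants (F1, F2, F3) in Hz for articulator positions ``a``.

    Accepts ``(..., 10)`` arrays and broadcasts.
    """
    x = forward_kinematics(a, geometry)
    return formant_map(x[..., 2], x[..., 3], x[..., 1])


@dataclass
class ChannelNorms:
    """Nominal per-group signal norms used to scale noise levels."""

    position: float = 1.0
    velocity: float = 1.0
    formant: float = 1.0
    motor: float = 1.0

    def somat_sigma_vector(self, level: float) -> np.ndarray:
        return level * np.concatenate(
            [np.full(N_ARTIC, self.position), np.full(N_ARTIC, self.velocity)]
        )


@dataclass
class NoiseConfig:
    """Noise levels (std as a fraction of the channel norm) per pathway."""

    motor_level: float = 1e-4
    aud_level: float = 1e-2
    somat_level: float = 1e-6
    channel_norms: ChannelNorms = field(default_factory=ChannelNorms)

    def __post_init__(self) -> None:
        for name in ("motor_level", "aud_level", "somat_level"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def motor_sigma(self) -> float:
        return self.motor_level * self.channel_norms.motor

    @property
    def aud_sigma(self) -> float:
        return self.aud_level * self.channel_norms.formant

    def with_levels(self, **levels: float) -> "NoiseConfig":
        return replace(self, **levels)


@dataclass
class SensoryObservation:
    """One noisy sensory frame: 20-dim somatosensory + 3 formants (Hz)."""

    y_somat: np.ndarray
    y_aud: np.ndarray

    def __post_init__(self) -> None:
        self.y_somat = np.asarray(self.y_somat, dtype=float)
        self.y_aud = np.asarray(self.y_aud, dtype=float)
        if self.y_somat.shape != (2 * N_ARTIC,) or self.y_aud.shape != (3,):
            raise ValueError("observation must be 20-dim somat + 3-dim aud")

    def stacked(self) -> np.ndarray:
        return np.concatenate([self.y_somat, self.y_aud])


@dataclass
class PlantState:
    """Ground-truth plant state plus active perturbation flags."""

    artic: ArticulatoryState
    t: float = 0.0
    jaw_clamped: bool = False
    f1_shift_hz: float = 0.0

    @classmethod
    def neutral(cls) -> "PlantState":
        return cls(ArticulatoryState.neutral())


def integrate_articulators(
    a: np.ndarray, a_dot: np.ndarray, a_ddot: np.ndarray, dt: float, clamp: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Classical RK4 step of (ȧ, ä) with the acceleration held constant.

    Shared verbatim by the plant and the observer's process model so that
    efference-copy prediction reproduces the plant exactly in the
    noiseless, unperturbed case.  With ``clamp=True`` (the plant),
    positions are clamped to the articulator range box, zeroing the
    velocity of any articulator pinned at a bound; the observer's process
    model runs unclamped (``clamp=False``) so it stays smooth — a
    requirement for sigma-point propagation — and agrees with the plant
    exactly on interior trajectories.  Broadcasts over leading axes.
    """
    # RK4 on y' = [a_dot, a_ddot] with constant a_ddot
    k1_a, k1_v = a_dot, a_ddot
    k2_a = a_dot + 0.5 * dt * k1_v
    k3_a = a_dot + 0.5 * dt * k1_v
    k4_a = a_dot + dt * k1_v
    a_new = a + (dt / 6.0) * (k1_a + 2.0 * k2_a + 2.0 * k3_a + k4_a)
    v_new = a_dot + dt * a_ddot
    if not clamp:
        return a_new, v_new
    low = np.broadcast_to(RANGE_LOW, a_new.shape)
    high = np.broadcast_to(RANGE_HIGH, a_new.shape)
    clipped = np.clip(a_new, low, high)
    at_bound = clipped != a_new
    v_new = np.where(at_bound, 0.0, v_new)
    return clipped, v_new


def step(
    state: PlantState,
    cmd: MotorCommand,
    noise: NoiseConfig,
    dt: float,
    rng: np.random.Generator | None = None,
    geometry: Geometry = DEFAULT_GEOMETRY,
) -> PlantState:
    """Advance the plant one control step of length ``dt``.

    Zero-mean Gaussian motor noise (std ``motor_level × motor norm``) is
    added to the commanded accelerations before integration.  An active
    jaw clamp freezes the jaw angle and zeroes its velocity regardless of
    the command — the observer is never told.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    a_ddot = np.array(cmd.a_ddot, dtype=float, copy=True)
    if not np.all(np.isfinite(a_ddot)):
        raise ValueError("non-finite motor command")
    sigma = noise.motor_sigma
    if sigma > 0:
        if rng is None:
            raise ValueError("rng required when motor noise level > 0")
        a_ddot = a_ddot + rng.normal(0.0, sigma, size=N_ARTIC)

    a, v = state.artic.a, state.artic.a_dot
    a_new, v_new = integrate_articulators(a, v, a_ddot, dt)
    if state.jaw_clamped:
        a_new = a_new.copy()
        v_new = v_new.copy()
        a_new[JA] = a[JA]
        v_new[JA] = 0.0
    return replace(
        state,
        artic=ArticulatoryState(a_new, v_new),
        t=state.t + dt,
    )


def observe(
    state: PlantState,
    noise: NoiseConfig,
    rng: np.random.Generator | None = None,
    geometry: Geometry = DEFAULT_GEOMETRY,
    formant_map: FormantMap = DEFAULT_FORMANT_MAP,
) -> SensoryObservation:
    """Noisy sensory signals for the current plant state.

    The perceived-F1 shift, when active, is added to the *perceived*
    auditory signal after noise; the plant's produced formants are
    untouched.
    """
    y_somat = state.artic.as_vector()
    y_aud = synthesize(state.artic.a, geometry, formant_map)
    need_noise = noise.somat_level > 0 or noise.aud_level > 0
    if need_noise and rng is None:
        raise ValueError("rng required when sensory noise levels > 0")
    if noise.somat_level > 0:
        y_somat = y_somat + rng.normal(
            0.0, 1.0, size=2 * N_ARTIC
        ) * noise.channel_norms.somat_sigma_vector(noise.somat_level)
    if noise.aud_level > 0:
        y_aud = y_aud + rng.normal(0.0, noise.aud_sigma, size=3)
    if state.f1_shift_hz:
        y_aud = y_aud + np.array([state.f1_shift_hz, 0.0, 0.0])
    return SensoryObservation(np.asarray(y_somat), np.asarray(y_aud))


def calibrate_norms(trajectory) -> ChannelNorms:
    """Per-group RMS norms from a noiseless calibration trajectory.

    ``trajectory`` is any object exposing ``positions`` (T, 10),
    ``velocities`` (T, 10), ``formants`` (T, 3) and ``commands`` (T, 10)
    arrays (a :class:`speechsfc.experiments.TrialResult` works).
    """
    def rms(arr):
        val = float(np.sqrt(np.mean(np.square(arr))))
        return val if val > 0 else 1.0

    return ChannelNorms(
        position=rms(trajectory.positions),
        velocity=rms(trajectory.velocities),
        formant=rms(trajectory.formants),
        motor=rms(trajectory.commands),
    )
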