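"""Articulator geometry, forward kinematics, Jacobians and the
articulatory (inverse-kinematics) feedback control law.

The vocal tract is a planar surrogate: a fixed temporomandibular joint at
the origin, a vocal-tract outline of radius ``R(phi) = R0 + R1*cos(phi -
phi0)`` and a circular tongue body of radius ``rt`` whose centre sits at
polar position ``(CL, JA + CA)``.  The tongue tip rides at a polar offset
``(TTL, TTA)`` from the tongue-body centre, and the lips are independent
vertical/horizontal degrees of freedom coupled to the jaw.  The geometry is
smooth, nonlinear and redundant: the jaw participates in both the lip and
the tongue constrictions, which is what makes task-specific compensation
possible.

Seven constriction task variables are derived from ten articulators:

========  =====================================  ==========
task      meaning                                units
========  =====================================  ==========
LA        lip aperture                           cm
PRO       lip protrusion                         cm
TBCD      tongue-body constriction degree        cm
TBCL      tongue-body constriction location      rad
TTCD      tongue-tip constriction degree         cm
TTCL      tongue-tip constriction location       rad
VEL       velic aperture                         cm
========  =====================================  ==========

Articulators (in order): JA jaw angle (rad), CA condyle angle (rad), CL
condyle length (cm), TTA tongue-tip angle (rad), TTL tongue-tip length
(cm), ULV/LLV upper/lower lip vertical (cm), ULH/LLH upper/lower lip
horizontal (cm), VEL velum (cm).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

TASKS = ("LA", "PRO", "TBCD", "TBCL", "TTCD", "TTCL", "VEL")
N_TASKS = len(TASKS)
TASK_INDEX = {name: i for i, name in enumerate(TASKS)}

ARTICULATORS = ("JA", "CA", "CL", "TTA", "TTL", "ULV", "LLV", "ULH", "LLH", "VEL")
N_ARTIC = len(ARTICULATORS)
ARTIC_INDEX = {name: i for i, name in enumerate(ARTICULATORS)}

#: lower/upper bounds of the articulator range box
RANGE_LOW = np.array([-0.30, 0.00, 1.50, -0.50, 1.50, -0.80, -1.20, -1.00, -1.00, 0.00])
RANGE_HIGH = np.array([0.60, 1.20, 3.50, 1.00, 3.50, 1.20, 0.80, 1.00, 1.00, 1.00])

#: neutral (rest) posture; the null-space attractor pulls uncontrolled
#: degrees of freedom back here
NEUTRAL = np.array([0.15, 0.635, 2.50, 0.30, 2.50, 0.60, -0.60, 0.00, 0.00, 0.00])


@dataclass(frozen=True)
class Geometry:
    """Constants of the surrogate vocal-tract outline and lip coupling."""

    r0: float = 5.0        # mean outline radius, cm
    r1: float = 0.8        # outline eccentricity, cm
    phi0: float = np.pi / 2  # angle of maximal radius (palate), rad
    rt: float = 2.0        # tongue-body radius, cm
    kappa_jaw: float = 2.0  # jaw-to-lip-aperture coupling, cm/rad
    ja0: float = 0.15      # neutral jaw angle, rad

    def outline_radius(self, phi):
        return self.r0 + self.r1 * np.cos(phi - self.phi0)


DEFAULT_GEOMETRY = Geometry()


@dataclass
class ArticulatoryState:
    """Positions and velocities of the ten model articulators."""

    a: np.ndarray
    a_dot: np.ndarray

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.a_dot = np.asarray(self.a_dot, dtype=float)
        if self.a.shape != (N_ARTIC,) or self.a_dot.shape != (N_ARTIC,):
            raise ValueError(f"articulatory state must be {N_ARTIC}-dimensional")
        if not (np.all(np.isfinite(self.a)) and np.all(np.isfinite(self.a_dot))):
            raise ValueError("non-finite articulatory state")

    @classmethod
    def neutral(cls) -> "ArticulatoryState":
        return cls(NEUTRAL.copy(), np.zeros(N_ARTIC))

    def as_vector(self) -> np.ndarray:
        """Stacked [a; a_dot] 20-vector."""
        return np.concatenate([self.a, self.a_dot])

    @classmethod
    def from_vector(cls, s: np.ndarray) -> "ArticulatoryState":
        s = np.asarray(s, dtype=float)
        return cls(s[:N_ARTIC].copy(), s[N_ARTIC:].copy())


@dataclass
class MotorCommand:
    """Commanded articulator accelerations (the plant input)."""

    a_ddot: np.ndarray

    def __post_init__(self) -> None:
        self.a_ddot = np.asarray(self.a_ddot, dtype=float)
        if self.a_ddot.shape != (N_ARTIC,):
            raise ValueError(f"motor command must be {N_ARTIC}-dimensional")
        if not np.all(np.isfinite(self.a_ddot)):
            raise ValueError("non-finite motor command")


def clamp_to_box(a: np.ndarray, warn: bool = False) -> np.ndarray:
    out = np.clip(a, RANGE_LOW, RANGE_HIGH)
    if warn and np.any(out != a):
        names = [ARTICULATORS[i] for i in np.nonzero(out != np.asarray(a))[-1].ravel()]
        logger.warning("articulator position(s) clamped to range box: %s", names)
    return out


def forward_kinematics(a: np.ndarray, geometry: Geometry = DEFAULT_GEOMETRY) -> np.ndarray:
    """Map articulator positions to the seven constriction task variables.

    Accepts a single 10-vector or an ``(..., 10)`` array and broadcasts.
    Out-of-box positions are clamped (with a logged warning for single
    inputs), mirroring the plant's enforcement of the same range box.
    """
    a = np.asarray(a, dtype=float)
    single = a.ndim == 1
    a = clamp_to_box(a, warn=single)

    g = geometry
    ja, ca, cl = a[..., 0], a[..., 1], a[..., 2]
    tta, ttl = a[..., 3], a[..., 4]
    ulv, llv, ulh, llh, vel = (a[..., i] for i in range(5, 10))

    theta = ja + ca
    tbcl = theta
    tbcd = g.outline_radius(theta) - cl - g.rt

    cx = cl * np.cos(theta)
    cy = cl * np.sin(theta)
    tipx = cx + ttl * np.cos(theta + tta)
    tipy = cy + ttl * np.sin(theta + tta)
    rho = np.hypot(tipx, tipy)
    ttcl = np.arctan2(tipy, tipx)
    ttcd = g.outline_radius(ttcl) - rho

    la = ulv - llv - g.kappa_jaw * (ja - g.ja0)
    pro = (ulh + llh) / 2.0

    return np.stack([la, pro, tbcd, tbcl, ttcd, ttcl, vel], axis=-1)


def tongue_center(a: np.ndarray) -> np.ndarray:
    """Cartesian (x, y) position of the tongue-body centre, cm."""
    a = np.asarray(a, dtype=float)
    theta = a[..., 0] + a[..., 1]
    cl = a[..., 2]
    return np.stack([cl * np.cos(theta), cl * np.sin(theta)], axis=-1)


_FD_STEP = 1e-6


def jacobian(a: np.ndarray, geometry: Geometry = DEFAULT_GEOMETRY) -> np.ndarray:
    """7x10 Jacobian of :func:`forward_kinematics` by central differences."""
    a = np.asarray(a, dtype=float)
    eye = np.eye(N_ARTIC) * _FD_STEP
    # suppress box-clamp warnings for probe points straddling the boundary
    hi = forward_kinematics(a + eye, geometry)
    lo = forward_kinematics(a - eye, geometry)
    return (hi - lo).T / (2.0 * _FD_STEP)


def jacobian_dot(
    a: np.ndarray, a_dot: np.ndarray, geometry: Geometry = DEFAULT_GEOMETRY
) -> np.ndarray:
    """Time derivative of the Jacobian, J̇ᵢⱼ = Σₖ ∂Jᵢⱼ/∂aₖ ȧₖ.

    Computed as the directional derivative of J along ``a_dot``.
    """
    a = np.asarray(a, dtype=float)
    a_dot = np.asarray(a_dot, dtype=float)
    nrm = float(np.linalg.norm(a_dot))
    if nrm == 0.0:
        return np.zeros((N_TASKS, N_ARTIC))
    step = _FD_STEP / nrm
    jp = jacobian(a + step * a_dot, geometry)
    jm = jacobian(a - step * a_dot, geometry)
    return (jp - jm) / (2.0 * step)


class SingularTaskError(np.linalg.LinAlgError):
    """Raised when the active task rows are rank-deficient beyond repair."""


def weighted_pseudoinverse(
    J: np.ndarray,
    W: np.ndarray | None = None,
    mask: np.ndarray | None = None,
    eps: float = 1e-8,
) -> np.ndarray:
    """Weighted right pseudoinverse J* = W⁻¹ Jₐᵀ (Jₐ W⁻¹ Jₐᵀ + eps·I)⁻¹.

    Rows of ``J`` selected by ``mask`` (the active tasks) are inverted; the
    returned 10x7 matrix carries zero columns for inactive tasks, so
    ``J* @ x_ddot`` ignores commands on inactive task variables.
    """
    J = np.asarray(J, dtype=float)
    n_tasks, n_art = J.shape
    if mask is None:
        mask = np.ones(n_tasks, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if W is None:
        W_inv = np.eye(n_art)
    else:
        W = np.asarray(W, dtype=float)
        if not np.allclose(W, W.T):
            raise ValueError("weight matrix must be symmetric")
        W_inv = np.linalg.inv(W)

    Jstar = np.zeros((n_art, n_tasks))
    if not mask.any():
        return Jstar
    Ja = J[mask]
    M = Ja @ W_inv @ Ja.T + eps * np.eye(int(mask.sum()))
    cond = np.linalg.cond(M)
    if not np.isfinite(cond) or cond > 1e12:
        bad = [TASKS[i] for i in np.nonzero(mask)[0]] if n_tasks == N_TASKS else list(np.nonzero(mask)[0])
        raise SingularTaskError(
            f"active task rows are singular beyond regularization (cond={cond:.3g}): {bad}"
        )
    Jstar[:, mask] = W_inv @ Ja.T @ np.linalg.inv(M)
    return Jstar


@dataclass
class NullSpaceConfig:
    """Neutral attractor acting in the null space of the active tasks.

    Uncontrolled degrees of freedom would otherwise drift under motor
    noise; a weak critically-damped pull toward the neutral posture keeps
    them bounded without disturbing the active tasks.
    """

    enabled: bool = True
    stiffness: float = 10.0  # s^-2
    damping: float = field(default=2.0 * np.sqrt(10.0))  # s^-1, critical


def articulatory_command(
    x_ddot: np.ndarray,
    est: ArticulatoryState,
    mask: np.ndarray | None = None,
    W: np.ndarray | None = None,
    null_space: NullSpaceConfig | None = None,
    geometry: Geometry = DEFAULT_GEOMETRY,
    _jacobians: tuple[np.ndarray, np.ndarray] | None = None,
) -> MotorCommand:
    """Articulatory state feedback control law.

    ``ä = J*(ã) ẍ − J*(ã) J̇(ã, ȧ̃) ȧ̃ + (I − J* Jₐ) u_neutral``:
    inverse kinematics from commanded task accelerations to articulator
    accelerations computed at the *estimated* articulatory state, plus a
    null-space neutral attractor on uncontrolled directions.
    """
    x_ddot = np.asarray(x_ddot, dtype=float)
    if not np.all(np.isfinite(x_ddot)):
        raise ValueError("non-finite task command")
    if _jacobians is not None:
        J, Jdot = _jacobians
    else:
        J = jacobian(est.a, geometry)
        Jdot = jacobian_dot(est.a, est.a_dot, geometry)
    if mask is None:
        mask = np.ones(J.shape[0], dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    Jstar = weighted_pseudoinverse(J, W=W, mask=mask)
    a_ddot = Jstar @ x_ddot - Jstar @ (Jdot @ est.a_dot)

    ns = null_space or NullSpaceConfig()
    if ns.enabled:
        N = np.eye(N_ARTIC) - Jstar[:, mask] @ J[mask]
        pull = -ns.stiffness * (est.a - NEUTRAL) - ns.damping * est.a_dot
        a_ddot = a_ddot + N @ pull
    return MotorCommand(a_ddot)
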