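"""Task-level state feedback control law and task state estimator.

Each active gesture drives its task variable with an independent
critically damped second-order point attractor,

    ẍᵢ = mᵢ⁻¹ (−bᵢ ẋ̃ᵢ − kᵢ (x̃ᵢ − x0ᵢ)),

evaluated at the *estimated* task state, so the commanded task
acceleration depends on the controller's belief about the vocal tract,
not on its true state.  Inactive tasks receive zero task-space command;
their articulators are kept bounded by the null-space neutral attractor
in :mod:`speechsfc.kinematics`.

The task state itself is never observed: it is re-derived from the
articulatory state estimate through the forward kinematics map,
x̃ = f(ã), ẋ̃ = J(ã) ȧ̃.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .kinematics import (
    DEFAULT_GEOMETRY,
    Geometry,
    ArticulatoryState,
    N_TASKS,
    forward_kinematics,
    jacobian,
)
from .score import ActiveSet


@dataclass
class TaskState:
    """Positions and velocities of the seven constriction task variables."""

    x: np.ndarray
    x_dot: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.x_dot = np.asarray(self.x_dot, dtype=float)
        if self.x.shape != (N_TASKS,) or self.x_dot.shape != (N_TASKS,):
            raise ValueError(f"task state must be {N_TASKS}-dimensional")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.x_dot))):
            raise ValueError("non-finite task state")


@dataclass
class TaskCommand:
    """Commanded task accelerations; zero on inactive tasks."""

    x_ddot: np.ndarray

    def __post_init__(self) -> None:
        self.x_ddot = np.asarray(self.x_ddot, dtype=float)
        if self.x_ddot.shape != (N_TASKS,):
            raise ValueError(f"task command must be {N_TASKS}-dimensional")
        if not np.all(np.isfinite(self.x_ddot)):
            raise ValueError("non-finite task command")


def task_command(est: TaskState, goals: ActiveSet) -> TaskCommand:
    """Critically-damped point-attractor command on the active tasks."""
    x_ddot = np.where(
        goals.mask,
        (-goals.damping * est.x_dot - goals.stiffness * (est.x - goals.target))
        / goals.mass,
        0.0,
    )
    return TaskCommand(x_ddot)


def task_state_estimate(
    artic_est: ArticulatoryState,
    geometry: Geometry = DEFAULT_GEOMETRY,
    forward: Callable[[np.ndarray], np.ndarray] | None = None,
    jac: Callable[[np.ndarray], np.ndarray] | None = None,
) -> TaskState:
    """Forward-kinematic task state estimate x̃ = f(ã), ẋ̃ = J(ã) ȧ̃.

    ``forward``/``jac`` allow substituting a test double for the
    kinematic map; by default the surrogate geometry is used.
    """
    f = forward if forward is not None else (lambda a: forward_kinematics(a, geometry))
    Jf = jac if jac is not None else (lambda a: jacobian(a, geometry))
    x = f(artic_est.a)
    x_dot = Jf(artic_est.a) @ artic_est.a_dot
    return TaskState(np.asarray(x, dtype=float), np.asarray(x_dot, dtype=float))
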