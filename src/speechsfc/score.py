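"""Gestural scores: timed activation of constriction-task goals.

A *gesture* is a critically damped second-order point attractor on one
task variable (e.g. "close the lips"), active on a half-open time interval
``[onset, offset)``.  A *gestural score* is the set of gestures for an
utterance.  Scores are the input to the simulator; they are serialized as
small JSON documents::

    {"duration": 1.5,
     "gestures": [{"task": "TBCD", "target": 0.2, "mass": 1.0,
                   "stiffness": 40.0, "damping": "critical",
                   "onset": 0.0, "offset": 0.35}, ...]}

``"damping": "critical"`` resolves to ``b = 2*sqrt(m*k)`` at load time.
Overlapping gestures on the same task variable are rejected: gesture
blending is out of scope, so at most one gesture per task is active at any
time.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Union

import numpy as np

from .kinematics import N_TASKS, TASK_INDEX, TASKS


class ScoreParseError(ValueError):
    """Malformed score document (names the offending gesture/field)."""


class ScoreValidationError(ValueError):
    """Well-formed document violating a score invariant."""


@dataclass(frozen=True)
class GestureSpec:
    """One timed point-attractor goal on a single task variable."""

    task_variable: str
    target: float
    mass: float = 1.0
    stiffness: float = 400.0
    damping: Union[float, str] = "critical"
    onset: float = 0.0
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.task_variable not in TASK_INDEX:
            raise ScoreValidationError(
                f"unknown task variable {self.task_variable!r}; expected one of {TASKS}"
            )
        if not self.mass > 0:
            raise ScoreValidationError(f"gesture mass must be > 0, got {self.mass}")
        if not self.stiffness > 0:
            raise ScoreValidationError(f"gesture stiffness must be > 0, got {self.stiffness}")
        if self.onset < 0 or not self.offset > self.onset:
            raise ScoreValidationError(
                f"gesture interval must satisfy offset > onset >= 0, got "
                f"[{self.onset}, {self.offset})"
            )
        if isinstance(self.damping, str):
            if self.damping != "critical":
                raise ScoreValidationError(
                    f"damping must be a number or 'critical', got {self.damping!r}"
                )
            object.__setattr__(
                self, "damping", 2.0 * math.sqrt(self.mass * self.stiffness)
            )
        elif self.damping < 0:
            raise ScoreValidationError(f"damping must be >= 0, got {self.damping}")

    @property
    def omega(self) -> float:
        """Natural frequency sqrt(k/m) of the gesture's attractor, s^-1."""
        return math.sqrt(self.stiffness / self.mass)

    def contains(self, t: float) -> bool:
        """Half-open activation convention: active on [onset, offset)."""
        return self.onset <= t < self.offset


@dataclass(frozen=True)
class GesturalScore:
    """Ordered collection of gestures plus the utterance duration."""

    gestures: tuple[GestureSpec, ...]
    duration: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "gestures", tuple(self.gestures))
        if self.duration < 0:
            raise ScoreValidationError("duration must be >= 0")
        if self.gestures and self.duration < max(g.offset for g in self.gestures):
            raise ScoreValidationError("duration must cover every gesture offset")
        by_task: dict[str, list[GestureSpec]] = {}
        for g in self.gestures:
            by_task.setdefault(g.task_variable, []).append(g)
        for task, gs in by_task.items():
            gs = sorted(gs, key=lambda g: g.onset)
            for a, b in zip(gs, gs[1:]):
                if b.onset < a.offset:
                    raise ScoreValidationError(
                        f"overlapping gestures on task {task}: "
                        f"[{a.onset}, {a.offset}) and [{b.onset}, {b.offset})"
                    )

    def breakpoints(self) -> np.ndarray:
        """Sorted unique onset/offset times (activation is piecewise constant)."""
        times = {g.onset for g in self.gestures} | {g.offset for g in self.gestures}
        return np.array(sorted(times))

    def gestures_for(self, task: str) -> list[GestureSpec]:
        return [g for g in self.gestures if g.task_variable == task]


@dataclass
class ActiveSet:
    """Active-task snapshot at one instant.

    ``mask`` flags tasks with an active gesture; ``target``, ``mass``,
    ``damping``, ``stiffness`` hold the containing gesture's parameters on
    active entries and neutral defaults (target 0, m=1, k=0, b=0, i.e. no
    task-space force) elsewhere.
    """

    mask: np.ndarray
    target: np.ndarray
    mass: np.ndarray
    damping: np.ndarray
    stiffness: np.ndarray


def active_set(score: GesturalScore, t: float) -> ActiveSet:
    """Query which gestures are active at time ``t`` (half-open intervals)."""
    if not 0.0 <= t <= score.duration:
        raise ValueError(f"t={t} outside [0, {score.duration}]")
    mask = np.zeros(N_TASKS, dtype=bool)
    target = np.zeros(N_TASKS)
    mass = np.ones(N_TASKS)
    damping = np.zeros(N_TASKS)
    stiffness = np.zeros(N_TASKS)
    for g in score.gestures:
        if g.contains(t):
            i = TASK_INDEX[g.task_variable]
            mask[i] = True
            target[i] = g.target
            mass[i] = g.mass
            damping[i] = g.damping
            stiffness[i] = g.stiffness
    return ActiveSet(mask, target, mass, damping, stiffness)


_REQUIRED_FIELDS = ("task", "target", "onset", "offset")


def parse_score(text: Union[str, dict]) -> GesturalScore:
    """Parse a JSON score document into a validated :class:`GesturalScore`."""
    if isinstance(text, dict):
        doc = text
    else:
        try:
            doc = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ScoreParseError(f"invalid JSON at line {exc.lineno}: {exc.msg}") from exc
    if not isinstance(doc, dict) or "duration" not in doc:
        raise ScoreParseError("score document must be an object with a 'duration' field")
    gestures = []
    for i, g in enumerate(doc.get("gestures", [])):
        for f in _REQUIRED_FIELDS:
            if f not in g:
                raise ScoreParseError(f"gesture #{i}: missing field {f!r}")
        gestures.append(
            GestureSpec(
                task_variable=g["task"],
                target=float(g["target"]),
                mass=float(g.get("mass", 1.0)),
                stiffness=float(g.get("stiffness", 400.0)),
                damping=g.get("damping", "critical"),
                onset=float(g["onset"]),
                offset=float(g["offset"]),
            )
        )
    return GesturalScore(tuple(gestures), float(doc["duration"]))


def write_score(score: GesturalScore) -> str:
    """Serialize a score back to its JSON document form."""
    doc = {
        "duration": score.duration,
        "gestures": [
            {
                "task": g.task_variable,
                "target": g.target,
                "mass": g.mass,
                "stiffness": g.stiffness,
                "damping": g.damping,
                "onset": g.onset,
                "offset": g.offset,
            }
            for g in score.gestures
        ],
    }
    return json.dumps(doc, indent=1)


# ---------------------------------------------------------------------------
# Bundled fixture scores.  Numeric targets are repository constants
# calibrated so that the default geometry and formant map produce vowel
# formants inside the map's calibration ranges; they are not transcriptions
# of any measured utterance.

_VOWELS = {
    # (TBCD target cm, TBCL target rad).  The schwa point is chosen where
    # the formant map carries F2/F3-independent information about F1
    # (away from the map's F1-gradient sign change near TBCL ~ 0.76 at
    # wide constrictions), so auditory feedback about F1 is usable there.
    "schwa": (0.30, 0.75),
    "a": (0.30, 0.15),
    "i": (0.40, 1.30),
}

_VOWEL_K = 400.0     # s^-2 -> omega = 20 s^-1, ~290 ms settle
_CONS_K = 400.0


def _vowel_gestures(vowel: str, onset: float, offset: float, k: float = _VOWEL_K):
    tbcd, tbcl = _VOWELS[vowel]
    return [
        GestureSpec("TBCD", tbcd, 1.0, k, "critical", onset, offset),
        GestureSpec("TBCL", tbcl, 1.0, k, "critical", onset, offset),
    ]


def vowel_sequence_score() -> GesturalScore:
    """[ǝ a i] vowel sequence: lower to [a], then raise and front to [i]."""
    gestures = (
        _vowel_gestures("schwa", 0.05, 0.45)
        + _vowel_gestures("a", 0.45, 0.95)
        + _vowel_gestures("i", 0.95, 1.45)
    )
    return GesturalScore(tuple(gestures), 1.5)


def sustained_schwa_score(duration: float = 1.5) -> GesturalScore:
    """Sustained [ǝ] used in the auditory-perturbation paradigm."""
    gestures = _vowel_gestures("schwa", 0.05, duration)
    return GesturalScore(tuple(gestures), duration)


def _vcv_score(consonant_task: str, consonant_target: float) -> GesturalScore:
    gestures = _vowel_gestures("a", 0.05, 1.25) + [
        GestureSpec(consonant_task, consonant_target, 1.0, _CONS_K, "critical", 0.55, 0.85)
    ]
    return GesturalScore(tuple(gestures), 1.3)


def aba_score() -> GesturalScore:
    """[aba]: vowel gestures plus a bilabial closure (LA -> 0)."""
    return _vcv_score("LA", 0.0)


def ada_score() -> GesturalScore:
    """[ada]: vowel gestures plus a tongue-tip closure (TTCD -> 0)."""
    return _vcv_score("TTCD", 0.05)


def mod_score() -> GesturalScore:
    """The word "mod": lip closure + velum opening + pharyngeal vowel
    gesture sharing an onset, followed by a tongue-tip closure."""
    gestures = (
        GestureSpec("LA", 0.0, 1.0, _CONS_K, "critical", 0.05, 0.35),
        GestureSpec("VEL", 0.5, 1.0, _CONS_K, "critical", 0.05, 0.35),
        GestureSpec("TBCD", 0.30, 1.0, _VOWEL_K, "critical", 0.05, 0.75),
        GestureSpec("TTCD", 0.05, 1.0, _CONS_K, "critical", 0.75, 1.05),
    )
    return GesturalScore(gestures, 1.2)
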