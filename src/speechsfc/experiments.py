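"""Closed-loop trials and the four simulation paradigms.

One control step of the loop:

1. the task state is estimated from the articulatory estimate
   (forward kinematics),
2. the task feedback law turns task error into task accelerations,
3. inverse kinematics turns those into a motor command,
4. the plant integrates the command (plus motor noise, plus any external
   perturbation) and emits noisy sensory signals,
5. the UKF observer fuses the efference copy of the command with the
   sensory signals into the next articulatory estimate.

The paradigms: feedback-deprivation conditions (both / somatosensory
only / auditory only / none), single-channel sensory-noise sweeps,
a mechanical jaw clamp during consonant closures, and a sustained-vowel
auditory (F1) perturbation with partial compensation as the outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import SimConfig
from .kinematics import (
    ARTIC_INDEX,
    ARTICULATORS,
    ArticulatoryState,
    N_ARTIC,
    RANGE_HIGH,
    RANGE_LOW,
    TASKS,
    articulatory_command,
    jacobian,
    jacobian_dot,
    tongue_center,
)
from .observer import ArticulatoryObserver, channel_mask
from .plant import NoiseConfig, PlantState, calibrate_norms, observe, step, synthesize
from .score import GesturalScore, active_set
from .tasks import TaskState, task_command, task_state_estimate
from .forward import ExactAuditoryMap

_CENTER = (RANGE_HIGH + RANGE_LOW) / 2.0
_EXTENT = RANGE_HIGH - RANGE_LOW


@dataclass
class TrialResult:
    """Per-step trajectory of one closed-loop trial."""

    t: np.ndarray            # (T,)
    positions: np.ndarray    # (T, 10) plant truth
    velocities: np.ndarray   # (T, 10)
    tasks: np.ndarray        # (T, 7) task variables of the truth
    formants: np.ndarray     # (T, 3) produced (noise-free) formants
    estimates: np.ndarray    # (T, 20) observer estimate [ã; ȧ̃]
    predictions: np.ndarray  # (T, 23) observer sensory prediction ŷ
    commands: np.ndarray     # (T, 10) motor commands
    jaw_clamped: np.ndarray  # (T,) bool
    f1_shift: np.ndarray     # (T,) Hz applied to perceived F1
    seed: int | None
    feedback: str
    divergent: bool = False
    labels: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-step table (the CSV trajectory format)."""
        cols: dict = {"t": self.t}
        for i, name in enumerate(ARTICULATORS):
            cols[name] = self.positions[:, i]
        for i, name in enumerate(ARTICULATORS):
            cols[f"{name}_dot"] = self.velocities[:, i]
        for i, name in enumerate(TASKS):
            cols[name] = self.tasks[:, i]
        for i, name in enumerate(("F1", "F2", "F3")):
            cols[name] = self.formants[:, i]
        for i in range(20):
            cols[f"est_{i}"] = self.estimates[:, i]
        for i in range(23):
            cols[f"yhat_{i}"] = self.predictions[:, i]
        cols["jaw_clamped"] = self.jaw_clamped.astype(int)
        cols["f1_shift"] = self.f1_shift
        return pd.DataFrame(cols)

    def tongue_center_xy(self) -> np.ndarray:
        return tongue_center(self.positions)


def calibrate(score: GesturalScore, config: SimConfig, auditory_map=None) -> SimConfig:
    """Fill in channel norms from a noiseless, unperturbed run of ``score``.

    The calibration trial runs the same closed loop with all noise levels
    and perturbations at zero; per-group RMS values of its positions,
    velocities, formants and commands become the channel norms.
    """
    quiet = replace(
        config,
        noise=NoiseConfig(0.0, 0.0, 0.0, config.noise.channel_norms),
        perturbation=replace(config.perturbation, jaw_clamp_onset=None, f1_shift_hz=0.0),
    )
    cal_map = auditory_map if auditory_map is not None else ExactAuditoryMap()
    trial = run_trial(score, quiet, seed=0, auditory_map=cal_map)
    norms = calibrate_norms(trial)
    return replace(config, noise=replace(config.noise, channel_norms=norms))


def run_trial(
    score: GesturalScore,
    config: SimConfig,
    seed: int | None,
    auditory_map,
    feedback: str | None = None,
) -> TrialResult:
    """Run one closed-loop trial; fully reproducible from (config, seed).

    Divergence (an estimate or true state far outside the articulator
    range box, or a non-finite value) flags the trial and stops the
    integration early rather than raising.
    """
    fb = feedback if feedback is not None else config.feedback
    mask = channel_mask(fb)
    dt = config.dt
    n_steps = int(round(score.duration / dt))
    rng = np.random.default_rng(seed)

    p_int, a_int, s_int = config.internal_noise_levels()
    observer = ArticulatoryObserver(
        auditory_map,
        dt=dt,
        process_noise=p_int,
        aud_noise=a_int,
        somat_noise=s_int,
        state_cov_init=config.ukf.state_cov_init,
        alpha=config.ukf.alpha,
        kappa=config.ukf.kappa,
        beta=config.ukf.beta,
        covariance_update=config.ukf.covariance_update,
    )

    state = PlantState.neutral()
    obs_state = observer.init_state(state.artic)
    pert = config.perturbation

    T = n_steps
    rec = {
        "t": np.zeros(T),
        "positions": np.zeros((T, N_ARTIC)),
        "velocities": np.zeros((T, N_ARTIC)),
        "tasks": np.zeros((T, len(TASKS))),
        "formants": np.zeros((T, 3)),
        "estimates": np.zeros((T, 20)),
        "predictions": np.zeros((T, 23)),
        "commands": np.zeros((T, N_ARTIC)),
        "jaw_clamped": np.zeros(T, dtype=bool),
        "f1_shift": np.zeros(T),
    }
    divergent = False
    k_done = T
    bound = config.divergence_factor * _EXTENT

    for k in range(T):
        t = k * dt
        clamp = (
            pert.jaw_clamp_onset is not None
            and pert.jaw_mode == "clamp"
            and t >= pert.jaw_clamp_onset
        )
        shift = pert.f1_shift_hz if (pert.f1_shift_hz and t >= pert.f1_shift_onset) else 0.0
        state = replace(state, jaw_clamped=clamp, f1_shift_hz=shift)

        est = ArticulatoryState.from_vector(obs_state.mean)
        est_clamped = ArticulatoryState(
            np.clip(est.a, RANGE_LOW, RANGE_HIGH), est.a_dot
        )
        goals = active_set(score, min(t, score.duration))
        task_est = task_state_estimate(est_clamped)
        tcmd = task_command(task_est, goals)
        J = jacobian(est_clamped.a)
        Jdot = jacobian_dot(est_clamped.a, est_clamped.a_dot)
        mcmd = articulatory_command(
            tcmd.x_ddot,
            est_clamped,
            mask=goals.mask,
            null_space=config.null_space,
            _jacobians=(J, Jdot),
        )

        rec["t"][k] = t
        rec["positions"][k] = state.artic.a
        rec["velocities"][k] = state.artic.a_dot
        truth_tasks = task_state_estimate(state.artic)
        rec["tasks"][k] = truth_tasks.x
        rec["formants"][k] = synthesize(state.artic.a)
        rec["estimates"][k] = obs_state.mean
        rec["commands"][k] = mcmd.a_ddot
        rec["jaw_clamped"][k] = clamp
        rec["f1_shift"][k] = shift

        plant_cmd = mcmd
        if (
            pert.jaw_clamp_onset is not None
            and pert.jaw_mode == "bias"
            and t >= pert.jaw_clamp_onset
        ):
            biased = np.array(mcmd.a_ddot)
            biased[ARTIC_INDEX["JA"]] += pert.jaw_bias_accel
            plant_cmd = replace(mcmd, a_ddot=biased)

        state = step(state, plant_cmd, config.noise, dt, rng)
        y = observe(state, config.noise, rng)
        obs_state = observer.step(obs_state, mcmd.a_ddot, y.stacked(), mask)
        yhat = obs_state.diagnostics.get("yhat")
        if yhat is not None:
            full = np.full(23, np.nan)
            full[mask] = yhat
            rec["predictions"][k] = full

        est_pos = obs_state.mean[:10]
        est_vel = obs_state.mean[10:]
        if (
            not np.all(np.isfinite(obs_state.mean))
            or np.any(np.abs(est_pos - _CENTER) > bound)
            or np.any(np.abs(est_vel) > 50.0 * bound)
        ):
            divergent = True
            k_done = k + 1
            break

    sl = slice(0, k_done)
    return TrialResult(
        t=rec["t"][sl],
        positions=rec["positions"][sl],
        velocities=rec["velocities"][sl],
        tasks=rec["tasks"][sl],
        formants=rec["formants"][sl],
        estimates=rec["estimates"][sl],
        predictions=rec["predictions"][sl],
        commands=rec["commands"][sl],
        jaw_clamped=rec["jaw_clamped"][sl],
        f1_shift=rec["f1_shift"][sl],
        seed=seed,
        feedback=fb,
        divergent=divergent,
        labels={"duration": score.duration},
    )


# ---------------------------------------------------------------------------
# Metrics


def prediction_error(trial: TrialResult) -> float:
    """Mean over the trial of ‖estimated − true articulator positions‖."""
    return float(
        np.mean(np.linalg.norm(trial.estimates[:, :10] - trial.positions, axis=1))
    )


@dataclass
class MetricsSummary:
    """Across-trial metrics for one experimental condition."""

    condition: str
    n_trials: int
    n_divergent: int
    endpoint_variability: float          # std of tongue centre at final sample, cm
    endpoint_ci: tuple[float, float]     # bootstrap 95% interval
    ca_variability: float                # std of condyle angle at endpoint, rad
    cl_variability: float                # std of condyle length at endpoint, cm
    prediction_error: float              # mean ‖â − a‖ over trials, cm
    extras: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {
            "condition": self.condition,
            "n_trials": self.n_trials,
            "n_divergent": self.n_divergent,
            "endpoint_variability": self.endpoint_variability,
            "endpoint_ci_low": self.endpoint_ci[0],
            "endpoint_ci_high": self.endpoint_ci[1],
            "ca_variability": self.ca_variability,
            "cl_variability": self.cl_variability,
            "prediction_error": self.prediction_error,
        }
        d.update(self.extras)
        return d


def _endpoint_stat(endpoints: np.ndarray) -> float:
    """Total tongue-centre spread: sqrt(var x + var y)."""
    return float(np.sqrt(np.var(endpoints[:, 0], ddof=1) + np.var(endpoints[:, 1], ddof=1)))


def _bootstrap_ci(
    endpoints: np.ndarray, rng: np.random.Generator, n_boot: int = 1000
) -> tuple[float, float]:
    n = len(endpoints)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        stats[b] = _endpoint_stat(endpoints[idx])
    return float(np.percentile(stats, 2.5)), float(np.percentile(stats, 97.5))


def summarize_condition(
    condition: str, trials: list[TrialResult], boot_seed: int = 0
) -> MetricsSummary:
    """Metrics over a set of trials; divergent trials are excluded and counted."""
    stable = [tr for tr in trials if not tr.divergent]
    n_div = len(trials) - len(stable)
    if len(stable) < 2:
        nan = float("nan")
        return MetricsSummary(condition, len(trials), n_div, nan, (nan, nan), nan, nan, nan)
    endpoints = np.stack([tr.tongue_center_xy()[-1] for tr in stable])
    ca = np.array([tr.positions[-1, ARTIC_INDEX["CA"]] for tr in stable])
    cl = np.array([tr.positions[-1, ARTIC_INDEX["CL"]] for tr in stable])
    rng = np.random.default_rng(boot_seed)
    return MetricsSummary(
        condition=condition,
        n_trials=len(trials),
        n_divergent=n_div,
        endpoint_variability=_endpoint_stat(endpoints),
        endpoint_ci=_bootstrap_ci(endpoints, rng),
        ca_variability=float(np.std(ca, ddof=1)),
        cl_variability=float(np.std(cl, ddof=1)),
        prediction_error=float(np.mean([prediction_error(tr) for tr in stable])),
    )


FEEDBACK_CONDITIONS = ("both", "somat", "aud", "none")


def feedback_conditions(
    score: GesturalScore,
    config: SimConfig,
    auditory_map,
    n_per_condition: int = 100,
    seed: int = 0,
) -> dict[str, MetricsSummary]:
    """Feedback-deprivation paradigm on a calibrated configuration.

    Runs ``n_per_condition`` trials for each of the four feedback
    conditions with matched seeds and summarizes endpoint variability,
    articulator variability and prediction error per condition.
    """
    out: dict[str, MetricsSummary] = {}
    for cond in FEEDBACK_CONDITIONS:
        trials = [
            run_trial(score, config, seed=seed + i, auditory_map=auditory_map, feedback=cond)
            for i in range(n_per_condition)
        ]
        out[cond] = summarize_condition(cond, trials, boot_seed=seed)
    return out


def noise_sweep(
    score: GesturalScore,
    config: SimConfig,
    auditory_map,
    channel: str,
    levels: tuple[float, ...] = (1e-1, 1e-2, 1e-3, 1e-4, 1e-5, 1e-6),
    n_per_level: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Single-channel noise sweep: the channel's true noise level and the
    observer's internal estimate of it vary in tandem; the other sensory
    channel is gated off entirely."""
    if channel not in ("aud", "somat"):
        raise ValueError("channel must be 'aud' or 'somat'")
    rows = []
    for level in levels:
        if channel == "aud":
            noise = replace(config.noise, aud_level=level)
        else:
            noise = replace(config.noise, somat_level=level)
        cfg = replace(config, noise=noise, feedback=channel)
        trials = [
            run_trial(score, cfg, seed=seed + i, auditory_map=auditory_map)
            for i in range(n_per_level)
        ]
        summary = summarize_condition(f"{channel}@{level:g}", trials, boot_seed=seed)
        row = summary.as_dict()
        row.update({"channel": channel, "level": level})
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class JawPerturbationResult:
    """Paired perturbed/unperturbed trials around one consonant closure."""

    consonant: str
    unperturbed: TrialResult
    perturbed: TrialResult
    clamp_onset: float
    upper_lip_lowering_diff: float   # cm; extra upper-lip lowering when clamped
    lower_lip_raising_diff: float    # cm
    la_closure_perturbed: float      # min lip aperture during gesture, cm
    closure_achieved: bool


def jaw_perturbation(
    score: GesturalScore,
    config: SimConfig,
    auditory_map,
    consonant_task: str,
    closure_criterion: float = 0.1,
    seed: int | None = None,
) -> JawPerturbationResult:
    """Clamp the jaw from the midpoint of the consonant gesture onward.

    The observer is not informed of the clamp; compensation (extra lip
    displacement for a bilabial, none for a tongue-tip consonant) must
    emerge from the corrected state estimates.
    """
    cons = [g for g in score.gestures if g.task_variable == consonant_task]
    if not cons:
        raise ValueError(f"score has no closure gesture on task {consonant_task!r}")
    g = cons[0]

    base = replace(config, perturbation=replace(config.perturbation, jaw_clamp_onset=None))
    tr0 = run_trial(score, base, seed=seed, auditory_map=auditory_map)

    # "midway through the closure": the instant the closing *movement* is
    # half complete in the unperturbed trial.  (At the midpoint of the
    # activation interval a critically damped gesture has already finished
    # its movement, so clamping there would probe nothing.)
    ti = TASKS.index(consonant_task)
    gest = (tr0.t >= g.onset) & (tr0.t < g.offset)
    x = tr0.tasks[:, ti]
    x_start = x[gest][0]
    dist = np.abs(x[gest] - g.target)
    half = np.nonzero(dist <= 0.5 * abs(x_start - g.target))[0]
    if half.size == 0 or abs(x_start - g.target) < 1e-9:
        raise ValueError(
            f"gesture on {consonant_task!r} has no closure movement to perturb"
        )
    onset = float(tr0.t[gest][half[0]])

    pert = replace(
        config,
        perturbation=replace(config.perturbation, jaw_clamp_onset=onset, jaw_mode=config.perturbation.jaw_mode),
    )
    tr1 = run_trial(score, pert, seed=seed, auditory_map=auditory_map)

    win = (tr0.t >= onset) & (tr0.t < g.offset)
    ulv = ARTIC_INDEX["ULV"]
    llv = ARTIC_INDEX["LLV"]
    ul_diff = float(np.max(tr0.positions[win, ulv] - tr1.positions[win, ulv]))
    ll_diff = float(np.max(tr1.positions[win, llv] - tr0.positions[win, llv]))
    gest_win = (tr1.t >= g.onset) & (tr1.t < g.offset)
    la = tr1.tasks[gest_win, TASKS.index("LA")]
    la_min = float(np.min(la)) if la.size else float("nan")
    return JawPerturbationResult(
        consonant=consonant_task,
        unperturbed=tr0,
        perturbed=tr1,
        clamp_onset=onset,
        upper_lip_lowering_diff=ul_diff,
        lower_lip_raising_diff=ll_diff,
        la_closure_perturbed=la_min,
        closure_achieved=bool(la_min < closure_criterion),
    )


@dataclass
class CompensationResult:
    """Auditory (F1) perturbation outcome."""

    shift_hz: float
    compensation_hz: float
    compensation_pct: float
    per_seed_hz: np.ndarray
    n_seeds: int


def f1_perturbation(
    score: GesturalScore,
    config: SimConfig,
    auditory_map,
    shift_hz: float = 100.0,
    n_seeds: int = 20,
    seed: int = 0,
    steady_fraction: float = 0.25,
) -> CompensationResult:
    """Sustained-vowel auditory perturbation.

    For each seed a perturbed and an unperturbed trial are run with the
    same noise realization seed; compensation is the drop in *produced*
    F1 (baseline minus perturbed) averaged over the final
    ``steady_fraction`` of the trial, then averaged over seeds.  Partial
    compensation (0 < compensation < shift) is the expected regime.
    """
    base_cfg = replace(
        config, perturbation=replace(config.perturbation, f1_shift_hz=0.0)
    )
    pert_cfg = replace(
        config, perturbation=replace(config.perturbation, f1_shift_hz=shift_hz)
    )
    per_seed = []
    for i in range(n_seeds):
        tr0 = run_trial(score, base_cfg, seed=seed + i, auditory_map=auditory_map)
        tr1 = run_trial(score, pert_cfg, seed=seed + i, auditory_map=auditory_map)
        if tr0.divergent or tr1.divergent:
            continue
        n0 = max(1, int(round(steady_fraction * len(tr0))))
        n1 = max(1, int(round(steady_fraction * len(tr1))))
        f1_base = float(np.mean(tr0.formants[-n0:, 0]))
        f1_pert = float(np.mean(tr1.formants[-n1:, 0]))
        per_seed.append(f1_base - f1_pert)
    per_seed = np.array(per_seed)
    comp = float(np.mean(per_seed)) if per_seed.size else float("nan")
    return CompensationResult(
        shift_hz=shift_hz,
        compensation_hz=comp,
        compensation_pct=100.0 * comp / shift_hz,
        per_seed_hz=per_seed,
        n_seeds=int(per_seed.size),
    )
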