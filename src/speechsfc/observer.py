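"""Augmented-state Unscented Kalman Filter observer.

The articulatory state estimator maintains an augmented vector
``s = [articulatory state (20); process noise v (10); observation noise
n (23)]`` with block covariance ``P = blkdiag(P_state, Q, R)``.  Sigma
points probe this distribution, are pushed through the process model
(the plant integrator, with the process-noise components added to the
efference copy) and the observation model (identity somatosensory branch
plus the learned auditory map, with observation-noise components added),
and the resulting cross- and innovation covariances yield the Kalman
gain that corrects the efference-copy prediction with sensory
prediction errors.

Sign convention: the innovation is the standard ``y − ŷ`` applied with
``+K``.  (Written with the opposite difference ``ŷ − y``, the same
correction would require ``−K``; pairing ``ŷ − y`` with ``+K`` — as a
literal reading of some presentations suggests — would drive the
estimate *away* from the observations, so the standard convention is
used and noted here.)

Feedback-channel gating is categorical: masked channels are removed from
the observation vector and covariance rows/columns entirely, rather than
being given infinite noise, so "no auditory feedback" really means the
channel does not exist for the filter.

Covariance policy: ``"static"`` (default) re-initializes the state-block
covariance every step — gains then reflect the configured prior
uncertainty throughout the trial; ``"filtered"`` propagates
``P ← P_prior − K P_yy Kᵀ`` across steps, which reduces exactly to the
classic Kalman filter on linear-Gaussian systems.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
from scipy import linalg as sla

N_STATE = 20   # articulatory positions + velocities
N_PROC = 10    # process (motor command) noise
N_OBS = 23     # 20 somatosensory + 3 auditory channels

SOMAT_CHANNELS = np.arange(20)
AUD_CHANNELS = np.arange(20, 23)


def channel_mask(feedback: str) -> np.ndarray:
    """Boolean mask over the 23 sensory channels for a feedback condition."""
    fb = feedback.lower()
    mask = np.zeros(N_OBS, dtype=bool)
    if fb in ("both", "somat", "somatosensory", "somat-only"):
        mask[SOMAT_CHANNELS] = True
    if fb in ("both", "aud", "auditory", "aud-only"):
        mask[AUD_CHANNELS] = True
    if fb not in ("both", "somat", "somatosensory", "somat-only", "aud",
                  "auditory", "aud-only", "none"):
        raise ValueError(f"unknown feedback condition {feedback!r}")
    return mask


@dataclass
class SigmaSet:
    """2L+1 sigma points with their mean and covariance weights."""

    points: np.ndarray   # (2L+1, L)
    wm: np.ndarray       # mean weights
    wc: np.ndarray       # covariance weights

    def mean(self) -> np.ndarray:
        return self.wm @ self.points

    def covariance(self) -> np.ndarray:
        d = self.points - self.mean()
        return (d * self.wc[:, None]).T @ d


def sigma_points(
    mean: np.ndarray,
    P: np.ndarray,
    lam: float,
    beta: float = 2.0,
    alpha: float | None = None,
) -> SigmaSet:
    """Scaled sigma points ``[ŝ, ŝ ± columns of sqrt((L+λ) P)]``.

    The matrix square root is a Cholesky factor; a symmetrization plus
    eigenvalue-floor repair is attempted once if P has drifted off the
    PSD cone through round-off.
    """
    mean = np.asarray(mean, dtype=float)
    P = np.asarray(P, dtype=float)
    L = mean.size
    scale = L + lam
    try:
        S = sla.cholesky(scale * P, lower=True)
    except sla.LinAlgError:
        S = sla.cholesky(scale * _repair_psd(P), lower=True)
    pts = np.empty((2 * L + 1, L))
    pts[0] = mean
    pts[1 : L + 1] = mean + S.T
    pts[L + 1 :] = mean - S.T
    wm = np.full(2 * L + 1, 1.0 / (2.0 * scale))
    wm[0] = lam / scale
    wc = wm.copy()
    if alpha is not None:
        wc[0] = wm[0] + (1.0 - alpha**2 + beta)
    return SigmaSet(pts, wm, wc)


def _repair_psd(P: np.ndarray, floor: float = 0.0) -> np.ndarray:
    Psym = 0.5 * (P + P.T)
    evals, evecs = np.linalg.eigh(Psym)
    if evals.min() < -1e-6 * max(1.0, evals.max()):
        raise np.linalg.LinAlgError(
            f"covariance is not PSD beyond round-off (min eigenvalue {evals.min():.3g})"
        )
    evals = np.clip(evals, max(floor, 1e-15 * max(1.0, evals.max())), None)
    return (evecs * evals) @ evecs.T


@dataclass
class ObserverState:
    """Mean and state-block covariance of the augmented observer."""

    mean: np.ndarray                 # (20,) articulatory estimate [ã; ȧ̃]
    P: np.ndarray                    # (20, 20) state covariance
    diagnostics: dict = field(default_factory=dict)

    def estimate_positions(self) -> np.ndarray:
        return self.mean[:10]

    def estimate_velocities(self) -> np.ndarray:
        return self.mean[10:]


class AugmentedUKF:
    """Generic augmented UKF over a process/observation function pair.

    Parameters
    ----------
    process_fn:
        ``f(X_state, X_v, u) -> X_state'`` vectorized over sigma points:
        ``X_state`` is ``(n_sigma, n_state)``, ``X_v`` the process-noise
        sigma components, ``u`` the control input.
    obs_fn:
        ``h(X_state, X_n) -> Y`` vectorized over sigma points, returning
        ``(n_sigma, n_obs)``.
    Q, R:
        Internal process/observation noise covariances (the observer's
        belief, which need not equal the true injected noise).
    P0:
        Initial state covariance.
    covariance_update:
        ``"static"`` resets P to ``P0`` every step; ``"filtered"``
        propagates the posterior ``P_prior − K P_yy Kᵀ``.
    """

    def __init__(
        self,
        process_fn: Callable,
        obs_fn: Callable,
        Q: np.ndarray,
        R: np.ndarray,
        P0: np.ndarray,
        alpha: float = 1e-3,
        kappa: float = 0.0,
        beta: float = 2.0,
        covariance_update: Literal["static", "filtered"] = "static",
    ) -> None:
        self.process_fn = process_fn
        self.obs_fn = obs_fn
        self.Q = np.atleast_2d(np.asarray(Q, dtype=float))
        self.R = np.atleast_2d(np.asarray(R, dtype=float))
        self.P0 = np.atleast_2d(np.asarray(P0, dtype=float))
        self.alpha = alpha
        self.kappa = kappa
        self.beta = beta
        if covariance_update not in ("static", "filtered"):
            raise ValueError("covariance_update must be 'static' or 'filtered'")
        self.covariance_update = covariance_update
        self.n_state = self.P0.shape[0]
        self.n_proc = self.Q.shape[0]
        self.n_obs = self.R.shape[0]

    # -- pieces, exposed for inspection and testing ------------------------
    def _lambda(self, L: int) -> float:
        return self.alpha**2 * (L + self.kappa) - L

    def augmented_sigma(self, mean: np.ndarray, P: np.ndarray) -> SigmaSet:
        L = self.n_state + self.n_proc + self.n_obs
        m_aug = np.concatenate([mean, np.zeros(self.n_proc + self.n_obs)])
        P_aug = sla.block_diag(P, self.Q, self.R)
        return sigma_points(m_aug, P_aug, self._lambda(L), self.beta, self.alpha)

    def ut_process(self, sigmas: SigmaSet, u) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Propagate state sigma points through F; return (â, P_prior, X')."""
        Xs = sigmas.points[:, : self.n_state]
        Xv = sigmas.points[:, self.n_state : self.n_state + self.n_proc]
        Xprop = self.process_fn(Xs, Xv, u)
        mean = sigmas.wm @ Xprop
        d = Xprop - mean
        P_prior = (d * sigmas.wc[:, None]).T @ d
        return mean, P_prior, Xprop

    def ut_observe(
        self, sigmas: SigmaSet, Xprop: np.ndarray, mask: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Push propagated sigma points through H on the active channels.

        Returns (ŷ, P_yy, P_ay) restricted to active channels.
        """
        Xn = sigmas.points[:, self.n_state + self.n_proc :]
        Y = self.obs_fn(Xprop, Xn)[:, mask]
        yhat = sigmas.wm @ Y
        dy = Y - yhat
        dx = Xprop - sigmas.wm @ Xprop
        P_yy = (dy * sigmas.wc[:, None]).T @ dy
        P_ay = (dx * sigmas.wc[:, None]).T @ dy
        return yhat, P_yy, P_ay

    @staticmethod
    def gain_and_correct(
        a_hat: np.ndarray,
        P_prior: np.ndarray,
        P_ay: np.ndarray,
        P_yy: np.ndarray,
        dy: np.ndarray,
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
        """K = P_ay P_yy⁻¹; ã = â + K Δy; P = P_prior − K P_yy Kᵀ.

        Ill-conditioned innovation covariances fall back to a
        pseudo-solve; the condition number is reported in diagnostics.
        """
        cond = float(np.linalg.cond(P_yy)) if P_yy.size else 0.0
        if P_yy.size == 0:
            return a_hat.copy(), P_prior, np.zeros((len(a_hat), 0)), cond
        if np.isfinite(cond) and cond < 1e12:
            K = sla.solve(P_yy, P_ay.T, assume_a="sym").T
        else:
            K = P_ay @ np.linalg.pinv(P_yy, hermitian=True)
        mean = a_hat + K @ dy
        P_post = P_prior - K @ P_yy @ K.T
        return mean, P_post, K, cond

    # -- one full step ------------------------------------------------------
    def step(
        self,
        state: ObserverState,
        u,
        y: np.ndarray | None,
        mask: np.ndarray | None = None,
    ) -> ObserverState:
        """Predict-correct cycle; with an all-false mask this is pure
        dead-reckoning on the efference copy."""
        if mask is None:
            mask = np.ones(self.n_obs, dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (self.n_obs,):
            raise ValueError(f"mask must have {self.n_obs} channels")
        P_in = self.P0 if self.covariance_update == "static" else state.P
        sigmas = self.augmented_sigma(state.mean, P_in)
        a_hat, P_prior, Xprop = self.ut_process(sigmas, u)
        if not mask.any():
            P_next = self.P0 if self.covariance_update == "static" else P_prior
            return ObserverState(a_hat, P_next, {"K_norm": 0.0, "cond": 0.0})
        y = np.asarray(y, dtype=float)
        if y.shape != (self.n_obs,):
            raise ValueError(f"observation must have {self.n_obs} channels")
        yhat, P_yy, P_ay = self.ut_observe(sigmas, Xprop, mask)
        dy = y[mask] - yhat
        mean, P_post, K, cond = self.gain_and_correct(a_hat, P_prior, P_ay, P_yy, dy)
        if self.covariance_update == "static":
            P_next = self.P0
        else:
            P_next = _repair_psd(P_post)
        diag = {
            "K_norm": float(np.linalg.norm(K)),
            "cond": cond,
            "innovation": dy,
            "K": K,
            "yhat": yhat,
        }
        return ObserverState(mean, P_next, diag)


# ---------------------------------------------------------------------------
# Speech-specific observer


class ArticulatoryObserver:
    """UKF observer over the articulatory plant.

    Process model: the plant integrator applied to each sigma point with
    the process-noise sigma components added to the efference copy of the
    motor command.  Observation model: identity on positions/velocities
    (somatosensory) and the learned auditory map on positions (auditory),
    with observation-noise sigma components added.

    Internal noise estimates default to the true noise *levels* — the
    internal covariance blocks are identity matrices scaled by the raw
    noise levels (process, auditory, somatosensory), and the state block
    starts at ``state_cov_init × I``.
    """

    def __init__(
        self,
        auditory_map,
        dt: float,
        process_noise: float = 1e-4,
        aud_noise: float = 1e-2,
        somat_noise: float = 1e-6,
        state_cov_init: float = 1e-2,
        alpha: float = 1e-3,
        kappa: float = 0.0,
        beta: float = 2.0,
        covariance_update: Literal["static", "filtered"] = "static",
    ) -> None:
        from .plant import integrate_articulators  # shared integrator

        self.auditory_map = auditory_map
        self.dt = dt

        def process_fn(Xs, Xv, u):
            a, v = Xs[:, :10], Xs[:, 10:]
            acc = u[None, :] + Xv
            a2, v2 = integrate_articulators(a, v, acc, dt, clamp=False)
            return np.concatenate([a2, v2], axis=1)

        def obs_fn(Xprop, Xn):
            if auditory_map is None or not getattr(auditory_map, "is_trained", False):
                from .forward import NotTrainedError

                raise NotTrainedError
            aud = auditory_map.predict(Xprop[:, :10])
            return np.concatenate([Xprop, aud], axis=1) + Xn

        self.ukf = AugmentedUKF(
            process_fn,
            obs_fn,
            Q=process_noise * np.eye(N_PROC),
            R=sla.block_diag(
                somat_noise * np.eye(20), aud_noise * np.eye(3)
            ),
            P0=state_cov_init * np.eye(N_STATE),
            alpha=alpha,
            kappa=kappa,
            beta=beta,
            covariance_update=covariance_update,
        )

    def init_state(self, artic_state) -> ObserverState:
        return ObserverState(np.array(artic_state.as_vector()), self.ukf.P0.copy())

    def step(
        self,
        state: ObserverState,
        efference: np.ndarray,
        observation: np.ndarray | None,
        mask: np.ndarray,
    ) -> ObserverState:
        """One observer cycle: efference from the previous control step,
        the current (possibly perturbed) sensory frame, and the feedback
        gating mask."""
        return self.ukf.step(state, np.asarray(efference, dtype=float), observation, mask)
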