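"""The observer's internal forward models.

*Process model* ``F``: predicts the next articulatory state from the
previous estimate and an efference copy of the motor command by running
the exact same integrator as the plant — with zero noise and no knowledge
of external perturbations.

*Observation model* ``H``: somatosensory predictions are the identity on
the predicted state; auditory predictions come from an
articulatory-to-formant map *learned* from internally generated
"babbling" data, standing in for a sensory mapping acquired during
development.

The auditory learner is a receptive-field local-linear ensemble in the
spirit of locally weighted projection regression: an input metric is
first adapted to the function's active subspace (estimated from local
gradients), receptive-field centres are placed by k-means in the adapted
metric, and each centre carries a Gaussian-weighted ridge-regularized
linear model; predictions blend the local models with normalized kernel
weights.  Inference is deterministic once fitted.
"""

from __future__ import annotations

from dataclasses import dataclass
import json

import numpy as np
from sklearn.cluster import MiniBatchKMeans
from sklearn.neighbors import NearestNeighbors

from .kinematics import ArticulatoryState, MotorCommand, N_ARTIC, RANGE_HIGH, RANGE_LOW
from .plant import DEFAULT_FORMANT_MAP, FormantMap, integrate_articulators, synthesize
from .kinematics import DEFAULT_GEOMETRY, Geometry


class NotTrainedError(RuntimeError):
    """Prediction requested from an untrained auditory map."""

    def __init__(self) -> None:
        super().__init__(
            "auditory map is not trained; call fit()/train_auditory_map() "
            "or load a serialized map first"
        )


def predict_state(
    prev_estimate: ArticulatoryState, efference: MotorCommand, dt: float
) -> ArticulatoryState:
    """Efference-copy state prediction: the plant integrator, noise-free.

    The observer shares the plant's integrator bit-for-bit but is ignorant
    of motor noise and of external perturbations (e.g. the jaw clamp), so
    its prediction diverges from the truth exactly when those act.  The
    range-box clamp is plant physics, not part of the internal model, so
    the prediction is unclamped (and smooth in the state).
    """
    a, v = integrate_articulators(
        prev_estimate.a, prev_estimate.a_dot, efference.a_ddot, dt, clamp=False
    )
    return ArticulatoryState(a, v)


def predict_sensory(predicted: ArticulatoryState, auditory_map) -> tuple[np.ndarray, np.ndarray]:
    """Sensory prediction ŷ = [ŷ_somat; ŷ_aud] for a predicted state.

    The somatosensory branch is the identity on the predicted positions
    and velocities; the auditory branch applies the (trained) map to the
    predicted positions.
    """
    if auditory_map is None or not getattr(auditory_map, "is_trained", False):
        raise NotTrainedError
    return predicted.as_vector(), np.asarray(auditory_map.predict(predicted.a))


# ---------------------------------------------------------------------------
# Babbling data


@dataclass
class BabbleSet:
    """Paired (articulator position, formant) samples with their seed."""

    positions: np.ndarray  # (n, 10)
    formants: np.ndarray   # (n, 3)
    seed: int

    def __len__(self) -> int:
        return len(self.positions)


def babble(
    n: int,
    seed: int,
    geometry: Geometry = DEFAULT_GEOMETRY,
    formant_map: FormantMap = DEFAULT_FORMANT_MAP,
    smoothing: float = 0.95,
) -> BabbleSet:
    """Exploratory articulator samples with noise-free formant targets.

    Articulator trajectories are low-pass-filtered random walks (an AR(1)
    smooth of white jumps, reflected at the range-box boundaries) so the
    workspace is covered densely but with realistic, smooth excursions.
    Targets are the plant's formants exactly (a noise-free teacher).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    half = (RANGE_HIGH - RANGE_LOW) / 2.0
    center = (RANGE_HIGH + RANGE_LOW) / 2.0
    # AR(1) with stationary std chosen to cover the box; reflected at walls
    stat_std = 0.55 * half
    innov = stat_std * np.sqrt(1.0 - smoothing**2)
    x = rng.normal(0.0, 1.0, size=N_ARTIC) * stat_std
    out = np.empty((n, N_ARTIC))
    for i in range(n):
        x = smoothing * x + rng.normal(0.0, 1.0, size=N_ARTIC) * innov
        out[i] = center + np.clip(x, -half, half)
    formants = synthesize(out, geometry, formant_map)
    return BabbleSet(out, formants, seed)


def train_test_split_babble(
    data: BabbleSet, heldout_fraction: float = 0.1, seed: int = 0
) -> tuple[BabbleSet, BabbleSet]:
    """Seeded 90/10 split into disjoint training and held-out sets."""
    rng = np.random.default_rng(seed)
    n = len(data)
    perm = rng.permutation(n)
    n_held = max(1, int(round(heldout_fraction * n)))
    held, train = perm[:n_held], perm[n_held:]
    return (
        BabbleSet(data.positions[train], data.formants[train], data.seed),
        BabbleSet(data.positions[held], data.formants[held], data.seed),
    )


# ---------------------------------------------------------------------------
# Learned auditory map


class AuditoryMap:
    """Receptive-field local-linear regression from articulator positions
    to formants, sklearn-style (``fit`` / ``predict``).

    Parameters
    ----------
    n_receptive_fields:
        Number of local linear models.
    bandwidth:
        Kernel width in adapted-metric units, relative to the typical
        centre spacing (larger = smoother, more bias).
    ridge:
        Ridge penalty of each local linear fit.
    metric_floor:
        Relative floor on the active-subspace metric eigenvalues; keeps
        irrelevant input directions from collapsing to zero weight
        entirely.
    """

    def __init__(
        self,
        n_receptive_fields: int = 600,
        bandwidth: float = 0.7,
        ridge: float = 1e-6,
        metric_floor: float = 1e-3,
        random_state: int = 0,
    ) -> None:
        self.n_receptive_fields = n_receptive_fields
        self.bandwidth = bandwidth
        self.ridge = ridge
        self.metric_floor = metric_floor
        self.random_state = random_state

    # -- estimator plumbing -------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_receptive_fields": self.n_receptive_fields,
            "bandwidth": self.bandwidth,
            "ridge": self.ridge,
            "metric_floor": self.metric_floor,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "AuditoryMap":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    @property
    def is_trained(self) -> bool:
        return hasattr(self, "coef_")

    # -- metric adaptation --------------------------------------------------
    def _fit_metric(self, X: np.ndarray, Y: np.ndarray, rng) -> None:
        """Active-subspace metric from local gradient estimates.

        Local weighted linear fits around a handful of anchor points give
        per-output gradients; the averaged outer product of the (output-
        normalized) gradients defines a Mahalanobis metric that stretches
        distances along directions the formants actually depend on.
        """
        n = len(X)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
        Z = X / scale
        k = min(max(200, n // 50), n)
        n_anchor = min(48, n)
        anchors = rng.choice(n, size=n_anchor, replace=False)
        nn = NearestNeighbors(n_neighbors=k).fit(Z)
        _, idx = nn.kneighbors(Z[anchors])
        ystd = Y.std(axis=0)
        ystd[ystd == 0] = 1.0
        A = np.zeros((X.shape[1], X.shape[1]))
        for row in idx:
            Zi = Z[row] - Z[row].mean(axis=0)
            Yi = (Y[row] - Y[row].mean(axis=0)) / ystd
            G, *_ = np.linalg.lstsq(
                Zi.T @ Zi + 1e-8 * np.eye(X.shape[1]), Zi.T @ Yi, rcond=None
            )
            A += G @ G.T
        A /= n_anchor
        evals, evecs = np.linalg.eigh(A)
        evals = np.maximum(evals, self.metric_floor * evals.max())
        # transform to whitened active-subspace coordinates
        self._input_scale_ = scale
        self._metric_transform_ = evecs * np.sqrt(evals)  # columns scaled

    def _to_metric(self, X: np.ndarray) -> np.ndarray:
        return (X / self._input_scale_) @ self._metric_transform_

    # -- fitting ------------------------------------------------------------
    def fit(self, X: np.ndarray, Y: np.ndarray) -> "AuditoryMap":
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if X.ndim != 2 or X.shape[1] != N_ARTIC:
            raise ValueError(f"X must be (n, {N_ARTIC})")
        if Y.ndim != 2 or Y.shape[1] != 3 or len(Y) != len(X):
            raise ValueError("Y must be (n, 3) aligned with X")
        rng = np.random.default_rng(self.random_state)
        self._fit_metric(X, Y, rng)
        Z = self._to_metric(X)

        n_rf = min(self.n_receptive_fields, len(X))
        km = MiniBatchKMeans(
            n_clusters=n_rf,
            random_state=self.random_state,
            n_init=3,
            batch_size=4096,
        ).fit(Z)
        centers = km.cluster_centers_
        # kernel width from typical nearest-centre spacing
        nn = NearestNeighbors(n_neighbors=2).fit(centers)
        d, _ = nn.kneighbors(centers)
        self._width_ = self.bandwidth * float(np.median(d[:, 1]))
        self.centers_metric_ = centers

        d2 = _sqdist(Z, centers)
        W = np.exp(-0.5 * d2 / self._width_**2)
        coef = np.empty((n_rf, N_ARTIC + 1, 3))
        Xa = np.concatenate([Z, np.ones((len(Z), 1))], axis=1)
        reg = self.ridge * np.eye(N_ARTIC + 1)
        reg[-1, -1] = 0.0  # don't shrink the intercept
        for j in range(n_rf):
            w = W[:, j]
            keep = w > 1e-4
            if keep.sum() < N_ARTIC + 2:
                keep = np.argsort(w)[-(N_ARTIC + 2):]
            Xw = Xa[keep] * w[keep][:, None]
            G = Xw.T @ Xa[keep] + reg
            coef[j] = np.linalg.solve(G, Xw.T @ Y[keep])
        self.coef_ = coef
        self.n_features_in_ = X.shape[1]
        # store centres in articulator units for diagnostics
        inv = np.linalg.inv(self._metric_transform_)
        self.centers_ = (centers @ inv) * self._input_scale_
        self.train_residual_ = float(np.mean(np.abs(self.predict(X) - Y)))
        return self

    # -- inference ----------------------------------------------------------
    def predict(self, X: np.ndarray) -> np.ndarray:
        if not self.is_trained:
            raise NotTrainedError
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        X2 = X[None, :] if single else X
        Z = self._to_metric(X2)
        d2 = _sqdist(Z, self.centers_metric_)
        logw = -0.5 * d2 / self._width_**2
        logw -= logw.max(axis=1, keepdims=True)
        W = np.exp(logw)
        W /= W.sum(axis=1, keepdims=True)
        Xa = np.concatenate([Z, np.ones((len(Z), 1))], axis=1)
        # blend local model coefficients per query point, then evaluate once
        n_rf = len(self.coef_)
        blended = (W @ self.coef_.reshape(n_rf, -1)).reshape(len(Z), Xa.shape[1], 3)
        out = np.einsum("ni,nik->nk", Xa, blended)
        return out[0] if single else out

    # -- serialization ------------------------------------------------------
    def to_json(self) -> str:
        if not self.is_trained:
            raise NotTrainedError
        payload = {
            "format": "speechsfc-auditory-map",
            "version": 1,
            "params": self.get_params(),
            "input_scale": self._input_scale_.tolist(),
            "metric_transform": self._metric_transform_.tolist(),
            "width": self._width_,
            "centers_metric": self.centers_metric_.tolist(),
            "coef": self.coef_.tolist(),
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "AuditoryMap":
        payload = json.loads(text)
        if payload.get("format") != "speechsfc-auditory-map":
            raise ValueError("not a serialized auditory map")
        obj = cls(**payload["params"])
        obj._input_scale_ = np.array(payload["input_scale"])
        obj._metric_transform_ = np.array(payload["metric_transform"])
        obj._width_ = float(payload["width"])
        obj.centers_metric_ = np.array(payload["centers_metric"])
        obj.coef_ = np.array(payload["coef"])
        obj.n_features_in_ = N_ARTIC
        inv = np.linalg.inv(obj._metric_transform_)
        obj.centers_ = (obj.centers_metric_ @ inv) * obj._input_scale_
        return obj


class ExactAuditoryMap:
    """A 'perfect' observation model: the plant's own formant map.

    Useful as an oracle in closed-loop self-consistency checks; the
    simulator normally runs with the learned :class:`AuditoryMap`.
    """

    def __init__(
        self,
        geometry: Geometry = DEFAULT_GEOMETRY,
        formant_map: FormantMap = DEFAULT_FORMANT_MAP,
    ) -> None:
        self.geometry = geometry
        self.formant_map = formant_map
        self.is_trained = True

    def predict(self, X: np.ndarray) -> np.ndarray:
        return synthesize(np.asarray(X, dtype=float), self.geometry, self.formant_map)


def _sqdist(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise squared Euclidean distances, (n, m)."""
    return (
        np.sum(A**2, axis=1)[:, None]
        + np.sum(B**2, axis=1)[None, :]
        - 2.0 * A @ B.T
    )


def train_auditory_map(data: BabbleSet, **params) -> AuditoryMap:
    """Fit an :class:`AuditoryMap` on a babble set."""
    return AuditoryMap(**params).fit(data.positions, data.formants)


@dataclass
class FitSummary:
    """Held-out absolute-error summary per formant (Hz)."""

    mean_abs: np.ndarray  # (3,)
    std_abs: np.ndarray   # (3,)
    n: int

    def as_dict(self) -> dict:
        return {
            "mean_abs_f1": float(self.mean_abs[0]),
            "mean_abs_f2": float(self.mean_abs[1]),
            "mean_abs_f3": float(self.mean_abs[2]),
            "std_abs_f1": float(self.std_abs[0]),
            "std_abs_f2": float(self.std_abs[1]),
            "std_abs_f3": float(self.std_abs[2]),
            "n": self.n,
        }


def evaluate_fit(map_: AuditoryMap, heldout: BabbleSet, train: BabbleSet | None = None) -> FitSummary:
    """Mean/std absolute prediction error per formant on held-out data.

    If ``train`` is given, raises when the held-out set shares samples
    with it (evaluating on training data would overstate accuracy).
    """
    if train is not None and len(train) and len(heldout):
        tr = {tuple(row) for row in np.round(train.positions, 12)}
        overlap = sum(tuple(row) in tr for row in np.round(heldout.positions, 12))
        if overlap:
            raise ValueError(f"{overlap} held-out samples overlap the training set")
    err = np.abs(map_.predict(heldout.positions) - heldout.formants)
    return FitSummary(err.mean(axis=0), err.std(axis=0), len(heldout))
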