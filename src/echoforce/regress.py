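"""Ridge regression (batch and incremental), evaluation and cluster safety.

Per-finger force decoding is linear: g = w^T v for feature vector v. With
n training pairs stacked into X (n x d) and targets y, the ridge solution
is

    w = (X^T X + lambda I_d)^(-1) X^T y,     lambda = 1 by default.

All fingers share the same inputs X, hence the same regularized inverse
A = (X^T X + lambda I_d)^(-1); only the cross-moment columns b = X^T y
differ. :class:`RidgeModel` therefore stores one A (d x d) and one B
(d x k), with W = A B recomputed lazily. A new (x', y') pair updates the
model in O(d^2), independent of how many samples were absorbed, via the
Sherman-Morrison rank-one identity

    A' = A - (A x' x'^T A) / (1 + x'^T A x'),      b' = b + x' y'

which makes streaming (re)training exactly equivalent to refitting from
scratch on the concatenated data, up to floating-point round-off.

Accuracy is summarized by the RMS error normalized by the ground-truth
range (nRMSE). :func:`cross_validate` follows the train-on-a-fraction /
test-on-the-rest scheme with repeated reshuffles; :func:`evaluate_transfer`
fits on on-off extremes only and scores on graded data — the protocol's
central question. :func:`safety_matrix` quantifies how separated the
extreme-force feature clusters are.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .errors import (InvalidInputError, InvalidParameterError,
                     NormalizationError, NumericalDegeneracyError)
from .stimulus import FINGERS

#: symmetrize the stored inverse every this many rank-one updates
_SYMMETRIZE_EVERY = 1000


@dataclass
class RidgeModel:
    """Per-finger linear force decoders sharing one regularized inverse.

    ``A`` is maintained as the *inverse* (X^T X + lambda I)^(-1) so that
    rank-one updates are O(d^2); ``B`` holds the per-finger X^T y columns.
    An empty model (``n_seen == 0``) has A = I/lambda, B = 0 and predicts
    0 for every finger.
    """

    d: int
    k: int
    lam: float = 1.0
    A: np.ndarray = None
    B: np.ndarray = None
    n_seen: int = 0
    _W: np.ndarray | None = field(default=None, repr=False, compare=False)
    _updates_since_symmetrize: int = field(default=0, repr=False, compare=False)

    def __post_init__(self):
        if self.lam <= 0:
            raise InvalidParameterError(f"lambda must be positive, got {self.lam!r}")
        if self.A is None:
            self.A = np.eye(self.d) / self.lam
        if self.B is None:
            self.B = np.zeros((self.d, self.k))

    @property
    def W(self) -> np.ndarray:
        """Weight matrix A @ B (d x k), recomputed lazily after updates."""
        if self._W is None:
            self._W = self.A @ self.B
        return self._W

    def predict(self, v) -> np.ndarray:
        return predict(self, v)

    def partial_fit(self, x, y) -> "RidgeModel":
        return update_incremental(self, x, y)

    def copy(self) -> "RidgeModel":
        return RidgeModel(d=self.d, k=self.k, lam=self.lam, A=self.A.copy(),
                          B=self.B.copy(), n_seen=self.n_seen)


def _check_finite(name, arr):
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"{name} contains non-finite values")


def fit_ridge(X, Y, lam: float = 1.0) -> RidgeModel:
    """Batch ridge fit; Y may be (n,), (n, 1) or (n, k)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if lam <= 0:
        raise InvalidParameterError(f"lambda must be positive, got {lam!r}")
    if len(X) != len(Y):
        raise InvalidInputError("X and Y must have the same number of rows")
    if len(X) < 1:
        raise InvalidInputError("need at least one sample")
    _check_finite("X", X)
    _check_finite("Y", Y)
    d = X.shape[1]
    G = X.T @ X + lam * np.eye(d)
    # updates need the explicit inverse; solve against I via Cholesky (SPD)
    A = linalg.solve(G, np.eye(d), assume_a="pos")
    A = (A + A.T) / 2.0
    return RidgeModel(d=d, k=Y.shape[1], lam=lam, A=A, B=X.T @ Y, n_seen=len(X))


def update_incremental(model: RidgeModel, x, y) -> RidgeModel:
    """Absorb one (x', y') pair via a Sherman-Morrison rank-one update.

    Mutates and returns ``model``; cost is O(d^2) regardless of
    ``n_seen``. Periodically re-symmetrizes A to cap round-off drift.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.atleast_1d(np.asarray(y, dtype=float)).ravel()
    if x.shape != (model.d,):
        raise InvalidInputError(f"sample has dimension {x.shape[0]}, model {model.d}")
    if y.shape != (model.k,):
        raise InvalidInputError(f"target has dimension {y.shape[0]}, model {model.k}")
    _check_finite("x", x)
    _check_finite("y", y)

    Ax = model.A @ x
    denom = 1.0 + x @ Ax
    if denom <= 0:  # impossible for SPD A; guards numerical blow-up
        raise NumericalDegeneracyError(
            f"rank-one denominator 1 + x'Ax' = {denom} <= 0")
    model.A -= np.outer(Ax, Ax) / denom
    model.B += np.outer(x, y)
    model.n_seen += 1
    model._W = None
    model._updates_since_symmetrize += 1
    if model._updates_since_symmetrize >= _SYMMETRIZE_EVERY:
        model.A = (model.A + model.A.T) / 2.0
        model._updates_since_symmetrize = 0
    return model


def predict(model: RidgeModel, v) -> np.ndarray:
    """Predict per-finger forces for one feature vector or a stack of them."""
    v = np.asarray(v, dtype=float)
    if v.shape[-1] != model.d:
        raise InvalidInputError(
            f"feature dimension {v.shape[-1]} does not match model d={model.d}")
    return v @ model.W


def nrmse(pred, truth) -> float:
    """RMS error of ``pred`` vs ``truth``, normalized by the truth range."""
    pred = np.asarray(pred, dtype=float).ravel()
    truth = np.asarray(truth, dtype=float).ravel()
    if pred.shape != truth.shape or pred.size < 2:
        raise InvalidInputError("pred and truth must be equal-length, size >= 2")
    rng = truth.max() - truth.min()
    if rng == 0:
        raise NormalizationError("ground-truth range is zero; nRMSE undefined")
    return float(np.sqrt(np.mean((pred - truth) ** 2)) / rng)


@dataclass
class EvalReport:
    """Per-finger nRMSE summary of one evaluation."""

    fingers: tuple[str, ...]
    mean_nrmse: np.ndarray
    sd_nrmse: np.ndarray
    mode: str = "force"          # ground truth: "force" | "stimulus"
    phases: str = ""             # e.g. "OO1/GR2"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "finger": list(self.fingers),
            "mode": self.mode,
            "phase_pair": self.phases,
            "mean_nrmse": self.mean_nrmse,
            "sd_nrmse": self.sd_nrmse,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _per_finger_nrmse(pred, truth):
    k = truth.shape[1]
    out = np.full(k, np.nan)
    for j in range(k):
        rng = truth[:, j].max() - truth[:, j].min()
        if rng == 0:
            continue
        out[j] = nrmse(pred[:, j], truth[:, j])
    return out


def cross_validate(X, Y, train_frac: float = 0.1, reps: int = 50,
                   lam: float = 1.0, seed=None,
                   fingers: tuple[str, ...] | None = None,
                   mode: str = "force", phases: str = "") -> EvalReport:
    """Repeated random-split evaluation: fit on a fraction, test on the rest.

    Each repetition reshuffles the samples with a seed derived from the
    master seed by counter, fits on ``train_frac`` of them and records the
    per-finger nRMSE on the remainder; the report carries mean and SD over
    repetitions. Fingers whose test targets have zero range in a given
    repetition are skipped for that repetition with a warning.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, k = len(X), Y.shape[1]
    n_train = int(round(n * train_frac))
    if n_train < 1:
        raise InvalidParameterError(
            f"train_frac {train_frac} yields an empty training set for n={n}")
    if n_train >= n:
        raise InvalidParameterError("train_frac leaves no test samples")
    streams = np.random.SeedSequence(seed).spawn(reps)
    scores = np.full((reps, k), np.nan)
    for r in range(reps):
        perm = np.random.default_rng(streams[r]).permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        model = fit_ridge(X[tr], Y[tr], lam=lam)
        scores[r] = _per_finger_nrmse(predict(model, X[te]), Y[te])
        if np.any(np.isnan(scores[r])):
            warnings.warn(f"repetition {r}: a finger's test targets are "
                          "constant; fold skipped for that finger", stacklevel=2)
    fingers = fingers or FINGERS[:k]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        return EvalReport(fingers=tuple(fingers),
                          mean_nrmse=np.nanmean(scores, axis=0),
                          sd_nrmse=np.nanstd(scores, axis=0),
                          mode=mode, phases=phases)


def evaluate_transfer(train_X, train_Y, test_X, test_Y, lam: float = 1.0,
                      fingers: tuple[str, ...] | None = None,
                      mode: str = "force", phases: str = "OO/GR") -> EvalReport:
    """Fit once on on-off extremes, score per-finger nRMSE on graded data."""
    train_Y = np.asarray(train_Y, dtype=float)
    test_Y = np.asarray(test_Y, dtype=float)
    if train_Y.ndim == 1:
        train_Y = train_Y[:, None]
    if test_Y.ndim == 1:
        test_Y = test_Y[:, None]
    model = fit_ridge(train_X, train_Y, lam=lam)
    per_finger = _per_finger_nrmse(predict(model, np.asarray(test_X, float)),
                                   test_Y)
    k = test_Y.shape[1]
    fingers = fingers or FINGERS[:k]
    return EvalReport(fingers=tuple(fingers), mean_nrmse=per_finger,
                      sd_nrmse=np.zeros(k), mode=mode, phases=phases)


@dataclass
class ClusterSet:
    """Labeled groups of feature vectors (rest plus one group per finger)."""

    clusters: dict[str, np.ndarray]

    def __post_init__(self):
        dims = set()
        for label, arr in self.clusters.items():
            arr = np.atleast_2d(np.asarray(arr, dtype=float))
            if len(arr) == 0:
                raise InvalidInputError(f"cluster {label!r} is empty")
            self.clusters[label] = arr
            dims.add(arr.shape[1])
        if len(dims) > 1:
            raise InvalidInputError("clusters must share one feature dimension")

    @property
    def labels(self) -> list[str]:
        return list(self.clusters)

    def centroid(self, label) -> np.ndarray:
        return self.clusters[label].mean(axis=0)

    def sigma(self, label) -> np.ndarray:
        """Per-dimension sample standard deviation (n-1 convention)."""
        return self.clusters[label].std(axis=0, ddof=1)


def safety_matrix(clusters: ClusterSet) -> tuple[list[str], np.ndarray]:
    """Pairwise cluster-separation indices s_ij (as fractions).

    s_ij = max over dimensions of cluster i's standard deviation, divided
    by the Euclidean distance between the centroids of clusters i and j.
    Small values mean the extreme-force patterns are well separated (and
    so trivially classifiable). The index is asymmetric — the numerator
    uses cluster i's spread only. The diagonal is undefined (NaN);
    coincident centroids yield inf with a warning.
    """
    labels = clusters.labels
    if len(labels) < 2:
        raise InvalidInputError("need at least two clusters")
    for label in labels:
        if len(clusters.clusters[label]) < 2:
            raise InvalidInputError(f"cluster {label!r} needs >= 2 members")
    m = len(labels)
    S = np.full((m, m), np.nan)
    for i, li in enumerate(labels):
        sig_max = clusters.sigma(li).max()
        ci = clusters.centroid(li)
        for j, lj in enumerate(labels):
            if i == j:
                continue
            dist = np.linalg.norm(ci - clusters.centroid(lj))
            if dist == 0:
                warnings.warn(f"clusters {li!r} and {lj!r} have coincident "
                              "centroids; safety index infinite", stacklevel=2)
                S[i, j] = np.inf
            else:
                S[i, j] = sig_max / dist
    return labels, S
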