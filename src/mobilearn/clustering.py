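"""Time-series K-means over four-limb baseline-ratio curves.

Each infant is represented by a multivariate series: the baseline ratio of
all four limb roles (ConA, UncA, IpsiL, ContL) down-sampled to 1 Hz.  The
objective is the plain Euclidean K-means cost

    D = Σ_i Σ_j Σ_t δ_{i,j} (x_{j,t} − v_{i,t})²

summed over limbs and time with no limb weighting and no additional
scaling (the baseline ratio is already normalised per limb).  Lloyd
iterations start from a random assignment of subjects to clusters and stop
when assignments no longer change; the best of several random restarts by
D is returned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, InvalidSpecError
from .kinematics import LIMB_ROLES, RatioSeries

__all__ = [
    "FeatureMatrix",
    "ClusterModel",
    "build_features",
    "kmeans_timeseries",
    "label_clusters",
    "SEMANTIC_LABELS",
]

logger = logging.getLogger(__name__)

SEMANTIC_LABELS = (
    "no_increase",
    "arm_increase",
    "all_limb_increase",
    "arm_more_increase",
)


@dataclass
class FeatureMatrix:
    """Per-subject multivariate feature series, shape (n, 4, T)."""

    subjects: list[str]
    X: np.ndarray  # (n_subjects, 4 limb roles, T time points)
    t: np.ndarray  # (T,) feature timestamps (s)

    def __post_init__(self):
        if self.X.ndim != 3 or self.X.shape[1] != len(LIMB_ROLES):
            raise ValueError("X must have shape (n, 4, T)")
        if len(self.subjects) != self.X.shape[0]:
            raise ValueError("subject list does not match X")
        if not np.isfinite(self.X).all():
            raise ValueError("features contain non-finite values")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def flat(self) -> np.ndarray:
        """Subjects × concatenated (limb, time) vectors."""
        return self.X.reshape(self.n, -1)


@dataclass
class ClusterModel:
    """Fitted K-means model over a feature matrix."""

    k: int
    centres: np.ndarray  # (k, 4, T)
    labels: np.ndarray  # (n,) cluster index 0..k-1
    D: float  # sum of squared distances to assigned centres
    n_iter: int
    seed: int
    restarts: int
    t: np.ndarray

    def assignment_onehot(self) -> np.ndarray:
        out = np.zeros((self.k, len(self.labels)))
        out[self.labels, np.arange(len(self.labels))] = 1.0
        return out

    def recompute_objective(self, F: FeatureMatrix) -> float:
        """D recomputed from (assignment, centres, features)."""
        diff = F.flat() - self.centres.reshape(self.k, -1)[self.labels]
        return float((diff**2).sum())


def build_features(
    ratio_series: Mapping[str, Mapping[str, RatioSeries]],
    feature_hz: float = 1.0,
    duration: float = 720.0,
) -> FeatureMatrix:
    """Stack per-subject, per-limb-role ratio series down-sampled to 1 Hz.

    Down-sampling is decimation: the full-rate series is sampled at the
    integer-second window centres (values are taken where timestamps
    coincide; no averaging, no further normalisation).  Subjects whose
    series do not cover the full session are excluded with a logged
    reason.
    """
    step = 1.0 / feature_hz
    t_feat = np.arange(0.0, duration, step)
    subjects, rows = [], []
    for sid, roles in ratio_series.items():
        if any(r not in roles for r in LIMB_ROLES):
            logger.warning("excluding %s: missing limb role", sid)
            continue
        limb_rows = []
        ok = True
        for role in LIMB_ROLES:
            series = roles[role]
            if series.t[0] > t_feat[0] + 1e-9 or series.t[-1] < t_feat[-1] - 1e-9:
                # the first/last window centres may sit just inside the
                # recording because endpoint samples are consumed by the
                # central difference; nearest-sample lookup handles that.
                if series.t[0] > 1.0 or series.t[-1] < duration - 1.0:
                    logger.warning("excluding %s: incomplete coverage", sid)
                    ok = False
                    break
            idx = np.clip(
                np.round((t_feat - series.t[0]) / series.sampling_period).astype(int),
                0,
                len(series.t) - 1,
            )
            limb_rows.append(series.ratio[idx])
        if ok:
            subjects.append(sid)
            rows.append(np.stack(limb_rows))
    if not rows:
        raise InsufficientDataError("no subject had complete feature coverage")
    return FeatureMatrix(subjects=subjects, X=np.stack(rows), t=t_feat)


def _lloyd(X: np.ndarray, k: int, rng: np.random.Generator, max_iter: int):
    """One K-means run from a random assignment.  Returns
    (labels, centres, D, n_iter)."""
    n = X.shape[0]
    labels = rng.integers(0, k, size=n)
    # guarantee every cluster starts non-empty when n >= k
    labels[rng.permutation(n)[:k]] = np.arange(k)
    centres = np.empty((k, X.shape[1]))
    prev_D = np.inf
    for it in range(1, max_iter + 1):
        for i in range(k):
            members = labels == i
            if members.any():
                centres[i] = X[members].mean(axis=0)
            else:
                # empty-cluster repair: reseed at the point farthest from
                # its current centre (deterministic given the state)
                d_all = ((X - centres[labels]) ** 2).sum(axis=1)
                far = int(np.argmax(d_all))
                centres[i] = X[far]
                labels[far] = i
        d2 = ((X[:, None, :] - centres[None, :, :]) ** 2).sum(axis=2)
        new_labels = np.argmin(d2, axis=1)  # ties break to lowest index
        D = float(d2[np.arange(n), new_labels].sum())
        if D > prev_D + 1e-9 * max(prev_D, 1.0):
            raise AssertionError("K-means objective increased")
        if np.array_equal(new_labels, labels) and it > 1:
            return labels, centres, D, it
        labels = new_labels
        prev_D = D
    return labels, centres, prev_D, max_iter


def kmeans_timeseries(
    F: FeatureMatrix,
    k: int = 4,
    restarts: int = 10,
    max_iter: int = 300,
    seed: int = 0,
) -> ClusterModel:
    """Best-of-restarts Lloyd K-means on the flattened (limb × time)
    vectors; deterministic given the seed."""
    if k < 1 or F.n < k:
        raise InvalidSpecError(f"need n >= k >= 1, got n={F.n}, k={k}")
    X = F.flat()
    if k > 1 and np.allclose(X, X[0]):
        logger.warning("all subjects identical; clustering is degenerate")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(restarts):
        labels, centres, D, n_iter = _lloyd(X, k, rng, max_iter)
        if best is None or D < best[2]:
            best = (labels, centres, D, n_iter)
    labels, centres, D, n_iter = best
    # final centre refresh so centres are exactly the member means
    for i in range(k):
        members = labels == i
        if members.any():
            centres[i] = X[members].mean(axis=0)
    D = float(((X - centres[labels]) ** 2).sum())
    return ClusterModel(
        k=k,
        centres=centres.reshape(k, len(LIMB_ROLES), -1),
        labels=labels,
        D=D,
        n_iter=n_iter,
        seed=seed,
        restarts=restarts,
        t=F.t,
    )


def label_clusters(
    model: ClusterModel,
    play: tuple[float, float] = (120.0, 720.0),
    p5: tuple[float, float] = (600.0, 720.0),
    arm_threshold: float = 1.5,
    arm_more_threshold: float = 2.5,
    leg_threshold: float = 1.5,
) -> dict[int, str]:
    """Assign semantic archetype labels to fitted clusters.

    Rules on cluster-mean ratio curves, in priority order
    (arm_more > all_limb > arm > none):

    * ``arm_more_increase`` — ConA final-block mean is the largest across
      clusters and exceeds ``arm_more_threshold``;
    * ``all_limb_increase`` — both leg play means exceed ``leg_threshold``;
    * ``arm_increase`` — ConA play mean ≥ ``arm_threshold``;
    * ``no_increase`` — otherwise.
    """
    play_mask = (model.t >= play[0]) & (model.t < play[1])
    p5_mask = (model.t >= p5[0]) & (model.t < p5[1])
    con = LIMB_ROLES.index("ConA")
    ipsi = LIMB_ROLES.index("IpsiL")
    cont = LIMB_ROLES.index("ContL")

    con_play = model.centres[:, con, :][:, play_mask].mean(axis=1)
    con_p5 = model.centres[:, con, :][:, p5_mask].mean(axis=1)
    leg_play = np.minimum(
        model.centres[:, ipsi, :][:, play_mask].mean(axis=1),
        model.centres[:, cont, :][:, play_mask].mean(axis=1),
    )

    labels = {}
    top = int(np.argmax(con_p5))
    for i in range(model.k):
        if i == top and con_p5[i] > arm_more_threshold:
            labels[i] = "arm_more_increase"
        elif leg_play[i] > leg_threshold:
            labels[i] = "all_limb_increase"
        elif con_play[i] >= arm_threshold:
            labels[i] = "arm_increase"
        else:
            labels[i] = "no_increase"
    return labels
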