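"""Movement measures for the mobile paradigm.

Raw marker positions are turned into three scalar measures per limb:

* **instantaneous speed** ``V_t`` — the magnitude of the 3-D velocity,
  estimated with the central difference method;
* **displacement rate** ``V̄_t`` — the sliding mean of ``V_t`` over a
  ``±τ`` window (τ = 30 s by default, i.e. a 1-min window), a measure of
  movement quantity rather than of momentary velocity;
* **baseline ratio** — the displacement rate divided by its own mean over
  the baseline phase, so that a value of 1 means "as much movement as
  before the mobile was connected" and 1.5 is the conventional learning
  criterion.

Sessions are summarised in six 2-min blocks: B (baseline) and P1–P5
(successive 2-min windows of the play phase).

Conventions: positions in millimetres, time in seconds from recording
start, intervals half-open ``[start, end)``.  Near the recording edges the
sliding window is truncated to the available support and the mean is taken
over the samples actually present, so rate curves cover the full session.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DegenerateBaselineError, InsufficientDataError

__all__ = [
    "PositionSeries",
    "SpeedSeries",
    "RateSeries",
    "RatioSeries",
    "Session",
    "MARKERS",
    "LIMB_ROLES",
    "DEFAULT_BLOCKS",
    "instantaneous_speed",
    "displacement_rate",
    "baseline_ratio",
    "relabel_limbs",
    "block_means",
]

#: Anatomical marker names, in canonical file order.
MARKERS = ("left_wrist", "right_wrist", "left_ankle", "right_ankle")

#: Limb roles relative to the connected wrist: connected arm, unconnected
#: arm, ipsilateral leg (same side as the connected arm), contralateral leg.
LIMB_ROLES = ("ConA", "UncA", "IpsiL", "ContL")

#: Six 2-min analysis blocks (seconds, half-open).
DEFAULT_BLOCKS: dict[str, tuple[float, float]] = {
    "B": (0.0, 120.0),
    "P1": (120.0, 240.0),
    "P2": (240.0, 360.0),
    "P3": (360.0, 480.0),
    "P4": (480.0, 600.0),
    "P5": (600.0, 720.0),
}


def _as_1d(a) -> np.ndarray:
    return np.ascontiguousarray(np.asarray(a, dtype=float))


@dataclass
class PositionSeries:
    """Uniformly sampled 3-D marker positions (mm)."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __post_init__(self):
        self.t = _as_1d(self.t)
        self.x = _as_1d(self.x)
        self.y = _as_1d(self.y)
        self.z = _as_1d(self.z)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.z) == n):
            raise ValueError("coordinate arrays must share the timestamp length")
        if n >= 2:
            dt = np.diff(self.t)
            if not np.allclose(dt, dt[0], rtol=0, atol=1e-6):
                raise ValueError("sampling must be uniform")

    @property
    def sampling_period(self) -> float:
        if len(self.t) < 2:
            raise InsufficientDataError("need at least 2 samples for a period")
        return float(self.t[1] - self.t[0])

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class SpeedSeries:
    """Instantaneous 3-D speed (mm/s) at interior samples."""

    t: np.ndarray
    v: np.ndarray

    def __post_init__(self):
        self.t = _as_1d(self.t)
        self.v = _as_1d(self.v)

    @property
    def sampling_period(self) -> float:
        return float(self.t[1] - self.t[0])

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class RateSeries:
    """Displacement rate: ±tau sliding mean of speed (mm/s)."""

    t: np.ndarray
    rate: np.ndarray
    tau: float = 30.0

    def __post_init__(self):
        self.t = _as_1d(self.t)
        self.rate = _as_1d(self.rate)
        if self.tau <= 0:
            raise ValueError("tau must be positive")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class RatioSeries:
    """Baseline ratio (dimensionless) and the baseline mean it divides by."""

    t: np.ndarray
    ratio: np.ndarray
    baseline_mean: float

    def __post_init__(self):
        self.t = _as_1d(self.t)
        self.ratio = _as_1d(self.ratio)

    @property
    def sampling_period(self) -> float:
        return float(self.t[1] - self.t[0])

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class Session:
    """One infant's recording: four marker position series plus metadata."""

    id: str
    age_group: str  # "2mo" | "3mo"
    connected_side: str  # "left" | "right"
    limbs: dict[str, PositionSeries]  # keyed by MARKERS entries
    phase_boundaries: tuple[float, float, float] = (0.0, 120.0, 720.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.age_group not in ("2mo", "3mo"):
            raise ValueError(f"unknown age group {self.age_group!r}")
        if self.connected_side not in ("left", "right"):
            raise ValueError(f"unknown connected side {self.connected_side!r}")
        missing = [m for m in MARKERS if m not in self.limbs]
        if missing:
            raise ValueError(f"session {self.id} missing limbs: {missing}")
        ts = [self.limbs[m].t for m in MARKERS]
        for other in ts[1:]:
            if len(other) != len(ts[0]) or not np.allclose(other, ts[0]):
                raise ValueError("all four limbs must share timestamps")

    @property
    def baseline(self) -> tuple[float, float]:
        return (self.phase_boundaries[0], self.phase_boundaries[1])

    @property
    def play(self) -> tuple[float, float]:
        return (self.phase_boundaries[1], self.phase_boundaries[2])


def instantaneous_speed(p: PositionSeries) -> SpeedSeries:
    """Instantaneous 3-D speed by the central difference method.

    ``V_t = sqrt(((x_{t+1}-x_{t-1})/2T)^2 + (y..)^2 + (z..)^2)`` for
    interior samples; the two endpoint samples are dropped.
    """
    if len(p) < 3:
        raise InsufficientDataError("central differences need at least 3 samples")
    T = p.sampling_period
    vx = (p.x[2:] - p.x[:-2]) / (2 * T)
    vy = (p.y[2:] - p.y[:-2]) / (2 * T)
    vz = (p.z[2:] - p.z[:-2]) / (2 * T)
    return SpeedSeries(t=p.t[1:-1], v=np.sqrt(vx**2 + vy**2 + vz**2))


def displacement_rate(v: SpeedSeries, tau: float = 30.0) -> RateSeries:
    """Sliding-window mean speed over ``[t−τ, t+τ]`` at every sample.

    Near the recording edges the window is truncated to the available
    support and normalised by the number of samples actually present, so
    the output covers the same timestamps as the input.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    n = len(v)
    if n < 2 or (v.t[-1] - v.t[0]) < 2 * tau:
        raise InsufficientDataError(
            f"series covers {v.t[-1] - v.t[0] if n else 0:.1f} s, "
            f"need at least 2*tau = {2 * tau:.1f} s"
        )
    period = v.sampling_period
    half = int(round(tau / period))
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    csum = np.concatenate([[0.0], np.cumsum(v.v)])
    rate = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)
    return RateSeries(t=v.t.copy(), rate=rate, tau=tau)


def baseline_divisor_mask(
    t: np.ndarray, baseline: tuple[float, float], tau: float
) -> np.ndarray:
    """Window centres whose full ``±τ`` window lies inside the baseline phase.

    Only these centres define the baseline mean, so play-phase movement
    cannot leak into the divisor through a straddling window.
    """
    lo, hi = baseline
    return (t >= lo + tau - 1e-9) & (t <= hi - tau + 1e-9)


def baseline_ratio(
    r: RateSeries, baseline: tuple[float, float] = (0.0, 120.0)
) -> RatioSeries:
    """Displacement rate divided by its baseline-phase mean.

    By construction the mean of the ratio over the baseline-defining window
    centres equals 1.
    """
    mask = baseline_divisor_mask(r.t, baseline, r.tau)
    if not mask.any():
        raise InsufficientDataError(
            "no window centres with full ±tau support inside the baseline phase"
        )
    divisor = float(r.rate[mask].mean())
    if divisor <= 0:
        raise DegenerateBaselineError(
            "baseline-phase mean displacement rate is zero"
        )
    return RatioSeries(t=r.t.copy(), ratio=r.rate / divisor, baseline_mean=divisor)


def relabel_limbs(s: Session) -> dict[str, str]:
    """Map anatomical markers to limb roles given the connected side.

    The connected wrist is ConA, the other wrist UncA; the ankle on the
    connected side is IpsiL, the other ContL.
    """
    if s.connected_side == "right":
        return {
            "right_wrist": "ConA",
            "left_wrist": "UncA",
            "right_ankle": "IpsiL",
            "left_ankle": "ContL",
        }
    return {
        "left_wrist": "ConA",
        "right_wrist": "UncA",
        "left_ankle": "IpsiL",
        "right_ankle": "ContL",
    }


def block_means(
    series: RateSeries | RatioSeries,
    blocks: Mapping[str, tuple[float, float]] = DEFAULT_BLOCKS,
) -> pd.Series:
    """Arithmetic mean of a series over each (half-open) analysis block."""
    values = series.rate if isinstance(series, RateSeries) else series.ratio
    out = {}
    for name, (lo, hi) in blocks.items():
        mask = (series.t >= lo) & (series.t < hi)
        if not mask.any():
            raise InsufficientDataError(f"block {name} [{lo}, {hi}) is empty")
        out[name] = float(values[mask].mean())
    return pd.Series(out, name="mean")


def session_block_table(
    session_id: str,
    role_rates: Mapping[str, RateSeries],
    role_ratios: Mapping[str, RatioSeries],
    blocks: Mapping[str, tuple[float, float]] = DEFAULT_BLOCKS,
) -> pd.DataFrame:
    """Tidy block-summary table for one session (one row per limb × block)."""
    rows = []
    for role in LIMB_ROLES:
        mr = block_means(role_rates[role], blocks)
        mq = block_means(role_ratios[role], blocks)
        for blk in blocks:
            rows.append(
                {
                    "session_id": session_id,
                    "limb_role": role,
                    "block": blk,
                    "mean_rate": mr[blk],
                    "mean_ratio": mq[blk],
                }
            )
    return pd.DataFrame(rows)
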