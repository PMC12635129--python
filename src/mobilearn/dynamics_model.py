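"""Infant–mobile coupled-oscillator model (Kelso–Fuchs).

The infant limb is a van der Pol oscillator with a Duffing (cubic
stiffness) term; the mobile is a damped harmonic oscillator forced by the
limb; a slow feedback variable δ raises the limb's oscillation frequency
while the mobile moves:

    ẍ + ẋ(γ + αx²) + x(ω₀² + δx²) = 0
    ÿ + εẏ + Ω₀² y = c·x
    δ̇ = a·y² − κ·δ

With γ < 0 < α the limb settles on a limit cycle — the model's picture of
spontaneous movement.  During the baseline phase the mobile is disconnected
(c = 0); during play c = 2 and the positive feedback loop x → y → δ → x
speeds the limb up, which is what the simulated "learning curve" measures.
ω₀ is the single parameter varied across infants: it sets the natural
frequency of spontaneous movement, and lower ω₀ leaves more headroom for
the feedback to raise the movement rate above baseline.

Integration is fixed-step classical Runge–Kutta (RK4) at step ``dt``
(default 0.01 model-time units).  One model time unit is mapped to one
second so simulated curves are directly comparable to the experimental
120 s baseline + 600 s play session.  A numba-compiled kernel is used when
numba is importable; a vectorised numpy kernel computes the identical
scheme otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import kinematics
from .errors import (
    DegenerateBaselineError,
    FittingFailureError,
    IntegrationFailureError,
)
from .kinematics import RatioSeries, SpeedSeries

__all__ = [
    "DynParams",
    "DynTrajectory",
    "DEFAULT_SCHEDULE",
    "CLUSTER_OMEGA0_RANGES",
    "simulate",
    "simulate_ensemble",
    "model_learning_curve",
    "simulate_cluster",
    "fit_omega0",
]

#: Baseline (c=0) then play (c=2) segment durations in model time units.
DEFAULT_SCHEDULE: tuple[tuple[float, float], ...] = ((120.0, 0.0), (600.0, 2.0))

#: Natural-frequency ranges fitted per behavioural cluster
#: (1: no increase … 4: arm more increase).  Each range has width 0.5.
CLUSTER_OMEGA0_RANGES: dict[int, tuple[float, float]] = {
    1: (2.8, 3.3),
    2: (0.9, 1.4),
    3: (1.4, 1.9),
    4: (0.3, 0.8),
}


@dataclass(frozen=True)
class DynParams:
    """Model parameters.  Defaults are the study values; only ω₀ varies
    across simulated infants."""

    gamma: float = -0.25  # linear damping (negative: energy injection)
    alpha: float = 1.0  # nonlinear damping
    omega0: float = 1.0  # limb natural frequency
    epsilon: float = 1.0  # mobile damping
    Omega0: float = 2.2  # mobile eigenfrequency
    a: float = 0.13  # feedback gain mobile → limb frequency
    kappa: float = 0.007  # δ decay rate
    dt: float = 0.01  # integration step (model time units)

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")


@dataclass
class DynTrajectory:
    """State history of one simulated infant–mobile pair."""

    t: np.ndarray
    x: np.ndarray
    xdot: np.ndarray
    y: np.ndarray
    ydot: np.ndarray
    delta: np.ndarray
    params: DynParams = field(default=DynParams())

    def __len__(self) -> int:
        return len(self.t)


def _rk4_numpy(state, om2, cvec, p: DynParams, n_steps, out):
    """Vectorised RK4 over an ensemble; state has shape (5, m)."""
    dt = p.dt
    gamma, alpha, eps, Om0sq, a, kappa = (
        p.gamma,
        p.alpha,
        p.epsilon,
        p.Omega0**2,
        p.a,
        p.kappa,
    )

    def deriv(s):
        x, xd, y, yd, d = s
        return np.stack(
            [
                xd,
                -xd * (gamma + alpha * x * x) - x * (om2 + d * x * x),
                yd,
                -eps * yd - Om0sq * y + cvec * x,
                a * y * y - kappa * d,
            ]
        )

    for i in range(n_steps):
        k1 = deriv(state)
        k2 = deriv(state + 0.5 * dt * k1)
        k3 = deriv(state + 0.5 * dt * k2)
        k4 = deriv(state + dt * k3)
        state = state + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        out[i] = state
    return state


try:  # pragma: no cover - exercised implicitly wherever numba is present
    from numba import njit

    @njit(cache=True)
    def _rk4_numba(state, om2, cvec, gamma, alpha, eps, Om0sq, a, kappa, dt, n_steps, out):
        m = state.shape[1]
        k = np.empty((4, 5, m))
        tmp = np.empty((5, m))
        for i in range(n_steps):
            for stage in range(4):
                if stage == 0:
                    src = state
                else:
                    f = 0.5 * dt if stage < 3 else dt
                    for q in range(5):
                        for j in range(m):
                            tmp[q, j] = state[q, j] + f * k[stage - 1, q, j]
                    src = tmp
                for j in range(m):
                    x = src[0, j]
                    xd = src[1, j]
                    y = src[2, j]
                    yd = src[3, j]
                    d = src[4, j]
                    k[stage, 0, j] = xd
                    k[stage, 1, j] = -xd * (gamma + alpha * x * x) - x * (
                        om2[j] + d * x * x
                    )
                    k[stage, 2, j] = yd
                    k[stage, 3, j] = -eps * yd - Om0sq * y + cvec[j] * x
                    k[stage, 4, j] = a * y * y - kappa * d
            for q in range(5):
                for j in range(m):
                    state[q, j] += (dt / 6.0) * (
                        k[0, q, j] + 2 * k[1, q, j] + 2 * k[2, q, j] + k[3, q, j]
                    )
            out[i] = state
        return state

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _run_segment(state, om2, cvec, p: DynParams, n_steps):
    out = np.empty((n_steps, 5, state.shape[1]))
    if _HAVE_NUMBA:
        state = _rk4_numba(
            np.ascontiguousarray(state),
            np.ascontiguousarray(om2),
            np.ascontiguousarray(cvec),
            p.gamma,
            p.alpha,
            p.epsilon,
            p.Omega0**2,
            p.a,
            p.kappa,
            p.dt,
            n_steps,
            out,
        )
    else:
        state = _rk4_numpy(state, om2, cvec, p, n_steps, out)
    return state, out


#: Default initial state (x, ẋ, y, ẏ, δ).
DEFAULT_INIT = (1.0, 0.0, 0.0, 0.0, 0.0)

#: Burn-in (model time units, c=0, discarded) so the limb starts the
#: baseline phase on its limit cycle rather than mid-transient.
DEFAULT_BURN_IN = 60.0


def simulate_ensemble(
    omega0: np.ndarray,
    params: DynParams = DynParams(),
    schedule=DEFAULT_SCHEDULE,
    coupling_gain: np.ndarray | None = None,
    init=DEFAULT_INIT,
    burn_in: float = DEFAULT_BURN_IN,
) -> DynTrajectory:
    """Integrate ``m`` infant–mobile pairs in parallel.

    Parameters
    ----------
    omega0 : array (m,)
        Natural frequency per ensemble member.
    schedule : sequence of (duration, c)
        Phase segments; state carries over between segments.
    coupling_gain : array (m,), optional
        Per-member multiplier on each segment's c (used by the synthetic
        generator to attenuate the coupling of unconnected limbs).
    init : 5-tuple
        Initial (x, ẋ, y, ẏ, δ); broadcast over members, or arrays of
        shape (m,) for per-member initial conditions.
    burn_in : float
        Pre-schedule c=0 segment that is integrated then discarded.

    Returns a trajectory whose arrays have shape (n_steps, m); ``t`` starts
    at 0 at the beginning of the first schedule segment.
    """
    omega0 = np.atleast_1d(np.asarray(omega0, dtype=float))
    m = omega0.shape[0]
    om2 = omega0**2
    gain = (
        np.ones(m)
        if coupling_gain is None
        else np.broadcast_to(np.asarray(coupling_gain, float), (m,)).copy()
    )
    state = np.empty((5, m))
    for q in range(5):
        state[q] = np.broadcast_to(np.asarray(init[q], float), (m,))

    if burn_in > 0:
        n_burn = int(round(burn_in / params.dt))
        state, _ = _run_segment(state, om2, np.zeros(m), params, n_burn)

    chunks = []
    t_chunks = []
    t_now = 0.0
    for duration, c in schedule:
        if duration <= 0:
            raise ValueError("segment durations must be positive")
        n_steps = int(round(duration / params.dt))
        if abs(n_steps * params.dt - duration) > 1e-9:
            raise ValueError("dt must divide every segment duration")
        state, out = _run_segment(state, om2, c * gain, params, n_steps)
        if not np.isfinite(state).all():
            bad = ~np.isfinite(out).all(axis=(1, 2))
            t_fail = t_now + (int(np.argmax(bad)) + 1) * params.dt
            raise IntegrationFailureError(
                f"non-finite state at t≈{t_fail:.2f}", t_fail=t_fail
            )
        chunks.append(out)
        t_chunks.append(t_now + params.dt * np.arange(1, n_steps + 1))
        t_now += duration

    hist = np.concatenate(chunks, axis=0)
    t = np.concatenate(t_chunks)
    return DynTrajectory(
        t=t,
        x=hist[:, 0],
        xdot=hist[:, 1],
        y=hist[:, 2],
        ydot=hist[:, 3],
        delta=hist[:, 4],
        params=params,
    )


def simulate(
    params: DynParams = DynParams(),
    schedule=DEFAULT_SCHEDULE,
    init=DEFAULT_INIT,
    burn_in: float = DEFAULT_BURN_IN,
) -> DynTrajectory:
    """Integrate a single infant–mobile pair (see :func:`simulate_ensemble`)."""
    traj = simulate_ensemble(
        np.array([params.omega0]), params, schedule, None, init, burn_in
    )
    return DynTrajectory(
        t=traj.t,
        x=traj.x[:, 0],
        xdot=traj.xdot[:, 0],
        y=traj.y[:, 0],
        ydot=traj.ydot[:, 0],
        delta=traj.delta[:, 0],
        params=params,
    )


def model_learning_curve(
    traj: DynTrajectory,
    tau: float = 30.0,
    baseline: tuple[float, float] = (0.0, 120.0),
    time_scale: float = 1.0,
) -> RatioSeries:
    """Simulated ConA learning curve from a trajectory.

    The model's movement-speed proxy is ``|ẋ(t)|``; it is run through the
    same displacement-rate and baseline-ratio operations as experimental
    speed series, so simulated and measured curves are computed identically.
    ``time_scale`` converts model time units to seconds (default 1:1).
    """
    xdot = traj.xdot
    if xdot.ndim != 1:
        raise ValueError("model_learning_curve expects a single trajectory")
    speed = SpeedSeries(t=traj.t * time_scale, v=np.abs(xdot))
    rate = kinematics.displacement_rate(speed, tau=tau)
    return kinematics.baseline_ratio(rate, baseline=baseline)


def _ensemble_curves(
    traj: DynTrajectory, tau: float, baseline: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Baseline-ratio curves for every ensemble member (vectorised Eq 2/3)."""
    speed = np.abs(traj.xdot)  # (n, m)
    n = speed.shape[0]
    period = float(traj.t[1] - traj.t[0])
    half = int(round(tau / period))
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    csum = np.concatenate([np.zeros((1, speed.shape[1])), np.cumsum(speed, axis=0)])
    rate = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)[:, None]
    mask = kinematics.baseline_divisor_mask(traj.t, baseline, tau)
    divisor = rate[mask].mean(axis=0)
    if np.any(divisor <= 0):
        raise DegenerateBaselineError("an ensemble member never moved in baseline")
    return traj.t, rate / divisor


@dataclass
class ClusterSimulation:
    """Ensemble of simulated learning curves for one cluster."""

    t: np.ndarray
    mean_curve: RatioSeries
    curves: np.ndarray  # (n_time, n_members)
    omega0: np.ndarray
    n_failed: int = 0


def simulate_cluster(
    n: int,
    omega0_range: tuple[float, float],
    params: DynParams = DynParams(),
    seed: int = 0,
    schedule=DEFAULT_SCHEDULE,
    tau: float = 30.0,
    baseline: tuple[float, float] = (0.0, 120.0),
    max_fail_frac: float = 0.1,
) -> ClusterSimulation:
    """Simulate ``n`` infants with ω₀ ~ Uniform(omega0_range) and average
    their learning curves, mirroring the per-cluster simulations that are
    compared with cluster-averaged experimental curves."""
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = omega0_range
    if not hi > lo:
        raise ValueError("omega0_range must have positive width")
    rng = np.random.default_rng(seed)
    omega0 = rng.uniform(lo, hi, size=n)
    try:
        traj = simulate_ensemble(omega0, params, schedule)
        t, curves = _ensemble_curves(traj, tau, baseline)
        failed = np.zeros(n, dtype=bool)
    except IntegrationFailureError:
        # Fall back to member-by-member integration so one blow-up does
        # not discard the whole ensemble.
        member_curves, t = [], None
        failed = np.zeros(n, dtype=bool)
        for i, w in enumerate(omega0):
            try:
                tr = simulate_ensemble(np.array([w]), params, schedule)
                t, cs = _ensemble_curves(tr, tau, baseline)
                member_curves.append(cs[:, 0])
            except IntegrationFailureError:
                failed[i] = True
        if failed.mean() > max_fail_frac:
            raise IntegrationFailureError(
                f"{int(failed.sum())}/{n} ensemble members failed to integrate"
            )
        curves = np.column_stack(member_curves)
    mean = curves.mean(axis=1)
    # mean of member ratios; its own baseline-window mean is 1 by linearity
    mean_series = RatioSeries(t=t, ratio=mean, baseline_mean=1.0)
    return ClusterSimulation(
        t=t,
        mean_curve=mean_series,
        curves=curves,
        omega0=omega0[~failed],
        n_failed=int(failed.sum()),
    )


@dataclass
class OmegaFit:
    """Grid-search result for the cluster-mean natural frequency."""

    best: float
    grid: np.ndarray
    losses: np.ndarray
    n: int
    seed: int


def fit_omega0(
    target: RatioSeries,
    params: DynParams = DynParams(),
    grid=None,
    n: int = 12,
    seed: int = 0,
    range_width: float = 0.5,
    play: tuple[float, float] = (120.0, 720.0),
) -> OmegaFit:
    """Fit the mean ω₀ of a cluster to a target mean learning curve.

    For each candidate mean ``m`` the cluster simulation is run with
    ω₀ ~ Uniform(m − width/2, m + width/2) and scored by the mean squared
    deviation from the target over play-phase points (compared at integer
    seconds).  Ties break toward the smaller candidate.
    """
    if grid is None:
        grid = np.arange(0.55, 3.06, 0.25)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("grid must be non-empty")

    sec = np.arange(math.ceil(play[0]), math.ceil(play[1]))
    tmask = (target.t >= play[0]) & (target.t < play[1])
    target_play = np.interp(sec, target.t[tmask], target.ratio[tmask])

    losses = np.full(grid.shape, np.nan)
    for i, m in enumerate(grid):
        rng_half = range_width / 2.0
        try:
            sim = simulate_cluster(
                n,
                (m - rng_half, m + rng_half),
                params=params,
                seed=seed,
            )
        except IntegrationFailureError:
            continue
        smask = (sim.t >= play[0]) & (sim.t < play[1])
        sim_play = np.interp(sec, sim.t[smask], sim.mean_curve.ratio[smask])
        losses[i] = float(np.mean((sim_play - target_play) ** 2))
    if np.isnan(losses).all():
        raise FittingFailureError("every candidate omega0 failed to integrate")
    best_idx = int(np.nanargmin(losses))  # nanargmin: first (smallest) on ties
    return OmegaFit(
        best=float(grid[best_idx]), grid=grid, losses=losses, n=n, seed=seed
    )
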