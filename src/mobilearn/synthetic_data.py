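"""Seedable synthetic sessions and cohorts for the mobile paradigm.

Real sessions are 60 Hz motion-capture recordings of four limb markers
over a 2-min baseline plus 10-min play phase.  The generator emulates them
by driving each limb with the infant–mobile oscillator model
(:mod:`mobilearn.dynamics_model`) and embedding the one-dimensional model
coordinate in 3-D:

    position(t) = rest_point + scale · x(t) · unit_direction + jitter

The downstream measures only consume speed magnitude, so the embedding
direction is immaterial; jitter is isotropic Gaussian measurement noise on
every coordinate.  Four archetypes mirror the behavioural clusters the
analysis recovers — their ω₀ ranges set how much the movement rate rises
during play, and their baseline levels reproduce the observation that the
"no increase" cluster starts from the most vigorous spontaneous movement.

All randomness descends from explicit integer seeds: a cohort's master
seed deterministically derives per-session seeds, and identical seeds give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import dynamics_model as dyn
from .errors import InvalidSpecError
from .kinematics import LIMB_ROLES, MARKERS, PositionSeries, Session, relabel_limbs

__all__ = [
    "ArchetypeSpec",
    "CohortSpec",
    "default_archetypes",
    "generate_session",
    "generate_cohort",
]

#: Fixed embedding direction per marker (unit vectors; direction is
#: immaterial for speed-based measures, distinct per limb for realism).
_DIRECTIONS = {
    "left_wrist": np.array([1.0, 1.0, 1.0]) / np.sqrt(3),
    "right_wrist": np.array([-1.0, 1.0, 1.0]) / np.sqrt(3),
    "left_ankle": np.array([1.0, -1.0, 1.0]) / np.sqrt(3),
    "right_ankle": np.array([-1.0, -1.0, 1.0]) / np.sqrt(3),
}

#: Nominal marker rest positions on the mat (mm).
_REST = {
    "left_wrist": np.array([150.0, 400.0, 80.0]),
    "right_wrist": np.array([-150.0, 400.0, 80.0]),
    "left_ankle": np.array([100.0, 80.0, 60.0]),
    "right_ankle": np.array([-100.0, 80.0, 60.0]),
}


@dataclass(frozen=True)
class ArchetypeSpec:
    """Generator recipe for one behavioural cluster.

    Parameters
    ----------
    cluster_id : int
        1 (no increase) … 4 (arm more increase).
    omega0_range : (float, float)
        Uniform range (width 0.5) for the limb oscillator's natural
        frequency; lower ranges produce larger play-phase increases.
    limb_gain : mapping role → float
        Dimensionless per-limb scale on the embedded amplitude.
    noise_sd : float
        SD (mm) of Gaussian positional jitter added per coordinate.
    baseline_level : float or None
        Target baseline displacement rate (mm/s).  When set, the embedding
        scale is chosen so each limb's baseline-phase mean speed equals
        ``limb_gain * baseline_level``; when None the model coordinate maps
        to millimetres as ``limb_gain`` alone (1:1 when limb_gain = 1).
    coupling_gain : mapping role → float
        Multiplier on the play-phase coupling c per limb role.  The
        connected arm always couples at full strength; attenuated values
        for other limbs produce the unconnected-limb increases seen in the
        "arm increase" and "all limb increase" archetypes.
    """

    cluster_id: int
    omega0_range: tuple[float, float]
    limb_gain: Mapping[str, float] = field(
        default_factory=lambda: {r: 1.0 for r in LIMB_ROLES}
    )
    noise_sd: float = 0.2
    baseline_level: float | None = None
    coupling_gain: Mapping[str, float] = field(
        default_factory=lambda: {"ConA": 1.0, "UncA": 1.0, "IpsiL": 0.0, "ContL": 0.0}
    )

    def __post_init__(self):
        lo, hi = self.omega0_range
        if not np.isclose(hi - lo, 0.5, atol=1e-9):
            raise InvalidSpecError("omega0_range must have width 0.5")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be >= 0")
        if any(self.limb_gain.get(r, 0.0) <= 0 for r in LIMB_ROLES):
            raise InvalidSpecError("limb_gain must be positive for all four limbs")


def default_archetypes() -> list[ArchetypeSpec]:
    """The four cluster archetypes with study-matched ω₀ ranges.

    Baseline levels (mm/s) follow the observed ordering: the "no increase"
    cluster moves most at baseline, the "arm (more) increase" clusters
    least.  Legs couple weakly only in the all-limb-increase archetype.
    """
    base = {1: 60.0, 2: 30.0, 3: 45.0, 4: 25.0}
    legs = {1: 0.0, 2: 0.0, 3: 0.5, 4: 0.0}
    return [
        ArchetypeSpec(
            cluster_id=c,
            omega0_range=dyn.CLUSTER_OMEGA0_RANGES[c],
            baseline_level=base[c],
            coupling_gain={
                "ConA": 1.0,
                "UncA": 1.0,
                "IpsiL": legs[c],
                "ContL": legs[c],
            },
        )
        for c in (1, 2, 3, 4)
    ]


@dataclass(frozen=True)
class CohortSpec:
    """Cohort composition.  Defaults mirror the study: 185 infants,
    102/47/27/9 per cluster and 90/95 per age group."""

    n_per_cluster: tuple[int, int, int, int] = (102, 47, 27, 9)
    n_per_age: tuple[int, int] = (90, 95)
    seed: int = 0
    sampling_rate: float = 60.0
    phase_durations: tuple[float, float] = (120.0, 600.0)

    def __post_init__(self):
        if any(n < 0 for n in self.n_per_cluster) or any(
            n < 0 for n in self.n_per_age
        ):
            raise InvalidSpecError("counts must be non-negative")
        if self.sampling_rate <= 0:
            raise InvalidSpecError("sampling_rate must be positive")
        if any(d <= 0 for d in self.phase_durations):
            raise InvalidSpecError("phase durations must be positive")
        if sum(self.n_per_cluster) != sum(self.n_per_age):
            raise InvalidSpecError(
                "n_per_cluster and n_per_age must sum to the same total"
            )


def generate_session(
    archetype: ArchetypeSpec,
    age_group: str,
    connected_side: str,
    seed: int,
    sampling_rate: float = 60.0,
    phase_durations: tuple[float, float] = (120.0, 600.0),
    params: dyn.DynParams = dyn.DynParams(),
    session_id: str | None = None,
    return_model: bool = False,
):
    """Generate one synthetic session.

    One ω₀ is drawn from the archetype's range and shared by all four
    limbs (the infant's intrinsic dynamics); limbs are decorrelated by
    randomised initial conditions and integrated as independent model
    trajectories whose play-phase coupling is scaled per limb role.

    With ``return_model=True`` returns ``(session, trajectory, scales)``
    — the underlying 4-member model trajectory (limbs in marker order)
    and the per-limb embedding scales — so downstream measures can be
    checked against the generating model.
    """
    if sampling_rate <= 0 or any(d <= 0 for d in phase_durations):
        raise InvalidSpecError("sampling rate and durations must be positive")
    rng = np.random.default_rng(seed)
    omega0 = rng.uniform(*archetype.omega0_range)
    base_dur, play_dur = phase_durations
    total = base_dur + play_dur

    session_id = session_id or f"synthetic-{archetype.cluster_id}-{seed}"
    # roles in marker order for this connected side
    role_of = _roles_for_side(connected_side)
    gains = np.array([archetype.coupling_gain.get(role_of[m], 0.0) for m in MARKERS])
    # randomised initial x and a per-limb burn-in jitter decorrelate phases
    init_x = rng.uniform(0.7, 1.3, size=4)
    traj = dyn.simulate_ensemble(
        np.full(4, omega0),
        params=params,
        schedule=((base_dur, 0.0), (play_dur, 2.0)),
        coupling_gain=gains,
        init=(init_x, np.zeros(4), np.zeros(4), np.zeros(4), np.zeros(4)),
        burn_in=dyn.DEFAULT_BURN_IN + float(rng.uniform(0, 10)),
    )

    # per-limb embedding scale (mm per model unit)
    scales = np.empty(4)
    base_mask = traj.t <= base_dur
    for i, marker in enumerate(MARKERS):
        g = archetype.limb_gain.get(role_of[marker], 1.0)
        if archetype.baseline_level is None:
            scales[i] = g
        else:
            mean_speed = np.abs(traj.xdot[base_mask, i]).mean()
            scales[i] = g * archetype.baseline_level / mean_speed

    # sample the model on the 60 Hz grid (linear interp; model dt = 0.01)
    t_out = np.arange(int(round(total * sampling_rate))) / sampling_rate
    limbs: dict[str, PositionSeries] = {}
    for i, marker in enumerate(MARKERS):
        x_model = np.interp(t_out, traj.t, traj.x[:, i])
        pos = _REST[marker][:, None] + scales[i] * x_model[None, :] * _DIRECTIONS[
            marker
        ][:, None]
        if archetype.noise_sd > 0:
            pos = pos + rng.normal(0.0, archetype.noise_sd, size=pos.shape)
        limbs[marker] = PositionSeries(t=t_out, x=pos[0], y=pos[1], z=pos[2])

    session = Session(
        id=session_id,
        age_group=age_group,
        connected_side=connected_side,
        limbs=limbs,
        phase_boundaries=(0.0, base_dur, total),
        meta={
            "true_cluster": archetype.cluster_id,
            "omega0": float(omega0),
            "seed": int(seed),
        },
    )
    if return_model:
        return session, traj, scales
    return session


def _roles_for_side(connected_side: str) -> dict[str, str]:
    if connected_side == "right":
        return {
            "right_wrist": "ConA",
            "left_wrist": "UncA",
            "right_ankle": "IpsiL",
            "left_ankle": "ContL",
        }
    if connected_side == "left":
        return {
            "left_wrist": "ConA",
            "right_wrist": "UncA",
            "left_ankle": "IpsiL",
            "right_ankle": "ContL",
        }
    raise InvalidSpecError(f"unknown connected side {connected_side!r}")


def generate_cohort(
    spec: CohortSpec,
    archetypes: Sequence[ArchetypeSpec] | None = None,
    params: dyn.DynParams = dyn.DynParams(),
) -> list[Session]:
    """Generate a full cohort of synthetic sessions.

    Sessions are tagged with their generating cluster in ``meta`` (ground
    truth for recovery tests).  Ages and connected sides are assigned
    deterministically: sides alternate within each cluster, and ages are
    interleaved across the cohort until each age-group quota is filled.
    Per-session seeds are spawned from the master seed.
    """
    if archetypes is None:
        archetypes = default_archetypes()
    if len(archetypes) != 4:
        raise InvalidSpecError("exactly four archetypes are required")

    total = sum(spec.n_per_cluster)
    # interleaved, quota-capped age assignment
    ages = []
    quota = list(spec.n_per_age)
    for i in range(total):
        pick = i % 2
        if quota[pick] == 0:
            pick = 1 - pick
        if quota[pick] == 0:
            raise InvalidSpecError("n_per_age quotas exhausted before cohort filled")
        ages.append("2mo" if pick == 0 else "3mo")
        quota[pick] -= 1

    ss = np.random.SeedSequence(spec.seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(total)]

    sessions: list[Session] = []
    idx = 0
    for arch, n in zip(archetypes, spec.n_per_cluster):
        for j in range(n):
            side = "right" if j % 2 == 0 else "left"
            s = generate_session(
                arch,
                age_group=ages[idx],
                connected_side=side,
                seed=child_seeds[idx],
                sampling_rate=spec.sampling_rate,
                phase_durations=spec.phase_durations,
                params=params,
                session_id=f"S{idx:03d}-c{arch.cluster_id}",
            )
            sessions.append(s)
            idx += 1
    return sessions
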