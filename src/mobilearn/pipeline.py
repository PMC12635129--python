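"""End-to-end orchestration, file formats and run configuration.

A full run goes: synthesise (or load) sessions → kinematic preprocessing
(speed, displacement rate, baseline ratio, block means) → time-series
K-means clustering → per-cluster model simulation and ω₀ fitting → group
statistics.  Every stage writes tidy CSV/JSON artifacts into the run
directory and the whole run is reproducible from the stored config and
master seed.

Session CSV dialect
-------------------
A comment header followed by one row per (limb, sample)::

    # session_id: S000-c1
    # age_group: 2mo
    # connected_side: right
    # rate_hz: 60
    limb,sample_index,x_mm,y_mm,z_mm
    LW,0,151.2,399.8,80.3
    ...

Limb codes: LW/RW left/right wrist, LA/RA left/right ankle.  Timestamps
are reconstructed as ``sample_index / rate_hz``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, dynamics_model as dyn, group_stats, kinematics, synthetic_data
from .errors import SessionParseError
from .kinematics import (
    DEFAULT_BLOCKS,
    LIMB_ROLES,
    MARKERS,
    PositionSeries,
    RateSeries,
    RatioSeries,
    Session,
)

__all__ = [
    "RunConfig",
    "read_session_csv",
    "write_session_csv",
    "process_session",
    "run_full",
]

logger = logging.getLogger(__name__)

_LIMB_CODES = {
    "LW": "left_wrist",
    "RW": "right_wrist",
    "LA": "left_ankle",
    "RA": "right_ankle",
}
_CODE_OF = {v: k for k, v in _LIMB_CODES.items()}


@dataclass
class RunConfig:
    """Serialisable configuration for a full pipeline run.

    Defaults are the study conditions: τ = 30 s windows on 60 Hz data,
    k = 4 clusters on 1 Hz features, the published model parameters with
    c = 0 (baseline) / c = 2 (play), and α = 0.01.
    """

    seed: int = 0
    n_per_cluster: tuple[int, int, int, int] = (102, 47, 27, 9)
    n_per_age: tuple[int, int] = (90, 95)
    sampling_rate: float = 60.0
    phase_durations: tuple[float, float] = (120.0, 600.0)
    tau: float = 30.0
    noise_sd: float = 0.2
    k: int = 4
    restarts: int = 10
    feature_hz: float = 1.0
    alpha: float = 0.01
    fit_grid_step: float = 0.25
    fit_n: int = 12
    sim_n_per_cluster: int | None = None  # None → use cluster sizes
    make_figures: bool = False
    model: dict = field(
        default_factory=lambda: dataclasses.asdict(dyn.DynParams())
    )

    def dyn_params(self) -> dyn.DynParams:
        return dyn.DynParams(**self.model)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("n_per_cluster", "n_per_age", "phase_durations"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def write_session_csv(session: Session, path: str | Path) -> None:
    """Write a session in the documented CSV dialect."""
    path = Path(path)
    rate = 1.0 / session.limbs[MARKERS[0]].sampling_period
    frames = []
    for marker in MARKERS:
        p = session.limbs[marker]
        frames.append(
            pd.DataFrame(
                {
                    "limb": _CODE_OF[marker],
                    "sample_index": np.arange(len(p)),
                    "x_mm": p.x,
                    "y_mm": p.y,
                    "z_mm": p.z,
                }
            )
        )
    body = pd.concat(frames, ignore_index=True)
    with open(path, "w") as fh:
        fh.write(f"# session_id: {session.id}\n")
        fh.write(f"# age_group: {session.age_group}\n")
        fh.write(f"# connected_side: {session.connected_side}\n")
        fh.write(f"# rate_hz: {rate:.6g}\n")
        body.to_csv(fh, index=False, float_format="%.6g")


def read_session_csv(path: str | Path) -> Session:
    """Read a session CSV, validating the dialect."""
    path = Path(path)
    header: dict[str, str] = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            try:
                key, val = line[1:].split(":", 1)
            except ValueError:
                raise SessionParseError(
                    f"{path}:{n_header}: malformed header line {line!r}"
                )
            header[key.strip()] = val.strip()
    for key in ("session_id", "age_group", "connected_side", "rate_hz"):
        if key not in header:
            raise SessionParseError(f"{path}: missing header field {key!r}")
    rate = float(header["rate_hz"])

    body = pd.read_csv(path, skiprows=n_header)
    expected_cols = ["limb", "sample_index", "x_mm", "y_mm", "z_mm"]
    if list(body.columns) != expected_cols:
        raise SessionParseError(
            f"{path}: expected columns {expected_cols}, got {list(body.columns)}"
        )
    unknown = set(body["limb"]) - set(_LIMB_CODES)
    if unknown:
        raise SessionParseError(f"{path}: unknown limb codes {sorted(unknown)}")

    limbs = {}
    for code, marker in _LIMB_CODES.items():
        sub = body[body["limb"] == code].sort_values("sample_index")
        if sub.empty:
            raise SessionParseError(f"{path}: missing limb {code}")
        idx = sub["sample_index"].to_numpy()
        if not np.array_equal(idx, np.arange(len(idx))):
            raise SessionParseError(f"{path}: non-contiguous samples for {code}")
        t = idx / rate
        limbs[marker] = PositionSeries(
            t=t,
            x=sub["x_mm"].to_numpy(),
            y=sub["y_mm"].to_numpy(),
            z=sub["z_mm"].to_numpy(),
        )
    total = len(limbs[MARKERS[0]]) / rate
    return Session(
        id=header["session_id"],
        age_group=header["age_group"],
        connected_side=header["connected_side"],
        limbs=limbs,
        phase_boundaries=(0.0, 120.0, round(total)),
    )


@dataclass
class ProcessedSession:
    """Kinematic measures for one session, keyed by limb role."""

    session: Session
    rates: dict[str, RateSeries]
    ratios: dict[str, RatioSeries]
    blocks: pd.DataFrame


def process_session(session: Session, tau: float = 30.0) -> ProcessedSession:
    """Speed → displacement rate → baseline ratio → block means, with
    limbs relabelled to roles relative to the connected side."""
    role_map = kinematics.relabel_limbs(session)
    rates, ratios = {}, {}
    for marker, role in role_map.items():
        speed = kinematics.instantaneous_speed(session.limbs[marker])
        rate = kinematics.displacement_rate(speed, tau=tau)
        rates[role] = rate
        ratios[role] = kinematics.baseline_ratio(rate, baseline=session.baseline)
    blocks = kinematics.session_block_table(session.id, rates, ratios)
    return ProcessedSession(session=session, rates=rates, ratios=ratios, blocks=blocks)


def tidy_series_table(processed: list[ProcessedSession]) -> pd.DataFrame:
    """Long-format rate/ratio table (session_id, limb_role, t_s, rate, ratio)."""
    frames = []
    for ps in processed:
        for role in LIMB_ROLES:
            frames.append(
                pd.DataFrame(
                    {
                        "session_id": ps.session.id,
                        "limb_role": role,
                        "t_s": ps.rates[role].t,
                        "rate_mm_s": ps.rates[role].rate,
                        "ratio": ps.ratios[role].ratio,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def _age_long_table(blocks: pd.DataFrame, sessions: dict[str, Session]) -> pd.DataFrame:
    con = blocks[blocks["limb_role"] == "ConA"]
    out = con.rename(columns={"mean_rate": "value", "block": "phase"})[
        ["session_id", "phase", "value"]
    ].copy()
    out["group"] = out["session_id"].map(lambda s: sessions[s].age_group)
    out = out.rename(columns={"session_id": "subject_id"})
    return out


def run_full(config: RunConfig, outdir: str | Path) -> dict:
    """Execute every stage and write artifacts; returns the summary dict.

    Artifacts: ``cohort_manifest.json``, ``block_summary.csv``,
    ``assignments.csv``, ``centres.csv``, ``cluster_run.json``,
    ``simulated_curves.csv``, ``omega0_fits.json``, ``anova_*.csv``,
    ``summary.json`` and (optionally) figures.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    params = config.dyn_params()

    # ---- synthesise -----------------------------------------------------
    logger.info("generating cohort (seed=%d)", config.seed)
    archetypes = [
        dataclasses.replace(a, noise_sd=config.noise_sd)
        for a in synthetic_data.default_archetypes()
    ]
    spec = synthetic_data.CohortSpec(
        n_per_cluster=config.n_per_cluster,
        n_per_age=config.n_per_age,
        seed=config.seed,
        sampling_rate=config.sampling_rate,
        phase_durations=config.phase_durations,
    )
    sessions = synthetic_data.generate_cohort(spec, archetypes, params=params)
    manifest = [
        {
            "session_id": s.id,
            "age_group": s.age_group,
            "connected_side": s.connected_side,
            "true_cluster": s.meta.get("true_cluster"),
            "seed": s.meta.get("seed"),
        }
        for s in sessions
    ]
    (outdir / "cohort_manifest.json").write_text(json.dumps(manifest, indent=1))

    # ---- preprocess -----------------------------------------------------
    logger.info("preprocessing %d sessions", len(sessions))
    processed = [process_session(s, tau=config.tau) for s in sessions]
    blocks = pd.concat([p.blocks for p in processed], ignore_index=True)
    blocks.to_csv(outdir / "block_summary.csv", index=False)

    # ---- cluster --------------------------------------------------------
    features = clustering.build_features(
        {p.session.id: p.ratios for p in processed},
        feature_hz=config.feature_hz,
        duration=sum(config.phase_durations),
    )
    model = clustering.kmeans_timeseries(
        features, k=config.k, restarts=config.restarts, seed=config.seed
    )
    labels = clustering.label_clusters(model)
    assign = pd.DataFrame(
        {
            "session_id": features.subjects,
            "cluster_id": model.labels + 1,
            "semantic_label": [labels[i] for i in model.labels],
        }
    )
    assign.to_csv(outdir / "assignments.csv", index=False)
    centre_rows = []
    for i in range(model.k):
        for r, role in enumerate(LIMB_ROLES):
            centre_rows.append(
                pd.DataFrame(
                    {
                        "cluster_id": i + 1,
                        "limb_role": role,
                        "t_s": model.t,
                        "value": model.centres[i, r],
                    }
                )
            )
    pd.concat(centre_rows, ignore_index=True).to_csv(
        outdir / "centres.csv", index=False
    )
    (outdir / "cluster_run.json").write_text(
        json.dumps(
            {
                "k": model.k,
                "seed": model.seed,
                "restarts": model.restarts,
                "D": model.D,
                "n_iter": model.n_iter,
                "labels": labels,
            },
            indent=1,
        )
    )

    # ---- simulate & fit -------------------------------------------------
    cluster_sizes = dict(zip(*np.unique(model.labels, return_counts=True)))
    sim_rows, fits = [], {}
    sem_to_arch = {
        "no_increase": 1,
        "arm_increase": 2,
        "all_limb_increase": 3,
        "arm_more_increase": 4,
    }
    con = LIMB_ROLES.index("ConA")
    for i in range(model.k):
        arch_id = sem_to_arch[labels[i]]
        n_sim = config.sim_n_per_cluster or int(cluster_sizes.get(i, 1))
        sim = dyn.simulate_cluster(
            n_sim,
            dyn.CLUSTER_OMEGA0_RANGES[arch_id],
            params=params,
            seed=config.seed + i,
        )
        sim_rows.append(
            pd.DataFrame(
                {
                    "cluster_id": i + 1,
                    "t_s": sim.t,
                    "ratio": sim.mean_curve.ratio,
                }
            )
        )
        target = RatioSeries(
            t=model.t, ratio=model.centres[i, con], baseline_mean=1.0
        )
        fit = dyn.fit_omega0(
            target,
            params=params,
            grid=np.arange(0.55, 3.06, config.fit_grid_step),
            n=config.fit_n,
            seed=config.seed + i,
        )
        fits[str(i + 1)] = {
            "semantic_label": labels[i],
            "best_mean_omega0": fit.best,
            "grid": fit.grid.tolist(),
            "losses": fit.losses.tolist(),
        }
    pd.concat(sim_rows, ignore_index=True).to_csv(
        outdir / "simulated_curves.csv", index=False
    )
    (outdir / "omega0_fits.json").write_text(json.dumps(fits, indent=1))

    # ---- group statistics ----------------------------------------------
    sess_by_id = {s.id: s for s in sessions}
    age_long = _age_long_table(blocks, sess_by_id)
    anova_age = group_stats.mixed_anova(age_long)
    anova_age.to_csv(outdir / "anova_age.csv", index=False)

    cluster_of = dict(zip(assign["session_id"], assign["cluster_id"]))
    cl_long = age_long.copy()
    cl_long["group"] = cl_long["subject_id"].map(cluster_of)
    anova_cluster = group_stats.mixed_anova(cl_long)
    anova_cluster.to_csv(outdir / "anova_cluster.csv", index=False)

    posthoc = group_stats.tukey_hsd_within(age_long)
    posthoc.to_csv(outdir / "tukey_phases.csv", index=False)

    learners = {}
    for p in processed:
        con_blocks = p.blocks[p.blocks["limb_role"] == "ConA"].set_index("block")[
            "mean_ratio"
        ]
        learners[p.session.id] = group_stats.learner_flag(con_blocks)

    summary = {
        "n_sessions": len(sessions),
        "cluster_sizes": {
            str(i + 1): int(cluster_sizes.get(i, 0)) for i in range(model.k)
        },
        "cluster_labels": {str(i + 1): labels[i] for i in range(model.k)},
        "kmeans_D": model.D,
        "fitted_omega0": {c: f["best_mean_omega0"] for c, f in fits.items()},
        "n_learners": int(sum(learners.values())),
        "anova_age": {
            r["source"]: group_stats.format_effect(r)
            for _, r in anova_age.iterrows()
        },
        "anova_cluster": {
            r["source"]: group_stats.format_effect(r)
            for _, r in anova_cluster.iterrows()
        },
        "seed": config.seed,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))

    if config.make_figures:
        _figures(outdir, model, sim_rows)
    return summary


def _figures(outdir: Path, model, sim_rows) -> None:
    """Cluster-centre learning curves with simulation overlays."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(model.k, 1, figsize=(7, 2.2 * model.k), sharex=True)
    axes = np.atleast_1d(axes)
    for i, ax in enumerate(axes):
        for r, role in enumerate(LIMB_ROLES):
            ax.plot(model.t, model.centres[i, r], label=role, lw=1)
        sim = sim_rows[i]
        ax.plot(sim["t_s"], sim["ratio"], "k--", lw=1, label="model ConA")
        ax.axvline(120, color="grey", lw=0.5)
        ax.set_ylabel(f"cluster {i + 1}")
    axes[0].legend(fontsize=7, ncol=5)
    axes[-1].set_xlabel("time (s)")
    fig.suptitle("Cluster-mean baseline ratios and model overlay")
    fig.tight_layout()
    fig.savefig(outdir / "cluster_curves.png", dpi=120)
    plt.close(fig)
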