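"""Synthetic cohorts of simulated path-drawing agents.

The generator gives the pipeline known ground truth: each agent owns a
dispersion scale (how unusual its paths are), a drawing speed, and a
"uniqueness cost" that charges extra time per unit of dispersion.  Paths
are drawn sequentially against the session time budget, so agents that
draw more dispersed (more unique) paths complete fewer of them — the
uniqueness-fluency trade-off emerges mechanically from the budget, not
from any hand-coded correlation.

Path shapes are cubic splines through waypoints on the start-end chord
whose lateral offsets are Normal(0, sigma^2); the bulge side is a fair
coin per path, so mirror-image pairs occur naturally.  Optional tremor is
an additive lateral sinusoid (default 4 Hz).  Condition labels (e.g., ON
vs OFF medication, drug vs placebo) act through three orthogonal knobs:
a multiplicative speed shift, a multiplicative dispersion shift, and a
"uniqueness boost" that widens paths *without* charging the time cost —
i.e., raises uniqueness at a fixed path duration, which is exactly the
residual drug effect the mixed model is meant to isolate.

The generator makes no claim of motor realism (no minimum-jerk, no Fitts'
law); it exists so every pipeline stage is testable without human data.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .model import Cohort, RawTrajectory, Session, TaskGeometry

__all__ = [
    "ConditionEffect",
    "AgentParams",
    "GeneratorConfig",
    "DESIGNS",
    "sample_agents",
    "simulate_path",
    "simulate_session",
    "simulate_cohort",
    "simulate_control_task",
]

DESIGNS = ("single_session", "ON_OFF_crossover", "drug_placebo_crossover")

# waypoint positions along the chord for the path spline; ends are pinned
_WAYPOINT_FRACTIONS = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
_N_INTERIOR = 3
_DENSE_SAMPLES = 400  # spline evaluation grid before arc-length timing


@dataclass(frozen=True)
class ConditionEffect:
    """Multiplicative/additive shifts a condition label applies to an agent."""

    speed_mult: float = 1.0
    sigma_mult: float = 1.0
    unique_boost: float = 0.0  # widens paths without charging drawing time


# study condition for the dopamine-like manipulation: faster drawing,
# narrower dispersion, plus a residual uniqueness gain at fixed duration
DOPAMINE_EFFECT = ConditionEffect(speed_mult=1.35, sigma_mult=0.7, unique_boost=0.25)


@dataclass(frozen=True)
class AgentParams:
    """One simulated participant."""

    agent_id: str
    dispersion_sigma: float  # mm, lateral spread of waypoint offsets
    speed: float  # mm/s drawing speed
    uniqueness_cost: float = 0.1  # s of extra time per mm of dispersion draw
    tremor_amplitude: float = 0.0  # mm
    tremor_frequency: float = 4.0  # Hz
    motivation: float = 0.0
    apathy: float = 0.0
    condition_effects: dict[str, ConditionEffect] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion_sigma < 0:
            raise ValueError("dispersion_sigma must be >= 0")
        if self.speed <= 0:
            raise ValueError("speed must be positive")
        if self.tremor_frequency <= 0:
            raise ValueError("tremor_frequency must be positive")

    def effect(self, condition: str) -> ConditionEffect:
        return self.condition_effects.get(condition, ConditionEffect())


@dataclass(frozen=True)
class GeneratorConfig:
    """Population-level settings for a simulated cohort.

    Defaults emulate the option-generation task conditions: a 240 s budget
    on the standard geometry, 60 Hz sampling, drawing speeds lognormal
    around ~80 mm/s, per-agent dispersion uniform on 5-55 mm, and a time
    cost of 0.1 s per mm of per-path dispersion.  Motivation is built to
    covary positively with speed and negatively with dispersion (motivated
    agents churn out many ordinary paths), mimicking the observed
    motivation-fluency / motivation-uniqueness associations.
    """

    n_agents: int = 30
    geometry: TaskGeometry = field(default_factory=TaskGeometry)
    sampling_rate: float = 60.0  # Hz
    speed_log_mean: float = math.log(80.0)
    speed_log_sd: float = 0.25
    sigma_range: tuple[float, float] = (5.0, 55.0)
    uniqueness_cost: float = 0.1
    tremor_amplitude: float = 0.0
    tremor_frequency: float = 4.0
    gap_s: float = 1.5  # pause between consecutive paths
    gap_jitter_s: float = 1.0
    motivation_noise_sd: float = 0.5
    irregular_sampling: bool = False
    master_seed: int = 0
    condition_effects: dict[str, ConditionEffect] | None = None

    def __post_init__(self) -> None:
        if self.n_agents < 1:
            raise ValueError("n_agents must be >= 1")
        if self.sampling_rate < 30:
            raise ValueError("sampling_rate must be >= 30 Hz")


def sample_agents(config: GeneratorConfig) -> list[AgentParams]:
    """Draw the agent population from the configured distributions."""
    ss = np.random.SeedSequence(config.master_seed)
    agent_seeds = ss.spawn(config.n_agents)
    rng = np.random.default_rng(ss.spawn(1)[0])
    log_speed = rng.normal(config.speed_log_mean, config.speed_log_sd, config.n_agents)
    sigma = rng.uniform(*config.sigma_range, config.n_agents)
    z_speed = (log_speed - config.speed_log_mean) / config.speed_log_sd
    lo, hi = config.sigma_range
    z_sigma = (sigma - (lo + hi) / 2) / ((hi - lo) / math.sqrt(12.0))
    motivation = (
        0.6 * z_speed
        - 0.6 * z_sigma
        + rng.normal(0.0, config.motivation_noise_sd, config.n_agents)
    )
    apathy = -motivation + rng.normal(0.0, 0.25, config.n_agents)
    effects = (
        config.condition_effects
        if config.condition_effects is not None
        else {"ON": DOPAMINE_EFFECT, "drug": DOPAMINE_EFFECT}
    )
    width = len(str(config.n_agents))
    return [
        AgentParams(
            agent_id=f"agent{idx + 1:0{width}d}",
            dispersion_sigma=float(sigma[idx]),
            speed=float(math.exp(log_speed[idx])),
            uniqueness_cost=config.uniqueness_cost,
            tremor_amplitude=config.tremor_amplitude,
            tremor_frequency=config.tremor_frequency,
            motivation=float(motivation[idx]),
            apathy=float(apathy[idx]),
            condition_effects=dict(effects),
            seed=int(agent_seeds[idx].generate_state(1)[0] % (2**31)),
        )
        for idx in range(config.n_agents)
    ]


def _chord_frame(geom: TaskGeometry) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    start = np.asarray(geom.start_center, dtype=float)
    end = np.asarray(geom.end_center, dtype=float)
    chord = end - start
    length = np.linalg.norm(chord)
    along = chord / length
    lateral = np.array([-along[1], along[0]])  # 90 deg left of travel
    return start, along * length, lateral


def simulate_path(
    agent: AgentParams,
    geom: TaskGeometry,
    path_index: int,
    rng: np.random.Generator,
    condition: str = "baseline",
    sampling_rate: float = 60.0,
    irregular_sampling: bool = False,
) -> tuple[RawTrajectory, float]:
    """Generate one drawn path; returns (trajectory, dispersion_draw).

    The trajectory's timestamps start at 0 and span the full path duration
    L/speed + uniqueness_cost * dispersion_draw, where the dispersion draw
    is the mean absolute waypoint offset (before any uniqueness boost), so
    more unusual paths take longer — the engine of the trade-off.
    """
    eff = agent.effect(condition)
    sigma = agent.dispersion_sigma * eff.sigma_mult
    speed = agent.speed * eff.speed_mult

    side = 1.0 if rng.random() < 0.5 else -1.0  # mirror side, fair coin
    offsets = side * rng.normal(0.0, 1.0, _N_INTERIOR) * sigma
    dispersion_draw = float(np.mean(np.abs(offsets)))
    phase = rng.uniform(0.0, 2.0 * math.pi)  # always drawn: keeps rng streams aligned

    lateral_offsets = np.zeros(len(_WAYPOINT_FRACTIONS))
    lateral_offsets[1:-1] = offsets * (1.0 + eff.unique_boost)

    start, chord_vec, lateral = _chord_frame(geom)
    waypoints = (
        start
        + _WAYPOINT_FRACTIONS[:, None] * chord_vec
        + lateral_offsets[:, None] * lateral
    )
    spline = CubicSpline(_WAYPOINT_FRACTIONS, waypoints, bc_type="natural")
    dense = spline(np.linspace(0.0, 1.0, _DENSE_SAMPLES))
    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    length = float(s[-1])

    duration = length / speed + agent.uniqueness_cost * dispersion_draw
    n_samples = max(2, int(round(duration * sampling_rate)) + 1)
    t = np.linspace(0.0, duration, n_samples)
    if irregular_sampling:
        jitter = rng.uniform(-0.2, 0.2, n_samples) / sampling_rate
        jitter[0] = jitter[-1] = 0.0
        t = np.sort(t + jitter)
    # constant effective arc speed: arc position proportional to time
    s_targets = length * t / duration
    xy = np.column_stack(
        [np.interp(s_targets, s, dense[:, 0]), np.interp(s_targets, s, dense[:, 1])]
    )
    if agent.tremor_amplitude > 0:
        xy = xy + (
            agent.tremor_amplitude
            * np.sin(2.0 * math.pi * agent.tremor_frequency * t + phase)
        )[:, None] * lateral
    traj = RawTrajectory(
        path_id=f"p{path_index:04d}",
        samples=np.column_stack([t, xy]),
        onset=0.0,
    )
    return traj, dispersion_draw


def simulate_session(
    agent: AgentParams,
    geom: TaskGeometry,
    condition: str = "baseline",
    session_index: int = 1,
    sampling_rate: float = 60.0,
    gap_s: float = 1.5,
    gap_jitter_s: float = 1.0,
    irregular_sampling: bool = False,
    rng: np.random.Generator | None = None,
) -> Session:
    """Draw paths sequentially until the next one would exceed the budget."""
    if rng is None:
        rng = np.random.default_rng((agent.seed, session_index))
    trajectories: list[RawTrajectory] = []
    clock = 0.0
    idx = 0
    while True:
        idx += 1
        gap = gap_s + rng.uniform(0.0, gap_jitter_s)
        traj, _ = simulate_path(
            agent,
            geom,
            idx,
            rng,
            condition=condition,
            sampling_rate=sampling_rate,
            irregular_sampling=irregular_sampling,
        )
        onset = clock + gap
        if onset + traj.duration > geom.time_limit:
            break
        shifted = traj.samples.copy()
        shifted[:, 0] += onset
        trajectories.append(
            RawTrajectory(path_id=traj.path_id, samples=shifted, onset=onset)
        )
        clock = onset + traj.duration
    return Session(
        participant_id=agent.agent_id,
        session_index=session_index,
        condition=condition,
        task_kind="option_generation",
        trajectories=trajectories,
        covariates={
            "motivation": agent.motivation,
            "apathy": agent.apathy,
            "dispersion_sigma": agent.dispersion_sigma,
            "speed": agent.speed,
        },
    )


def simulate_cohort(config: GeneratorConfig, design: str = "single_session") -> Cohort:
    """Simulate a full cohort under one of the study designs.

    ``single_session``: one baseline session per agent.  The crossover
    designs give each agent two counterbalanced sessions (baseline label
    OFF/placebo and treated label ON/drug with the configured condition
    effects); session order alternates across agents.
    """
    if design not in DESIGNS:
        raise ValueError(f"unknown design {design!r}; expected one of {DESIGNS}")
    agents = sample_agents(config)
    if design == "single_session":
        condition_pairs = [("baseline",)]
    elif design == "ON_OFF_crossover":
        condition_pairs = [("OFF", "ON")]
    else:
        condition_pairs = [("placebo", "drug")]
    sessions: list[Session] = []
    for a_idx, agent in enumerate(agents):
        conditions = list(condition_pairs[0])
        if len(conditions) == 2 and a_idx % 2 == 1:
            conditions = conditions[::-1]  # counterbalanced order
        for s_idx, condition in enumerate(conditions, start=1):
            sess = simulate_session(
                agent,
                config.geometry,
                condition=condition,
                session_index=s_idx,
                sampling_rate=config.sampling_rate,
                gap_s=config.gap_s,
                gap_jitter_s=config.gap_jitter_s,
                irregular_sampling=config.irregular_sampling,
            )
            sess.covariates["session_order"] = float(s_idx)
            sessions.append(sess)
    cohort = Cohort(
        sessions=sessions,
        geometry=config.geometry,
        provenance=f"simulated design={design} seed={config.master_seed}",
    )
    cohort.validate()
    return cohort


def simulate_control_task(
    agent: AgentParams,
    geom: TaskGeometry,
    task_kind: str,
    session_index: int = 1,
    condition: str = "baseline",
    sampling_rate: float = 60.0,
    rng: np.random.Generator | None = None,
) -> Session:
    """Simulate one of the three control tasks.

    motor_execution: ten near-straight start-to-end lines, untimed.
    cued_action: straight lines from the start to computer-chosen targets
    at the chord distance, random angle within +-90 deg of the task axis,
    90 s budget.  option_selection: like cued_action but the target is the
    agent's own pick among 24 equally spaced arc locations, 90 s budget.
    """
    if rng is None:
        rng = np.random.default_rng((agent.seed, 7, session_index))
    eff = agent.effect(condition)
    speed = agent.speed * eff.speed_mult
    start, chord_vec, lateral = _chord_frame(geom)
    chord_len = float(np.linalg.norm(chord_vec))
    axis_angle = math.atan2(chord_vec[1], chord_vec[0])

    def straight_path(idx: int, target: np.ndarray, onset: float) -> RawTrajectory:
        length = float(np.linalg.norm(target - start))
        duration = length / speed
        n = max(2, int(round(duration * sampling_rate)) + 1)
        t = np.linspace(0.0, duration, n)
        frac = (t / duration)[:, None]
        # tiny lateral wobble so paths are near- but not perfectly straight
        wobble = 0.5 * np.sin(math.pi * frac[:, 0]) * rng.normal(0.0, 1.0)
        xy = start + frac * (target - start) + wobble[:, None] * lateral
        xy[0], xy[-1] = start, target
        return RawTrajectory(
            path_id=f"p{idx:04d}",
            samples=np.column_stack([t + onset, xy]),
            onset=onset,
        )

    trajectories: list[RawTrajectory] = []
    if task_kind == "motor_execution":
        end = start + chord_vec
        clock = 0.0
        for idx in range(1, 11):
            onset = clock + 1.0 + rng.uniform(0.0, 0.5)
            traj = straight_path(idx, end, onset)
            trajectories.append(traj)
            clock = onset + traj.duration
    elif task_kind in ("cued_action", "option_selection"):
        budget = 90.0
        if task_kind == "option_selection":
            arc_angles = np.linspace(-math.pi / 2, math.pi / 2, 24)
        clock, idx = 0.0, 0
        while True:
            idx += 1
            if task_kind == "cued_action":
                rel = rng.uniform(-math.pi / 2, math.pi / 2)
            else:
                rel = float(arc_angles[rng.integers(0, 24)])
            ang = axis_angle + rel
            target = start + chord_len * np.array([math.cos(ang), math.sin(ang)])
            onset = clock + 1.0 + rng.uniform(0.0, 0.5)
            traj = straight_path(idx, target, onset)
            if onset + traj.duration > budget:
                break
            trajectories.append(traj)
            clock = onset + traj.duration
    else:
        raise ValueError(f"unsupported control task {task_kind!r}")
    return Session(
        participant_id=agent.agent_id,
        session_index=session_index,
        condition=condition,
        task_kind=task_kind,
        trajectories=trajectories,
        covariates={},
    )
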