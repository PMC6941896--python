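"""Closed-loop trial execution.

Each call (every 50 ms): synthesize the binaural echo train at the current
pose and gaze -> cochlear model per ear -> emission removal -> first-echo
detection -> strategy command -> discrete unicycle step -> collision check.

Collision handling mirrors the physical protocol: in the arena a collision
is recorded, the robot is turned to face directly away from the contacted
surface (nudged to 1 cm clearance) and the run resumes; in the corridor the
trial terminates on collision, on turning around, or on reaching the goal
line at the far end.

Every trial is fully deterministic given (environment, seed): a single seed
sequence is split into named streams for receiver noise, control
tie-breaks/random-walk draws, and initial-pose sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd

from . import acoustics, auditory, control
from .acoustics import BinauralGainModel, EmissionModel
from .auditory import CochlearParams, SonarReading
from .control import ControlCommand, KinematicLaws, DLALParams, RandomWalkParams
from .environments import (
    DEFAULT_ROBOT_RADIUS,
    Contact,
    Environment,
    check_collision,
    nearest_obstacle_distance,
)

__all__ = [
    "RobotState",
    "TrialConfig",
    "CollisionEvent",
    "TrialResult",
    "step_kinematics",
    "run_trial",
    "detect_turnaround",
    "run_experiment",
]


def _wrap_angle(deg: float) -> float:
    return (deg + 180.0) % 360.0 - 180.0


@dataclass
class RobotState:
    """Robot pose: position (m), heading theta and body-relative head angle phi (deg)."""

    position: np.ndarray
    theta: float
    phi: float = 0.0
    speed: float = 0.0


@dataclass
class TrialConfig:
    """Configuration of one closed-loop trial.

    ``initial_pose`` is either "random" (collision-free uniform position and
    uniform heading in the arena; corridor entrance with ±10° heading jitter
    in the corridor) or an explicit (x, y, theta_deg) tuple.
    """

    strategy: Literal["fixed_head", "dlal", "random_walk"] = "fixed_head"
    n_calls: int = 600
    ipi: float = 0.05
    robot_radius: float = DEFAULT_ROBOT_RADIUS
    seed: int = 0
    noise_rms: float = 2e-5
    initial_pose: str | tuple[float, float, float] = "random"
    emission: EmissionModel = field(default_factory=EmissionModel)
    ears: BinauralGainModel = field(default_factory=BinauralGainModel)
    cochlear: CochlearParams = field(default_factory=CochlearParams)
    laws: KinematicLaws = field(default_factory=KinematicLaws)
    dlal: DLALParams | None = None
    random_walk: RandomWalkParams = field(default_factory=RandomWalkParams)
    range_cap: float = acoustics.DEFAULT_RANGE_CAP
    absorption_db_per_m: float = acoustics.DEFAULT_ABSORPTION_DB_PER_M
    speed_of_sound: float = acoustics.SPEED_OF_SOUND
    direct_level: float = 1.0
    turnaround_run: int = 10
    collision_nudge: float = 0.01

    def __post_init__(self) -> None:
        if self.n_calls <= 0:
            raise ValueError("n_calls must be > 0")
        if self.robot_radius <= 0:
            raise ValueError("robot_radius must be > 0")
        if self.dlal is None:
            self.dlal = DLALParams(laws=self.laws)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["initial_pose"] = (
            list(self.initial_pose) if not isinstance(self.initial_pose, str) else self.initial_pose
        )
        return d


@dataclass(frozen=True)
class CollisionEvent:
    call_index: int
    position: tuple[float, float]
    kind: Literal["obstacle", "wall"]
    primitive_index: int


@dataclass
class TrialResult:
    """Full record of one trial (per-call arrays are aligned by call index)."""

    strategy: str
    seed: int
    n_calls_executed: int
    time: np.ndarray
    x: np.ndarray
    y: np.ndarray
    theta: np.ndarray
    phi: np.ndarray
    speed: np.ndarray
    d_hat: np.ndarray
    detected: np.ndarray
    energy_left: np.ndarray
    energy_right: np.ndarray
    delta_theta: np.ndarray
    delta_phi: np.ndarray
    true_nearest: np.ndarray
    collision_flag: np.ndarray
    collisions: list[CollisionEvent]
    termination: Literal["completed", "collision", "turned_around", "timeout"]
    path_length: float
    duration: float

    def to_dataframe(self) -> pd.DataFrame:
        """Per-call command log (call, t, pose, command, percept, collision flag)."""
        return pd.DataFrame(
            {
                "call": np.arange(self.n_calls_executed),
                "t": self.time,
                "x": self.x,
                "y": self.y,
                "theta": self.theta,
                "phi": self.phi,
                "v": self.speed,
                "d_hat": self.d_hat,
                "detected": self.detected,
                "E_L": self.energy_left,
                "E_R": self.energy_right,
                "delta_theta": self.delta_theta,
                "delta_phi": self.delta_phi,
                "true_nearest": self.true_nearest,
                "collision": self.collision_flag,
            }
        )


def step_kinematics(state: RobotState, cmd: ControlCommand, ipi: float) -> RobotState:
    """Discrete unicycle step at the call rate.

    The body rotation is applied first, then the robot advances by
    speed * ipi along the new heading; the head angle is clamped to ±90°.
    """
    theta = _wrap_angle(state.theta + cmd.delta_theta)
    phi = float(np.clip(state.phi + cmd.delta_phi, -90.0, 90.0))
    rad = math.radians(theta)
    pos = state.position + cmd.speed * ipi * np.array([math.cos(rad), math.sin(rad)])
    return RobotState(position=pos, theta=theta, phi=phi, speed=cmd.speed)


def detect_turnaround(
    trajectory: np.ndarray | "TrialResult",
    env: Environment,
    run_length: int = 10,
) -> bool:
    """Whether the trajectory ends with the robot heading back down the corridor.

    True when the heading's component along the corridor axis is negative
    for ``run_length`` consecutive calls AND the axial position decreases
    over that run.  ``trajectory`` is an (n, 3) array of (x, y, theta_deg)
    rows (or a TrialResult).
    """
    if env.kind != "corridor":
        raise ValueError("turn-around detection applies to corridor environments only")
    if isinstance(trajectory, TrialResult):
        traj = np.c_[trajectory.x, trajectory.y, trajectory.theta]
    else:
        traj = np.asarray(trajectory, dtype=float)
    if len(traj) < run_length + 1:
        return False
    ax = np.asarray(env.corridor_axis, dtype=float)
    tail = traj[-(run_length + 1):]
    headings = np.radians(tail[1:, 2])
    along = np.cos(headings) * ax[0] + np.sin(headings) * ax[1]
    axial = tail[:, :2] @ ax
    return bool(np.all(along < 0.0) and axial[-1] < axial[0])


def _sample_initial_pose(
    env: Environment, config: TrialConfig, rng: np.random.Generator
) -> RobotState:
    if not isinstance(config.initial_pose, str):
        x, y, theta = config.initial_pose
        pos = np.array([x, y], dtype=float)
        if nearest_obstacle_distance(pos, env) < config.robot_radius:
            raise ValueError("initial pose is in collision")
        return RobotState(position=pos, theta=float(theta))
    if env.kind == "corridor":
        # centred at the entrance, heading along the axis with +/-10 deg jitter
        start = np.array([config.robot_radius + 0.05, 0.0])
        return RobotState(position=start, theta=float(rng.uniform(-10.0, 10.0)))
    xmin, ymin, xmax, ymax = env.bounds
    m = config.robot_radius + 0.02
    for _ in range(10_000):
        pos = rng.uniform([xmin + m, ymin + m], [xmax - m, ymax - m])
        if nearest_obstacle_distance(pos, env) >= config.robot_radius + 0.02:
            return RobotState(position=pos, theta=float(rng.uniform(-180.0, 180.0)))
    raise RuntimeError("could not sample a collision-free initial pose")


def _first_contact(
    start: np.ndarray, end: np.ndarray, radius: float, env: Environment
) -> tuple[np.ndarray, Contact] | None:
    # midpoint check guards against tunneling through thin primitives
    mid = 0.5 * (start + end)
    for p in (mid, end):
        c = check_collision(p, radius, env)
        if c is not None:
            return p, c
    return None


def run_trial(env: Environment, config: TrialConfig) -> TrialResult:
    """Run one closed-loop trial; deterministic given (env, config.seed)."""
    ss = np.random.SeedSequence(config.seed)
    rng_noise, rng_ctrl, rng_init = (np.random.default_rng(s) for s in ss.spawn(3))

    fs = config.cochlear.sample_rate
    threshold = auditory.calibrate_threshold(config.noise_rms, config.cochlear)
    em_env = auditory.emission_envelope(
        config.emission, config.cochlear, level=config.direct_level
    )
    strategy = control.make_strategy(
        config.strategy, laws=config.laws, dlal=config.dlal, random_walk=config.random_walk
    )
    strategy.reset(rng_ctrl)

    state = _sample_initial_pose(env, config, rng_init)

    n = config.n_calls
    rec = {
        k: np.zeros(n)
        for k in (
            "time x y theta phi speed d_hat energy_left energy_right "
            "delta_theta delta_phi true_nearest"
        ).split()
    }
    detected = np.zeros(n, dtype=bool)
    collision_flag = np.zeros(n, dtype=bool)
    collisions: list[CollisionEvent] = []
    termination: str = "completed"
    path_length = 0.0
    i = 0

    for i in range(n):
        t = i * config.ipi
        gaze = state.theta + state.phi
        recording = acoustics.synthesize_echoes(
            state.position,
            gaze,
            env,
            config.emission,
            config.ears,
            noise_rms=config.noise_rms,
            seed=rng_noise,
            sample_rate=fs,
            range_cap=config.range_cap,
            absorption_db_per_m=config.absorption_db_per_m,
            speed_of_sound=config.speed_of_sound,
            direct_level=config.direct_level,
            call_time=t,
        )
        env_l = auditory.remove_emission(
            auditory.cochlear_model(recording.left, config.cochlear), em_env
        )
        env_r = auditory.remove_emission(
            auditory.cochlear_model(recording.right, config.cochlear), em_env
        )
        reading = auditory.detect_first_echo(
            env_l,
            env_r,
            threshold,
            config.cochlear,
            speed_of_sound=config.speed_of_sound,
            call_index=i,
        )
        cmd = strategy.step(reading, state.phi, t)
        new_state = step_kinematics(state, cmd, config.ipi)

        rec["time"][i] = t
        rec["x"][i], rec["y"][i] = state.position
        rec["theta"][i] = state.theta
        rec["phi"][i] = new_state.phi
        rec["speed"][i] = cmd.speed
        rec["d_hat"][i] = reading.d_hat if reading.detected else np.nan
        detected[i] = reading.detected
        rec["energy_left"][i] = reading.energy_left
        rec["energy_right"][i] = reading.energy_right
        rec["delta_theta"][i] = cmd.delta_theta
        rec["delta_phi"][i] = cmd.delta_phi
        rec["true_nearest"][i] = nearest_obstacle_distance(state.position, env)

        hit = _first_contact(state.position, new_state.position, config.robot_radius, env)
        if hit is not None:
            at, contact = hit
            collision_flag[i] = True
            collisions.append(
                CollisionEvent(
                    call_index=i,
                    position=tuple(at),
                    kind=contact.kind,
                    primitive_index=contact.index,
                )
            )
            nrm = np.asarray(contact.normal)
            resume_pos = np.asarray(contact.point) + nrm * (
                config.robot_radius + config.collision_nudge
            )
            path_length += float(np.linalg.norm(at - state.position))
            if env.kind == "corridor":
                state = RobotState(
                    position=np.asarray(at, dtype=float),
                    theta=new_state.theta,
                    phi=new_state.phi,
                    speed=cmd.speed,
                )
                termination = "collision"
                i += 1
                break
            # arena: turn away from the contacted surface and resume
            state = RobotState(
                position=resume_pos,
                theta=math.degrees(math.atan2(nrm[1], nrm[0])),
                phi=new_state.phi,
                speed=cmd.speed,
            )
            continue

        path_length += float(np.linalg.norm(new_state.position - state.position))
        state = new_state

        if env.kind == "corridor":
            ax = np.asarray(env.corridor_axis)
            if float(state.position @ ax) >= env.goal_line:
                termination = "completed"
                i += 1
                break
            traj = np.c_[rec["x"][: i + 1], rec["y"][: i + 1], rec["theta"][: i + 1]]
            if detect_turnaround(traj, env, config.turnaround_run):
                termination = "turned_around"
                i += 1
                break
    else:
        i = n
        # corridor trials that exhaust the call budget without reaching the
        # goal line are recorded as timeouts (not successes)
        termination = "completed" if env.kind == "arena" else "timeout"

    n_exec = i
    return TrialResult(
        strategy=config.strategy,
        seed=config.seed,
        n_calls_executed=n_exec,
        time=rec["time"][:n_exec],
        x=rec["x"][:n_exec],
        y=rec["y"][:n_exec],
        theta=rec["theta"][:n_exec],
        phi=rec["phi"][:n_exec],
        speed=rec["speed"][:n_exec],
        d_hat=rec["d_hat"][:n_exec],
        detected=detected[:n_exec],
        energy_left=rec["energy_left"][:n_exec],
        energy_right=rec["energy_right"][:n_exec],
        delta_theta=rec["delta_theta"][:n_exec],
        delta_phi=rec["delta_phi"][:n_exec],
        true_nearest=rec["true_nearest"][:n_exec],
        collision_flag=collision_flag[:n_exec],
        collisions=collisions,
        termination=termination,
        path_length=path_length,
        duration=n_exec * config.ipi,
    )


def run_experiment(
    env_factory: Callable[[], Environment] | Environment,
    strategy: str,
    n_trials: int,
    base_seed: int,
    **config_kwargs,
) -> list[TrialResult]:
    """Run ``n_trials`` independent trials with derived seeds base_seed + index.

    ``env_factory`` may be a ready Environment (shared across trials, as a
    single physical arena is) or a zero-argument callable producing one.
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be > 0")
    results = []
    for j in range(n_trials):
        env = env_factory() if callable(env_factory) else env_factory
        cfg = TrialConfig(strategy=strategy, seed=base_seed + j, **config_kwargs)
        results.append(run_trial(env, cfg))
    return results
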