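"""Per-call steering strategies.

Three controllers act on the per-call sonar percept (nearest distance
estimate d_hat and the onset interaural level difference):

* **Fixed Head** — gaze locked to the drive direction; the body turns away
  from the louder ear by a distance-dependent angle (50° at close range
  down to 25° far away) and slows near obstacles.
* **DLAL** (delayed linear adaptive law) — the *head* turns away from the
  louder ear by the same distance-dependent angle (gaze scanning, limited
  to ±90°), while the body turn rate follows the head angle a delay tau
  earlier: theta_dot = k * phi(t - tau), with k = 10 /s and tau = 50 ms.
  Over one interpulse interval this gives Delta_theta_i = k * phi_tau *
  delta_t.  Speed is set by the gaze angle (3 m/s straight ahead, 1 m/s at
  |phi| >= 45°).
* **Random Walk** — baseline: fixed 2 m/s, per-call rotation drawn
  uniformly from [25°, 50°] with a random sign.

Sign convention: positive angles are counterclockwise (turn left).  A
louder right ear means the nearest clutter is on the right, so the head or
body turns left (positive).

The feasibility bound caps the body turn rate at the maximal curvature a
bat can fly, Omega = G * 9.81 / v (rad/s) with G = 4 g of centripetal
acceleration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .auditory import SonarReading

__all__ = [
    "KinematicLaws",
    "DLALParams",
    "RandomWalkParams",
    "ControlCommand",
    "HeadHistory",
    "rotation_magnitude",
    "speed_from_distance",
    "speed_from_gaze",
    "turn_sign",
    "dlal_head_update",
    "dlal_body_update",
    "fixed_head_step",
    "random_walk_step",
    "max_body_rotation_rate",
    "feasibility_check",
    "FeasibilityReport",
    "Strategy",
    "FixedHeadStrategy",
    "DLALStrategy",
    "RandomWalkStrategy",
    "make_strategy",
]


@dataclass(frozen=True)
class KinematicLaws:
    """Distance- and gaze-dependent rotation and speed laws.

    All laws interpolate linearly between their endpoints and clamp
    outside [d_near, d_far] (or [0°, 45°] for the gaze-speed law).  With the
    50 ms interpulse interval the rotation law spans head/body rates of
    1000 °/s (close) down to 500 °/s (far), and speeds of 1–3 m/s give
    per-call displacements of 5–15 cm.
    """

    d_near: float = 0.3
    d_far: float = 1.5
    rotation_at_near: float = 50.0
    rotation_at_far: float = 25.0
    speed_at_near: float = 1.0
    speed_at_far: float = 3.0
    speed_at_gaze0: float = 3.0
    speed_at_gaze45: float = 1.0
    ipi: float = 0.05

    def __post_init__(self) -> None:
        if not (self.d_near < self.d_far):
            raise ValueError("d_near must be < d_far")
        if not (self.rotation_at_near >= self.rotation_at_far > 0):
            raise ValueError("require rotation_at_near >= rotation_at_far > 0")
        if min(self.speed_at_near, self.speed_at_far, self.speed_at_gaze0, self.speed_at_gaze45) <= 0:
            raise ValueError("speeds must be > 0")


@dataclass(frozen=True)
class DLALParams:
    """DLAL gains: body turn rate = k * (head angle tau seconds ago).

    ``k`` is in 1/s; with k = 10 /s and tau = ipi = 50 ms the body turns by
    half the delayed head angle each call.  ``clamp_body_rate`` optionally
    limits |Delta_theta| to the flight-feasibility bound Omega(v) * ipi.
    """

    k: float = 10.0
    tau: float = 0.05
    head_limit: float = 90.0
    laws: KinematicLaws = field(default_factory=KinematicLaws)
    clamp_body_rate: bool = False
    g_limit: float = 4.0

    def __post_init__(self) -> None:
        if self.k <= 0 or self.tau <= 0 or self.head_limit <= 0:
            raise ValueError("k, tau and head_limit must be > 0")


@dataclass(frozen=True)
class RandomWalkParams:
    speed: float = 2.0
    rotation_low: float = 25.0
    rotation_high: float = 50.0

    def __post_init__(self) -> None:
        if not (0 < self.rotation_low < self.rotation_high):
            raise ValueError("require 0 < rotation_low < rotation_high")


@dataclass(frozen=True)
class ControlCommand:
    """Per-call motor command: body rotation, head rotation (deg, + = left), speed (m/s)."""

    delta_theta: float
    delta_phi: float
    speed: float


class HeadHistory:
    """Time-stamped record of the body-relative head angle phi.

    ``phi_at(t)`` linearly interpolates past samples; queries before the
    first sample return 0 (the head starts centred).
    """

    def __init__(self) -> None:
        self._t: list[float] = []
        self._phi: list[float] = []

    def record(self, t: float, phi: float) -> None:
        if self._t and t <= self._t[-1]:
            raise ValueError("timestamps must be strictly increasing")
        self._t.append(t)
        self._phi.append(phi)

    def phi_at(self, t: float) -> float:
        if not self._t or t < self._t[0]:
            return 0.0
        return float(np.interp(t, self._t, self._phi))

    def __len__(self) -> int:
        return len(self._t)


# ---------------------------------------------------------------------------
# kinematic laws
# ---------------------------------------------------------------------------

def rotation_magnitude(d_hat: float, laws: KinematicLaws | None = None) -> float:
    """Per-call rotation magnitude (deg): 50° at/below d_near, 25° at/beyond d_far."""
    laws = laws or KinematicLaws()
    if d_hat < 0:
        raise ValueError("d_hat must be >= 0")
    return float(
        np.interp(d_hat, [laws.d_near, laws.d_far], [laws.rotation_at_near, laws.rotation_at_far])
    )


def speed_from_distance(d_hat: float, laws: KinematicLaws | None = None) -> float:
    """Fixed-Head speed law (m/s): slow (1 m/s) near obstacles, fast (3 m/s) in the open."""
    laws = laws or KinematicLaws()
    if d_hat < 0:
        raise ValueError("d_hat must be >= 0")
    return float(
        np.interp(d_hat, [laws.d_near, laws.d_far], [laws.speed_at_near, laws.speed_at_far])
    )


def speed_from_gaze(phi: float, laws: KinematicLaws | None = None) -> float:
    """DLAL speed law (m/s): 3 m/s looking ahead, 1 m/s at |phi| >= 45°; even in phi."""
    laws = laws or KinematicLaws()
    return float(
        np.interp(abs(phi), [0.0, 45.0], [laws.speed_at_gaze0, laws.speed_at_gaze45])
    )


def turn_sign(
    reading: SonarReading,
    rng: np.random.Generator | None = None,
    previous_sign: float = 1.0,
) -> float:
    """Steering sign from the ILD: away from the louder ear.

    Left louder -> turn right (-1); right louder -> turn left (+1).  An
    exact tie is broken by a fair coin from ``rng``; an undetected echo
    keeps the previous call's sign (straight-ish flight toward open space).
    """
    if not reading.detected:
        return previous_sign
    if reading.energy_left > reading.energy_right:
        return -1.0
    if reading.energy_right > reading.energy_left:
        return 1.0
    if rng is None:
        return previous_sign
    return 1.0 if rng.random() < 0.5 else -1.0


def dlal_head_update(
    reading: SonarReading,
    current_phi: float,
    params: DLALParams | None = None,
    rng: np.random.Generator | None = None,
    previous_sign: float = 1.0,
) -> float:
    """New head angle: turn away from the louder ear by the distance-dependent
    magnitude, clamped to ±head_limit."""
    params = params or DLALParams()
    d = reading.d_hat if reading.detected else params.laws.d_far
    sign = turn_sign(reading, rng, previous_sign)
    new_phi = current_phi + sign * rotation_magnitude(d, params.laws)
    return float(np.clip(new_phi, -params.head_limit, params.head_limit))


def dlal_body_update(
    history: HeadHistory, now: float, params: DLALParams | None = None
) -> float:
    """Body rotation for this call (deg): Delta_theta = k * phi(now - tau) * ipi.

    The delayed head angle is linearly interpolated from the recorded
    history; history not reaching back far enough reads as 0.
    """
    params = params or DLALParams()
    phi_tau = history.phi_at(now - params.tau)
    return params.k * phi_tau * params.laws.ipi


def fixed_head_step(
    reading: SonarReading,
    laws: KinematicLaws | None = None,
    rng: np.random.Generator | None = None,
    previous_sign: float = 1.0,
) -> ControlCommand:
    """Fixed Head command: head never moves; body turns away from the louder
    ear by the distance-dependent magnitude; speed from distance."""
    laws = laws or KinematicLaws()
    d = reading.d_hat if reading.detected else laws.d_far
    sign = turn_sign(reading, rng, previous_sign)
    return ControlCommand(
        delta_theta=sign * rotation_magnitude(d, laws),
        delta_phi=0.0,
        speed=speed_from_distance(d, laws),
    )


def random_walk_step(
    rng: np.random.Generator, params: RandomWalkParams | None = None
) -> ControlCommand:
    """Baseline command: rotation magnitude ~ U(25°, 50°), fair random sign, 2 m/s."""
    params = params or RandomWalkParams()
    mag = rng.uniform(params.rotation_low, params.rotation_high)
    sign = 1.0 if rng.random() < 0.5 else -1.0
    return ControlCommand(delta_theta=sign * mag, delta_phi=0.0, speed=params.speed)


def max_body_rotation_rate(v: float, G: float = 4.0) -> float:
    """Flight-feasibility bound on the body turn rate, Omega = G * 9.81 / v (rad/s).

    Limits the centripetal acceleration v * Omega to G gravities.
    """
    if v <= 0:
        raise ValueError("v must be > 0")
    return G * 9.81 / v


@dataclass
class FeasibilityReport:
    distances: np.ndarray
    commanded_rate_deg: np.ndarray  # rotation_magnitude / ipi
    bound_deg: np.ndarray  # Omega(speed_from_distance(d)) in deg/s
    margin_deg: np.ndarray
    passed: bool


def feasibility_check(
    laws: KinematicLaws | None = None, G: float = 4.0, n_grid: int = 101
) -> FeasibilityReport:
    """Check the Fixed-Head rotation law against the G-limited turn-rate bound.

    Evaluates, over a grid of distances in [d_near, d_far], whether the
    commanded rate rotation_magnitude(d)/ipi stays below Omega(v(d)); with
    the defaults and G = 4 the law passes everywhere (1000 °/s vs 2248 °/s
    at the near end, 500 °/s vs 749 °/s at the far end).
    """
    laws = laws or KinematicLaws()
    d = np.linspace(laws.d_near, laws.d_far, n_grid)
    commanded = np.array([rotation_magnitude(x, laws) for x in d]) / laws.ipi
    if G <= 0:
        bound = np.zeros_like(d)
    else:
        bound = np.degrees(
            np.array([max_body_rotation_rate(speed_from_distance(x, laws), G) for x in d])
        )
    margin = bound - commanded
    return FeasibilityReport(
        distances=d,
        commanded_rate_deg=commanded,
        bound_deg=bound,
        margin_deg=margin,
        passed=bool(np.all(margin >= 0)),
    )


# ---------------------------------------------------------------------------
# stateful per-trial strategy objects (used by the simulator loop)
# ---------------------------------------------------------------------------

class Strategy:
    """A per-trial controller: consumes one SonarReading per call."""

    name: str = "strategy"

    def reset(self, rng: np.random.Generator) -> None:
        raise NotImplementedError

    def step(self, reading: SonarReading, phi: float, t: float) -> ControlCommand:
        """Command for the call at time ``t`` given the current head angle ``phi``."""
        raise NotImplementedError


class FixedHeadStrategy(Strategy):
    name = "fixed_head"

    def __init__(self, laws: KinematicLaws | None = None) -> None:
        self.laws = laws or KinematicLaws()

    def reset(self, rng: np.random.Generator) -> None:
        self._rng = rng
        self._sign = 1.0

    def step(self, reading: SonarReading, phi: float, t: float) -> ControlCommand:
        cmd = fixed_head_step(reading, self.laws, self._rng, self._sign)
        if cmd.delta_theta != 0:
            self._sign = math.copysign(1.0, cmd.delta_theta)
        return cmd


class DLALStrategy(Strategy):
    """Gaze-scanning controller.

    The head command issued at call i is executed by the pan servo over the
    following interpulse interval (the commanded swings of 25-50° at the
    head's 500-1000 °/s rotation rates span roughly one full interval), so
    the head *arrives* at the new angle one IPI after the command.  The
    head-angle history is therefore time-stamped at arrival, and the
    delayed angle phi(t - tau) driving the body is interpolated from that
    record.
    """

    name = "dlal"

    def __init__(self, params: DLALParams | None = None) -> None:
        self.params = params or DLALParams()

    def reset(self, rng: np.random.Generator) -> None:
        self._rng = rng
        self._sign = 1.0
        self.history = HeadHistory()

    def step(self, reading: SonarReading, phi: float, t: float) -> ControlCommand:
        p = self.params
        new_phi = dlal_head_update(reading, phi, p, self._rng, self._sign)
        if new_phi != phi:
            self._sign = math.copysign(1.0, new_phi - phi)
        self.history.record(t + p.laws.ipi, new_phi)  # servo arrival time
        dtheta = dlal_body_update(self.history, t, p)
        speed = speed_from_gaze(new_phi, p.laws)
        if p.clamp_body_rate:
            cap = math.degrees(max_body_rotation_rate(speed, p.g_limit)) * p.laws.ipi
            dtheta = float(np.clip(dtheta, -cap, cap))
        return ControlCommand(delta_theta=dtheta, delta_phi=new_phi - phi, speed=speed)


class RandomWalkStrategy(Strategy):
    name = "random_walk"

    def __init__(self, params: RandomWalkParams | None = None) -> None:
        self.params = params or RandomWalkParams()

    def reset(self, rng: np.random.Generator) -> None:
        self._rng = rng

    def step(self, reading: SonarReading, phi: float, t: float) -> ControlCommand:
        return random_walk_step(self._rng, self.params)


def make_strategy(
    name: str,
    laws: KinematicLaws | None = None,
    dlal: DLALParams | None = None,
    random_walk: RandomWalkParams | None = None,
) -> Strategy:
    """Factory for the three named strategies."""
    if name == "fixed_head":
        return FixedHeadStrategy(laws)
    if name == "dlal":
        return DLALStrategy(dlal or DLALParams(laws=laws or KinematicLaws()))
    if name == "random_walk":
        return RandomWalkStrategy(random_walk)
    raise ValueError(f"unknown strategy {name!r}")
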