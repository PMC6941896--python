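"""Arena and corridor scene generation plus geometric queries.

The two test environments emulate standard bat-behaviour setups: a walled
3 x 4 m rectangular arena containing vertical poles wrapped in foliage-like
clutter (~1 pole per m^2), and a narrow corridor (0.9 x 3 m) whose walls are
lined with rough reflectors (egg-carton texture).  Each physical reflector is
represented twice:

* as *collision geometry* (discs for poles, segments for walls), and
* as an *acoustic scatterer ensemble* — point scatterers with random
  positions and log-normal reflection strengths, so that every sonar call
  returns a cascade of overlapping echoes rather than one clean echo.

World frame: metres, x along the arena long side / corridor axis, angles in
degrees, counterclockwise positive.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "Scatterer",
    "ObstacleDisc",
    "WallSegment",
    "Environment",
    "Contact",
    "make_arena",
    "make_corridor",
    "nearest_obstacle_distance",
    "check_collision",
    "PlacementError",
]

DEFAULT_ROBOT_RADIUS = 0.165
"""Effective robot radius in m (the physical platform measured 28 x 33 cm)."""


class PlacementError(RuntimeError):
    """Raised when obstacle placement constraints cannot be satisfied."""


@dataclass(frozen=True)
class Scatterer:
    """A point reflector: position (m) and dimensionless reflection strength.

    ``normal`` and ``directivity_exponent`` model the angular reflectance of
    the parent surface: the returned amplitude is scaled by
    cos(angle of incidence)**directivity_exponent.  Exponent 0 (the default)
    is an isotropic reflector (foliage clutter, egg-carton facets); a large
    exponent approximates a smooth panel that only returns energy near
    normal incidence (quasi-specular).
    """

    position: tuple[float, float]
    strength: float
    normal: tuple[float, float] | None = None
    directivity_exponent: float = 0.0

    def __post_init__(self) -> None:
        if self.strength <= 0:
            raise ValueError("scatterer strength must be > 0")
        if self.directivity_exponent < 0:
            raise ValueError("directivity_exponent must be >= 0")
        if self.directivity_exponent > 0 and self.normal is None:
            raise ValueError("a directional scatterer needs a surface normal")


@dataclass(frozen=True)
class ObstacleDisc:
    """A cylindrical obstacle seen from above.

    ``collision_radius`` is the radius of the solid core (a 4 cm diameter
    cardboard tube -> 0.02 m); ``scatter_radius`` is the radius of the cloud
    of foliage scatterers wrapped around it.
    """

    center: tuple[float, float]
    collision_radius: float = 0.02
    scatter_radius: float = 0.10

    def __post_init__(self) -> None:
        if not (0 < self.collision_radius <= self.scatter_radius):
            raise ValueError("require 0 < collision_radius <= scatter_radius")


@dataclass(frozen=True)
class WallSegment:
    """A straight wall between two endpoints (m)."""

    p0: tuple[float, float]
    p1: tuple[float, float]

    def __post_init__(self) -> None:
        if math.dist(self.p0, self.p1) == 0.0:
            raise ValueError("wall segment must have nonzero length")

    @property
    def length(self) -> float:
        return math.dist(self.p0, self.p1)


@dataclass
class Environment:
    """A complete scene: collision geometry + acoustic scatterer ensemble."""

    kind: Literal["arena", "corridor"]
    walls: list[WallSegment]
    obstacles: list[ObstacleDisc]
    scatterers: list[Scatterer]
    bounds: tuple[float, float, float, float]  # xmin, ymin, xmax, ymax
    corridor_axis: tuple[float, float] | None = None
    goal_line: float | None = None
    seed: int | None = None
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    # -- cached array views used by the per-call acoustic synthesis ---------
    @property
    def scatterer_xy(self) -> np.ndarray:
        if "xy" not in self._cache:
            self._cache["xy"] = np.array(
                [s.position for s in self.scatterers], dtype=float
            ).reshape(-1, 2)
        return self._cache["xy"]

    @property
    def scatterer_strength(self) -> np.ndarray:
        if "strength" not in self._cache:
            self._cache["strength"] = np.array(
                [s.strength for s in self.scatterers], dtype=float
            )
        return self._cache["strength"]

    @property
    def scatterer_directivity(self) -> tuple[np.ndarray, np.ndarray]:
        """(normals, exponents); isotropic scatterers get a zero exponent."""
        if "directivity" not in self._cache:
            normals = np.array(
                [s.normal if s.normal is not None else (0.0, 0.0) for s in self.scatterers],
                dtype=float,
            ).reshape(-1, 2)
            exponents = np.array(
                [s.directivity_exponent for s in self.scatterers], dtype=float
            )
            self._cache["directivity"] = (normals, exponents)
        return self._cache["directivity"]

    @property
    def wall_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        if "walls" not in self._cache:
            p0 = np.array([w.p0 for w in self.walls], dtype=float).reshape(-1, 2)
            p1 = np.array([w.p1 for w in self.walls], dtype=float).reshape(-1, 2)
            self._cache["walls"] = (p0, p1)
        return self._cache["walls"]

    @property
    def obstacle_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        if "obst" not in self._cache:
            c = np.array([o.center for o in self.obstacles], dtype=float).reshape(-1, 2)
            r = np.array([o.collision_radius for o in self.obstacles], dtype=float)
            self._cache["obst"] = (c, r)
        return self._cache["obst"]

    def contains(self, point: Sequence[float]) -> bool:
        x, y = point
        xmin, ymin, xmax, ymax = self.bounds
        return xmin <= x <= xmax and ymin <= y <= ymax

    # -- JSON round trip ----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": self.kind,
                "seed": self.seed,
                "bounds": list(self.bounds),
                "corridor_axis": list(self.corridor_axis) if self.corridor_axis else None,
                "goal_line": self.goal_line,
                "walls": [[list(w.p0), list(w.p1)] for w in self.walls],
                "obstacles": [
                    {
                        "center": list(o.center),
                        "collision_radius": o.collision_radius,
                        "scatter_radius": o.scatter_radius,
                    }
                    for o in self.obstacles
                ],
                "scatterers": [
                    {
                        "position": list(s.position),
                        "strength": s.strength,
                        "normal": list(s.normal) if s.normal is not None else None,
                        "directivity_exponent": s.directivity_exponent,
                    }
                    for s in self.scatterers
                ],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "Environment":
        d = json.loads(text)
        return cls(
            kind=d["kind"],
            walls=[WallSegment(tuple(a), tuple(b)) for a, b in d["walls"]],
            obstacles=[
                ObstacleDisc(tuple(o["center"]), o["collision_radius"], o["scatter_radius"])
                for o in d["obstacles"]
            ],
            scatterers=[
                Scatterer(
                    tuple(s["position"]),
                    s["strength"],
                    tuple(s["normal"]) if s.get("normal") else None,
                    s.get("directivity_exponent", 0.0),
                )
                for s in d["scatterers"]
            ],
            bounds=tuple(d["bounds"]),
            corridor_axis=tuple(d["corridor_axis"]) if d["corridor_axis"] else None,
            goal_line=d["goal_line"],
            seed=d["seed"],
        )


@dataclass(frozen=True)
class Contact:
    """Report of a collision contact with one geometric primitive."""

    kind: Literal["obstacle", "wall"]
    index: int
    point: tuple[float, float]  # closest point on the primitive surface
    normal: tuple[float, float]  # outward unit normal (away from primitive)
    distance: float  # distance from query position to the primitive surface


# ---------------------------------------------------------------------------
# geometric queries
# ---------------------------------------------------------------------------

def _segment_closest_points(point: np.ndarray, p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
    """Closest point on each segment (p0[i], p1[i]) to ``point`` (vectorised)."""
    d = p1 - p0
    denom = np.einsum("ij,ij->i", d, d)
    t = np.einsum("ij,ij->i", point[None, :] - p0, d) / np.where(denom == 0, 1.0, denom)
    t = np.clip(t, 0.0, 1.0)
    return p0 + t[:, None] * d


def nearest_obstacle_distance(point: Sequence[float], env: Environment) -> float:
    """Ground-truth distance (m) from ``point`` to the nearest obstacle surface or wall.

    The minimum over all primitives; a point inside an obstacle core returns 0.
    """
    p = np.asarray(point, dtype=float)
    best = math.inf
    centers, radii = env.obstacle_arrays
    if len(centers):
        d = np.hypot(*(p - centers).T) - radii
        best = min(best, float(d.min()))
    p0, p1 = env.wall_arrays
    if len(p0):
        cp = _segment_closest_points(p, p0, p1)
        d = np.hypot(*(p - cp).T)
        best = min(best, float(d.min()))
    return max(best, 0.0)


def check_collision(
    position: Sequence[float], robot_radius: float, env: Environment
) -> Contact | None:
    """Contact report if a robot disc of ``robot_radius`` at ``position`` touches anything.

    Contact occurs iff the distance to the nearest primitive surface is below
    ``robot_radius``; the returned normal points from the primitive toward the
    robot centre.
    """
    if robot_radius <= 0:
        raise ValueError("robot_radius must be > 0")
    p = np.asarray(position, dtype=float)

    best: tuple[float, str, int, np.ndarray] | None = None
    centers, radii = env.obstacle_arrays
    if len(centers):
        d = np.hypot(*(p - centers).T) - radii
        i = int(np.argmin(d))
        best = (float(d[i]), "obstacle", i, centers[i])
    p0, p1 = env.wall_arrays
    if len(p0):
        cp = _segment_closest_points(p, p0, p1)
        d = np.hypot(*(p - cp).T)
        i = int(np.argmin(d))
        if best is None or d[i] < best[0]:
            best = (float(d[i]), "wall", i, cp[i])
    if best is None:
        return None
    dist, kind, idx, ref = best
    if dist >= robot_radius:
        return None

    if kind == "obstacle":
        # surface point and outward normal from the disc centre
        delta = p - ref
        norm = np.linalg.norm(delta)
        n = delta / norm if norm > 0 else np.array([1.0, 0.0])
        surf = ref + n * env.obstacles[idx].collision_radius
    else:
        delta = p - ref
        norm = np.linalg.norm(delta)
        if norm > 0:
            n = delta / norm
        else:  # centre exactly on the wall: push along any perpendicular
            w = np.asarray(env.walls[idx].p1) - np.asarray(env.walls[idx].p0)
            n = np.array([-w[1], w[0]]) / np.linalg.norm(w)
        surf = ref
    return Contact(kind=kind, index=idx, point=tuple(surf), normal=tuple(n), distance=max(dist, 0.0))


# ---------------------------------------------------------------------------
# scene generation
# ---------------------------------------------------------------------------

def _box_walls(xmin: float, ymin: float, xmax: float, ymax: float) -> list[WallSegment]:
    return [
        WallSegment((xmin, ymin), (xmax, ymin)),
        WallSegment((xmax, ymin), (xmax, ymax)),
        WallSegment((xmax, ymax), (xmin, ymax)),
        WallSegment((xmin, ymax), (xmin, ymin)),
    ]


def _wall_scatterers(
    wall: WallSegment,
    inward: np.ndarray,
    rng: np.random.Generator,
    spacing: float,
    jitter: float,
    base_strength: float,
    strength_sigma: float,
    directivity_exponent: float = 0.0,
) -> list[Scatterer]:
    """Wall scatterer band: one scatterer every ``spacing`` m along the wall,
    displaced inward by ``jitter ± jitter`` m (so the band lies inside the
    bounds), with log-normal strengths.  A positive ``directivity_exponent``
    makes the band quasi-specular (smooth panel); zero makes it diffuse
    (rough lining)."""
    p0 = np.asarray(wall.p0, dtype=float)
    p1 = np.asarray(wall.p1, dtype=float)
    length = wall.length
    n = max(int(length / spacing), 1)
    t = (np.arange(n) + 0.5) * spacing / length
    pts = p0 + t[:, None] * (p1 - p0)
    offset = jitter + rng.uniform(-jitter, jitter, size=n)
    pts = pts + offset[:, None] * inward[None, :]
    strengths = rng.lognormal(mean=math.log(base_strength), sigma=strength_sigma, size=n)
    normal = tuple(inward) if directivity_exponent > 0 else None
    return [
        Scatterer(tuple(p), float(s), normal, directivity_exponent)
        for p, s in zip(pts, strengths)
    ]


def _pole_scatterers(
    obstacle: ObstacleDisc,
    rng: np.random.Generator,
    n: int,
    base_strength: float,
    strength_sigma: float,
) -> list[Scatterer]:
    # uniform in the scatter disc; log-normal amplitudes around the pole base
    r = obstacle.scatter_radius * np.sqrt(rng.uniform(size=n))
    ang = rng.uniform(0, 2 * math.pi, size=n)
    pts = np.asarray(obstacle.center) + np.c_[r * np.cos(ang), r * np.sin(ang)]
    strengths = rng.lognormal(mean=math.log(base_strength), sigma=strength_sigma, size=n)
    return [Scatterer(tuple(p), float(s)) for p, s in zip(pts, strengths)]


def make_arena(
    seed: int,
    n_obstacles: int = 11,
    *,
    length: float = 4.0,
    width: float = 3.0,
    min_spacing: float = 0.4,
    max_nn_spacing: float = 1.0,
    wall_margin: float = 0.6,
    scatterers_per_pole: int = 20,
    pole_strength: float = 0.01,
    pole_strength_sigma: float = 0.5,
    wall_spacing: float = 0.03,
    wall_jitter: float = 0.005,
    wall_strength: float = 0.005,
    wall_strength_sigma: float = 0.15,
    wall_directivity_exponent: float = 8.0,
    max_attempts: int = 500,
) -> Environment:
    """Generate the walled rectangular arena with clutter poles.

    Default geometry is the 3 x 4 m flight-cage replica with 11 poles
    (about one per square metre).  Poles are placed by rejection sampling:
    pairwise centre spacing at least ``min_spacing`` (poles must not
    physically overlap), every pole's nearest neighbour closer than
    ``max_nn_spacing`` (the poles form a dense, challenging field rather
    than isolated targets), and centres at least ``wall_margin`` from the
    panels (free-standing tubes in a walled cage).  Pole scatterers are
    diffuse (ivy foliage); the smooth cardboard panels get a weakly
    jittered, quasi-specular scatterer band (``wall_directivity_exponent``)
    that returns energy only near normal incidence.  The same seed always
    yields the identical environment.
    """
    if n_obstacles < 0:
        raise ValueError("n_obstacles must be >= 0")
    rng = np.random.default_rng(seed)
    bounds = (0.0, 0.0, length, width)
    walls = _box_walls(*bounds)

    centers: np.ndarray | None = None
    for _ in range(max_attempts):
        pts: list[np.ndarray] = []
        ok = True
        for _ in range(n_obstacles):
            for _ in range(200):
                cand = rng.uniform(
                    [wall_margin, wall_margin], [length - wall_margin, width - wall_margin]
                )
                if all(np.linalg.norm(cand - p) >= min_spacing for p in pts):
                    pts.append(cand)
                    break
            else:
                ok = False
                break
        if not ok:
            continue
        arr = np.array(pts).reshape(-1, 2)
        if n_obstacles >= 2:
            dd = np.linalg.norm(arr[:, None, :] - arr[None, :, :], axis=-1)
            np.fill_diagonal(dd, np.inf)
            if dd.min(axis=1).max() >= max_nn_spacing:
                continue
        centers = arr
        break
    if centers is None:
        raise PlacementError(
            f"could not place {n_obstacles} obstacles under the spacing constraints"
        )

    obstacles = [ObstacleDisc(tuple(c)) for c in centers]
    scatterers: list[Scatterer] = []
    for obs in obstacles:
        scatterers.extend(
            _pole_scatterers(obs, rng, scatterers_per_pole, pole_strength, pole_strength_sigma)
        )
    inward_normals = [np.array(v) for v in ((0.0, 1.0), (-1.0, 0.0), (0.0, -1.0), (1.0, 0.0))]
    for wall, inward in zip(walls, inward_normals):
        scatterers.extend(
            _wall_scatterers(
                wall,
                inward,
                rng,
                wall_spacing,
                wall_jitter,
                wall_strength,
                wall_strength_sigma,
                wall_directivity_exponent,
            )
        )
    return Environment(
        kind="arena",
        walls=walls,
        obstacles=obstacles,
        scatterers=scatterers,
        bounds=bounds,
        seed=seed,
    )


def make_corridor(
    seed: int,
    width: float = 0.9,
    length: float = 3.0,
    *,
    robot_radius: float = DEFAULT_ROBOT_RADIUS,
    wall_spacing: float = 0.03,
    wall_jitter: float = 0.02,
    wall_strength: float = 0.005,
    wall_strength_sigma: float = 0.5,
) -> Environment:
    """Generate the rough-walled corridor (default 0.9 m wide, 3 m long).

    The two walls run parallel to the x axis at y = ±width/2 and carry dense
    position- and strength-jittered scatterer bands emulating the egg-carton
    lining.  The goal line sits at x = ``length``.
    """
    if width <= 2 * robot_radius:
        raise ValueError(
            f"corridor width {width} m must exceed the robot diameter {2 * robot_radius} m"
        )
    if length <= 0:
        raise ValueError("length must be > 0")
    rng = np.random.default_rng(seed)
    half = width / 2.0
    bounds = (0.0, -half, length, half)
    walls = [
        WallSegment((0.0, -half), (length, -half)),
        WallSegment((0.0, half), (length, half)),
    ]
    scatterers: list[Scatterer] = []
    for wall, inward in zip(walls, (np.array([0.0, 1.0]), np.array([0.0, -1.0]))):
        scatterers.extend(
            _wall_scatterers(
                wall, inward, rng, wall_spacing, wall_jitter, wall_strength, wall_strength_sigma
            )
        )
    return Environment(
        kind="corridor",
        walls=walls,
        obstacles=[],
        scatterers=scatterers,
        bounds=bounds,
        corridor_axis=(1.0, 0.0),
        goal_line=length,
        seed=seed,
    )
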