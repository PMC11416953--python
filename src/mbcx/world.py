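"""Seeded 2D foraging worlds, skyline rendering, kinematics, learning walks.

The arena is a disc containing a nest, point feeders, and opaque cylindrical
landmarks.  Vision is a 1D panoramic skyline: for each egocentric azimuth bin
the maximum angular elevation subtended by any landmark (0 = open sky).  PN
features for the mushroom body are the elevations plus their circular first
differences (edge-like elementary processing).

Coordinates are allocentric Cartesian with angles counter-clockwise from +x;
the panorama is egocentric with bin 0 straight ahead, so allocentric
information reaches the agent only through the central complex.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .cx import wrap_angle
from .exceptions import CollisionError, ConfigurationError, GenerationError

__all__ = [
    "Pose",
    "Feeder",
    "Landmark",
    "World",
    "PanoramicView",
    "generate_world",
    "render_panorama",
    "view_features",
    "place_signature",
    "step_kinematics",
    "scripted_learning_walk",
    "sense_and_reward",
]


@dataclass
class Pose:
    """Agent position and allocentric heading (wrapped to (-pi, pi])."""

    x: float
    y: float
    kappa: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y) and math.isfinite(self.kappa)):
            raise ConfigurationError("pose coordinates must be finite")
        self.kappa = wrap_angle(self.kappa)


@dataclass
class Feeder:
    x: float
    y: float
    magnitude: float = 1.0
    depletable: bool = True
    active: bool = True

    def __post_init__(self) -> None:
        if self.magnitude < 0:
            raise ConfigurationError("feeder reward magnitude must be >= 0")


@dataclass
class Landmark:
    """Opaque cylinder (visual skyline object)."""

    x: float
    y: float
    radius: float
    height: float


@dataclass
class World:
    nest: tuple[float, float] = (0.0, 0.0)
    feeders: list[Feeder] = field(default_factory=list)
    landmarks: list[Landmark] = field(default_factory=list)
    arena_radius: float = 50.0
    capture_radius: float = 1.0
    aversive_zones: list[tuple[float, float, float, float]] = field(default_factory=list)
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "World":
        d = json.loads(text)
        d["nest"] = tuple(d["nest"])
        d["feeders"] = [Feeder(**f) for f in d["feeders"]]
        d["landmarks"] = [Landmark(**m) for m in d["landmarks"]]
        d["aversive_zones"] = [tuple(z) for z in d["aversive_zones"]]
        return cls(**d)

    def reset_feeders(self) -> None:
        for f in self.feeders:
            f.active = True


def _scatter_landmarks(
    rng: np.random.Generator,
    n: int,
    r_lo: float,
    r_hi: float,
    keep_clear: list[tuple[float, float]],
    clearance: float = 3.0,
    height_range: tuple[float, float] = (2.0, 14.0),
    cyl_radius_range: tuple[float, float] = (1.5, 4.0),
    max_tries: int = 400,
) -> list[Landmark]:
    """Cylinders scattered in an annulus with varied size and height.

    The irregular, dense skyline breaks rotational symmetry so panoramas
    discriminate both position and heading; ``keep_clear`` points (nest,
    feeders) stay at least ``clearance`` beyond any cylinder surface."""
    marks: list[Landmark] = []
    for _ in range(n):
        for _try in range(max_tries):
            ang = rng.uniform(-np.pi, np.pi)
            cyl_r = float(rng.uniform(*cyl_radius_range))
            # the whole cylinder must stay inside the annulus' outer bound
            r = rng.uniform(r_lo, max(r_lo + 1e-6, r_hi - cyl_r))
            x, y = r * np.cos(ang), r * np.sin(ang)
            if all(
                np.hypot(x - px, y - py) >= cyl_r + clearance for px, py in keep_clear
            ) and all(
                np.hypot(x - m.x, y - m.y) >= cyl_r + m.radius + 0.5 for m in marks
            ):
                marks.append(
                    Landmark(float(x), float(y), cyl_r, float(rng.uniform(*height_range)))
                )
                break
        else:
            raise GenerationError("could not scatter landmarks with required clearance")
    return marks


def generate_world(config: dict | None = None, seed: int = 0) -> World:
    """Deterministic world generation from a preset name plus overrides.

    Presets:

    * ``"homing"`` — nest at origin inside an irregular landmark ring.
    * ``"traplining"`` — nest plus ``k`` replenishable feeders with a minimum
      pairwise separation, inside a landmark ring.
    * ``"shortcut"`` — nest (A) and two feeders B and C in a triangle, C
      closer to the nest than B.
    """
    config = dict(config or {})
    preset = config.pop("preset", "homing")
    arena_radius = config.pop("arena_radius", 50.0)
    n_landmarks = config.pop("n_landmarks", 30)
    min_feeder_sep = config.pop("min_feeder_sep", 8.0)
    k = config.pop("k_feeders", 3)
    feeder_radius = config.pop("feeder_ring", 0.45 * arena_radius)
    feeder_positions = config.pop("feeder_positions", None)
    landmark_annulus = config.pop("landmark_annulus", (0.35, 0.92))
    if config:
        raise ConfigurationError(f"unknown world config keys: {sorted(config)}")

    rng = np.random.default_rng(seed)
    world = World(arena_radius=arena_radius, seed=seed)

    if preset == "homing":
        pass
    elif preset == "traplining":
        if feeder_positions is not None:
            world.feeders = [Feeder(x=float(x), y=float(y)) for x, y in feeder_positions]
            keep = [world.nest] + [(f.x, f.y) for f in world.feeders]
            world.landmarks = _scatter_landmarks(
                rng, n_landmarks, landmark_annulus[0] * arena_radius,
                landmark_annulus[1] * arena_radius, keep
            )
            return world
        placed: list[tuple[float, float]] = []
        for _ in range(k):
            for _attempt in range(200):
                ang = rng.uniform(-np.pi, np.pi)
                r = feeder_radius * (1.0 + rng.uniform(-0.2, 0.2))
                x, y = r * np.cos(ang), r * np.sin(ang)
                ok = all(np.hypot(x - px, y - py) >= min_feeder_sep for px, py in placed)
                ok = ok and np.hypot(x, y) >= min_feeder_sep
                if ok:
                    placed.append((x, y))
                    break
            else:
                raise GenerationError("could not place feeders with required separation")
        world.feeders = [Feeder(x=float(x), y=float(y)) for x, y in placed]
    elif preset == "shortcut":
        # nest A at origin; C nearer the nest than B, B off at an angle
        d_c = 0.3 * arena_radius
        d_b = 0.55 * arena_radius
        ang_c = rng.uniform(-np.pi, np.pi)
        ang_b = ang_c + rng.uniform(0.6, 1.2) * rng.choice([-1.0, 1.0])
        world.feeders = [
            Feeder(x=float(d_b * np.cos(ang_b)), y=float(d_b * np.sin(ang_b))),  # B = 0
            Feeder(x=float(d_c * np.cos(ang_c)), y=float(d_c * np.sin(ang_c))),  # C = 1
        ]
    else:
        raise ConfigurationError(f"unknown preset {preset!r}")
    keep_clear = [world.nest] + [(f.x, f.y) for f in world.feeders]
    world.landmarks = _scatter_landmarks(
        rng, n_landmarks, landmark_annulus[0] * arena_radius,
        landmark_annulus[1] * arena_radius, keep_clear
    )
    return world


@dataclass(frozen=True)
class PanoramicView:
    """1D skyline: max angular elevation per egocentric azimuth bin."""

    elevations: np.ndarray  # (n_azimuth,) in [0, pi/2)

    @property
    def n_azimuth(self) -> int:
        return self.elevations.size


def render_panorama(world: World, pose: Pose, n_azimuth: int = 72) -> PanoramicView:
    """Render the skyline seen from ``pose``.

    For each cylinder the subtended azimuth interval is computed from its
    angular half-width ``asin(radius/d)``; every bin whose centre falls in
    that interval sees elevation ``atan(height / (d - radius))`` (distance to
    the cylinder surface).  Overlaps resolve by max (occlusion).  Bin 0 is
    straight ahead.  Raises `CollisionError` for a pose inside a cylinder.
    """
    if np.hypot(pose.x, pose.y) > world.arena_radius:
        raise ConfigurationError("pose outside the arena")
    if not world.landmarks:
        return PanoramicView(np.zeros(n_azimuth))
    lx = np.array([lm.x for lm in world.landmarks])
    ly = np.array([lm.y for lm in world.landmarks])
    lr = np.array([lm.radius for lm in world.landmarks])
    lh = np.array([lm.height for lm in world.landmarks])
    dx, dy = lx - pose.x, ly - pose.y
    d = np.hypot(dx, dy)
    if np.any(d <= lr):
        raise CollisionError("pose inside a landmark cylinder")
    az_ego = np.arctan2(dy, dx) - pose.kappa
    half_width = np.arcsin(np.minimum(lr / d, 1.0))
    e = np.arctan(lh / (d - lr))
    bin_width = 2 * np.pi / n_azimuth
    centers = np.arange(n_azimuth) * bin_width  # egocentric bin centres
    # bins whose centre lies within each cylinder's subtended interval;
    # occlusion resolves by max over cylinders
    diff = np.abs(
        (centers[None, :] - az_ego[:, None] + np.pi) % (2 * np.pi) - np.pi
    )
    hit = diff <= half_width[:, None]
    elev = np.max(np.where(hit, e[:, None], 0.0), axis=0)
    return PanoramicView(elev)


def view_features(view: PanoramicView) -> np.ndarray:
    """PN input: skyline elevations concatenated with their circular first
    differences (rectified, both signs) — a minimal edge-like preprocessing
    that supports left/right discrimination."""
    e = view.elevations
    d = np.roll(e, -1) - e
    return np.concatenate([e, np.maximum(d, 0.0), np.maximum(-d, 0.0)])


def place_signature(view: PanoramicView, n_harmonics: int = 19) -> np.ndarray:
    """Rotation-invariant view summary: skyline harmonic amplitudes.

    The magnitudes of the low azimuthal Fourier harmonics of the skyline
    (and of its edge profile) are unchanged by body rotation, so they act as
    a *place* signature: views from the same spot match regardless of
    heading, while views from distant spots differ.  Used as the sub-goal
    selector's state input; the steering circuits keep the retinotopic
    panorama.
    """
    e = view.elevations
    d = np.roll(e, -1) - e
    return np.concatenate(
        [np.abs(np.fft.rfft(e))[:n_harmonics], np.abs(np.fft.rfft(d))[:n_harmonics]]
    )


def step_kinematics(
    pose: Pose,
    turn_rate: float,
    speed: float,
    dt: float = 0.1,
    motor_noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    arena_radius: float | None = None,
) -> Pose:
    """Unicycle step: turn, then advance along the new heading.

    Gaussian motor noise perturbs the heading; the arena boundary is
    reflective (heading mirrored about the local tangent).
    """
    if speed < 0:
        raise ConfigurationError("speed must be >= 0")
    eps = 0.0
    if motor_noise_sd > 0:
        if rng is None:
            raise ConfigurationError("rng required when motor_noise_sd > 0")
        eps = float(rng.normal(0.0, motor_noise_sd))
    kappa = wrap_angle(pose.kappa + turn_rate * dt + eps)
    x = pose.x + speed * dt * math.cos(kappa)
    y = pose.y + speed * dt * math.sin(kappa)
    if arena_radius is not None and np.hypot(x, y) > arena_radius:
        phi = math.atan2(y, x)  # outward normal direction
        kappa = wrap_angle(2 * phi + np.pi - kappa)  # reflect about tangent
        r = min(np.hypot(x, y), arena_radius)
        x, y = r * math.cos(phi) * 0.999, r * math.sin(phi) * 0.999
    return Pose(x, y, kappa)


def resolve_collision(world: World, pose: Pose, margin: float = 0.3) -> Pose:
    """Push a pose out of any landmark cylinder it penetrated.

    The agent is placed just outside the surface along the radial direction
    and its heading deflected away (specular-ish bounce), modelling simple
    obstacle avoidance without contact dynamics.
    """
    for lm in world.landmarks:
        dx, dy = pose.x - lm.x, pose.y - lm.y
        d = float(np.hypot(dx, dy))
        if d < lm.radius + margin:
            if d < 1e-9:
                dx, dy, d = 1.0, 0.0, 1.0
            scale = (lm.radius + margin) / d
            nx = lm.x + dx * scale
            ny = lm.y + dy * scale
            # a rim cylinder must not eject the agent past the arena edge
            rr = float(np.hypot(nx, ny))
            if rr > world.arena_radius:
                f = 0.999 * world.arena_radius / rr
                nx, ny = nx * f, ny * f
            normal = math.atan2(dy, dx)
            kappa = wrap_angle(2 * normal + np.pi - pose.kappa)
            return Pose(float(nx), float(ny), kappa)
    return pose


def scripted_learning_walk(
    world: World,
    n_loops: int = 4,
    max_radius: float = 15.0,
    steps_per_loop: int = 120,
    seed: int = 0,
    center: tuple[float, float] | None = None,
) -> list[Pose]:
    """Synthetic learning walk: expanding loops with goal-facing turn-backs.

    ``center`` defaults to the nest; a feeder location produces the
    orientation walk insects perform around a newly discovered food site.

    Emulates the structure of recorded learning walks: the agent spirals
    outward around the nest in ``n_loops`` loops of growing radius, pausing
    regularly to face toward or away from the nest, so that views paired
    with goal-left and goal-right headings are both sampled in every
    azimuthal sector.  Poses are generated parametrically (the walk is the
    *off-policy* behaviour, not a learned trajectory).
    """
    if max_radius >= world.arena_radius:
        raise ConfigurationError("max_radius must be smaller than the arena radius")
    rng = np.random.default_rng(seed)
    nx, ny = world.nest if center is None else center
    poses: list[Pose] = []
    phase0 = rng.uniform(-np.pi, np.pi)
    for loop in range(1, n_loops + 1):
        r_loop = max_radius * loop / n_loops
        direction = 1.0 if loop % 2 == 0 else -1.0  # alternate circling sense
        for t in range(steps_per_loop):
            frac = t / steps_per_loop
            phi = phase0 + direction * 2 * np.pi * frac
            r = r_loop * (0.35 + 0.65 * frac) * (1 + 0.05 * rng.standard_normal())
            r = min(abs(r), max_radius)
            x, y = nx + r * np.cos(phi), ny + r * np.sin(phi)
            bearing_nest = math.atan2(ny - y, nx - x)
            mod = t % 8
            if mod in (0, 1):  # nest-facing turn-back segment
                kappa = bearing_nest + rng.normal(0.0, 0.15)
            elif mod in (2, 3):  # nest left of heading
                kappa = bearing_nest - np.pi / 2 + rng.normal(0.0, 0.3)
            elif mod in (4, 5):  # nest right of heading
                kappa = bearing_nest + np.pi / 2 + rng.normal(0.0, 0.3)
            else:  # free scanning: arbitrary heading
                kappa = rng.uniform(-np.pi, np.pi)
            poses.append(resolve_collision(world, Pose(float(x), float(y), float(kappa))))
    return poses


def sense_and_reward(world: World, pose: Pose, n_azimuth: int = 72) -> tuple[PanoramicView, float, float]:
    """Render the view and collect any external reward at the pose.

    A feeder within the capture radius pays its magnitude once and is then
    depleted if depletable.  ``r_minus`` accrues from configured aversive
    zones (circles ``(x, y, radius, magnitude)``); none by default.
    """
    view = render_panorama(world, pose, n_azimuth)
    r_plus = 0.0
    for f in world.feeders:
        if f.active and np.hypot(pose.x - f.x, pose.y - f.y) <= world.capture_radius:
            r_plus += f.magnitude
            if f.depletable:
                f.active = False
    r_minus = 0.0
    for (zx, zy, zr, zm) in world.aversive_zones:
        if np.hypot(pose.x - zx, pose.y - zy) <= zr:
            r_minus += zm
    return view, r_plus, r_minus
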