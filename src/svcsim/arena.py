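"""Square arena geometry: wall landmarks, agent poses, visibility, gaze rays.

Angular conventions used throughout the package: compass bearings with
0 deg = north (+y), increasing clockwise, kept in [0, 360); egocentric angles
are signed, clockwise positive, in (-180, 180] (0 = straight ahead).  Wall
locations are expressed on an "unrolled" perimeter coordinate s in [0, 4*side),
starting at the south-west corner and running clockwise when viewed on a
standard map: south wall (west to east), east wall (south to north), north
wall (east to west), west wall (north to south).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Arena",
    "AgentPose",
    "CueView",
    "wrap_deg",
    "bearing_deg",
    "enumerate_poses",
    "visible_cues",
    "gaze_wall_point",
]


def wrap_deg(angle):
    """Wrap angle(s) to (-180, 180]."""
    a = np.mod(np.asarray(angle, dtype=float) + 180.0, 360.0) - 180.0
    return np.where(a == -180.0, 180.0, a) if np.ndim(a) else (180.0 if a == -180.0 else float(a))


def bearing_deg(dx, dy):
    """Compass bearing of displacement (dx, dy): 0 = north, clockwise, [0,360)."""
    return np.mod(np.degrees(np.arctan2(dx, dy)), 360.0)


@dataclass(frozen=True)
class AgentPose:
    """Agent place (x, y), head direction theta (deg), field of view alpha (deg)."""
    x: float
    y: float
    theta: float
    fov: float = 360.0

    def __post_init__(self):
        if not 0.0 < self.fov <= 360.0:
            raise ValueError("field of view must be in (0, 360]")


@dataclass(frozen=True)
class CueView:
    """One landmark as seen from a pose."""
    landmark_id: int
    egocentric: float     # signed deg, 0 = straight ahead, clockwise positive
    allocentric: float    # compass bearing from the agent, deg from north


@dataclass
class Arena:
    """Square arena with landmarks on the walls.

    ``landmarks`` is a list of (wall, position-along-wall) pairs with wall in
    {0: south, 1: east, 2: north, 3: west} and position measured along the
    perimeter direction of that wall, in [0, side].
    """

    side: float = 1.0
    landmarks: list = field(default_factory=list)

    def __post_init__(self):
        if self.side <= 0:
            raise ValueError("arena side must be positive")
        if len(self.landmarks) < 3:
            raise ValueError("arena needs at least 3 landmarks")
        for wall, t in self.landmarks:
            if wall not in (0, 1, 2, 3):
                raise ValueError(f"wall must be 0..3, got {wall}")
            if not 0.0 <= t <= self.side:
                raise ValueError("landmark position outside wall extent")

    @property
    def n_landmarks(self) -> int:
        return len(self.landmarks)

    @property
    def perimeter(self) -> float:
        return 4.0 * self.side

    def landmark_xy(self) -> np.ndarray:
        """(K, 2) landmark positions in arena coordinates."""
        pts = []
        L = self.side
        for wall, t in self.landmarks:
            if wall == 0:
                pts.append((t, 0.0))
            elif wall == 1:
                pts.append((L, t))
            elif wall == 2:
                pts.append((L - t, L))
            else:
                pts.append((0.0, L - t))
        return np.array(pts)

    def landmark_perimeter(self) -> np.ndarray:
        """Perimeter coordinate s of each landmark."""
        return np.array([wall * self.side + t for wall, t in self.landmarks])

    def contains(self, x: float, y: float) -> bool:
        return 0.0 <= x <= self.side and 0.0 <= y <= self.side

    def xy_to_perimeter(self, x, y) -> float:
        """Perimeter coordinate of a boundary point (snaps to nearest wall)."""
        L = self.side
        walls = np.array([y, L - x, L - y, x])  # distance to S, E, N, W walls
        w = int(np.argmin(walls))
        t = (x, y, L - x, L - y)[w]
        return float(w * L + np.clip(t, 0.0, L))

    def perimeter_distance(self, s1, s2) -> float:
        """Shortest distance between two perimeter coordinates (circular)."""
        d = abs(float(s1) - float(s2)) % self.perimeter
        return min(d, self.perimeter - d)


def enumerate_poses(arena: Arena, grid_n: int, dtheta: float) -> np.ndarray:
    """Deterministic pose stream over a grid_n x grid_n place grid with head
    direction stepped by *dtheta* degrees.

    Returns an (grid_n^2 * 360/dtheta, 3) array of (x, y, theta) rows, in
    row-major place order with theta ascending fastest.  *dtheta* must divide
    360 exactly.
    """
    if grid_n < 2:
        raise ValueError("grid_n must be >= 2")
    if 360.0 % dtheta != 0.0:
        raise ValueError(f"dtheta={dtheta} does not divide 360")
    n_dir = int(360.0 // dtheta)
    coords = (np.arange(grid_n) + 0.5) * (arena.side / grid_n)
    thetas = np.arange(n_dir) * float(dtheta)
    yy, xx, tt = np.meshgrid(coords, coords, thetas, indexing="ij")
    return np.column_stack([xx.ravel(), yy.ravel(), tt.ravel()])


def landmark_bearings(arena: Arena, xy: np.ndarray) -> np.ndarray:
    """(M, K) compass bearings from each of M positions to each landmark."""
    lm = arena.landmark_xy()
    d = lm[None, :, :] - np.atleast_2d(xy)[:, None, :]
    return bearing_deg(d[..., 0], d[..., 1])


def visible_cues(arena: Arena, pose: AgentPose) -> list[CueView]:
    """Landmarks within +/- fov/2 of the head direction, sorted by egocentric
    angle (no occlusion: every landmark inside the cone is visible)."""
    if not arena.contains(pose.x, pose.y):
        raise ValueError("pose outside arena")
    bearings = landmark_bearings(arena, np.array([[pose.x, pose.y]]))[0]
    ego = wrap_deg(bearings - pose.theta)
    half = pose.fov / 2.0
    out = [CueView(i, float(ego[i]), float(bearings[i]))
           for i in range(arena.n_landmarks) if abs(ego[i]) <= half]
    return sorted(out, key=lambda c: c.egocentric)


def gaze_wall_point(arena: Arena, x, y, bearing) -> float:
    """Perimeter coordinate where the ray from (x, y) along *bearing* meets
    the arena boundary."""
    L = arena.side
    b = np.radians(float(bearing) % 360.0)
    dx, dy = np.sin(b), np.cos(b)
    ts = []
    if dx > 0:
        ts.append((L - x) / dx)
    elif dx < 0:
        ts.append(-x / dx)
    if dy > 0:
        ts.append((L - y) / dy)
    elif dy < 0:
        ts.append(-y / dy)
    if not ts:
        raise RuntimeError("degenerate gaze ray")
    t = min(t for t in ts if t >= 0)
    px = float(np.clip(x + t * dx, 0.0, L))
    py = float(np.clip(y + t * dy, 0.0, L))
    return arena.xy_to_perimeter(px, py)


def gaze_wall_points(arena: Arena, xy: np.ndarray, bearings: np.ndarray) -> np.ndarray:
    """Vectorised :func:`gaze_wall_point` over M positions/bearings."""
    L = arena.side
    b = np.radians(np.asarray(bearings, dtype=float) % 360.0)
    x = np.asarray(xy)[:, 0]
    y = np.asarray(xy)[:, 1]
    dx, dy = np.sin(b), np.cos(b)
    with np.errstate(divide="ignore"):
        tx = np.where(dx > 0, (L - x) / dx, np.where(dx < 0, -x / dx, np.inf))
        ty = np.where(dy > 0, (L - y) / dy, np.where(dy < 0, -y / dy, np.inf))
    t = np.minimum(tx, ty)
    px = np.clip(x + t * dx, 0.0, L)
    py = np.clip(y + t * dy, 0.0, L)
    # nearest-wall snap, vectorised
    walls = np.stack([py, L - px, L - py, px])
    w = np.argmin(walls, axis=0)
    tt = np.choose(w, [px, py, L - px, L - py])
    return w * L + np.clip(tt, 0.0, L)
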