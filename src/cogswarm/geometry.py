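"""Polygonal 2-D arenas: walls, cues, rewards, spawn disks.

An :class:`Arena` is a simple outer ring (which may be highly non-convex,
e.g. comb-shaped maze walls traced into the boundary), optional interior hole
rings (free-standing obstacles), point cues and rewards, and circular spawn
regions. Coordinates are continuous Cartesian "points" with y increasing
upward. Points exactly on a wall are not allowable; sight lines are nudged
inward by ``EPS_LOS`` before intersection testing so that grazing contacts at
shared ring vertices do not spuriously block visibility.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from shapely.geometry import Polygon

from . import _kernels as _k

__all__ = [
    "EPS_LOS",
    "ArenaError",
    "PointFeature",
    "SpawnDisk",
    "WallQuery",
    "Arena",
    "notional_radius",
    "point_allowable",
    "line_of_sight",
    "wall_query",
]

#: inward nudge (points) applied to sight-segment endpoints before
#: intersection testing, resolving grazing contact at wall vertices
EPS_LOS = 1e-6


class ArenaError(ValueError):
    """Invalid or degenerate arena description."""


@dataclass(frozen=True)
class PointFeature:
    """A labelled point of interest (cue or reward)."""

    id: str
    xy: tuple[float, float]


@dataclass(frozen=True)
class SpawnDisk:
    """Circular initialization region for agent/particle positions."""

    center: tuple[float, float]
    radius: float


@dataclass(frozen=True)
class WallQuery:
    """Distance to the nearest wall and unit normal pointing back into the
    interior (from the nearest wall point toward the query point)."""

    distance: float
    normal: np.ndarray


def _shoelace(ring: np.ndarray) -> float:
    x = ring[:, 0]
    y = ring[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def _as_ring(points) -> np.ndarray:
    ring = np.asarray(points, dtype=np.float64)
    if ring.ndim != 2 or ring.shape[1] != 2 or ring.shape[0] < 3:
        raise ArenaError("a ring needs at least 3 (x, y) vertices")
    # drop an explicitly repeated closing vertex; rings close implicitly
    if np.array_equal(ring[0], ring[-1]):
        ring = ring[:-1]
    if ring.shape[0] < 3:
        raise ArenaError("a ring needs at least 3 distinct vertices")
    return ring


class Arena:
    """A closed polygonal environment with holes, cues, rewards and spawn disks.

    Parameters
    ----------
    outer_ring:
        Vertices of the outer boundary (implicitly closed).
    hole_rings:
        Interior obstacle rings, pairwise disjoint and inside the outer ring.
    cues, rewards:
        ``PointFeature`` sequences (or ``(id, x, y)`` tuples).
    spawn_disks:
        ``SpawnDisk`` sequence (or ``(x, y, radius)`` tuples).
    """

    def __init__(
        self,
        outer_ring,
        hole_rings: Sequence = (),
        cues: Sequence = (),
        rewards: Sequence = (),
        spawn_disks: Sequence = (),
        name: str = "arena",
        validate: bool = True,
    ):
        self.outer_ring = _as_ring(outer_ring)
        self.hole_rings = [_as_ring(h) for h in hole_rings]
        self.cues = [
            c if isinstance(c, PointFeature) else PointFeature(str(c[0]), (float(c[1]), float(c[2])))
            for c in cues
        ]
        self.rewards = [
            r if isinstance(r, PointFeature) else PointFeature(str(r[0]), (float(r[1]), float(r[2])))
            for r in rewards
        ]
        self.spawn_disks = [
            s if isinstance(s, SpawnDisk) else SpawnDisk((float(s[0]), float(s[1])), float(s[2]))
            for s in spawn_disks
        ]
        self.name = name
        self._build_walls()
        self._cue_xy = np.array([c.xy for c in self.cues], dtype=np.float64).reshape(-1, 2)
        self._reward_xy = np.array([r.xy for r in self.rewards], dtype=np.float64).reshape(-1, 2)
        if validate:
            self._validate()

    # -- construction ---------------------------------------------------

    def _build_walls(self) -> None:
        seg_a = []
        seg_b = []
        for ring in [self.outer_ring, *self.hole_rings]:
            seg_a.append(ring)
            seg_b.append(np.roll(ring, -1, axis=0))
        self.seg_a = np.ascontiguousarray(np.vstack(seg_a))
        self.seg_b = np.ascontiguousarray(np.vstack(seg_b))

    def _validate(self) -> None:
        poly = Polygon(self.outer_ring, [h for h in self.hole_rings])
        if not poly.is_valid:
            raise ArenaError(f"invalid arena polygon: {self.name}")
        if self.allowable_area <= 0:
            raise ArenaError(f"arena {self.name!r} has non-positive allowable area")
        for feat in [*self.cues, *self.rewards]:
            if not self.point_allowable(feat.xy):
                raise ArenaError(f"feature {feat.id!r} at {feat.xy} is not allowable")
        for disk in self.spawn_disks:
            if disk.radius <= 0:
                raise ArenaError("spawn disk radius must be positive")
            if not self.point_allowable(disk.center):
                raise ArenaError(f"spawn disk center {disk.center} is not allowable")

    # -- geometry queries ------------------------------------------------

    @property
    def allowable_area(self) -> float:
        """Interior area (shoelace formula): outer ring minus holes."""
        area = _shoelace(self.outer_ring)
        for hole in self.hole_rings:
            area -= _shoelace(hole)
        return area

    @property
    def notional_radius(self) -> float:
        """Radius of the disk whose area equals the allowable interior.

        Scale-dependent model parameters (``sigma``, ``kappa``, ``D_max``)
        are multiplied by this length.
        """
        area = self.allowable_area
        if area <= 0:
            raise ArenaError("degenerate arena: allowable area <= 0")
        return math.sqrt(area / math.pi)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        xmin, ymin = self.outer_ring.min(axis=0)
        xmax, ymax = self.outer_ring.max(axis=0)
        return float(xmin), float(ymin), float(xmax), float(ymax)

    def point_allowable(self, p) -> bool:
        """True iff ``p`` is strictly inside the outer ring and strictly
        outside every hole (even-odd rule; wall points are not allowable)."""
        P = np.asarray(p, dtype=np.float64).reshape(1, 2)
        return bool(_k.points_inside(P, self.seg_a, self.seg_b)[0])

    def points_allowable(self, P) -> np.ndarray:
        P = np.ascontiguousarray(np.asarray(P, dtype=np.float64).reshape(-1, 2))
        return _k.points_inside(P, self.seg_a, self.seg_b)

    def line_of_sight(self, a, b, eps: float = EPS_LOS) -> bool:
        """True iff the open segment (a, b) crosses no wall segment."""
        ax, ay = map(float, a)
        bx, by = map(float, b)
        return bool(_k.los_clear(ax, ay, bx, by, self.seg_a, self.seg_b, eps))

    def wall_query(self, p) -> WallQuery:
        d, n = self.wall_query_batch(np.asarray(p, dtype=np.float64).reshape(1, 2))
        return WallQuery(float(d[0]), n[0])

    def wall_query_batch(self, P) -> tuple[np.ndarray, np.ndarray]:
        P = np.ascontiguousarray(np.asarray(P, dtype=np.float64).reshape(-1, 2))
        return _k.wall_query_batch(P, self.seg_a, self.seg_b)

    # -- feature arrays --------------------------------------------------

    @property
    def cue_xy(self) -> np.ndarray:
        return self._cue_xy

    @property
    def reward_xy(self) -> np.ndarray:
        return self._reward_xy

    @property
    def reward_ids(self) -> list[str]:
        return [r.id for r in self.rewards]

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "outer_ring": self.outer_ring.tolist(),
            "hole_rings": [h.tolist() for h in self.hole_rings],
            "cues": [{"id": c.id, "x": c.xy[0], "y": c.xy[1]} for c in self.cues],
            "rewards": [{"id": r.id, "x": r.xy[0], "y": r.xy[1]} for r in self.rewards],
            "spawn_disks": [
                {"x": s.center[0], "y": s.center[1], "radius": s.radius}
                for s in self.spawn_disks
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Arena":
        return cls(
            outer_ring=d["outer_ring"],
            hole_rings=d.get("hole_rings", []),
            cues=[(c["id"], c["x"], c["y"]) for c in d.get("cues", [])],
            rewards=[(r["id"], r["x"], r["y"]) for r in d.get("rewards", [])],
            spawn_disks=[(s["x"], s["y"], s["radius"]) for s in d.get("spawn_disks", [])],
            name=d.get("name", "arena"),
        )

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path) -> "Arena":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"Arena({self.name!r}, {len(self.outer_ring)} outer vertices, "
            f"{len(self.hole_rings)} holes, {len(self.cues)} cues, "
            f"{len(self.rewards)} rewards, {len(self.spawn_disks)} spawn disks)"
        )


# -- module-level functional forms ---------------------------------------


def notional_radius(arena: Arena) -> float:
    return arena.notional_radius


def point_allowable(p, arena: Arena) -> bool:
    return arena.point_allowable(p)


def line_of_sight(a, b, arena: Arena, eps: float = EPS_LOS) -> bool:
    return arena.line_of_sight(a, b, eps)


def wall_query(p, arena: Arena) -> WallQuery:
    return arena.wall_query(p)
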