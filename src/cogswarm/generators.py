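"""Parametric arena generators.

Two study environments are produced synthetically: a fragmented multi-reward
arena (three rewards in north-west / south-west / south-east compartments,
seven cues, three spawn disks, ~500-point height) and a rectangular hairpin
maze (885x519 points by default, five hallways separated by alternating
top/bottom divider walls, rewards in three hallways, seven cues, four spawn
disks). A third open single-reward arena supports structure-formation
studies. Wall layouts are deterministic; cue placement is drawn from the
seeded generator, so arenas are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Arena, ArenaError

__all__ = [
    "GenerationError",
    "MultirewardSpec",
    "HairpinSpec",
    "make_multireward_arena",
    "make_hairpin_maze",
    "make_open_arena",
]


class GenerationError(RuntimeError):
    """Raised when feature placement fails after bounded retries."""


def _place_cues(arena_factory, rng, n_cues, clearance, separation, max_tries=20000):
    """Rejection-sample cue points with wall clearance and mutual separation.

    ``arena_factory`` builds the arena without cues so placement can query
    allowability and wall distance against the final wall layout.
    """
    arena = arena_factory()
    xmin, ymin, xmax, ymax = arena.bounds
    placed: list[tuple[float, float]] = []
    tries = 0
    while len(placed) < n_cues:
        if tries >= max_tries:
            raise GenerationError(
                f"failed to place {n_cues} cues after {max_tries} tries"
            )
        tries += 1
        x = rng.uniform(xmin, xmax)
        y = rng.uniform(ymin, ymax)
        if not arena.point_allowable((x, y)):
            continue
        if arena.wall_query((x, y)).distance < clearance:
            continue
        if any((x - px) ** 2 + (y - py) ** 2 < separation**2 for px, py in placed):
            continue
        placed.append((x, y))
    return placed


@dataclass(frozen=True)
class MultirewardSpec:
    """Generator parameters for the fragmented multi-reward arena."""

    width: float = 700.0
    height: float = 500.0
    wall_thickness: float = 12.0
    n_cues: int = 7
    cue_clearance: float = 25.0
    cue_separation: float = 70.0
    spawn_radius: float = 45.0


def make_multireward_arena(spec: MultirewardSpec | None = None, seed: int = 0) -> Arena:
    """Fragmented compartmented arena with 3 rewards (NW, SW, SE), 7 cues and
    3 spawn disks (SW, south-central, SE; the SW disk is listed first so a
    lone agent spawns in the south-west corner)."""
    spec = spec or MultirewardSpec()
    W, H, t = spec.width, spec.height, spec.wall_thickness
    sx = W / 700.0
    sy = H / 500.0

    def xs(v):
        return v * sx

    def ys(v):
        return v * sy

    # interior walls traced into the outer boundary (comb construction).
    # Compartment mouths are wide and the dividers short, so each reward is
    # occluded from the opposite compartments but visible from much of the
    # central band -- which is what lets the long-range reward kernel
    # recruit particles across compartments:
    #   A: from the west wall at y~[320, 332], reaching to x=200 (NW/SW split)
    #   B: from the floor at x~[250, 262], reaching to y=140 (SW/central split)
    #   C: from the floor at x~[450, 462], reaching to y=140 (central/SE split)
    #   D: from the ceiling at x~[430, 442], down to y=360 (NW/NE split)
    outer = [
        (0, 0),
        (xs(250), 0),
        (xs(250), ys(140)),
        (xs(250) + t, ys(140)),
        (xs(250) + t, 0),
        (xs(450), 0),
        (xs(450), ys(140)),
        (xs(450) + t, ys(140)),
        (xs(450) + t, 0),
        (W, 0),
        (W, H),
        (xs(430) + t, H),
        (xs(430) + t, ys(360)),
        (xs(430), ys(360)),
        (xs(430), H),
        (0, H),
        (0, ys(320) + t),
        (xs(200), ys(320) + t),
        (xs(200), ys(320)),
        (0, ys(320)),
    ]
    hole = [
        (xs(330), ys(240)),
        (xs(370), ys(240)),
        (xs(370), ys(280)),
        (xs(330), ys(280)),
    ]
    rewards = [
        ("NW", xs(60), ys(450)),
        ("SW", xs(60), ys(55)),
        ("SE", xs(645), ys(70)),
    ]
    spawn_disks = [
        (xs(130), ys(130), spec.spawn_radius),
        (xs(355), ys(110), spec.spawn_radius),
        (xs(580), ys(110), spec.spawn_radius),
    ]

    def factory(cues=()):
        return Arena(
            outer_ring=outer,
            hole_rings=[hole],
            cues=cues,
            rewards=rewards,
            spawn_disks=spawn_disks,
            name="multireward",
        )

    rng = np.random.default_rng(seed)
    cue_pts = _place_cues(
        factory, rng, spec.n_cues, spec.cue_clearance, spec.cue_separation
    )
    return factory(cues=[(f"C{i}", x, y) for i, (x, y) in enumerate(cue_pts)])


@dataclass(frozen=True)
class HairpinSpec:
    """Generator parameters for the hairpin maze."""

    wall_thickness: float = 9.0
    gap_frac: float = 0.2
    n_cues: int = 7
    n_spawn: int = 4
    cue_clearance: float = 20.0
    cue_separation: float = 60.0
    min_hallway_width: float = 40.0


def make_hairpin_maze(
    width: float = 885.0,
    height: float = 519.0,
    n_hallways: int = 5,
    rewards_in: tuple[int, ...] = (0, 2, 4),
    spec: HairpinSpec | None = None,
    seed: int = 0,
) -> Arena:
    """Rectangular maze partitioned into ``n_hallways`` by divider walls with
    alternating top/bottom gaps (hairpin pattern).

    Odd-numbered dividers attach to the floor (gap at the top); even-numbered
    dividers attach to the ceiling (gap at the bottom), so consecutive
    hallways connect in a snake. Rewards go near the occluded end of their
    hallway; spawn disks are centered in the first ``n_spawn`` hallways.
    """
    spec = spec or HairpinSpec()
    if n_hallways < 2:
        raise GenerationError("hairpin maze needs at least 2 hallways")
    W, H, t = float(width), float(height), spec.wall_thickness
    hw = (W - (n_hallways - 1) * t) / n_hallways
    if hw < spec.min_hallway_width:
        raise GenerationError(
            f"hallway width {hw:.1f} below clearance threshold "
            f"{spec.min_hallway_width}"
        )
    gap = spec.gap_frac * H

    def divider_x(i):  # divider i sits between hallways i-1 and i
        xl = i * hw + (i - 1) * t
        return xl, xl + t

    ring: list[tuple[float, float]] = [(0.0, 0.0)]
    for i in range(1, n_hallways):
        if i % 2 == 1:  # floor-attached, gap at top
            xl, xr = divider_x(i)
            ring += [(xl, 0.0), (xl, H - gap), (xr, H - gap), (xr, 0.0)]
    ring += [(W, 0.0), (W, H)]
    for i in range(n_hallways - 1, 0, -1):
        if i % 2 == 0:  # ceiling-attached, gap at bottom
            xl, xr = divider_x(i)
            ring += [(xr, H), (xr, gap), (xl, gap), (xl, H)]
    ring += [(0.0, H)]

    def hall_center(i):
        return i * (hw + t) + hw / 2.0

    def gap_sides(i):
        sides = set()
        if i >= 1:
            sides.add("top" if i % 2 == 1 else "bottom")
        if i + 1 <= n_hallways - 1:
            sides.add("top" if (i + 1) % 2 == 1 else "bottom")
        return sides

    rewards = []
    for h in rewards_in:
        if not 0 <= h < n_hallways:
            raise GenerationError(f"reward hallway {h} out of range")
        sides = gap_sides(h)
        if sides == {"top"}:
            y = 0.1 * H
        elif sides == {"bottom"}:
            y = 0.9 * H
        else:
            y = 0.5 * H
        rewards.append((f"R{h}", hall_center(h), y))

    spawn_disks = [
        (hall_center(i), H / 2.0, min(0.35 * hw, 50.0))
        for i in range(min(spec.n_spawn, n_hallways))
    ]

    def factory(cues=()):
        return Arena(
            outer_ring=ring,
            cues=cues,
            rewards=rewards,
            spawn_disks=spawn_disks,
            name="hairpin",
        )

    rng = np.random.default_rng(seed)
    cue_pts = _place_cues(
        factory, rng, spec.n_cues, spec.cue_clearance, spec.cue_separation
    )
    return factory(cues=[(f"C{i}", x, y) for i, (x, y) in enumerate(cue_pts)])


def make_open_arena(
    width: float = 500.0,
    height: float = 500.0,
    n_cues: int = 7,
    seed: int = 0,
) -> Arena:
    """Open rectangular arena with a single central reward, ``n_cues`` seeded
    cues and three spawn disks; used for ring/structure formation studies."""
    W, H = float(width), float(height)
    rad = 0.1 * min(W, H)
    ring = [(0.0, 0.0), (W, 0.0), (W, H), (0.0, H)]
    spawn_disks = [
        (0.25 * W, 0.25 * H, rad),
        (0.75 * W, 0.3 * H, rad),
        (0.5 * W, 0.8 * H, rad),
    ]
    rewards = [("C", 0.5 * W, 0.5 * H)]

    def factory(cues=()):
        return Arena(
            outer_ring=ring,
            cues=cues,
            rewards=rewards,
            spawn_disks=spawn_disks,
            name="open",
        )

    rng = np.random.default_rng(seed)
    cue_pts = _place_cues(factory, rng, n_cues, 0.05 * min(W, H), 0.12 * min(W, H))
    return factory(cues=[(f"C{i}", x, y) for i, (x, y) in enumerate(cue_pts)])
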