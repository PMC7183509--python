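import numpy as np
import pytest

import cogswarm as cs


@pytest.fixture(scope="session")
def square_arena():
    """Empty convex 200x200 arena."""
    return cs.Arena(outer_ring=[(0, 0), (200, 0), (200, 200), (0, 200)], name="square")


@pytest.fixture(scope="session")
def divided_arena():
    """Square arena with a free-standing vertical wall slab in the middle."""
    return cs.Arena(
        outer_ring=[(0, 0), (200, 0), (200, 200), (0, 200)],
        hole_rings=[[(95, 20), (105, 20), (105, 180), (95, 180)]],
        name="divided",
    )


@pytest.fixture(scope="session")
def duet_arena():
    """Two-agent arena: one cue visible from everywhere, two tight spawn
    disks on a horizontal line."""
    return cs.Arena(
        outer_ring=[(0, 0), (200, 0), (200, 200), (0, 200)],
        cues=[("C0", 100, 120)],
        spawn_disks=[(70, 100, 1.0), (130, 100, 1.0)],
        name="duet",
    )


@pytest.fixture(scope="session")
def multireward_arena():
    return cs.make_multireward_arena(seed=7)


@pytest.fixture(scope="session")
def hairpin_arena():
    return cs.make_hairpin_maze(seed=3)


@pytest.fixture(scope="session")
def open_arena():
    return cs.make_open_arena(seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_allowable_points(arena, rng, n):
    """Rejection-sample n allowable points (test helper)."""
    xmin, ymin, xmax, ymax = arena.bounds
    pts = []
    while len(pts) < n:
        p = (rng.uniform(xmin, xmax), rng.uniform(ymin, ymax))
        if arena.point_allowable(p):
            pts.append(p)
    return np.asarray(pts)
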