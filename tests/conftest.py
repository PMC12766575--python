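import numpy as np
import pytest

from operant_arena import ArenaGeometry, trajectory_from_arrays


@pytest.fixture
def geom():
    """10 x 2 unit arena, boundary at mid-length, ROSA on the high-x end."""
    return ArenaGeometry(
        length=10.0,
        width=2.0,
        boundary_position=5.0,
        rosa_side="high",
        rosa_port=(9.5, 1.0),
        nosa_port=(0.5, 1.0),
        px_per_unit=10.0,
    )


@pytest.fixture
def make_traj():
    """Build a trajectory from x positions (y defaults to mid-width)."""

    def _make(xs, ys=None, fps=1.0, fly_id="toy"):
        xs = np.asarray(xs, dtype=float)
        if ys is None:
            ys = np.full_like(xs, 1.0)
        return trajectory_from_arrays(xs, np.asarray(ys, float), fps=fps, fly_id=fly_id)

    return _make


@pytest.fixture
def random_occupancy():
    """Seeded random Boolean occupancy series factory."""
    from operant_arena import OccupancySeries

    def _make(n, fps=15.0, p=0.5, seed=0):
        rng = np.random.default_rng(seed)
        return OccupancySeries(values=rng.random(n) < p, fps=fps)

    return _make
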