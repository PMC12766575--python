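"""Per-frame occupancy, time-binned occupation scores and bout segmentation.

The per-frame Boolean occupation score (1 in ROSA, 0 in NoSA) is the
backbone of the assay: averaged over time bins it yields the occupancy
scores plotted in heat maps, and its run-length structure defines bouts —
single entry-to-exit episodes of residence in a region, the unit of
stimulus self-administration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .geometry import NOSA, ROSA, ArenaGeometry, depths_toward_port, rosa_mask
from .trajio import Trajectory


@dataclass
class OccupancySeries:
    """Per-frame Boolean ROSA membership aligned to a trajectory.

    ``values[i]`` is True when the fly is in ROSA at frame ``i``.  Frames
    whose position was never observed carry the nearest observed value and
    ``imputed`` True.
    """

    values: np.ndarray
    fps: float
    imputed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.imputed is None:
            self.imputed = np.zeros(len(self.values), dtype=bool)
        else:
            self.imputed = np.asarray(self.imputed, dtype=bool)
        if len(self.imputed) != len(self.values):
            raise ValueError("imputed flags must align with values")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def duration_s(self) -> float:
        return len(self.values) / self.fps

    def region_values(self, region: str) -> np.ndarray:
        if region == ROSA:
            return self.values
        if region == NOSA:
            return ~self.values
        raise ValueError(f"unknown region {region!r}")

    def time_in_region(self, region: str) -> float:
        """Seconds spent in ``region`` over the whole series."""
        return float(self.region_values(region).sum()) / self.fps


@dataclass
class Bout:
    """One entry-to-exit episode of residence in a region.

    Frames covered are the half-open interval [entry_frame, exit_frame).
    ``truncated`` marks a residence still in progress at session end.
    ``distance`` and ``max_depth`` are filled by :func:`annotate_bouts`.
    """

    region: str
    entry_frame: int
    exit_frame: int
    fps: float
    truncated: bool = False
    distance: float = float("nan")
    max_depth: float = float("nan")

    def __post_init__(self) -> None:
        if self.exit_frame <= self.entry_frame:
            raise ValueError("exit_frame must exceed entry_frame")

    @property
    def n_frames(self) -> int:
        return self.exit_frame - self.entry_frame

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    @property
    def entry_s(self) -> float:
        return self.entry_frame / self.fps

    @property
    def exit_s(self) -> float:
        return self.exit_frame / self.fps


# -- occupancy ----------------------------------------------------------------


def occupancy_from_trajectory(traj: Trajectory, g: ArenaGeometry) -> OccupancySeries:
    """Per-frame region assignment of a (repaired) trajectory.

    Frames that remain invalid after repair carry the last valid region
    (or the first valid one, for a leading gap) and are flagged imputed,
    so every frame of the session is assigned to exactly one region.
    """
    valid = traj.valid
    if not valid.any():
        raise ValueError(f"{traj.fly_id}: cannot derive occupancy, no valid frames")
    x = traj.x
    y = traj.y
    inside = (x >= 0) & (x <= g.length) & (y >= 0) & (y <= g.width)
    bad = valid & ~inside
    if bad.any():
        frame = int(np.flatnonzero(bad)[0])
        raise ValueError(f"{traj.fly_id}: position outside arena at frame {frame}")

    values = np.zeros(len(x), dtype=bool)
    values[valid] = rosa_mask(x[valid], g)
    # carry nearest observed region into unrepaired gaps
    idx = np.arange(len(x))
    prev = np.where(valid, idx, -1)
    prev = np.maximum.accumulate(prev)
    first_valid = int(np.flatnonzero(valid)[0])
    prev[prev < 0] = first_valid
    values = values[prev]
    imputed = traj.imputed | ~valid
    return OccupancySeries(values=values, fps=traj.fps, imputed=imputed)


def binned_occupation_score(
    occ: OccupancySeries, bin_seconds: float, drop_partial: bool = False
) -> np.ndarray:
    """Mean occupation score per half-open time bin [k*b, (k+1)*b).

    Each bin's score is (number of ROSA frames) / (frames in bin), in
    [0, 1].  A final partial bin is kept (averaged over its actual frame
    count) unless ``drop_partial``.
    """
    if bin_seconds <= 0:
        raise ValueError("bin_seconds must be > 0")
    v = occ.values
    if len(v) == 0:
        raise ValueError("empty occupancy series")
    per_bin = int(round(bin_seconds * occ.fps))
    if per_bin < 1:
        raise ValueError("bin shorter than one frame")
    n_full = len(v) // per_bin
    scores = [v[k * per_bin : (k + 1) * per_bin].mean() for k in range(n_full)]
    rem = len(v) - n_full * per_bin
    if rem and not drop_partial:
        scores.append(v[n_full * per_bin :].mean())
    return np.asarray(scores, dtype=float)


def last_bin_partial(occ: OccupancySeries, bin_seconds: float) -> bool:
    per_bin = int(round(bin_seconds * occ.fps))
    return len(occ) % per_bin != 0


# -- bouts --------------------------------------------------------------------


def segment_bouts(
    occ: OccupancySeries, region: str, min_bout_frames: int = 1
) -> list[Bout]:
    """Split the occupancy series into maximal runs of ``region`` membership.

    Runs shorter than ``min_bout_frames`` are discarded (the default of 1
    keeps every run: the assay defines no minimum bout duration, and short
    bouts are part of the reported duration histograms — the knob exists
    for noisy trackers).  A run still in progress at session end yields a
    bout with ``truncated=True``.
    """
    if min_bout_frames < 1:
        raise ValueError("min_bout_frames must be >= 1")
    member = occ.region_values(region)
    n = len(member)
    if n == 0:
        return []
    # run-length boundaries
    change = np.flatnonzero(np.diff(member.astype(np.int8))) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [n]))
    bouts = []
    for s, e in zip(starts, ends):
        if not member[s]:
            continue
        if e - s < min_bout_frames:
            continue
        bouts.append(
            Bout(
                region=region,
                entry_frame=int(s),
                exit_frame=int(e),
                fps=occ.fps,
                truncated=bool(e == n),
            )
        )
    return bouts


def step_lengths(traj: Trajectory) -> np.ndarray:
    """Per-frame displacement, attributed to the destination frame.

    ``out[i]`` is the Euclidean distance from frame ``i-1`` to frame ``i``;
    ``out[0]`` is 0.  Steps into or out of an unobserved (invalid or
    imputed) frame contribute 0, so held positions never fabricate travel.
    """
    x, y = traj.x, traj.y
    d = np.zeros(len(x))
    if len(x) > 1:
        d[1:] = np.hypot(np.diff(x), np.diff(y))
    ok = traj.observed
    good = np.zeros(len(x), dtype=bool)
    if len(x) > 1:
        good[1:] = ok[1:] & ok[:-1]
    d[~good] = 0.0
    return d


def annotate_bouts(
    bouts: Sequence[Bout], traj: Trajectory, g: ArenaGeometry
) -> list[Bout]:
    """Fill per-bout distance and maximum depth from the trajectory.

    Distance sums the step lengths whose destination frame lies in the
    bout (so the entry step, which crosses the boundary, counts toward the
    bout it opens).  Max depth is the deepest long-axis penetration toward
    the region's port over the bout's frames, evaluated on observed frames.
    """
    steps = step_lengths(traj)
    obs = traj.observed
    out = []
    for b in bouts:
        sl = slice(b.entry_frame, b.exit_frame)
        b.distance = float(steps[sl].sum())
        frames_obs = obs[sl]
        if frames_obs.any():
            d = depths_toward_port(traj.x[sl][frames_obs], g, b.region)
            b.max_depth = float(d.max())
        else:
            b.max_depth = 0.0
        out.append(b)
    return out


def latencies_to_reenter(bouts: Sequence[Bout], fps: float | None = None) -> np.ndarray:
    """Seconds between each bout's exit and the next bout's entry.

    The final bout has no successor and contributes nothing (a truncated
    final bout never exited at all).  Empty input yields an empty array.
    """
    if len(bouts) < 2:
        return np.empty(0)
    regions = {b.region for b in bouts}
    if len(regions) > 1:
        raise ValueError(f"bouts from multiple regions: {sorted(regions)}")
    fps = fps or bouts[0].fps
    lat = [
        (nxt.entry_frame - cur.exit_frame) / fps
        for cur, nxt in zip(bouts[:-1], bouts[1:])
    ]
    return np.asarray(lat, dtype=float)


def heatmap_matrix(
    occs: Sequence[OccupancySeries],
    bin_seconds: float = 60.0,
    truncate: bool = False,
) -> np.ndarray:
    """Fly x time-bin matrix of occupation scores (rows in input order).

    All series must share fps and duration; pass ``truncate=True`` to clip
    heterogeneous sessions to the shortest one instead of erroring.
    """
    if not occs:
        raise ValueError("no occupancy series given")
    fps = occs[0].fps
    if any(o.fps != fps for o in occs):
        raise ValueError("heterogeneous fps across series")
    lengths = {len(o) for o in occs}
    if len(lengths) > 1:
        if not truncate:
            raise ValueError(
                "heterogeneous session durations; pass truncate=True to clip"
            )
        n = min(lengths)
        occs = [OccupancySeries(o.values[:n], fps, o.imputed[:n]) for o in occs]
    rows = [binned_occupation_score(o, bin_seconds) for o in occs]
    return np.vstack(rows)
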