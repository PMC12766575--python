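"""Session/bout behavioral metrics, preference and operant-learning indices,
per-minute metric time series, duration histograms, and the PCA valence
summary.

Session behaviors summarise one fly's whole 15-min session with respect to
one region: total time spent there, total distance moved while there, and
maximum depth (long-axis penetration) toward the region's port.  Bout
behaviors describe the periodic structure of residence: number of entries,
mean bout duration, mean distance per bout and mean latency to re-enter.

Two dimensionless indices summarise preference and within-session change:

* preference index  PI = (time_ROSA - time_NoSA) / (time_ROSA + time_NoSA),
  computed over the last seven minutes of the 15-min session;
* operant learning index  OLI = (L - E) / (L + E), comparing a metric's
  value in the late 1-min bin (minute 14, frames [780 s, 840 s)) against
  the early bin (minute 1, frames [0 s, 60 s)).

Both live in [-1, 1]; a zero denominator yields an undefined marker (None),
never a zero, so degenerate flies do not deflate group averages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA

from .bouts import (
    Bout,
    OccupancySeries,
    annotate_bouts,
    latencies_to_reenter,
    segment_bouts,
    step_lengths,
)
from .geometry import NOSA, ROSA, ArenaGeometry, depths_toward_port
from .trajio import Trajectory

#: default bout-duration histogram edges (seconds); terminal bin is [30, inf)
DEFAULT_HIST_EDGES: tuple[float, ...] = (0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0)

#: default preference-index window: the last seven minutes of a 15-min session
DEFAULT_PI_WINDOW: tuple[float, float] = (480.0, 900.0)

METRIC_NAMES = ("time", "distance", "depth")


@dataclass
class MetricsRecord:
    """All per-fly, per-region metrics and indices for one session.

    Means over zero bouts/latencies and indices with zero denominators are
    ``None`` (undefined), never 0.
    """

    fly_id: str
    region: str
    total_time_s: float
    total_distance: float
    max_depth: float
    n_bouts: int
    mean_bout_duration_s: float | None
    mean_bout_distance: float | None
    mean_latency_s: float | None
    preference_index: float | None
    oli_time: float | None
    oli_distance: float | None
    oli_depth: float | None
    duration_histogram: np.ndarray = field(default_factory=lambda: np.zeros(0))
    hist_edges: tuple = DEFAULT_HIST_EDGES
    time_series: np.ndarray = field(default_factory=lambda: np.zeros(0))
    distance_series: np.ndarray = field(default_factory=lambda: np.zeros(0))
    depth_series: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @staticmethod
    def scalar_fields() -> tuple[str, ...]:
        return (
            "fly_id",
            "region",
            "total_time_s",
            "total_distance",
            "max_depth",
            "n_bouts",
            "mean_bout_duration_s",
            "mean_bout_distance",
            "mean_latency_s",
            "preference_index",
            "oli_time",
            "oli_distance",
            "oli_depth",
        )

    def to_dict(self) -> dict:
        """Flatten to one tidy row; arrays expand into numbered columns."""
        row = {k: getattr(self, k) for k in self.scalar_fields()}
        for i, c in enumerate(np.asarray(self.duration_histogram, dtype=float)):
            edges = self.hist_edges
            label = (
                f"hist_{edges[i]:g}_{edges[i + 1]:g}s"
                if i + 1 < len(edges)
                else f"hist_{edges[-1]:g}s_plus"
            )
            row[label] = c
        for name, series in (
            ("time", self.time_series),
            ("distance", self.distance_series),
            ("depth", self.depth_series),
        ):
            for i, v in enumerate(np.asarray(series, dtype=float), start=1):
                row[f"{name}_bin{i:02d}"] = v
        return row


# -- session & bout metrics ---------------------------------------------------


def session_metrics(
    traj: Trajectory,
    occ: OccupancySeries,
    g: ArenaGeometry,
    region: str = ROSA,
) -> dict:
    """Total time, total distance and max depth for one region.

    time   = (frames in region) / fps;
    distance sums Euclidean step lengths whose destination frame is in the
    region (steps touching unobserved frames contribute 0);
    max_depth is the deepest penetration toward the region's port over the
    region's observed frames, 0 if the fly never entered.
    """
    if len(occ) != traj.n_frames:
        raise ValueError("trajectory and occupancy series lengths differ")
    member = occ.region_values(region)
    total_time = float(member.sum()) / occ.fps
    steps = step_lengths(traj)
    total_distance = float(steps[member].sum())
    obs = traj.observed & member
    if obs.any():
        max_depth = float(depths_toward_port(traj.x[obs], g, region).max())
        max_depth = max(max_depth, 0.0)
    else:
        max_depth = 0.0
    return {
        "total_time_s": total_time,
        "total_distance": total_distance,
        "max_depth": max_depth,
    }


def bout_metrics(bouts: Sequence[Bout], latencies: np.ndarray) -> dict:
    """Count and arithmetic means of bout duration/distance/latency.

    With no bouts (or no latencies) the corresponding means are ``None``.
    """
    n = len(bouts)
    durations = np.array([b.duration_s for b in bouts])
    distances = np.array([b.distance for b in bouts])
    latencies = np.asarray(latencies, dtype=float)
    return {
        "n_bouts": n,
        "mean_bout_duration_s": float(durations.mean()) if n else None,
        "mean_bout_distance": (
            float(distances.mean()) if n and np.isfinite(distances).all() else None
        ),
        "mean_latency_s": float(latencies.mean()) if latencies.size else None,
    }


def duration_histogram(
    bouts: Sequence[Bout] | np.ndarray,
    edges: Sequence[float] = DEFAULT_HIST_EDGES,
) -> np.ndarray:
    """Bout counts per duration category.

    Bins are half-open [e_i, e_{i+1}) plus a terminal [e_last, inf); with
    e_0 = 0 the counts always sum to the number of bouts.
    """
    edges = np.asarray(edges, dtype=float)
    if len(edges) < 1 or np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be strictly increasing")
    if len(bouts) and isinstance(bouts[0], Bout):
        durations = np.array([b.duration_s for b in bouts])
    else:
        durations = np.asarray(bouts, dtype=float)
    full_edges = np.concatenate((edges, [np.inf]))
    counts, _ = np.histogram(durations, bins=full_edges)
    return counts


# -- indices ------------------------------------------------------------------


def preference_index(
    total_time_rosa: float, total_time_nosa: float
) -> float | None:
    """(R - N) / (R + N): positive means ROSA preference, in [-1, 1].

    Undefined (None) when both times are zero.
    """
    r, n = float(total_time_rosa), float(total_time_nosa)
    if r < 0 or n < 0:
        raise ValueError("region times must be non-negative")
    if r + n == 0:
        return None
    return (r - n) / (r + n)


def preference_index_from_occupancy(
    occ: OccupancySeries, window: tuple[float, float] | None = DEFAULT_PI_WINDOW
) -> float | None:
    """PI over a half-open time window [start, stop) in seconds.

    The default window is the last seven minutes of a 15-min session.
    ``window=None`` uses the whole series.  Sessions shorter than the
    requested window are clipped to what exists.
    """
    if window is None:
        sl = slice(None)
    else:
        start, stop = window
        if not 0 <= start < stop:
            raise ValueError(f"bad window {window}")
        sl = slice(int(np.floor(start * occ.fps)), int(np.floor(stop * occ.fps)))
    v = occ.values[sl]
    if v.size == 0:
        return None
    r = float(v.sum()) / occ.fps
    n = float((~v).sum()) / occ.fps
    return preference_index(r, n)


def operant_learning_index(
    metric_bin_late: float, metric_bin_early: float, allow_negative: bool = False
) -> float | None:
    """(L - E) / (L + E): within-session change of a metric, in [-1, 1].

    L and E are the metric's values in the late (minute-14) and early
    (minute-1) bins.  L = E gives 0; L = E = 0 is undefined (None) and
    should be excluded from aggregation.  Time and distance metrics must be
    non-negative; depth uses the per-bin maximum clipped at 0, so it too is
    non-negative here.
    """
    late, early = float(metric_bin_late), float(metric_bin_early)
    if not allow_negative and (late < 0 or early < 0):
        raise ValueError("metric values must be non-negative")
    if late == early == 0:
        return None
    if late == early:
        return 0.0
    return (late - early) / (late + early)


# -- time series --------------------------------------------------------------


def metric_time_series(
    traj: Trajectory,
    occ: OccupancySeries,
    g: ArenaGeometry,
    metric: str,
    bin_seconds: float = 60.0,
    region: str = ROSA,
    depth_stat: str = "max",
) -> np.ndarray:
    """Per-bin region metric over the session (bins half-open, 1-indexed).

    metric ``"time"``: seconds in region per bin; ``"distance"``: distance
    moved in region per bin; ``"depth"``: deepest penetration toward the
    region's port per bin (0 when absent; ``depth_stat="mean"`` averages
    instead).  Binned time and distance sum exactly to the session totals.
    """
    if metric not in METRIC_NAMES:
        raise ValueError(f"unknown metric {metric!r}; options {METRIC_NAMES}")
    if bin_seconds <= 0:
        raise ValueError("bin_seconds must be > 0")
    if len(occ) != traj.n_frames:
        raise ValueError("trajectory and occupancy series lengths differ")
    member = occ.region_values(region)
    per_bin = int(round(bin_seconds * occ.fps))
    n_bins = int(np.ceil(len(member) / per_bin))
    if metric == "distance":
        steps = step_lengths(traj)
    if metric == "depth":
        depths = depths_toward_port(traj.x, g, region)
        usable = member & traj.observed
    out = np.zeros(n_bins)
    for k in range(n_bins):
        sl = slice(k * per_bin, (k + 1) * per_bin)
        if metric == "time":
            out[k] = member[sl].sum() / occ.fps
        elif metric == "distance":
            out[k] = steps[sl][member[sl]].sum()
        else:
            m = usable[sl]
            if m.any():
                d = depths[sl][m]
                out[k] = max(d.max(), 0.0) if depth_stat == "max" else max(
                    d.mean(), 0.0
                )
    return out


# -- full record --------------------------------------------------------------


def compute_metrics_record(
    traj: Trajectory,
    occ: OccupancySeries,
    g: ArenaGeometry,
    region: str = ROSA,
    pi_window: tuple[float, float] | None = DEFAULT_PI_WINDOW,
    oli_bins: tuple[int, int] = (1, 14),
    hist_edges: Sequence[float] = DEFAULT_HIST_EDGES,
    bin_seconds: float = 60.0,
    min_bout_frames: int = 1,
) -> tuple[MetricsRecord, list[Bout]]:
    """Assemble the full per-fly metrics record for one region.

    ``oli_bins`` gives the (early, late) 1-indexed minute bins entering the
    operant learning indices; sessions too short for the late bin leave the
    OLIs undefined.  Returns the record and the annotated bouts.
    """
    sess = session_metrics(traj, occ, g, region)
    bouts = segment_bouts(occ, region, min_bout_frames=min_bout_frames)
    bouts = annotate_bouts(bouts, traj, g)
    lats = latencies_to_reenter(bouts, occ.fps)
    bm = bout_metrics(bouts, lats)
    hist = duration_histogram(bouts, hist_edges)

    series = {
        m: metric_time_series(traj, occ, g, m, bin_seconds=bin_seconds, region=region)
        for m in METRIC_NAMES
    }
    early, late = oli_bins
    olis: dict[str, float | None] = {}
    for m in METRIC_NAMES:
        s = series[m]
        if late <= len(s) and early <= len(s):
            olis[m] = operant_learning_index(s[late - 1], s[early - 1])
        else:
            olis[m] = None

    pi = preference_index_from_occupancy(occ, window=pi_window)
    if region == NOSA and pi is not None:
        pi = -pi  # mirror: preference for the record's own region

    record = MetricsRecord(
        fly_id=traj.fly_id,
        region=region,
        preference_index=pi,
        oli_time=olis["time"],
        oli_distance=olis["distance"],
        oli_depth=olis["depth"],
        duration_histogram=hist,
        hist_edges=tuple(hist_edges),
        time_series=series["time"],
        distance_series=series["distance"],
        depth_series=series["depth"],
        **sess,
        **bm,
    )
    return record, bouts


# -- PCA valence summary ------------------------------------------------------


@dataclass
class PCAResult:
    """Principal components of the z-scored fly x metric matrix.

    ``loadings`` has one row per component (orthonormal); eigenvalues
    (``explained_variance``) sum to the number of kept columns.  A
    component is retained when its eigenvalue exceeds 1 — i.e. it explains
    more variance than any single standardized variable (Kaiser rule).
    """

    loadings: np.ndarray
    scores: np.ndarray
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    retained: np.ndarray
    columns: list[str]
    dropped_columns: list[str]
    dropped_rows: list[int]


def pca_valence(
    matrix: np.ndarray, columns: Sequence[str] | None = None
) -> PCAResult:
    """PCA of behavioral metrics after column-wise z-scoring (sample SD).

    Rows containing undefined (NaN) metrics are dropped and reported;
    zero-variance columns are dropped with a warning.  Component signs are
    fixed so each component's largest-magnitude loading is positive.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("metric matrix must be 2-D (flies x metrics)")
    columns = list(columns) if columns is not None else [
        f"metric_{j}" for j in range(X.shape[1])
    ]
    if len(columns) != X.shape[1]:
        raise ValueError("column names do not match matrix width")

    row_ok = np.isfinite(X).all(axis=1)
    dropped_rows = np.flatnonzero(~row_ok).tolist()
    X = X[row_ok]
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 complete flies and 2 metrics")

    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    dropped_columns = [c for c, k in zip(columns, keep) if not k]
    if dropped_columns:
        warnings.warn(
            f"dropping zero-variance metric columns {dropped_columns}",
            stacklevel=2,
        )
    X = X[:, keep]
    columns = [c for c, k in zip(columns, keep) if k]
    if X.shape[1] < 2:
        raise ValueError("fewer than 2 metrics with variance")

    Z = (X - X.mean(axis=0)) / X[:, :].std(axis=0, ddof=1)
    pca = PCA(n_components=min(Z.shape[0] - 1, Z.shape[1]))
    scores = pca.fit_transform(Z)
    loadings = pca.components_.copy()
    # sign convention: largest-|loading| entry of each component positive
    for i in range(loadings.shape[0]):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] *= -1
            scores[:, i] *= -1
    ev = pca.explained_variance_.copy()
    return PCAResult(
        loadings=loadings,
        scores=scores,
        explained_variance=ev,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        retained=ev > 1.0,
        columns=columns,
        dropped_columns=dropped_columns,
        dropped_rows=dropped_rows,
    )
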