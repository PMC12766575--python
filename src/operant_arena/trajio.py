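"""Reading, validating and repairing per-frame trajectory tables.

The acquisition side of a self-administration arena writes one CSV per fly
per session with the fly position in x- and y-coordinates per frame (and
optionally the hardware's own Boolean occupation score).  This module reads
that dialect into a :class:`Trajectory`, turns unparseable or missing rows
into flagged invalid frames, and offers a hold-last-position gap repair for
short tracking dropouts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .metrics import MetricsRecord

#: default column-name mapping of the acquisition CSV dialect
DEFAULT_SCHEMA: dict[str, str] = {
    "frame": "frame",
    "x": "x",
    "y": "y",
    "occupation": "occupation",
}

FRAME_COLUMNS = ["frame", "t", "x", "y", "valid", "imputed"]


@dataclass
class Trajectory:
    """One fly's per-frame positions for a single session.

    ``frames`` is a DataFrame with columns ``frame`` (contiguous ints from
    0), ``t`` (= frame / fps, seconds), ``x``, ``y`` (NaN on invalid
    frames), ``valid`` (position observed or imputed), ``imputed``
    (position held from the last valid frame by gap repair).
    """

    fly_id: str
    fps: float
    frames: pd.DataFrame
    meta: dict = field(default_factory=dict)
    stored_occupation: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        missing = [c for c in FRAME_COLUMNS if c not in self.frames.columns]
        if missing:
            raise ValueError(f"trajectory frame table missing columns {missing}")
        idx = self.frames["frame"].to_numpy()
        if len(idx) and not np.array_equal(idx, np.arange(idx[0], idx[0] + len(idx))):
            raise ValueError("frame indices must be contiguous and increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    @property
    def x(self) -> np.ndarray:
        return self.frames["x"].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.frames["y"].to_numpy(dtype=float)

    @property
    def valid(self) -> np.ndarray:
        return self.frames["valid"].to_numpy(dtype=bool)

    @property
    def imputed(self) -> np.ndarray:
        return self.frames["imputed"].to_numpy(dtype=bool)

    @property
    def observed(self) -> np.ndarray:
        """Frames with a genuinely observed (non-imputed) position."""
        return self.valid & ~self.imputed


def _frame_table(frame: np.ndarray, t, x, y, valid, imputed) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "frame": np.asarray(frame, dtype=int),
            "t": np.asarray(t, dtype=float),
            "x": np.asarray(x, dtype=float),
            "y": np.asarray(y, dtype=float),
            "valid": np.asarray(valid, dtype=bool),
            "imputed": np.asarray(imputed, dtype=bool),
        }
    )


def trajectory_from_arrays(
    x: np.ndarray,
    y: np.ndarray,
    fps: float,
    fly_id: str = "fly",
    valid: np.ndarray | None = None,
    meta: dict | None = None,
) -> Trajectory:
    """Convenience constructor from position arrays (NaN means invalid)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if valid is None:
        valid = np.isfinite(x) & np.isfinite(y)
    n = len(x)
    frames = _frame_table(
        np.arange(n), np.arange(n) / fps, x, y, valid, np.zeros(n, dtype=bool)
    )
    frames.loc[~frames["valid"], ["x", "y"]] = np.nan
    return Trajectory(fly_id=fly_id, fps=fps, frames=frames, meta=dict(meta or {}))


def read_trajectory(
    path: str | Path,
    fps: float = 15.0,
    schema: Mapping[str, str] | None = None,
    fly_id: str | None = None,
    meta: dict | None = None,
) -> Trajectory:
    """Read an acquisition CSV into a :class:`Trajectory`.

    Rows with unparseable or absent coordinates become invalid frames;
    gaps in the frame index are filled with invalid frames so the stream is
    contiguous.  A stored occupation-score column, if present, is retained
    on the result for cross-checking only — region membership is always
    recomputed from geometry downstream.

    Raises on missing required columns, duplicate frame indices, or an
    empty file.
    """
    path = Path(path)
    cols = dict(DEFAULT_SCHEMA)
    cols.update(schema or {})
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty trajectory file")
    required = [cols["frame"], cols["x"], cols["y"]]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")

    frame_idx = pd.to_numeric(df[cols["frame"]], errors="raise").astype(int).to_numpy()
    if len(np.unique(frame_idx)) != len(frame_idx):
        dupes = np.unique(frame_idx[pd.Series(frame_idx).duplicated().to_numpy()])
        raise ValueError(f"{path}: duplicate frame indices {dupes.tolist()[:5]}")
    order = np.argsort(frame_idx)
    frame_idx = frame_idx[order]

    x = pd.to_numeric(df[cols["x"]], errors="coerce").to_numpy(dtype=float)[order]
    y = pd.to_numeric(df[cols["y"]], errors="coerce").to_numpy(dtype=float)[order]

    lo, hi = int(frame_idx[0]), int(frame_idx[-1])
    n = hi - lo + 1
    full_x = np.full(n, np.nan)
    full_y = np.full(n, np.nan)
    full_x[frame_idx - lo] = x
    full_y[frame_idx - lo] = y
    valid = np.isfinite(full_x) & np.isfinite(full_y)
    full_x[~valid] = np.nan
    full_y[~valid] = np.nan

    stored_occ = None
    if cols["occupation"] in df.columns:
        occ = pd.to_numeric(df[cols["occupation"]], errors="coerce").to_numpy(float)
        stored = np.full(n, np.nan)
        stored[frame_idx - lo] = occ[order]
        stored_occ = stored

    frames = _frame_table(
        np.arange(n),
        np.arange(n) / fps,
        full_x,
        full_y,
        valid,
        np.zeros(n, dtype=bool),
    )
    traj = Trajectory(
        fly_id=fly_id or path.stem,
        fps=fps,
        frames=frames,
        meta=dict(meta or {}),
    )
    traj.stored_occupation = stored_occ
    return traj


def repair_gaps(traj: Trajectory, max_gap_frames: int = 15) -> Trajectory:
    """Fill short runs of invalid frames by holding the last valid position.

    Runs of at most ``max_gap_frames`` consecutive invalid frames are filled
    with the preceding valid position and flagged ``imputed``; longer runs
    (and any leading run with no preceding valid frame) stay invalid.  Valid
    frames are untouched, so the operation is idempotent.  The default of 15
    frames is one second at 15 fps: long enough that a brief occlusion does
    not fragment a bout, short enough that a lost fly is not fabricated.
    """
    if max_gap_frames < 0:
        raise ValueError("max_gap_frames must be >= 0")
    valid = traj.valid
    if not valid.any():
        raise ValueError(f"{traj.fly_id}: trajectory has no valid frames")
    x = traj.x.copy()
    y = traj.y.copy()
    new_valid = valid.copy()
    imputed = traj.imputed.copy()

    n = len(valid)
    i = 0
    while i < n:
        if new_valid[i]:
            i += 1
            continue
        j = i
        while j < n and not new_valid[j]:
            j += 1
        run = j - i
        if i > 0 and run <= max_gap_frames:
            x[i:j] = x[i - 1]
            y[i:j] = y[i - 1]
            new_valid[i:j] = True
            imputed[i:j] = True
        i = j

    frames = _frame_table(
        traj.frames["frame"].to_numpy(),
        traj.frames["t"].to_numpy(),
        x,
        y,
        new_valid,
        imputed,
    )
    out = Trajectory(
        fly_id=traj.fly_id, fps=traj.fps, frames=frames, meta=dict(traj.meta)
    )
    out.stored_occupation = traj.stored_occupation
    return out


# -- metrics tables -----------------------------------------------------------


def write_metrics_table(records: Iterable["MetricsRecord"], path: str | Path) -> None:
    """Write one tidy CSV row per fly x region with all metrics and indices."""
    rows = [r.to_dict() for r in records]
    if rows:
        df = pd.DataFrame(rows)
    else:
        from .metrics import MetricsRecord

        df = pd.DataFrame(columns=list(MetricsRecord.scalar_fields()))
    df.to_csv(path, index=False)


def read_metrics_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def check_stored_occupation(
    traj: Trajectory, computed: np.ndarray, tolerance: float = 0.01
) -> float:
    """Compare a file's occupation column against geometry-derived occupancy.

    Returns the mismatch fraction over frames where both are defined and
    warns when it reaches ``tolerance`` (default 1%): the hardware ROI and
    the analysis ROI should agree to within rounding at the boundary.
    """
    stored = traj.stored_occupation
    if stored is None:
        return 0.0
    ok = np.isfinite(stored) & traj.observed
    if not ok.any():
        return 0.0
    mismatch = float(np.mean(stored[ok].astype(bool) != computed[ok].astype(bool)))
    if mismatch >= tolerance:
        warnings.warn(
            f"{traj.fly_id}: stored occupation score disagrees with geometry on "
            f"{mismatch:.1%} of frames",
            stacklevel=2,
        )
    return mismatch
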