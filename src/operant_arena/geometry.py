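"""Arena geometry: the two-zone oblong chamber and its region/depth calculus.

The arena is a rectangle whose long axis carries a single boundary splitting
it into a region of self-administration (ROSA), where presence triggers
stimulus delivery, and the opposite non-self-administration region (NoSA).
Each end of the long axis carries a port: the stimulus delivery port at the
ROSA end, the vacuum port at the NoSA end.

Coordinate convention: origin at the top-left of the camera image, ``x``
along the long axis, ``y`` down, all distances in physical units (the
calibration factor ``px_per_unit`` converts camera pixels to those units).
Points exactly on the boundary belong to NoSA by default, so that stimulus
valves never open on an ambiguous frame; the opposite convention is
available via ``boundary_is_rosa``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

ROSA = "ROSA"
NOSA = "NoSA"
REGIONS = (ROSA, NOSA)


class OutOfArenaError(ValueError):
    """A point fell outside the arena rectangle."""


@dataclass(frozen=True)
class Point:
    """A 2-D position, in pixels or physical units depending on context."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite point ({self.x}, {self.y})")


@dataclass(frozen=True)
class ArenaGeometry:
    """Two-zone oblong arena.

    Defaults are placeholders for a generic 10 x 2 unit lane with the
    boundary at mid-length and ROSA on the high-``x`` end; real arenas
    should supply measured dimensions via :meth:`from_config`.

    Parameters
    ----------
    length, width : float
        Arena extent along the long (``x``) and short (``y``) axes.
    boundary_position : float
        Coordinate on the long axis separating ROSA from NoSA.
    rosa_side : {"high", "low"}
        Which end of the long axis is ROSA.
    rosa_port, nosa_port : Point
        Stimulus delivery port (ROSA end) and vacuum port (NoSA end).
    px_per_unit : float
        Camera calibration, pixels per physical unit (> 0).
    boundary_is_rosa : bool
        If True, points exactly on the boundary count as ROSA.
    """

    length: float = 10.0
    width: float = 2.0
    boundary_position: float = 5.0
    rosa_side: str = "high"
    rosa_port: Point = Point(9.5, 1.0)
    nosa_port: Point = Point(0.5, 1.0)
    px_per_unit: float = 10.0
    boundary_is_rosa: bool = False

    def __post_init__(self) -> None:
        if self.length <= 0 or self.width <= 0:
            raise ValueError("arena dimensions must be positive")
        if not 0 < self.boundary_position < self.length:
            raise ValueError(
                f"boundary_position {self.boundary_position} must lie strictly "
                f"inside (0, {self.length})"
            )
        if self.rosa_side not in ("high", "low"):
            raise ValueError(f"rosa_side must be 'high' or 'low', got {self.rosa_side!r}")
        if self.px_per_unit <= 0:
            raise ValueError("px_per_unit must be > 0")
        for name in ("rosa_port", "nosa_port"):
            p = getattr(self, name)
            if not isinstance(p, Point):
                object.__setattr__(self, name, Point(*p))
        for name, region in (("rosa_port", ROSA), ("nosa_port", NOSA)):
            p = getattr(self, name)
            if not self.contains(p):
                raise ValueError(f"{name} {p} lies outside the arena")
            if depth_toward_port(p, self, region) <= 0:
                raise ValueError(f"{name} must sit inside the {region} region")

    # -- helpers -------------------------------------------------------------

    def contains(self, p: Point) -> bool:
        return 0 <= p.x <= self.length and 0 <= p.y <= self.width

    def rosa_span(self) -> tuple[float, float]:
        """(low, high) x-interval occupied by ROSA."""
        if self.rosa_side == "high":
            return (self.boundary_position, self.length)
        return (0.0, self.boundary_position)

    def nosa_span(self) -> tuple[float, float]:
        if self.rosa_side == "high":
            return (0.0, self.boundary_position)
        return (self.boundary_position, self.length)

    def with_boundary_convention(self, boundary_is_rosa: bool) -> "ArenaGeometry":
        return replace(self, boundary_is_rosa=boundary_is_rosa)

    @classmethod
    def from_config(cls, source: str | Path | Mapping) -> "ArenaGeometry":
        """Build a geometry from a YAML/JSON file or an already-parsed mapping.

        Recognised keys: length, width, boundary_position *or*
        boundary_fraction (default 0.5), rosa_side, rosa_port, nosa_port,
        px_per_unit, boundary_is_rosa.  Either a flat mapping or one nested
        under an ``arena`` key is accepted.
        """
        if isinstance(source, (str, Path)):
            text = Path(source).read_text()
            cfg = (
                json.loads(text)
                if str(source).endswith(".json")
                else yaml.safe_load(text)
            )
        else:
            cfg = dict(source)
        if "arena" in cfg:
            cfg = cfg["arena"]
        cfg = dict(cfg)
        length = float(cfg.pop("length", cls.length))
        if "boundary_position" in cfg:
            boundary = float(cfg.pop("boundary_position"))
            cfg.pop("boundary_fraction", None)
        else:
            boundary = length * float(cfg.pop("boundary_fraction", 0.5))
        kwargs = dict(length=length, boundary_position=boundary)
        for key in ("width", "px_per_unit"):
            if key in cfg:
                kwargs[key] = float(cfg.pop(key))
        if "rosa_side" in cfg:
            kwargs["rosa_side"] = str(cfg.pop("rosa_side"))
        if "boundary_is_rosa" in cfg:
            kwargs["boundary_is_rosa"] = bool(cfg.pop("boundary_is_rosa"))
        for key in ("rosa_port", "nosa_port"):
            if key in cfg:
                kwargs[key] = Point(*cfg.pop(key))
        if cfg:
            raise ValueError(f"unknown geometry config keys: {sorted(cfg)}")
        return cls(**kwargs)


# -- region assignment --------------------------------------------------------


def rosa_mask(x: np.ndarray, g: ArenaGeometry) -> np.ndarray:
    """Vectorised ROSA membership for long-axis coordinates ``x``.

    Boundary points follow ``g.boundary_is_rosa`` (NoSA by default).
    """
    x = np.asarray(x, dtype=float)
    b = g.boundary_position
    if g.rosa_side == "high":
        return x >= b if g.boundary_is_rosa else x > b
    return x <= b if g.boundary_is_rosa else x < b


def assign_region(p: Point, g: ArenaGeometry, frame: int | None = None) -> str:
    """Label a point ROSA or NoSA; error on points outside the arena."""
    if not g.contains(p):
        where = f" at frame {frame}" if frame is not None else ""
        raise OutOfArenaError(f"point ({p.x}, {p.y}){where} lies outside the arena")
    return ROSA if bool(rosa_mask(np.float64(p.x), g)) else NOSA


# -- depth --------------------------------------------------------------------


def depths_toward_port(x: np.ndarray, g: ArenaGeometry, region: str) -> np.ndarray:
    """Signed long-axis penetration from the boundary toward a region's port.

    Positive inside ``region``, negative outside, zero exactly on the
    boundary.  Antisymmetric in the region label.
    """
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r}")
    x = np.asarray(x, dtype=float)
    d_rosa = x - g.boundary_position
    if g.rosa_side == "low":
        d_rosa = -d_rosa
    return d_rosa if region == ROSA else -d_rosa


def depth_toward_port(p: Point, g: ArenaGeometry, region: str) -> float:
    if not g.contains(p):
        raise OutOfArenaError(f"point ({p.x}, {p.y}) lies outside the arena")
    return float(depths_toward_port(np.float64(p.x), g, region))


def port_distance(p: Point, g: ArenaGeometry, region: str) -> float:
    """Euclidean distance to a region's port (alternative proximity measure).

    The canonical depth metric is long-axis penetration
    (:func:`depth_toward_port`), which is monotone in port proximity for an
    oblong arena while ignoring lateral wobble; this Euclidean variant is
    provided for users who prefer the literal port distance.
    """
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r}")
    port = g.rosa_port if region == ROSA else g.nosa_port
    return math.hypot(p.x - port.x, p.y - port.y)


def calibrate(px: float | np.ndarray, g: ArenaGeometry) -> float | np.ndarray:
    """Convert a pixel length to physical units (linear, px / px_per_unit)."""
    if g.px_per_unit <= 0:
        raise ValueError("px_per_unit must be > 0")
    out = np.asarray(px, dtype=float) / g.px_per_unit
    return float(out) if out.ndim == 0 else out
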