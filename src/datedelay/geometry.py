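"""Screen geometry, AOI layout, trial timing and block counterbalancing.

The task displays two intertemporal options side by side; each option is a
reward amount stacked above a time attribute, giving four attribute regions
(areas of interest, AOIs): ``reward_left``, ``reward_right``, ``time_left``,
``time_right``.  Gaze is recorded in screen pixels with the origin at the
top-left corner and y increasing downward; analyses work in degrees of
visual angle measured from the screen centre.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

AOI_LABELS = ("reward_left", "reward_right", "time_left", "time_right")

__all__ = [
    "AOI_LABELS",
    "ScreenGeometry",
    "AOIBox",
    "TrialTiming",
    "BlockPlan",
    "InvalidGeometryError",
    "AOIOverlapError",
    "px_to_deg",
    "px_to_deg_xy",
    "deg_xy_to_px",
    "expected_trial_duration",
    "sample_trial_durations",
    "build_block_plan",
    "make_default_aois",
    "aoi_table",
    "load_geometry_config",
    "CALIBRATION_GRID",
    "calibration_angles",
]


class InvalidGeometryError(ValueError):
    """Raised for physically impossible screen geometry."""


class AOIOverlapError(ValueError):
    """Raised when two AOI boxes overlap (AOI assignment would be ambiguous)."""


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical monitor description used for pixel <-> visual-angle conversion.

    Defaults are a 32-inch 1920x1080 display viewed from 1900 mm, i.e. the
    MR-compatible setup the analyses assume; the printed calibration angles
    back-solve to a viewing distance of exactly 1900 mm.
    """

    width_px: int = 1920
    height_px: int = 1080
    width_mm: float = 698.4
    height_mm: float = 392.85
    viewing_distance_mm: float = 1900.0

    def __post_init__(self) -> None:
        for name in ("width_px", "height_px", "width_mm", "height_mm",
                     "viewing_distance_mm"):
            if getattr(self, name) <= 0:
                raise InvalidGeometryError(f"{name} must be positive")

    @property
    def mm_per_px_x(self) -> float:
        return self.width_mm / self.width_px

    @property
    def mm_per_px_y(self) -> float:
        return self.height_mm / self.height_px

    @property
    def center_px(self) -> tuple[float, float]:
        # pixel indices are 0-based, so the centre of a 1920x1080 screen is
        # the (960, 540) pixel used by the calibration grid
        return (self.width_px / 2.0, self.height_px / 2.0)

    def is_isotropic(self, tol: float = 1e-6) -> bool:
        return abs(self.mm_per_px_x - self.mm_per_px_y) < tol


@dataclass(frozen=True)
class AOIBox:
    """Rectangular AOI around one attribute centre.

    ``width_deg``/``height_deg`` are full extents in visual angle; the box
    edges are inclusive (a point on the edge is inside).
    """

    label: str
    center_px: tuple[float, float]
    width_deg: float = 9.76
    height_deg: float = 2.46

    def __post_init__(self) -> None:
        if self.label not in AOI_LABELS:
            raise ValueError(f"unknown AOI label {self.label!r}")
        if self.width_deg <= 0 or self.height_deg <= 0:
            raise ValueError("AOI extents must be positive")

    def half_extent_px(self, geometry: ScreenGeometry) -> tuple[float, float]:
        d = geometry.viewing_distance_mm
        hw = math.tan(math.radians(self.width_deg / 2.0)) * d / geometry.mm_per_px_x
        hh = math.tan(math.radians(self.height_deg / 2.0)) * d / geometry.mm_per_px_y
        return hw, hh

    def contains(self, point_px, geometry: ScreenGeometry):
        hw, hh = self.half_extent_px(geometry)
        pt = np.asarray(point_px, dtype=float)
        dx = np.abs(pt[..., 0] - self.center_px[0])
        dy = np.abs(pt[..., 1] - self.center_px[1])
        # closed boxes: edge points count as inside (tolerance absorbs
        # floating-point roundoff)
        return (dx <= hw + 1e-9) & (dy <= hh + 1e-9)

    def on_screen(self, geometry: ScreenGeometry) -> bool:
        hw, hh = self.half_extent_px(geometry)
        cx, cy = self.center_px
        return (cx - hw >= 0 and cx + hw <= geometry.width_px - 1
                and cy - hh >= 0 and cy + hh <= geometry.height_px - 1)


@dataclass(frozen=True)
class TrialTiming:
    """Timing model: fixed 6 s decision window, uniform 4-8 s jitter.

    Unused decision time is appended to the trial-end fixation, so total
    trial duration is decision_window + jitter regardless of the response
    time.
    """

    decision_window_ms: float = 6000.0
    jitter_low_ms: float = 4000.0
    jitter_high_ms: float = 8000.0
    first_fixation_ms: float = 6000.0

    def __post_init__(self) -> None:
        if self.jitter_low_ms > self.jitter_high_ms:
            raise ValueError("jitter_low_ms must be <= jitter_high_ms")
        if self.decision_window_ms <= 0:
            raise ValueError("decision_window_ms must be positive")


@dataclass(frozen=True)
class BlockPlan:
    """Counterbalanced 4-block plan: 2 blocks per condition, alternating.

    ``trial_orders`` holds one permutation of item indices per block;
    ``sir_left`` maps item index -> SIR shown on the left in blocks 1/2
    (blocks 3/4 use the mirrored assignment).
    """

    block_order: tuple[str, str, str, str]
    trial_orders: tuple[tuple[int, ...], ...]
    sir_left: dict[int, bool] = field(repr=False)

    def sir_on_left(self, item_index: int, block: int) -> bool:
        base = self.sir_left[item_index]
        return base if block < 2 else not base


def px_to_deg_xy(point_px, geometry: ScreenGeometry) -> np.ndarray:
    """Signed per-axis visual angles (deg) of screen points from the centre.

    x positive rightward, y positive downward (screen convention).
    """
    if geometry.viewing_distance_mm <= 0:
        raise InvalidGeometryError("viewing distance must be positive")
    pt = np.asarray(point_px, dtype=float)
    cx, cy = geometry.center_px
    dx_mm = (pt[..., 0] - cx) * geometry.mm_per_px_x
    dy_mm = (pt[..., 1] - cy) * geometry.mm_per_px_y
    d = geometry.viewing_distance_mm
    return np.degrees(np.stack([np.arctan2(dx_mm, d), np.arctan2(dy_mm, d)], axis=-1))


def deg_xy_to_px(point_deg, geometry: ScreenGeometry) -> np.ndarray:
    """Inverse of :func:`px_to_deg_xy`."""
    pt = np.asarray(point_deg, dtype=float)
    d = geometry.viewing_distance_mm
    cx, cy = geometry.center_px
    x = cx + np.tan(np.radians(pt[..., 0])) * d / geometry.mm_per_px_x
    y = cy + np.tan(np.radians(pt[..., 1])) * d / geometry.mm_per_px_y
    return np.stack([x, y], axis=-1)


def px_to_deg(point_px, geometry: ScreenGeometry) -> np.ndarray | float:
    """Radial visual angle (deg) of a screen point from the screen centre.

    Computed as atan(euclidean offset in mm / viewing distance); symmetric
    under reflection about the centre.
    """
    if geometry.viewing_distance_mm <= 0:
        raise InvalidGeometryError("viewing distance must be positive")
    pt = np.asarray(point_px, dtype=float)
    cx, cy = geometry.center_px
    dx_mm = (pt[..., 0] - cx) * geometry.mm_per_px_x
    dy_mm = (pt[..., 1] - cy) * geometry.mm_per_px_y
    r_mm = np.hypot(dx_mm, dy_mm)
    ang = np.degrees(np.arctan2(r_mm, geometry.viewing_distance_mm))
    return float(ang) if ang.ndim == 0 else ang


def expected_trial_duration(timing: TrialTiming) -> float:
    """Analytic mean trial duration in ms (decision window + mean jitter)."""
    return timing.decision_window_ms + 0.5 * (timing.jitter_low_ms + timing.jitter_high_ms)


def sample_trial_durations(timing: TrialTiming, n: int, rng) -> np.ndarray:
    """Draw n trial durations; independent of response times by design."""
    rng = np.random.default_rng(rng)
    jitter = rng.uniform(timing.jitter_low_ms, timing.jitter_high_ms, size=n)
    return timing.decision_window_ms + jitter


def build_block_plan(n_items: int, start_condition: str = "delay",
                     seed: int | np.random.Generator = 0,
                     conditions: tuple[str, str] = ("delay", "date"),
                     warn_nonstandard: bool = True) -> BlockPlan:
    """Randomised trial orders and counterbalanced side assignment.

    Block order alternates starting from ``start_condition`` (A-B-A-B).
    Item positions drawn for the first block of the starting condition are
    reused for the matching items of the other condition's first block;
    blocks 3/4 replay blocks 1/2 with the SIR side mirrored.
    """
    if start_condition not in conditions:
        raise ValueError(f"start_condition must be one of {conditions}")
    if warn_nonstandard and n_items != 27:
        import warnings
        warnings.warn(f"item bank has {n_items} items (standard menu has 27)",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    other = conditions[1] if start_condition == conditions[0] else conditions[0]
    block_order = (start_condition, other, start_condition, other)
    trial_orders = tuple(tuple(rng.permutation(n_items).tolist()) for _ in range(4))
    left = np.zeros(n_items, dtype=bool)
    half = n_items // 2
    idx = rng.permutation(n_items)
    left[idx[:half + (n_items % 2) * int(rng.integers(0, 2))]] = True
    sir_left = {i: bool(left[i]) for i in range(n_items)}
    return BlockPlan(block_order=block_order, trial_orders=trial_orders,
                     sir_left=sir_left)


def make_default_aois(geometry: ScreenGeometry | None = None,
                      eccentricity_deg: float = 6.93,
                      elevation_deg: float = 40.0,
                      width_deg: float = 9.76,
                      height_deg: float = 2.46) -> list[AOIBox]:
    """Four AOIs at a fixed radial eccentricity from the screen centre.

    Reward AOIs sit above time AOIs on each side.  ``elevation_deg`` sets
    the angle of each attribute centre above/below the horizontal meridian
    (measured in the screen plane); the radial eccentricity is held at
    ``eccentricity_deg`` exactly.  Raises :class:`AOIOverlapError` if the
    resulting boxes overlap or leave the screen.
    """
    geometry = geometry or ScreenGeometry()
    if eccentricity_deg <= 0 or width_deg <= 0 or height_deg <= 0:
        raise ValueError("eccentricity and AOI extents must be positive")
    d = geometry.viewing_distance_mm
    r_mm = math.tan(math.radians(eccentricity_deg)) * d
    theta = math.radians(elevation_deg)
    dx_px = r_mm * math.cos(theta) / geometry.mm_per_px_x
    dy_px = r_mm * math.sin(theta) / geometry.mm_per_px_y
    cx, cy = geometry.center_px
    boxes = [
        AOIBox("reward_left", (cx - dx_px, cy - dy_px), width_deg, height_deg),
        AOIBox("reward_right", (cx + dx_px, cy - dy_px), width_deg, height_deg),
        AOIBox("time_left", (cx - dx_px, cy + dy_px), width_deg, height_deg),
        AOIBox("time_right", (cx + dx_px, cy + dy_px), width_deg, height_deg),
    ]
    _check_layout(boxes, geometry)
    return boxes


def _check_layout(boxes: list[AOIBox], geometry: ScreenGeometry) -> None:
    if len({b.label for b in boxes}) != len(boxes):
        raise ValueError("AOI labels must be distinct")
    for i, a in enumerate(boxes):
        if not a.on_screen(geometry):
            raise AOIOverlapError(f"AOI {a.label} extends beyond the screen")
        ahw, ahh = a.half_extent_px(geometry)
        for b in boxes[i + 1:]:
            bhw, bhh = b.half_extent_px(geometry)
            if (abs(a.center_px[0] - b.center_px[0]) < ahw + bhw
                    and abs(a.center_px[1] - b.center_px[1]) < ahh + bhh):
                raise AOIOverlapError(f"AOIs {a.label} and {b.label} overlap")


def aoi_table(boxes: list[AOIBox]):
    """AOI layout as a 4-row DataFrame (label, cx, cy, w_deg, h_deg)."""
    import pandas as pd
    return pd.DataFrame(
        {"label": [b.label for b in boxes],
         "cx": [b.center_px[0] for b in boxes],
         "cy": [b.center_px[1] for b in boxes],
         "w_deg": [b.width_deg for b in boxes],
         "h_deg": [b.height_deg for b in boxes]})


def load_geometry_config(path) -> tuple[ScreenGeometry, list[AOIBox]]:
    """Load screen geometry and AOI layout from a YAML or JSON config file."""
    with open(path) as fh:
        text = fh.read()
    cfg = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    geom = ScreenGeometry(**cfg.get("screen", {}))
    if "aois" in cfg:
        boxes = [AOIBox(label=a["label"], center_px=(a["cx"], a["cy"]),
                        width_deg=a.get("w_deg", 9.76),
                        height_deg=a.get("h_deg", 2.46)) for a in cfg["aois"]]
        _check_layout(boxes, geom)
    else:
        boxes = make_default_aois(geom, **cfg.get("aoi_layout", {}))
    return geom, boxes


# nine-point calibration grid (3x3, pixel coordinates)
CALIBRATION_GRID = [(960, 540), (960, 92), (960, 988), (115, 540), (1805, 540),
                    (115, 92), (1805, 92), (115, 988), (1805, 988)]


def calibration_angles(geometry: ScreenGeometry | None = None) -> dict[str, float]:
    """Radial angles of the horizontal, vertical and diagonal grid points."""
    geometry = geometry or ScreenGeometry()
    return {
        "horizontal": px_to_deg((115, 540), geometry),
        "vertical": px_to_deg((960, 92), geometry),
        "diagonal": px_to_deg((1805, 988), geometry),
    }
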