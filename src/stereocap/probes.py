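"""The three 2D stereological probes: unbiased counting frame, point grid,
and test lines, with exact geometric counting rules.

Counting semantics follow standard design-based practice:

* **Counting frame** -- a profile is counted when it meets the closed frame
  (inside, or touching the inclusion lines: top and right edges) and does
  not touch a forbidden line.  The ``paper_simple`` rule forbids only the
  bottom and left edges; the default ``gundersen_full`` rule additionally
  forbids the upward extension of the left edge and the downward extension
  of the right-edge line below the bottom-right corner, which guarantees
  each profile is countable in exactly one frame of a tiling whatever its
  size or shape.  At exact edge contact forbidden wins over inclusion.
* **Point grid** -- the test point is the mathematical grid node (drawn as
  the upper-right corner of the printed cross); it scores when it lies
  strictly inside a capillary profile.
* **Test lines** -- parallel segments with uniform random offset and
  orientation; each transversal crossing of a profile boundary counts 1 (a
  line passing through a profile counts 2), tangencies count once.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import _geometry as geo
from .phantom import WMRegion
from .sectioning import ProfileSet

Rect = geo.Rect


# --------------------------------------------------------------------------
# Point grid
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PointGrid:
    """Square point lattice with a uniform random offset within one cell;
    each point represents an area a(p) = spacing^2."""

    spacing_mm: float
    offset: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.spacing_mm <= 0:
            raise ValueError("grid spacing must be positive")
        if not (0.0 <= self.offset[0] < self.spacing_mm and 0.0 <= self.offset[1] < self.spacing_mm):
            raise ValueError("grid offset must lie in [0, spacing)^2")

    @property
    def a_p_mm2(self) -> float:
        return self.spacing_mm**2

    def nodes_in_rect(self, rect: Rect) -> np.ndarray:
        """All lattice nodes inside the closed rectangle, as (N, 2)."""
        x0, y0, x1, y1 = rect
        s = self.spacing_mm
        ix0 = int(np.ceil((x0 - self.offset[0]) / s))
        ix1 = int(np.floor((x1 - self.offset[0]) / s))
        iy0 = int(np.ceil((y0 - self.offset[1]) / s))
        iy1 = int(np.floor((y1 - self.offset[1]) / s))
        if ix1 < ix0 or iy1 < iy0:
            return np.empty((0, 2))
        xs = self.offset[0] + s * np.arange(ix0, ix1 + 1)
        ys = self.offset[1] + s * np.arange(iy0, iy1 + 1)
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel()])


def make_point_grid(spacing_mm: float, rng: np.random.Generator) -> PointGrid:
    off = rng.uniform(0.0, spacing_mm, size=2)
    return PointGrid(spacing_mm=spacing_mm, offset=(float(off[0]), float(off[1])))


def grid_hit_points(
    grid: PointGrid, region: WMRegion, cut_z: float, axis: int = 2
) -> np.ndarray:
    """3D coordinates of the grid nodes on the cut plane at ``cut_z`` that
    fall inside the region cross-section (the points that 'hit the white
    matter', also the candidates for tissue-block sampling)."""
    lo, hi = region.bounds
    in_plane = [i for i in range(3) if i != axis]
    rect = (lo[in_plane[0]], lo[in_plane[1]], hi[in_plane[0]], hi[in_plane[1]])
    nodes = grid.nodes_in_rect(rect)
    if len(nodes) == 0:
        return np.empty((0, 3))
    pts3 = np.empty((len(nodes), 3))
    pts3[:, in_plane[0]] = nodes[:, 0]
    pts3[:, in_plane[1]] = nodes[:, 1]
    pts3[:, axis] = cut_z
    return pts3[region.contains(pts3)]


def count_grid_hits_region(
    grid: PointGrid, region: WMRegion, cut_z: float, axis: int = 2
) -> int:
    """Cavalieri point count: grid nodes whose location on the cut plane at
    ``cut_z`` lies inside the region cross-section."""
    return len(grid_hit_points(grid, region, cut_z, axis))


# --------------------------------------------------------------------------
# Counting frame
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CountingFrame:
    """Unbiased counting frame: a rectangle with inclusion edges top+right
    and forbidden edges bottom+left (plus extensions under the
    ``gundersen_full`` rule)."""

    rect: Rect
    rule: str = "gundersen_full"

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.rect
        if not (x1 > x0 and y1 > y0):
            raise ValueError("frame must have positive area")
        if self.rule not in ("paper_simple", "gundersen_full"):
            raise ValueError(f"unknown frame rule: {self.rule!r}")

    @property
    def area_mm2(self) -> float:
        x0, y0, x1, y1 = self.rect
        return (x1 - x0) * (y1 - y0)

    def forbidden_segments(self, field: Rect | None = None) -> list[tuple[np.ndarray, np.ndarray]]:
        x0, y0, x1, y1 = self.rect
        segs = [
            (np.array([x0, y0]), np.array([x1, y0])),  # bottom
            (np.array([x0, y0]), np.array([x0, y1])),  # left
        ]
        if self.rule == "gundersen_full":
            if field is None:
                # Extend well past anything a profile in play can reach.
                span = 100.0 * max(x1 - x0, y1 - y0)
                top_y, bot_y = y1 + span, y0 - span
            else:
                top_y, bot_y = field[3], field[1]
            if top_y > y1:
                segs.append((np.array([x0, y1]), np.array([x0, top_y])))  # left edge, up
            if bot_y < y0:
                segs.append((np.array([x1, y0]), np.array([x1, bot_y])))  # right line, down
        return segs


def count_frame(profiles: ProfileSet, frame: CountingFrame, field: Rect | None = None) -> int:
    """Count capillary profiles by the unbiased-counting-frame rule."""
    caps = profiles.capillaries
    if len(caps) == 0:
        return 0
    x0, y0, x1, y1 = frame.rect
    fy0 = field[1] if field is not None else y0 - 100.0 * (y1 - y0)
    fy1 = field[3] if field is not None else y1 + 100.0 * (y1 - y0)
    # Generous bbox prefilter: everything countable or forbidden lives in the
    # vertical strip of the frame, padded by each profile's semi-major axis.
    maj = caps.semi_major_mm
    near = (
        (caps.center[:, 0] >= x0 - maj)
        & (caps.center[:, 0] <= x1 + maj)
        & (caps.center[:, 1] >= fy0 - maj)
        & (caps.center[:, 1] <= fy1 + maj)
    )
    if not near.any():
        return 0
    caps = caps.subset(near)
    cx, cy = caps.center[:, 0], caps.center[:, 1]
    a, b, th = caps.semi_major_mm, caps.semi_minor_mm, caps.angle_rad
    hit = geo.ellipses_touch_rect(frame.rect, cx, cy, a, b, th)
    forb = np.zeros(len(caps), dtype=bool)
    for p0, p1 in frame.forbidden_segments(field):
        forb |= geo.segments_touch_ellipses(p0, p1, cx, cy, a, b, th)
    return int(np.sum(hit & ~forb))


# --------------------------------------------------------------------------
# Grid points over profiles
# --------------------------------------------------------------------------


def count_grid_hits_profiles(
    grid: PointGrid, profiles: ProfileSet, field: Rect
) -> tuple[int, int]:
    """(sum P_cap, sum P_ref): grid nodes strictly inside any capillary
    profile, and nodes inside the reference area (the field, taken to be
    white matter throughout)."""
    nodes = grid.nodes_in_rect(field)
    p_ref = len(nodes)
    if p_ref == 0:
        return 0, 0
    caps = profiles.capillaries
    if len(caps) == 0:
        return 0, p_ref
    maj = caps.semi_major_mm
    near = (
        (caps.center[:, 0] >= field[0] - maj)
        & (caps.center[:, 0] <= field[2] + maj)
        & (caps.center[:, 1] >= field[1] - maj)
        & (caps.center[:, 1] <= field[3] + maj)
    )
    caps = caps.subset(near)
    if len(caps) == 0:
        return 0, p_ref
    inside = geo.points_in_ellipses(
        nodes,
        caps.center[:, 0],
        caps.center[:, 1],
        caps.semi_major_mm,
        caps.semi_minor_mm,
        caps.angle_rad,
        strict=True,
    )
    p_cap = int(inside.any(axis=1).sum())
    return p_cap, p_ref


# --------------------------------------------------------------------------
# Test lines
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TestLineSet:
    """Parallel test segments clipped to the observation field."""

    segments: tuple[tuple[tuple[float, float], tuple[float, float]], ...]

    def __post_init__(self) -> None:
        if self.total_length_mm <= 0:
            raise ValueError("test line set must have positive total length")

    @property
    def total_length_mm(self) -> float:
        return float(
            sum(
                np.hypot(p1[0] - p0[0], p1[1] - p0[1])
                for p0, p1 in self.segments
            )
        )


def make_test_lines(field: Rect, spacing_mm: float, rng: np.random.Generator) -> TestLineSet:
    """A family of parallel lines with uniform random offset in [0, spacing)
    and uniform random orientation, clipped to the field."""
    if spacing_mm <= 0:
        raise ValueError("line spacing must be positive")
    x0, y0, x1, y1 = field
    cx, cy = (x0 + x1) / 2.0, (y0 + y1) / 2.0
    diag = float(np.hypot(x1 - x0, y1 - y0))
    alpha = rng.uniform(0.0, np.pi)
    d = np.array([np.cos(alpha), np.sin(alpha)])  # line direction
    nvec = np.array([-d[1], d[0]])  # offset direction
    phase = rng.uniform(0.0, spacing_mm)
    k_max = int(np.ceil(diag / 2.0 / spacing_mm)) + 1
    segs = []
    for k in range(-k_max, k_max + 1):
        base = np.array([cx, cy]) + (phase + k * spacing_mm) * nvec
        p0 = base - d * diag
        p1 = base + d * diag
        clipped = geo.clip_segment_to_rect(p0, p1, field)
        if clipped is not None:
            q0, q1 = clipped
            if np.linalg.norm(q1 - q0) > 0:
                segs.append(((float(q0[0]), float(q0[1])), (float(q1[0]), float(q1[1]))))
    return TestLineSet(segments=tuple(segs))


def count_line_intersections(lines: TestLineSet, profiles: ProfileSet) -> tuple[int, float]:
    """(sum I, sum L): boundary crossings between the test segments and the
    capillary profile boundaries, and the total test line length."""
    total_len = lines.total_length_mm
    caps = profiles.capillaries
    if len(caps) == 0:
        return 0, total_len
    cx, cy = caps.center[:, 0], caps.center[:, 1]
    a, b, th = caps.semi_major_mm, caps.semi_minor_mm, caps.angle_rad
    total = 0
    for p0, p1 in lines.segments:
        p0a, p1a = np.asarray(p0), np.asarray(p1)
        lo = np.minimum(p0a, p1a)
        hi = np.maximum(p0a, p1a)
        near = (
            (cx >= lo[0] - a) & (cx <= hi[0] + a) & (cy >= lo[1] - a) & (cy <= hi[1] + a)
        )
        if not near.any():
            continue
        total += int(
            geo.segment_boundary_crossings(
                p0a, p1a, cx[near], cy[near], a[near], b[near], th[near]
            ).sum()
        )
    return total, total_len


# --------------------------------------------------------------------------
# Count records and the CSV boundary
# --------------------------------------------------------------------------


@dataclass
class CountRecord:
    """Raw probe counts for one animal/section/field.

    ``probe`` is one of: cavalieri_p (count = sum P_wm, area = a(p), length
    = slab thickness t), frame_q (area = frame area), point_cap / point_ref
    (area = fine-grid a(p)), line_i (length = sum L in the field).
    """

    animal: str
    group: str
    section: str
    fieldno: int
    probe: str
    count: int
    probe_area_mm2: float = np.nan
    probe_length_mm: float = np.nan


COUNTS_COLUMNS = [
    "animal",
    "group",
    "section",
    "field",
    "probe",
    "count",
    "probe_area_mm2",
    "probe_length_mm",
]


def records_to_frame(records: list[CountRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "animal": r.animal,
                "group": r.group,
                "section": r.section,
                "field": r.fieldno,
                "probe": r.probe,
                "count": r.count,
                "probe_area_mm2": r.probe_area_mm2,
                "probe_length_mm": r.probe_length_mm,
            }
            for r in records
        ],
        columns=COUNTS_COLUMNS,
    )


def counts_to_csv(records: list[CountRecord] | pd.DataFrame, path) -> pd.DataFrame:
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    df.to_csv(path, index=False, float_format="%.10g")
    return df


def counts_from_csv(path) -> pd.DataFrame:
    """Read a count table; this is the boundary at which real (non-
    synthetic) data may enter the pipeline."""
    df = pd.read_csv(Path(path))
    missing = set(COUNTS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    return df
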