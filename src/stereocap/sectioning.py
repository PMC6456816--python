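"""Sectioning of phantoms: Cavalieri slabs, block sampling, and isector
isotropic-uniform-random (IUR) section planes.

The histological chain being emulated is: continuous 1-mm coronal slabs with
a uniform random start (the Cavalieri design), a few tissue blocks sampled
at the grid points that hit the white matter, and isector sections -- planes
whose normals are uniform on the unit sphere -- cut through those blocks.
On IUR planes the classical identities hold: capillary profile count per
area Q_A = L_V / 2, profile area fraction A_A = V_V (Delesse), and profile
boundary length per area B_A = (pi/4) S_V; the test suite uses these as
Monte-Carlo oracles.

Sections are modelled as ideal planes; the 4 um physical thickness is
carried as metadata only (the density formulas assume planar probes, and
overprojection over ~3 um vessels is a documented, unmodelled bias).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phantom import CapillaryNetwork, WMRegion

__all__ = [
    "Slab",
    "SectionPlane",
    "Block",
    "SectionProfile",
    "ProfileSet",
    "cavalieri_slabs",
    "sample_blocks",
    "isector_plane",
    "section_network",
    "profiles_to_csv",
]


# --------------------------------------------------------------------------
# Cavalieri slabs
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Slab:
    """One systematic slab [z0, z0 + t) along the slicing axis."""

    axis: int
    z0: float
    t: float

    @property
    def cut_z(self) -> float:
        """Position of the cut surface on which areas/points are read."""
        return self.z0


def cavalieri_slabs(
    region: WMRegion,
    t_mm: float = 1.0,
    seed: int | np.random.Generator = 0,
    axis: int = 2,
) -> list[Slab]:
    """Systematic slabs of thickness t with a uniform random start.

    The first cut lies at ``zmin - U(0, t) + t`` so the slab family tiles
    the axis with random phase; slabs that do not intersect the region are
    dropped.  The slab count is ceil(extent / t) or that + 1 depending on
    the phase.
    """
    if t_mm <= 0:
        raise ValueError("slab thickness must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = region.bounds
    extent = hi[axis] - lo[axis]
    if t_mm > extent:
        warnings.warn("slab thickness exceeds region extent; a single slab results")
    start = lo[axis] - rng.uniform(0.0, t_mm)
    slabs = []
    z = start
    while z < hi[axis]:
        if z + t_mm > lo[axis]:  # intersects region
            slabs.append(Slab(axis=axis, z0=z, t=t_mm))
        z += t_mm
    return slabs


# --------------------------------------------------------------------------
# Block sampling
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Block:
    """Small cube of tissue around a sampled grid point."""

    center: tuple[float, float, float]
    edge_mm: float = 0.3

    @property
    def half(self) -> float:
        return self.edge_mm / 2.0


def sample_blocks(
    candidates: np.ndarray,
    region: WMRegion,
    k_range: tuple[int, int] = (3, 4),
    edge_mm: float = 0.3,
    seed: int | np.random.Generator = 0,
) -> list[Block]:
    """Uniformly sample 3-4 blocks (without replacement) from the grid
    points that hit the white matter.

    Block centres are clamped so the cube lies inside the region's bounding
    extent (blocks must contain tissue on all sides).  Fewer candidates than
    k yields all of them with a warning; zero candidates yields an empty
    list with a warning.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pts = np.atleast_2d(np.asarray(candidates, dtype=float))
    if pts.size == 0:
        warnings.warn("no grid points hit the region; no blocks sampled")
        return []
    k = int(rng.integers(k_range[0], k_range[1] + 1))
    if len(pts) < k:
        warnings.warn(f"only {len(pts)} candidate points for {k} blocks; using all")
        chosen = pts
    else:
        idx = rng.choice(len(pts), size=k, replace=False)
        chosen = pts[idx]
    lo, hi = region.bounds
    half = edge_mm / 2.0
    if np.any(hi - lo < edge_mm):
        raise ValueError("block edge exceeds a region extent")
    clamped = np.clip(chosen, lo + half, hi - half)
    return [Block(center=tuple(c), edge_mm=edge_mm) for c in clamped]


# --------------------------------------------------------------------------
# Isector planes
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SectionPlane:
    """An ideal section plane: point + unit normal; nominal physical
    thickness in um is metadata only."""

    point: tuple[float, float, float]
    normal: tuple[float, float, float]
    thickness_um: float = 4.0

    def __post_init__(self) -> None:
        n = np.linalg.norm(self.normal)
        if not np.isclose(n, 1.0, atol=1e-9):
            raise ValueError("plane normal must be a unit vector")

    @property
    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Deterministic in-plane orthonormal frame (Gram-Schmidt against
        the canonical axis least aligned with the normal)."""
        n = np.asarray(self.normal, dtype=float)
        k = np.zeros(3)
        k[int(np.argmin(np.abs(n)))] = 1.0
        e1 = k - np.dot(k, n) * n
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(n, e1)
        return e1, e2

    def to_plane_coords(self, points: np.ndarray) -> np.ndarray:
        e1, e2 = self.basis
        d = np.atleast_2d(points) - np.asarray(self.point)
        return np.column_stack([d @ e1, d @ e2])


def isector_plane(
    block: Block,
    seed: int | np.random.Generator = 0,
    offset_frac: float = 0.6,
    thickness_um: float = 4.0,
) -> SectionPlane:
    """IUR plane through a block: normal uniform on the sphere
    (z ~ U(-1, 1), azimuth ~ U(0, 2 pi)), offset along the normal uniform
    within ``offset_frac`` of the block half-edge.

    Restricting the offset keeps the cube's cross-section large enough to
    hold an observation field regardless of orientation (the in-plane disk
    of radius sqrt(h^2 - s^2) about the block centre is always tissue).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = rng.uniform(-1.0, 1.0)
    az = rng.uniform(0.0, 2.0 * np.pi)
    s = np.sqrt(1.0 - z * z)
    normal = np.array([s * np.cos(az), s * np.sin(az), z])
    offset = rng.uniform(-offset_frac * block.half, offset_frac * block.half)
    point = np.asarray(block.center) + offset * normal
    return SectionPlane(point=tuple(point), normal=tuple(normal), thickness_um=thickness_um)


# --------------------------------------------------------------------------
# Plane-network intersection
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SectionProfile:
    """One elliptical capillary transect on a section."""

    center: tuple[float, float]  # in-plane mm
    semi_minor_mm: float  # = cylinder radius
    semi_major_mm: float  # = r / sin(phi), phi = axis-plane angle
    angle_rad: float  # in-plane major-axis direction
    parent_index: int
    parent_diameter_um: float
    is_capillary: bool


@dataclass
class ProfileSet:
    """Vectorised collection of section profiles (one IUR section's worth)."""

    center: np.ndarray  # (M, 2)
    semi_minor_mm: np.ndarray
    semi_major_mm: np.ndarray
    angle_rad: np.ndarray
    parent_index: np.ndarray
    parent_diameter_um: np.ndarray
    is_capillary: np.ndarray
    section_id: str = ""

    def __len__(self) -> int:
        return len(self.semi_minor_mm)

    def subset(self, mask: np.ndarray) -> "ProfileSet":
        return ProfileSet(
            center=self.center[mask],
            semi_minor_mm=self.semi_minor_mm[mask],
            semi_major_mm=self.semi_major_mm[mask],
            angle_rad=self.angle_rad[mask],
            parent_index=self.parent_index[mask],
            parent_diameter_um=self.parent_diameter_um[mask],
            is_capillary=self.is_capillary[mask],
            section_id=self.section_id,
        )

    @property
    def capillaries(self) -> "ProfileSet":
        return self.subset(self.is_capillary)

    @property
    def area_mm2(self) -> np.ndarray:
        return np.pi * self.semi_minor_mm * self.semi_major_mm

    def profiles(self) -> list[SectionProfile]:
        return [
            SectionProfile(
                center=(float(self.center[i, 0]), float(self.center[i, 1])),
                semi_minor_mm=float(self.semi_minor_mm[i]),
                semi_major_mm=float(self.semi_major_mm[i]),
                angle_rad=float(self.angle_rad[i]),
                parent_index=int(self.parent_index[i]),
                parent_diameter_um=float(self.parent_diameter_um[i]),
                is_capillary=bool(self.is_capillary[i]),
            )
            for i in range(len(self))
        ]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "section": self.section_id,
                "center_x_um": self.center[:, 0] * 1000.0,
                "center_y_um": self.center[:, 1] * 1000.0,
                "semi_minor_um": self.semi_minor_mm * 1000.0,
                "semi_major_um": self.semi_major_mm * 1000.0,
                "angle_rad": self.angle_rad,
                "parent_diameter_um": self.parent_diameter_um,
                "is_capillary": self.is_capillary,
            }
        )


def section_network(
    network: CapillaryNetwork,
    plane: SectionPlane,
    window=None,
    aspect_cap: float = 1e4,
    section_id: str = "",
) -> ProfileSet:
    """Intersect every cylinder with the plane and emit elliptical profiles.

    A profile exists iff the plane crosses the cylinder's axis segment
    strictly between its endpoints (end-cap truncation is ignored; the error
    is O(r / segment length)).  The ellipse has semi-minor axis r and
    semi-major axis r / sin(phi), phi being the angle between the cylinder
    axis and the plane; sin(phi) = 0 (plane parallel to the axis) is a
    measure-zero event and emits nothing.  ``aspect_cap`` bounds the aspect
    ratio purely as a numerical safeguard for near-parallel hits.

    ``window`` is an optional (x0, y0, x1, y1) rectangle in plane
    coordinates; profiles are kept by centre membership.  Vessels with
    parent diameter >= 10 um are flagged non-capillary and excluded from
    capillary counts downstream, but retained here for the filter test.
    """
    n = np.asarray(plane.normal, dtype=float)
    p0 = np.asarray(plane.point, dtype=float)
    da = (network.a - p0) @ n
    db = (network.b - p0) @ n
    crossing = (da * db) < 0.0  # strictly between endpoints
    if not crossing.any():
        empty = np.empty(0)
        return ProfileSet(
            center=np.empty((0, 2)),
            semi_minor_mm=empty,
            semi_major_mm=empty,
            angle_rad=empty,
            parent_index=np.empty(0, dtype=int),
            parent_diameter_um=empty,
            is_capillary=np.empty(0, dtype=bool),
            section_id=section_id,
        )

    idx = np.nonzero(crossing)[0]
    a = network.a[idx]
    b = network.b[idx]
    t = da[idx] / (da[idx] - db[idx])
    centers3 = a + t[:, None] * (b - a)
    axes = network.axes[idx]
    sin_phi = np.abs(axes @ n)
    keep = sin_phi > 0.0
    idx, centers3, axes, sin_phi = idx[keep], centers3[keep], axes[keep], sin_phi[keep]
    r = network.radius_mm[idx]

    semi_major = r / np.maximum(sin_phi, 1.0 / aspect_cap)

    e1, e2 = plane.basis
    center2 = np.column_stack([(centers3 - p0) @ e1, (centers3 - p0) @ e2])
    # Major axis direction = projection of the cylinder axis onto the plane.
    proj = axes - (axes @ n)[:, None] * n[None, :]
    pnorm = np.linalg.norm(proj, axis=1)
    # For a perpendicular hit the profile is a circle; any angle will do.
    safe = pnorm > 1e-12
    ang = np.zeros(len(idx))
    ang[safe] = np.arctan2(proj[safe] @ e2, proj[safe] @ e1)

    ps = ProfileSet(
        center=center2,
        semi_minor_mm=r,
        semi_major_mm=semi_major,
        angle_rad=ang,
        parent_index=idx,
        parent_diameter_um=network.diameter_um[idx],
        is_capillary=network.is_capillary[idx],
        section_id=section_id,
    )
    if window is not None:
        x0, y0, x1, y1 = window
        m = (
            (center2[:, 0] >= x0)
            & (center2[:, 0] <= x1)
            & (center2[:, 1] >= y0)
            & (center2[:, 1] <= y1)
        )
        ps = ps.subset(m)
    return ps


def profiles_to_csv(profile_sets: list[ProfileSet], path) -> pd.DataFrame:
    df = pd.concat([ps.to_dataframe() for ps in profile_sets], ignore_index=True)
    df.to_csv(path, index=False, float_format="%.6g")
    return df
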