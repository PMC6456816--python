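"""Shared fixtures and brute-force geometric oracles.

The oracles deliberately avoid the package's analytic geometry: ellipses are
discretised into fine polygons (shapely) so the exact affine/quadratic
predicates in the implementation are checked against an independent route.
"""

from __future__ import annotations

import numpy as np
import pytest
import shapely.geometry as sgeom

from stereocap import RadiusParams, generate_network, generate_region
from stereocap.sectioning import ProfileSet

# ---------------------------------------------------------------------------
# Phantom fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def unit_region():
    return generate_region((1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def unit_network(unit_region):
    """Isotropic network at roughly the wild-type capillary length density,
    with a dispersed radius distribution, in a 1 mm^3 cube."""
    return generate_network(
        unit_region,
        length_mm=1000.0,
        radius=RadiusParams(mean_um=1.37, sd_um=0.64),
        seed=42,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_profiles(rng, n, span=1.0, r_um=(1.0, 2.5), aspect_iur=True):
    """Random elliptical profiles scattered over [-span, span]^2 (mm)."""
    r = rng.uniform(*r_um, size=n) / 1000.0
    if aspect_iur:
        s = np.sqrt(rng.uniform(0.0, 1.0, size=n))  # sin(phi), crossing-weighted
    else:
        s = np.ones(n)
    return ProfileSet(
        center=rng.uniform(-span, span, size=(n, 2)),
        semi_minor_mm=r,
        semi_major_mm=r / s,
        angle_rad=rng.uniform(0.0, np.pi, size=n),
        parent_index=np.arange(n),
        parent_diameter_um=2000.0 * r,
        is_capillary=np.ones(n, dtype=bool),
    )


# ---------------------------------------------------------------------------
# Polygonal (shapely) oracles
# ---------------------------------------------------------------------------

_N_POLY = 4096


def ellipse_polygon(cx, cy, a, b, theta, n=_N_POLY) -> sgeom.Polygon:
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    x = a * np.cos(t)
    y = b * np.sin(t)
    ct, st = np.cos(theta), np.sin(theta)
    return sgeom.Polygon(
        np.column_stack([cx + x * ct - y * st, cy + x * st + y * ct])
    )


def oracle_point_inside(px, py, cx, cy, a, b, theta) -> bool:
    return ellipse_polygon(cx, cy, a, b, theta).contains(sgeom.Point(px, py))


def oracle_segment_crossings(p0, p1, cx, cy, a, b, theta) -> int:
    ring = ellipse_polygon(cx, cy, a, b, theta).exterior
    inter = sgeom.LineString([p0, p1]).intersection(ring)
    if inter.is_empty:
        return 0
    if inter.geom_type == "Point":
        return 1
    if hasattr(inter, "geoms"):
        return len(inter.geoms)
    return 1


def oracle_frame_count(profiles: ProfileSet, frame, field=None) -> int:
    """Brute-force unbiased-counting-frame decision per profile."""
    x0, y0, x1, y1 = frame.rect
    box = sgeom.box(x0, y0, x1, y1)
    forb = [sgeom.LineString([tuple(p0), tuple(p1)]) for p0, p1 in frame.forbidden_segments(field)]
    n = 0
    caps = profiles.capillaries
    for i in range(len(caps)):
        poly = ellipse_polygon(
            caps.center[i, 0], caps.center[i, 1],
            caps.semi_major_mm[i], caps.semi_minor_mm[i], caps.angle_rad[i],
        )
        if not poly.intersects(box):
            continue
        if any(poly.intersects(f) for f in forb):
            continue
        n += 1
    return n
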