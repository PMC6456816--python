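"""Synthetic capillary phantoms with analytically known ground truth.

The phantom stands in for the biological material of a two-group mouse
study: per-animal white-matter regions of known volume (~12-13 mm^3),
capillary networks of thin cylinders (diameter < 10 um) with isotropic
orientations, and Morris-water-maze escape-latency series negatively
correlated with the capillary totals.  Because every quantity the
stereological pipeline estimates (reference volume, total capillary length,
volume and surface area) has a closed form on the phantom, estimator
unbiasedness can be checked without any animal data.

Units: all geometry is in mm internally; capillary radii/diameters are
exposed in um where the capillary definition (diameter < 10 um) applies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

MAX_CAPILLARY_DIAMETER_UM = 10.0  # vessels at or above this are not capillaries

_GROUP_WT = "wild_type"
_GROUP_TG = "tg2576"


# --------------------------------------------------------------------------
# Reference region
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class WMRegion:
    """Axis-aligned box (or disjoint union of boxes) standing in for the
    dissected white matter.

    ``boxes`` is a tuple of (lo, hi) corner pairs in mm.  The analytic
    volume is the sum of box volumes; point membership is exact.
    """

    boxes: tuple[tuple[tuple[float, float, float], tuple[float, float, float]], ...]

    def __post_init__(self) -> None:
        if not self.boxes:
            raise ValueError("region needs at least one box")
        for lo, hi in self.boxes:
            if not all(h > l for l, h in zip(lo, hi)):
                raise ValueError(f"non-positive box dimension: lo={lo}, hi={hi}")
        # Disjointness keeps the analytic volume a plain sum.
        for i, (lo_i, hi_i) in enumerate(self.boxes):
            for lo_j, hi_j in self.boxes[i + 1 :]:
                overlap = all(
                    min(hi_i[k], hi_j[k]) > max(lo_i[k], lo_j[k]) for k in range(3)
                )
                if overlap:
                    raise ValueError("region boxes must be disjoint")

    @classmethod
    def box(cls, dims: tuple[float, float, float], origin=(0.0, 0.0, 0.0)) -> "WMRegion":
        lo = tuple(float(o) for o in origin)
        hi = tuple(float(o + d) for o, d in zip(origin, dims))
        return cls(boxes=((lo, hi),))

    @property
    def volume_mm3(self) -> float:
        return float(
            sum(np.prod([h - l for l, h in zip(lo, hi)]) for lo, hi in self.boxes)
        )

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        los = np.array([lo for lo, _ in self.boxes])
        his = np.array([hi for _, hi in self.boxes])
        return los.min(axis=0), his.max(axis=0)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Exact membership for an (N, 3) array of points (closed boxes)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        inside = np.zeros(len(pts), dtype=bool)
        for lo, hi in self.boxes:
            lo = np.asarray(lo)
            hi = np.asarray(hi)
            inside |= np.all((pts >= lo) & (pts <= hi), axis=1)
        return inside

    def sample_points(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Uniform random points in the region (box chosen by volume)."""
        vols = np.array(
            [np.prod([h - l for l, h in zip(lo, hi)]) for lo, hi in self.boxes]
        )
        which = rng.choice(len(self.boxes), size=n, p=vols / vols.sum())
        out = np.empty((n, 3))
        for i, (lo, hi) in enumerate(self.boxes):
            mask = which == i
            k = int(mask.sum())
            if k:
                out[mask] = rng.uniform(lo, hi, size=(k, 3))
        return out


def generate_region(dims_mm: tuple[float, float, float], origin=(0.0, 0.0, 0.0)) -> WMRegion:
    """Axis-aligned box region with exact analytic volume."""
    return WMRegion.box(dims_mm, origin)


# --------------------------------------------------------------------------
# Cylinders and networks
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Cylinder:
    """A straight capillary segment: endpoints in mm, radius in mm."""

    endpoint_a: tuple[float, float, float]
    endpoint_b: tuple[float, float, float]
    radius_mm: float

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("cylinder radius must be positive")
        if self.length_mm <= 0:
            raise ValueError("cylinder endpoints must differ")

    @property
    def length_mm(self) -> float:
        a = np.asarray(self.endpoint_a)
        b = np.asarray(self.endpoint_b)
        return float(np.linalg.norm(b - a))

    @property
    def diameter_um(self) -> float:
        return 2.0 * self.radius_mm * 1000.0


@dataclass(frozen=True)
class TruthRecord:
    """Closed-form totals of a phantom: the ground-truth counterparts of the
    estimated white-matter volume and capillary length/volume/surface."""

    length_mm: float
    cap_volume_mm3: float
    surface_mm2: float
    wm_volume_mm3: float

    @property
    def length_m(self) -> float:
        return self.length_mm / 1000.0


@dataclass
class CapillaryNetwork:
    """A set of finite cylinders inside a reference region.

    Arrays ``a``, ``b`` are (N, 3) endpoints in mm, ``radius_mm`` is (N,).
    ``is_capillary`` flags cylinders with diameter < 10 um; larger vessels
    may be present to exercise the capillary filter, and are excluded from
    the ground-truth capillary totals.
    """

    region: WMRegion
    a: np.ndarray
    b: np.ndarray
    radius_mm: np.ndarray
    is_capillary: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.a = np.atleast_2d(np.asarray(self.a, dtype=float))
        self.b = np.atleast_2d(np.asarray(self.b, dtype=float))
        self.radius_mm = np.asarray(self.radius_mm, dtype=float)
        if self.is_capillary is None:
            self.is_capillary = self.diameter_um < MAX_CAPILLARY_DIAMETER_UM
        self.is_capillary = np.asarray(self.is_capillary, dtype=bool)
        if np.any(self.radius_mm <= 0):
            raise ValueError("all radii must be positive")
        if np.any(self.segment_length_mm <= 0):
            raise ValueError("all segments must have positive length")

    def __len__(self) -> int:
        return len(self.radius_mm)

    @property
    def segment_length_mm(self) -> np.ndarray:
        return np.linalg.norm(self.b - self.a, axis=1)

    @property
    def diameter_um(self) -> np.ndarray:
        return 2.0 * self.radius_mm * 1000.0

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.a + self.b)

    @property
    def axes(self) -> np.ndarray:
        """Unit axis direction of each cylinder."""
        d = self.b - self.a
        return d / np.linalg.norm(d, axis=1, keepdims=True)

    @property
    def cylinders(self) -> list[Cylinder]:
        return [
            Cylinder(tuple(pa), tuple(pb), float(r))
            for pa, pb, r in zip(self.a, self.b, self.radius_mm)
        ]

    @property
    def truth(self) -> TruthRecord:
        """Analytic capillary totals: L = sum |b-a|, V = sum pi r^2 |b-a|,
        S = sum 2 pi r |b-a| (capillary-flagged cylinders only)."""
        m = self.is_capillary
        ell = self.segment_length_mm[m]
        r = self.radius_mm[m]
        return TruthRecord(
            length_mm=float(ell.sum()),
            cap_volume_mm3=float(np.sum(np.pi * r**2 * ell)),
            surface_mm2=float(np.sum(2.0 * np.pi * r * ell)),
            wm_volume_mm3=self.region.volume_mm3,
        )


# --------------------------------------------------------------------------
# Radius distributions
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class RadiusParams:
    """Capillary radius distribution in um: lognormal with the given mean
    and SD, truncated to (0, max_um].  sd_um = 0 gives a fixed radius."""

    mean_um: float
    sd_um: float = 0.0
    max_um: float = MAX_CAPILLARY_DIAMETER_UM / 2.0

    def __post_init__(self) -> None:
        if self.mean_um <= 0 or self.sd_um < 0:
            raise ValueError("radius mean must be > 0 and sd >= 0")
        if not (0 < self.mean_um <= self.max_um):
            raise ValueError(f"capillary radius mean must lie in (0, {self.max_um}] um")

    def sample_mm(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.sd_um == 0.0:
            return np.full(n, self.mean_um / 1000.0)
        mu, sigma = _truncated_lognormal_params(self.mean_um, self.sd_um, self.max_um)
        r = rng.lognormal(mu, sigma, size=n)
        # Truncate to the capillary range by resampling the tail; the
        # parameters above already compensate, so the truncated draw has the
        # requested mean and SD.
        for _ in range(100):
            bad = r > self.max_um
            if not bad.any():
                break
            r[bad] = rng.lognormal(mu, sigma, size=int(bad.sum()))
        np.clip(r, None, self.max_um, out=r)
        return r / 1000.0


def _truncated_lognormal_params(mean: float, sd: float, cap: float) -> tuple[float, float]:
    """Lognormal (mu, sigma) whose *truncation to (0, cap]* has the given
    mean and SD.  Falls back to plain moment matching when the solver cannot
    honour the cap (very wide targets)."""
    from scipy.optimize import root
    from scipy.stats import norm

    sigma2 = np.log1p((sd / mean) ** 2)
    x0 = np.array([np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)])

    lc = np.log(cap)

    def trunc_moment(k, mu, sigma):
        z = (lc - mu) / sigma
        denom = norm.cdf(z)
        return np.exp(k * mu + 0.5 * k * k * sigma * sigma) * norm.cdf(z - k * sigma) / denom

    def eqs(p):
        mu, sigma = p
        if sigma <= 0:
            return [1e6, 1e6]
        m1 = trunc_moment(1, mu, sigma)
        m2 = trunc_moment(2, mu, sigma)
        return [m1 - mean, m2 - (mean**2 + sd**2)]

    sol = root(eqs, x0)
    if sol.success and sol.x[1] > 0:
        return float(sol.x[0]), float(sol.x[1])
    return float(x0[0]), float(x0[1])


def radius_params_from_totals(length_mm: float, volume_mm3: float, surface_mm2: float) -> RadiusParams:
    """Moment-match a radius distribution to target capillary totals.

    For cylinders of common segment length, V = pi E[r^2] L and
    S = 2 pi E[r] L, so E[r] = S/(2 pi L) and E[r^2] = V/(pi L).  When the
    implied variance is non-positive (targets consistent with a single
    calibre) a fixed radius matching S/L is used.
    """
    if min(length_mm, volume_mm3, surface_mm2) <= 0:
        raise ValueError("totals must be positive")
    mean_r_mm = surface_mm2 / (2.0 * np.pi * length_mm)
    mean_r2_mm2 = volume_mm3 / (np.pi * length_mm)
    var = mean_r2_mm2 - mean_r_mm**2
    sd_mm = np.sqrt(var) if var > 0 else 0.0
    return RadiusParams(mean_um=mean_r_mm * 1000.0, sd_um=sd_mm * 1000.0)


# --------------------------------------------------------------------------
# Network generation
# --------------------------------------------------------------------------


def _isotropic_directions(n: int, rng: np.random.Generator) -> np.ndarray:
    """Axis directions uniform on the unit sphere: z ~ U(-1, 1),
    azimuth ~ U(0, 2 pi)."""
    z = rng.uniform(-1.0, 1.0, size=n)
    az = rng.uniform(0.0, 2.0 * np.pi, size=n)
    s = np.sqrt(1.0 - z**2)
    return np.column_stack([s * np.cos(az), s * np.sin(az), z])


def generate_network(
    region: WMRegion,
    *,
    length_mm: float | None = None,
    length_density_mm2: float | None = None,
    radius: RadiusParams | None = None,
    orientation: str = "isotropic",
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0),
    segment_length_mm: float = 0.05,
    large_vessel_fraction: float = 0.0,
    large_vessel_diameter_um: tuple[float, float] = (10.0, 20.0),
    seed: int | np.random.Generator | np.random.SeedSequence = 0,
) -> CapillaryNetwork:
    """Place cylinders with uniform random midpoints until the capillary
    length target is met (within 0.1%, by trimming the final segment).

    ``orientation`` is "isotropic" (axes uniform on the sphere, the default
    and the assumption under which the section estimators are unbiased) or
    "fixed-axis" (all cylinders parallel to ``axis``, used to demonstrate
    the anisotropy bias the isector removes).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if radius is None:
        radius = RadiusParams(mean_um=1.67, sd_um=0.0)
    if (length_mm is None) == (length_density_mm2 is None):
        raise ValueError("give exactly one of length_mm or length_density_mm2")
    if length_density_mm2 is not None:
        length_mm = length_density_mm2 * region.volume_mm3
    assert length_mm is not None
    if length_mm <= 0:
        raise ValueError("length target must be positive")
    if segment_length_mm <= 0:
        raise ValueError("segment length must be positive")
    if not 0.0 <= large_vessel_fraction < 1.0:
        raise ValueError("large_vessel_fraction must be in [0, 1)")
    if orientation not in ("isotropic", "fixed-axis"):
        raise ValueError(f"unknown orientation mode: {orientation!r}")

    n = max(1, int(np.ceil(length_mm / segment_length_mm)))
    lengths = np.full(n, segment_length_mm)
    lengths[-1] = length_mm - segment_length_mm * (n - 1)
    if lengths[-1] <= 0:  # target an exact multiple
        lengths = lengths[:-1]
        n -= 1

    mid = region.sample_points(n, rng)
    if orientation == "isotropic":
        dirs = _isotropic_directions(n, rng)
    else:
        ax = np.asarray(axis, dtype=float)
        nrm = np.linalg.norm(ax)
        if nrm == 0:
            raise ValueError("fixed axis must be non-zero")
        dirs = np.tile(ax / nrm, (n, 1))

    half = (lengths / 2.0)[:, None] * dirs
    a = mid - half
    b = mid + half
    r = radius.sample_mm(n, rng)

    is_cap = np.ones(n, dtype=bool)
    n_large = int(round(large_vessel_fraction * n))
    if n_large:
        idx = rng.choice(n, size=n_large, replace=False)
        d_lo, d_hi = large_vessel_diameter_um
        r[idx] = rng.uniform(d_lo, d_hi, size=n_large) / 2.0 / 1000.0
        is_cap[idx] = False

    net = CapillaryNetwork(region=region, a=a, b=b, radius_mm=r, is_capillary=is_cap)
    achieved = net.truth.length_mm
    target_cap = length_mm * (1.0 - large_vessel_fraction)
    if abs(achieved - target_cap) > 1e-3 * target_cap + 1e-9:
        raise RuntimeError("length target missed beyond 0.1% -- unreachable with given segment lengths")
    return net


# --------------------------------------------------------------------------
# Cohort: two groups with behaviour
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupConfig:
    """Calibration of one experimental group.

    Means/SDs default to the study's printed group values; the latency
    model is linear in the standardised total capillary length with
    day-decreasing intercepts (a learning curve), clamped to the maze's
    [0, 60] s trial window.
    """

    label: str
    n: int = 7
    wm_volume_mm3: float = 12.87
    wm_volume_cv: float = 0.44 / 12.87
    length_m: float = 12.44
    length_cv: float = 2.64 / 12.44
    cap_volume_mm3: float = 0.0891
    cap_volume_cv: float = 0.0145 / 0.0891
    surface_mm2: float = 106.81
    surface_cv: float = 20.17 / 106.81
    # Morris water maze: 6 days x 4 trials, latencies in seconds.
    latency_intercepts_s: tuple[float, ...] = (42.0, 35.0, 28.0, 22.0, 18.0, 15.0)
    latency_slope_s: float = 6.0
    latency_noise_sd_s: float = 6.0
    # Probe trial (day 7) summaries; no group difference by default.
    crossings_mean: float = 4.0
    crossings_sd: float = 1.5
    quadrant_time_pct_mean: float = 35.0
    quadrant_time_pct_sd: float = 8.0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group size must be at least 2 (group SD undefined below)")
        if len(self.latency_intercepts_s) != 6:
            raise ValueError("the hidden-platform task runs 6 days")
        if self.latency_noise_sd_s < 0:
            raise ValueError("noise SD must be non-negative")
        for name in ("wm_volume_mm3", "length_m", "cap_volume_mm3", "surface_mm2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


WILD_TYPE = GroupConfig(label=_GROUP_WT)
TG2576 = GroupConfig(
    label=_GROUP_TG,
    wm_volume_mm3=12.33,
    wm_volume_cv=1.01 / 12.33,
    length_m=6.90,
    length_cv=0.82 / 6.90,
    cap_volume_mm3=0.0648,
    cap_volume_cv=0.0167 / 0.0648,
    surface_mm2=61.77,
    surface_cv=13.80 / 61.77,
    latency_intercepts_s=(48.0, 44.0, 40.0, 37.0, 34.0, 31.0),
)


@dataclass(frozen=True)
class CohortConfig:
    """Two-group cohort; per-animal totals are the group mean scaled by a
    lognormal animal factor, with L, V and S sharing one latent size factor
    (correlation ``shared_rho``) so behaviour correlates with all three."""

    groups: tuple[GroupConfig, GroupConfig] = (WILD_TYPE, TG2576)
    shared_rho: float = 0.98
    n_days: int = 6
    n_trials: int = 4

    def __post_init__(self) -> None:
        if not 0.0 <= self.shared_rho <= 1.0:
            raise ValueError("shared_rho must lie in [0, 1]")

    def with_n(self, n: int) -> "CohortConfig":
        return replace(self, groups=tuple(replace(g, n=n) for g in self.groups))


DEFAULT_COHORT = CohortConfig()


@dataclass
class AnimalRecord:
    """One animal: ground-truth targets, behaviour, and (after the pipeline
    has run) the stereological estimates."""

    animal_id: str
    group: str
    truth: TruthRecord
    latency_s: np.ndarray  # (6 days, 4 trials)
    platform_crossings: int
    quadrant_time_pct: float
    network_seed: tuple[int, ...] = ()
    estimates: dict | None = None

    @property
    def final_day_latency_s(self) -> float:
        return float(np.mean(self.latency_s[-1]))

    @property
    def daily_latency_s(self) -> np.ndarray:
        return self.latency_s.mean(axis=1)


def _lognormal_factors(cv: float, z: np.ndarray) -> np.ndarray:
    """Mean-one lognormal factors driven by standard-normal draws z."""
    if cv == 0:
        return np.ones_like(z)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(sigma * z - sigma**2 / 2.0)


def generate_cohort(config: CohortConfig = DEFAULT_COHORT, seed: int = 0) -> list[AnimalRecord]:
    """Generate the two-group cohort with per-animal truths and behaviour.

    Deterministic per seed: every group and animal derives its RNG stream
    from a stable (seed, group, animal) key, so results do not depend on
    evaluation order.
    """
    animals: list[AnimalRecord] = []
    rho = config.shared_rho
    for gi, g in enumerate(config.groups):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 1000 + gi]))
        u = rng.standard_normal(g.n)  # latent animal size factor
        eps = rng.standard_normal((3, g.n))  # independent parts for L, V, S
        zL = rho * u + np.sqrt(1 - rho**2) * eps[0]
        zV = rho * u + np.sqrt(1 - rho**2) * eps[1]
        zS = rho * u + np.sqrt(1 - rho**2) * eps[2]
        length_mm = g.length_m * 1000.0 * _lognormal_factors(g.length_cv, zL)
        cap_vol = g.cap_volume_mm3 * _lognormal_factors(g.cap_volume_cv, zV)
        surface = g.surface_mm2 * _lognormal_factors(g.surface_cv, zS)
        wm_vol = g.wm_volume_mm3 * _lognormal_factors(
            g.wm_volume_cv, rng.standard_normal(g.n)
        )

        # Latency: intercept_d - slope * z(L) + noise, clamped to [0, 60] s.
        sd_L = length_mm.std(ddof=1)
        z_of_L = (length_mm - length_mm.mean()) / sd_L if sd_L > 0 else np.zeros(g.n)
        noise = rng.normal(0.0, g.latency_noise_sd_s, size=(g.n, config.n_days, config.n_trials)) \
            if g.latency_noise_sd_s > 0 else np.zeros((g.n, config.n_days, config.n_trials))
        intercepts = np.asarray(g.latency_intercepts_s)[None, :, None]
        lat = intercepts - g.latency_slope_s * z_of_L[:, None, None] + noise
        lat = np.clip(lat, 0.0, 60.0)

        crossings = np.maximum(
            0, np.rint(rng.normal(g.crossings_mean, g.crossings_sd, size=g.n))
        ).astype(int)
        quadrant = np.clip(
            rng.normal(g.quadrant_time_pct_mean, g.quadrant_time_pct_sd, size=g.n),
            0.0,
            100.0,
        )

        for ai in range(g.n):
            animals.append(
                AnimalRecord(
                    animal_id=f"{g.label}_{ai + 1:02d}",
                    group=g.label,
                    truth=TruthRecord(
                        length_mm=float(length_mm[ai]),
                        cap_volume_mm3=float(cap_vol[ai]),
                        surface_mm2=float(surface[ai]),
                        wm_volume_mm3=float(wm_vol[ai]),
                    ),
                    latency_s=lat[ai],
                    platform_crossings=int(crossings[ai]),
                    quadrant_time_pct=float(quadrant[ai]),
                    network_seed=(seed, 2000 + gi, ai),
                )
            )
    return animals


def build_animal_region(record: AnimalRecord, y_mm: float = 0.9,
                        z_extent_mm: float = 6.5) -> WMRegion:
    """Box region matching the animal's white-matter volume: the y and z
    extents are fixed (z is the slicing axis, ~6.5 mm of 1 mm slabs as in a
    mouse hemisphere) and x is scaled to the target volume."""
    x = record.truth.wm_volume_mm3 / (y_mm * z_extent_mm)
    return WMRegion.box((x, y_mm, z_extent_mm))


def build_animal_network(
    record: AnimalRecord,
    region: WMRegion | None = None,
    segment_length_mm: float = 0.05,
    orientation: str = "isotropic",
    large_vessel_fraction: float = 0.0,
) -> CapillaryNetwork:
    """Realise the animal's capillary network from its truth targets.

    Radius moments are matched to the (L, V, S) targets so the network's
    analytic truth lands on them (up to radius-sampling noise and the
    capillary-range truncation)."""
    if region is None:
        region = build_animal_region(record)
    t = record.truth
    radius = radius_params_from_totals(t.length_mm, t.cap_volume_mm3, t.surface_mm2)
    rng = np.random.default_rng(np.random.SeedSequence(list(record.network_seed) + [7]))
    lf = 0.0 if large_vessel_fraction == 0 else large_vessel_fraction
    target = t.length_mm if lf == 0 else t.length_mm / (1.0 - lf)
    return generate_network(
        region,
        length_mm=target,
        radius=radius,
        orientation=orientation,
        segment_length_mm=segment_length_mm,
        large_vessel_fraction=lf,
        seed=rng,
    )


# --------------------------------------------------------------------------
# External interfaces
# --------------------------------------------------------------------------


def cohort_to_json(animals: list[AnimalRecord], config: CohortConfig, seed: int, path) -> None:
    """Write the cohort (config echo + per-animal truths and behaviour
    summaries) as JSON."""
    payload = {
        "seed": seed,
        "config": {
            "shared_rho": config.shared_rho,
            "groups": [
                {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(g).items()}
                for g in config.groups
            ],
        },
        "animals": [
            {
                "animal_id": a.animal_id,
                "group": a.group,
                "truth": vars(a.truth),
                "final_day_latency_s": a.final_day_latency_s,
                "platform_crossings": a.platform_crossings,
                "quadrant_time_pct": a.quadrant_time_pct,
            }
            for a in animals
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def latencies_to_csv(animals: list[AnimalRecord], path) -> pd.DataFrame:
    """Tidy escape-latency table: animal, group, day, trial, latency_s."""
    rows = []
    for a in animals:
        for d in range(a.latency_s.shape[0]):
            for t in range(a.latency_s.shape[1]):
                rows.append(
                    {
                        "animal": a.animal_id,
                        "group": a.group,
                        "day": d + 1,
                        "trial": t + 1,
                        "latency_s": a.latency_s[d, t],
                    }
                )
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False, float_format="%.6g")
    return df
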