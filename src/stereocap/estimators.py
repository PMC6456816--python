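"""Density and total estimators of design-based capillary stereology.

The four estimating equations are

* Cavalieri reference volume:   V_wm = t * a(p) * sum P(wm)
* length density:               L_V  = 2 * sum Q / sum A        [mm^-2]
* volume density (Delesse):     V_V  = sum P_cap / sum P_ref    [-]
* surface density:              S_V  = 2 * sum I / sum L        [mm^-1]

and absolute totals are density x reference volume (reporting the total
length in metres, as is conventional).  Pooling across sections is by
ratio of sums -- the literal reading of the sigma notation -- not by
averaging per-section ratios; the two differ whenever section probe areas
differ, and only the ratio of sums is unbiased for the pooled density.

All internal lengths are in mm; display-unit conversion (m for length)
happens only in :class:`TotalEstimates`.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


# --------------------------------------------------------------------------
# The four estimating equations
# --------------------------------------------------------------------------


def cavalieri_volume(p_wm: int, a_p_mm2: float, t_mm: float) -> float:
    """Total reference volume from systematic point counts: t * a(p) * sum P."""
    if p_wm < 0:
        raise ValueError("point count must be non-negative")
    if a_p_mm2 <= 0 or t_mm <= 0:
        raise ValueError("a(p) and slab thickness must be positive")
    return t_mm * a_p_mm2 * p_wm


def length_density(q: int, area_mm2: float) -> float:
    """Capillary length density L_V = 2 * sum Q / sum A (mm^-2).

    The factor 2 converts the profile count per area on isotropic sections
    into length per volume (an isotropic unit segment crosses a unit-area
    IUR plane with probability 1/2).
    """
    if area_mm2 <= 0:
        raise ValueError("total frame area must be positive")
    if q < 0:
        raise ValueError("profile count must be non-negative")
    return 2.0 * q / area_mm2


def volume_density(p_cap: int, p_ref: int) -> float:
    """Capillary volume fraction V_V = sum P_cap / sum P_ref."""
    if p_ref <= 0:
        raise ValueError("reference point count must be positive")
    if p_cap < 0:
        raise ValueError("capillary point count must be non-negative")
    if p_cap > p_ref:
        raise ValueError("capillary points exceed reference points (test point outside reference)")
    return p_cap / p_ref


def surface_density(i: int, l_mm: float) -> float:
    """Capillary surface density S_V = 2 * sum I / sum L (mm^-1)."""
    if l_mm <= 0:
        raise ValueError("total test-line length must be positive")
    if i < 0:
        raise ValueError("intersection count must be non-negative")
    return 2.0 * i / l_mm


# --------------------------------------------------------------------------
# Containers and conversions
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class DensityEstimates:
    """Per-animal pooled densities."""

    lv_mm2: float  # length density, mm/mm^3 = mm^-2
    vv: float  # volume fraction
    sv_mm1: float  # surface density, mm^2/mm^3 = mm^-1

    def __post_init__(self) -> None:
        if min(self.lv_mm2, self.vv, self.sv_mm1) < 0:
            raise ValueError("densities must be non-negative")
        if self.vv > 1:
            raise ValueError("volume fraction cannot exceed 1")


@dataclass(frozen=True)
class TotalEstimates:
    """Absolute per-animal totals in the display units of the field."""

    wm_volume_mm3: float
    length_m: float
    cap_volume_mm3: float
    surface_mm2: float

    @property
    def mean_diameter_um(self) -> float:
        """Calibre implied by the cylinder identity d = 4 V / S."""
        if self.surface_mm2 == 0:
            return float("nan")
        return 4.0 * self.cap_volume_mm3 / self.surface_mm2 * 1000.0


def totals(densities: DensityEstimates, v_wm_mm3: float) -> TotalEstimates:
    """Densities x reference volume; total length converted mm -> m."""
    if v_wm_mm3 <= 0:
        raise ValueError("reference volume must be positive")
    return TotalEstimates(
        wm_volume_mm3=v_wm_mm3,
        length_m=densities.lv_mm2 * v_wm_mm3 / 1000.0,
        cap_volume_mm3=densities.vv * v_wm_mm3,
        surface_mm2=densities.sv_mm1 * v_wm_mm3,
    )


# --------------------------------------------------------------------------
# Pooling from count tables
# --------------------------------------------------------------------------


def densities_from_counts(counts: pd.DataFrame) -> DensityEstimates:
    """Pool one animal's probe counts (ratio of sums) into densities.

    ``counts`` uses the tidy probe schema (see probes.COUNTS_COLUMNS):
    frame_q rows carry the frame area, point_cap/point_ref the fine-grid
    point counts, line_i the test-line length.
    """
    by = counts.groupby("probe")["count"].sum()
    q = int(by.get("frame_q", 0))
    area = float(counts.loc[counts.probe == "frame_q", "probe_area_mm2"].sum())
    p_cap = int(by.get("point_cap", 0))
    p_ref = int(by.get("point_ref", 0))
    i = int(by.get("line_i", 0))
    l_mm = float(counts.loc[counts.probe == "line_i", "probe_length_mm"].sum())
    return DensityEstimates(
        lv_mm2=length_density(q, area),
        vv=volume_density(p_cap, p_ref),
        sv_mm1=surface_density(i, l_mm),
    )


def cavalieri_from_counts(counts: pd.DataFrame) -> float:
    """Pool one animal's Cavalieri rows: V = t * a(p) * sum P."""
    rows = counts.loc[counts.probe == "cavalieri_p"]
    if rows.empty:
        raise ValueError("no cavalieri_p rows for this animal")
    a_p = float(rows["probe_area_mm2"].iloc[0])
    t = float(rows["probe_length_mm"].iloc[0])
    return cavalieri_volume(int(rows["count"].sum()), a_p, t)


def estimate_animal_totals(counts: pd.DataFrame) -> TotalEstimates:
    """Full per-animal estimate from that animal's count table."""
    v_wm = cavalieri_from_counts(counts)
    return totals(densities_from_counts(counts), v_wm)


def estimates_from_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-animal estimates table from a pooled (multi-animal) count table.

    Returns columns: animal, group, V_wm_mm3, L_m, Vcap_mm3, Scap_mm2.
    """
    rows = []
    for animal, sub in counts.groupby("animal", sort=True):
        tot = estimate_animal_totals(sub)
        rows.append(
            {
                "animal": animal,
                "group": sub["group"].iloc[0],
                "V_wm_mm3": tot.wm_volume_mm3,
                "L_m": tot.length_m,
                "Vcap_mm3": tot.cap_volume_mm3,
                "Scap_mm2": tot.surface_mm2,
            }
        )
    return pd.DataFrame(rows)


def estimates_to_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def estimates_from_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    needed = {"animal", "group", "V_wm_mm3", "L_m", "Vcap_mm3", "Scap_mm2"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"estimates table missing columns: {sorted(missing)}")
    return df
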