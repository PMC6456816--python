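"""Group statistics, behavioural analysis, the correlation table, and the
pipeline that chains phantom -> sectioning -> probes -> estimators -> report.

Statistical conventions follow the study design being emulated: the animal
is the experimental unit; stereological quantities are compared by an
unpaired pooled-variance Student t test and summarised as mean +/- SD;
behavioural quantities are summarised as mean +/- SEM; escape latencies
across the six hidden-platform days are analysed by a two-factor
repeated-measures ANOVA (group between, day within, no sphericity
correction); and structure-behaviour association is the Pearson
correlation of the final-day escape latency with each absolute capillary
total, with a two-tailed p from t = r sqrt(n-2) / sqrt(1-r^2) on n-2 df.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import estimators, phantom, probes, sectioning

__all__ = [
    "TestResult",
    "unpaired_t",
    "pearson_r",
    "pearson_p",
    "rm_anova",
    "build_table1",
    "StudyConfig",
    "load_config",
    "probe_animal",
    "run_study",
    "group_summary",
    "run_pipeline",
]


# --------------------------------------------------------------------------
# Elementary tests
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    df: tuple[float, ...]
    p: float
    note: str = ""

    def as_dict(self) -> dict:
        return {
            "name": self.name,
            "statistic": self.statistic,
            "df": list(self.df),
            "p": self.p,
            "note": self.note,
        }


def unpaired_t(a, b, name: str = "unpaired_t") -> TestResult:
    """Two-sample pooled-variance Student t test, two-tailed.

    Degenerate case of zero pooled variance: equal means give t = 0, p = 1;
    unequal means give p = 0 (flagged in the note).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 observations")
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if sp2 == 0.0:
        if diff == 0.0:
            return TestResult(name, 0.0, (df,), 1.0, note="degenerate: zero variance")
        return TestResult(
            name, float(np.inf) if diff > 0 else float(-np.inf), (df,), 0.0,
            note="degenerate: zero variance, unequal means",
        )
    t = diff / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(name, float(t), (df,), float(p))


def pearson_r(x, y) -> float:
    """Sample Pearson product-moment correlation; NaN when either variable
    has zero variance (undefined, flagged to the caller via NaN)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    r = float(np.sum((x - x.mean()) * (y - y.mean())) / ((len(x) - 1) * sx * sy))
    return max(-1.0, min(1.0, r))


def pearson_p(r: float, n: int) -> float:
    """Two-tailed p for a Pearson r at sample size n, from the exact null
    distribution t = r sqrt(n-2) / sqrt(1-r^2) ~ t(n-2)."""
    if n < 3:
        raise ValueError("need n >= 3")
    if np.isnan(r):
        return float("nan")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * sps.t.sf(abs(t), n - 2))


def rm_anova(groups: dict[str, np.ndarray]) -> dict[str, TestResult]:
    """Two-factor mixed (repeated-measures) ANOVA: group between-subjects,
    day within-subjects, balanced and complete, no sphericity correction.

    ``groups`` maps group label -> (n_subjects, n_days) latency matrix.
    Returns F tests for the group effect on (g-1, N-g) df, and day and
    group x day effects on ((d-1), (d-1)(N-g)) df.
    """
    labels = list(groups.keys())
    mats = [np.asarray(groups[k], dtype=float) for k in labels]
    d = mats[0].shape[1]
    if any(m.ndim != 2 or m.shape[1] != d for m in mats):
        raise ValueError("all groups need the same number of days")
    if any(np.isnan(m).any() for m in mats):
        raise ValueError("missing latency cells are not supported (no imputation)")
    ns = [m.shape[0] for m in mats]
    if min(ns) != max(ns):
        raise ValueError("balanced design required: equal group sizes")
    g = len(mats)
    n = ns[0]
    N = g * n
    y = np.concatenate(mats, axis=0)  # (N, d)
    grand = y.mean()

    subj_means = y.mean(axis=1)
    group_means = np.array([m.mean() for m in mats])
    day_means = y.mean(axis=0)

    ss_group = d * n * np.sum((group_means - grand) ** 2)
    ss_between_subj = d * np.sum((subj_means - grand) ** 2)
    ss_subj_within = ss_between_subj - ss_group

    ss_day = N * np.sum((day_means - grand) ** 2)
    gxd = np.stack([m.mean(axis=0) for m in mats])  # (g, d)
    ss_cells = n * np.sum((gxd - grand) ** 2)
    ss_interaction = ss_cells - ss_group - ss_day
    ss_total = np.sum((y - grand) ** 2)
    ss_error = ss_total - ss_between_subj - ss_day - ss_interaction

    df_group, df_subj = g - 1, N - g
    df_day = d - 1
    df_int = (g - 1) * (d - 1)
    df_err = (d - 1) * (N - g)

    def f_test(name, ss_eff, df_eff, ss_den, df_den):
        ms_eff = ss_eff / df_eff
        ms_den = ss_den / df_den
        if ms_den <= 0.0:
            if ms_eff <= 0.0:
                return TestResult(name, 0.0, (df_eff, df_den), 1.0, note="degenerate: no variance")
            return TestResult(name, float(np.inf), (df_eff, df_den), 0.0,
                              note="degenerate: zero error variance")
        F = ms_eff / ms_den
        return TestResult(name, float(F), (df_eff, df_den), float(sps.f.sf(F, df_eff, df_den)))

    return {
        "group": f_test("rm_anova_group", ss_group, df_group, ss_subj_within, df_subj),
        "day": f_test("rm_anova_day", ss_day, df_day, ss_error, df_err),
        "group_x_day": f_test("rm_anova_group_x_day", ss_interaction, df_int, ss_error, df_err),
    }


def shapiro_flags(df: pd.DataFrame, variables: list[str]) -> dict:
    """Pass-through normality screen (never gates the pipeline)."""
    out: dict = {}
    for var in variables:
        out[var] = {}
        for grp, sub in df.groupby("group"):
            x = sub[var].to_numpy(dtype=float)
            if len(x) < 3 or np.ptp(x) == 0:
                out[var][grp] = None
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                stat, p = sps.shapiro(x)
            out[var][grp] = {"W": float(stat), "p": float(p)}
    return out


# --------------------------------------------------------------------------
# Correlation table (structure vs behaviour)
# --------------------------------------------------------------------------

_TABLE1_MEASURES = [("L_m", "length"), ("Vcap_mm3", "volume"), ("Scap_mm2", "surface")]


def build_table1(animals: pd.DataFrame) -> pd.DataFrame:
    """Per-group Pearson (r, p) of final-day escape latency against each
    absolute capillary total (length, volume, surface area)."""
    needed = {"group", "final_day_latency_s"} | {c for c, _ in _TABLE1_MEASURES}
    missing = needed - set(animals.columns)
    if missing:
        raise ValueError(f"animal table missing columns: {sorted(missing)}")
    rows = []
    for grp, sub in animals.groupby("group", sort=True):
        row: dict = {"group": grp, "n": len(sub)}
        for col, short in _TABLE1_MEASURES:
            r = pearson_r(sub["final_day_latency_s"], sub[col])
            row[f"r_{short}"] = r
            row[f"p_{short}"] = pearson_p(r, len(sub))
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Study configuration
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class StudyConfig:
    """Everything the synthetic study needs besides the master seed.

    Probe geometry defaults give a per-animal frame count of sum Q ~ 100
    (coefficient of error ~10%, typical stereological practice); spacings
    and field counts are deliberately config-exposed because the emulated
    protocol does not pin them.
    """

    cohort: phantom.CohortConfig = phantom.DEFAULT_COHORT
    # Cavalieri / sampling chain
    t_mm: float = 1.0
    a_p_mm2: float = 0.59
    block_edge_mm: float = 0.3
    blocks_range: tuple[int, int] = (3, 4)
    sections_per_animal: int = 4
    fields_per_section: int = 20
    # In-section probes (um converted at use sites)
    field_um: float = 80.0
    frame_um: float = 50.0
    frame_rule: str = "gundersen_full"
    grid_spacing_um: float = 4.0
    line_spacing_um: float = 20.0
    # Phantom realisation
    segment_length_mm: float = 0.05
    guard_mm: float = 0.6
    large_vessel_fraction: float = 0.0
    orientation: str = "isotropic"
    # Region shape: y and slicing-axis extents are fixed, x scales to the
    # animal's white-matter volume
    region_y_mm: float = 0.9
    region_z_mm: float = 6.5

    def __post_init__(self) -> None:
        for name in ("t_mm", "a_p_mm2", "block_edge_mm", "field_um", "frame_um",
                     "grid_spacing_um", "line_spacing_um", "segment_length_mm", "guard_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.frame_um >= self.field_um:
            raise ValueError("frame_um must be smaller than field_um")
        if self.sections_per_animal < 1 or self.fields_per_section < 1:
            raise ValueError("need at least one section and one field")
        if self.frame_rule not in ("paper_simple", "gundersen_full"):
            raise ValueError(f"unknown frame rule: {self.frame_rule!r}")


_SCHEMA = {
    "cohort": {"n_per_group": int, "shared_rho": float, "latency_slope_s": float,
               "latency_noise_sd_s": float},
    "sampling": {"t_mm": float, "a_p_mm2": float, "block_edge_mm": float,
                 "blocks_min": int, "blocks_max": int,
                 "sections_per_animal": int, "fields_per_section": int},
    "probes": {"field_um": float, "frame_um": float, "frame_rule": str,
               "grid_spacing_um": float, "line_spacing_um": float},
    "phantom": {"segment_length_mm": float, "guard_mm": float,
                "large_vessel_fraction": float, "orientation": str,
                "region_y_mm": float, "region_z_mm": float},
}


def config_from_dict(raw: dict) -> StudyConfig:
    """Build a StudyConfig from a nested dict (parsed YAML/JSON), reporting
    schema violations with the offending field path."""
    if not isinstance(raw, dict):
        raise ValueError("config: expected a mapping at the top level")
    kwargs: dict = {}
    cohort = phantom.DEFAULT_COHORT
    for section, val in raw.items():
        if section not in _SCHEMA:
            raise ValueError(f"config: unknown section '{section}'")
        if not isinstance(val, dict):
            raise ValueError(f"config: '{section}' must be a mapping")
        for key, v in val.items():
            if key not in _SCHEMA[section]:
                raise ValueError(f"config: unknown field '{section}.{key}'")
            want = _SCHEMA[section][key]
            if want in (int, float) and not isinstance(v, (int, float)) or (
                want is str and not isinstance(v, str)
            ):
                raise ValueError(
                    f"config: field '{section}.{key}' must be {want.__name__}, got {type(v).__name__}"
                )
    c = raw.get("cohort", {})
    if "n_per_group" in c:
        cohort = cohort.with_n(int(c["n_per_group"]))
    if "shared_rho" in c:
        cohort = replace(cohort, shared_rho=float(c["shared_rho"]))
    for k_src, k_grp in (("latency_slope_s", "latency_slope_s"),
                         ("latency_noise_sd_s", "latency_noise_sd_s")):
        if k_src in c:
            cohort = replace(
                cohort,
                groups=tuple(replace(g, **{k_grp: float(c[k_src])}) for g in cohort.groups),
            )
    kwargs["cohort"] = cohort
    s = raw.get("sampling", {})
    for k in ("t_mm", "a_p_mm2", "block_edge_mm", "sections_per_animal", "fields_per_section"):
        if k in s:
            kwargs[k] = s[k]
    if "blocks_min" in s or "blocks_max" in s:
        kwargs["blocks_range"] = (int(s.get("blocks_min", 3)), int(s.get("blocks_max", 4)))
    p = raw.get("probes", {})
    for k in ("field_um", "frame_um", "frame_rule", "grid_spacing_um", "line_spacing_um"):
        if k in p:
            kwargs[k] = p[k]
    ph = raw.get("phantom", {})
    for k in ("segment_length_mm", "guard_mm", "large_vessel_fraction", "orientation",
              "region_y_mm", "region_z_mm"):
        if k in ph:
            kwargs[k] = ph[k]
    return StudyConfig(**kwargs)


def load_config(path) -> StudyConfig:
    raw = yaml.safe_load(Path(path).read_text())
    return config_from_dict(raw or {})


# --------------------------------------------------------------------------
# Per-animal probing
# --------------------------------------------------------------------------


def probe_animal(
    network: phantom.CapillaryNetwork,
    record: phantom.AnimalRecord,
    config: StudyConfig,
    seed_key: tuple[int, ...],
) -> list[probes.CountRecord]:
    """Run the full probing chain on one animal's phantom.

    Cavalieri slabs + point grid give sum P(wm) per cut surface (and the
    block-sampling candidates); 3-4 blocks are sampled at grid hits; each
    isector section through a block yields elliptical profiles; every field
    receives a counting frame, a fine point grid and a test-line set.
    """
    region = network.region
    ss = np.random.SeedSequence(list(seed_key))
    rng_cav, rng_blk, rng_sec, rng_fld = [
        np.random.default_rng(s) for s in ss.spawn(4)
    ]
    recs: list[probes.CountRecord] = []

    # Cavalieri stage: fresh grid offset per photographed cut surface.
    slabs = sectioning.cavalieri_slabs(region, config.t_mm, rng_cav)
    spacing = float(np.sqrt(config.a_p_mm2))
    candidates = []
    for si, slab in enumerate(slabs):
        grid = probes.make_point_grid(spacing, rng_cav)
        pts = probes.grid_hit_points(grid, region, slab.cut_z, axis=slab.axis)
        candidates.append(pts)
        recs.append(
            probes.CountRecord(
                animal=record.animal_id, group=record.group,
                section=f"slab{si:02d}", fieldno=0, probe="cavalieri_p",
                count=len(pts), probe_area_mm2=config.a_p_mm2,
                probe_length_mm=config.t_mm,
            )
        )
    candidates = np.concatenate(candidates) if candidates else np.empty((0, 3))

    blocks = sectioning.sample_blocks(
        candidates, region, config.blocks_range, config.block_edge_mm, rng_blk
    )
    if not blocks:
        return recs

    field_half = config.field_um / 2000.0  # mm
    frame_half = config.frame_um / 2000.0
    field_halfdiag = field_half * np.sqrt(2.0)

    for sec in range(config.sections_per_animal):
        block = blocks[sec % len(blocks)]
        plane = sectioning.isector_plane(block, rng_sec)
        n = np.asarray(plane.normal)
        c3 = np.asarray(block.center)
        s_off = float((np.asarray(plane.point) - c3) @ n)
        rho = float(np.sqrt(max(block.half**2 - s_off**2, 0.0)))
        # Field centres stay inside the disk of guaranteed tissue.
        w = max((rho - field_halfdiag) / np.sqrt(2.0), 0.0)
        c2 = plane.to_plane_coords(c3[None, :])[0]
        guard = config.guard_mm
        win = (
            c2[0] - w - field_half - guard,
            c2[1] - w - field_half - guard,
            c2[0] + w + field_half + guard,
            c2[1] + w + field_half + guard,
        )
        prof = sectioning.section_network(
            network, plane, window=win, section_id=f"{record.animal_id}_s{sec:02d}"
        )
        for f in range(config.fields_per_section):
            fc = c2 + rng_fld.uniform(-w, w, size=2)
            field_rect = (fc[0] - field_half, fc[1] - field_half,
                          fc[0] + field_half, fc[1] + field_half)
            # Counting frame uniform within the field.
            fr = rng_fld.uniform(-(field_half - frame_half), field_half - frame_half, size=2)
            frame = probes.CountingFrame(
                rect=(fc[0] + fr[0] - frame_half, fc[1] + fr[1] - frame_half,
                      fc[0] + fr[0] + frame_half, fc[1] + fr[1] + frame_half),
                rule=config.frame_rule,
            )
            q = probes.count_frame(prof, frame, field=field_rect)
            grid = probes.make_point_grid(config.grid_spacing_um / 1000.0, rng_fld)
            p_cap, p_ref = probes.count_grid_hits_profiles(grid, prof, field_rect)
            lines = probes.make_test_lines(field_rect, config.line_spacing_um / 1000.0, rng_fld)
            n_i, l_mm = probes.count_line_intersections(lines, prof)
            sec_id = prof.section_id
            recs.extend(
                [
                    probes.CountRecord(record.animal_id, record.group, sec_id, f,
                                       "frame_q", q, probe_area_mm2=frame.area_mm2),
                    probes.CountRecord(record.animal_id, record.group, sec_id, f,
                                       "point_cap", p_cap, probe_area_mm2=grid.a_p_mm2),
                    probes.CountRecord(record.animal_id, record.group, sec_id, f,
                                       "point_ref", p_ref, probe_area_mm2=grid.a_p_mm2),
                    probes.CountRecord(record.animal_id, record.group, sec_id, f,
                                       "line_i", n_i, probe_length_mm=l_mm),
                ]
            )
    return recs


# --------------------------------------------------------------------------
# The whole study
# --------------------------------------------------------------------------


@dataclass
class StudyResult:
    animals: pd.DataFrame
    counts: pd.DataFrame
    latencies: pd.DataFrame
    summary: pd.DataFrame
    tests: dict
    table1: pd.DataFrame
    cohort: list
    config: StudyConfig
    seed: int


_STEREO_VARS = ["V_wm_mm3", "L_m", "Vcap_mm3", "Scap_mm2"]
_BEHAV_VARS = ["final_day_latency_s", "platform_crossings", "quadrant_time_pct"]


def run_study(config: StudyConfig = StudyConfig(), seed: int = 0) -> StudyResult:
    """Generate the cohort, probe every animal's phantom, estimate, and test."""
    cohort = phantom.generate_cohort(config.cohort, seed=seed)
    all_recs: list[probes.CountRecord] = []
    rows = []
    for rec in cohort:
        region = phantom.build_animal_region(rec, config.region_y_mm, config.region_z_mm)
        net = phantom.build_animal_network(
            rec, region,
            segment_length_mm=config.segment_length_mm,
            orientation=config.orientation,
            large_vessel_fraction=config.large_vessel_fraction,
        )
        recs = probe_animal(net, rec, config, seed_key=tuple(rec.network_seed) + (11,))
        all_recs.extend(recs)
        counts = probes.records_to_frame(recs)
        tot = estimators.estimate_animal_totals(counts)
        rec.estimates = {
            "V_wm_mm3": tot.wm_volume_mm3,
            "L_m": tot.length_m,
            "Vcap_mm3": tot.cap_volume_mm3,
            "Scap_mm2": tot.surface_mm2,
        }
        truth = net.truth
        rows.append(
            {
                "animal": rec.animal_id,
                "group": rec.group,
                **rec.estimates,
                "true_V_wm_mm3": truth.wm_volume_mm3,
                "true_L_m": truth.length_m,
                "true_Vcap_mm3": truth.cap_volume_mm3,
                "true_Scap_mm2": truth.surface_mm2,
                "final_day_latency_s": rec.final_day_latency_s,
                "platform_crossings": rec.platform_crossings,
                "quadrant_time_pct": rec.quadrant_time_pct,
            }
        )
    animals = pd.DataFrame(rows)
    counts = probes.records_to_frame(all_recs)
    latencies = pd.DataFrame(
        [
            {"animal": r.animal_id, "group": r.group, "day": d + 1, "trial": t + 1,
             "latency_s": r.latency_s[d, t]}
            for r in cohort
            for d in range(r.latency_s.shape[0])
            for t in range(r.latency_s.shape[1])
        ]
    )
    summary = group_summary(animals)
    tests = study_tests(animals, cohort)
    table1 = build_table1(animals)
    return StudyResult(animals, counts, latencies, summary, tests, table1,
                       cohort, config, seed)


def group_summary(animals: pd.DataFrame) -> pd.DataFrame:
    """Group means with the field's dispersion conventions: SD for the
    stereological quantities, SEM for the behavioural ones."""
    rows = []
    for grp, sub in animals.groupby("group", sort=True):
        n = len(sub)
        for var in _STEREO_VARS + [v for v in _BEHAV_VARS if v in sub.columns]:
            if var not in sub.columns:
                continue
            x = sub[var].to_numpy(dtype=float)
            sd = float(x.std(ddof=1))
            behav = var in _BEHAV_VARS
            rows.append(
                {
                    "group": grp,
                    "variable": var,
                    "n": n,
                    "mean": float(x.mean()),
                    "dispersion": sd / np.sqrt(n) if behav else sd,
                    "dispersion_kind": "sem" if behav else "sd",
                }
            )
    return pd.DataFrame(rows)


def study_tests(animals: pd.DataFrame, cohort: list) -> dict:
    """All hypothesis tests of the study: unpaired t per stereological and
    probe-trial variable, and the repeated-measures ANOVA on latencies."""
    groups = sorted(animals["group"].unique())
    if len(groups) != 2:
        raise ValueError("study tests expect exactly two groups")
    ga = animals[animals.group == groups[0]]
    gb = animals[animals.group == groups[1]]
    out: dict = {"groups": groups}
    for var in _STEREO_VARS + _BEHAV_VARS[1:]:
        out[var] = unpaired_t(ga[var], gb[var], name=f"t_{var}").as_dict()
    daily = {
        g: np.stack([r.daily_latency_s for r in cohort if r.group == g]) for g in groups
    }
    out["latency_rm_anova"] = {k: v.as_dict() for k, v in rm_anova(daily).items()}
    out["shapiro"] = shapiro_flags(animals, _STEREO_VARS)
    return out


# --------------------------------------------------------------------------
# File outputs
# --------------------------------------------------------------------------


def run_pipeline(config: StudyConfig | str | Path, seed: int, outdir) -> dict:
    """Run the whole study and write every report file; bit-identical
    across re-runs with the same config and seed.

    Returns a manifest of written paths and their SHA256 digests.
    """
    if not isinstance(config, StudyConfig):
        config = load_config(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    res = run_study(config, seed=seed)

    phantom.cohort_to_json(res.cohort, config.cohort, seed, out / "cohort.json")
    phantom.latencies_to_csv(res.cohort, out / "latencies.csv")
    probes.counts_to_csv(res.counts, out / "counts.csv")
    estimators.estimates_to_csv(
        res.animals[["animal", "group"] + _STEREO_VARS], out / "estimates.csv"
    )
    res.animals.to_csv(out / "animals.csv", index=False, float_format="%.10g")
    res.summary.to_csv(out / "group_summary.csv", index=False, float_format="%.10g")
    res.table1.to_csv(out / "table1.csv", index=False, float_format="%.10g")
    (out / "tests.json").write_text(json.dumps(res.tests, indent=2, sort_keys=True))
    log = {
        "seed": seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config).items()
            if k != "cohort"
        },
        "cohort": {
            "shared_rho": config.cohort.shared_rho,
            "groups": [
                {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(g).items()}
                for g in config.cohort.groups
            ],
        },
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))

    manifest = {}
    for f in sorted(out.iterdir()):
        if f.is_file():
            manifest[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    return manifest
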