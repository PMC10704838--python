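"""End-to-end orchestration: simulate -> stereology -> ultrastructure ->
histology -> statistics -> report.

Every stage is a pure function of (inputs, config, seed); repeated runs
with the same configuration and seed reproduce byte-identical outputs.
Per-sample analysis randomness (field-of-view placement, measurement-site
rotation) is drawn from substreams keyed by sample id, independent of the
generator's substreams.
"""

from __future__ import annotations

import datetime
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from . import histology, stereology, ultrastructure
from .histology import FiberTable, count_cells_per_10hpf, derive_atrophy_flags
from .io import RunConfig, RunManifest, file_sha256, write_ground_truth_tsv
from .stats import TukeyResult, anova_tukey
from .synthetic import SampleRecord, generate_cohort, sample_fovs, sample_rng


def fiber_table_from_scene(
    record: SampleRecord,
    rng: np.random.Generator,
    atrophy_relative_cutoff: float = 0.5,
    mhc1_positive_fraction: float = 0.02,
) -> FiberTable:
    """Per-fiber annotation table for a synthetic scene.

    The atrophic flag is derived (area below half the same-type median);
    sarcolemmal MHC-class-I positivity is a sparse random annotation since
    the geometric generator carries no staining signal.
    """
    scene = record.scene
    df = pd.DataFrame(
        {
            "fiber_id": [f"{scene.sample_id}-f{i + 1}" for i in range(len(scene.fibers))],
            "fiber_type": [f.fiber_type for f in scene.fibers],
            "area_um2": [f.area for f in scene.fibers],
            "min_diameter_um": [f.min_diameter for f in scene.fibers],
        }
    )
    df["mhc1_sarcolemmal"] = rng.random(len(df)) < mhc1_positive_fraction
    df["atrophic"] = derive_atrophy_flags(df, atrophy_relative_cutoff)
    return FiberTable(df=df)


class SampleAnalysis(NamedTuple):
    row: dict  # one per-sample summary row
    capillaries: list[dict]  # per-capillary morphometry rows
    sites: list[dict]  # long-format single CBM site measurements
    exclusions: list[dict]


def analyze_sample(record: SampleRecord, config: RunConfig) -> SampleAnalysis:
    """All measurement stages for one sample."""
    sid = record.scene.sample_id
    rng = sample_rng(config.seed + 1_000_003, sid)  # analysis stream, distinct from generation

    # --- stereology over fields of view (guard margin keeps frames off the
    # depopulated scene border, where frame counts of polygons lose unbiasedness)
    from .synthetic import guard_margin

    fovs = sample_fovs(
        record.scene,
        (config.fov_size_um, config.fov_size_um),
        config.n_fov,
        rng,
        margin=guard_margin(record.scene),
    )
    est = stereology.measure_sample(record.scene, fovs, config.grid_rows, config.grid_cols)

    # --- ultrastructure
    included, excluded, morphs = ultrastructure.filter_profiles(
        record.tem_profiles, config.ultrastructure, return_morphometry=True
    )
    cap_rows, site_rows, msets = [], [], []
    for p in included:
        ar, morph = morphs[p.capillary_id]
        mset = ultrastructure.measure_cbm(p, config.ultrastructure, rng)
        msets.append(mset)
        flags = ultrastructure.flags_from_profile(p, morph)
        cap_rows.append(
            {
                "capillary_id": p.capillary_id,
                "sample_id": sid,
                "included": True,
                "exclusion_reason": "",
                "aspect_ratio": ar,
                "cbm_mean_nm": mset.capillary_mean,
                "lumen_radius_nm": morph.lumen_radius,
                "ec_thickness_nm": morph.ec_thickness,
                "bm_thickness_nm": morph.bm_thickness,
                "pericyte_coverage_pct": morph.pericyte_coverage,
                "pathology_score": ultrastructure.score_capillary_pathology(flags),
            }
        )
        for k, (ang, th) in enumerate(zip(mset.site_angles, mset.site_thicknesses)):
            site_rows.append(
                {
                    "capillary_id": p.capillary_id,
                    "sample_id": sid,
                    "site_index": k,
                    "angle_rad": ang,
                    "thickness_nm": th,
                    "outlier_flag": th > config.ultrastructure.outlier_nm,
                }
            )
    exclusion_rows = [
        {"capillary_id": e.capillary_id, "sample_id": sid, "stage": "ultrastructure", "reason": e.reason, "value": e.value}
        for e in excluded
    ]
    cbm = ultrastructure.aggregate_cbm(msets, config.ultrastructure.outlier_nm) if msets else None

    # --- histology
    fibers = fiber_table_from_scene(record, rng)
    atrophy = histology.score_type2b_atrophy(fibers)
    mhc1_score, mhc1_sig = histology.score_mhc1(fibers)
    comp = histology.fiber_type_composition(fibers)
    cells = count_cells_per_10hpf(sid, record.truth["cell_fields"])

    row = {
        "sample_id": sid,
        "group": record.truth["group"],
        "n_fov": len(fovs),
        "cf_ratio": est.cf_ratio,
        "mcsfa_um2": est.mcsfa,
        "cap_density_per_mm2": est.capillary_density,
        "n_tem_included": len(included),
        "n_tem_excluded": len(excluded),
        "cbm_mean_nm": cbm.mean_of_capillary_means if cbm else np.nan,
        "cbm_sd_nm": cbm.sd_of_capillary_means if cbm else np.nan,
        "cbm_n_sites": cbm.n_measurements if cbm else 0,
        "cbm_outliers_flagged": cbm.n_outliers_flagged if cbm else 0,
        "atrophy_score": atrophy,
        "mhc1_score": mhc1_score,
        "mhc1_significant": mhc1_sig,
        "pct_type1": comp["1"],
        "pct_type2a": comp["2a"],
        "pct_type2b": comp["2b"],
    }
    for rec in cells:
        row[f"cells_{rec.marker}_per_10hpf"] = rec.total_per_10hpf
    return SampleAnalysis(row=row, capillaries=cap_rows, sites=site_rows, exclusions=exclusion_rows)


STAT_VARIABLES = ("cf_ratio", "mcsfa_um2", "cap_density_per_mm2", "cbm_mean_nm")


def group_statistics(samples: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, TukeyResult]]:
    """One-way ANOVA + Tukey per morphometric/cell-count variable."""
    variables = [v for v in STAT_VARIABLES if v in samples.columns]
    variables += [c for c in samples.columns if c.startswith("cells_")]
    rows = []
    tukeys: dict[str, TukeyResult] = {}
    for var in variables:
        values = {
            g: sub[var].dropna().to_numpy() for g, sub in samples.groupby("group", sort=False)
        }
        if any(len(v) < 2 for v in values.values()):
            continue
        f_stat, p_omni, tk = anova_tukey(values)
        tukeys[var] = tk
        for pair in tk.pairs:
            rows.append(
                {
                    "variable": var,
                    "pair": f"{pair.group_i} vs {pair.group_j}",
                    "mean_diff": pair.mean_difference,
                    "se": pair.standard_error,
                    "q": pair.q_statistic,
                    "p_adj": pair.p_adjusted,
                    "f_omnibus": f_stat,
                    "p_omnibus": p_omni,
                }
            )
    return pd.DataFrame(rows), tukeys


def analyze_cohort(cohort: dict[str, SampleRecord], config: RunConfig) -> dict:
    """Run every analysis stage over a generated cohort (in memory)."""
    analyses = [analyze_sample(rec, config) for rec in cohort.values()]
    samples = pd.DataFrame([a.row for a in analyses])
    capillaries = pd.DataFrame([r for a in analyses for r in a.capillaries])
    sites = pd.DataFrame([r for a in analyses for r in a.sites])
    exclusions = pd.DataFrame([r for a in analyses for r in a.exclusions])
    stats_df, tukeys = group_statistics(samples)
    return {
        "samples": samples,
        "capillaries": capillaries,
        "sites": sites,
        "exclusions": exclusions,
        "stats": stats_df,
        "tukeys": tukeys,
    }


def run_pipeline(config: RunConfig) -> RunManifest:
    """Simulate a cohort, analyse it, and write all stage outputs.

    Emits ground-truth, per-sample, per-capillary, per-site, exclusion and
    statistics TSVs plus a manifest listing every output file with its
    SHA-256 checksum.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    config.cohort.seed = config.seed
    cohort = generate_cohort(config.cohort)
    results = analyze_cohort(cohort, config)

    files: dict[str, str] = {}

    def _write(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
        files[name] = file_sha256(path)

    truth_path = write_ground_truth_tsv(cohort, out / "ground_truth.tsv")
    files["ground_truth.tsv"] = file_sha256(truth_path)
    _write(results["samples"], "samples.tsv")
    _write(results["capillaries"], "capillaries.tsv")
    _write(results["sites"], "cbm_sites.tsv")
    _write(results["exclusions"], "exclusions.tsv")
    _write(results["stats"], "group_stats.tsv")
    cfg_path = config.to_json(out / "config.json")
    files["config.json"] = file_sha256(cfg_path)

    manifest = RunManifest(
        config_hash=config.config_hash(),
        seed=config.seed,
        files=files,
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )
    manifest.to_json(out / "manifest.json")
    return manifest
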