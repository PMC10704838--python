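"""Serialization, configuration and run manifests.

All on-disk formats are human-diffable plain text: one JSON document per
sample (scene geometry, TEM contours under the keys "lumen",
"ec_abluminal", "bm_outer", "pericyte_arcs", and a sibling "truth"
object), TSV tables for ground truth, per-sample results and fiber/cell
annotations, and a JSON run manifest with per-file checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .histology import FiberTable
from .synthetic import (
    CohortSpec,
    FiberProfile,
    SampleRecord,
    TEMCapillaryProfile,
    TissueScene,
)
from .ultrastructure import UltrastructureConfig

CONTOUR_KEYS = ("lumen", "ec_abluminal", "bm_outer")


# ---------------------------------------------------------------------------
# Scene / profile serialization
# ---------------------------------------------------------------------------


def profile_to_dict(p: TEMCapillaryProfile) -> dict:
    return {
        "capillary_id": p.capillary_id,
        "lumen": np.round(p.lumen_contour, 4).tolist(),
        "ec_abluminal": np.round(p.ec_abluminal_contour, 4).tolist(),
        "bm_outer": np.round(p.bm_outer_contour, 4).tolist(),
        "pericyte_arcs": [[round(a, 8), round(b, 8)] for a, b in p.pericyte_arcs],
        "obliqueness": p.obliqueness,
        "true_cbm_field": np.round(p.true_cbm_field, 4).tolist(),
    }


def profile_from_dict(d: dict, context: str = "profile") -> TEMCapillaryProfile:
    for key in CONTOUR_KEYS:
        if key not in d:
            raise ValueError(f"{context}: missing required contour key '{key}'")
    return TEMCapillaryProfile(
        capillary_id=str(d.get("capillary_id", "cap")),
        lumen_contour=np.asarray(d["lumen"], dtype=float),
        ec_abluminal_contour=np.asarray(d["ec_abluminal"], dtype=float),
        bm_outer_contour=np.asarray(d["bm_outer"], dtype=float),
        pericyte_arcs=[(float(a), float(b)) for a, b in d.get("pericyte_arcs", [])],
        obliqueness=float(d.get("obliqueness", 1.0)),
        true_cbm_field=np.asarray(d.get("true_cbm_field", []), dtype=float),
    )


def scene_to_dict(scene: TissueScene) -> dict:
    return {
        "sample_id": scene.sample_id,
        "scene_extent": list(scene.scene_extent),
        "fibers": [
            {
                "polygon": np.round(f.polygon, 4).tolist(),
                "fiber_type": f.fiber_type,
                "area": round(f.area, 4),
                "min_diameter": round(f.min_diameter, 4),
                "shrunk": f.shrunk,
            }
            for f in scene.fibers
        ],
        "capillaries": np.round(scene.capillaries, 4).tolist(),
        "cell_markers": {m: np.round(pts, 4).tolist() for m, pts in scene.cell_markers.items()},
    }


def scene_from_dict(d: dict) -> TissueScene:
    for key in ("sample_id", "scene_extent", "fibers", "capillaries"):
        if key not in d:
            raise ValueError(f"scene: missing required key '{key}'")
    fibers = [
        FiberProfile(
            polygon=np.asarray(f["polygon"], dtype=float),
            fiber_type=str(f["fiber_type"]),
            area=float(f["area"]),
            min_diameter=float(f["min_diameter"]),
            shrunk=bool(f.get("shrunk", False)),
        )
        for f in d["fibers"]
    ]
    return TissueScene(
        sample_id=str(d["sample_id"]),
        fibers=fibers,
        capillaries=np.asarray(d["capillaries"], dtype=float).reshape(-1, 2),
        cell_markers={
            m: np.asarray(pts, dtype=float).reshape(-1, 2)
            for m, pts in d.get("cell_markers", {}).items()
        },
        scene_extent=tuple(d["scene_extent"]),
    )


def write_sample_json(record: SampleRecord, path: str | Path) -> Path:
    path = Path(path)
    doc = {
        "scene": scene_to_dict(record.scene),
        "tem_profiles": [profile_to_dict(p) for p in record.tem_profiles],
        "truth": record.truth,
    }
    path.write_text(json.dumps(doc, sort_keys=True))
    return path


def read_sample_json(path: str | Path) -> SampleRecord:
    doc = json.loads(Path(path).read_text())
    return SampleRecord(
        scene=scene_from_dict(doc["scene"]),
        tem_profiles=[
            profile_from_dict(p, context=f"{path} tem_profiles[{i}]")
            for i, p in enumerate(doc.get("tem_profiles", []))
        ],
        truth=doc.get("truth", {}),
    )


def read_contours(path: str | Path) -> list[TEMCapillaryProfile]:
    """Read a standalone JSON list of capillary contour sets."""
    doc = json.loads(Path(path).read_text())
    if isinstance(doc, dict):
        doc = doc.get("tem_profiles", [doc])
    return [profile_from_dict(p, context=f"{path}[{i}]") for i, p in enumerate(doc)]


# ---------------------------------------------------------------------------
# Tabular formats
# ---------------------------------------------------------------------------


def read_fiber_table(path: str | Path) -> FiberTable:
    """TSV with columns fiber_id, fiber_type, area_um2, min_diameter_um,
    mhc1_sarcolemmal, atrophic; malformed rows are rejected with their
    line number."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in FiberTable.REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in ("area_um2", "min_diameter_um"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() | (
            pd.to_numeric(df[col], errors="coerce") <= 0
        )
        if bad.any():
            line = int(df.index[bad][0]) + 2  # header is line 1
            raise ValueError(f"{path}:{line}: invalid {col} value '{df.loc[df.index[bad][0], col]}'")
    df["mhc1_sarcolemmal"] = df["mhc1_sarcolemmal"].astype(bool)
    df["atrophic"] = df["atrophic"].astype(bool)
    df["fiber_type"] = df["fiber_type"].astype(str)
    return FiberTable(df=df)


def read_cell_counts(path: str | Path) -> dict[str, dict[str, list[int]]]:
    """TSV (sample_id, marker, field_index, count) -> nested counts map."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "marker", "field_index", "count"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: must have columns {sorted(required)}")
    bad = pd.to_numeric(df["count"], errors="coerce").isna() | (df["count"].astype(float) < 0)
    if bad.any():
        line = int(df.index[bad][0]) + 2
        raise ValueError(f"{path}:{line}: invalid count")
    out: dict[str, dict[str, list[int]]] = {}
    for (sid, marker), sub in df.groupby(["sample_id", "marker"]):
        sub = sub.sort_values("field_index")
        out.setdefault(str(sid), {})[str(marker)] = [int(c) for c in sub["count"]]
    return out


def write_ground_truth_tsv(cohort: dict[str, SampleRecord], path: str | Path) -> Path:
    rows = []
    for sid, rec in cohort.items():
        t = rec.truth
        rows.append(
            {
                "sample_id": sid,
                "group": t["group"],
                "cf_true": t["cf_true"],
                "mcsfa_true": t["mcsfa_true"],
                "cbm_mean_true": t["cbm_mean_true"],
                "n_fibers": t["n_fibers"],
                "n_capillaries": t["n_capillaries"],
                "n_tem_profiles": t["n_tem_profiles"],
                "atrophic_2b_fraction": t["atrophic_2b_fraction"],
            }
        )
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


# ---------------------------------------------------------------------------
# Run configuration and manifest
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Everything a pipeline run depends on besides the code version."""

    seed: int = 0
    cohort: CohortSpec = field(default_factory=CohortSpec)
    fov_size_um: float = 250.0
    n_fov: int = 10
    grid_rows: int = 10
    grid_cols: int = 10
    ultrastructure: UltrastructureConfig = field(default_factory=UltrastructureConfig)
    alpha: float = 0.05
    out_dir: str = "capimorph_out"

    def validate(self) -> None:
        self.cohort.validate()
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.fov_size_um <= 0 or self.n_fov < 1:
            raise ValueError("fov_size_um must be > 0 and n_fov >= 1")
        u = self.ultrastructure
        for name in ("max_aspect", "large_vessel_nm", "max_pericyte_coverage_pct", "pericyte_margin_deg", "outlier_nm"):
            if getattr(u, name) <= 0:
                raise ValueError(f"ultrastructure threshold {name} must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            c = dict(d["cohort"])
            for key in (
                "group_names", "group_sizes", "cf_true", "mcsfa_true",
                "type2b_atrophy_factor", "type2b_atrophy_fraction",
                "fiber_type_props", "cbm_mean", "cbm_sd",
                "capillaries_per_sample_range",
            ):
                if key in c and isinstance(c[key], list):
                    c[key] = tuple(c[key])
            if "cells_per_10hpf_mean" in c:
                c["cells_per_10hpf_mean"] = {
                    m: tuple(v) for m, v in c["cells_per_10hpf_mean"].items()
                }
            d["cohort"] = CohortSpec(**c)
        if "ultrastructure" in d and isinstance(d["ultrastructure"], dict):
            d["ultrastructure"] = UltrastructureConfig(**d["ultrastructure"])
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), sort_keys=True, indent=1))
        return path

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    files: dict  # relative path -> sha256
    timestamp: str = ""
    version: str = "0.1.0"

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), sort_keys=True, indent=1))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
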