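"""TEM capillary morphometry: screening, contour measures, six-site CBM
thickness, and the 0-4 pathology rubric.

Uses synthetic nested-contour profiles with a known per-vertex basement
membrane (CBM) thickness field, so the measured six-site means can be
compared with the generating truth.
"""

import numpy as np

from capimorph import (
    UltrastructureConfig,
    aggregate_cbm,
    aspect_ratio,
    filter_profiles,
    measure_cbm,
    score_capillary_pathology,
    tbia_morphometry,
)
from capimorph.synthetic import make_tem_profile
from capimorph.ultrastructure import Ensheathment, FeatureFlags, VesicleMitoGrade

rng = np.random.default_rng(11)

# --- Generate profiles, some deliberately oblique ------------------------
profiles = [
    make_tem_profile(
        lumen_radius=2200.0,
        ec_thickness=250.0,
        cbm_mean=320.0,
        cbm_sd=50.0,
        pericyte_coverage=0.30,
        obliqueness=1.0 if i % 4 else 1.45,  # every 4th cut is oblique
        seed=rng,
        capillary_id=f"cap-{i:02d}",
    )
    for i in range(12)
]
for p in profiles[:3]:
    print(f"{p.capillary_id}: aspect ratio {aspect_ratio(p.bm_outer_contour):.3f}")

# --- Screening: oblique sections (largest/smallest Feret > 1.2) out ------
config = UltrastructureConfig()
included, excluded = filter_profiles(profiles, config)
print(f"\nincluded {len(included)}/{len(profiles)}; excluded:")
for e in excluded:
    print(f"  {e.capillary_id}: {e.reason} (value {e.value:.3f})")

# --- Contour morphometry (TBIA-style formulas) ---------------------------
m = tbia_morphometry(included[0])
print(
    f"\n{included[0].capillary_id}: lumen radius {m.lumen_radius:.0f} nm, "
    f"EC thickness {m.ec_thickness:.0f} nm, BM thickness {m.bm_thickness:.0f} nm, "
    f"pericyte coverage {m.pericyte_coverage:.1f}%"
)

# --- Six-site CBM thickness, pooled over the sample ----------------------
sets = [measure_cbm(p, config, seed=rng) for p in included]
first = sets[0]
print(
    f"\nsix sites on {first.capillary_id}: "
    + ", ".join(f"{t:.0f}" for t in first.site_thicknesses)
    + f" nm -> capillary mean {first.capillary_mean:.1f} nm"
)
summary = aggregate_cbm(sets, outlier_nm=config.outlier_nm)
print(
    f"sample: {summary.n_measurements} single measurements over "
    f"{summary.n_capillaries} capillaries; mean {summary.mean_single:.1f} nm "
    f"(generating mean 320), {summary.n_outliers_flagged} flagged > "
    f"{config.outlier_nm:.0f} nm"
)

# --- Pathology rubric ----------------------------------------------------
cases = {
    "normal": FeatureFlags(),
    "5 pericyte processes": FeatureFlags(n_pericyte_processes=5),
    "ensheathment present": FeatureFlags(ensheathment=Ensheathment.PRESENT),
    "prominent + severe": FeatureFlags(
        vesicle_mito_grade=VesicleMitoGrade.PROMINENT, severe=True
    ),
    "endothelial necrosis": FeatureFlags(ec_necrosis_or_debris=True),
}
print("\npathology rubric:")
for label, flags in cases.items():
    print(f"  {label}: grade {score_capillary_pathology(flags)}")
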