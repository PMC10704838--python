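"""Group statistics: Tukey from published-style summaries or raw values,
Pearson correlation, and ddCt relative gene expression."""

import numpy as np
import pandas as pd

from capimorph.stats import (
    GroupSummary,
    anova_tukey,
    ddct_fold_change,
    format_p,
    pearson_r,
    tukey_from_summary,
)

# --- Tukey HSD directly from (mean, SD, n) group summaries ---------------
# This is the path for re-analysing published tables where raw values are
# unavailable: macrophage counts per 10 HPF in three groups.
cd68 = [
    GroupSummary("HDC", mean=32.0, sd=12.0, n=8),
    GroupSummary("2BA", mean=34.0, sd=15.0, n=8),
    GroupSummary("PCS", mean=58.0, sd=16.0, n=11),
]
result = tukey_from_summary(cd68)
print("CD68 cells/10HPF, Tukey-adjusted pairwise p-values:")
for pair in result.pairs:
    print(
        f"  {pair.group_i} vs {pair.group_j}: diff {pair.mean_difference:+.1f}, "
        f"q = {pair.q_statistic:.2f}, {format_p(pair.p_adjusted)}"
    )

# --- ANOVA + Tukey from raw per-sample values ----------------------------
rng = np.random.default_rng(2)
values = {
    "HDC": rng.normal(1.8, 0.15, size=8),
    "2BA": rng.normal(1.8, 0.15, size=8),
    "PCS": rng.normal(1.5, 0.15, size=11),
}
f_stat, p_omnibus, tukey = anova_tukey(values)
print(f"\nC/F ratio omnibus: F = {f_stat:.2f}, {format_p(p_omnibus)}")
print(f"HDC vs PCS adjusted: {format_p(tukey.pair('HDC', 'PCS').p_adjusted)}")

# --- Pearson correlation -------------------------------------------------
x = rng.normal(size=30)
y = 0.6 * x + rng.normal(scale=0.8, size=30)
r, p = pearson_r(x, y)
print(f"\nPearson: r = {r:.3f}, {format_p(p)}")

# --- ddCt with the 40-cycle expression rule ------------------------------
def rows(sample_id, group, gene, cts):
    return [
        {"sample_id": sample_id, "group": group, "gene": gene, "replicate": i, "ct": c}
        for i, c in enumerate(cts)
    ]

ct_table = pd.DataFrame(
    rows("p1", "PCS", "GAPDH", [20.0, 20.1, 19.9])
    + rows("p1", "PCS", "IFNB1", [26.0, 26.2, 25.8])   # dCt = 6
    + rows("p1", "PCS", "ISG15", [39.0, 41.0, 38.0])   # 41 dropped (> 40 cycles)
    + rows("c1", "HDC", "GAPDH", [20.0, 20.0, 20.0])
    + rows("c1", "HDC", "IFNB1", [25.0, 25.0, 25.0])   # dCt = 5
    + rows("c1", "HDC", "ISG15", [30.0, 30.0, 30.0])
)
print("\nddCt (PCS vs HDC, reference GAPDH):")
for rec in ddct_fold_change(ct_table, case_group="PCS", control_group="HDC"):
    print(
        f"  {rec.target_gene}: ddCt = {rec.delta_delta_ct:+.2f}, "
        f"fold change = {rec.fold_change:.3f}, expressed = {rec.expressed}"
    )
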