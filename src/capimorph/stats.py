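"""Group-comparison statistics: one-way ANOVA with Tukey's test, Pearson
correlation, and ddCt relative gene expression.

Tukey's multiple-comparison test is available both from raw per-sample
values and from printed summary statistics (mean, SD, n per group), with
the Tukey-Kramer standard error for unequal group sizes:

    MSE  = sum_i (n_i - 1) s_i^2 / sum_i (n_i - 1)
    SE_ij = sqrt(MSE / 2 * (1 / n_i + 1 / n_j))
    q_ij  = |xbar_i - xbar_j| / SE_ij

with the adjusted p-value the upper tail of the studentized-range
distribution with k groups and df_error = sum_i (n_i - 1). The raw-data
path reduces exactly to the summary path applied to the groups' computed
means/SDs/ns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class GroupSummary:
    group: str
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group {self.group}: n must be >= 2")
        if self.sd < 0:
            raise ValueError(f"group {self.group}: sd must be >= 0")


@dataclass
class PairwiseComparison:
    group_i: str
    group_j: str
    mean_difference: float  # xbar_i - xbar_j (signed)
    standard_error: float
    q_statistic: float
    p_adjusted: float


@dataclass
class TukeyResult:
    pairs: list[PairwiseComparison]
    mse: float
    df_error: int
    k_groups: int

    def pair(self, a: str, b: str) -> PairwiseComparison:
        for p in self.pairs:
            if {p.group_i, p.group_j} == {a, b}:
                return p
        raise KeyError(f"no comparison for ({a}, {b})")


def tukey_from_summary(groups: list[GroupSummary]) -> TukeyResult:
    """All-pairs Tukey(-Kramer) test from per-group mean/SD/n."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    df_error = sum(g.n - 1 for g in groups)
    mse = sum((g.n - 1) * g.sd**2 for g in groups) / df_error
    k = len(groups)
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            gi, gj = groups[i], groups[j]
            diff = gi.mean - gj.mean
            if mse == 0:
                if diff != 0:
                    warnings.warn(
                        "zero pooled variance with nonzero mean difference; p set to 0",
                        RuntimeWarning,
                        stacklevel=2,
                    )
                    se, q, p = 0.0, np.inf, 0.0
                else:
                    se, q, p = 0.0, 0.0, 1.0
            else:
                se = np.sqrt(mse / 2.0 * (1.0 / gi.n + 1.0 / gj.n))
                q = abs(diff) / se
                p = float(sps.studentized_range.sf(q, k, df_error))
            pairs.append(
                PairwiseComparison(
                    group_i=gi.group,
                    group_j=gj.group,
                    mean_difference=diff,
                    standard_error=se,
                    q_statistic=q,
                    p_adjusted=min(max(p, 0.0), 1.0),
                )
            )
    return TukeyResult(pairs=pairs, mse=mse, df_error=df_error, k_groups=k)


def _group_arrays(values: dict[str, np.ndarray]) -> list[np.ndarray]:
    if len(values) < 2:
        raise ValueError("need at least 2 groups")
    arrays = []
    for g, v in values.items():
        arr = np.asarray(v, dtype=float)
        if len(arr) < 2:
            raise ValueError(f"group {g}: n must be >= 2")
        arrays.append(arr)
    return arrays


def anova_f(values: dict[str, np.ndarray]) -> tuple[float, float]:
    """Omnibus one-way ANOVA on raw per-group data: (F, p)."""
    arrays = _group_arrays(values)
    grand = np.concatenate(arrays).mean()
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_between = len(arrays) - 1
    df_within = sum(len(a) - 1 for a in arrays)
    if ss_within == 0:
        if ss_between > 0:
            warnings.warn("zero within-group variance; omnibus p set to 0", RuntimeWarning, stacklevel=2)
            f_stat, p_omnibus = np.inf, 0.0
        else:
            f_stat, p_omnibus = 0.0, 1.0
    else:
        f_stat = (ss_between / df_between) / (ss_within / df_within)
        p_omnibus = float(sps.f.sf(f_stat, df_between, df_within))
    return float(f_stat), p_omnibus


def anova_tukey(values: dict[str, np.ndarray]) -> tuple[float, float, TukeyResult]:
    """Omnibus one-way ANOVA plus Tukey pairwise comparisons on raw data.

    Returns (F, omnibus p, TukeyResult). The pairwise result is by
    construction identical to ``tukey_from_summary`` applied to the
    groups' computed summaries.
    """
    arrays = _group_arrays(values)
    summaries = [
        GroupSummary(group=g, mean=float(a.mean()), sd=float(a.std(ddof=1)), n=len(a))
        for g, a in zip(values, arrays)
    ]
    f_stat, p_omnibus = anova_f(values)
    return f_stat, p_omnibus, tukey_from_summary(summaries)


def pearson_r(x, y) -> tuple[float, float]:
    """Product-moment correlation with the two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("x and y must have equal length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for constant input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def format_p(p: float) -> str:
    """Report-layer p formatting: one significant figure below 0.001,
    three decimals otherwise. Full precision is kept internally."""
    if p < 0.001:
        return f"{p:.1g}"
    return f"{p:.3f}"


# ---------------------------------------------------------------------------
# ddCt relative expression
# ---------------------------------------------------------------------------

EXPRESSION_CUTOFF_CYCLES = 40.0


@dataclass
class DdctRecord:
    target_gene: str
    reference_gene: str
    delta_ct_case: float
    delta_ct_control: float
    delta_delta_ct: float
    fold_change: float
    expressed: bool


def _mean_expressed_ct(cts: np.ndarray) -> float:
    """Triplicate mean after dropping cycles above the expression cutoff."""
    cts = np.asarray(cts, dtype=float)
    ok = cts <= EXPRESSION_CUTOFF_CYCLES
    if not ok.any():
        return np.nan
    return float(cts[ok].mean())


def ddct_fold_change(
    ct_table,
    case_group: str,
    control_group: str,
    reference_gene: str = "GAPDH",
) -> list[DdctRecord]:
    """Relative expression 2^-ddCt per target gene.

    ``ct_table`` is a long-format DataFrame with columns sample_id, group,
    gene, replicate, ct. Per sample and gene, replicate CTs above 40
    cycles are dropped as not expressed before averaging; dCt = mean CT of
    the target minus mean CT of the reference gene per sample; ddCt is the
    case-group mean dCt minus the control-group mean dCt; fold change is
    2^-ddCt. A target whose replicates are all above the cutoff in either
    group is reported not-expressed; the same for the reference gene is an
    error.
    """
    import pandas as pd

    df = pd.DataFrame(ct_table)
    required = {"sample_id", "group", "gene", "ct"}
    if not required <= set(df.columns):
        raise ValueError(f"ct table must have columns {sorted(required)}")
    per_sample = (
        df.groupby(["sample_id", "group", "gene"])["ct"]
        .apply(lambda s: _mean_expressed_ct(s.to_numpy()))
        .reset_index(name="ct_mean")
    )
    ref = per_sample[per_sample["gene"] == reference_gene].set_index("sample_id")["ct_mean"]
    if ref.isna().all() or len(ref) == 0:
        raise ValueError(f"reference gene {reference_gene} not expressed in any sample")
    if ref.isna().any():
        bad = ref.index[ref.isna()][0]
        raise ValueError(f"reference gene {reference_gene} not expressed in sample {bad}")

    out = []
    for gene, sub in per_sample[per_sample["gene"] != reference_gene].groupby("gene"):
        sub = sub.copy()
        sub["delta_ct"] = sub["ct_mean"] - sub["sample_id"].map(ref)
        case = sub.loc[sub["group"] == case_group, "delta_ct"]
        control = sub.loc[sub["group"] == control_group, "delta_ct"]
        if case.isna().all() or control.isna().all():
            out.append(
                DdctRecord(
                    target_gene=str(gene),
                    reference_gene=reference_gene,
                    delta_ct_case=np.nan,
                    delta_ct_control=np.nan,
                    delta_delta_ct=np.nan,
                    fold_change=np.nan,
                    expressed=False,
                )
            )
            continue
        dct_case = float(case.dropna().mean())
        dct_control = float(control.dropna().mean())
        ddct = dct_case - dct_control
        out.append(
            DdctRecord(
                target_gene=str(gene),
                reference_gene=reference_gene,
                delta_ct_case=dct_case,
                delta_ct_control=dct_control,
                delta_delta_ct=ddct,
                fold_change=float(2.0 ** (-ddct)),
                expressed=True,
            )
        )
    return out
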