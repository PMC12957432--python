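"""Group statistics: descriptives, t tests, ANOVA, bin exclusion, 2^-ΔΔCt.

Conventions
-----------
* Descriptives use the sample SD (n-1 denominator); SEM = SD/sqrt(n).
* t tests are unpaired, two-sided, pooled-variance (Student), so
  df = nA + nB - 2.  Two identical constant groups give t = 0, p = 1;
  zero variance with unequal means is an error.
* One-way ANOVA reports F, (df_between, df_within) and p; all-identical
  constant groups give F = 0, p = 1.  Post hoc comparisons are pairwise
  pooled-variance t tests over a declared comparison family, Bonferroni
  adjusted with m = family size (adjusted p = min(1, m * p)).
* Two-way ANOVA fits the factorial linear model; for unbalanced designs the
  sums of squares are marginal (each effect adjusted for the others, Type
  II), which reduces to the sequential decomposition when the design is
  balanced.
* Islet size-bin categories with fewer than 5 islets in at least one group
  are excluded from binned analyses.
* qPCR fold changes: ΔCt = Ct_target - mean(reference Cts) (equivalent to
  normalising by the geometric mean of the reference genes in linear
  space); ΔΔCt relative to the control condition's mean ΔCt; fold = 2^-ΔΔCt.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "ComparisonResult",
    "summarize",
    "t_test_unpaired",
    "anova_oneway",
    "anova_twoway",
    "exclude_sparse_bins",
    "delta_delta_ct",
    "bonferroni",
]


@dataclass
class GroupSummary:
    group: str
    n: int
    mean: float
    sd: float
    sem: float


@dataclass
class ComparisonResult:
    label: str
    statistic: float
    df: tuple[float, ...]
    p: float
    p_adjusted: float
    family_size: int


def bonferroni(p: float, m: int) -> float:
    return min(1.0, m * p)


def summarize(values_by_group: dict[str, np.ndarray]) -> list[GroupSummary]:
    """Mean, sample SD, SEM and n per group; empty groups are an error."""
    out = []
    for group, values in values_by_group.items():
        v = np.asarray(values, dtype=float)
        if v.size == 0:
            raise ValueError(f"group {group!r} is empty")
        sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
        out.append(
            GroupSummary(
                group=str(group),
                n=int(v.size),
                mean=float(v.mean()),
                sd=sd,
                sem=sd / np.sqrt(v.size),
            )
        )
    return out


def _pooled_t(a: np.ndarray, b: np.ndarray) -> tuple[float, int, float]:
    na, nb = len(a), len(b)
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if sp2 == 0.0:
        if diff == 0.0:
            return 0.0, df, 1.0
        raise ZeroDivisionError(
            "zero pooled variance with unequal group means; t statistic undefined"
        )
    t = diff / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), df, float(p)


def t_test_unpaired(
    group_a: np.ndarray,
    group_b: np.ndarray,
    label: str = "A vs B",
    family_size: int = 1,
) -> ComparisonResult:
    """Two-sided pooled-variance (Student) t test; df = nA + nB - 2."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    t, df, p = _pooled_t(a, b)
    return ComparisonResult(
        label=label,
        statistic=t,
        df=(float(df),),
        p=p,
        p_adjusted=bonferroni(p, family_size),
        family_size=family_size,
    )


def anova_oneway(
    values_by_group: dict[str, np.ndarray],
    comparisons: list[tuple[str, str]] | None = None,
) -> tuple[ComparisonResult, list[ComparisonResult]]:
    """One-way ANOVA plus Bonferroni-adjusted pairwise post hocs.

    *comparisons* declares the post hoc family (pairs of group labels); by
    default all pairwise comparisons are performed.  The Bonferroni family
    size m is the number of comparisons actually performed.
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("one-way ANOVA needs at least 2 groups")
    for g, v in groups.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} needs at least 2 observations")
    arrays = list(groups.values())
    grand = np.concatenate(arrays)
    k, n = len(arrays), len(grand)
    df_b, df_w = k - 1, n - k
    ss_b = sum(len(a) * (a.mean() - grand.mean()) ** 2 for a in arrays)
    ss_w = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if ss_w == 0.0 and ss_b == 0.0:
        f, p = 0.0, 1.0  # all groups a single constant
    elif ss_w == 0.0:
        f, p = np.inf, 0.0
    else:
        f = (ss_b / df_b) / (ss_w / df_w)
        p = float(sps.f.sf(f, df_b, df_w))
    omnibus = ComparisonResult(
        label="one-way ANOVA",
        statistic=float(f),
        df=(float(df_b), float(df_w)),
        p=float(p),
        p_adjusted=float(p),
        family_size=1,
    )
    labels = list(groups)
    if comparisons is None:
        comparisons = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1 :]]
    m = len(comparisons)
    posthoc = [
        t_test_unpaired(groups[a], groups[b], label=f"{a} vs {b}", family_size=m)
        for a, b in comparisons
    ]
    return omnibus, posthoc


def anova_twoway(
    values: np.ndarray,
    factor_a: np.ndarray,
    factor_b: np.ndarray,
    posthoc_within_b: bool = False,
) -> dict[str, ComparisonResult]:
    """Two-way factorial ANOVA with marginal (Type II) sums of squares.

    Returns results keyed ``factor_a``, ``factor_b`` and ``interaction``.
    With *posthoc_within_b*, pairwise factor-A comparisons within each level
    of factor B are added (Bonferroni m = total number of such comparisons),
    keyed ``"{b}: {a1} vs {a2}"`` — the within-bin between-group family used
    for size-binned islet analyses.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame(
        {
            "y": np.asarray(values, dtype=float),
            "A": pd.Categorical(np.asarray(factor_a)),
            "B": pd.Categorical(np.asarray(factor_b)),
        }
    )
    if df["A"].nunique() < 2 or df["B"].nunique() < 2:
        raise ValueError("each factor needs at least 2 levels")
    cell_n = df.groupby(["A", "B"], observed=True).size()
    if (cell_n < 1).any() or len(cell_n) < df["A"].nunique() * df["B"].nunique():
        raise ValueError(
            "empty factor cell; re-run the sparse-bin exclusion before this analysis"
        )
    model = smf.ols("y ~ C(A) * C(B)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    out: dict[str, ComparisonResult] = {}
    for key, term in (("factor_a", "C(A)"), ("factor_b", "C(B)"), ("interaction", "C(A):C(B)")):
        f = float(table.loc[term, "F"])
        p = float(table.loc[term, "PR(>F)"])
        if np.isnan(f):  # zero residual variance, degenerate constant input
            f, p = 0.0, 1.0
        out[key] = ComparisonResult(
            label=key,
            statistic=f,
            df=(float(table.loc[term, "df"]), float(table.loc["Residual", "df"])),
            p=p,
            p_adjusted=p,
            family_size=1,
        )
    if posthoc_within_b:
        pairs = []
        a_levels = list(df["A"].cat.categories)
        for b_level in df["B"].cat.categories:
            sub = df[df["B"] == b_level]
            for i, a1 in enumerate(a_levels):
                for a2 in a_levels[i + 1 :]:
                    va = sub.loc[sub["A"] == a1, "y"].to_numpy()
                    vb = sub.loc[sub["A"] == a2, "y"].to_numpy()
                    if len(va) >= 2 and len(vb) >= 2:
                        pairs.append((f"{b_level}: {a1} vs {a2}", va, vb))
        m = len(pairs)
        for label, va, vb in pairs:
            out[label] = t_test_unpaired(va, vb, label=label, family_size=m)
    return out


def exclude_sparse_bins(
    islet_table: pd.DataFrame,
    group_col: str,
    bin_col: str = "size_bin",
    min_islets: int = 5,
) -> tuple[pd.DataFrame, list]:
    """Drop size bins with fewer than *min_islets* islets in any group.

    A bin is removed for **all** groups if at least one group has fewer than
    *min_islets* islets in it (bins absent from a group count as 0).
    Returns the filtered table and the list of excluded bins.
    """
    for col in (group_col, bin_col):
        if col not in islet_table.columns:
            raise KeyError(f"column {col!r} missing from islet table")
    counts = (
        islet_table.groupby([bin_col, group_col], observed=False).size().unstack(fill_value=0)
    )
    sparse = counts[(counts < min_islets).any(axis=1)].index.tolist()
    kept = islet_table[~islet_table[bin_col].isin(sparse)].copy()
    return kept, sparse


def delta_delta_ct(
    samples: pd.DataFrame,
    control_condition: str,
    target_col: str = "ct_target",
    reference_cols: tuple[str, ...] = ("ct_ref1", "ct_ref2", "ct_ref3", "ct_ref4"),
    condition_col: str = "condition",
) -> pd.DataFrame:
    """Relative expression by the 2^-ΔΔCt method.

    Each sample's target Ct is normalised against the geometric mean of the
    four reference genes (arithmetic mean of their Cts in log2 space), then
    referenced to the mean ΔCt of *control_condition*.  Adds ``delta_ct``
    and ``fold_change`` columns.
    """
    for col in (condition_col, target_col, *reference_cols):
        if col not in samples.columns:
            raise ValueError(f"qPCR table is missing column {col!r}")
    ref = samples[list(reference_cols)]
    if ref.isna().any().any() or samples[target_col].isna().any():
        raise ValueError("missing Ct value in qPCR table")
    out = samples.copy()
    out["delta_ct"] = out[target_col] - ref.mean(axis=1)
    control = out.loc[out[condition_col] == control_condition, "delta_ct"]
    if control.empty:
        raise ValueError(f"control condition {control_condition!r} not present")
    out["fold_change"] = 2.0 ** -(out["delta_ct"] - control.mean())
    return out
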