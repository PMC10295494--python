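"""Cohort-level statistics: median splits, gated two-sample tests,
descriptive and correlation tables.

The comparison machinery mirrors standard clinical-paper practice: each
continuous variable is dichotomized at its sample median (ties join the
">= median" group), subgroup means are compared with Student's t-test when
both subgroups pass Shapiro–Wilk normality at alpha, and with the
Mann–Whitney U test otherwise. No multiple-testing correction is applied;
reports carry the number of tests performed instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateSplitError, DomainError

#: EAT predictors (rows) and aortic outcome variables (columns) of the
#: default correlation report.
EAT_VARIABLES = ["eat_thickness", "eat_volume", "eat_thickness_index", "eat_volume_index"]
AO_VARIABLES = ["ao_stiffness_index", "ao_strain", "ao_distensibility"]


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    sd: float


@dataclass(frozen=True)
class SubgroupComparison:
    """Result of one median-split two-sample comparison."""

    split_variable: str
    split_median: float
    outcome_variable: str
    group_ge: GroupSummary
    group_lt: GroupSummary
    test_used: str  # "student_t" | "mann_whitney_u"
    p_value: float
    significant: bool
    alpha: float = 0.05


def median_split(values, ids=None) -> tuple[list, list, float]:
    """Split at the sample median; ties at the median join the ">=" group.

    Returns (ge_ids, lt_ids, median). With ``ids=None`` positional indices
    are used. Raises :class:`DegenerateSplitError` if either group is empty.
    """
    values = np.asarray(values, float)
    if values.size < 2:
        raise DegenerateSplitError("need at least 2 values to split")
    if ids is None:
        ids = list(range(values.size))
    ids = list(ids)
    if len(ids) != values.size:
        raise ValueError("ids and values must have equal length")
    med = float(np.median(values))
    ge = [i for i, v in zip(ids, values) if v >= med]
    lt = [i for i, v in zip(ids, values) if v < med]
    if not ge or not lt:
        raise DegenerateSplitError(
            f"median split at {med} leaves an empty subgroup (all values tied)"
        )
    return ge, lt, med


def compare_groups(
    outcome_ge,
    outcome_lt,
    alpha: float = 0.05,
    *,
    split_variable: str = "",
    split_median: float = float("nan"),
    outcome_variable: str = "",
    t_variant: str = "pooled",
    normality_alpha: float = 0.05,
) -> SubgroupComparison:
    """Normality-gated two-sample comparison of an outcome across subgroups.

    Shapiro–Wilk is run on each subgroup; only if both pass
    (p > ``normality_alpha``, fixed at 0.05 independently of the reporting
    ``alpha``) is the two-sided Student t-test used (pooled variance by
    default, Welch with ``t_variant="welch"``), otherwise the two-sided
    Mann–Whitney U (normal approximation with tie correction, as
    implemented by scipy).
    """
    a = np.asarray(outcome_ge, float)
    b = np.asarray(outcome_lt, float)
    for name, g in (("ge", a), ("lt", b)):
        if g.size < 3:
            raise DomainError(f"group '{name}' has n={g.size}; need at least 3")
    if t_variant not in ("pooled", "welch"):
        raise ValueError("t_variant must be 'pooled' or 'welch'")

    def _normal(g):
        if np.ptp(g) == 0:  # Shapiro-Wilk undefined on constant data
            return False
        return stats.shapiro(g).pvalue > normality_alpha

    if _normal(a) and _normal(b):
        test_used = "student_t"
        res = stats.ttest_ind(a, b, equal_var=(t_variant == "pooled"))
        p = float(res.pvalue)
    else:
        test_used = "mann_whitney_u"
        if np.ptp(np.concatenate([a, b])) == 0:
            p = 1.0  # all observations tied: no evidence of a shift
        else:
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue)
    return SubgroupComparison(
        split_variable=split_variable,
        split_median=split_median,
        outcome_variable=outcome_variable,
        group_ge=GroupSummary(int(a.size), float(a.mean()), float(a.std(ddof=1))),
        group_lt=GroupSummary(int(b.size), float(b.mean()), float(b.std(ddof=1))),
        test_used=test_used,
        p_value=p,
        significant=bool(p < alpha),
        alpha=alpha,
    )


def subgroup_table(
    derived: pd.DataFrame,
    split_variables,
    outcome_variables,
    alpha: float = 0.05,
    t_variant: str = "pooled",
) -> list[SubgroupComparison]:
    """Median-split each split variable and compare every outcome across it."""
    out = []
    for sv in split_variables:
        ge_idx, lt_idx, med = median_split(derived[sv].to_numpy(), list(derived.index))
        for ov in outcome_variables:
            out.append(
                compare_groups(
                    derived.loc[ge_idx, ov],
                    derived.loc[lt_idx, ov],
                    alpha,
                    split_variable=sv,
                    split_median=med,
                    outcome_variable=ov,
                    t_variant=t_variant,
                )
            )
    return out


def comparisons_to_frame(comparisons: list[SubgroupComparison]) -> pd.DataFrame:
    rows = [
        {
            "split_variable": c.split_variable,
            "split_median": c.split_median,
            "outcome_variable": c.outcome_variable,
            "n_ge": c.group_ge.n,
            "mean_ge": c.group_ge.mean,
            "sd_ge": c.group_ge.sd,
            "n_lt": c.group_lt.n,
            "mean_lt": c.group_lt.mean,
            "sd_lt": c.group_lt.sd,
            "test_used": c.test_used,
            "p_value": c.p_value,
            "significant": c.significant,
        }
        for c in comparisons
    ]
    return pd.DataFrame(rows)


def correlation_table(
    derived: pd.DataFrame,
    rows=EAT_VARIABLES,
    columns=AO_VARIABLES,
    method: str = "pearson",
) -> pd.DataFrame:
    """Correlations of each EAT variable against each aortic variable.

    Pearson product–moment by default (the associations of interest are
    linear); ``method="spearman"`` for the rank flavour. A zero-variance
    column makes the coefficient undefined and raises.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    for name in list(rows) + list(columns):
        col = derived[name].to_numpy(float)
        if np.ptp(col) == 0:
            raise DomainError(f"correlation undefined: column {name!r} has zero variance")
    table = pd.DataFrame(index=list(rows), columns=list(columns), dtype=float)
    for r in rows:
        for c in columns:
            if method == "pearson":
                table.loc[r, c] = float(stats.pearsonr(derived[r], derived[c]).statistic)
            else:
                table.loc[r, c] = float(stats.spearmanr(derived[r], derived[c]).statistic)
    return table


def descriptive_table(derived: pd.DataFrame) -> dict:
    """Mean/SD for numeric columns, counts/percentages for categoricals.

    SD is reported as NaN for a single record (rendered as an em dash
    downstream).
    """
    if len(derived) == 0:
        raise ValueError("cannot describe an empty cohort")
    numeric = derived.select_dtypes("number")
    cont = pd.DataFrame(
        {
            "mean": numeric.mean(),
            "sd": numeric.std(ddof=1) if len(derived) > 1 else np.nan,
        }
    )
    cats = {}
    for col in derived.columns:
        if col in numeric.columns or col == "id":
            continue
        counts = derived[col].value_counts()
        cats[col] = pd.DataFrame(
            {"n": counts, "percent": 100.0 * counts / len(derived)}
        )
    return {"continuous": cont, "categorical": cats}


__all__ = [
    "EAT_VARIABLES",
    "AO_VARIABLES",
    "GroupSummary",
    "SubgroupComparison",
    "median_split",
    "compare_groups",
    "subgroup_table",
    "comparisons_to_frame",
    "correlation_table",
    "descriptive_table",
]
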