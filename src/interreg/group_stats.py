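"""Between-group statistics: Welch t-tests, edgewise matrix comparison,
one-way ANOVA with post-hoc pairwise tests, and Benjamini–Hochberg FDR.

Connectivity values are compared between subject groups (e.g. healthy
controls vs a patient group) with the unequal-variance two-sample t-test,
using the Welch–Satterthwaite approximation for the degrees of freedom, and
two-sided p-values throughout.  Multiple testing is handled by the
Benjamini–Hochberg step-up procedure, applied *within families*: the family
for an edgewise matrix comparison is the set of all upper-triangle edges;
for the derived measures each measure type (R1, R12, R2, RI) forms one
family across its comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import GroupComparison, RunConfig

__all__ = [
    "welch_t",
    "bh_fdr",
    "compare_edge_matrices",
    "anova_posthoc",
    "apply_bh_by_family",
    "measure_group_tests",
    "EdgeComparisonResult",
]


def welch_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Unequal-variance two-sample t-test.

    Returns ``(t, df, p)`` where ``t = (mean(x) - mean(y)) /
    sqrt(s_x^2/n_x + s_y^2/n_y)``, ``df`` is the Welch–Satterthwaite
    effective degrees of freedom, and ``p`` is the two-sided tail
    probability of Student's t.

    Degenerate inputs: if both samples are constant with equal means the
    test is undefined and a ``ValueError`` is raised; if both are constant
    with unequal means, ``(inf, df, 0)`` is returned with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("each sample needs at least 2 observations")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if x.mean() == y.mean():
            raise ValueError("both samples constant and equal: t undefined")
        warnings.warn("both samples constant but unequal; reporting p = 0")
        return (np.inf if x.mean() > y.mean() else -np.inf, float(nx + ny - 2), 0.0)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def bh_fdr(p_values: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up procedure.

    Sorts the m p-values ascending, finds the largest k with
    ``p_(k) <= k * alpha / m`` and rejects the k smallest.  Also returns the
    BH-adjusted p-values ``min_{j >= rank} (m/j) p_(j)`` capped at 1;
    rejecting where adjusted p <= alpha reproduces the step-up rejection
    set.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    crit = ranked <= (np.arange(1, m + 1) * alpha / m)
    reject = np.zeros(m, dtype=bool)
    if crit.any():
        k = int(np.max(np.nonzero(crit)[0])) + 1
        reject[order[:k]] = True
    adj_sorted = np.minimum.accumulate((ranked * m / np.arange(1, m + 1))[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(adj_sorted, 1.0)
    return reject, adjusted


@dataclass
class EdgeComparisonResult:
    """Edgewise two-group comparison of stacked correlation matrices."""

    labels: list[str]
    t_matrix: np.ndarray
    p_matrix: np.ndarray
    mask_uncorrected: np.ndarray  # p < p_display, off-diagonal
    mask_fdr: np.ndarray  # BH-significant at fdr_alpha over upper-triangle family


def compare_edge_matrices(
    stack_a: np.ndarray,
    stack_b: np.ndarray,
    labels: list[str],
    config: RunConfig | None = None,
) -> EdgeComparisonResult:
    """Welch-test every off-diagonal edge of group A's matrices against
    group B's.

    ``stack_a`` and ``stack_b`` are ``(subjects, K, K)`` arrays over the
    same node labels.  Two significance masks are returned: uncorrected
    ``p < p_display`` (default 0.001) and BH-FDR at ``fdr_alpha`` (default
    0.05) over the family of all upper-triangle edges; both masks are
    symmetrised.
    """
    config = config or RunConfig()
    A = np.asarray(stack_a, dtype=float)
    B = np.asarray(stack_b, dtype=float)
    K = len(labels)
    if A.ndim != 3 or B.ndim != 3 or A.shape[1:] != (K, K) or B.shape[1:] != (K, K):
        raise ValueError("stacks must be (subjects, K, K) over the given labels")
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    iu, ju = np.triu_indices(K, k=1)
    t_mat = np.zeros((K, K))
    p_mat = np.ones((K, K))
    pvals = np.empty(len(iu))
    for e, (i, j) in enumerate(zip(iu, ju)):
        t, _, p = welch_t(A[:, i, j], B[:, i, j])
        t_mat[i, j] = t_mat[j, i] = t
        p_mat[i, j] = p_mat[j, i] = p
        pvals[e] = p
    reject, _ = bh_fdr(pvals, alpha=config.fdr_alpha)
    mask_unc = np.zeros((K, K), dtype=bool)
    mask_fdr = np.zeros((K, K), dtype=bool)
    mask_unc[iu, ju] = pvals < config.p_display
    mask_fdr[iu, ju] = reject
    mask_unc |= mask_unc.T
    mask_fdr |= mask_fdr.T
    return EdgeComparisonResult(list(labels), t_mat, p_mat, mask_unc, mask_fdr)


def apply_bh_by_family(
    comparisons: list[GroupComparison], alpha: float = 0.05
) -> list[GroupComparison]:
    """Fill ``p_adjusted`` and ``significant`` in place, correcting within
    each declared family independently."""
    by_family: dict[str, list[GroupComparison]] = {}
    for c in comparisons:
        by_family.setdefault(c.family, []).append(c)
    for members in by_family.values():
        reject, adjusted = bh_fdr(np.array([c.p_value for c in members]), alpha=alpha)
        for c, r, a in zip(members, reject, adjusted):
            c.p_adjusted = float(a)
            c.significant = bool(r)
    return comparisons


def anova_posthoc(
    groups: dict[str, np.ndarray],
    measure: str = "measure",
    family: str | None = None,
    alpha: float = 0.05,
) -> tuple[tuple[float, float] | None, list[GroupComparison]]:
    """One-way ANOVA across >= 3 groups plus pairwise Welch post-hoc tests.

    Returns ``(omnibus, comparisons)`` where ``omnibus`` is ``(F, p)`` or
    ``None`` when only two groups are supplied (the omnibus test is then
    skipped and the comparison reduces to a single Welch test).  Post-hoc
    p-values are BH-corrected within the declared ``family`` (by default
    the measure's own pairwise set).
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    for g in names:
        if len(groups[g]) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    omnibus = None
    if len(names) >= 3:
        F, p = stats.f_oneway(*[np.asarray(groups[g], float) for g in names])
        omnibus = (float(F), float(p))
    comparisons = []
    fam = family or f"{measure}:posthoc"
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            t, df, p = welch_t(groups[names[i]], groups[names[j]])
            comparisons.append(
                GroupComparison(
                    measure=measure,
                    group_a=names[i],
                    group_b=names[j],
                    statistic=t,
                    df=df,
                    p_value=p,
                    family=fam,
                )
            )
    apply_bh_by_family(comparisons, alpha=alpha)
    return omnibus, comparisons


def measure_group_tests(
    values: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Two-group Welch tests of network-level measures, BH-corrected within
    one family per measure type.

    ``values`` needs columns ``subject, group, network, measure, value``
    with exactly two group labels; one test is run per (network, measure)
    cell and each measure's tests across networks form one BH family.
    """
    required = {"subject", "group", "network", "measure", "value"}
    if not required.issubset(values.columns):
        raise ValueError(f"values frame needs columns {sorted(required)}")
    grp_labels = sorted(values["group"].unique())
    if len(grp_labels) != 2:
        raise ValueError("measure_group_tests expects exactly 2 groups")
    ga, gb = grp_labels
    comparisons = []
    rows = []
    for (network, measure), sub in values.groupby(["network", "measure"], sort=True):
        x = sub.loc[sub["group"] == ga, "value"].to_numpy()
        y = sub.loc[sub["group"] == gb, "value"].to_numpy()
        t, df, p = welch_t(x, y)
        c = GroupComparison(
            measure=measure, group_a=ga, group_b=gb,
            statistic=t, df=df, p_value=p, family=measure,
        )
        comparisons.append(c)
        rows.append({"network": network, "measure": measure, "comparison": c,
                     "mean_a": float(x.mean()), "mean_b": float(y.mean())})
    apply_bh_by_family(comparisons, alpha=alpha)
    return pd.DataFrame(
        [
            {
                "network": r["network"],
                "measure": r["measure"],
                "group_a": ga,
                "group_b": gb,
                "mean_a": r["mean_a"],
                "mean_b": r["mean_b"],
                "t": r["comparison"].statistic,
                "df": r["comparison"].df,
                "p": r["comparison"].p_value,
                "p_bh": r["comparison"].p_adjusted,
                "significant": r["comparison"].significant,
            }
            for r in rows
        ]
    )
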