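"""Small shared statistics: BH adjustment, ANOVA-gated pairwise t-tests, Welch t.

These back the summary figures (thymic cellularity comparisons across mouse
strains and genotypes) and are reused by the enrichment and composition
modules for multiple-testing control.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["bh_adjust", "anova_then_pairwise", "welch_t"]


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Parameters
    ----------
    p
        Sequence of raw p-values in [0, 1].

    Returns
    -------
    ndarray of the same length, monotone in the input and capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must be finite and within [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    # enforce monotonicity from the largest p downwards (step-up)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def welch_t(a, b) -> tuple[float, float, float]:
    """Two-sided Welch t-test with Satterthwaite degrees of freedom.

    Returns ``(t, p, df)``.  Two identical, zero-variance groups give p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0, float(a.size + b.size - 2)
        raise ZeroDivisionError("zero variance in both groups with unequal means")
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(p), float(df)


def anova_then_pairwise(data: pd.DataFrame, alpha: float = 0.05,
                        value: str = "value", group: str = "group"):
    """One-way ANOVA; if significant, all pairwise two-sided t-tests with
    Bonferroni correction.

    This is the comparison scheme used for per-animal measurements such as
    thymocyte and TEC counts: the pairwise stage is only performed after a
    significant (p < ``alpha``) ANOVA.

    Parameters
    ----------
    data
        Long-format table with one row per animal/organ.
    alpha
        Gate for the pairwise stage.
    value, group
        Column names.

    Returns
    -------
    dict with keys ``anova_F``, ``anova_p``, ``performed`` and ``pairwise``
    (a DataFrame of raw and Bonferroni-multiplied p-values, or None when the
    ANOVA is not significant).
    """
    groups = {k: np.asarray(v[value], dtype=float) for k, v in data.groupby(group)}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for name, vals in groups.items():
        if vals.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
    F, p = sps.f_oneway(*groups.values())
    result = {"anova_F": float(F), "anova_p": float(p), "performed": bool(p < alpha),
              "pairwise": None}
    if p >= alpha:
        return result
    rows = []
    pairs = list(combinations(sorted(groups), 2))
    for ga, gb in pairs:
        a, b = groups[ga], groups[gb]
        if (a.var(ddof=1) == 0 and a.size == 2) or (b.var(ddof=1) == 0 and b.size == 2):
            warnings.warn(f"zero-variance group in pair ({ga}, {gb}); using Welch fallback")
            t, praw, _ = welch_t(a, b)
        else:
            t, praw = sps.ttest_ind(a, b)
        rows.append({"group_a": ga, "group_b": gb, "t": float(t), "p_raw": float(praw)})
    table = pd.DataFrame(rows)
    table["p_bonferroni"] = np.minimum(table["p_raw"] * len(pairs), 1.0)
    result["pairwise"] = table
    return result
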