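"""Exclusive mimetic-cell label calling from score tables.

Cells may exceed the (manually chosen) AUC threshold of several signatures;
such cells are disambiguated by comparing, per eligible signature, how far
to the right the cell sits in that signature's AUC distribution.  That
"position on the histogram" is formalized as the cell's quantile rank: the
fraction of all cells with a strictly smaller AUC, which makes positions
comparable across signatures.  Remaining ties are broken by the larger
z-standardized AUC, and exact ties by signature name (logged).  Overlapping
sister signatures (Tuft1/Tuft2, Skin_basal/Skin_keratinized) are collapsed
into unified populations after calling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from mimetect.lineage import wilson_interval
from mimetect.scoring import ScoreTable, standardize_scores

logger = logging.getLogger(__name__)

__all__ = ["ThresholdConfig", "CallResult", "apply_thresholds", "disambiguate_calls",
           "merge_signatures", "expression_proportion"]

UNASSIGNED = "unassigned"


@dataclass
class ThresholdConfig:
    """Per-signature AUC thresholds plus optional merge groups.

    ``merge`` maps a group label to the member signature names collapsed
    into it, e.g. ``{"Tuft": ["Tuft1", "Tuft2"]}``.  Groups must be disjoint.
    """

    thresholds: dict
    merge: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, thr in self.thresholds.items():
            if not (0.0 <= float(thr) <= 1.0):
                raise ValueError(f"threshold for {name!r} outside [0, 1]: {thr}")
        seen: set = set()
        for grp, members in self.merge.items():
            members = set(members)
            if members & seen:
                raise ValueError(f"merge group {grp!r} overlaps another group")
            seen |= members


@dataclass
class CallResult:
    """One exclusive label per cell plus its supporting evidence.

    ``calls`` has one row per cell with columns ``label``, ``n_eligible``,
    ``quantile`` and ``z`` (of the winning signature; NaN when unassigned).
    ``eligibility`` is the boolean cells x signatures matrix.
    """

    calls: pd.DataFrame
    eligibility: pd.DataFrame

    @property
    def labels(self) -> pd.Series:
        return self.calls["label"]

    def counts(self) -> pd.Series:
        return self.calls["label"].value_counts()


def apply_thresholds(scores: ScoreTable, cfg: ThresholdConfig) -> pd.DataFrame:
    """Boolean eligibility: AUC >= threshold (closed boundary).

    Every scored signature must have a threshold (error listing the missing
    names); thresholds for unknown signatures only warn.
    """
    auc = scores.auc
    missing = [c for c in auc.columns if c not in cfg.thresholds]
    if missing:
        raise ValueError(f"no threshold configured for signature(s): {missing}")
    unknown = [n for n in cfg.thresholds if n not in auc.columns]
    if unknown:
        logger.warning("thresholds for unscored signature(s) ignored: %s", unknown)
    thr = pd.Series({c: float(cfg.thresholds[c]) for c in auc.columns})
    return auc.ge(thr, axis=1)


def disambiguate_calls(scores: ScoreTable, eligibility: pd.DataFrame) -> CallResult:
    """Resolve multi-eligible cells to a single label.

    For each cell the eligible signatures are ordered first by the cell's
    quantile rank within that signature's AUCs across all cells, then by the
    z-standardized AUC, then lexically by name (with a warning).
    """
    auc = scores.auc
    if eligibility.shape != auc.shape or list(eligibility.columns) != list(auc.columns):
        raise ValueError("eligibility matrix does not conform with the score table")
    if scores.z is None:
        scores = standardize_scores(scores)
    z = scores.z
    n = auc.shape[0]
    # fraction of cells with strictly smaller AUC, per signature column
    quant = pd.DataFrame(
        {c: (rankdata(auc[c].values, method="min") - 1) / n for c in auc.columns},
        index=auc.index,
    )
    elig = eligibility.values
    qv, zv = quant.values, z.values
    labels, win_q, win_z, n_elig = [], [], [], []
    cols = np.asarray(auc.columns)
    for i in range(n):
        j = np.flatnonzero(elig[i])
        n_elig.append(len(j))
        if len(j) == 0:
            labels.append(UNASSIGNED)
            win_q.append(np.nan)
            win_z.append(np.nan)
            continue
        q_i, z_i = qv[i, j], zv[i, j]
        best_q = q_i.max()
        tied = j[q_i == best_q]
        if len(tied) > 1:
            z_t = zv[i, tied]
            tied = tied[z_t == z_t.max()]
            if len(tied) > 1:
                logger.warning("cell %s: exact quantile and z tie among %s; "
                               "lexical tie-break", auc.index[i], list(cols[tied]))
                tied = tied[np.argsort(cols[tied])][:1]
        k = tied[0]
        labels.append(cols[k])
        win_q.append(qv[i, k])
        win_z.append(zv[i, k])
    calls = pd.DataFrame({"label": labels, "n_eligible": n_elig,
                          "quantile": win_q, "z": win_z}, index=auc.index)
    return CallResult(calls=calls, eligibility=eligibility)


def merge_signatures(calls: CallResult, cfg: ThresholdConfig) -> CallResult:
    """Collapse labels inside each merge group into the group label.

    Cell counts are conserved; an empty merge map is the identity.
    """
    rename = {}
    for grp, members in cfg.merge.items():
        for m in members:
            if m in rename:
                raise ValueError(f"signature {m!r} appears in two merge groups")
            rename[m] = grp
    merged = calls.calls.copy()
    merged["label"] = merged["label"].map(lambda s: rename.get(s, s))
    return CallResult(calls=merged, eligibility=calls.eligibility)


def auc_histograms(scores: ScoreTable, thresholds: dict | None = None,
                   bins: int = 50):
    """Per-signature AUC histograms to support manual threshold choice.

    Returns a matplotlib figure; configured thresholds are drawn as
    vertical lines.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    cols = list(scores.auc.columns)
    ncol = min(4, len(cols))
    nrow = (len(cols) + ncol - 1) // ncol
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2 * nrow),
                             squeeze=False)
    for ax, name in zip(axes.ravel(), cols):
        ax.hist(scores.auc[name].values, bins=bins)
        ax.set_title(name, fontsize=8)
        if thresholds and name in thresholds:
            ax.axvline(thresholds[name], color="red", lw=1)
    for ax in axes.ravel()[len(cols):]:
        ax.axis("off")
    fig.tight_layout()
    return fig


def expression_proportion(counts, cells, gene: str, level: float = 0.95):
    """Fraction of a cell subset with detectable (count > 0) expression of a
    gene, with a Wilson confidence interval.

    Used e.g. for the proportion of Foxn1-expressing cells per population.
    """
    if isinstance(counts, pd.DataFrame):
        mat = counts
    elif hasattr(counts, "X"):  # AnnData
        X = counts.X
        if hasattr(X, "toarray"):
            X = X.toarray()
        mat = pd.DataFrame(X, index=counts.obs_names, columns=counts.var_names)
    else:
        raise TypeError("counts must be a DataFrame or AnnData with named genes")
    cells = list(cells)
    if not cells:
        raise ValueError("cell subset is empty")
    if gene not in mat.columns:
        raise KeyError(f"gene {gene!r} not in matrix")
    sub = mat.loc[cells, gene]
    x = int((sub > 0).sum())
    n = len(sub)
    return x / n, wilson_interval(x, n, level=level)
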