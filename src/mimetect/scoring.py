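"""Per-cell rank-AUC signature scoring.

Each cell's genes are ranked by decreasing expression (ties broken by a
seeded jitter so reruns are identical).  A signature's score in a cell is
the area under the recovery curve of signature genes within the top-ranked
fraction of genes, normalized by the maximal achievable area, so scores are
comparable across signature sizes and invariant to any strictly monotone
transform of the expression values.

With per-cell ranks r_g over G genes, K = ceil(top_fraction * G), and
n_s measured signature genes, the recovery curve is
R(k) = |{g in sig : r_g <= k}| and

    AUC = sum_{k=1..K} R(k)  /  sum_{k=1..K} min(k, n_s).

The numerator telescopes to sum over signature genes of max(0, K - r_g + 1),
which is what the implementation computes; tests check it against a direct
enumeration of R(k).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mimetect.signatures import GeneSignature

__all__ = ["RankedExpression", "ScoreTable", "rank_genes_per_cell", "score_auc",
           "score_signatures", "standardize_scores"]


def _as_dense(counts):
    """Accept ndarray, DataFrame or AnnData; return (matrix, genes, cells)."""
    genes = cells = None
    X = counts
    if hasattr(counts, "X"):  # AnnData
        genes = np.asarray(counts.var_names)
        cells = np.asarray(counts.obs_names)
        X = counts.X
    elif isinstance(counts, pd.DataFrame):
        genes = np.asarray(counts.columns)
        cells = np.asarray(counts.index)
        X = counts.values
    if hasattr(X, "toarray"):
        X = X.toarray()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("counts must be a 2-D cells x genes matrix")
    if genes is None:
        genes = np.array([f"g{i}" for i in range(X.shape[1])])
    if cells is None:
        cells = np.array([f"c{i}" for i in range(X.shape[0])])
    return X, genes, cells


@dataclass
class RankedExpression:
    """Per-cell descending-expression ranks (1 = highest) over all G genes."""

    ranks: np.ndarray          # cells x genes, each row a permutation of 1..G
    genes: np.ndarray
    cells: np.ndarray
    tie_seed: int

    @property
    def n_genes(self) -> int:
        return self.ranks.shape[1]

    @property
    def n_cells(self) -> int:
        return self.ranks.shape[0]


@dataclass
class ScoreTable:
    """Cells x signatures AUC scores with a z-standardized companion."""

    auc: pd.DataFrame
    top_fraction: float
    n_genes: int
    n_sig_genes: dict = field(default_factory=dict)
    z: pd.DataFrame | None = None


def rank_genes_per_cell(counts, tie_seed: int = 0) -> RankedExpression:
    """Rank genes within each cell by decreasing expression.

    Ties are broken by seeded uniform jitter, i.e. tied genes receive a
    random permutation of the tied rank range; the same ``tie_seed``
    reproduces the same permutation.  Cells whose counts are all zero are
    ranked entirely by jitter and trigger a warning.
    """
    X, genes, cells = _as_dense(counts)
    if np.any(X < 0):
        raise ValueError("counts must be non-negative")
    n_cells, n_genes = X.shape
    all_zero = ~X.any(axis=1)
    if all_zero.any():
        warnings.warn(f"{int(all_zero.sum())} cell(s) have all-zero counts; "
                      "their ranks are pure jitter")
    rng = np.random.default_rng(tie_seed)
    jitter = rng.random(size=X.shape)
    # lexsort: primary key -X (descending expression), secondary jitter
    ranks = np.empty(X.shape, dtype=np.int64)
    arange = np.arange(1, n_genes + 1)
    for i in range(n_cells):
        order = np.lexsort((jitter[i], -X[i]))
        ranks[i, order] = arange
    return RankedExpression(ranks=ranks, genes=genes, cells=cells, tie_seed=int(tie_seed))


def score_auc(ranks: RankedExpression, sig: GeneSignature,
              top_fraction: float = 0.05) -> np.ndarray:
    """Rank-AUC score of one signature in every cell.

    Equals 1 when all measured signature genes occupy the top n_s ranks
    (and K >= n_s), and 0 when none is within the top K.
    """
    if not (0 < top_fraction <= 1):
        raise ValueError("top_fraction must be in (0, 1]")
    G = ranks.n_genes
    K = math.ceil(top_fraction * G)
    if K < 1:
        raise ValueError("top fraction yields an empty top set")
    gene_index = {g: i for i, g in enumerate(ranks.genes)}
    idx = [gene_index[g] for g in sig.genes if g in gene_index]
    if not idx:
        raise ValueError(f"no gene of signature {sig.name!r} is measured")
    n_s = len(idx)
    r = ranks.ranks[:, idx]                       # cells x n_s
    numer = np.maximum(0, K - r + 1).sum(axis=1)  # telescoped sum of R(k)
    if K >= n_s:
        denom = n_s * (n_s + 1) // 2 + (K - n_s) * n_s
    else:
        denom = K * (K + 1) // 2
    return numer / denom


def score_signatures(ranks: RankedExpression, sigs: list[GeneSignature],
                     top_fraction: float = 0.05, standardize: bool = True) -> ScoreTable:
    """Score a collection of signatures; optionally add z-standardization."""
    cols = {}
    n_sig = {}
    for sig in sigs:
        cols[sig.name] = score_auc(ranks, sig, top_fraction=top_fraction)
        n_sig[sig.name] = sum(1 for g in sig.genes if g in set(ranks.genes))
    auc = pd.DataFrame(cols, index=ranks.cells)
    table = ScoreTable(auc=auc, top_fraction=top_fraction, n_genes=ranks.n_genes,
                       n_sig_genes=n_sig)
    return standardize_scores(table) if standardize else table


def standardize_scores(scores: ScoreTable) -> ScoreTable:
    """Z-standardize each signature's AUC column across cells (population sd).

    Constant columns get z = 0 with a warning.  Idempotent: standardizing the
    result again reproduces it.
    """
    auc = scores.auc
    if auc.shape[0] < 2:
        raise ValueError("z-standardization needs at least 2 cells")
    mean = auc.mean(axis=0)
    sd = auc.std(axis=0, ddof=0)
    zero = sd == 0
    if zero.any():
        warnings.warn(f"constant AUC column(s) {list(auc.columns[zero])}; z set to 0")
    safe_sd = sd.where(~zero, 1.0)
    z = (auc - mean) / safe_sd
    z.loc[:, zero] = 0.0
    return ScoreTable(auc=auc, top_fraction=scores.top_fraction, n_genes=scores.n_genes,
                      n_sig_genes=dict(scores.n_sig_genes), z=z)
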