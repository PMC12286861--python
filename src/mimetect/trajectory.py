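"""Trajectory inference: diffusion pseudotime, a combined pseudotime /
connectivity transition kernel, terminal-state selection by signature
score, absorption-based fate probabilities and fate overlap.

The developmental question is which terminal populations (Aire-stage and
the mimetic cell types) a transient epithelial cell is headed for.  A
random walk over the k-nearest-neighbour graph is biased along diffusion
pseudotime (soft logistic directionality), mixed with the undirected
connectivity walk, and the terminal cells -- per population, those with the
highest signature AUC -- are made absorbing.  The fate probability of a
transient cell for a terminal population is its absorption probability in
that population's cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components, shortest_path

from mimetect.scoring import ScoreTable

logger = logging.getLogger(__name__)

__all__ = ["Pseudotime", "TransitionKernel", "FateMatrix", "diffusion_pseudotime",
           "build_combined_kernel", "select_terminal_cells",
           "absorption_probabilities", "fate_overlap_jaccard"]


def _as_dense_conn(graph) -> np.ndarray:
    C = graph
    if hasattr(C, "toarray"):
        C = C.toarray()
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("connectivity must be a square matrix")
    if not np.allclose(C, C.T, atol=1e-9):
        raise ValueError("connectivity must be symmetric")
    if np.any(C < 0):
        raise ValueError("connectivity weights must be non-negative")
    C = C.copy()
    np.fill_diagonal(C, 0.0)
    return C


@dataclass
class Pseudotime:
    t: np.ndarray
    root: int


@dataclass
class TransitionKernel:
    """Row-stochastic transition matrix with its mixture parameters."""

    P: np.ndarray
    lambda_: float
    kappa: float


@dataclass
class FateMatrix:
    """Transient-cells x terminal-populations absorption probabilities."""

    probabilities: pd.DataFrame
    terminals: dict


def diffusion_pseudotime(graph, root: int, n_comps: int | None = None) -> Pseudotime:
    """Diffusion pseudotime from a root cell.

    Eigendecomposes the symmetrized random-walk operator of the
    connectivity matrix; with nontrivial eigenpairs (lambda_l, psi_l) of the
    walk, the pseudotime of cell i is the diffusion distance to the root,

        t_i = sqrt( sum_{l>=2} (lambda_l / (1 - lambda_l))^2
                               (psi_l(i) - psi_l(root))^2 ),

    which is 0 at the root and finite for every cell reachable from it.
    """
    C = _as_dense_conn(graph)
    n = C.shape[0]
    if not (0 <= root < n):
        raise IndexError("root out of range")
    n_comp, labels = connected_components(C > 0, directed=False)
    if n_comp > 1:
        unreachable = np.flatnonzero(labels != labels[root])
        raise ValueError(f"graph disconnected from root; unreachable cells: "
                         f"{unreachable.tolist()[:20]}")
    deg = C.sum(axis=1)
    dinv = 1.0 / np.sqrt(deg)
    M = C * np.outer(dinv, dinv)          # symmetric conjugate of D^-1 C
    evals, evecs = np.linalg.eigh(M)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    psi = evecs * dinv[:, None]           # right eigenvectors of the walk
    if n_comps is None:
        n_comps = min(n - 1, 15)
    lam = np.clip(evals[1: 1 + n_comps], None, 1.0 - 1e-12)
    comp = psi[:, 1: 1 + n_comps]
    scale = lam / (1.0 - lam)
    diff = (comp - comp[root]) * scale
    t = np.sqrt((diff**2).sum(axis=1))
    t[root] = 0.0
    return Pseudotime(t=t, root=int(root))


def build_combined_kernel(graph, t: Pseudotime | np.ndarray, lambda_: float = 0.8,
                          kappa: float | None = None) -> TransitionKernel:
    """Mix a pseudotime-directed kernel with the undirected connectivity kernel.

    The pseudotime kernel weights each neighbour edge by a logistic gate on
    the pseudotime increment, P_pt(i,j) proportional to
    c_ij * logistic(kappa (t_j - t_i)), plus a self term at the gate's
    neutral value (the "weight of staying"); rows are normalized.  The
    connectivity kernel is the row-normalized connectivity.  The combined
    kernel is P = lambda * P_pt + (1 - lambda) * P_conn.

    ``kappa`` defaults to 1 / median(|t_j - t_i|) over edges, which adapts
    the directionality softness to the pseudotime scale.
    """
    C = _as_dense_conn(graph)
    tv = t.t if isinstance(t, Pseudotime) else np.asarray(t, dtype=float)
    if not np.all(np.isfinite(tv)):
        raise ValueError("pseudotime must be finite")
    if not (0.0 <= lambda_ <= 1.0):
        raise ValueError("lambda_ must be in [0, 1]")
    deg = C.sum(axis=1)
    if np.any(deg == 0):
        raise ValueError(f"isolated cell(s) without neighbours: "
                         f"{np.flatnonzero(deg == 0).tolist()}")
    if kappa is None:
        ii, jj = np.nonzero(np.triu(C, 1))
        dt = np.abs(tv[jj] - tv[ii])
        med = np.median(dt)
        kappa = 1.0 / med if med > 0 else 1.0
    dt = tv[None, :] - tv[:, None]
    gate = 1.0 / (1.0 + np.exp(-np.clip(kappa * dt, -500, 500)))
    W = C * gate
    # self term: staying put carries the neutral gate value on the mean edge
    nnz = (C > 0).sum(axis=1)
    np.fill_diagonal(W, 0.5 * deg / nnz)
    P_pt = W / W.sum(axis=1, keepdims=True)
    P_conn = C / deg[:, None]
    P = lambda_ * P_pt + (1.0 - lambda_) * P_conn
    return TransitionKernel(P=P, lambda_=float(lambda_), kappa=float(kappa))


def select_terminal_cells(scores: ScoreTable, populations: list[str],
                          n_per: int = 30) -> dict:
    """Pick, per terminal population, the ``n_per`` cells with the highest
    AUC for that population's signature.

    Populations sharing a picked cell, or with fewer than ``n_per`` scored
    cells, raise an error naming them.
    """
    auc = scores.auc
    picked: dict[str, list] = {}
    for pop in populations:
        if pop not in auc.columns:
            raise KeyError(f"population {pop!r} has no scored signature")
        col = auc[pop]
        if len(col) < n_per:
            raise ValueError(f"population {pop!r}: only {len(col)} cells scored, "
                             f"need {n_per}")
        picked[pop] = list(col.sort_values(ascending=False, kind="mergesort").index[:n_per])
    seen: dict = {}
    for pop, cells in picked.items():
        for c in cells:
            if c in seen:
                raise ValueError(f"terminal cell {c!r} picked by both "
                                 f"{seen[c]!r} and {pop!r}")
            seen[c] = pop
    return picked


def absorption_probabilities(kernel: TransitionKernel | np.ndarray,
                             terminals: dict, cell_names=None) -> FateMatrix:
    """Fate probabilities by absorbing-chain analysis.

    Terminal cells are made absorbing.  With the transient block Q and the
    transient-to-absorbing block R of the transition matrix, the absorption
    probabilities solve (I - Q) F = R; columns are aggregated by terminal
    population.  Rows sum to 1 when absorption is certain.
    """
    P = kernel.P if isinstance(kernel, TransitionKernel) else np.asarray(kernel, float)
    n = P.shape[0]
    if cell_names is None:
        cell_names = np.arange(n)
    name_pos = {c: i for i, c in enumerate(cell_names)}
    term_idx: dict[str, np.ndarray] = {}
    all_term: list = []
    for pop, cells in terminals.items():
        idx = np.array([name_pos[c] for c in cells], dtype=int)
        term_idx[pop] = idx
        all_term.extend(idx.tolist())
    all_term = np.array(sorted(set(all_term)), dtype=int)
    trans = np.array([i for i in range(n) if i not in set(all_term.tolist())], dtype=int)
    if trans.size == 0:
        raise ValueError("no transient cells left")
    # reachability: every transient cell must reach some terminal cell
    reach = shortest_path(P[np.ix_(np.arange(n), np.arange(n))] > 0, method="D",
                          directed=True, unweighted=True, indices=trans)
    ok = np.isfinite(reach[:, all_term]).any(axis=1)
    if not ok.all():
        bad = [cell_names[i] for i in trans[~ok]]
        raise ValueError(f"transient cell(s) with no path to any terminal: {bad[:20]}")
    Q = P[np.ix_(trans, trans)]
    R = P[np.ix_(trans, all_term)]
    F = np.linalg.solve(np.eye(trans.size) - Q, R)
    col_of = {i: k for k, i in enumerate(all_term)}
    agg = {}
    for pop, idx in term_idx.items():
        agg[pop] = F[:, [col_of[i] for i in idx]].sum(axis=1)
    probs = pd.DataFrame(agg, index=[cell_names[i] for i in trans])
    return FateMatrix(probabilities=probs, terminals={k: list(v) for k, v in terminals.items()})


def fate_overlap_jaccard(F: FateMatrix | pd.DataFrame, threshold: float = 0.5) -> pd.DataFrame:
    """Jaccard overlap of high-fate cell sets between terminal populations.

    A cell belongs to population a's set when its fate probability for a
    exceeds ``threshold``; J(a, b) = |A & B| / |A | B| and is reported as 0
    (logged) when both sets are empty.
    """
    probs = F.probabilities if isinstance(F, FateMatrix) else F
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    pops = list(probs.columns)
    sets = {p: set(probs.index[probs[p] > threshold]) for p in pops}
    out = pd.DataFrame(0.0, index=pops, columns=pops)
    for a in pops:
        for b in pops:
            union = sets[a] | sets[b]
            if not union:
                logger.info("empty union for pair (%s, %s); Jaccard set to 0", a, b)
                out.loc[a, b] = 0.0
            else:
                out.loc[a, b] = len(sets[a] & sets[b]) / len(union)
    return out
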