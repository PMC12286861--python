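"""Reference-based compositional differential abundance with a
multi-reference consensus.

Cell-type counts per sample are compositional: an increase of one type
forces apparent decreases elsewhere, so differential abundance is only
defined relative to a reference type whose abundance is assumed unchanged.
Following the multi-reference strategy, the model is fitted once per
candidate reference (the major populations: early and postnatal
progenitors, mTEC, cTEC, Aire-stage, unassigned) and a cell type is deemed
*overall changed* only when a strict majority of the fits flag it.  The
final reported reference is the one whose fit flags the fewest changes.

Model
-----
Counts per sample follow a Dirichlet-multinomial: with condition indicator
x in {0, 1}, the expected composition is

    p_k(x) = softmax(alpha_k + beta_k x),   alpha_ref = beta_ref = 0,

with a common precision gamma > 0 (concentration gamma * p gives
overdispersion relative to the multinomial).  Maximum likelihood is found
by quasi-Newton optimization with restarts; each non-reference type's
condition effect beta_k is tested with a likelihood-ratio test against the
constrained refit (beta_k = 0), BH-adjusted across types, flagged at
adjusted p < 0.05.  This is a frequentist analog of the Bayesian
spike-and-slab formulation used in scCODA; the consensus logic is
unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps
from scipy.special import gammaln

from mimetect.stats import bh_adjust

logger = logging.getLogger(__name__)

__all__ = ["CompositionCounts", "DirichletMultinomialDA", "CompositionResults",
           "ConsensusResult", "fit_dm", "consensus_over_references",
           "majority_rule", "aggregate_calls"]


@dataclass
class CompositionCounts:
    """Samples x cell-types integer counts with a two-level condition."""

    counts: pd.DataFrame
    condition: pd.Series

    def __post_init__(self):
        self.condition = pd.Series(self.condition, index=self.counts.index)
        if (self.counts.sum(axis=1) <= 0).any():
            raise ValueError("every sample needs a positive total count")
        if self.condition.nunique() != 2:
            raise ValueError("condition must have exactly 2 levels")


def _dm_loglike(x: np.ndarray, alpha: np.ndarray) -> float:
    """Dirichlet-multinomial log-likelihood, summed over samples.

    ``x`` samples x types counts, ``alpha`` samples x types concentrations.
    """
    n = x.sum(axis=1)
    a0 = alpha.sum(axis=1)
    ll = gammaln(a0) - gammaln(n + a0) \
        + (gammaln(x + alpha) - gammaln(alpha)).sum(axis=1)
    return float(ll.sum())


@dataclass
class CompositionResults:
    """Per-type estimates and tests for one reference choice."""

    reference: str
    alpha: pd.Series            # per type, reference fixed at 0
    beta: pd.Series
    gamma: float
    loglike: float
    tests: pd.DataFrame         # per non-reference type: lrt, p, adj_p, changed
    fdr: float

    @property
    def changed(self) -> pd.Series:
        return self.tests["changed"]

    def fitted_proportions(self, x: int) -> pd.Series:
        eta = self.alpha + self.beta * x
        w = np.exp(eta - eta.max())
        return w / w.sum()

    def summary(self) -> str:
        lines = [f"Dirichlet-multinomial differential abundance (reference: {self.reference})",
                 f"  precision gamma = {self.gamma:.3g}   log-likelihood = {self.loglike:.3f}",
                 f"  types flagged at FDR {self.fdr}: "
                 f"{list(self.tests.index[self.tests['changed']])}"]
        return "\n".join(lines)


class DirichletMultinomialDA:
    """Dirichlet-multinomial differential-abundance model for one reference.

    Parameters
    ----------
    counts
        Samples x cell-types counts (or a :class:`CompositionCounts`).
    condition
        Two-level per-sample labels; the effect is for the second level
        (sorted order) relative to the first.
    reference
        Cell-type column held fixed (alpha = beta = 0).
    """

    def __init__(self, counts, condition=None, reference: str = None):
        if isinstance(counts, CompositionCounts):
            condition = counts.condition
            counts = counts.counts
        cc = CompositionCounts(counts, condition)
        if reference not in cc.counts.columns:
            raise ValueError(f"reference {reference!r} not among cell types")
        absent = cc.counts.columns[(cc.counts == 0).all(axis=0)]
        if len(absent):
            logger.warning("cell type(s) absent in all samples excluded: %s", list(absent))
            cc = CompositionCounts(cc.counts.drop(columns=list(absent)), cc.condition)
            if reference not in cc.counts.columns:
                raise ValueError(f"reference {reference!r} is absent in all samples")
        self.counts = cc.counts
        levels = sorted(cc.condition.unique())
        self.x = (cc.condition == levels[1]).astype(float).values
        self.levels = levels
        self.reference = reference
        # reference column moved last for a stable parameter layout
        self.types = [c for c in self.counts.columns if c != reference] + [reference]
        self.X = self.counts[self.types].values.astype(float)
        self.K = len(self.types)

    # parameter vector: alpha_(K-1), beta_(K-1), log_gamma
    def _unpack(self, theta, fixed_beta_at=None):
        K = self.K
        alpha = np.concatenate([theta[: K - 1], [0.0]])
        beta = np.concatenate([theta[K - 1: 2 * K - 2], [0.0]])
        if fixed_beta_at is not None:
            beta[fixed_beta_at] = 0.0
        log_gamma = theta[-1]
        return alpha, beta, log_gamma

    def _negll(self, theta, fixed_beta_at=None):
        alpha, beta, log_gamma = self._unpack(theta, fixed_beta_at)
        eta = alpha[None, :] + np.outer(self.x, beta)
        eta -= eta.max(axis=1, keepdims=True)
        p = np.exp(eta)
        p /= p.sum(axis=1, keepdims=True)
        gamma = np.exp(np.clip(log_gamma, -10, 20))
        conc = np.maximum(gamma * p, 1e-10)
        return -_dm_loglike(self.X, conc)

    def _initial(self, rng):
        prop = (self.X + 0.5) / (self.X + 0.5).sum(axis=1, keepdims=True)
        logp = np.log(prop.mean(axis=0))
        alpha0 = logp[:-1] - logp[-1]
        theta = np.concatenate([alpha0, np.zeros(self.K - 1), [np.log(50.0)]])
        if rng is not None:
            theta = theta + rng.normal(scale=0.3, size=theta.size)
        return theta

    def _optimize(self, fixed_beta_at=None, seed: int = 0, n_restarts: int = 5):
        rng = np.random.default_rng(seed)
        best = None
        for r in range(n_restarts):
            theta0 = self._initial(None if r == 0 else rng)
            res = optimize.minimize(self._negll, theta0, args=(fixed_beta_at,),
                                    method="L-BFGS-B",
                                    options={"maxiter": 500, "ftol": 1e-12})
            if best is None or res.fun < best.fun - 1e-9:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise RuntimeError(f"Dirichlet-multinomial fit failed to converge "
                               f"(reference {self.reference!r})")
        return best

    def fit(self, seed: int = 0, n_restarts: int = 5, fdr: float = 0.05) -> CompositionResults:
        full = self._optimize(seed=seed, n_restarts=n_restarts)
        alpha, beta, log_gamma = self._unpack(full.x)
        ll_full = -full.fun
        rows = []
        for k in range(self.K - 1):          # each non-reference type
            red = self._optimize(fixed_beta_at=k, seed=seed + 1 + k,
                                 n_restarts=n_restarts)
            ll_reduced = -red.fun
            lrt = max(0.0, 2.0 * (ll_full - ll_reduced))
            rows.append({"type": self.types[k], "lrt": lrt,
                         "p": float(sps.chi2.sf(lrt, 1))})
        tests = pd.DataFrame(rows).set_index("type")
        tests["adj_p"] = bh_adjust(tests["p"].values)
        tests["changed"] = tests["adj_p"] < fdr
        return CompositionResults(
            reference=self.reference,
            alpha=pd.Series(alpha, index=self.types),
            beta=pd.Series(beta, index=self.types),
            gamma=float(np.exp(log_gamma)),
            loglike=ll_full,
            tests=tests,
            fdr=fdr,
        )


def fit_dm(counts, condition, reference: str, seed: int = 0,
           n_restarts: int = 5, fdr: float = 0.05) -> CompositionResults:
    """Fit the Dirichlet-multinomial model for one reference choice."""
    return DirichletMultinomialDA(counts, condition, reference).fit(
        seed=seed, n_restarts=n_restarts, fdr=fdr)


@dataclass
class ConsensusResult:
    """Strict-majority consensus over reference choices."""

    flags: pd.DataFrame           # types x references boolean
    n_flagged: pd.Series          # per type
    total_references: int
    overall_changed: pd.Series    # n_flagged > total/2
    final_reference: str
    fits: dict

    def summary(self) -> str:
        lines = [f"Compositional consensus over {self.total_references} references "
                 f"(final reference: {self.final_reference})"]
        for t in self.overall_changed.index:
            lines.append(f"  {t}: {int(self.n_flagged[t])}/{self.total_references} "
                         f"-> {'CHANGED' if self.overall_changed[t] else 'unchanged'}")
        return "\n".join(lines)


def majority_rule(flags: pd.DataFrame) -> pd.Series:
    """Strict-majority consensus: a type is overall changed iff *more than
    half* of the reference fits flag it (types x references boolean in,
    boolean per type out)."""
    return flags.sum(axis=1) > flags.shape[1] / 2.0


def consensus_over_references(counts, condition, references: list[str],
                              seed: int = 0, n_restarts: int = 5,
                              fdr: float = 0.05) -> ConsensusResult:
    """Run the model once per reference and apply the strict-majority rule.

    A type is *overall changed* iff more than half of the successful fits
    flag it.  The final reference is the one whose fit flags the fewest
    changes (ties broken lexically, logged).  References whose fit fails are
    dropped with a warning; fewer than 2 successes is an error.
    """
    if len(references) < 2:
        raise ValueError("need at least 2 candidate references")
    fits: dict[str, CompositionResults] = {}
    for i, ref in enumerate(references):
        try:
            fits[ref] = fit_dm(counts, condition, ref, seed=seed + 1000 * i,
                               n_restarts=n_restarts, fdr=fdr)
        except Exception as exc:  # noqa: BLE001 - single-fit failure tolerated
            logger.warning("reference %r dropped (fit failed: %s)", ref, exc)
    if len(fits) < 2:
        raise RuntimeError("fewer than 2 reference fits succeeded")
    types = sorted({t for f in fits.values() for t in f.tests.index})
    flags = pd.DataFrame(
        {ref: f.tests["changed"].reindex(types, fill_value=False) for ref, f in fits.items()},
        index=types,
    )
    n_flagged = flags.sum(axis=1)
    total = len(fits)
    overall = majority_rule(flags)
    change_counts = {ref: int(f.tests["changed"].sum()) for ref, f in fits.items()}
    fewest = min(change_counts.values())
    winners = sorted(r for r, c in change_counts.items() if c == fewest)
    if len(winners) > 1:
        logger.info("reference tie %s; lexical choice %r", winners, winners[0])
    return ConsensusResult(flags=flags, n_flagged=n_flagged, total_references=total,
                           overall_changed=overall, final_reference=winners[0],
                           fits=fits)


def aggregate_calls(labels: pd.Series, sample: pd.Series, condition_of_sample: dict) -> CompositionCounts:
    """Aggregate per-cell labels into a samples x cell-types count table."""
    tab = pd.crosstab(pd.Series(sample, name="sample"), pd.Series(labels, name="type"))
    cond = pd.Series({s: condition_of_sample[s] for s in tab.index})
    return CompositionCounts(tab, cond)
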