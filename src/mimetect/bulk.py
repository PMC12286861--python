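"""Bulk-enrichment engine for signature heat maps.

Purified-TEC bulk RNA-seq contrasts (e.g. E15.5 vs P28, mutant vs wild type)
are summarized per gene by an empirical-Bayes moderated t-statistic tested
against a minimum log-fold-change threshold, and per signature by a
correlation-adjusted competitive test of the in-set statistics against the
remaining genes.  Results are reported as Benjamini-Hochberg adjusted
p-values on a signed log10 scale (negative = depleted, positive = enriched),
clipped for display.

Model
-----
For gene g the two-group fit gives effect b_g (log2 fold change), unscaled
standard error u_g, residual variance s_g^2 on d_g df.  The variances are
shrunk towards a prior (d0, s0^2) estimated by moment matching on log s^2:

    s~_g^2 = (d0 s0^2 + d_g s_g^2) / (d0 + d_g),
    t_g    = b_g / (s~_g u_g)  on  d0 + d_g df.

The fold-change-threshold test replaces the point null with |b| <= tau:
with se = s~ u, t_r = (|b| - tau)/se and t_l = (|b| + tau)/se,
p = P(T > t_r) + P(T > t_l).  The competitive set test compares the mean
in-set statistic against the out-set mean with a variance inflation factor
VIF = 1 + (m - 1) rho for inter-gene correlation rho.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats as sps

from mimetect.signatures import GeneSignature
from mimetect.stats import bh_adjust

logger = logging.getLogger(__name__)

__all__ = ["filter_genes", "logcpm", "ModeratedContrast", "ModeratedContrastResults",
           "fit_moderated_t", "treat_test", "camera_pr", "adjust_and_sign",
           "DEFAULT_TAU"]

DEFAULT_TAU = math.log2(1.2)
_D0_CAP = 1e7  # stands in for an infinite prior df


def filter_genes(counts: pd.DataFrame, min_count: int = 5,
                 min_fraction: float = 0.5) -> pd.DataFrame:
    """Keep genes whose count exceeds ``min_count`` (strictly) in at least
    ``min_fraction`` of all samples."""
    frac = (counts > min_count).mean(axis=1)
    kept = counts.loc[frac >= min_fraction]
    if kept.empty:
        raise ValueError("no genes survive the expression filter")
    return kept


def logcpm(counts: pd.DataFrame, prior: float = 0.5) -> pd.DataFrame:
    """log2 counts per million with a prior count.

    y = log2((count + prior) / (libsize + 2 * prior) * 1e6).
    """
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive")
    return np.log2((counts + prior).div(lib + 2.0 * prior, axis=1) * 1e6)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        raise ValueError("trigamma inverse requires y > 0")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match (d0, s0^2) so that s^2 ~ s0^2 * F(df, d0), via the
    digamma/trigamma representation of log s^2."""
    ok = s2 > 0
    if not ok.any():
        raise ValueError("all residual variances are zero")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    emean = e.mean()
    n = e.size
    evar = e.var(ddof=1) if n > 1 else 0.0
    evar -= float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = math.exp(emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        logger.info("no excess variability in log s^2: prior df set to infinity "
                    "(capped at %g)", _D0_CAP)
        d0 = math.inf
        s02 = math.exp(emean)
    return d0, s02


@dataclass
class ModeratedContrastResults:
    """Per-gene moderated ranking statistics for one two-group contrast.

    ``table`` has one row per gene: ``coef`` (log2FC), ``u`` (unscaled se),
    ``s2`` and ``df`` (residual variance and df), ``s2_post`` (moderated),
    ``t`` and ``df_total``.
    """

    table: pd.DataFrame
    d0: float
    s02: float
    contrast: tuple

    @property
    def t(self) -> pd.Series:
        return self.table["t"]

    def treat(self, tau: float = DEFAULT_TAU) -> pd.DataFrame:
        return treat_test(self, tau=tau)

    def summary(self) -> str:
        top = self.table.reindex(self.table["t"].abs().sort_values(ascending=False).index)
        lines = [f"Moderated contrast {self.contrast[0]} vs {self.contrast[1]}",
                 f"  genes: {len(self.table)}   prior df d0 = {self.d0:.4g}   "
                 f"prior variance s0^2 = {self.s02:.4g}",
                 "  top genes by |t|:"]
        lines += [f"    {g}: coef={r.coef:+.3f} t={r.t:+.3f}" for g, r in top.head(5).iterrows()]
        return "\n".join(lines)


class ModeratedContrast:
    """Two-group linear model on log-expression with empirical-Bayes
    variance moderation.

    Parameters
    ----------
    y
        genes x samples matrix of log2-CPM values (see :func:`logcpm`).
    conditions
        Per-sample condition labels aligned with the columns of ``y``.
    contrast
        Pair ``(A, B)``; the per-gene effect is mean(A) - mean(B).
    """

    def __init__(self, y: pd.DataFrame, conditions, contrast: tuple):
        conditions = pd.Series(list(conditions), index=y.columns)
        a, b = contrast
        self.cols_a = conditions.index[conditions == a]
        self.cols_b = conditions.index[conditions == b]
        if len(self.cols_a) < 2 or len(self.cols_b) < 2:
            raise ValueError("need >= 2 samples per contrasted condition")
        self.y = y
        self.contrast = (a, b)

    def fit(self, d0: float | None = None) -> ModeratedContrastResults:
        """Fit the per-gene model and moderate the variances.

        ``d0`` forces the prior df (``math.inf`` gives s~^2 = s0^2 for every
        gene); by default it is estimated from the data.
        """
        ya = self.y[self.cols_a].values
        yb = self.y[self.cols_b].values
        na, nb = ya.shape[1], yb.shape[1]
        dfg = na + nb - 2
        if dfg <= 0:
            raise ValueError("zero residual degrees of freedom")
        coef = ya.mean(axis=1) - yb.mean(axis=1)
        ss = ((ya - ya.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) \
            + ((yb - yb.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        s2 = ss / dfg
        u = math.sqrt(1.0 / na + 1.0 / nb)
        est_d0, s02 = _fit_f_dist(s2, float(dfg))
        if d0 is None:
            d0 = est_d0
        if math.isinf(d0):
            s2_post = np.full_like(s2, s02)
            df_total = np.full_like(s2, _D0_CAP)
        else:
            s2_post = (d0 * s02 + dfg * s2) / (d0 + dfg)
            df_total = np.full_like(s2, min(d0 + dfg, _D0_CAP))
        t = coef / (np.sqrt(s2_post) * u)
        table = pd.DataFrame({"coef": coef, "u": u, "s2": s2, "df": float(dfg),
                              "s2_post": s2_post, "t": t, "df_total": df_total},
                             index=self.y.index)
        return ModeratedContrastResults(table=table, d0=float(d0), s02=float(s02),
                                        contrast=self.contrast)


def fit_moderated_t(y: pd.DataFrame, conditions, contrast: tuple,
                    d0: float | None = None) -> ModeratedContrastResults:
    """Functional wrapper around :class:`ModeratedContrast`."""
    return ModeratedContrast(y, conditions, contrast).fit(d0=d0)


def treat_test(stats: ModeratedContrastResults, tau: float = DEFAULT_TAU) -> pd.DataFrame:
    """Moderated t-test against the threshold null |log2FC| <= tau.

    At tau = 0 this reduces exactly to the ordinary two-sided moderated-t
    p-value.  The reported statistic is sign(coef) * max(t_r, 0): genes
    whose estimated effect lies inside the threshold band carry statistic 0
    (only the p-value distinguishes them), matching the reference
    implementation of the threshold test.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    tb = stats.table
    se = np.sqrt(tb["s2_post"]) * tb["u"]
    t_r = (tb["coef"].abs() - tau) / se
    t_l = (tb["coef"].abs() + tau) / se
    df = tb["df_total"]
    p = sps.t.sf(t_r, df) + sps.t.sf(t_l, df)
    return pd.DataFrame({"t": np.sign(tb["coef"]) * np.maximum(t_r, 0.0),
                         "p": np.minimum(p, 1.0)},
                        index=tb.index)


def camera_pr(stat: pd.Series, sets: list[GeneSignature], rho: float = 0.01) -> pd.DataFrame:
    """Pre-ranked competitive gene-set test with inter-gene correlation.

    For each set of m measured genes among G statistics, the difference
    delta between the in-set and out-set means is referred to a t
    distribution on G - 2 df with standard error
    sqrt(sigma^2 (VIF/m + 1/(G - m))), where sigma^2 pools the within-group
    sums of squares and VIF = 1 + (m - 1) rho.  At rho = 0 this is exactly
    the pooled two-sample t-test.

    Returns a table indexed by set name: ``size``, ``delta``, ``direction``,
    ``p``, ``klass``.
    """
    stat = stat.astype(float)
    G = len(stat)
    values = stat.values
    gene_pos = {g: i for i, g in enumerate(stat.index)}
    rows = []
    for sig in sets:
        idx = np.array(sorted(gene_pos[g] for g in sig.genes if g in gene_pos), dtype=int)
        m = idx.size
        if m == 0:
            logger.warning("set %r has no measured genes; skipped", sig.name)
            continue
        if m < 2 or m >= G:
            logger.warning("set %r has degenerate size m=%d (G=%d); skipped", sig.name, m, G)
            continue
        inset = values[idx]
        mask = np.zeros(G, dtype=bool)
        mask[idx] = True
        outset = values[~mask]
        delta = inset.mean() - outset.mean()
        ss = ((inset - inset.mean()) ** 2).sum() + ((outset - outset.mean()) ** 2).sum()
        sigma2 = ss / (G - 2)
        vif = 1.0 + (m - 1) * rho
        se = math.sqrt(sigma2 * (vif / m + 1.0 / (G - m)))
        if se == 0:
            z, p = 0.0, 1.0
        else:
            z = delta / se
            p = 2.0 * sps.t.sf(abs(z), G - 2)
        rows.append({"name": sig.name, "size": m, "delta": float(delta),
                     "direction": "up" if delta > 0 else "down",
                     "p": float(min(p, 1.0)), "klass": sig.klass})
    if not rows:
        return pd.DataFrame(columns=["size", "delta", "direction", "p", "klass"],
                            index=pd.Index([], name="name"))
    return pd.DataFrame(rows).set_index("name")


def adjust_and_sign(table: pd.DataFrame, clip: float = 10.0) -> pd.DataFrame:
    """BH-adjust the competitive p-values jointly and report them as signed
    log10 values: log10(adj p), multiplied by -1 for enriched (up) sets, so
    positive means enriched and negative means depleted.  Values beyond
    +/- clip are rounded to the nearest limit.
    """
    if clip <= 0:
        raise ValueError("clip must be positive")
    out = table.copy()
    out["adj_p"] = bh_adjust(out["p"].values)
    with np.errstate(divide="ignore"):
        logp = np.log10(out["adj_p"].values)
    sign = np.where(out["direction"].values == "up", -1.0, 1.0)
    signed = logp * sign
    out["signed_logp"] = signed
    out["clipped"] = np.clip(signed, -clip, clip)
    return out
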