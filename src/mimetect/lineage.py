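"""Lineage-barcode statistics.

CRISPR-Cas9-induced barcodes recorded per cell are binarized (present /
absent) and used to ask whether barcode detection differs across signature
populations: a logistic regression of the per-cell detection indicator on
categorical ``signature`` and ``sample`` covariates is compared against a
sample-only reduced model by likelihood-ratio test.  Proportions between
two populations are compared with an exact conditional binomial test, and
detection proportions are reported with Wilson score intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = ["BarcodeMatrix", "AssociationResults", "BarcodeAssociation",
           "binarize_barcodes", "test_signature_association",
           "binomial_proportion_test", "wilson_interval",
           "detection_proportions"]


@dataclass
class BarcodeMatrix:
    """Cells x barcodes presence indicators with per-cell annotations."""

    presence: pd.DataFrame      # 0/1 entries
    signature: pd.Series        # per-cell population label
    sample: pd.Series           # per-cell sample id

    @property
    def any_detected(self) -> pd.Series:
        """Per-cell indicator: at least one barcode detected."""
        return (self.presence.sum(axis=1) > 0).astype(int)


def binarize_barcodes(raw: pd.DataFrame, signature=None, sample=None) -> BarcodeMatrix:
    """Binarize barcode counts: entry 1 iff raw count > 0.

    All-zero barcode columns are retained but flagged with a warning.
    Idempotent on already-binary input.
    """
    presence = (raw > 0).astype(int)
    dead = presence.columns[presence.sum(axis=0) == 0]
    if len(dead):
        logger.warning("%d barcode column(s) with no detections retained: %s",
                       len(dead), list(dead[:5]))
    if signature is None:
        signature = pd.Series("all", index=raw.index)
    if sample is None:
        sample = pd.Series("s0", index=raw.index)
    return BarcodeMatrix(presence=presence,
                         signature=pd.Series(signature, index=raw.index),
                         sample=pd.Series(sample, index=raw.index))


# --------------------------------------------------------------------------
# logistic regression by IRLS

def _dummy_design(signature: pd.Series, sample: pd.Series, include_signature: bool):
    cols = [np.ones(len(signature))]
    names = ["intercept"]
    for series, tag in ((sample, "sample"), (signature, "signature")):
        if tag == "signature" and not include_signature:
            continue
        levels = sorted(series.unique())
        for lev in levels[1:]:  # first level is the baseline
            cols.append((series == lev).astype(float).values)
            names.append(f"{tag}[{lev}]")
    return np.column_stack(cols), names


def _irls_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 100,
                   tol: float = 1e-8, ridge: float = 0.0):
    """Logistic fit by iteratively reweighted least squares with step-halving.

    Returns (beta, deviance).  Raises on apparent complete separation.
    """
    n, p = X.shape
    beta = np.zeros(p)

    def deviance(b):
        eta = np.clip(X @ b, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        eps = 1e-12
        return -2.0 * np.sum(y * np.log(mu + eps) + (1 - y) * np.log(1 - mu + eps))

    dev = deviance(beta)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-10)
        z = eta + (y - mu) / w
        WX = X * w[:, None]
        H = X.T @ WX + ridge * np.eye(p)
        try:
            new = np.linalg.solve(H, WX.T @ z)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(f"singular IRLS system: {exc}") from exc
        step, new_dev = 1.0, deviance(new)
        while new_dev > dev + 1e-10 and step > 1e-6:  # step-halving
            step /= 2.0
            new = beta + step * (new - beta)
            new_dev = deviance(new)
        if np.max(np.abs(new)) > 30:
            raise FloatingPointError(
                "diverging coefficients indicate complete separation; "
                "refit with a small ridge penalty (ridge > 0, Firth-style stabilization)")
        converged = abs(dev - new_dev) < tol
        beta, dev = new, new_dev
        if converged:
            break
    return beta, dev


@dataclass
class AssociationResults:
    """Likelihood-ratio comparison of the signature-bearing logistic model
    against the sample-only reduced model."""

    deviance_full: float
    deviance_reduced: float
    lrt: float
    df: int
    p: float
    coef_full: dict

    def summary(self) -> str:
        return (f"Barcode-detection association\n"
                f"  LRT = {self.lrt:.4f} on {self.df} df, p = {self.p:.3g}\n"
                f"  deviance full/reduced = {self.deviance_full:.3f}"
                f"/{self.deviance_reduced:.3f}")


class BarcodeAssociation:
    """Model: per-cell barcode-detection indicator ~ signature + sample.

    ``fit`` compares this full model against the sample-only model with a
    chi-square likelihood-ratio test on (signature levels - 1) df.
    """

    def __init__(self, bm: BarcodeMatrix, outcome: str = "any"):
        if outcome == "any":
            y = bm.any_detected
        elif outcome in bm.presence.columns:  # per-barcode mode
            y = bm.presence[outcome]
        else:
            raise ValueError(f"unknown outcome {outcome!r}")
        keep = pd.Series(True, index=y.index)
        counts = bm.signature.value_counts()
        empty = counts[counts == 0]
        if len(empty):
            logger.warning("dropping empty signature level(s): %s", list(empty.index))
        self.y = np.asarray(y[keep], dtype=float)
        self.signature = bm.signature[keep]
        self.sample = bm.sample[keep]
        if self.signature.nunique() < 2:
            raise ValueError("need at least 2 signature levels")
        if self.sample.nunique() < 1:
            raise ValueError("need at least 1 sample")

    def fit(self, ridge: float = 0.0) -> AssociationResults:
        Xf, names = _dummy_design(self.signature, self.sample, include_signature=True)
        Xr, _ = _dummy_design(self.signature, self.sample, include_signature=False)
        bf, dev_f = _irls_logistic(Xf, self.y, ridge=ridge)
        br, dev_r = _irls_logistic(Xr, self.y, ridge=ridge)
        lrt = max(0.0, dev_r - dev_f)
        df = self.signature.nunique() - 1
        p = float(sps.chi2.sf(lrt, df))
        return AssociationResults(deviance_full=float(dev_f), deviance_reduced=float(dev_r),
                                  lrt=float(lrt), df=int(df), p=p,
                                  coef_full=dict(zip(names, bf)))


def test_signature_association(bm: BarcodeMatrix, outcome: str = "any",
                               ridge: float = 0.0) -> AssociationResults:
    """Convenience wrapper: build and fit :class:`BarcodeAssociation`."""
    return BarcodeAssociation(bm, outcome=outcome).fit(ridge=ridge)


test_signature_association.__test__ = False  # not a pytest item when imported


# --------------------------------------------------------------------------
# exact proportion statistics

def binomial_proportion_test(xA: int, nA: int, xB: int, nB: int) -> float:
    """Exact conditional two-sided test of equal detection proportions.

    Conditional on the total x = xA + xB, xA ~ Binomial(x, nA/(nA+nB)) under
    the null; the two-sided p sums the probabilities of all outcomes no more
    likely than the observed one (minimum-likelihood rule), capped at 1.
    """
    for x, n in ((xA, nA), (xB, nB)):
        if n <= 0:
            raise ValueError("group sizes must be positive")
        if not (0 <= x <= n):
            raise ValueError("counts must satisfy 0 <= x <= n")
    total = xA + xB
    if total == 0:
        return 1.0
    q = nA / (nA + nB)
    support = np.arange(0, total + 1)
    pmf = sps.binom.pmf(support, total, q)
    obs = pmf[xA]
    return float(min(1.0, pmf[pmf <= obs * (1 + 1e-12)].sum()))


def wilson_interval(x: int, n: int, level: float = 0.95,
                    brown_adjust: bool = False) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion.

    ``brown_adjust`` applies the boundary modification for extreme observed
    proportions (x in {0, 1, 2} or {n-2, n-1, n} replaced by a Poisson-based
    bound); the plain Wilson interval is the default.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not (0 <= x <= n):
        raise ValueError("x must satisfy 0 <= x <= n")
    z = sps.norm.ppf(0.5 + level / 2.0)
    phat = x / n
    denom = 1.0 + z * z / n
    centre = (phat + z * z / (2 * n)) / denom
    half = z * np.sqrt(phat * (1 - phat) / n + z * z / (4 * n * n)) / denom
    lo, hi = max(0.0, centre - half), min(1.0, centre + half)
    if x == 0:
        lo = 0.0
    if x == n:
        hi = 1.0
    if brown_adjust:
        if 0 < x <= 2:
            lo = min(lo, 0.5 * sps.chi2.ppf(0.5 - level / 2.0, 2 * x) / n)
        if n - 2 <= x < n:
            hi = max(hi, 1.0 - 0.5 * sps.chi2.ppf(0.5 - level / 2.0, 2 * (n - x)) / n)
    return float(lo), float(hi)


def detection_proportions(bm: BarcodeMatrix, level: float = 0.95) -> pd.DataFrame:
    """Per-signature barcode-detection proportion with Wilson intervals."""
    rows = []
    det = bm.any_detected
    for sig, idx in bm.signature.groupby(bm.signature).groups.items():
        x = int(det.loc[idx].sum())
        n = len(idx)
        lo, hi = wilson_interval(x, n, level=level)
        rows.append({"signature": sig, "detected": x, "n": n,
                     "proportion": x / n, "lower": lo, "upper": hi})
    return pd.DataFrame(rows).set_index("signature")
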