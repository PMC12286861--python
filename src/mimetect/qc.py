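"""Droplet-level QC and clustering-parameter selection for snRNA-seq.

Droplets are excluded on fixed thresholds for total UMI (< ``umi_min``) and
mitochondrial fraction (> ``mito_max``), and on robust outlier rules for the
number of detected genes and the library complexity (detected genes per
UMI): values beyond a given number of median absolute deviations from the
per-sample median are removed.  The MAD is the raw (unscaled) median
absolute deviation; a flag applies the 1.4826 normal-consistency factor.

Clustering parameters (e.g. resolution) are selected by sweeping candidate
clusterings and maximizing the mean silhouette width in the embedding; the
total within-cluster sum of squares is reported alongside for subcluster
evaluation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_samples

__all__ = ["DropletQC", "ClusteringEval", "mad_filter", "silhouette_sweep"]


@dataclass
class DropletQC:
    """Per-droplet QC covariates, per-rule pass flags and the keep flag."""

    table: pd.DataFrame

    @property
    def keep(self) -> pd.Series:
        return self.table["keep"]

    def n_kept(self) -> int:
        return int(self.table["keep"].sum())


def _mad(v: np.ndarray, scaled: bool) -> float:
    m = np.median(np.abs(v - np.median(v)))
    return 1.4826 * m if scaled else m


def mad_filter(qc: pd.DataFrame, umi_min: int = 500, mito_max: float = 0.05,
               genes_mads: float = 1.0, complexity_mads: float = 3.0,
               sample_col: str | None = "sample", scaled_mad: bool = False) -> DropletQC:
    """Apply the four droplet-exclusion rules.

    ``qc`` needs columns ``total_umi``, ``mito_frac``, ``detected_genes``
    and optionally a sample column (medians/MADs are computed per sample
    when present).  A droplet is excluded iff

    - total UMI < ``umi_min`` (strict), or
    - mitochondrial fraction > ``mito_max`` (strict), or
    - |detected genes - median| > ``genes_mads`` * MAD, or
    - |complexity - median| > ``complexity_mads`` * MAD,

    with complexity = detected genes / total UMI.  A zero MAD skips that
    rule with a warning.
    """
    req = {"total_umi", "mito_frac", "detected_genes"}
    missing = req - set(qc.columns)
    if missing:
        raise ValueError(f"QC table missing columns: {sorted(missing)}")
    for c in req:
        if not np.all(np.isfinite(qc[c].values.astype(float))):
            raise ValueError(f"non-finite values in column {c!r}")
    out = qc.copy()
    out["complexity"] = out["detected_genes"] / out["total_umi"]
    out["pass_umi"] = out["total_umi"] >= umi_min
    out["pass_mito"] = out["mito_frac"] <= mito_max
    if sample_col is not None and sample_col in out.columns:
        groups = out.groupby(sample_col, sort=False).groups
    else:
        groups = {"_all": out.index}
    pass_genes = pd.Series(True, index=out.index)
    pass_cplx = pd.Series(True, index=out.index)
    for name, idx in groups.items():
        for col, k, target in (("detected_genes", genes_mads, pass_genes),
                               ("complexity", complexity_mads, pass_cplx)):
            v = out.loc[idx, col].values.astype(float)
            med = np.median(v)
            mad = _mad(v, scaled_mad)
            if mad == 0:
                warnings.warn(f"MAD of {col} is zero in sample {name!r}; rule skipped")
                continue
            target.loc[idx] = np.abs(v - med) <= k * mad
    out["pass_genes"] = pass_genes
    out["pass_complexity"] = pass_cplx
    out["keep"] = out[["pass_umi", "pass_mito", "pass_genes", "pass_complexity"]].all(axis=1)
    return DropletQC(table=out)


@dataclass
class ClusteringEval:
    parameter: object
    labels: np.ndarray
    mean_silhouette: float
    wcss: float


def _wcss(X: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for lab in np.unique(labels):
        pts = X[labels == lab]
        total += ((pts - pts.mean(axis=0)) ** 2).sum()
    return float(total)


def silhouette_sweep(embedding, clusterings) -> tuple[list[ClusteringEval], object]:
    """Evaluate candidate clusterings and select the silhouette maximizer.

    Parameters
    ----------
    embedding
        cells x dims array (Euclidean distances).
    clusterings
        Mapping parameter -> label array, or a sequence of (parameter,
        labels) pairs.  Duplicate parameters are an error.

    Returns
    -------
    (list of :class:`ClusteringEval` in input order, selected parameter).
    Singleton clusters contribute silhouette 0 (with a warning); a
    clustering with fewer than 2 clusters is an error.
    """
    X = np.asarray(embedding, dtype=float)
    if hasattr(clusterings, "items"):
        items = list(clusterings.items())
    else:
        items = list(clusterings)
    params = [p for p, _ in items]
    if len(set(map(str, params))) != len(params):
        raise ValueError("duplicate parameter keys in the sweep")
    evals = []
    for param, labels in items:
        labels = np.asarray(labels)
        uniq, counts = np.unique(labels, return_counts=True)
        if uniq.size < 2:
            raise ValueError(f"clustering {param!r} has fewer than 2 clusters")
        if (counts == 1).any():
            warnings.warn(f"clustering {param!r} has singleton cluster(s); "
                          "their silhouette is 0")
        sil = float(silhouette_samples(X, labels).mean())
        evals.append(ClusteringEval(parameter=param, labels=labels,
                                    mean_silhouette=sil, wcss=_wcss(X, labels)))
    best = max(evals, key=lambda e: e.mean_silhouette)
    return evals, best.parameter
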