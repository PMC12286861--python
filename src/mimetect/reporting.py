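"""Assembly of the signature-enrichment heat map and gene-level panels.

The heat map is the central visual of the bulk analysis: rows are
signatures (ordered canonical, then mimetic, then background), columns are
contrasts, and each cell holds the clipped signed log10 adjusted p-value
from the competitive test.  A signature skipped in a contrast is rendered
as explicitly missing (NaN), never as zero.  Every figure's underlying
matrix is also emitted as a table so the visual is machine-checkable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from mimetect.bulk import ModeratedContrastResults
from mimetect.signatures import GeneSignature

__all__ = ["build_heatmap", "gene_line_panel"]

_KLASS_ORDER = {"canonical": 0, "mimetic": 1, "background": 2}


def build_heatmap(tables: dict, clip: float = 10.0, render: bool = False):
    """Assemble the signatures x contrasts matrix of clipped signed values.

    Parameters
    ----------
    tables
        Mapping contrast label -> enrichment table (the output of
        :func:`mimetect.bulk.adjust_and_sign`, with ``signed_logp`` and
        ``klass`` columns).
    clip
        Symmetric display limit; values beyond it are rounded to it.
    render
        Also return a matplotlib figure.

    Returns
    -------
    DataFrame (and a figure when ``render``); missing combinations are NaN.
    """
    if not tables:
        raise ValueError("no enrichment tables supplied")
    klass_of: dict[str, str] = {}
    for contrast, tab in tables.items():
        for name, k in tab["klass"].items():
            if klass_of.setdefault(name, k) != k:
                raise ValueError(f"signature {name!r} has contradictory class "
                                 f"tags across contrasts")
    rows = sorted(klass_of, key=lambda n: (_KLASS_ORDER.get(klass_of[n], 3), n))
    mat = pd.DataFrame(np.nan, index=rows, columns=list(tables))
    for contrast, tab in tables.items():
        vals = np.clip(tab["signed_logp"].values, -clip, clip)
        mat.loc[tab.index, contrast] = vals
    if not render:
        return mat
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(2 + 0.8 * mat.shape[1], 1 + 0.25 * mat.shape[0]))
    im = ax.imshow(mat.values, cmap="RdBu_r", vmin=-clip, vmax=clip, aspect="auto")
    ax.set_xticks(range(mat.shape[1]), mat.columns, rotation=45, ha="right")
    ax.set_yticks(range(mat.shape[0]), mat.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="signed log10(adj. p)")
    fig.tight_layout()
    return mat, fig


def gene_line_panel(stats: ModeratedContrastResults, sigs: list[GeneSignature],
                    enrichment: pd.DataFrame | None = None):
    """Per-signature strip of gene t-statistics on a shared axis.

    Each line marks one signature gene's moderated t-statistic; the
    annotation is the signed log10 adjusted p from the competitive test
    when an enrichment table is supplied.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    t = stats.t
    panels = []
    for sig in sigs:
        vals = t.reindex([g for g in sig.genes if g in t.index]).dropna()
        if vals.empty:
            raise ValueError(f"signature {sig.name!r} has no genes among the statistics")
        panels.append((sig.name, vals.values))
    fig, axes = plt.subplots(len(panels), 1, sharex=True,
                             figsize=(6, 0.5 * len(panels) + 1), squeeze=False)
    for ax, (name, vals) in zip(axes[:, 0], panels):
        ax.vlines(vals, 0, 1, lw=0.8)
        ax.set_yticks([])
        label = name
        if enrichment is not None and name in enrichment.index:
            label += f"  ({enrichment.loc[name, 'signed_logp']:+.1f})"
        ax.set_ylabel(label, rotation=0, ha="right", va="center", fontsize=7)
        ax.axvline(0, color="grey", lw=0.5)
    axes[-1, 0].set_xlabel("moderated t-statistic")
    fig.tight_layout()
    return fig
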