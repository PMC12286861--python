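"""Building, filtering and translating gene-signature collections.

A signature is a named gene set characterizing a cell population (canonical
TEC compartments, mimetic cell types, or unrelated background tissues used
as negative controls in competitive enrichment).  Signatures are derived
from single-cell differential-expression tables by fixed thresholds,
background collections are size-matched to the focal signatures, and
cross-species analyses use many-to-many orthology transfer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["GeneSignature", "derive_signatures", "select_background_sets", "map_orthologs"]

_KLASSES = ("canonical", "mimetic", "background")


@dataclass(frozen=True)
class GeneSignature:
    """A named gene set with a class tag.

    Attributes
    ----------
    name
        Unique label within a collection (e.g. ``"enterohepatic"``).
    genes
        Non-empty set of gene identifiers (opaque strings).
    klass
        One of ``"canonical"``, ``"mimetic"``, ``"background"``.
    description
        Free text carried through GMT round trips.
    """

    name: str
    genes: frozenset = field(default_factory=frozenset)
    klass: str = "mimetic"
    description: str = ""

    def __post_init__(self):
        object.__setattr__(self, "genes", frozenset(self.genes))
        if not self.genes:
            raise ValueError(f"signature {self.name!r} has no genes")
        if self.klass not in _KLASSES:
            raise ValueError(f"klass must be one of {_KLASSES}, got {self.klass!r}")

    def __len__(self) -> int:
        return len(self.genes)

    def intersect(self, universe) -> "GeneSignature":
        """Restrict to genes present in ``universe`` (the measured genes)."""
        kept = self.genes & frozenset(universe)
        if not kept:
            raise ValueError(f"signature {self.name!r} has no genes in the universe")
        return replace(self, genes=kept)


def derive_signatures(de: pd.DataFrame, max_adj_p: float = 0.01,
                      min_abs_log2fc: float = 1.0, min_pct: float = 0.10,
                      klass: str = "mimetic") -> list[GeneSignature]:
    """Derive one signature per population from a differential-expression table.

    A gene enters its population's signature when all three predicates hold:
    adjusted p strictly below ``max_adj_p``, absolute log2 fold change
    strictly above ``min_abs_log2fc``, and expressed in at least ``min_pct``
    of the population's cells (closed boundary).

    Parameters
    ----------
    de
        Table with columns ``gene``, ``log2fc``, ``adj_p``, ``pct_expressed``,
        ``population``.

    Returns
    -------
    list of :class:`GeneSignature`, one per population with >= 1 passing
    gene, in order of first appearance.  Populations left empty are dropped
    with a logged warning.
    """
    if de is None or len(de) == 0:
        raise ValueError("differential-expression table is empty")
    required = {"gene", "log2fc", "adj_p", "pct_expressed", "population"}
    missing = required - set(de.columns)
    if missing:
        raise ValueError(f"DE table is missing columns: {sorted(missing)}")
    if not (0 < max_adj_p <= 1):
        raise ValueError("max_adj_p must be in (0, 1]")
    if min_abs_log2fc < 0:
        raise ValueError("min_abs_log2fc must be >= 0")
    if not (0 <= min_pct <= 1):
        raise ValueError("min_pct must be in [0, 1]")
    for pop, sub in de.groupby("population", sort=False):
        if sub["gene"].duplicated().any():
            dups = sub.loc[sub["gene"].duplicated(), "gene"].tolist()
            raise ValueError(f"duplicate gene ids within population {pop!r}: {dups[:5]}")

    keep = (
        (de["adj_p"] < max_adj_p)
        & (de["log2fc"].abs() > min_abs_log2fc)
        & (de["pct_expressed"] >= min_pct)
    )
    out = []
    for pop in de["population"].drop_duplicates():
        genes = de.loc[keep & (de["population"] == pop), "gene"]
        if genes.empty:
            logger.warning("population %r retained no genes after filtering; dropped", pop)
            continue
        out.append(GeneSignature(name=str(pop), genes=frozenset(genes), klass=klass))
    return out


def select_background_sets(candidates: list[GeneSignature], focal: list[GeneSignature],
                           slack: float = 0.10, universe=None) -> list[GeneSignature]:
    """Size-match background candidates to the focal (TEC + mimetic) signatures.

    A candidate is retained when its size lies in the closed interval
    ``[(1 - slack) * min focal size, (1 + slack) * max focal size]`` -- i.e.
    up to 10% fewer genes than the smallest and up to 10% more than the
    largest focal signature under the default slack.  Retained sets are
    re-tagged ``klass="background"``.  When a measured-gene ``universe`` is
    supplied, candidates are intersected with it *before* the size filter.
    """
    if not focal:
        raise ValueError("focal signature list must be non-empty")
    if slack < 0:
        raise ValueError("slack must be >= 0")
    sizes = [len(s) for s in focal]
    lo = (1.0 - slack) * min(sizes)
    hi = (1.0 + slack) * max(sizes)
    kept = []
    for cand in candidates:
        if universe is not None:
            try:
                cand = cand.intersect(universe)
            except ValueError:
                logger.warning("background candidate %r has no measured genes; dropped", cand.name)
                continue
        if lo <= len(cand) <= hi:
            kept.append(replace(cand, klass="background"))
    if not kept:
        logger.warning("no background candidates fall within size interval [%.1f, %.1f]", lo, hi)
    return kept


def map_orthologs(sig: GeneSignature, mapping: pd.DataFrame) -> GeneSignature:
    """Orthology transfer of a signature across species.

    Many-to-many relationships are expanded: the output gene set is the
    union of every target gene of any source gene in ``sig``.  Source genes
    without any ortholog are dropped; their count is logged.

    Parameters
    ----------
    mapping
        Two-column table; first column source gene ids, second column target
        gene ids (column names are ignored).
    """
    if mapping is None or len(mapping) == 0:
        raise ValueError("orthology map is empty")
    src = mapping.iloc[:, 0].astype(str)
    tgt = mapping.iloc[:, 1].astype(str)
    lookup: dict[str, set] = {}
    for s, t in zip(src, tgt):
        lookup.setdefault(s, set()).add(t)
    mapped: set = set()
    unmapped = 0
    for g in sig.genes:
        targets = lookup.get(str(g))
        if targets is None:
            unmapped += 1
        else:
            mapped |= targets
    if unmapped:
        logger.warning("signature %r: %d source genes had no ortholog", sig.name, unmapped)
    if not mapped:
        raise ValueError(f"signature {sig.name!r}: no gene could be mapped")
    return replace(sig, genes=frozenset(mapped))
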