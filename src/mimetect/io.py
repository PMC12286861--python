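"""File formats: MatrixMarket count matrices, GMT signature collections,
annotated TSV tables.

Gene and cell identifiers are opaque strings; matrices are 0-indexed in
memory and written 1-indexed per the MatrixMarket standard.  All tabular
outputs are TSV with a header and an optional ``#`` metadata preamble.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import io as spio, sparse

from mimetect.signatures import GeneSignature

__all__ = ["load_counts", "write_counts_mtx", "read_gmt", "write_gmt",
           "read_tsv", "write_tsv"]


def load_counts(path, fmt: str = "mtx_dir") -> AnnData:
    """Load a cells x genes count matrix.

    ``mtx_dir`` expects ``matrix.mtx`` (genes x cells triples, as written
    by ``write_counts_mtx``), ``genes.tsv`` and ``cells.tsv``; ``tsv`` a
    dense cells x genes table with cell ids in the first column.  Duplicate
    identifiers and dimension mismatches are errors.
    """
    path = Path(path)
    if fmt == "mtx_dir":
        mat = spio.mmread(path / "matrix.mtx").tocsr().T  # stored genes x cells
        genes = pd.read_csv(path / "genes.tsv", sep="\t", header=None)[0].astype(str)
        cells = pd.read_csv(path / "cells.tsv", sep="\t", header=None)[0].astype(str)
        if mat.shape != (len(cells), len(genes)):
            raise ValueError(f"matrix is {mat.shape} but annotations give "
                             f"({len(cells)}, {len(genes)})")
    elif fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        mat = sparse.csr_matrix(df.values)
        genes = pd.Series(df.columns.astype(str))
        cells = pd.Series(df.index.astype(str))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    for name, ids in (("gene", genes), ("cell", cells)):
        dup = ids[ids.duplicated()]
        if len(dup):
            raise ValueError(f"duplicate {name} id(s): {dup.tolist()[:5]}")
    return AnnData(X=mat, obs=pd.DataFrame(index=cells.values),
                   var=pd.DataFrame(index=genes.values))


def write_counts_mtx(adata: AnnData, outdir) -> None:
    """Write an AnnData as matrix.mtx (genes x cells) + genes.tsv + cells.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X
    if not sparse.issparse(X):
        X = sparse.csr_matrix(X)
    spio.mmwrite(str(outdir / "matrix.mtx"), X.T.tocoo())
    pd.Series(adata.var_names).to_csv(outdir / "genes.tsv", sep="\t",
                                      index=False, header=False)
    pd.Series(adata.obs_names).to_csv(outdir / "cells.tsv", sep="\t",
                                      index=False, header=False)


def read_gmt(path) -> list[GeneSignature]:
    """Read a GMT file (name <tab> description <tab> gene...)."""
    sigs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, "
                                 f"description and at least one gene")
            name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if not genes:
                raise ValueError(f"{path}:{lineno}: empty gene list for {name!r}")
            sigs.append(GeneSignature(name=name, genes=frozenset(genes),
                                      description=desc))
    return sigs


def write_gmt(sigs: list[GeneSignature], path) -> None:
    with open(path, "w") as fh:
        for s in sigs:
            fh.write("\t".join([s.name, s.description or s.klass, *sorted(s.genes)]) + "\n")


def read_tsv(path, **kwargs) -> pd.DataFrame:
    """TSV with optional '#' metadata preamble."""
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_tsv(df: pd.DataFrame, path, metadata: dict | None = None,
              index: bool = True) -> None:
    with open(path, "w") as fh:
        if metadata:
            fh.write("# " + json.dumps(metadata, default=str) + "\n")
        df.to_csv(fh, sep="\t", index=index)
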