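"""End-to-end orchestration on synthetic data.

``run_pipeline`` executes the full synthetic workflow -- simulate, score,
call, aggregate compositions, bulk enrichment, barcode association,
fate probabilities, time-course nadir -- writing every stage's output as
TSV/CSV plus a manifest (inputs, parameters, per-stage seeds, output
hashes) that makes a run bit-reproducible: the same config and seed yield
identical manifest hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from mimetect import bulk as bulk_mod
from mimetect import calling, composition, io as mio, lineage, scoring, smoothing, synthetic, trajectory
from mimetect.reporting import build_heatmap

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "derive_seeds", "DEFAULT_CONFIG"]

DEFAULT_CONFIG = {
    "seed": 0,
    "n_cells": 3000,
    "n_genes": 1200,
    "auc_threshold": 0.30,
    "top_fraction": 0.05,
    "lambda": 0.8,
    "rho": 0.01,
    "clip": 10.0,
    "tau_lfc": 1.2,          # fold-change threshold, as a fold change
    "n_replicates": 3,
    "bulk_shift_log2fc": -1.5,
    "timecourse": {"nadir_age": 21.0, "n_mice": 60, "noise_sd": 0.2,
                   "age_range": [0.0, 56.0]},
    "n_barcodes": 40,
    "barcode_detection_rate": 0.5,
}

_STAGES = ("simulate", "score", "call", "composition", "enrich", "lineage",
           "fate", "nadir")


class RunConfig(dict):
    """Pipeline configuration; missing keys fall back to defaults."""

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = cls(DEFAULT_CONFIG)
        cfg.update(user)
        return cfg

    def validate(self) -> None:
        if self.get("n_cells", 1) <= 0 or self.get("n_genes", 1) <= 0:
            raise ValueError("n_cells and n_genes must be positive")
        thr = self.get("auc_threshold", 0.3)
        if not (0 <= thr <= 1):
            raise ValueError("auc_threshold must be in [0, 1]")


def derive_seeds(seed: int, n: int) -> list[int]:
    """Expand one global seed into deterministic per-stage substreams."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s % (2**31)) for s in state]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: RunConfig | dict, outdir) -> dict:
    """Run all stages in dependency order; returns the manifest."""
    cfg = RunConfig({**DEFAULT_CONFIG, **dict(cfg)})
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = dict(zip(_STAGES, derive_seeds(int(cfg["seed"]), len(_STAGES))))
    manifest = {"config": {k: v for k, v in cfg.items()}, "seeds": seeds, "outputs": {}}

    def emit(df, name, metadata=None, index=True):
        path = outdir / name
        mio.write_tsv(df, path, metadata=metadata, index=index)
        manifest["outputs"][name] = _sha256(path)
        return path

    try:
        # ------------------------------------------------------ simulate
        pops = synthetic.default_populations(cfg["n_genes"])
        sim_cfg = synthetic.SimConfig(n_cells=cfg["n_cells"], n_genes=cfg["n_genes"],
                                      seed=seeds["simulate"], populations=pops)
        adata, truth = synthetic.simulate_single_cell(sim_cfg)
        mio.write_counts_mtx(adata, outdir / "counts")
        emit(truth.cell_labels.to_frame(), "truth_labels.tsv")
        sigs = synthetic.population_signatures(pops)

        # --------------------------------------------------------- score
        ranks = scoring.rank_genes_per_cell(adata, tie_seed=seeds["score"])
        scores = scoring.score_signatures(ranks, sigs, top_fraction=cfg["top_fraction"])
        emit(scores.auc, "scores_auc.tsv",
             metadata={"top_fraction": cfg["top_fraction"], "n_genes": scores.n_genes,
                       "n_sig_genes": scores.n_sig_genes, "tie_seed": seeds["score"]})

        # ---------------------------------------------------------- call
        thr_cfg = calling.ThresholdConfig(
            thresholds={s.name: cfg["auc_threshold"] for s in sigs})
        elig = calling.apply_thresholds(scores, thr_cfg)
        calls = calling.merge_signatures(
            calling.disambiguate_calls(scores, elig), thr_cfg)
        emit(calls.calls, "calls.tsv")

        # --------------------------------------------------- composition
        rng = np.random.default_rng(seeds["composition"])
        n_samples = 8
        sample = pd.Series(rng.integers(0, n_samples, len(calls.calls)),
                           index=calls.calls.index).map(lambda i: f"s{i}")
        cond_of = {f"s{i}": ("A" if i < n_samples // 2 else "B") for i in range(n_samples)}
        comp = composition.aggregate_calls(calls.calls["label"], sample, cond_of)
        refs = [c for c in ("cTEC", "mTEC", "early_progenitor", "postnatal_progenitor",
                            "unassigned") if c in comp.counts.columns][:4]
        consensus = composition.consensus_over_references(
            comp.counts, comp.condition, refs, seed=seeds["composition"],
            n_restarts=2)
        emit(consensus.flags.assign(overall=consensus.overall_changed),
             "composition_consensus.tsv",
             metadata={"final_reference": consensus.final_reference})

        # -------------------------------------------------------- enrich
        late = [p.name for p in pops if p.wave == "late"]
        shifts = {name: {"embryonic": cfg["bulk_shift_log2fc"]} for name in late}
        bulk_cfg = synthetic.SimConfig(n_cells=cfg["n_cells"], n_genes=cfg["n_genes"],
                                       seed=seeds["enrich"], populations=pops)
        counts, meta = synthetic.simulate_bulk(bulk_cfg, ["embryonic", "P28"], shifts,
                                               n_replicates=cfg["n_replicates"])
        kept = bulk_mod.filter_genes(counts)
        y = bulk_mod.logcpm(kept)
        res = bulk_mod.fit_moderated_t(y, meta["condition"], ("embryonic", "P28"))
        tt = res.treat(tau=float(np.log2(cfg["tau_lfc"])))
        enr = bulk_mod.adjust_and_sign(
            bulk_mod.camera_pr(tt["t"], sigs, rho=cfg["rho"]), clip=cfg["clip"])
        emit(enr, "enrichment.tsv")
        heat = build_heatmap({"embryonic_vs_P28": enr}, clip=cfg["clip"])
        emit(heat, "heatmap.tsv")

        # ------------------------------------------------------- lineage
        all_pops = set(truth.cell_labels.unique())
        # one broad clone keeps every population detectable (no separation)
        sharing = [all_pops, {"postnatal_progenitor", "enterohepatic"},
                   {"early_progenitor", "muscle"}, {"mTEC"}]
        bc = synthetic.simulate_barcodes(truth, cfg["n_barcodes"], sharing,
                                         detection_rate=cfg["barcode_detection_rate"],
                                         seed=seeds["lineage"])
        bm = lineage.binarize_barcodes(bc, signature=truth.cell_labels, sample=sample)
        assoc = lineage.test_signature_association(bm)
        emit(lineage.detection_proportions(bm), "lineage_proportions.tsv",
             metadata={"lrt": assoc.lrt, "df": assoc.df, "p": assoc.p})

        # ---------------------------------------------------------- fate
        fate = _fate_stage(adata, scores, truth, cfg, seeds["fate"])
        emit(fate.probabilities, "fate_probabilities.tsv")
        emit(trajectory.fate_overlap_jaccard(fate, threshold=0.5), "fate_jaccard.tsv")

        # --------------------------------------------------------- nadir
        tc = cfg["timecourse"]
        table = synthetic.simulate_timecourse(
            nadir_age=tc["nadir_age"], n_mice=tc["n_mice"], noise_sd=tc["noise_sd"],
            age_range=tuple(tc["age_range"]), seed=seeds["nadir"])
        loess = smoothing.select_span_cv(table["age"], table["ratio"], seed=seeds["nadir"])
        nadir, band = smoothing.find_nadir(loess)
        emit(pd.DataFrame({"nadir_age": [nadir], "band_lo": [band[0]],
                           "band_hi": [band[1]], "span": [loess.span]}),
             "nadir.tsv", index=False)
    except Exception as exc:
        manifest["failed"] = f"{type(exc).__name__}: {exc}"
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _fate_stage(adata, scores, truth, cfg, seed: int):
    """kNN graph on a PCA embedding, pseudotime from the top
    early-progenitor cell, terminals per mimetic population."""
    from sklearn.decomposition import PCA
    from sklearn.neighbors import kneighbors_graph

    X = adata.X
    if hasattr(X, "toarray"):
        X = X.toarray()
    X = np.log1p(X)
    emb = PCA(n_components=min(20, X.shape[1] - 1),
              random_state=seed % (2**31)).fit_transform(X)
    knn = kneighbors_graph(emb, n_neighbors=15, mode="connectivity")
    conn = knn.maximum(knn.T).toarray()
    root = int(np.argmax(scores.auc["early_progenitor"].values))
    pt = trajectory.diffusion_pseudotime(conn, root)
    kernel = trajectory.build_combined_kernel(conn, pt, lambda_=cfg["lambda"])
    # a few well-populated terminal populations
    label_counts = truth.cell_labels.value_counts()
    pops = [p for p in label_counts.index
            if p in scores.auc.columns and p not in ("early_progenitor",)
            and label_counts[p] >= 12][:4]
    terminals = trajectory.select_terminal_cells(scores, pops, n_per=10)
    return trajectory.absorption_probabilities(kernel, terminals,
                                               cell_names=list(scores.auc.index))
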