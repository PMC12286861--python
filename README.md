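# mimetect

Detection and quantification of **thymic mimetic cells** — rare medullary
thymic epithelial cells (mTECs) that transcriptionally imitate peripheral
cell types (muscle, ionocyte, goblet, ciliated, enterohepatic, skin, tuft,
microfold, neuroendocrine, pancreatic, lung-basal) and contribute to central
T-cell tolerance by displaying peripheral self-antigens.

The package is a reusable, tested implementation of the computational
pipeline needed to study these populations across single-cell and bulk
transcriptomes, for immunologists and computational biologists working on
thymic epithelium:

| stage | module | core statistic |
|---|---|---|
| per-cell signature scoring | `mimetect.scoring` | rank-AUC (recovery-curve area within the top-ranked gene fraction) |
| exclusive mimetic calling | `mimetect.calling` | quantile-rank disambiguation with z-score tie-break |
| bulk signature enrichment | `mimetect.bulk` | empirical-Bayes moderated *t* with fold-change threshold; correlation-adjusted competitive set test |
| differential abundance | `mimetect.composition` | Dirichlet-multinomial LRT with multi-reference strict-majority consensus |
| lineage barcodes | `mimetect.lineage` | logistic-regression LRT, exact binomial test, Wilson intervals |
| fate probabilities | `mimetect.trajectory` | diffusion pseudotime + connectivity kernel, absorbing-chain fates |
| droplet QC / clustering | `mimetect.qc` | MAD outlier rules, silhouette-maximizing parameter sweeps |
| time-course smoothing | `mimetect.smoothing` | LOESS with 10-fold-CV span selection and nadir detection |
| synthetic ground truth | `mimetect.synthetic` | NB counts with planted populations, shifts, clones, nadir |

## The statistics in brief

**Rank-AUC score.** Within each cell, genes are ranked by decreasing
expression (seeded jitter on ties). For a signature with n_s measured genes,
K = ⌈top_fraction · G⌉ and recovery curve R(k) = |{g ∈ sig : r_g ≤ k}|,

    AUC = Σ_{k≤K} R(k) / Σ_{k≤K} min(k, n_s) ∈ [0, 1],

i.e. the area under the recovery curve normalized by its maximum, invariant
to any monotone transform of expression.

**Moderated threshold test and competitive enrichment.** Per gene a
two-group fit gives effect b_g, residual variance s²_g on d_g df; variances
are shrunk via the empirical-Bayes prior (d₀, s₀²) estimated by
digamma/trigamma moment matching, s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g).
Against the threshold null |b| ≤ τ (default τ = log₂ 1.2), with se = s̃·u,
p = P(T > (|b|−τ)/se) + P(T > (|b|+τ)/se) on d₀+d_g df. Signatures are then
tested competitively: the mean in-set statistic versus the out-set mean with
variance inflation VIF = 1 + (m−1)ρ for inter-gene correlation ρ, referred
to t on G−2 df, BH-adjusted, and reported as signed log₁₀(adj p) — positive
for enrichment, negative for depletion, clipped for display.

**Compositional consensus.** Cell-type counts per sample follow a
Dirichlet-multinomial with composition softmax(α_k + β_k·condition), one
reference type fixed at zero, common precision γ. Each non-reference type's
β is tested by likelihood-ratio against the constrained refit (BH, FDR
0.05). The model is refitted once per candidate reference and a type is
*overall changed* only when a strict majority of fits flag it.

**Fate probabilities.** A random walk on the kNN connectivity graph is
biased along diffusion pseudotime by a logistic gate, mixed with the
undirected walk (P = λ·P_pt + (1−λ)·P_conn), terminal cells (top signature
AUC per population) are made absorbing, and (I − Q)F = R gives each
transient cell's absorption probability per terminal population.

## Worked example

```python
import numpy as np
from mimetect import synthetic, scoring, calling, bulk, smoothing

# 1. simulate a small thymic epithelial dataset with planted mimetic populations
cfg = synthetic.SimConfig(n_cells=3000, n_genes=2000, seed=1)
adata, truth = synthetic.simulate_single_cell(cfg)
sigs = synthetic.population_signatures(cfg.populations)

# 2. score every signature per cell and call mimetic cells
ranks = scoring.rank_genes_per_cell(adata, tie_seed=1)
scores = scoring.score_signatures(ranks, sigs)
thr = calling.ThresholdConfig(thresholds={s.name: 0.30 for s in sigs})
calls = calling.disambiguate_calls(scores, calling.apply_thresholds(scores, thr))
print(calls.counts().head(8))

# 3. bulk contrast with a planted depletion of the enterohepatic signature
counts, meta = synthetic.simulate_bulk(cfg, ["embryonic", "P28"],
                                       {"enterohepatic": {"embryonic": -1.5}},
                                       n_replicates=3)
y = bulk.logcpm(bulk.filter_genes(counts))
res = bulk.fit_moderated_t(y, meta["condition"], ("embryonic", "P28"))
enr = bulk.adjust_and_sign(bulk.camera_pr(res.treat()["t"], sigs), clip=10)
print(enr.loc[["enterohepatic", "muscle"], ["direction", "adj_p", "clipped"]])

# 4. cTEC/mTEC ratio time course: CV span selection and nadir
tc = synthetic.simulate_timecourse(nadir_age=21.0, n_mice=60, noise_sd=0.2, seed=1)
fit = smoothing.select_span_cv(tc["age"], tc["ratio"], seed=1)
nadir, band = smoothing.find_nadir(fit)
print(f"selected span {fit.span:.2f}; nadir at {nadir:.1f} days")
```

This prints:

```
label
unassigned              1593
postnatal_progenitor     388
cTEC                     313
mTEC                     272
early_progenitor         122
muscle                    60
ionocyte                  36
enterohepatic             36
Name: count, dtype: int64
              direction     adj_p    clipped
name
enterohepatic      down  0.000000 -10.000000
muscle               up  0.906415   0.042673
selected span 0.40; nadir at 20.5 days
```

Reading the output: the caller assigns each cell at most one label (most
cells are canonical TEC compartments or unassigned; the planted rare
mimetic populations are recovered at their simulated frequencies). In the
bulk contrast the planted −1.5 log₂FC on the enterohepatic signature shows
up as strong depletion (clipped signed log p of −10) while the unshifted
muscle signature stays near zero. The time-course stage re-finds the
planted ratio minimum at ≈ day 21 — the transition age between
early-progenitor and postnatal-progenitor dominance.

A thin CLI mirrors the library (`mimetect simulate|score|call|enrich|
composition|lineage|nadir|report|pipeline`); `mimetect pipeline --out DIR`
runs the full synthetic workflow and writes a manifest with per-stage seeds
and output hashes for bit-reproducibility.

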