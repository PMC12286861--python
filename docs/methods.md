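# Methods

This note documents the models and procedures implemented in `mimetect`,
the parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was open.

## Scope and shape

The package covers the downstream computational stages of a mimetic-cell
study: everything from a count matrix (single-cell/nucleus UMI or bulk) to
called populations, enrichment heat maps, abundance tests, lineage
statistics, fate probabilities and time-course smoothing. Upstream
processing (alignment, counting, ambient-RNA removal, doublet detection,
data integration) is out of scope; inputs are assumed to be clean count
tables. Most stages are deterministic transforms and are exposed as
functions; the four genuinely model-like analyses are exposed as
model/results pairs in the style of statsmodels (`ModeratedContrast` →
`ModeratedContrastResults`, `DirichletMultinomialDA` →
`CompositionResults`, `BarcodeAssociation` → `AssociationResults`,
`LoessCV` → `LoessResults`), each with estimates, uncertainties and a
`summary()`.

## Rank-AUC signature scoring (`scoring`)

Genes are ranked per cell by decreasing expression. Ties — ubiquitous in
sparse UMI data — are broken by seeded uniform jitter, so tied genes
receive a random permutation of the tied rank range and reruns with the
same seed are bit-identical. Average-rank tie handling was rejected because
it breaks the permutation semantics the recovery-curve formula assumes.

The score of signature *S* in a cell is the area under the recovery curve
R(k) = |{g ∈ S : r_g ≤ k}| for k = 1..K, K = ⌈top_fraction·G⌉, normalized
by the maximal achievable area (all n_s measured signature genes in the top
ranks). The implementation uses the telescoped form
Σ_g max(0, K − r_g + 1); tests verify exact agreement with an explicit
enumeration of R(k).

Parameters: `top_fraction` (default 0.05, dimensionless) controls how deep
into the ranking the curve is integrated. Results are sensitive to it, so
it is recorded in all outputs. Z-standardization uses the population
(1/n) standard deviation; the choice only rescales, never reorders, and is
stated here because both conventions are common.

## Calling (`calling`)

Thresholds are deliberately manual (per-signature minimum AUC, closed
boundary `≥`), supported by a histogram helper (`auc_histograms`);
automatic bimodality-based thresholding is intentionally not provided. A
cell eligible for several signatures is assigned to the one where it sits
furthest right in that signature's AUC distribution, formalized as the
quantile rank (fraction of all cells with strictly smaller AUC) — the only
formalization that makes positions comparable across signatures with
different score scales. Exact quantile ties fall back to the larger
z-standardized AUC, then to lexical name order with a log entry, making
runs reproducible. Quantiles are computed over **all** cells, not only
eligible ones. Overlapping sister signatures (e.g. two tuft-cell programs,
basal vs keratinized skin) are collapsed after calling via configured merge
groups; merging conserves cell counts.

## Bulk enrichment (`bulk`)

Gene filter: count strictly greater than 5 in at least half of all samples
(all samples jointly, not per condition). Expression is log2-CPM with a 0.5
prior count. Mean-variance precision weights are not applied: the
competitive test consumes ranking statistics, whose ordering the weights
barely move at the replicate numbers used here (2–15 per group), and
omitting them keeps the per-gene model a plain two-group fit. The
winsorized ("robust") variant of the variance prior is likewise not
implemented — the standard moment-matching estimator is used.

Variance moderation follows the scaled-F model: s² ~ s₀²·F(d, d₀), with
(d₀, s₀²) estimated by matching moments of log s² through digamma/trigamma
inversion (Newton iteration for the trigamma inverse). No excess spread in
log s² yields d₀ = ∞ (capped at 10⁷ for df arithmetic, logged). The
threshold test uses τ = log₂(1.2) ≈ 0.263 by default; at τ = 0 it reduces
to the ordinary two-sided moderated t. The reported statistic is
sign(b)·max(t_r, 0) — genes inside the threshold band carry statistic 0 —
matching the reference implementation bit-for-bit (verified against
R/limma in the test suite on a shared fixture).

The competitive test compares in-set vs out-set mean statistics with
pooled within-group variance on G−2 df and variance inflation
VIF = 1 + (m−1)ρ; ρ defaults to 0.01 and is configurable. At ρ = 0 the
test is exactly the pooled two-sample t-test. BH adjustment spans all
signatures (canonical + mimetic + background) tested in one contrast,
matching joint heat-map reporting. Signed values are log₁₀(adj p) with a
sign making enrichment positive; the display clip limit is a parameter
(`--clip`, default 10) since no canonical value exists.

Background signatures for the competitive test are size-matched: candidates
are kept when their size lies in the closed interval
[(1−slack)·min focal, (1+slack)·max focal], slack 0.10. Whether candidates
should first be intersected with the measured gene universe is genuinely
ambiguous; intersection happens only when a universe is passed explicitly.

## Composition (`composition`)

The Bayesian spike-and-slab sampler used in the original scCODA approach
is deliberately replaced by a maximum-likelihood Dirichlet-multinomial:
composition softmax(α_k + β_k·x) with the reference type's parameters fixed
at zero and a common precision γ; β_k is tested by likelihood-ratio against
the constrained refit, χ²₁, BH across types, flagged at FDR 0.05 (the
credibility level of the original is unstated; 0.05 is configurable). The
reference-logic is preserved exactly: one fit per candidate reference,
*overall changed* only under a strict majority of flags, and the final
reference is the fit with the fewest flagged types (ties lexical, logged).
Optimization is L-BFGS on (α, β, log γ) with an empirical-proportion
initialization and seeded random restarts (5 by default); permutation
experiments in the test suite show the LRT p-values are uniform on null
data (KS distance ≈ 0.02–0.08 at the study's sample sizes).

## Lineage (`lineage`)

Barcode tables are binarized (count > 0). The association model is a
logistic regression of the per-cell "any barcode detected" indicator
(default; a per-barcode outcome is available for shared-clone analyses) on
categorical signature + sample, fitted by IRLS with step-halving
(deviance tolerance 1e-8, max 100 iterations), compared against the
sample-only model by χ² LRT on (levels − 1) df. Apparent complete
separation (diverging coefficients) raises an error advising the small
ridge stabilization flag rather than silently returning an unstable fit.
The fit is verified against an independent GLM implementation in the
tests. The two-proportion comparison is the exact conditional binomial
test with the minimum-likelihood two-sided rule. Wilson score intervals
are the default; the boundary-adjusted variant for extreme proportions is
behind `brown_adjust=True`.

## Trajectory (`trajectory`)

Pseudotime is the diffusion distance to a chosen root (the cell with the
highest early-progenitor AUC, in the pipeline), computed from the
eigendecomposition of the symmetrized random-walk operator with weights
λ/(1−λ) per nontrivial component (15 components by default). Macrostate
estimation is out of scope; terminal cells are selected explicitly as the
`n_per` top-AUC cells per terminal population, with overlaps between
populations treated as errors rather than resolved silently.

The transition kernel mixes a soft-directed pseudotime kernel with the
undirected connectivity kernel, P = λ·P_pt + (1−λ)·P_conn (λ default 0.8).
Soft logistic directionality (gate σ(κ·Δt), κ defaulting to the inverse
median absolute neighbour pseudotime difference) was chosen over hard
forward-masking to keep the chain irreducible enough for absorption; each
cell also carries a self-loop at the gate's neutral value. Fate
probabilities solve the absorbing-chain system (I−Q)F = R directly (dense
solve; exact to the gambler's-ruin closed form at 1e-8 in tests). Only
terminal populations appear as fate columns — intermediate states are
never retained by construction. Fate overlap uses the Jaccard index of
cells above a fate-probability threshold (default 0.5, configurable; above
0.5 off-diagonal overlap is impossible by pigeonhole, so smaller values
are the informative regime).

## QC and clustering selection (`qc`)

Droplets are excluded on: total UMI < 500 (strict), mitochondrial fraction
> 5% (strict), detected genes beyond 1 MAD from the median, or complexity
(genes per UMI) beyond 3 MADs. The MAD is raw (unscaled) by default — the
rules quote plain MADs — with the 1.4826 consistency factor behind a flag.
Medians and MADs are computed per sample when a sample column is present,
since depth differences between libraries would otherwise dominate the
rules. Note the 1-MAD genes rule is intentionally strict: on wide
distributions it removes roughly half the tail mass.

Clustering parameters are selected by maximizing mean silhouette width in
the embedding (Euclidean); within-cluster sum of squares is reported
alongside for subcluster decisions. The clustering algorithm itself is
pluggable — any parameter → labels mapping — because the selection
criterion, not the clusterer, is the defined computation.

## Time-course smoothing (`smoothing`)

Local linear regression with tricube weights over the ⌈span·n⌉ nearest
points (degree 2 optional). The span is selected on the grid 0.40–0.90 in
steps of 0.01 by 10-fold cross-validation with a seeded random partition;
ties (to numerical precision) take the smaller span. Held-out points
falling outside a fold's training range are predicted by the local
polynomial of the nearest boundary neighbourhood rather than clamped,
which keeps CV unbiased on polynomial data. The nadir is the argmin of the
fitted curve on a 0.25-day grid; the pointwise 95% band comes from the
linear-smoother variance (fit = l(x)'y ⇒ var = σ̂²‖l(x)‖², σ̂² on
n − tr(L) df); a bootstrap band is not provided. The fit matches an
independent reference lowess implementation to ~1e-10 on shared fixtures.
Local linear fits are biased upward at a sharp minimum, so the band covers
the fitted curve, not necessarily the true minimum value.

## Synthetic data (`synthetic`)

The generator provides planted ground truth for every stage, not fixtures:

- **Single cell**: negative-binomial counts (mean/size parameterization,
  dispersion 2), gamma-distributed baseline gene means (mean 0.5/gene),
  lognormal per-cell library factors (σ 0.35). The default design is 4
  canonical TEC populations (early/postnatal progenitors, cTEC, mTEC,
  together ~90% of cells) plus the 11 mimetic types at 0.5–2% each —
  frequencies are not published, so these are defaults chosen to be rare
  but recoverable, and fully configurable. Mimetic markers are 30
  disjoint genes at +4 log₂FC (sharply restricted peripheral programs);
  canonical markers +2.5. Populations carry an early/late *wave* tag so
  that time-point constructions can mirror the two successive waves in
  which mimetic types arise (muscle/ionocyte/goblet/ciliated before
  birth; enterohepatic/skin and others postnatally).
- **Bulk**: the population-frequency-weighted mixture of the single-cell
  profiles, NB-sampled at 10× lower dispersion, with per-signature,
  per-condition log₂FC shifts applied multiplicatively.
- **Barcodes**: clones are population sets; a barcode is present only in
  its clone's populations, thinned by a detection rate (optionally
  per-population).
- **Time course**: ratio(age) = baseline + depth·((age − nadir)/scale)²
  with scale the start-to-nadir distance, so the ratio falls by the full
  depth from age 0 to the nadir (defaults: baseline 0.6, depth 2, nadir
  day 21 in 0–56 days) and rebounds more steeply after — the prominent
  perinatal-high / third-week-low morphology of the measured cTEC/mTEC
  ratio — plus Gaussian noise.

Not emulated: ambient RNA, doublets, batch effects, gene–gene correlation
beyond population structure, UMI saturation. Tests passing on this
generator therefore demonstrate correctness of the statistics and
recoverability of planted effects under clean NB noise — not robustness to
the artefacts that the out-of-scope preprocessing tools exist to remove.

## Problem sizes and determinism

The test and acceptance runs use deliberately compact sizes chosen to
exercise every claim while staying cheap: 5,000 cells × 2,000 genes for
planted-recovery calling, 20 null bulk simulations of 1,200 genes, 200
permutations × 4 types for composition calibration, 200 replicates for
lineage calibration, 50 seeds for nadir recovery, 1,000 random instances
for the AUC oracle. One global seed expands into per-stage substreams
(`pipeline.derive_seeds`, SeedSequence-based, values < 2³¹); every
stochastic step consumes an explicit seed and reruns are bit-identical,
which the pipeline manifest (output SHA-256 hashes) makes checkable.

## Known limitations

- The Dirichlet-multinomial consensus is a frequentist analog, not a
  reimplementation, of the spike-and-slab original; borderline shifts can
  be flagged by only a subset of references (the strict majority rule is
  then conservative by design).
- LOESS span selection on noisy short series is itself noisy; the selected
  span should be read together with its CV-MSE profile, and the nadir with
  its band.
- The logistic association model assumes independent cells; clonal
  correlation within barcodes is not modelled (the per-barcode outcome
  mode mitigates this for single-clone questions).
- `camera`-style competitive tests treat the inter-gene correlation ρ as a
  constant; it is a parameter here, not an estimate.
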