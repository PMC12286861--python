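"""Synthetic data with planted ground truth.

Every downstream stage of the pipeline is testable without downloads: this
module generates UMI count matrices with canonical TEC populations plus
rare planted mimetic populations, bulk count tables with condition-specific
signature shifts, clonal barcode-presence tables, droplet QC covariates and
a cTEC/mTEC-ratio time course with a known nadir.

Counts are negative-binomial in the mean/size parameterization with a
per-cell lognormal library factor (the standard UMI noise model); marker
genes act multiplicatively on the mean.  Populations carry a *wave* tag
(early = present before birth, late = postnatal only) so that simulated
time points can mirror the two successive waves in which mimetic cell
types appear during development.  One seed makes every generator
bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from anndata import AnnData

from mimetect.signatures import GeneSignature

__all__ = ["PopulationSpec", "SimConfig", "SimTruth", "default_populations",
           "simulate_single_cell", "simulate_bulk", "simulate_barcodes",
           "simulate_timecourse", "population_signatures"]

CANONICAL = ("early_progenitor", "postnatal_progenitor", "cTEC", "mTEC")
EARLY_WAVE = ("muscle", "ionocyte", "goblet", "ciliated")
LATE_WAVE = ("enterohepatic", "skin", "tuft", "microfold", "neuroendocrine",
             "pancreatic", "lung_basal")
MIMETIC = EARLY_WAVE + LATE_WAVE


@dataclass(frozen=True)
class PopulationSpec:
    """One simulated cell population.

    ``frequency`` is the fraction of cells, ``marker_genes`` the genes whose
    negative-binomial mean is elevated by ``2**marker_log2fc`` in member
    cells, and ``wave`` tags whether the population is present at early
    (embryonic) time points or only late (postnatal).
    """

    name: str
    frequency: float
    marker_genes: tuple
    marker_log2fc: float = 4.0
    wave: str = "early"

    def __post_init__(self):
        if not (0.0 < self.frequency <= 1.0):
            raise ValueError(f"{self.name}: frequency must be in (0, 1]")
        if not self.marker_genes:
            raise ValueError(f"{self.name}: marker_genes must be non-empty")
        if self.marker_log2fc < 0:
            raise ValueError(f"{self.name}: marker_log2fc must be >= 0")
        if self.wave not in ("early", "late"):
            raise ValueError(f"{self.name}: wave must be 'early' or 'late'")


@dataclass
class SimConfig:
    """Global simulation settings.

    ``dispersion`` is the negative-binomial size parameter (smaller = more
    overdispersed); ``library_size_spread`` the sigma of the lognormal
    per-cell library factor.
    """

    n_cells: int = 5000
    n_genes: int = 2000
    baseline_mean: float = 0.5
    dispersion: float = 2.0
    library_size_spread: float = 0.35
    seed: int = 0
    populations: list = field(default_factory=list)

    def __post_init__(self):
        if self.n_cells <= 0 or self.n_genes <= 0:
            raise ValueError("counts must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        if self.populations:
            total = sum(p.frequency for p in self.populations)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"population frequencies sum to {total}, not 1")
            names = [p.name for p in self.populations]
            if len(set(names)) != len(names):
                raise ValueError("duplicate population names")


@dataclass
class SimTruth:
    """Planted ground truth accompanying a simulated dataset."""

    cell_labels: pd.Series | None = None
    barcode_clones: dict = field(default_factory=dict)
    bulk_shifts: dict = field(default_factory=dict)
    nadir_age: float | None = None


def default_populations(n_genes: int = 2000, n_markers: int = 30,
                        mimetic_log2fc: float = 4.0,
                        canonical_log2fc: float = 2.5) -> list[PopulationSpec]:
    """The default study design: 4 canonical TEC populations plus the 11
    mimetic cell types at rare (0.5-2%) frequencies.

    Marker blocks are disjoint gene ranges.  Mimetic markers are strongly
    population-specific (log2FC 4 by default), canonical markers broader
    and weaker, mirroring the contrast between compartment programmes and
    the sharply restricted peripheral-tissue programmes of mimetic cells.
    """
    mimetic_freq = {
        "muscle": 0.020, "ionocyte": 0.012, "goblet": 0.010, "ciliated": 0.008,
        "enterohepatic": 0.012, "skin": 0.010, "tuft": 0.009, "microfold": 0.007,
        "neuroendocrine": 0.006, "pancreatic": 0.005, "lung_basal": 0.005,
    }
    canonical_freq = {"early_progenitor": 0.18, "postnatal_progenitor": 0.22,
                      "cTEC": 0.26, "mTEC": 0.236}
    need = (len(mimetic_freq) + len(canonical_freq)) * n_markers
    if need > n_genes:
        raise ValueError(f"{n_genes} genes cannot host {need} marker genes")
    specs = []
    cursor = 0
    for name, freq in {**canonical_freq, **mimetic_freq}.items():
        markers = tuple(f"g{cursor + i}" for i in range(n_markers))
        cursor += n_markers
        specs.append(PopulationSpec(
            name=name, frequency=freq, marker_genes=markers,
            marker_log2fc=canonical_log2fc if name in CANONICAL else mimetic_log2fc,
            wave="late" if name in LATE_WAVE or name == "postnatal_progenitor" else "early",
        ))
    total = sum(p.frequency for p in specs)
    assert abs(total - 1.0) < 1e-9, total
    return specs


def population_signatures(populations: list[PopulationSpec]) -> list[GeneSignature]:
    """Marker gene sets of the simulated populations, as signatures."""
    return [GeneSignature(name=p.name, genes=frozenset(p.marker_genes),
                          klass="canonical" if p.name in CANONICAL else "mimetic")
            for p in populations]


def _gene_names(n_genes: int) -> np.ndarray:
    return np.array([f"g{i}" for i in range(n_genes)])


def simulate_single_cell(config: SimConfig) -> tuple[AnnData, SimTruth]:
    """Simulate a cells x genes UMI matrix with planted populations.

    Returns an :class:`anndata.AnnData` (integer counts, ``obs['population']``)
    and the :class:`SimTruth` with per-cell labels.  The same seed gives
    bit-identical output.  A population whose expected cell count is below 1
    is an error naming it.
    """
    pops = config.populations or default_populations(config.n_genes)
    config.populations = pops          # materialize the design on the config
    cfg = SimConfig(**{**config.__dict__, "populations": pops})
    rng = np.random.default_rng(cfg.seed)
    for p in pops:
        if p.frequency * cfg.n_cells < 1.0:
            raise ValueError(f"population {p.name!r}: expected cell count "
                             f"{p.frequency * cfg.n_cells:.2f} < 1")
    genes = _gene_names(cfg.n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    # heterogeneous baseline means (gamma-shaped, as in real UMI data)
    base = cfg.baseline_mean * rng.gamma(shape=1.5, scale=1.0 / 1.5, size=cfg.n_genes)
    base = np.maximum(base, 1e-3)
    # deterministic label assignment by frequency, then shuffled
    counts_per_pop = np.floor(np.array([p.frequency for p in pops]) * cfg.n_cells).astype(int)
    remainder = cfg.n_cells - counts_per_pop.sum()
    frac = np.array([p.frequency for p in pops]) * cfg.n_cells - counts_per_pop
    for i in np.argsort(-frac)[:remainder]:
        counts_per_pop[i] += 1
    labels = np.repeat([p.name for p in pops], counts_per_pop)
    rng.shuffle(labels)
    lib = np.exp(rng.normal(0.0, cfg.library_size_spread, size=cfg.n_cells))
    mean_by_pop = {}
    for p in pops:
        mu = base.copy()
        idx = [gene_pos[g] for g in p.marker_genes if g in gene_pos]
        if len(idx) < len(p.marker_genes):
            missing = set(p.marker_genes) - set(genes)
            raise ValueError(f"population {p.name!r} markers not in gene universe: "
                             f"{sorted(missing)[:5]}")
        mu[idx] *= 2.0 ** p.marker_log2fc
        mean_by_pop[p.name] = mu
    mu_cells = np.stack([mean_by_pop[lab] for lab in labels]) * lib[:, None]
    r = cfg.dispersion
    X = rng.negative_binomial(r, r / (r + mu_cells))
    cells = np.array([f"cell{i}" for i in range(cfg.n_cells)])
    adata = AnnData(X=X, obs=pd.DataFrame({"population": labels}, index=cells),
                    var=pd.DataFrame(index=genes))
    truth = SimTruth(cell_labels=pd.Series(labels, index=cells, name="population"))
    return adata, truth


def simulate_bulk(config: SimConfig, conditions: list[str], shifts: dict,
                  n_replicates: int = 3, signatures: list[GeneSignature] | None = None,
                  target_libsize: float = 2e6) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a genes x samples bulk count table with signature shifts.

    ``shifts`` maps signature name -> {condition: log2fc}; signature genes
    in a shifted condition have their expected counts scaled by 2**log2fc.
    Signatures default to the marker sets of ``config.populations``.  Genes
    named in a shift that are absent from the gene universe raise an error
    listing them.

    Returns ``(counts, metadata)`` with metadata columns ``sample`` and
    ``condition``.
    """
    if n_replicates < 2:
        raise ValueError("need n_replicates >= 2 per condition")
    pops = config.populations or default_populations(config.n_genes)
    if signatures is None:
        signatures = population_signatures(pops)
    sig_by_name = {s.name: s for s in signatures}
    genes = _gene_names(config.n_genes)
    universe = set(genes)
    for sig_name in shifts:
        if sig_name not in sig_by_name:
            raise KeyError(f"shift for unknown signature {sig_name!r}")
        missing = sorted(set(sig_by_name[sig_name].genes) - universe)
        if missing:
            raise ValueError(f"signature {sig_name!r} genes not in universe: {missing[:10]}")
    rng = np.random.default_rng(config.seed)
    base = config.baseline_mean * rng.gamma(shape=1.5, scale=1.0 / 1.5, size=config.n_genes)
    base = np.maximum(base, 1e-3)
    # bulk TEC profile: populations contribute proportionally to frequency
    profile = np.zeros(config.n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for p in pops:
        mu = base.copy()
        idx = [gene_pos[g] for g in p.marker_genes]
        mu[idx] *= 2.0 ** p.marker_log2fc
        profile += p.frequency * mu
    data = {}
    meta = []
    r = config.dispersion * 10.0   # bulk is much less dispersed than single cells
    for cond in conditions:
        mu_cond = profile.copy()
        for sig_name, per_cond in shifts.items():
            if not isinstance(per_cond, dict):
                raise TypeError("shifts must map signature -> {condition: log2fc}")
            lfc = float(per_cond.get(cond, 0.0))
            if lfc != 0.0:
                idx = [gene_pos[g] for g in sig_by_name[sig_name].genes]
                mu_cond[idx] = mu_cond[idx] * 2.0 ** lfc
        mu_cond = mu_cond / mu_cond.sum() * target_libsize
        for rep in range(n_replicates):
            lib = math.exp(rng.normal(0.0, config.library_size_spread))
            mu = mu_cond * lib
            name = f"{cond}_rep{rep + 1}"
            data[name] = rng.negative_binomial(r, r / (r + mu))
            meta.append({"sample": name, "condition": cond})
    counts = pd.DataFrame(data, index=genes)
    return counts, pd.DataFrame(meta).set_index("sample")


def simulate_barcodes(truth: SimTruth, n_barcodes: int, sharing: list,
                      detection_rate: float = 1.0, seed: int = 0,
                      detection_by_population: dict | None = None) -> pd.DataFrame:
    """Clonal barcode presence: each barcode belongs to a clone spanning a
    set of populations and appears only in cells of those populations,
    thinned by the detection rate.

    ``sharing`` is a list of population sets; barcodes cycle through it.
    ``detection_by_population`` optionally overrides the global detection
    rate per population (for planting detection differences).
    """
    if truth.cell_labels is None:
        raise ValueError("truth has no cell labels")
    if not (0.0 < detection_rate <= 1.0):
        raise ValueError("detection_rate must be in (0, 1]")
    labels = truth.cell_labels
    known = set(labels.unique())
    for clone in sharing:
        unknown = set(clone) - known
        if unknown:
            raise ValueError(f"sharing set references unknown population(s): {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    presence = np.zeros((len(labels), n_barcodes), dtype=int)
    clones = {}
    for b in range(n_barcodes):
        clone = set(sharing[b % len(sharing)])
        clones[f"bc{b}"] = sorted(clone)
        member = labels.isin(clone).values
        if detection_by_population:
            rate = labels.map(lambda l: detection_by_population.get(l, detection_rate)).values
        else:
            rate = np.full(len(labels), detection_rate)
        detected = member & (rng.random(len(labels)) < rate)
        presence[detected, b] = 1
    truth.barcode_clones = clones
    return pd.DataFrame(presence, index=labels.index,
                        columns=[f"bc{b}" for b in range(n_barcodes)])


def simulate_timecourse(nadir_age: float = 21.0, n_mice: int = 60,
                        noise_sd: float = 0.2, age_range: tuple = (0.0, 56.0),
                        seed: int = 0, depth: float = 2.0,
                        baseline: float = 0.6) -> pd.DataFrame:
    """cTEC/mTEC ratio over age: a smooth convex curve with its minimum at
    ``nadir_age`` plus Gaussian noise.

    The expected curve is ``baseline + depth * ((age - nadir) / scale)**2``
    with ``scale`` the distance from the range start to the nadir, so the
    ratio falls by the full ``depth`` from age 0 to its minimum and rebounds
    more steeply afterwards -- the prominent perinatal-high / third-week-low
    shape of the measured ratio.  Needs at least 10 mice (fewer leaves no
    room for cross-validation).
    """
    lo, hi = age_range
    if not (lo <= nadir_age <= hi):
        raise ValueError("nadir_age must lie inside age_range")
    if n_mice < 10:
        raise ValueError("need at least 10 mice for cross-validated smoothing")
    rng = np.random.default_rng(seed)
    ages = np.sort(rng.uniform(lo, hi, size=n_mice))
    scale = nadir_age - lo if nadir_age > lo else hi - nadir_age
    expected = baseline + depth * ((ages - nadir_age) / scale) ** 2
    ratio = expected + rng.normal(0.0, noise_sd, size=n_mice)
    return pd.DataFrame({"age": ages, "ratio": ratio})


def simulate_qc_covariates(n_droplets: int = 2000, seed: int = 0,
                           frac_low_umi: float = 0.05, frac_high_mito: float = 0.05,
                           n_samples: int = 2) -> pd.DataFrame:
    """Droplet QC covariates with planted failure modes.

    Most droplets are healthy nuclei; small planted fractions have low
    total UMI or high mitochondrial content.
    """
    rng = np.random.default_rng(seed)
    total = np.exp(rng.normal(8.5, 0.4, size=n_droplets)).astype(int) + 1
    mito = rng.beta(2, 120, size=n_droplets)
    detected = (total * rng.beta(30, 20, size=n_droplets)).astype(int) + 1
    low = rng.random(n_droplets) < frac_low_umi
    total[low] = rng.integers(50, 450, size=low.sum())
    detected[low] = np.minimum(detected[low], total[low])
    high = rng.random(n_droplets) < frac_high_mito
    mito[high] = rng.uniform(0.10, 0.6, size=high.sum())
    sample = rng.integers(0, n_samples, size=n_droplets)
    return pd.DataFrame({
        "total_umi": total, "mito_frac": mito,
        "detected_genes": np.minimum(detected, total),
        "sample": [f"s{k}" for k in sample],
        "planted_fail": low | high,
    }, index=[f"d{i}" for i in range(n_droplets)])
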