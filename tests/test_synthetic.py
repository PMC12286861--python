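import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mimetect.synthetic import (
    PopulationSpec,
    SimConfig,
    default_populations,
    simulate_barcodes,
    simulate_bulk,
    simulate_single_cell,
    simulate_timecourse,
)


def _one_pop_config(n_cells=400, n_genes=200, log2fc=0.0, seed=0):
    pop = PopulationSpec(name="only", frequency=1.0,
                         marker_genes=tuple(f"g{i}" for i in range(10)),
                         marker_log2fc=log2fc)
    return SimConfig(n_cells=n_cells, n_genes=n_genes, seed=seed, populations=[pop])


class TestSingleCell:
    def test_same_seed_bit_identical(self):
        cfg = _one_pop_config(seed=7)
        a, _ = simulate_single_cell(cfg)
        b, _ = simulate_single_cell(_one_pop_config(seed=7))
        assert np.array_equal(a.X, b.X)
        c, _ = simulate_single_cell(_one_pop_config(seed=8))
        assert not np.array_equal(a.X, c.X)

    def test_counts_are_nonnegative_integers(self):
        adata, _ = simulate_single_cell(_one_pop_config())
        X = np.asarray(adata.X)
        assert np.all(X >= 0) and np.all(X == X.astype(int))

    def test_null_effect_leaves_markers_flat(self):
        adata, _ = simulate_single_cell(_one_pop_config(log2fc=0.0, seed=1))
        X = np.asarray(adata.X, dtype=float)
        marker_mean = X[:, :10].mean()
        rest_mean = X[:, 10:].mean()
        # markers share the baseline's gamma-mean distribution: same order
        assert marker_mean == pytest.approx(rest_mean, rel=0.5)

    def test_realized_marker_elevation_near_target(self):
        pops = [
            PopulationSpec(name="big", frequency=0.7,
                           marker_genes=tuple(f"g{i}" for i in range(20)),
                           marker_log2fc=3.0),
            PopulationSpec(name="other", frequency=0.3,
                           marker_genes=tuple(f"g{i}" for i in range(20, 40)),
                           marker_log2fc=0.0),
        ]
        cfg = SimConfig(n_cells=2000, n_genes=300, seed=2, populations=pops)
        adata, truth = simulate_single_cell(cfg)
        X = np.asarray(adata.X, dtype=float)
        members = (truth.cell_labels == "big").values
        assert members.sum() >= 200
        mean_in = X[members][:, :20].mean(axis=0) + 1e-6
        mean_out = X[~members][:, :20].mean(axis=0) + 1e-6
        realized = np.log2(mean_in.sum() / mean_out.sum())
        assert realized == pytest.approx(3.0, abs=0.3)

    def test_every_cell_labelled(self):
        adata, truth = simulate_single_cell(_one_pop_config())
        assert truth.cell_labels.notna().all()
        assert len(truth.cell_labels) == adata.n_obs

    def test_vanishing_population_rejected(self):
        pops = [PopulationSpec(name="a", frequency=0.999, marker_genes=("g0",)),
                PopulationSpec(name="tiny", frequency=0.001, marker_genes=("g1",))]
        cfg = SimConfig(n_cells=100, n_genes=10, seed=0, populations=pops)
        with pytest.raises(ValueError, match="tiny"):
            simulate_single_cell(cfg)

    def test_frequencies_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            SimConfig(populations=[PopulationSpec(name="a", frequency=0.5,
                                                  marker_genes=("g0",))])

    def test_default_design_has_fifteen_populations(self):
        pops = default_populations(2000)
        assert len(pops) == 15
        mimetic = [p for p in pops if p.name not in
                   ("early_progenitor", "postnatal_progenitor", "cTEC", "mTEC")]
        assert len(mimetic) == 11
        assert all(0.005 <= p.frequency <= 0.02 for p in mimetic)


class TestBulk:
    def test_empty_shifts_is_valid_null(self):
        cfg = _one_pop_config()
        counts, meta = simulate_bulk(cfg, ["A", "B"], {}, n_replicates=3)
        assert counts.shape == (200, 6)
        assert set(meta["condition"]) == {"A", "B"}

    def test_seed_determinism(self):
        cfg = _one_pop_config(seed=7)
        a, _ = simulate_bulk(cfg, ["A"], {}, n_replicates=2)
        b, _ = simulate_bulk(_one_pop_config(seed=7), ["A"], {}, n_replicates=2)
        assert a.equals(b)

    def test_shifted_signature_scales_expected_counts(self):
        cfg = _one_pop_config(n_cells=1000, seed=3)
        shifted, _ = simulate_bulk(cfg, ["A", "B"], {"only": {"B": 1.0}},
                                   n_replicates=6, target_libsize=5e6)
        marker = [f"g{i}" for i in range(10)]
        a_cols = [c for c in shifted.columns if c.startswith("A")]
        b_cols = [c for c in shifted.columns if c.startswith("B")]
        # compare marker share of the library between conditions
        share_a = shifted.loc[marker, a_cols].sum().sum() / shifted[a_cols].sum().sum()
        share_b = shifted.loc[marker, b_cols].sum().sum() / shifted[b_cols].sum().sum()
        assert share_b / share_a == pytest.approx(2.0, rel=0.25)

    def test_unknown_signature_rejected(self):
        with pytest.raises(KeyError, match="ghost"):
            simulate_bulk(_one_pop_config(), ["A"], {"ghost": {"A": 1.0}}, 2)

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            simulate_bulk(_one_pop_config(), ["A"], {}, n_replicates=1)


class TestBarcodes:
    def _truth(self):
        cfg = _one_pop_config()
        pops = [PopulationSpec(name="x", frequency=0.5, marker_genes=("g0",)),
                PopulationSpec(name="y", frequency=0.5, marker_genes=("g1",))]
        cfg = SimConfig(n_cells=400, n_genes=10, seed=0, populations=pops)
        _, truth = simulate_single_cell(cfg)
        return truth

    def test_full_detection_covers_clone_populations(self):
        truth = self._truth()
        bc = simulate_barcodes(truth, 3, [{"x", "y"}], detection_rate=1.0, seed=1)
        assert (bc.sum(axis=1) == 3).all()

    def test_barcode_confined_to_clone(self):
        truth = self._truth()
        bc = simulate_barcodes(truth, 2, [{"x"}], detection_rate=1.0, seed=1)
        in_y = truth.cell_labels == "y"
        assert bc.loc[in_y.values].values.sum() == 0

    def test_detection_rate_within_binomial_bounds(self):
        truth = self._truth()
        bc = simulate_barcodes(truth, 1, [{"x", "y"}], detection_rate=0.3, seed=2)
        n = len(truth.cell_labels)
        x = int(bc.values.sum())
        lo, hi = sps.binom.ppf([0.005, 0.995], n, 0.3)
        assert lo <= x <= hi

    def test_unknown_population_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            simulate_barcodes(self._truth(), 1, [{"nope"}], 1.0, 0)


class TestTimecourse:
    def test_ages_within_range_and_deterministic(self):
        a = simulate_timecourse(nadir_age=21, n_mice=30, noise_sd=0.1,
                                age_range=(0, 56), seed=4)
        assert a["age"].between(0, 56).all()
        b = simulate_timecourse(nadir_age=21, n_mice=30, noise_sd=0.1,
                                age_range=(0, 56), seed=4)
        assert a.equals(b)

    def test_noiseless_minimum_at_nadir(self):
        tc = simulate_timecourse(nadir_age=21, n_mice=40, noise_sd=0.0, seed=5)
        assert tc.loc[tc["ratio"].idxmin(), "age"] == pytest.approx(21, abs=4)

    def test_nadir_outside_range_rejected(self):
        with pytest.raises(ValueError):
            simulate_timecourse(nadir_age=100, n_mice=30, noise_sd=0.1,
                                age_range=(0, 56))

    def test_too_few_mice_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            simulate_timecourse(nadir_age=21, n_mice=5, noise_sd=0.1)
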