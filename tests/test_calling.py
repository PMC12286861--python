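import numpy as np
import pandas as pd
import pytest

from mimetect.calling import (
    ThresholdConfig,
    apply_thresholds,
    disambiguate_calls,
    expression_proportion,
    merge_signatures,
)
from mimetect.scoring import ScoreTable, standardize_scores


def _table(auc: dict, index=None):
    df = pd.DataFrame(auc, index=index)
    return standardize_scores(ScoreTable(auc=df, top_fraction=0.05, n_genes=100))


class TestThresholds:
    def test_exact_boundary_is_eligible(self):
        t = _table({"s": [0.30, 0.29]})
        elig = apply_thresholds(t, ThresholdConfig(thresholds={"s": 0.30}))
        assert list(elig["s"]) == [True, False]

    def test_unreachable_thresholds_yield_no_calls(self):
        t = _table({"a": [0.9, 0.99], "b": [0.8, 0.7]})
        elig = apply_thresholds(t, ThresholdConfig(thresholds={"a": 1.0, "b": 1.0}))
        calls = disambiguate_calls(t, elig)
        assert (calls.labels == "unassigned").all()

    def test_matches_elementwise_oracle(self, rng):
        auc = pd.DataFrame(rng.random((50, 4)), columns=list("abcd"))
        t = _table(auc.to_dict("list"))
        thr = {c: rng.random() for c in "abcd"}
        elig = apply_thresholds(t, ThresholdConfig(thresholds=thr))
        for c in "abcd":
            assert np.array_equal(elig[c].values, t.auc[c].values >= thr[c])

    def test_missing_threshold_is_error(self):
        t = _table({"a": [0.5, 0.6], "b": [0.5, 0.6]})
        with pytest.raises(ValueError, match="b"):
            apply_thresholds(t, ThresholdConfig(thresholds={"a": 0.5}))


class TestDisambiguation:
    def test_single_eligible_wins(self):
        t = _table({"a": [0.9, 0.1], "b": [0.1, 0.9]})
        elig = apply_thresholds(t, ThresholdConfig(thresholds={"a": 0.5, "b": 0.5}))
        calls = disambiguate_calls(t, elig)
        assert list(calls.labels) == ["a", "b"]

    def test_quantile_comparison_on_constructed_table(self, rng):
        # 100 cells; the probe cell is at quantile 0.99 for muscle and 0.80
        # for goblet, both eligible -> muscle wins
        muscle = np.sort(rng.uniform(0.0, 0.5, 100))
        goblet = np.sort(rng.uniform(0.0, 0.5, 100))
        muscle[99] = 0.6    # top cell for muscle
        goblet[80] = 0.45
        probe_muscle = muscle[99]
        # put the probe cell at index 0
        auc = pd.DataFrame({"muscle": np.r_[probe_muscle, muscle[:99]],
                            "goblet": np.r_[goblet[80], np.delete(goblet, 80)]})
        t = _table(auc.to_dict("list"))
        elig = pd.DataFrame(False, index=t.auc.index, columns=t.auc.columns)
        elig.iloc[0] = True
        calls = disambiguate_calls(t, elig)
        assert calls.labels.iloc[0] == "muscle"
        assert calls.calls.iloc[0]["quantile"] == pytest.approx(0.99)

    def test_equal_quantiles_broken_by_z(self):
        # both signatures give the cell the top AUC (equal quantiles); the
        # larger z-standardized AUC decides
        auc = pd.DataFrame({"a": [0.90, 0.85, 0.84, 0.86],
                            "b": [0.90, 0.20, 0.30, 0.25]})
        t = _table(auc.to_dict("list"))
        za = t.z.loc[0, "a"]
        zb = t.z.loc[0, "b"]
        elig = pd.DataFrame(False, index=t.auc.index, columns=t.auc.columns)
        elig.iloc[0] = True
        winner = disambiguate_calls(t, elig).labels.iloc[0]
        assert winner == ("a" if za > zb else "b") == "b"

    def test_every_cell_gets_exactly_one_label(self, small_scores):
        table, _ = small_scores
        cfg = ThresholdConfig(thresholds={c: 0.3 for c in table.auc.columns})
        calls = disambiguate_calls(table, apply_thresholds(table, cfg))
        assert len(calls.labels) == table.auc.shape[0]
        assert calls.labels.notna().all()

    def test_permutation_invariance_to_signature_order(self, small_scores):
        table, _ = small_scores
        cfg = ThresholdConfig(thresholds={c: 0.3 for c in table.auc.columns})
        a = disambiguate_calls(table, apply_thresholds(table, cfg)).labels
        rev_auc = table.auc[table.auc.columns[::-1]]
        t2 = standardize_scores(ScoreTable(auc=rev_auc, top_fraction=0.05, n_genes=800))
        b = disambiguate_calls(t2, apply_thresholds(t2, cfg)).labels
        assert (a == b).all()


class TestMerge:
    def _calls(self):
        t = _table({"Tuft1": [0.9, 0.1, 0.5], "Tuft2": [0.1, 0.9, 0.1]})
        cfg = ThresholdConfig(thresholds={"Tuft1": 0.4, "Tuft2": 0.4},
                              merge={"Tuft": ["Tuft1", "Tuft2"]})
        return disambiguate_calls(t, apply_thresholds(t, cfg)), cfg

    def test_collapse_into_unified_population(self):
        calls, cfg = self._calls()
        merged = merge_signatures(calls, cfg)
        assert set(merged.labels) == {"Tuft"}

    def test_counts_conserved(self):
        calls, cfg = self._calls()
        merged = merge_signatures(calls, cfg)
        assert merged.counts().sum() == calls.counts().sum()

    def test_empty_merge_is_identity(self):
        calls, _ = self._calls()
        ident = merge_signatures(calls, ThresholdConfig(thresholds={}))
        assert (ident.labels == calls.labels).all()

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError):
            ThresholdConfig(thresholds={}, merge={"A": ["x"], "B": ["x"]})


class TestExpressionProportion:
    def _counts(self):
        return pd.DataFrame({"Foxn1": [3, 0, 1, 0, 2, 0, 1, 1, 1, 1],
                             "Aire": [0] * 10},
                            index=[f"c{i}" for i in range(10)])

    def test_seven_of_ten_with_wilson(self):
        frac, (lo, hi) = expression_proportion(self._counts(), [f"c{i}" for i in range(10)], "Foxn1")
        assert frac == pytest.approx(0.7)
        assert lo == pytest.approx(0.3968, abs=1e-3)
        assert hi == pytest.approx(0.8922, abs=1e-3)

    def test_all_zero_counts(self):
        frac, (lo, _) = expression_proportion(self._counts(), ["c0", "c1"], "Aire")
        assert frac == 0.0 and lo == 0.0

    def test_absent_gene_and_empty_subset(self):
        with pytest.raises(KeyError):
            expression_proportion(self._counts(), ["c0"], "nope")
        with pytest.raises(ValueError):
            expression_proportion(self._counts(), [], "Foxn1")


def test_auc_histograms_figure(small_scores):
    from mimetect.calling import auc_histograms
    table, _ = small_scores
    fig = auc_histograms(table, thresholds={c: 0.3 for c in table.auc.columns})
    assert fig is not None
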