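import math
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats as sps

from mimetect.bulk import (
    ModeratedContrastResults,
    _fit_f_dist,
    adjust_and_sign,
    camera_pr,
    filter_genes,
    fit_moderated_t,
    logcpm,
    treat_test,
)
from mimetect.signatures import GeneSignature


class TestFilterGenes:
    def test_half_of_samples_suffices(self):
        counts = pd.DataFrame({"s1": [6, 5], "s2": [6, 5], "s3": [0, 5], "s4": [0, 5]},
                              index=["keep", "drop"])
        kept = filter_genes(counts)
        assert list(kept.index) == ["keep"]

    def test_exceeded_is_strict(self):
        counts = pd.DataFrame([[5, 5, 5, 5], [6, 6, 6, 6]], index=["all5", "all6"])
        assert list(filter_genes(counts).index) == ["all6"]

    def test_nothing_surviving_is_error(self):
        with pytest.raises(ValueError):
            filter_genes(pd.DataFrame([[0, 0]]))


class TestLogCPM:
    def test_zero_count_formula(self):
        counts = pd.DataFrame({"s": [0, 10**6 - 0]})
        y = logcpm(counts)
        expect = math.log2(0.5 / (10**6 + 1.0) * 1e6)
        assert y.iloc[0, 0] == pytest.approx(expect, abs=1e-9)

    def test_scale_invariance_up_to_prior(self):
        rng = np.random.default_rng(4)
        counts = pd.DataFrame(rng.integers(100, 1000, (50, 4)).astype(float))
        y1, y2 = logcpm(counts), logcpm(2 * counts)
        assert np.abs(y1.values - y2.values).max() < 0.01


class TestModeratedFit:
    def _simulate(self, seed=0, n_genes=300, shift_first=0):
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(2.0 * 10 / sps.chi2.rvs(10, size=n_genes, random_state=rng) / 10) * 1
        y = rng.normal(0, 1, (n_genes, 6)) * sigma[:, None]
        y[:shift_first, 3:] += 1.0
        cols = [f"s{i}" for i in range(6)]
        return pd.DataFrame(y, columns=cols, index=[f"g{i}" for i in range(n_genes)]), \
            pd.Series(["A"] * 3 + ["B"] * 3, index=cols)

    def test_equal_variances_give_infinite_prior_df(self):
        y, cond = self._simulate()
        # replace with exactly equal residual variances: y rows scaled copies
        base = np.array([[0.0, 1.0, -1.0, 0.5, 0.0, -0.5]])
        y = pd.DataFrame(np.repeat(base, 50, axis=0), columns=y.columns[:6],
                         index=[f"g{i}" for i in range(50)])
        res = fit_moderated_t(y, cond, ("B", "A"))
        assert res.d0 == math.inf or res.d0 > 1e6
        assert np.allclose(res.table["s2_post"], res.s02)

    def test_forced_infinite_prior_flattens_variances(self):
        y, cond = self._simulate(seed=1)
        res = fit_moderated_t(y, cond, ("B", "A"), d0=math.inf)
        assert np.allclose(res.table["s2_post"], res.s02)

    def test_prior_parameters_recovered_from_scaled_chi2(self):
        # s^2 ~ s0^2 * F(d, d0) with s0^2 = 2, d0 = 10, d = 4
        rng = np.random.default_rng(7)
        d0_true, s02_true, d = 10.0, 2.0, 4
        sigma2 = d0_true * s02_true / sps.chi2.rvs(d0_true, size=5000, random_state=rng)
        s2 = sigma2 * sps.chi2.rvs(d, size=5000, random_state=rng) / d
        d0_hat, s02_hat = _fit_f_dist(s2, float(d))
        assert d0_hat == pytest.approx(d0_true, rel=0.15)
        assert s02_hat == pytest.approx(s02_true, rel=0.15)

    def test_shifted_genes_rank_top(self):
        y, cond = self._simulate(seed=2, shift_first=20)
        res = fit_moderated_t(y, cond, ("B", "A"))
        top = set(res.table["t"].nlargest(20).index)
        assert len(top & {f"g{i}" for i in range(20)}) >= 15


class TestTreat:
    def _stats(self, coef, se, df):
        table = pd.DataFrame({"coef": coef, "u": 0.5,
                              "s2": np.asarray(se) ** 2 * 4, "df": df,
                              "s2_post": np.asarray(se) ** 2 * 4,
                              "t": np.asarray(coef) / np.asarray(se),
                              "df_total": df},
                             index=[f"g{i}" for i in range(len(coef))])
        return ModeratedContrastResults(table=table, d0=4.0, s02=1.0, contrast=("A", "B"))

    def test_tau_zero_reduces_to_two_sided_t(self):
        stats = self._stats([0.8, -0.4, 0.1], [0.25, 0.2, 0.3], 10)
        out = treat_test(stats, tau=0.0)
        t = stats.table["coef"] / (np.sqrt(stats.table["s2_post"]) * stats.table["u"])
        expect = 2 * sps.t.sf(np.abs(t), 10)
        assert np.allclose(out["p"], expect, atol=1e-12)

    def test_worked_example_with_quadrature_oracle(self):
        tau = math.log2(1.2)
        stats = self._stats([1.0], [0.25], 10)
        out = treat_test(stats, tau=tau)
        t_r, t_l = (1 - tau) / 0.25, (1 + tau) / 0.25
        assert t_r == pytest.approx(2.948, abs=2e-3)
        assert t_l == pytest.approx(5.052, abs=2e-3)
        pdf = sps.t(10).pdf
        tail_r, _ = integrate.quad(pdf, t_r, np.inf)
        tail_l, _ = integrate.quad(pdf, t_l, np.inf)
        assert out["p"].iloc[0] == pytest.approx(tail_r + tail_l, abs=1e-10)
        assert out["t"].iloc[0] == pytest.approx(t_r)

    def test_p_nondecreasing_in_tau(self):
        stats = self._stats([0.9], [0.3], 8)
        ps = [treat_test(stats, tau=tau)["p"].iloc[0] for tau in (0.0, 0.1, 0.3, 0.6)]
        assert np.all(np.diff(ps) >= 0)

    def test_negative_tau_rejected(self):
        with pytest.raises(ValueError):
            treat_test(self._stats([1.0], [0.2], 5), tau=-0.1)


class TestCameraPR:
    def _stat(self, values):
        return pd.Series(values, index=[f"g{i}" for i in range(len(values))])

    def test_rho_zero_reduces_to_pooled_t(self, rng):
        t = self._stat(rng.normal(0, 1, 200))
        genes = [f"g{i}" for i in range(30)]
        sig = GeneSignature(name="s", genes=set(genes))
        out = camera_pr(t, [sig], rho=0.0)
        t_ref, p_ref = sps.ttest_ind(t[genes], t.drop(genes))
        assert out.loc["s", "p"] == pytest.approx(p_ref, abs=1e-10)

    def test_zero_delta_gives_p_one(self):
        t = self._stat([1.0, -1.0, 1.0, -1.0, 0.5, -0.5])
        sig = GeneSignature(name="s", genes={"g0", "g1"})  # mean 0 = out mean 0
        assert camera_pr(t, [sig], rho=0.01).loc["s", "p"] == pytest.approx(1.0)

    def test_manual_formula_trace(self):
        vals = np.array([2.0, 1.5, 0.1, -0.2, 0.3, -1.0, 0.05, -0.3])
        t = self._stat(vals)
        sig = GeneSignature(name="s", genes={"g0", "g1"})
        out = camera_pr(t, [sig], rho=0.01)
        inset, outset = vals[:2], vals[2:]
        delta = inset.mean() - outset.mean()
        sigma2 = (((inset - inset.mean()) ** 2).sum()
                  + ((outset - outset.mean()) ** 2).sum()) / 6
        se = math.sqrt(sigma2 * ((1 + 1 * 0.01) / 2 + 1 / 6))
        p = 2 * sps.t.sf(abs(delta / se), 6)
        assert out.loc["s", "p"] == pytest.approx(p, abs=1e-12)
        assert out.loc["s", "direction"] == "up"

    def test_invariant_to_constant_shift_and_relabeling(self, rng):
        vals = rng.normal(0, 1, 100)
        t = self._stat(vals)
        sig = GeneSignature(name="s", genes={f"g{i}" for i in range(10)})
        p1 = camera_pr(t, [sig]).loc["s", "p"]
        p2 = camera_pr(t + 5.0, [sig]).loc["s", "p"]
        assert p1 == pytest.approx(p2, abs=1e-10)
        # relabeling: permute gene names together with values
        perm = rng.permutation(100)
        t3 = pd.Series(vals[perm], index=[f"g{i}" for i in perm])
        assert camera_pr(t3, [sig]).loc["s", "p"] == pytest.approx(p1, abs=1e-10)

    def test_degenerate_sets_skipped(self):
        t = self._stat([1.0, 2.0, 3.0])
        tiny = GeneSignature(name="tiny", genes={"g0"})
        alien = GeneSignature(name="alien", genes={"zz"})
        out = camera_pr(t, [tiny, alien])
        assert out.empty


class TestAdjustAndSign:
    def _table(self, p, direction):
        return pd.DataFrame({"size": 10, "delta": 1.0, "direction": direction,
                             "p": p, "klass": "mimetic"},
                            index=[f"s{i}" for i in range(len(p))])

    def test_up_at_adj_001_gives_plus_two(self):
        out = adjust_and_sign(self._table([0.01], ["up"]), clip=10)
        assert out["signed_logp"].iloc[0] == pytest.approx(2.0)

    def test_adj_p_one_gives_zero(self):
        out = adjust_and_sign(self._table([1.0, 1.0], ["up", "down"]), clip=10)
        assert np.allclose(out["signed_logp"], 0.0)

    def test_single_hypothesis_unchanged_by_bh(self):
        out = adjust_and_sign(self._table([0.037], ["down"]), clip=10)
        assert out["adj_p"].iloc[0] == pytest.approx(0.037)
        assert out["signed_logp"].iloc[0] < 0

    def test_clipping_rounds_to_limit(self):
        out = adjust_and_sign(self._table([1e-15], ["up"]), clip=10)
        assert out["clipped"].iloc[0] == 10.0
        assert out["signed_logp"].iloc[0] > 10.0


class TestAgainstLimma:
    """Independent oracle: the reference R implementation of the moderated
    fold-change-threshold test and the competitive pre-ranked set test."""

    def test_treat_and_camera_match_limma(self, tmp_path, rng):
        n_genes, n = 400, 6
        sigma = np.sqrt(0.5 * 8 / sps.chi2.rvs(8, size=n_genes, random_state=rng))
        y = rng.normal(0, 1, (n_genes, n)) * sigma[:, None]
        y[:30, 3:] += 1.2
        ydf = pd.DataFrame(y, index=[f"g{i}" for i in range(n_genes)],
                           columns=[f"s{i}" for i in range(n)])
        cond = pd.Series(["A"] * 3 + ["B"] * 3, index=ydf.columns)
        ydf.to_csv(tmp_path / "y.csv")
        script = textwrap.dedent("""
            suppressMessages(library(limma))
            y <- as.matrix(read.csv(file.path("%s", "y.csv"), row.names=1))
            design <- model.matrix(~0+factor(c("A","A","A","B","B","B")))
            colnames(design) <- c("A","B")
            fit <- lmFit(y, design)
            fit2 <- contrasts.fit(fit, makeContrasts(B-A, levels=design))
            tr <- treat(fit2, lfc=log2(1.2), robust=FALSE)
            cam <- cameraPR(tr$t[,1], list(set1=1:30, set2=101:160),
                            inter.gene.cor=0.01, sort=FALSE)
            write.csv(data.frame(t=tr$t[,1], p=tr$p.value[,1],
                                 d0=tr$df.prior, s02=tr$s2.prior),
                      file.path("%s", "treat.csv"))
            write.csv(cam, file.path("%s", "camera.csv"))
        """ % (tmp_path, tmp_path, tmp_path))
        (tmp_path / "oracle.R").write_text(script)
        subprocess.run(["Rscript", str(tmp_path / "oracle.R")], check=True,
                       capture_output=True)
        ref = pd.read_csv(tmp_path / "treat.csv", index_col=0)
        res = fit_moderated_t(ydf, cond, ("B", "A"))
        assert res.d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-4)
        assert res.s02 == pytest.approx(ref["s02"].iloc[0], rel=1e-4)
        ours = treat_test(res)
        assert np.allclose(ours["t"], ref["t"], atol=1e-6)
        assert np.allclose(ours["p"], ref["p"], atol=1e-8)
        cam_ref = pd.read_csv(tmp_path / "camera.csv", index_col=0)
        sets = [GeneSignature(name="set1", genes={f"g{i}" for i in range(30)}),
                GeneSignature(name="set2", genes={f"g{i}" for i in range(100, 160)})]
        cam = camera_pr(ours["t"], sets, rho=0.01)
        assert np.allclose(cam["p"].values, cam_ref["PValue"].values, atol=1e-10)
        assert [d.lower() for d in cam_ref["Direction"]] == list(cam["direction"])
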