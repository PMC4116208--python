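"""Group-model fits, empirical-Bayes moderation, BY, fold filter, patterns, ORA."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.stats import f as f_dist

from subtypekit.containers import ExpressionMatrix
from subtypekit.dge import (
    VariancePrior,
    by_adjust,
    estimate_prior,
    fc_filter,
    fit_group_model,
    moderated_f,
    ora_hypergeometric,
    pairwise_dge,
    pattern_classify,
)


def em(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


class TestFitGroupModel:
    def test_hand_computation_two_groups(self):
        m = em([[1, 3, 5, 7]])
        fit = fit_group_model(m, {"s0": "a", "s1": "a", "s2": "b", "s3": "b"})
        assert fit.means.loc["g0", "a"] == 2.0
        assert fit.means.loc["g0", "b"] == 6.0
        assert fit.s2.loc["g0"] == pytest.approx(2.0)
        assert fit.df_residual == 2

    def test_zero_within_group_variance_is_valid(self):
        m = em([[4, 4, 9, 9]])
        fit = fit_group_model(m, {"s0": "a", "s1": "a", "s2": "b", "s3": "b"})
        assert fit.s2.loc["g0"] == 0.0

    def test_matches_loop_oracle(self, rng):
        vals = rng.normal(size=(50, 9))
        labels = {f"s{i}": "abc"[i // 3] for i in range(9)}
        fit = fit_group_model(em(vals), labels)
        for g in range(50):
            resid = []
            for grp in "abc":
                xs = [vals[g, i] for i in range(9) if labels[f"s{i}"] == grp]
                mean = sum(xs) / len(xs)
                assert fit.means.iloc[g][grp] == pytest.approx(mean, abs=1e-12)
                resid += [(x - mean) ** 2 for x in xs]
            assert fit.s2.iloc[g] == pytest.approx(sum(resid) / 6, abs=1e-12)

    def test_small_group_errors(self):
        m = em(np.ones((2, 3)))
        with pytest.raises(ValueError, match="< 2"):
            fit_group_model(m, {"s0": "a", "s1": "a", "s2": "b"})


class TestEstimatePrior:
    def test_recovers_known_hyperparameters(self):
        rng = np.random.default_rng(3)
        d0, s0sq, d = 4.0, 0.05, 18
        sigma2 = s0sq * d0 / rng.chisquare(d0, size=2000)
        s2 = sigma2 * rng.chisquare(d, size=2000) / d
        prior = estimate_prior(s2, d)
        assert prior.d0 == pytest.approx(d0, abs=1.5)
        assert prior.s0_sq == pytest.approx(s0sq, rel=0.20)

    def test_identical_variances_hit_infinite_d0_branch(self):
        prior = estimate_prior(np.full(100, 0.3), df=5)
        assert np.isinf(prior.d0)
        assert prior.s0_sq > 0

    def test_invariant_to_gene_order(self, rng):
        s2 = rng.chisquare(5, 500) / 5
        a = estimate_prior(s2, df=5)
        b = estimate_prior(s2[::-1], df=5)
        assert a.d0 == pytest.approx(b.d0)
        assert a.s0_sq == pytest.approx(b.s0_sq)

    def test_too_few_genes_errors(self):
        with pytest.raises(ValueError, match=">= 10"):
            estimate_prior(np.ones(5), df=3)


class TestModeratedF:
    def fit(self, rng, n_genes=20):
        vals = rng.normal(size=(n_genes, 10))
        vals[: n_genes // 2, 5:] += 2.0
        labels = {f"s{i}": ("a" if i < 5 else "b") for i in range(10)}
        return fit_group_model(em(vals), labels)

    def test_d0_to_zero_limit_is_ordinary_f(self, rng):
        fit = self.fit(rng)
        out = moderated_f(fit, VariancePrior(d0=1e-12, s0_sq=1.0))
        ordinary = out["ms_between"] / fit.s2
        assert np.allclose(out["moderated_F"], ordinary, rtol=1e-9)

    def test_d0_infinite_limit_uses_prior_variance(self, rng):
        fit = self.fit(rng)
        out = moderated_f(fit, VariancePrior(d0=np.inf, s0_sq=0.7))
        assert np.allclose(out["moderated_F"], out["ms_between"] / 0.7)

    def test_matches_direct_formula_oracle(self, rng):
        fit = self.fit(rng)
        prior = VariancePrior(d0=4.0, s0_sq=0.5)
        out = moderated_f(fit, prior)
        for g in fit.s2.index:
            s2_post = (4.0 * 0.5 + fit.df_residual * fit.s2[g]) / (4.0 + fit.df_residual)
            n_a = n_b = 5
            diff = fit.means.loc[g, "a"] - fit.means.loc[g, "b"]
            ms = (n_a * n_b / (n_a + n_b)) * diff ** 2
            F = ms / s2_post
            assert out.loc[g, "moderated_F"] == pytest.approx(F, rel=1e-9)
            assert out.loc[g, "p_raw"] == pytest.approx(
                f_dist.sf(F, 1, 4.0 + fit.df_residual), rel=1e-9)

    def test_moderated_f_between_limits(self, rng):
        fit = self.fit(rng)
        prior = VariancePrior(d0=4.0, s0_sq=float(np.median(fit.s2)))
        mod = moderated_f(fit, prior)["moderated_F"]
        lo = moderated_f(fit, VariancePrior(d0=1e-12, s0_sq=prior.s0_sq))["moderated_F"]
        hi = moderated_f(fit, VariancePrior(d0=np.inf, s0_sq=prior.s0_sq))["moderated_F"]
        lower = np.minimum(lo, hi)
        upper = np.maximum(lo, hi)
        assert ((mod >= lower - 1e-9) & (mod <= upper + 1e-9)).all()


def test_matches_r_limma_on_small_fixture(tmp_path):
    """Cross-check prior estimation and posterior variances against limma."""
    rng = np.random.default_rng(11)
    vals = rng.normal(size=(60, 12))
    vals[:10, 6:] += 1.5
    labels = {f"s{i}": ("a" if i < 6 else "b") for i in range(12)}
    fit = fit_group_model(em(vals), labels)
    prior = estimate_prior(fit.s2, fit.df_residual)
    mat = tmp_path / "m.tsv"
    pd.DataFrame(vals).to_csv(mat, sep="\t", index=False, header=False)
    script = textwrap.dedent(f"""
        suppressMessages(library(limma))
        x <- as.matrix(read.table("{mat}", sep="\\t"))
        design <- model.matrix(~factor(rep(c("a","b"), each=6)))
        fit <- lmFit(x, design)
        fit <- eBayes(fit)
        cat(fit$df.prior, fit$s2.prior, "\\n")
        cat(fit$s2.post, sep="\\n")
    """)
    r = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True)
    assert r.returncode == 0, r.stderr
    lines = r.stdout.strip().splitlines()
    d0_r, s0_r = (float(x) for x in lines[0].split())
    s2_post_r = np.array([float(x) for x in lines[1:]])
    assert prior.d0 == pytest.approx(d0_r, rel=1e-3)
    assert prior.s0_sq == pytest.approx(s0_r, rel=1e-3)
    out = moderated_f(fit, prior)
    assert np.allclose(out["s2_posterior"], s2_post_r, rtol=1e-3)


class TestBYAdjust:
    def test_three_value_direct_formula(self):
        adj = by_adjust([0.01, 0.02, 0.03])
        # m * c(m) * p_(j) / j minimized over the tail: all equal 3*(11/6)*0.01
        assert np.allclose(adj, 3 * (11 / 6) * 0.01)

    def test_single_value_unchanged(self):
        assert by_adjust([0.2])[0] == pytest.approx(0.2)

    def test_by_at_least_bh_at_least_raw(self, rng):
        from statsmodels.stats.multitest import multipletests
        p = rng.uniform(size=50)
        by = by_adjust(p)
        bh = multipletests(p, method="fdr_bh")[1]
        assert (by >= bh - 1e-12).all()
        assert (by >= p - 1e-12).all()
        assert (by <= 1.0).all()

    def test_matches_stepup_formula_oracle(self, rng):
        p = np.sort(rng.uniform(size=12))
        m = len(p)
        c = sum(1 / i for i in range(1, m + 1))
        expected = [min(1.0, min(m * c * p[j] / (j + 1) for j in range(i, m)))
                    for i in range(m)]
        assert np.allclose(by_adjust(p), expected)


class TestFCFilter:
    def frame(self, lfc, p_by):
        return pd.DataFrame({"log2_fc": lfc, "p_by": p_by},
                            index=[f"g{i}" for i in range(len(lfc))])

    def test_boundary_fold_change_inclusive(self):
        up, down = fc_filter(self.frame([1.0, -1.0], [1e-6, 1e-6]))
        assert up == ["g0"] and down == ["g1"]

    def test_below_fold_excluded_despite_significance(self):
        up, down = fc_filter(self.frame([0.9], [1e-6]))
        assert up == [] and down == []

    def test_nonsignificant_excluded_despite_fold(self):
        up, down = fc_filter(self.frame([3.0], [0.2]))
        assert up == []

    def test_planted_four_fold_genes_recovered(self, rng):
        """40 planted 4-fold genes among 2,000 nulls at BY < 0.05."""
        n_genes, n_planted, n_per = 2040, 40, 15
        vals = rng.normal(0, 0.5, size=(n_genes, 2 * n_per))
        vals[:n_planted, n_per:] += 2.0  # 4-fold on log2 scale
        labels = {f"s{i}": ("a" if i < n_per else "b") for i in range(2 * n_per)}
        res = pairwise_dge(em(vals), labels, focal="b")["a"]
        up, down = fc_filter(res)
        hits = set(up) | set(down)
        planted = {f"g{i}" for i in range(n_planted)}
        assert len(hits & planted) >= 36
        false = hits - planted
        assert len(false) <= 0.05 * max(len(hits), 1)


class TestPatternClassify:
    means = pd.DataFrame({"f": [5.0, 1.0, 3.0], "a": [3.0, 3.0, 1.0],
                          "b": [1.0, 5.0, 5.0]}, index=["g1", "g2", "g3"])

    def test_three_patterns(self):
        out = pattern_classify(self.means, focal="f")
        assert out.tolist() == ["pattern1", "pattern2", "pattern3"]

    def test_tolerance_window(self):
        means = pd.DataFrame({"f": [4.8], "a": [5.0], "b": [1.0]}, index=["g"])
        assert pattern_classify(means, focal="f", tol=0.25).iloc[0] == "pattern1"
        assert pattern_classify(means, focal="f", tol=0.1).iloc[0] == "pattern3"

    def test_unknown_focal_errors(self):
        with pytest.raises(ValueError, match="focal"):
            pattern_classify(self.means, focal="zz")


class TestORA:
    def test_exact_combinatorial_toy(self):
        universe = [f"u{i}" for i in range(10)]
        res = ora_hypergeometric(universe[:4], universe,
                                 {"set": universe[:5]})
        assert res.loc["set", "overlap"] == 4
        assert res.loc["set", "p_raw"] == pytest.approx(5 / 210, abs=1e-12)

    def test_zero_overlap_tail_is_one(self):
        # the upper tail includes the observed overlap of 0, so p = 1 exactly
        universe = [f"u{i}" for i in range(20)]
        res = ora_hypergeometric(universe[:3], universe, {"s": universe[18:]})
        assert res.loc["s", "overlap"] == 0
        assert res.loc["s", "p_raw"] == pytest.approx(1.0, abs=1e-12)

    def test_saturated_selection_gives_p_one(self):
        universe = [f"u{i}" for i in range(8)]
        res = ora_hypergeometric(universe, universe, {"s": universe[:3]})
        assert res.loc["s", "overlap"] == 3
        assert res.loc["s", "p_raw"] == pytest.approx(1.0)

    def test_selection_outside_universe_errors(self):
        with pytest.raises(ValueError, match="outside"):
            ora_hypergeometric(["x"], ["a", "b"], {})

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError, match="empty universe"):
            ora_hypergeometric([], [], {})
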