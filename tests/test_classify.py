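"""Nearest-centroid assignment, EM mixture fitting, cutoff derivation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from subtypekit.classify import (
    MixtureFit,
    assign_subtypes,
    derive_cutoff,
    fit_correlation_mixture,
    mixture_lrt_pvalue,
    reassignment_experiment,
)
from subtypekit.containers import CentroidSet, ExpressionMatrix


def em_cs(X, C):
    X = np.asarray(X, dtype=float)
    C = np.asarray(C, dtype=float)
    genes = [f"g{i}" for i in range(X.shape[0])]
    m = ExpressionMatrix(pd.DataFrame(X, index=genes,
                                      columns=[f"s{j}" for j in range(X.shape[1])]))
    c = CentroidSet(pd.DataFrame(C, index=genes,
                                 columns=[f"c{j}" for j in range(C.shape[1])]))
    return m, c


class TestAssignSubtypes:
    def test_sample_equal_to_centroid_wins_with_correlation_one(self, rng):
        C = rng.normal(size=(20, 3))
        m, c = em_cs(C[:, [1]], C)
        res = assign_subtypes(m, c, cutoff=1.0)
        assert res.best_subtype.iloc[0] == "c1"
        assert res.max_corr.iloc[0] == pytest.approx(1.0)
        assert bool(res.assigned.iloc[0])

    def test_max_corr_below_cutoff_stays_unclassified(self, rng):
        # engineer a sample with max Spearman correlation just under 0.3
        C = rng.normal(size=(11, 1))
        ranks = np.argsort(np.argsort(C[:, 0]))
        perm = ranks.copy()
        best = None
        for _ in range(2000):
            p = rng.permutation(11)
            r = np.corrcoef(np.argsort(np.argsort(p)), ranks)[0, 1]
            if r < 0.3 and (best is None or r > best[1]):
                best = (p, r)
        x = np.sort(C[:, 0])[best[0]]
        m, c = em_cs(x[:, None], C)
        res = assign_subtypes(m, c, cutoff=0.3)
        assert res.max_corr.iloc[0] < 0.3
        assert not bool(res.assigned.iloc[0])
        assert res.assigned_label.iloc[0] == "unclassified"

    def test_recovers_synthetic_reference_labels(self, panel, reference_centroids):
        from subtypekit.preprocess import median_center
        X = median_center(panel.expression)
        res = assign_subtypes(X, reference_centroids, cutoff=0.3)
        agreement = (res.assigned_label == panel.true_subtype).mean()
        assert agreement >= 29 / 30

    def test_raising_cutoff_never_increases_assigned_count(self, mixed,
                                                           reference_centroids):
        from subtypekit.preprocess import median_center
        X = median_center(mixed.expression)
        counts = []
        for cutoff in (-1.0, 0.0, 0.2, 0.3, 0.5, 0.8, 1.01):
            res = assign_subtypes(X, reference_centroids, cutoff=cutoff)
            counts.append(int(res.assigned.sum()))
        assert counts == sorted(counts, reverse=True)

    def test_no_shared_genes_errors(self, rng):
        m, _ = em_cs(rng.normal(size=(5, 2)), rng.normal(size=(5, 2)))
        c = CentroidSet(pd.DataFrame(rng.normal(size=(5, 2)),
                                     index=[f"other{i}" for i in range(5)],
                                     columns=["a", "b"]))
        with pytest.raises(ValueError, match="shared"):
            assign_subtypes(m, c, cutoff=0.3)

    def test_constant_sample_reported_unassignable(self, rng):
        X = np.column_stack([np.full(8, 3.0), rng.normal(size=8)])
        m, c = em_cs(X, rng.normal(size=(8, 2)))
        with pytest.warns(UserWarning, match="constant"):
            res = assign_subtypes(m, c, cutoff=0.0)
        assert not bool(res.assigned.iloc[0])
        assert res.assigned_label.iloc[0] == "unclassified"
        assert bool(res.assigned.iloc[1]) or res.max_corr.iloc[1] < 0

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_spearman_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(15, 2))
        C = rng.normal(size=(15, 2))
        m, c = em_cs(X, C)
        base = assign_subtypes(m, c, cutoff=0.0).correlations
        m2, _ = em_cs(np.exp(0.5 * X) + 1.0, C)  # strictly monotone transform
        trans = assign_subtypes(m2, c, cutoff=0.0).correlations
        assert np.allclose(base.to_numpy(), trans.to_numpy(), atol=1e-12)


class TestMixtureFit:
    def test_single_component_closed_form(self, rng):
        x = rng.normal(0.4, 0.1, 200)
        fit = fit_correlation_mixture(x, k=1, n_starts=1, seed=0)
        assert fit.means[0] == pytest.approx(x.mean(), abs=1e-6)
        assert fit.sds[0] == pytest.approx(x.std(), abs=1e-6)

    def test_two_component_parameter_recovery(self):
        rng = np.random.default_rng(42)
        x = np.concatenate([rng.normal(0.15, 0.05, 1000),
                            rng.normal(0.60, 0.10, 1000)])
        fit = fit_correlation_mixture(x, k=2, n_starts=5, seed=0)
        assert fit.converged
        assert fit.means[0] == pytest.approx(0.15, abs=0.02)
        assert fit.means[1] == pytest.approx(0.60, abs=0.02)

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_log_likelihood_non_decreasing(self, seed):
        rng = np.random.default_rng(seed)
        x = np.concatenate([rng.normal(0, 1, 30), rng.normal(3, 0.5, 30)])
        fit = fit_correlation_mixture(x, k=2, n_starts=3, seed=1)
        assert np.all(np.diff(fit.log_likelihood_path) > -1e-7)

    def test_matches_sklearn_gaussian_mixture(self):
        from sklearn.mixture import GaussianMixture
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(0.1, 0.05, 400), rng.normal(0.6, 0.1, 600)])
        fit = fit_correlation_mixture(x, k=2, n_starts=5, seed=0)
        gm = GaussianMixture(2, n_init=5, random_state=0, tol=1e-8,
                             max_iter=500).fit(x[:, None])
        means = np.sort(gm.means_.ravel())
        assert np.allclose(fit.means, means, atol=5e-3)

    def test_identical_observations_error(self):
        with pytest.raises(ValueError, match="identical"):
            fit_correlation_mixture(np.full(20, 0.5), k=2)

    def test_too_few_observations_error(self):
        with pytest.raises(ValueError, match=">= 10"):
            fit_correlation_mixture(np.arange(5) / 5.0)


class TestDeriveCutoff:
    def mk(self, weights, means, sds):
        return MixtureFit(k=2, weights=np.asarray(weights, float),
                          means=np.asarray(means, float),
                          sds=np.asarray(sds, float), log_likelihood=0.0,
                          n_iter=1, converged=True)

    def test_symmetric_mixture_cuts_at_midpoint(self):
        fit = self.mk([0.5, 0.5], [0.2, 0.6], [0.05, 0.05])
        assert derive_cutoff(fit) == pytest.approx(0.4, abs=1e-6)

    def test_matches_grid_search_oracle(self):
        fit = self.mk([0.7, 0.3], [0.1, 0.6], [0.05, 0.1])
        grid = np.linspace(0.1, 0.6, 500001)
        dens = np.abs(0.7 * norm.pdf(grid, 0.1, 0.05)
                      - 0.3 * norm.pdf(grid, 0.6, 0.1))
        assert derive_cutoff(fit) == pytest.approx(grid[np.argmin(dens)], abs=1e-3)

    def test_cutoff_lies_between_fitted_means(self):
        rng = np.random.default_rng(42)
        x = np.concatenate([rng.normal(0.15, 0.05, 1000),
                            rng.normal(0.60, 0.10, 1000)])
        fit = fit_correlation_mixture(x, k=2, n_starts=5, seed=0)
        assert 0.15 < derive_cutoff(fit) < 0.60

    def test_unconverged_fit_errors(self):
        fit = self.mk([0.5, 0.5], [0.2, 0.6], [0.05, 0.05])
        fit.converged = False
        with pytest.raises(ValueError, match="converge"):
            derive_cutoff(fit)

    def test_wrong_component_count_errors(self):
        fit = MixtureFit(k=1, weights=np.array([1.0]), means=np.array([0.3]),
                         sds=np.array([0.1]), log_likelihood=0.0, n_iter=1,
                         converged=True)
        with pytest.raises(ValueError, match="2-component"):
            derive_cutoff(fit)


def test_bimodal_distribution_rejects_single_component():
    rng = np.random.default_rng(7)
    x = np.concatenate([rng.normal(0.15, 0.05, 150), rng.normal(0.6, 0.1, 150)])
    p = mixture_lrt_pvalue(x, B=49, seed=0)
    assert p <= 0.05


class TestReassignment:
    def test_counts_sum_and_single_winner(self, rng):
        C = rng.normal(size=(30, 3))
        # five samples all nearest to centroid 0, but below cutoff
        X = np.column_stack([0.2 * C[:, 0] + rng.normal(0, 1.5, 30)
                             for _ in range(5)])
        m, c = em_cs(X, C)
        res = assign_subtypes(m, c, cutoff=0.99)
        re = reassignment_experiment(res)
        assert re.total == 5
        assert re.counts.sum() == 5
        assert set(re.counts.index) == {"c0", "c1", "c2"}

    def test_novel_samples_lean_luminal(self, mixed, reference_centroids):
        from subtypekit.preprocess import median_center
        X = median_center(mixed.expression)
        res = assign_subtypes(X, reference_centroids, cutoff=0.3)
        re = reassignment_experiment(res)
        luminal = re.counts[["luminal_a", "luminal_b"]].sum()
        assert luminal / re.total > 0.5

    def test_no_unassigned_errors(self, rng):
        C = rng.normal(size=(10, 2))
        m, c = em_cs(C, C)
        res = assign_subtypes(m, c, cutoff=-1.0)
        with pytest.raises(ValueError, match="no unassigned"):
            reassignment_experiment(res)
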