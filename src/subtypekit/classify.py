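"""Nearest-centroid subtype assignment and EM-based cutoff selection.

Samples are assigned to the subtype whose standardized centroid they
correlate with best (Spearman, over the genes shared between matrix and
centroid set).  A sample whose maximal correlation falls below the cutoff
stays unclassified.  The cutoff itself is derived from a two-component
Gaussian mixture fitted by EM to the cohort's maximal-correlation
distribution: the equal weighted-density crossing between the two
component means separates the "matches some subtype" mode from the
"matches nothing" mode.  A parametric-bootstrap likelihood-ratio test
(two components vs one) provides a significance check for that split.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import logsumexp
from scipy.stats import norm, rankdata

from .containers import AssignmentResult, CentroidSet, ExpressionMatrix

__all__ = ["MixtureFit", "assign_subtypes", "fit_correlation_mixture",
           "derive_cutoff", "mixture_lrt_pvalue", "reassignment_experiment",
           "ReassignmentResult"]

log = logging.getLogger(__name__)

EM_TOL = 1e-8
EM_MAX_ITER = 500
_SD_FLOOR = 1e-4  # guards EM against variance collapse on a single point


# ---------------------------------------------------------------------------
# assignment
# ---------------------------------------------------------------------------

def _spearman_matrix(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Spearman correlations between columns of X (samples) and C (centroids)."""
    RX = np.apply_along_axis(rankdata, 0, X)
    RC = np.apply_along_axis(rankdata, 0, C)
    RX = RX - RX.mean(axis=0)
    RC = RC - RC.mean(axis=0)
    sx = np.sqrt((RX ** 2).sum(axis=0))
    sc = np.sqrt((RC ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (RX.T @ RC) / np.outer(sx, sc)
    return corr


def assign_subtypes(matrix: ExpressionMatrix, centroids: CentroidSet,
                    cutoff: float) -> AssignmentResult:
    """Assign each sample to its maximally correlated centroid.

    Correlations are computed over the gene intersection of matrix and
    centroids (the count is logged, mirroring classification across
    platforms with partially shared gene lists).  Argmax ties are broken by
    declared centroid order with a warning; constant sample vectors are
    reported unassignable (NaN correlations) with a warning.
    """
    shared = matrix.data.index.intersection(centroids.values.index)
    if len(shared) < 2:
        raise ValueError(f"only {len(shared)} gene(s) shared between matrix and centroids")
    log.info("classifying %d samples over %d shared genes (matrix %d, centroids %d)",
             matrix.n_samples, len(shared), matrix.n_genes, len(centroids.gene_symbols))
    X = matrix.data.loc[shared].to_numpy()
    C = centroids.values.loc[shared].to_numpy()
    const = np.ptp(X, axis=0) == 0
    corr = _spearman_matrix(X, C)
    if const.any():
        bad = [matrix.sample_ids[j] for j in np.flatnonzero(const)]
        warnings.warn(f"constant expression vector(s); unassignable sample(s): {bad[:5]}")
        corr[const, :] = np.nan
    finite = ~np.all(np.isnan(corr), axis=1)
    with np.errstate(invalid="ignore"):
        mx = np.nanmax(np.where(np.isnan(corr), -np.inf, corr), axis=1)
        n_ties = (np.isclose(corr, mx[:, None])).sum(axis=1)
    tied = finite & (n_ties > 1)
    if tied.any():
        warnings.warn(f"{int(tied.sum())} sample(s) with tied maximal correlations; "
                      "broken by centroid order")
    frame = pd.DataFrame(corr, index=matrix.sample_ids, columns=centroids.subtype_names)
    return AssignmentResult(correlations=frame, cutoff=float(cutoff))


# ---------------------------------------------------------------------------
# EM Gaussian mixture on maximal correlations
# ---------------------------------------------------------------------------

@dataclass
class MixtureFit:
    """Univariate Gaussian mixture fitted by EM (components sorted by mean)."""

    k: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    log_likelihood: float
    n_iter: int
    converged: bool
    #: per-iteration log-likelihood trace of the winning start (non-decreasing)
    log_likelihood_path: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if (self.sds <= 0).any():
            raise ValueError("mixture SDs must be positive")


def _em_run(x: np.ndarray, k: int, means0: np.ndarray, sds0: np.ndarray,
            weights0: np.ndarray) -> MixtureFit:
    n = x.size
    means, sds, weights = means0.copy(), sds0.copy(), weights0.copy()
    path = []
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, EM_MAX_ITER + 1):
        logp = (np.log(weights)[None, :]
                + norm.logpdf(x[:, None], means[None, :], sds[None, :]))
        ll = float(logsumexp(logp, axis=1).sum())
        path.append(ll)
        resp = np.exp(logp - logsumexp(logp, axis=1, keepdims=True))
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        weights = nk / n
        means = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        sds = np.maximum(np.sqrt(var), _SD_FLOOR)
        if abs(ll - prev) < EM_TOL:
            converged = True
            break
        prev = ll
    order = np.argsort(means)
    return MixtureFit(k=k, weights=weights[order], means=means[order],
                      sds=sds[order], log_likelihood=path[-1], n_iter=it,
                      converged=converged, log_likelihood_path=np.asarray(path))


def fit_correlation_mixture(max_corrs: Sequence[float], k: int = 2,
                            n_starts: int = 5, seed: int = 0) -> MixtureFit:
    """Best-of-``n_starts`` EM fit of a k-component univariate Gaussian mixture.

    The first start places component means at evenly spaced quantiles
    (25th/75th percentile for k = 2); further starts draw means from the
    data.  Convergence: absolute log-likelihood change < 1e-8 or 500
    iterations.  Deterministic given ``seed``.
    """
    x = np.asarray(list(max_corrs), dtype=float)
    if x.size < 10:
        raise ValueError(f"need >= 10 observations, got {x.size}")
    if k < 1:
        raise ValueError("k must be >= 1")
    if np.ptp(x) == 0:
        raise ValueError("all observations identical: degenerate variance")
    rng = np.random.default_rng(seed)
    sd0 = max(float(np.std(x)), _SD_FLOOR)
    best: MixtureFit | None = None
    for s in range(max(n_starts, 1)):
        if s == 0:
            qs = (np.arange(k) + 0.5) / k * 100.0 if k > 2 else ([50.0] if k == 1 else [25.0, 75.0])
            means0 = np.percentile(x, qs)
        else:
            means0 = rng.choice(x, size=k, replace=False)
        fit = _em_run(x, k, np.asarray(means0, dtype=float),
                      np.full(k, sd0), np.full(k, 1.0 / k))
        if best is None or fit.log_likelihood > best.log_likelihood:
            best = fit
    assert best is not None
    return best


def derive_cutoff(fit: MixtureFit, tol: float = 1e-6) -> float:
    """Equal weighted-density crossing between the two component means.

    The point x in (m1, m2) where w1*phi1(x) = w2*phi2(x), located by
    bisection; equivalent to the equal-posterior boundary between the two
    components.
    """
    if fit.k != 2:
        raise ValueError("cutoff derivation needs a 2-component fit")
    if not fit.converged:
        raise ValueError("mixture fit did not converge")
    w1, w2 = fit.weights
    m1, m2 = fit.means
    s1, s2 = fit.sds

    def f(x: float) -> float:
        return w1 * norm.pdf(x, m1, s1) - w2 * norm.pdf(x, m2, s2)

    if m2 - m1 < 1e-12:
        raise ValueError("component means coincide; no crossing")
    a, b = m1, m2
    if f(a) * f(b) > 0:
        raise ValueError("no equal-density crossing between the component means")
    return float(brentq(f, a, b, xtol=tol))


def mixture_lrt_pvalue(max_corrs: Sequence[float], B: int = 100, seed: int = 0,
                       n_starts: int = 3) -> float:
    """Parametric-bootstrap likelihood-ratio test of 2 components vs 1.

    Simulates B datasets from the single-Gaussian fit, refits both models,
    and returns the add-one permutation estimate
    (1 + #{boot LRT >= observed}) / (1 + B).
    """
    x = np.asarray(list(max_corrs), dtype=float)
    fit1 = fit_correlation_mixture(x, k=1, n_starts=1, seed=seed)
    fit2 = fit_correlation_mixture(x, k=2, n_starts=n_starts, seed=seed)
    observed = 2.0 * (fit2.log_likelihood - fit1.log_likelihood)
    rng = np.random.default_rng(seed + 1)
    exceed = 0
    for b in range(B):
        sim = rng.normal(fit1.means[0], fit1.sds[0], size=x.size)
        s1 = fit_correlation_mixture(sim, k=1, n_starts=1, seed=seed + 2 + b)
        s2 = fit_correlation_mixture(sim, k=2, n_starts=n_starts, seed=seed + 2 + b)
        if 2.0 * (s2.log_likelihood - s1.log_likelihood) >= observed:
            exceed += 1
    return (1 + exceed) / (1 + B)


# ---------------------------------------------------------------------------
# forced re-assignment of unclassified samples
# ---------------------------------------------------------------------------

@dataclass
class ReassignmentResult:
    """Where unclassified samples would land if forced into a subtype."""

    counts: pd.Series                       # subtype -> sample count
    coefficients: dict[str, np.ndarray]     # subtype -> winning correlations
    forced_label: pd.Series                 # sample -> forced subtype

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def reassignment_experiment(result: AssignmentResult) -> ReassignmentResult:
    """Force each unassigned sample to its best subtype, ignoring the cutoff.

    Returns per-subtype counts (zeros included) and the per-subtype sets of
    winning correlation coefficients, for rank-based comparisons of how
    closely the unclassifiable population leans toward each subtype.
    """
    unassigned = ~result.assigned
    usable = unassigned & result.max_corr.notna()
    if not unassigned.any():
        raise ValueError("no unassigned samples to re-assign")
    best = result.best_subtype[usable]
    mx = result.max_corr[usable]
    subtypes = list(result.correlations.columns)
    counts = best.value_counts().reindex(subtypes, fill_value=0)
    coefs = {s: mx[best == s].to_numpy() for s in subtypes}
    return ReassignmentResult(counts=counts, coefficients=coefs, forced_label=best)
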