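"""Cluster-structure discovery among unclassified samples.

Two complementary tools:

* **NMF consensus clustering** — the expression submatrix is made
  nonnegative by subtracting its global minimum, factorized repeatedly at a
  candidate rank with multiplicative-update (Euclidean) NMF from random
  seeded initializations, and samples are hard-clustered by their dominant
  metagene coefficient.  The consensus matrix records how often two samples
  co-cluster; its cophenetic coefficient measures how tree-like (stable)
  the consensus is, and the rank maximizing it is selected.  Rank 2 is the
  smallest testable rank, so a maximum there is flagged: the one-cluster
  hypothesis must then be examined by reproducibility in independent data.

* **In-Group Proportion (IGP)** — for a group defined by a centroid, the
  fraction of test samples classified to that centroid whose nearest
  neighbor (highest Pearson correlation among the other test samples) is
  classified to it too.  Significance comes from a permutation null that
  scrambles the group centroid's gene values and recomputes the IGP.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import NMF

from .containers import CentroidSet, ExpressionMatrix

__all__ = ["ConsensusResult", "RankSelection", "IGPResult", "nmf_consensus",
           "consensus_clusters", "select_rank", "compute_igp"]

log = logging.getLogger(__name__)

NMF_MAX_ITER = 2000
NMF_TOL = 1e-6


@dataclass
class ConsensusResult:
    """Consensus matrix and cophenetic coefficient for one NMF rank."""

    rank: int
    consensus: pd.DataFrame   # samples x samples, entries in [0, 1], diagonal 1
    cophenetic: float
    n_runs: int
    seed: int


@dataclass
class RankSelection:
    rank: int
    #: True when the maximum sits at rank 2, the smallest testable rank —
    #: the one-cluster hypothesis then needs an independent check (IGP)
    at_minimum_rank: bool
    cophenetics: dict[int, float]


@dataclass
class IGPResult:
    group: str
    igp: float
    n_in_group: int
    null_igps: np.ndarray
    p_value: float


def _cophenetic_coefficient(consensus: np.ndarray) -> float:
    """Pearson correlation between 1-consensus distances and their tree.

    Degenerate flat inputs (zero-variance distance vectors, e.g. a single
    perfectly stable cluster) are scored 1.0 when the tree reproduces the
    distances exactly and 0.0 otherwise.
    """
    d = squareform(1.0 - consensus, checks=False)
    Z = linkage(d, method="average")
    if np.ptp(d) == 0:
        coph_d = cophenet(Z)
        return 1.0 if np.allclose(coph_d, d, atol=1e-12) else 0.0
    c, _ = cophenet(Z, d)
    return float(c)


def nmf_consensus(matrix: ExpressionMatrix, rank: int, n_runs: int = 30,
                  seed: int = 0) -> ConsensusResult:
    """Consensus over ``n_runs`` seeded multiplicative-update NMF runs.

    The matrix is shifted by its global minimum to become nonnegative
    (rank-structure preserving).  Each run clusters samples by dominant
    coefficient; consensus(i, j) is the fraction of runs co-clustering i
    and j.
    """
    n = matrix.n_samples
    if rank >= n:
        raise ValueError(f"rank {rank} must be < sample count {n}")
    if rank < 2:
        raise ValueError("rank must be >= 2")
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    X = matrix.data.to_numpy()
    X = X - X.min()
    rng = np.random.default_rng(seed)
    run_seeds = rng.integers(0, 2**31 - 1, size=n_runs)
    co = np.zeros((n, n))
    for rs in run_seeds:
        model = NMF(n_components=rank, init="random", solver="mu",
                    beta_loss="frobenius", max_iter=NMF_MAX_ITER, tol=NMF_TOL,
                    random_state=int(rs))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence warnings at tight tol
            model.fit(X)
        labels = np.argmax(model.components_, axis=0)
        co += labels[:, None] == labels[None, :]
    consensus = co / n_runs
    np.fill_diagonal(consensus, 1.0)
    coph = _cophenetic_coefficient(consensus)
    frame = pd.DataFrame(consensus, index=matrix.sample_ids, columns=matrix.sample_ids)
    return ConsensusResult(rank=rank, consensus=frame, cophenetic=coph,
                           n_runs=n_runs, seed=seed)


def consensus_clusters(result: ConsensusResult, k: int | None = None) -> pd.Series:
    """Cut the consensus tree into ``k`` (default: the result's rank) clusters."""
    k = result.rank if k is None else k
    d = squareform(1.0 - result.consensus.to_numpy(), checks=False)
    Z = linkage(d, method="average")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=result.consensus.index, name="cluster")


def select_rank(results: list[ConsensusResult]) -> RankSelection:
    """Pick the rank with maximal cophenetic coefficient (ties -> smaller)."""
    if not results:
        raise ValueError("no consensus results supplied")
    ranks = sorted(r.rank for r in results)
    if ranks[0] != 2 or ranks != list(range(2, 2 + len(ranks))):
        raise ValueError(f"need consecutive ranks starting at 2, got {ranks}")
    coph = {r.rank: r.cophenetic for r in results}
    best = max(sorted(coph), key=lambda r: coph[r])
    ties = [r for r in coph if np.isclose(coph[r], coph[best])]
    if len(ties) > 1:
        warnings.warn(f"cophenetic tie among ranks {sorted(ties)}; picking {min(ties)}")
        best = min(ties)
    return RankSelection(rank=best, at_minimum_rank=(best == 2), cophenetics=coph)


# ---------------------------------------------------------------------------
# In-Group Proportion
# ---------------------------------------------------------------------------

def _pearson_cols(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson correlations between columns of A and columns of B."""
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    sa = np.sqrt((A ** 2).sum(axis=0))
    sb = np.sqrt((B ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (A.T @ B) / np.outer(sa, sb)


def compute_igp(test_matrix: ExpressionMatrix, centroids: CentroidSet,
                group: str, B: int = 1000, seed: int = 0) -> IGPResult:
    """IGP of ``group`` in an independent cohort, with a permutation p-value.

    Samples are classified to their nearest centroid (highest Pearson
    correlation over shared genes); nearest neighbors among samples also
    use Pearson correlation.  The null applies one shared permutation of
    the gene rows to the whole centroid matrix per draw — preserving each
    centroid's value distribution and the inter-centroid geometry while
    destroying the gene correspondence to the data — then reclassifies all
    samples and recomputes the group's IGP (an empty permuted group scores
    0).  Permuting only the group's own centroid would leave a degenerate
    point-mass-at-zero null in any well-separated dataset, declaring every
    nonempty group "reproducible".  The p-value uses the add-one estimator
    (1 + #{null >= observed}) / (1 + B) and is therefore never exactly 0.
    """
    if group not in centroids.subtype_names:
        raise ValueError(f"group {group!r} not among centroids {centroids.subtype_names}")
    shared = test_matrix.data.index.intersection(centroids.values.index)
    if len(shared) < 2:
        raise ValueError("need >= 2 shared genes between test matrix and centroids")
    X = test_matrix.data.loc[shared].to_numpy()
    C = centroids.values.loc[shared].to_numpy()
    names = centroids.subtype_names
    gi = names.index(group)

    corr = _pearson_cols(X, C)              # samples x centroids
    sample_corr = _pearson_cols(X, X)       # samples x samples
    np.fill_diagonal(sample_corr, -np.inf)
    nn = np.argmax(sample_corr, axis=1)

    def igp_for(assign: np.ndarray, allow_empty: bool) -> float:
        members = np.flatnonzero(assign == gi)
        if members.size == 0:
            if allow_empty:
                return 0.0
            raise ValueError(f"empty group: no sample classified to {group!r}")
        return float(np.mean(assign[nn[members]] == gi))

    assign = np.argmax(corr, axis=1)
    observed = igp_for(assign, allow_empty=False)
    n_in_group = int((assign == gi).sum())

    rng = np.random.default_rng(seed)
    null = np.empty(B)
    for b in range(B):
        P = C[rng.permutation(C.shape[0]), :]
        null[b] = igp_for(np.argmax(_pearson_cols(X, P), axis=1), allow_empty=True)
    p = (1 + int((null >= observed).sum())) / (1 + B)
    return IGPResult(group=group, igp=observed, n_in_group=n_in_group,
                     null_igps=null, p_value=p)
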