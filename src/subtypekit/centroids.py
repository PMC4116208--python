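"""Standardized subtype centroids and their inter-relationships.

A standardized centroid entry for gene g in subtype j is the mean
expression of g across the subtype's reference samples divided by the
sample SD (n-1 denominator) of g across those samples.  Relationships
between centroids are characterized by Spearman rank correlation and
average-linkage clustering on 1 - Spearman distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import dendrogram, linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

from .containers import CentroidSet, ExpressionMatrix

__all__ = ["CentroidError", "Dendrogram", "compute_centroids",
           "centroid_correlation_matrix", "cluster_centroids"]


class CentroidError(ValueError):
    pass


def compute_centroids(matrix: ExpressionMatrix,
                      labels: Mapping[str, str] | pd.Series,
                      intrinsic_genes: Iterable[str]) -> CentroidSet:
    """Per-subtype standardized centroids over the intrinsic gene list.

    Raises :class:`CentroidError` when a subtype has fewer than 2 samples or
    when any gene has zero within-subtype SD (no silent epsilon patching —
    that would invisibly distort downstream rank correlations).
    """
    labels = pd.Series(dict(labels)) if not isinstance(labels, pd.Series) else labels
    genes = list(intrinsic_genes)
    missing = set(genes) - set(matrix.gene_symbols)
    if missing:
        raise CentroidError(f"intrinsic genes absent from matrix: {sorted(missing)[:5]}")
    samples = [s for s in matrix.sample_ids if s in labels.index]
    labels = labels.loc[samples]
    X = matrix.data.loc[genes, samples]
    out = {}
    for subtype in pd.unique(labels):
        members = labels.index[labels == subtype]
        if len(members) < 2:
            raise CentroidError(f"subtype {subtype!r} has {len(members)} sample(s); need >= 2")
        sub = X.loc[:, members]
        mean = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        zero = sd == 0
        if zero.any():
            gene = sd.index[zero][0]
            raise CentroidError(
                f"zero standard deviation for gene {gene!r} in subtype {subtype!r}")
        out[subtype] = mean / sd
    return CentroidSet(pd.DataFrame(out, index=genes))


def centroid_correlation_matrix(centroids: CentroidSet) -> pd.DataFrame:
    """Symmetric subtype x subtype Spearman correlation matrix (diagonal 1).

    Ties receive average ranks.  A constant centroid yields undefined
    correlations, reported as NaN with a warning.
    """
    if len(centroids.gene_symbols) < 2:
        raise CentroidError("need >= 2 genes to correlate centroids")
    V = centroids.values.to_numpy()
    names = centroids.subtype_names
    const = [n for n, col in zip(names, V.T) if np.ptp(col) == 0]
    if const:
        warnings.warn(f"constant centroid vector(s) {const}: correlations undefined")
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy's own constant-input warning
        rho = spearmanr(V, axis=0).statistic
    if np.ndim(rho) == 0:  # spearmanr collapses the 2x2 case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    rho = np.asarray(rho, dtype=float)
    np.fill_diagonal(rho, 1.0)
    for n in const:
        i = names.index(n)
        rho[i, :] = rho[:, i] = np.nan
    return pd.DataFrame(rho, index=names, columns=names)


@dataclass
class Dendrogram:
    """Average-linkage merge tree with deterministic leaf order."""

    linkage: np.ndarray      # scipy linkage matrix
    labels: list[str]
    leaf_order: list[str]


def cluster_centroids(centroids: CentroidSet) -> Dendrogram:
    """Average-linkage tree of centroids at distance 1 - Spearman correlation."""
    names = centroids.subtype_names
    if len(names) < 2:
        raise CentroidError("need >= 2 centroids to cluster")
    rho = centroid_correlation_matrix(centroids).to_numpy()
    if np.isnan(rho).any():
        raise CentroidError("cannot cluster: undefined correlations (constant centroid)")
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = linkage(squareform(dist, checks=False), method="average")
    order = dendrogram(Z, no_plot=True)["leaves"]
    return Dendrogram(linkage=Z, labels=list(names),
                      leaf_order=[names[i] for i in order])
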