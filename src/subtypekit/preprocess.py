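"""Sample QC, symbol collapsing, median-centering, batch adjustment.

The QC filter mirrors standard multi-cohort microarray curation: a sample
is retained only if its housekeeping-gene profile correlates (Pearson
r > 0.95 by default) with at least half of the other samples.  Batch
adjustment is a per-gene location-scale standardization of each batch onto
the pooled mean/SD — a simplified merger step whose testable contract is
that per-gene per-batch means are equalized.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

__all__ = ["QCReport", "collapse_by_symbol", "housekeeping_filter",
           "median_center", "batch_adjust"]

log = logging.getLogger(__name__)


@dataclass
class QCReport:
    """Outcome of the housekeeping correlation filter."""

    kept: list[str]
    dropped: list[str]
    #: per sample, the fraction of other samples with Pearson r above threshold
    frac_passing: pd.Series

    def __post_init__(self) -> None:
        if set(self.kept) & set(self.dropped):
            raise ValueError("kept and dropped overlap")


def collapse_by_symbol(matrix: ExpressionMatrix,
                       probe_to_symbol: Mapping[str, str]) -> ExpressionMatrix:
    """Average probe rows sharing a gene symbol; drop unmapped probes.

    Output rows are ordered lexicographically by symbol.
    """
    if len(probe_to_symbol) == 0:
        raise ValueError("probe-to-symbol mapping is empty")
    mapped = {p: s for p, s in probe_to_symbol.items() if p in matrix.data.index}
    if not mapped:
        raise ValueError("no probe in the mapping matches the matrix")
    sub = matrix.data.loc[list(mapped)]
    symbols = pd.Series([mapped[p] for p in sub.index], index=sub.index)
    collapsed = sub.groupby(symbols).mean().sort_index()
    return ExpressionMatrix(collapsed, matrix.batch)


def housekeeping_filter(matrix: ExpressionMatrix, hk_genes: Iterable[str],
                        r_threshold: float = 0.95,
                        frac: float = 0.5) -> QCReport:
    """Keep samples correlating with enough of the cohort over housekeeping genes.

    A sample passes iff its Pearson correlation over ``hk_genes`` exceeds
    ``r_threshold`` with at least ``ceil(frac * (n - 1))`` of the other
    samples.  An undefined correlation (a constant housekeeping vector)
    counts as a failure for that pair.
    """
    hk = list(hk_genes)
    missing = set(hk) - set(matrix.gene_symbols)
    if missing:
        raise ValueError(f"housekeeping genes absent from matrix: {sorted(missing)[:5]}")
    n = matrix.n_samples
    if n < 2:
        raise ValueError("housekeeping filter needs at least 2 samples")
    X = matrix.data.loc[hk].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X, rowvar=False)
    if np.isnan(R).any():
        const = [matrix.sample_ids[j] for j in range(n) if np.std(X[:, j]) == 0]
        log.warning("constant housekeeping vector in %d sample(s) %s; "
                    "their pairwise correlations count as failing",
                    len(const), const[:5])
    passing = (R > r_threshold) & ~np.isnan(R)
    np.fill_diagonal(passing, False)
    counts = passing.sum(axis=1)
    needed = math.ceil(frac * (n - 1))
    keep_mask = counts >= needed
    ids = matrix.sample_ids
    frac_passing = pd.Series(counts / (n - 1), index=ids, name="frac_passing")
    kept = [s for s, k in zip(ids, keep_mask) if k]
    dropped = [s for s, k in zip(ids, keep_mask) if not k]
    if dropped:
        log.info("housekeeping filter dropped %d/%d samples", len(dropped), n)
    return QCReport(kept=kept, dropped=dropped, frac_passing=frac_passing)


def median_center(matrix: ExpressionMatrix, axis: str = "gene") -> ExpressionMatrix:
    """Subtract per-gene (axis="gene") or per-sample (axis="sample") medians."""
    if matrix.data.size == 0:
        raise ValueError("empty matrix")
    if axis == "gene":
        centered = matrix.data.sub(matrix.data.median(axis=1), axis=0)
    elif axis == "sample":
        centered = matrix.data.sub(matrix.data.median(axis=0), axis=1)
    else:
        raise ValueError(f"axis must be 'gene' or 'sample', got {axis!r}")
    return ExpressionMatrix(centered, matrix.batch)


def batch_adjust(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene location-scale standardization of each batch to the pooled scale.

    Each batch's values for a gene are shifted/scaled so their mean and SD
    match the pooled per-gene mean and SD; a batch with zero within-batch
    variance for a gene is shifted only (logged).  After adjustment the
    per-gene per-batch means agree to numerical tolerance.
    """
    if matrix.batch is None:
        raise ValueError("batch labels are required for batch adjustment")
    counts = matrix.batch.value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"every batch needs >= 2 samples; too small: {list(small.index)}")
    X = matrix.data.to_numpy(copy=True)
    pooled_mean = X.mean(axis=1)
    pooled_sd = X.std(axis=1, ddof=1)
    n_shift_only = 0
    for bname in counts.index:
        cols = np.asarray(matrix.batch.to_numpy() == bname)
        B = X[:, cols]
        bmean = B.mean(axis=1)
        bsd = B.std(axis=1, ddof=1)
        zero = bsd == 0
        n_shift_only += int(zero.sum())
        scale = np.where(zero | (pooled_sd == 0), 1.0, pooled_sd / np.where(bsd == 0, 1.0, bsd))
        X[:, cols] = (B - bmean[:, None]) * scale[:, None] + pooled_mean[:, None]
    if n_shift_only:
        log.warning("batch adjustment used shift-only (zero within-batch variance) "
                    "for %d gene-batch pairs", n_shift_only)
    return ExpressionMatrix(pd.DataFrame(X, index=matrix.data.index,
                                         columns=matrix.data.columns), matrix.batch)
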