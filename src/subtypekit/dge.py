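"""Moderated-F differential expression, BY adjustment, fold filtering, ORA.

Per-gene one-way group-means fits give a residual variance s_g^2 on d_g
degrees of freedom.  An empirical-Bayes prior (d0, s0^2) is estimated by
moment-matching the log sample variances against their theoretical scaled-F
distribution (digamma/trigamma equations, trigamma inverted by Newton).
Each gene's posterior variance

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

replaces s_g^2 in the ordinary F statistic; the reference distribution is
F(k-1, d0 + d_g).  Pairwise contrasts against a focal subtype, BY
(Benjamini-Yekutieli) adjustment, a 2-fold |log2 FC| filter and a 3-way
expression-pattern call (focal near the max / near the min / intermediate)
complete the module, plus a generic hypergeometric over-representation
test over GMT gene sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import polygamma
from scipy.stats import chi2, f as f_dist, hypergeom
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix

__all__ = ["GroupFit", "VariancePrior", "fit_group_model", "estimate_prior",
           "moderated_f", "by_adjust", "fc_filter", "pattern_classify",
           "pairwise_dge", "ora_hypergeometric"]

log = logging.getLogger(__name__)


@dataclass
class GroupFit:
    """Per-gene one-way group-means fit."""

    means: pd.DataFrame       # genes x groups
    s2: pd.Series             # pooled residual variance per gene
    df_residual: int          # n - k
    n_per_group: pd.Series


@dataclass
class VariancePrior:
    """Empirical-Bayes variance hyperparameters (d0 may be infinite)."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise ValueError("d0 must be > 0")
        if not (self.s0_sq > 0):
            raise ValueError("s0_sq must be > 0")


def fit_group_model(matrix: ExpressionMatrix,
                    labels: Mapping[str, str] | pd.Series) -> GroupFit:
    """One-way fit: per-gene group means and pooled residual variance."""
    labels = pd.Series(dict(labels)) if not isinstance(labels, pd.Series) else labels
    samples = [s for s in matrix.sample_ids if s in labels.index]
    labels = labels.loc[samples]
    groups = list(pd.unique(labels))
    sizes = labels.value_counts()
    small = sizes[sizes < 2]
    if len(small):
        raise ValueError(f"groups with < 2 samples: {list(small.index)}")
    n, k = len(samples), len(groups)
    if n - k <= 0:
        raise ValueError(f"non-positive residual df: n={n}, k={k}")
    X = matrix.data.loc[:, samples]
    means = X.T.groupby(labels).mean().T[groups]
    ss_within = np.zeros(matrix.n_genes)
    for g in groups:
        sub = X.loc[:, labels.index[labels == g]]
        ss_within += ((sub.sub(means[g], axis=0)) ** 2).sum(axis=1).to_numpy()
    s2 = pd.Series(ss_within / (n - k), index=X.index, name="s2")
    return GroupFit(means=means, s2=s2, df_residual=n - k,
                    n_per_group=sizes[groups])


def _trigamma_inverse(t: float, tol: float = 1e-8, max_iter: int = 100) -> float:
    """Solve trigamma(y) = t for y > 0 by Newton iteration."""
    if t <= 0:
        raise ValueError("trigamma inverse needs a positive target")
    y = 0.5 + 1.0 / t
    for _ in range(max_iter):
        tri = float(polygamma(1, y))
        tet = float(polygamma(2, y))
        step = (tri - t) / tet
        y_new = y - step
        if y_new <= 0:
            y_new = y / 2.0
        if abs(y_new - y) < tol * max(1.0, abs(y)):
            return y_new
        y = y_new
    return y


def estimate_prior(s2: Sequence[float] | pd.Series, df: int) -> VariancePrior:
    """Moment-match (d0, s0^2) from the spread of log sample variances.

    With true residual variance shared across genes, s_g^2/sigma_g^2 is
    scaled chi-square, so z_g = log s_g^2 has variance trigamma(d/2) plus
    the prior's trigamma(d0/2).  Excess spread is inverted through the
    trigamma function; spread at or below the theoretical minimum yields
    d0 = inf with a geometric-mean-based s0^2 (logged).
    Genes with nonpositive s_g^2 carry no log-variance information and are
    excluded from hyperparameter estimation.
    """
    s2 = np.asarray(pd.Series(s2), dtype=float)
    pos = s2[s2 > 0]
    if pos.size < 10:
        raise ValueError(f"need >= 10 genes with positive variance, got {pos.size}")
    if df < 1:
        raise ValueError("residual df must be >= 1")
    z = np.log(pos)
    e = z - float(polygamma(0, df / 2.0)) + np.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1))
    excess = e_var - float(polygamma(1, df / 2.0))
    if excess <= 0:
        log.info("log-variance spread at/below theoretical minimum; d0 = inf")
        return VariancePrior(d0=np.inf, s0_sq=float(np.exp(e_mean)))
    half_d0 = _trigamma_inverse(excess)
    d0 = 2.0 * half_d0
    s0_sq = float(np.exp(e_mean + float(polygamma(0, half_d0)) - np.log(half_d0)))
    return VariancePrior(d0=d0, s0_sq=s0_sq)


def moderated_f(fit: GroupFit, prior: VariancePrior) -> pd.DataFrame:
    """Moderated F statistics and raw p-values for the fit's k groups.

    Returns a frame with columns ``ms_between``, ``s2_posterior``,
    ``moderated_F`` and ``p_raw``.  d0 -> 0 recovers the ordinary F
    statistic; d0 = inf tests against the prior variance with an
    F(k-1, inf) (i.e. scaled chi-square) reference.
    """
    k = fit.means.shape[1]
    if k < 2:
        raise ValueError("need >= 2 groups for an F statistic")
    n = fit.n_per_group.to_numpy(dtype=float)
    grand = (fit.means.to_numpy() * n).sum(axis=1) / n.sum()
    ms_between = ((fit.means.to_numpy() - grand[:, None]) ** 2 * n).sum(axis=1) / (k - 1)
    d_g = fit.df_residual
    if np.isinf(prior.d0):
        s2_post = np.full(len(fit.s2), prior.s0_sq)
        df_total = np.inf
    else:
        s2_post = (prior.d0 * prior.s0_sq + d_g * fit.s2.to_numpy()) / (prior.d0 + d_g)
        df_total = prior.d0 + d_g
    if np.any(s2_post <= 0):
        bad = fit.s2.index[s2_post <= 0][0]
        raise ValueError(f"nonpositive posterior variance for gene {bad!r}")
    F = ms_between / s2_post
    if np.isinf(df_total):
        p = chi2.sf(F * (k - 1), df=k - 1)
    else:
        p = f_dist.sf(F, k - 1, df_total)
    return pd.DataFrame({"ms_between": ms_between, "s2_posterior": s2_post,
                         "moderated_F": F, "p_raw": p}, index=fit.s2.index)


def by_adjust(p_raw: Sequence[float]) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjustment (valid under dependence).

    Equivalent to the step-up rule adjusted_(i) = min over j >= i of
    m * c(m) * p_(j) / j with c(m) = sum_{i=1..m} 1/i, capped at 1, with
    the original order restored.
    """
    p = np.asarray(list(p_raw), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_by")[1]


def fc_filter(result: pd.DataFrame, threshold_fold: float = 2.0,
              alpha: float = 0.05) -> tuple[list[str], list[str]]:
    """Significant genes with at least ``threshold_fold``-fold change.

    A gene is retained iff its BY-adjusted p-value is below ``alpha`` and
    |log2 FC| >= log2(threshold_fold), inclusive at the fold boundary.
    Returns (up-regulated, down-regulated) gene lists.
    """
    needed = {"log2_fc", "p_by"}
    if not needed <= set(result.columns):
        raise ValueError(f"result frame needs columns {sorted(needed)}")
    lfc_min = np.log2(threshold_fold)
    keep = (result["p_by"] < alpha) & (result["log2_fc"].abs() >= lfc_min)
    up = list(result.index[keep & (result["log2_fc"] > 0)])
    down = list(result.index[keep & (result["log2_fc"] < 0)])
    return up, down


def pattern_classify(means: pd.DataFrame, focal: str,
                     tol: float = 0.25) -> pd.Series:
    """Classify each gene's expression pattern relative to the focal group.

    pattern1: the focal group's mean is within ``tol`` log2 units of the
    maximum across groups (focal among the highest expressers); pattern2:
    within ``tol`` of the minimum; pattern3: intermediate.
    """
    if focal not in means.columns:
        raise ValueError(f"focal group {focal!r} not among means columns")
    fm = means[focal]
    hi = means.max(axis=1)
    lo = means.min(axis=1)
    out = pd.Series("pattern3", index=means.index, name="pattern")
    out[fm >= hi - tol] = "pattern1"
    out[(fm <= lo + tol) & (fm < hi - tol)] = "pattern2"
    return out


def pairwise_dge(matrix: ExpressionMatrix, labels: Mapping[str, str] | pd.Series,
                 focal: str, pooling: str = "pair", alpha: float = 0.05,
                 threshold_fold: float = 2.0) -> dict[str, pd.DataFrame]:
    """Moderated-F contrasts of the focal subtype vs each other subtype.

    ``pooling="pair"`` estimates residual variance and the variance prior
    within each compared pair; ``pooling="all"`` uses the all-group fit.
    Each contrast frame has log2_fc (focal minus other, log2 scale),
    moderated_F, p_raw, p_by, direction and passes_fc columns; BY
    adjustment is applied across genes within the contrast.
    """
    labels = pd.Series(dict(labels)) if not isinstance(labels, pd.Series) else labels
    if pooling not in ("pair", "all"):
        raise ValueError("pooling must be 'pair' or 'all'")
    others = [g for g in pd.unique(labels) if g != focal]
    if focal not in set(labels):
        raise ValueError(f"focal group {focal!r} absent from labels")
    results: dict[str, pd.DataFrame] = {}
    if pooling == "all":
        full_fit = fit_group_model(matrix, labels)
        full_prior = estimate_prior(full_fit.s2, full_fit.df_residual)
    for other in others:
        pair_labels = labels[labels.isin([focal, other])]
        fit = fit_group_model(matrix, pair_labels)
        if pooling == "pair":
            prior = estimate_prior(fit.s2, fit.df_residual)
        else:
            fit = GroupFit(means=fit.means, s2=full_fit.s2,
                           df_residual=full_fit.df_residual,
                           n_per_group=fit.n_per_group)
            prior = full_prior
        stats = moderated_f(fit, prior)
        lfc = fit.means[focal] - fit.means[other]
        frame = pd.DataFrame({
            "log2_fc": lfc,
            "moderated_F": stats["moderated_F"],
            "p_raw": stats["p_raw"],
            "p_by": by_adjust(stats["p_raw"]),
        })
        frame["direction"] = np.where(frame["log2_fc"] >= 0, "up", "down")
        frame["passes_fc"] = frame["log2_fc"].abs() >= np.log2(threshold_fold)
        results[other] = frame
    return results


def ora_hypergeometric(selected: Iterable[str], universe: Iterable[str],
                       collections: Mapping[str, Sequence[str]]) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of each gene set.

    Gene sets are intersected with the universe; the tail probability of
    drawing at least the observed overlap when sampling |selected| genes
    without replacement is reported, BY-adjusted across sets.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    selected = set(selected)
    stray = selected - universe
    if stray:
        raise ValueError(f"selected genes outside the universe: {sorted(stray)[:5]}")
    N, n = len(universe), len(selected)
    rows = []
    for name, genes in collections.items():
        members = set(genes) & universe
        K = len(members)
        k = len(members & selected)
        p = float(hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append((name, K, k, p))
    out = pd.DataFrame(rows, columns=["gene_set", "n_set", "overlap", "p_raw"])
    out["p_by"] = by_adjust(out["p_raw"]) if len(out) else []
    return out.set_index("gene_set")
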