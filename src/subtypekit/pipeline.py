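"""End-to-end orchestration: QC -> centroids -> classification -> cutoff ->
discovery -> merged-subtype validation -> survival -> DGE -> patterns/ORA.

``run_full`` executes the whole analysis from a YAML/py config, writes every
stage's output as plain CSV/TSV into the output directory together with a
manifest (package version, seed, parameters), and returns a summary dict.
Runs are reproducible: the same config and seed produce byte-identical
outputs (the timestamped log excepted).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.cluster.hierarchy import dendrogram, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import kruskal, norm, rankdata, tiecorrect

from . import __version__ as _pkg_version
from .containers import (
    DEFAULT_SIGNATURE_PANEL,
    CentroidSet,
    ExpressionMatrix,
    SignaturePanel,
    read_gene_list,
    read_gmt,
    read_survival_csv,
)
from .centroids import centroid_correlation_matrix, cluster_centroids, compute_centroids
from .classify import (
    assign_subtypes,
    derive_cutoff,
    fit_correlation_mixture,
    mixture_lrt_pvalue,
    reassignment_experiment,
)
from .discovery import compute_igp, consensus_clusters, nmf_consensus, select_rank
from .dge import fc_filter, pairwise_dge, pattern_classify, fit_group_model, ora_hypergeometric
from .preprocess import batch_adjust, housekeeping_filter, median_center
from .survival import (
    bonferroni,
    event_redistribution,
    km_estimate,
    logrank_pair,
    multigroup_logrank,
    survival_at,
)

__all__ = ["PipelineConfig", "PipelineError", "run_full", "signature_heatcluster",
           "SignatureClustering", "kruskal_wallis", "KruskalResult",
           "SignaturePanel", "DEFAULT_SIGNATURE_PANEL"]

log = logging.getLogger(__name__)

NOVEL_SUBTYPE_NAME = "luminal_like"


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name in its message."""


@dataclass
class PipelineConfig:
    """Paths and parameters for a full run.  ``cutoff`` may be 'auto'."""

    expression: str
    reference_expression: str
    reference_labels: str
    clinical: str
    intrinsic_genes: str
    housekeeping_genes: str
    out_dir: str
    batch: str | None = None
    test_expression: str | None = None
    gmt: str | None = None
    cutoff: float | str = 0.3
    nmf_ranks: Sequence[int] = (2, 3, 4)
    nmf_runs: int = 20
    igp_b: int = 500
    lrt_b: int = 0              # bootstrap LRT draws for the cutoff (0 = skip)
    endpoints: Sequence[str] = ("DFS", "OS")
    alpha: float = 0.05
    fold_threshold: float = 2.0
    pattern_tol: float = 0.25
    survival_horizon: float = 5.0
    center_axis: str = "gene"
    qc_r_threshold: float = 0.95
    qc_frac: float = 0.5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)

    def validate_paths(self) -> None:
        for name in ("expression", "reference_expression", "reference_labels",
                     "clinical", "intrinsic_genes", "housekeeping_genes",
                     "batch", "test_expression", "gmt"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise PipelineError(f"config: missing input file for {name}: {p}")


# ---------------------------------------------------------------------------
# statistics utilities
# ---------------------------------------------------------------------------

@dataclass
class KruskalResult:
    h: float
    p_value: float
    dunn: pd.DataFrame  # pairwise z and Bonferroni-adjusted p


def kruskal_wallis(groups: Mapping[str, Sequence[float]]) -> KruskalResult:
    """Tie-corrected Kruskal-Wallis H with Dunn's post-hoc pairwise z tests.

    Dunn z uses the tie-corrected rank variance
    (N(N+1)/12 - sum(t^3 - t)/(12(N-1))); pairwise p-values are two-sided
    normal, Bonferroni-adjusted over all pairs.
    """
    names = [g for g in groups if len(groups[g]) > 0]
    if len(names) < 2:
        raise ValueError("need >= 2 nonempty groups")
    values = [np.asarray(groups[g], dtype=float) for g in names]
    pooled = np.concatenate(values)
    if np.ptp(pooled) == 0:
        raise ValueError("all values identical")
    h, p = kruskal(*values)
    ranks = rankdata(pooled)
    n_tot = pooled.size
    offsets = np.cumsum([0] + [v.size for v in values])
    mean_ranks = {g: ranks[offsets[i]:offsets[i + 1]].mean() for i, g in enumerate(names)}
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float((counts ** 3 - counts).sum()) / (12.0 * (n_tot - 1))
    var_base = n_tot * (n_tot + 1) / 12.0 - tie_term
    rows = []
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    for a, b in pairs:
        se = np.sqrt(var_base * (1.0 / len(groups[a]) + 1.0 / len(groups[b])))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        rows.append((a, b, float(z), float(2 * norm.sf(abs(z)))))
    dunn = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p_raw"])
    dunn["p_bonferroni"] = bonferroni(dunn["p_raw"], m=len(pairs))
    return KruskalResult(h=float(h), p_value=float(p), dunn=dunn)


@dataclass
class SignatureClustering:
    """Hierarchical clustering over a marker panel + per-subtype mean scores."""

    sample_linkage: np.ndarray
    gene_linkage: np.ndarray
    sample_leaf_order: list[str]
    gene_leaf_order: list[str]
    #: rows = subtype, columns = cluster_d / cluster_g mean expression
    scores: pd.DataFrame
    genes_present: list[str]
    genes_missing: list[str]


def signature_heatcluster(matrix: ExpressionMatrix, panel: SignaturePanel,
                          labels: Mapping[str, str] | pd.Series) -> SignatureClustering:
    """Cluster samples (Spearman distance) and panel genes (Euclidean).

    Both trees use average linkage, restricted to the panel genes present
    in the matrix (missing genes logged).  Per-subtype mean expression of
    the cluster-D and cluster-G genes is reported so "this subtype is not
    characterized by high panel expression" becomes a numeric assertion.
    """
    labels = pd.Series(dict(labels)) if not isinstance(labels, pd.Series) else labels
    present = [g for g in panel.all_genes if g in matrix.data.index]
    missing = [g for g in panel.all_genes if g not in matrix.data.index]
    if not present:
        raise ValueError("no panel gene present in the matrix")
    if missing:
        log.info("signature panel: %d gene(s) absent from matrix: %s",
                 len(missing), missing)
    X = matrix.data.loc[present]
    # samples: 1 - Spearman correlation distance
    R = np.apply_along_axis(rankdata, 0, X.to_numpy())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(R, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    zs = linkage(squareform(np.clip((dist + dist.T) / 2, 0, None), checks=False),
                 method="average")
    zg = linkage(pdist(X.to_numpy(), metric="euclidean"), method="average")
    s_order = [matrix.sample_ids[i] for i in dendrogram(zs, no_plot=True)["leaves"]]
    g_order = [present[i] for i in dendrogram(zg, no_plot=True)["leaves"]]
    rows = {}
    d_present = [g for g in panel.cluster_d if g in X.index]
    g_present = [g for g in panel.cluster_g if g in X.index]
    for subtype in pd.unique(labels.loc[matrix.sample_ids]):
        members = [s for s in matrix.sample_ids if labels.get(s) == subtype]
        rows[subtype] = {
            "cluster_d": float(X.loc[d_present, members].to_numpy().mean()) if d_present else np.nan,
            "cluster_g": float(X.loc[g_present, members].to_numpy().mean()) if g_present else np.nan,
            "n": len(members),
        }
    scores = pd.DataFrame(rows).T
    scores.index.name = "subtype"
    return SignatureClustering(sample_linkage=zs, gene_linkage=zg,
                               sample_leaf_order=s_order, gene_leaf_order=g_order,
                               scores=scores, genes_present=present,
                               genes_missing=missing)


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_json(payload: dict, path: Path) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True,
                               default=_json_default) + "\n")


def run_full(config: PipelineConfig) -> dict:
    """Execute the full analysis; write per-stage outputs and a summary.

    Stage order: QC filter -> batch adjustment -> median centering ->
    reference centroids -> classification (fixed or auto cutoff) ->
    forced re-assignment of unclassified samples -> novel-subtype centroid
    and centroid relationships -> NMF consensus discovery -> IGP
    validation (split vs merged) on the independent test cohort ->
    survival (KM, pairwise log-rank + Bonferroni, HRs, 5-y survival,
    event redistribution) -> pairwise moderated-F DGE with BY and fold
    filtering -> expression patterns and optional ORA -> signature-panel
    check.  Any stage failure raises :class:`PipelineError` naming the
    stage.
    """
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed}

    @_stage("load")
    def load():
        batch = None
        if config.batch is not None:
            batch = pd.read_csv(config.batch, index_col=0).iloc[:, 0].astype(str)
        expr = ExpressionMatrix.from_tsv(config.expression, batch=batch)
        ref = ExpressionMatrix.from_tsv(config.reference_expression)
        ref_labels = pd.read_csv(config.reference_labels, index_col=0).iloc[:, 0]
        clinical = read_survival_csv(config.clinical)
        intrinsic = read_gene_list(config.intrinsic_genes)
        hk = read_gene_list(config.housekeeping_genes)
        test = (ExpressionMatrix.from_tsv(config.test_expression)
                if config.test_expression else None)
        return expr, ref, ref_labels, clinical, intrinsic, hk, test

    expr, ref, ref_labels, clinical, intrinsic, hk, test_expr = load()

    @_stage("batch_adjust")
    def batch_stage(expr):
        # batch merging precedes QC: cross-batch shifts would otherwise
        # depress housekeeping correlations for every sample
        if expr.batch is not None and expr.batch.value_counts().min() >= 2 \
                and expr.batch.nunique() > 1:
            expr = batch_adjust(expr)
        return expr

    expr = batch_stage(expr)

    @_stage("qc")
    def qc(expr):
        report = housekeeping_filter(expr, hk, config.qc_r_threshold, config.qc_frac)
        frame = report.frac_passing.rename_axis("sample_id").to_frame()
        frame["kept"] = frame.index.isin(report.kept)
        frame.to_csv(out / "qc_report.csv")
        summary["n_samples_input"] = expr.n_samples
        summary["n_samples_kept"] = len(report.kept)
        summary["n_samples_dropped_qc"] = len(report.dropped)
        return expr.subset_samples(report.kept)

    expr = qc(expr)

    @_stage("median_center")
    def center(expr, ref):
        return (median_center(expr, axis=config.center_axis),
                median_center(ref, axis=config.center_axis))

    expr, ref = center(expr, ref)

    @_stage("centroids")
    def build_centroids():
        genes = [g for g in intrinsic if g in ref.gene_symbols]
        cents = compute_centroids(ref, ref_labels, genes)
        cents.to_tsv(out / "reference_centroids.tsv")
        return cents

    cents = build_centroids()

    @_stage("classify")
    def classify_stage():
        prelim = assign_subtypes(expr, cents, cutoff=0.0)
        max_corrs = prelim.max_corr.dropna().to_numpy()
        if config.cutoff == "auto":
            fit = fit_correlation_mixture(max_corrs, k=2, n_starts=5, seed=config.seed)
            cut = derive_cutoff(fit)
            summary["mixture_means"] = [float(m) for m in fit.means]
            summary["mixture_weights"] = [float(w) for w in fit.weights]
            if config.lrt_b > 0:
                summary["cutoff_lrt_p"] = mixture_lrt_pvalue(
                    max_corrs, B=config.lrt_b, seed=config.seed)
        else:
            cut = float(config.cutoff)
        result = assign_subtypes(expr, cents, cutoff=cut)
        result.to_csv(out / "assignments.csv")
        summary["cutoff"] = float(cut)
        n_un = int((~result.assigned).sum())
        summary["n_unclassified"] = n_un
        summary["pct_unclassified"] = round(100.0 * n_un / result.correlations.shape[0], 2)
        return result

    assignment = classify_stage()
    unassigned_ids = [s for s, a in assignment.assigned.items() if not a]

    @_stage("reassignment")
    def reassign():
        if not unassigned_ids:
            return None
        re = reassignment_experiment(assignment)
        re.counts.rename_axis("subtype").rename("n_samples").to_csv(
            out / "reassignment_counts.csv")
        groups = {s: list(v) for s, v in re.coefficients.items() if len(v) >= 2}
        if len(groups) >= 2:
            kw = kruskal_wallis(groups)
            kw.dunn.to_csv(out / "reassignment_dunn.csv", index=False)
            summary["reassignment_kruskal_p"] = kw.p_value
        return re

    reassigned = reassign()

    @_stage("novel_centroid")
    def novel_centroid():
        if len(unassigned_ids) < 2:
            return cents
        genes = [g for g in intrinsic if g in expr.gene_symbols]
        novel_cent = compute_centroids(
            expr.subset_samples(unassigned_ids),
            pd.Series(NOVEL_SUBTYPE_NAME, index=unassigned_ids), genes)
        combined = cents.with_centroid(NOVEL_SUBTYPE_NAME,
                                       novel_cent.values[NOVEL_SUBTYPE_NAME])
        combined.to_tsv(out / "centroids_with_novel.tsv")
        corr = centroid_correlation_matrix(combined)
        corr.round(4).to_csv(out / "centroid_correlations.csv")
        dend = cluster_centroids(combined)
        (out / "centroid_dendrogram_order.txt").write_text(
            "\n".join(dend.leaf_order) + "\n")
        top = corr[NOVEL_SUBTYPE_NAME].drop(NOVEL_SUBTYPE_NAME).sort_values()
        summary["novel_centroid_best_match"] = str(top.index[-1])
        summary["novel_centroid_best_corr"] = round(float(top.iloc[-1]), 4)
        return combined

    combined_cents = novel_centroid()

    @_stage("discovery")
    def discovery_stage():
        if len(unassigned_ids) < max(config.nmf_ranks) + 1:
            return None, None
        sub = expr.subset_samples(unassigned_ids)
        results = [nmf_consensus(sub, rank=r, n_runs=config.nmf_runs,
                                 seed=config.seed + r)
                   for r in config.nmf_ranks]
        sel = select_rank(results)
        pd.Series(sel.cophenetics, name="cophenetic").rename_axis("rank").to_csv(
            out / "nmf_cophenetics.csv")
        summary["selected_rank"] = sel.rank
        summary["rank_at_minimum"] = sel.at_minimum_rank
        summary["cophenetic_at_selected"] = round(sel.cophenetics[sel.rank], 4)
        rank2 = next(r for r in results if r.rank == 2)
        split = consensus_clusters(rank2, k=2)
        split.rename_axis("sample_id").to_csv(out / "nmf_rank2_split.csv")
        return sel, split

    rank_sel, split = discovery_stage()

    @_stage("igp")
    def igp_stage():
        if test_expr is None or split is None or len(unassigned_ids) < 4:
            return
        genes = [g for g in intrinsic if g in expr.gene_symbols]
        test_centered = median_center(test_expr, axis=config.center_axis)
        halves = {}
        for cl in (1, 2):
            ids = list(split.index[split == cl])
            if len(ids) >= 2:
                halves[f"split_{cl}"] = ids
        # both split-half centroids must compete in the same centroid set;
        # tested separately, each would trivially absorb the whole novel
        # population of the test cohort
        split_set = cents
        for name, ids in halves.items():
            cent = compute_centroids(expr.subset_samples(ids),
                                     pd.Series(name, index=ids), genes)
            split_set = split_set.with_centroid(name, cent.values[name])
        igp_rows = []
        for name in halves:
            try:
                res = compute_igp(test_centered, split_set, name,
                                  B=config.igp_b, seed=config.seed)
                igp_rows.append((name, res.igp, res.n_in_group, res.p_value))
                summary[f"igp_{name}_p"] = res.p_value
            except ValueError as exc:
                log.warning("IGP for %s: %s", name, exc)
                igp_rows.append((name, np.nan, 0, np.nan))
                summary[f"igp_{name}_p"] = None
        merged = compute_igp(test_centered, combined_cents, NOVEL_SUBTYPE_NAME,
                             B=config.igp_b, seed=config.seed)
        igp_rows.append(("merged", merged.igp, merged.n_in_group, merged.p_value))
        summary["igp_merged_p"] = merged.p_value
        pd.DataFrame(igp_rows, columns=["group", "igp", "n_in_group", "p_value"]) \
            .to_csv(out / "igp_results.csv", index=False)

    igp_stage()

    # from here on, unclassified samples ARE the novel subtype
    final_labels = assignment.assigned_label.replace(
        {"unclassified": NOVEL_SUBTYPE_NAME})

    @_stage("survival")
    def survival_stage():
        for endpoint in config.endpoints:
            ep = clinical[clinical["endpoint"] == endpoint].copy()
            ep = ep[ep["sample_id"].isin(final_labels.index)]
            ep["subtype"] = ep["sample_id"].map(final_labels)
            groups = [g for g in ep["subtype"].unique() if g != NOVEL_SUBTYPE_NAME]
            rows, raw_ps = [], []
            for g in sorted(groups):
                sub = ep[ep["subtype"] == g]
                surv5 = survival_at(km_estimate(ep, g), config.survival_horizon) \
                    if sub["event"].size else np.nan
                try:
                    lr = logrank_pair(ep, g, NOVEL_SUBTYPE_NAME)
                    raw_ps.append(lr.p_value)
                    rows.append([g, len(sub), lr.p_value, lr.hr, lr.ci_low,
                                 lr.ci_high, round(100 * surv5, 1)])
                except ValueError:
                    raw_ps.append(1.0)
                    rows.append([g, len(sub), np.nan, np.nan, np.nan, np.nan,
                                 round(100 * surv5, 1)])
            adj = bonferroni(raw_ps, m=len(raw_ps)) if raw_ps else []
            frame = pd.DataFrame(rows, columns=["subtype", "n", "p_raw", "hr",
                                                "ci_low", "ci_high",
                                                "survival_5y_pct"])
            frame["p_bonferroni"] = adj
            novel_rows = ep[ep["subtype"] == NOVEL_SUBTYPE_NAME]
            if len(novel_rows):
                s5 = survival_at(km_estimate(ep, NOVEL_SUBTYPE_NAME),
                                 config.survival_horizon)
                frame.loc[len(frame)] = [NOVEL_SUBTYPE_NAME, len(novel_rows),
                                         np.nan, np.nan, np.nan, np.nan,
                                         round(100 * s5, 1), np.nan]
                summary[f"survival_5y_{endpoint}_novel_pct"] = round(100 * s5, 1)
            frame.to_csv(out / f"survival_{endpoint}.csv", index=False)
            if ep["subtype"].nunique() >= 2 and ep["event"].sum() > 0:
                stat, df, p = multigroup_logrank(ep)
                summary[f"logrank_{endpoint}_p"] = p
            if reassigned is not None:
                forced = reassigned.forced_label
                forced = forced[forced.index.isin(ep["sample_id"])]
                if len(forced):
                    event_redistribution(ep, forced).to_csv(
                        out / f"event_redistribution_{endpoint}.csv")

    survival_stage()

    @_stage("dge")
    def dge_stage():
        counts_labels = final_labels.value_counts()
        usable = counts_labels[counts_labels >= 2].index
        labels_use = final_labels[final_labels.isin(usable)]
        if NOVEL_SUBTYPE_NAME not in set(labels_use) or labels_use.nunique() < 2:
            return None
        contrasts = pairwise_dge(expr, labels_use, focal=NOVEL_SUBTYPE_NAME,
                                 alpha=config.alpha,
                                 threshold_fold=config.fold_threshold)
        intrinsic_set = set(intrinsic)
        rows = []
        de_union: set[str] = set()
        for other, frame in sorted(contrasts.items()):
            frame.rename_axis("gene_symbol").to_csv(out / f"dge_vs_{other}.csv")
            up, down = fc_filter(frame, config.fold_threshold, config.alpha)
            de_union |= set(up) | set(down)
            rows.append([other, len(down), len(up),
                         len([g for g in down if g in intrinsic_set]),
                         len([g for g in up if g in intrinsic_set])])
        table3 = pd.DataFrame(rows, columns=["vs_subtype", "down", "up",
                                             "down_intrinsic", "up_intrinsic"])
        table3.to_csv(out / "dge_counts.csv", index=False)
        summary["dge_total_genes"] = int(sum(r[1] + r[2] for r in rows))
        summary["dge_min_contrast"] = (
            str(table3.set_index("vs_subtype")[["down", "up"]].sum(axis=1).idxmin())
            if len(table3) else None)
        # expression patterns of the DE genes relative to the novel subtype
        full_fit = fit_group_model(expr, labels_use)
        patterns = pattern_classify(full_fit.means, NOVEL_SUBTYPE_NAME,
                                    tol=config.pattern_tol)
        de_sorted = sorted(de_union)
        patt = patterns.loc[de_sorted]
        patt.rename_axis("gene_symbol").to_csv(out / "dge_patterns.csv")
        summary["pattern_counts"] = patt.value_counts().to_dict()
        if config.gmt:
            sets = read_gmt(config.gmt)
            universe = set(expr.gene_symbols)
            chosen = [g for g in de_sorted if patt[g] in ("pattern1", "pattern2")]
            ora = ora_hypergeometric(set(chosen) & universe, universe, sets)
            ora.to_csv(out / "ora_results.csv")
        return table3

    dge_stage()

    @_stage("signature")
    def signature_stage():
        try:
            sc = signature_heatcluster(expr, DEFAULT_SIGNATURE_PANEL, final_labels)
        except ValueError as exc:
            log.warning("signature stage skipped: %s", exc)
            return
        sc.scores.round(4).to_csv(out / "signature_scores.csv")
        (out / "signature_sample_order.txt").write_text(
            "\n".join(sc.sample_leaf_order) + "\n")
        (out / "signature_gene_order.txt").write_text(
            "\n".join(sc.gene_leaf_order) + "\n")
        if NOVEL_SUBTYPE_NAME in sc.scores.index:
            summary["novel_cluster_d_score"] = round(
                float(sc.scores.loc[NOVEL_SUBTYPE_NAME, "cluster_d"]), 4)
            summary["novel_cluster_g_score"] = round(
                float(sc.scores.loc[NOVEL_SUBTYPE_NAME, "cluster_g"]), 4)

    signature_stage()

    manifest = {
        "package": "subtypekit",
        "version": _pkg_version,
        "seed": config.seed,
        "parameters": {k: v for k, v in dataclasses.asdict(config).items()
                       if k != "out_dir"},
    }
    _write_json(manifest, out / "manifest.json")
    _write_json(summary, out / "summary.json")
    return summary
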