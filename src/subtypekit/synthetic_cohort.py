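"""Synthetic breast-tumor expression cohorts with known subtype structure.

Emulates, at desk scale, the statistical structure the subtyping analysis
assumes: several molecular subtypes with distinct intrinsic-gene mean
profiles and Gaussian within-subtype noise, near-constant housekeeping
genes, additive per-batch shifts, a deliberately "unclassifiable" novel
population whose maximal centroid correlation stays below a chosen bound,
occasional bad-quality samples that fail housekeeping QC, and
subtype-dependent exponential survival with uniform censoring.

Every generator is deterministic given the config seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import (
    DEFAULT_SIGNATURE_PANEL,
    CentroidSet,
    ExpressionMatrix,
    write_gene_list,
    write_survival_csv,
)

__all__ = [
    "SyntheticCohortConfig",
    "LabeledCohort",
    "GenerationError",
    "CANONICAL_SUBTYPES",
    "NOVEL_LABEL",
    "BAD_LABEL",
    "default_hazards",
    "generate_reference_panel",
    "generate_mixed_cohort",
    "generate_survival",
    "write_cohort",
]

log = logging.getLogger(__name__)

#: subtype names used when n_subtypes == 7, matching the established
#: breast-tumor molecular taxonomy the classifier targets
CANONICAL_SUBTYPES = ("basal_like", "claudin_low", "erbb2", "luminal_a",
                      "luminal_b", "normal_like", "apocrine")
NOVEL_LABEL = "novel"
BAD_LABEL = "bad"

BASELINE_LOG2 = 7.0          # background/intrinsic baseline intensity
HK_BASELINE_LOG2 = 9.0       # housekeeping genes sit high and stable
HK_NOISE_SD = 0.05           # keeps pairwise housekeeping Pearson r > 0.95
NOVEL_SHRINK = 0.85          # per-iteration shrink of the novel profile
NOVEL_MAX_ITER = 60


class GenerationError(RuntimeError):
    pass


@dataclass
class SyntheticCohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults are a desk-scale stand-in for a multi-cohort breast-tumor
    collection: 7 subtypes x 30 samples plus 70 novel samples (a quarter of
    the cohort unclassifiable), 350 intrinsic + 600 background genes, 68
    housekeeping genes, within-subtype noise of 0.5 log2 units around
    +/-2 log2 subtype offsets, and hazards spanning good-prognosis to
    poor-prognosis subtypes with the novel population in between.
    """

    n_subtypes: int = 7
    genes_intrinsic: int = 350
    genes_background: int = 600
    genes_housekeeping: int = 68
    samples_per_subtype: int = 30
    n_novel: int = 70
    n_bad_quality: int = 0
    noise_sd: float = 0.5
    mean_offset: float = 2.0
    batch_count: int = 1
    batch_shift_sd: float = 0.0
    novel_max_corr: float = 0.3
    hazard_per_subtype: Mapping[str, float] | None = None
    censor_time_max: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = dict(n_subtypes=self.n_subtypes, genes_intrinsic=self.genes_intrinsic,
                      genes_background=self.genes_background,
                      genes_housekeeping=self.genes_housekeeping,
                      samples_per_subtype=self.samples_per_subtype,
                      n_novel=self.n_novel, n_bad_quality=self.n_bad_quality,
                      batch_count=self.batch_count)
        for name, v in counts.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if not 0 <= self.novel_max_corr < 1:
            raise ValueError("novel_max_corr must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.batch_shift_sd < 0:
            raise ValueError("batch_shift_sd must be >= 0")
        if self.censor_time_max <= 0:
            raise ValueError("censor_time_max must be > 0")
        if self.hazard_per_subtype is not None:
            for k, h in self.hazard_per_subtype.items():
                if h < 0:
                    raise ValueError(f"negative hazard for {k!r}: {h}")

    @property
    def subtype_names(self) -> list[str]:
        if self.n_subtypes == len(CANONICAL_SUBTYPES):
            return list(CANONICAL_SUBTYPES)
        return [f"subtype_{i + 1:02d}" for i in range(self.n_subtypes)]

    def hazards(self) -> dict[str, float]:
        if self.hazard_per_subtype is not None:
            return dict(self.hazard_per_subtype)
        return default_hazards(self.subtype_names)


def default_hazards(subtype_names: list[str]) -> dict[str, float]:
    """Per-subtype yearly event rates spanning good to poor prognosis.

    For the canonical 7-subtype taxonomy the ordering follows the clinical
    picture (luminal A / normal-like best, basal-like worst) with the novel
    population intermediate; otherwise rates are spread evenly.
    """
    canonical = {"basal_like": 0.15, "claudin_low": 0.10, "erbb2": 0.12,
                 "luminal_a": 0.03, "luminal_b": 0.11, "normal_like": 0.04,
                 "apocrine": 0.09}
    if set(subtype_names) <= set(canonical):
        hz = {s: canonical[s] for s in subtype_names}
    else:
        rates = np.linspace(0.04, 0.15, max(len(subtype_names), 1))
        hz = {s: float(r) for s, r in zip(subtype_names, rates)}
    hz[NOVEL_LABEL] = 0.07
    hz[BAD_LABEL] = 0.08
    return hz


@dataclass
class LabeledCohort:
    """Expression + ground-truth labels + clinical table for one cohort."""

    expression: ExpressionMatrix
    true_subtype: pd.Series
    clinical: pd.DataFrame

    def __post_init__(self) -> None:
        if set(self.true_subtype.index) != set(self.expression.sample_ids):
            raise ValueError("label map must cover exactly the expression sample ids")


# ---------------------------------------------------------------------------
# gene panel / mean-profile construction
# ---------------------------------------------------------------------------

def _gene_names(config: SyntheticCohortConfig) -> tuple[list[str], list[str], list[str]]:
    intrinsic = [f"ING{i + 1:04d}" for i in range(config.genes_intrinsic)]
    background = [f"BGG{i + 1:04d}" for i in range(config.genes_background)]
    housekeeping = [f"HKG{i + 1:04d}" for i in range(config.genes_housekeeping)]
    # With the canonical taxonomy, seed real marker symbols into the blocks
    # they mark in tumors: the luminal/ER program into the luminal A block,
    # proliferation markers into the basal-like block.  This lets the
    # signature-panel stage operate on synthetic cohorts.
    names = config.subtype_names
    if names == list(CANONICAL_SUBTYPES) and config.genes_intrinsic >= 2 * config.n_subtypes:
        blocks = _blocks(config)
        g_block = blocks[names.index("luminal_a")]
        d_block = blocks[names.index("basal_like")]
        for pos, sym in zip(g_block, DEFAULT_SIGNATURE_PANEL.cluster_g):
            intrinsic[pos] = sym
        for pos, sym in zip(d_block, DEFAULT_SIGNATURE_PANEL.cluster_d):
            intrinsic[pos] = sym
    return intrinsic, background, housekeeping


def _blocks(config: SyntheticCohortConfig) -> list[np.ndarray]:
    """Disjoint intrinsic-gene index blocks, one per subtype."""
    return [np.asarray(b) for b in
            np.array_split(np.arange(config.genes_intrinsic), config.n_subtypes)]


def _mean_profiles(config: SyntheticCohortConfig) -> pd.DataFrame:
    """Intrinsic-gene mean offsets (log2, relative to baseline) per subtype.

    Each subtype owns a disjoint gene block; the first half of its block is
    shifted up by ``mean_offset`` and the second half down by the same
    amount, yielding separable standardized centroids.
    """
    names = config.subtype_names
    prof = np.zeros((config.genes_intrinsic, config.n_subtypes))
    for j, block in enumerate(_blocks(config)):
        half = len(block) // 2
        prof[block[:half], j] = config.mean_offset
        prof[block[half:], j] = -config.mean_offset
    intrinsic, _, _ = _gene_names(config)
    return pd.DataFrame(prof, index=intrinsic, columns=names)


def _draw_block(rng: np.random.Generator, mean_vec: np.ndarray, n: int,
                sd: float) -> np.ndarray:
    return mean_vec[:, None] + rng.normal(0.0, sd, size=(mean_vec.size, n))


def _baseline_means(config: SyntheticCohortConfig, rng: np.random.Generator):
    """Per-gene baseline intensities shared by all samples (drawn once)."""
    bg = rng.normal(BASELINE_LOG2, 1.0, size=config.genes_background)
    hk = rng.normal(HK_BASELINE_LOG2, 1.0, size=config.genes_housekeeping)
    return bg, hk


def _assemble(config: SyntheticCohortConfig, rng: np.random.Generator,
              intrinsic_cols: list[np.ndarray], labels: list[str],
              ids: list[str], bg_mean: np.ndarray, hk_mean: np.ndarray,
              scramble_hk: set[str] | None = None) -> ExpressionMatrix:
    intrinsic_names, bg_names, hk_names = _gene_names(config)
    n = len(ids)
    intr = np.column_stack(intrinsic_cols) if intrinsic_cols else np.empty((config.genes_intrinsic, 0))
    bg = _draw_block(rng, bg_mean, n, config.noise_sd)
    hk = _draw_block(rng, hk_mean, n, HK_NOISE_SD)
    if scramble_hk:
        for j, sid in enumerate(ids):
            if sid in scramble_hk:
                hk[:, j] = rng.permutation(hk[:, j])
    data = pd.DataFrame(np.vstack([intr, bg, hk]),
                        index=intrinsic_names + bg_names + hk_names, columns=ids)
    return ExpressionMatrix(data)


# ---------------------------------------------------------------------------
# reference panel
# ---------------------------------------------------------------------------

def generate_reference_panel(config: SyntheticCohortConfig) -> LabeledCohort:
    """Labeled reference cohort for centroid building (no novel samples)."""
    if config.samples_per_subtype == 0:
        raise GenerationError("samples_per_subtype must be > 0 for a reference panel")
    rng = np.random.default_rng(config.seed)
    bg_mean, hk_mean = _baseline_means(config, rng)
    profiles = _mean_profiles(config)
    names = config.subtype_names

    ids: list[str] = []
    labels: list[str] = []
    cols: list[np.ndarray] = []
    for subtype in names:
        mean_vec = BASELINE_LOG2 + profiles[subtype].to_numpy()
        block = _draw_block(rng, mean_vec, config.samples_per_subtype, config.noise_sd)
        for i in range(config.samples_per_subtype):
            ids.append(f"ref_{subtype}_{i + 1:03d}")
            labels.append(subtype)
            cols.append(block[:, i])
    expr = _assemble(config, rng, cols, labels, ids, bg_mean, hk_mean)
    truth = pd.Series(labels, index=ids, name="subtype")
    clinical = _clinical_for(truth, config)
    return LabeledCohort(expr, truth, clinical)


# ---------------------------------------------------------------------------
# mixed cohort with novel / bad-quality populations
# ---------------------------------------------------------------------------

def _spearman_to_centroids(vec: pd.Series, centroids: CentroidSet) -> np.ndarray:
    shared = centroids.values.index.intersection(vec.index)
    x = rankdata(vec.loc[shared].to_numpy())
    C = centroids.values.loc[shared].to_numpy()
    xc = x - x.mean()
    out = np.empty(C.shape[1])
    for j in range(C.shape[1]):
        c = rankdata(C[:, j])
        cc = c - c.mean()
        denom = np.sqrt((xc ** 2).sum() * (cc ** 2).sum())
        out[j] = (xc @ cc) / denom if denom > 0 else np.nan
    return out


def _novel_pair(config: SyntheticCohortConfig) -> tuple[str, str]:
    names = config.subtype_names
    if "luminal_a" in names and "luminal_b" in names:
        return "luminal_a", "luminal_b"
    return names[0], names[min(1, len(names) - 1)]


def generate_mixed_cohort(config: SyntheticCohortConfig,
                          reference_centroids: CentroidSet) -> LabeledCohort:
    """Cohort of classifiable + novel + bad-quality samples.

    Novel samples form a single Gaussian cluster: an even mixture of two
    (luminal, when available) subtype profiles plus one cohort-level
    orthogonal direction, shrunk per sample until its maximal Spearman
    correlation to every reference centroid falls below
    ``config.novel_max_corr`` (verified numerically; a bounded iteration
    budget of 60 shrink steps applies).  Bad-quality samples have their
    housekeeping values scrambled so they fail QC.  Batch labels are
    assigned round-robin with additive per-gene shifts of SD
    ``batch_shift_sd``.
    """
    if len(reference_centroids.subtype_names) == 0:
        raise GenerationError("reference_centroids must be nonempty")
    rng = np.random.default_rng(config.seed + 1)
    bg_mean, hk_mean = _baseline_means(config, rng)
    profiles = _mean_profiles(config)
    names = config.subtype_names
    intrinsic_names, _, _ = _gene_names(config)

    ids: list[str] = []
    labels: list[str] = []
    cols: list[np.ndarray] = []
    for subtype in names:
        mean_vec = BASELINE_LOG2 + profiles[subtype].to_numpy()
        block = _draw_block(rng, mean_vec, config.samples_per_subtype, config.noise_sd)
        for i in range(config.samples_per_subtype):
            ids.append(f"mix_{subtype}_{i + 1:03d}")
            labels.append(subtype)
            cols.append(block[:, i])

    if config.n_novel > 0:
        a, b = _novel_pair(config)
        mix_dev = 0.5 * profiles[a].to_numpy() + 0.5 * profiles[b].to_numpy()
        # one orthogonal identity direction for the whole novel population
        u = rng.normal(size=config.genes_intrinsic)
        for v in (profiles[a].to_numpy(), profiles[b].to_numpy()):
            nv = v @ v
            if nv > 0:
                u -= (u @ v) / nv * v
        u *= 0.5 * np.linalg.norm(mix_dev) / max(np.linalg.norm(u), 1e-12)
        base = mix_dev + u
        for i in range(config.n_novel):
            noise = rng.normal(0.0, config.noise_sd, size=config.genes_intrinsic)
            lam, accepted = 1.0, False
            for _ in range(NOVEL_MAX_ITER):
                vec = BASELINE_LOG2 + lam * base + noise
                corr = _spearman_to_centroids(
                    pd.Series(vec, index=intrinsic_names), reference_centroids)
                if np.nanmax(corr) < config.novel_max_corr:
                    accepted = True
                    break
                lam *= NOVEL_SHRINK
            if not accepted:
                raise GenerationError(
                    f"novel sample failed to reach max correlation < "
                    f"{config.novel_max_corr} within {NOVEL_MAX_ITER} iterations")
            ids.append(f"mix_{NOVEL_LABEL}_{i + 1:03d}")
            labels.append(NOVEL_LABEL)
            cols.append(vec)

    scramble: set[str] = set()
    for i in range(config.n_bad_quality):
        sid = f"mix_{BAD_LABEL}_{i + 1:03d}"
        subtype = names[i % len(names)]
        vec = BASELINE_LOG2 + profiles[subtype].to_numpy() + \
            rng.normal(0.0, config.noise_sd, size=config.genes_intrinsic)
        ids.append(sid)
        labels.append(BAD_LABEL)
        cols.append(vec)
        scramble.add(sid)

    expr = _assemble(config, rng, cols, labels, ids, bg_mean, hk_mean,
                     scramble_hk=scramble)

    batch = None
    if config.batch_count >= 1:
        batch_labels = [f"batch_{(i % config.batch_count) + 1}" for i in range(len(ids))]
        batch = pd.Series(batch_labels, index=ids, name="batch")
        if config.batch_shift_sd > 0:
            shifted = expr.data.copy()
            for bname in sorted(set(batch_labels)):
                shift = rng.normal(0.0, config.batch_shift_sd, size=expr.n_genes)
                members = [s for s, bl in zip(ids, batch_labels) if bl == bname]
                shifted.loc[:, members] = shifted.loc[:, members].to_numpy() + shift[:, None]
            expr = ExpressionMatrix(shifted, batch)
        else:
            expr = ExpressionMatrix(expr.data, batch)

    truth = pd.Series(labels, index=ids, name="subtype")
    clinical = _clinical_for(truth, config)
    return LabeledCohort(expr, truth, clinical)


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def generate_survival(labels: Mapping[str, str] | pd.Series,
                      config: SyntheticCohortConfig,
                      endpoint: str = "DFS",
                      seed_offset: int = 0) -> pd.DataFrame:
    """Exponential event times by subtype hazard, uniform right censoring.

    Event time ~ Exp(hazard of the sample's subtype); censor time ~
    U(0, censor_time_max]; the recorded time is the minimum and event = 1
    iff the event came first.  Zero hazard means the event never occurs.
    """
    labels = pd.Series(dict(labels)) if not isinstance(labels, pd.Series) else labels
    hazards = config.hazards()
    missing = set(labels.unique()) - set(hazards)
    if missing:
        raise GenerationError(f"no hazard defined for labels: {sorted(missing)}")
    for k, h in hazards.items():
        if h < 0:
            raise GenerationError(f"negative hazard for {k!r}")
    rng = np.random.default_rng(config.seed + 1000 + seed_offset)
    rows = []
    for sid in labels.index:
        h = hazards[labels[sid]]
        event_time = rng.exponential(1.0 / h) if h > 0 else np.inf
        censor_time = rng.uniform(0.0, config.censor_time_max)
        time = min(event_time, censor_time)
        rows.append((sid, float(time), int(event_time <= censor_time),
                     endpoint, labels[sid]))
    return pd.DataFrame(rows, columns=["sample_id", "time", "event",
                                       "endpoint", "subtype"])


def _clinical_for(truth: pd.Series, config: SyntheticCohortConfig) -> pd.DataFrame:
    dfs = generate_survival(truth, config, endpoint="DFS", seed_offset=1)
    os_ = generate_survival(truth, config, endpoint="OS", seed_offset=2)
    return pd.concat([dfs, os_], ignore_index=True)


# ---------------------------------------------------------------------------
# on-disk layout
# ---------------------------------------------------------------------------

def write_cohort(cohort: LabeledCohort, out_dir: str | Path,
                 prefix: str = "cohort") -> dict[str, Path]:
    """Write expression TSV, clinical CSV, truth CSV (+ batch CSV, gene lists)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / f"{prefix}_expression.tsv",
        "clinical": out / f"{prefix}_clinical.csv",
        "truth": out / f"{prefix}_truth.csv",
    }
    cohort.expression.to_tsv(paths["expression"])
    write_survival_csv(cohort.clinical, paths["clinical"])
    cohort.true_subtype.rename_axis("sample_id").to_csv(paths["truth"])
    if cohort.expression.batch is not None:
        paths["batch"] = out / f"{prefix}_batch.csv"
        cohort.expression.batch.rename_axis("sample_id").to_csv(paths["batch"])
    genes = cohort.expression.gene_symbols
    paths["intrinsic_genes"] = out / f"{prefix}_intrinsic_genes.txt"
    paths["housekeeping_genes"] = out / f"{prefix}_housekeeping_genes.txt"
    write_gene_list([g for g in genes if not g.startswith(("BGG", "HKG"))],
                    paths["intrinsic_genes"])
    write_gene_list([g for g in genes if g.startswith("HKG")],
                    paths["housekeeping_genes"])
    return paths
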