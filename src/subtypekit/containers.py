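"""Shared data containers and plain-text I/O.

The package works on log2-scale gene x sample expression matrices.  All
tabular artifacts are plain text: expression as TSV (first column the gene
symbol, header row the sample ids), centroids as TSV (rows = genes,
columns = subtypes), clinical and assignment tables as CSV, gene sets as
GMT.  Every writer here round-trips losslessly through the matching reader.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "CentroidSet",
    "AssignmentResult",
    "SignaturePanel",
    "DEFAULT_SIGNATURE_PANEL",
    "SURVIVAL_COLUMNS",
    "validate_survival_table",
    "read_survival_csv",
    "write_survival_csv",
    "read_gene_list",
    "write_gene_list",
    "read_gmt",
    "write_gmt",
]

GENE_COLUMN = "gene_symbol"

#: columns of a clinical (survival) table
SURVIVAL_COLUMNS = ("sample_id", "time", "event", "endpoint", "subtype")


def _check_unique(labels: Sequence[str], what: str) -> None:
    if len(set(labels)) != len(labels):
        seen, dup = set(), set()
        for x in labels:
            (dup if x in seen else seen).add(x)
        raise ValueError(f"duplicate {what}: {sorted(dup)[:5]}")


@dataclass
class ExpressionMatrix:
    """Log2-scale expression values, genes in rows, samples in columns.

    Parameters
    ----------
    data:
        DataFrame indexed by unique gene symbols with unique sample-id
        columns; all values must be finite.
    batch:
        Optional per-sample batch labels (index = sample ids).
    """

    data: pd.DataFrame
    batch: pd.Series | None = None

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        _check_unique(list(self.data.index), "gene symbols")
        _check_unique(list(self.data.columns), "sample ids")
        if not np.isfinite(self.data.to_numpy()).all():
            raise ValueError("expression matrix contains non-finite values")
        if self.batch is not None:
            missing = set(self.data.columns) - set(self.batch.index)
            if missing:
                raise ValueError(f"batch labels missing for samples: {sorted(missing)[:5]}")
            self.batch = self.batch.reindex(self.data.columns)

    @property
    def gene_symbols(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = [g for g in genes if g in self.data.index]
        return ExpressionMatrix(self.data.loc[genes], self.batch)

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(sample_ids)
        batch = self.batch.loc[ids] if self.batch is not None else None
        return ExpressionMatrix(self.data.loc[:, ids], batch)

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.index.name = GENE_COLUMN
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, batch: pd.Series | None = None) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return cls(df, batch)


@dataclass
class CentroidSet:
    """Standardized subtype centroids over a shared intrinsic gene list.

    ``values`` is genes x subtypes (matching the on-disk layout); each
    column is one subtype's vector of per-gene mean/SD ratios.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        _check_unique(list(self.values.columns), "subtype names")
        _check_unique(list(self.values.index), "centroid gene symbols")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("centroid set contains non-finite values")

    @property
    def subtype_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def gene_symbols(self) -> list[str]:
        return list(self.values.index)

    def subset_genes(self, genes: Iterable[str]) -> "CentroidSet":
        genes = [g for g in genes if g in self.values.index]
        return CentroidSet(self.values.loc[genes])

    def with_centroid(self, name: str, vector: pd.Series) -> "CentroidSet":
        """Return a new set with an extra centroid aligned on shared genes."""
        shared = self.values.index.intersection(vector.index)
        out = self.values.loc[shared].copy()
        out[name] = vector.loc[shared]
        return CentroidSet(out)

    def to_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.index.name = GENE_COLUMN
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CentroidSet":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return cls(df)


UNCLASSIFIED_LABEL = "unclassified"


@dataclass
class AssignmentResult:
    """Per-sample centroid correlations and the resulting subtype call.

    ``correlations`` is samples x subtypes (Spearman coefficients; NaN row
    for unassignable constant samples).  A sample is *assigned* iff its
    maximal correlation reaches ``cutoff``; otherwise it carries the label
    ``"unclassified"``.
    """

    correlations: pd.DataFrame
    cutoff: float

    @property
    def sample_ids(self) -> list[str]:
        return list(self.correlations.index)

    @property
    def best_subtype(self) -> pd.Series:
        vals = self.correlations.to_numpy()
        cols = np.asarray(self.correlations.columns)
        out = []
        for row in vals:
            out.append(UNCLASSIFIED_LABEL if np.all(np.isnan(row)) else cols[int(np.nanargmax(row))])
        return pd.Series(out, index=self.correlations.index, name="best_subtype")

    @property
    def max_corr(self) -> pd.Series:
        with np.errstate(all="ignore"):
            m = np.nanmax(self.correlations.to_numpy(), axis=1, initial=-np.inf)
        m = np.where(np.isfinite(m), m, np.nan)
        return pd.Series(m, index=self.correlations.index, name="max_corr")

    @property
    def assigned(self) -> pd.Series:
        mc = self.max_corr
        return pd.Series(np.where(np.isnan(mc), False, mc >= self.cutoff),
                         index=mc.index, name="assigned").astype(bool)

    @property
    def assigned_label(self) -> pd.Series:
        """Best subtype where assigned, else ``"unclassified"``."""
        lab = self.best_subtype.where(self.assigned, UNCLASSIFIED_LABEL)
        lab.name = "assigned_label"
        return lab

    def to_frame(self) -> pd.DataFrame:
        out = self.correlations.copy()
        out["best_subtype"] = self.best_subtype
        out["max_corr"] = self.max_corr
        out["assigned"] = self.assigned
        out["assigned_label"] = self.assigned_label
        out.index.name = "sample_id"
        return out

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, cutoff: float) -> "AssignmentResult":
        df = pd.read_csv(path, index_col=0)
        corr = df.drop(columns=["best_subtype", "max_corr", "assigned", "assigned_label"],
                       errors="ignore")
        return cls(corr, cutoff)


def validate_survival_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a clinical table (sample_id, time, event, endpoint, subtype)."""
    missing = set(SURVIVAL_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"clinical table missing columns: {sorted(missing)}")
    t = table.copy()
    t["time"] = t["time"].astype(float)
    t["event"] = t["event"].astype(int)
    if (t["time"] < 0).any():
        raise ValueError("negative survival times")
    if not t["event"].isin((0, 1)).all():
        raise ValueError("event indicator must be 0 or 1")
    dup = t.duplicated(subset=["sample_id", "endpoint"])
    if dup.any():
        raise ValueError("duplicate (sample_id, endpoint) rows in clinical table")
    return t


def read_survival_csv(path: str | Path) -> pd.DataFrame:
    return validate_survival_table(pd.read_csv(path))


def write_survival_csv(table: pd.DataFrame, path: str | Path) -> None:
    validate_survival_table(table).to_csv(path, index=False)


def read_gene_list(path: str | Path) -> list[str]:
    """One gene symbol per line; blank lines ignored."""
    lines = Path(path).read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip()]


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(genes) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Standard GMT: name <TAB> description <TAB> member genes..."""
    sets: dict[str, list[str]] = {}
    for ln in Path(path).read_text().splitlines():
        if not ln.strip():
            continue
        parts = ln.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line (need name, description, >=1 gene): {ln[:60]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | Path,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


@dataclass(frozen=True)
class SignaturePanel:
    """Two marker-gene clusters used to probe luminal-C-like character.

    ``cluster_d`` carries proliferation/metabolism markers high in
    basal-like, ERBB2+ and the historical luminal C tumors; ``cluster_g``
    carries the classic luminal/ER program (ESR1, GATA3, FOXA1, ...).
    """

    cluster_d: tuple[str, ...]
    cluster_g: tuple[str, ...]

    def __post_init__(self) -> None:
        for name, genes in (("cluster_d", self.cluster_d), ("cluster_g", self.cluster_g)):
            if any(g != g.upper() for g in genes):
                raise ValueError(f"{name} symbols must be uppercase")

    @property
    def all_genes(self) -> tuple[str, ...]:
        return self.cluster_d + self.cluster_g


DEFAULT_SIGNATURE_PANEL = SignaturePanel(
    cluster_d=("TFRC", "MYBL2", "KIF23", "LAPTM4B", "GGH", "YBX1",
               "EBNA1BP2", "YWHAZ", "SQLE"),
    cluster_g=("ACADSB", "ESR1", "TFF3", "GATA3", "XBP1", "FOXA1",
               "AFF3", "LIV1", "TUBA1C", "NAT1", "MYO6"),
)
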