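"""Readers and writers for every tabular format the tool touches.

Expression matrices (TSV/CSV, genes as rows), Broad-dialect GMT gene sets,
MAF-style somatic mutation tables, sample-level clinical/covariate tables,
and per-sample score tables.  All loaders validate strictly: duplicate
identifiers, non-numeric cells and out-of-range clinical values are hard
errors with coordinates, never silent coercions.  Gene and sample
identifiers are opaque, case-sensitive strings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GeneSetCollection",
    "read_expression",
    "write_expression",
    "read_gmt",
    "read_maf",
    "read_cohort",
    "read_scores",
    "write_scores",
]

#: canonical clinical roles recognised by `read_cohort`; anything else is
#: kept as a generic covariate column.
CANONICAL_COHORT_COLUMNS = (
    "sample_id",
    "os_time",
    "os_event",
    "dfs_time",
    "dfs_event",
    "stage_group",
    "grade_group",
    "subtype",
    "purity",
    "tmb",
)

MAF_SAMPLE_COLUMN = "Tumor_Sample_Barcode"


def _sep_for(path: str | Path) -> str:
    """Delimiter by extension: .csv is comma, everything else tab."""
    return "," if str(path).endswith(".csv") else "\t"


def _list_duplicates(ids: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for x in ids:
        if x in seen and x not in dups:
            dups.append(x)
        seen.add(x)
    return dups


@dataclass
class ExpressionMatrix:
    """A genes × samples numeric expression matrix.

    Parameters
    ----------
    data
        DataFrame with unique gene ids as index and unique sample ids as
        columns; all values finite floats.
    scale
        ``"linear"`` for untransformed values (RSEM counts etc.) or
        ``"log2p1"`` for values already on the log2(x+1) scale.
    """

    data: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2p1"):
            raise ValueError(f"unknown scale {self.scale!r}")
        self.data = self.data.astype(float)
        self.data.index.name = "gene_id"
        self.data.columns.name = None
        self.validate()

    def validate(self) -> None:
        dup_g = _list_duplicates(list(self.data.index))
        if dup_g:
            raise ValueError(f"duplicate gene ids: {dup_g}")
        dup_s = _list_duplicates(list(self.data.columns))
        if dup_s:
            raise ValueError(f"duplicate sample ids: {dup_s}")
        vals = self.data.to_numpy()
        if vals.size and not np.isfinite(vals).all():
            i, j = np.argwhere(~np.isfinite(vals))[0]
            raise ValueError(
                "non-finite expression value at "
                f"gene {self.data.index[i]!r}, sample {self.data.columns[j]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        """(m genes, t samples)."""
        return self.data.shape

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.copy(), self.scale)


@dataclass
class GeneSetCollection:
    """Named gene sets (signatures / pathways) as parsed from a GMT file."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


def read_expression(
    path: str | Path,
    *,
    transpose: bool = False,
    na_policy: str = "drop_gene",
    collapse: str | None = None,
    scale: str = "linear",
) -> ExpressionMatrix:
    """Load a gene × sample expression table.

    The file has one header row of sample ids and a first column of gene
    ids (``transpose=True`` for the samples-as-rows layout).  Genes
    containing any missing value are dropped under ``na_policy="drop_gene"``
    (count logged) or abort the load under ``"fail"``.  Duplicate gene rows
    are a hard error unless ``collapse="max-mean"``, which keeps the
    duplicate row with the highest mean expression.
    """
    if na_policy not in ("drop_gene", "fail"):
        raise ValueError(f"unknown na_policy {na_policy!r}")
    if collapse not in (None, "max-mean"):
        raise ValueError(f"unknown collapse mode {collapse!r}")
    sep = _sep_for(path)
    raw = pd.read_csv(path, sep=sep, index_col=0, header=0)
    # pandas silently renames duplicate header fields; detect them from the
    # raw header line instead.
    with open(path) as fh:
        header_ids = fh.readline().rstrip("\r\n").split(sep)[1:]
    dup_cols = _list_duplicates(header_ids)
    if dup_cols:
        kind = "gene" if transpose else "sample"
        raise ValueError(f"duplicate {kind} ids in header: {dup_cols}")
    if transpose:
        raw = raw.T
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)

    dup_genes = _list_duplicates(list(raw.index))
    if dup_genes:
        if collapse == "max-mean":
            num_tmp = raw.apply(pd.to_numeric, errors="coerce")
            order = num_tmp.mean(axis=1).to_numpy()
            keep = np.zeros(len(raw), dtype=bool)
            for gene in raw.index.unique():
                pos = np.flatnonzero(raw.index.to_numpy() == gene)
                keep[pos[np.argmax(order[pos])]] = True
            logger.info(
                "collapsed %d duplicate gene rows by max-mean", (~keep).sum()
            )
            raw = raw.iloc[keep]
        else:
            raise ValueError(f"duplicate gene ids: {dup_genes}")
    dup_samples = _list_duplicates(list(raw.columns))
    if dup_samples:
        raise ValueError(f"duplicate sample ids: {dup_samples}")

    num = raw.apply(pd.to_numeric, errors="coerce")
    bad = num.isna() & raw.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric value {raw.iat[i, j]!r} at gene "
            f"{raw.index[i]!r}, sample {raw.columns[j]!r}"
        )
    missing = num.isna().any(axis=1)
    if missing.any():
        if na_policy == "fail":
            genes = list(num.index[missing])
            raise ValueError(f"missing values in genes {genes}")
        logger.warning(
            "dropping %d gene(s) with missing values", int(missing.sum())
        )
        num = num.loc[~missing]
    return ExpressionMatrix(num, scale=scale)


def write_expression(mat: ExpressionMatrix, path: str | Path) -> None:
    mat.data.to_csv(path, sep=_sep_for(path), index_label="gene_id")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a Broad-dialect GMT file: name, description, then genes.

    Empty lines are skipped; a line with fewer than three tab-separated
    fields, or a repeated set name, is an error naming the line number.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"GMT line {lineno}: expected at least 3 tab-separated "
                    f"fields (name, description, genes), got {len(fields)}"
                )
            name, desc = fields[0], fields[1]
            genes = [g for g in fields[2:] if g]
            if not genes:
                raise ValueError(f"GMT line {lineno}: set {name!r} has no genes")
            if name in sets:
                raise ValueError(f"GMT line {lineno}: duplicate set name {name!r}")
            sets[name] = genes
            descriptions[name] = desc
    if not sets:
        logger.warning("GMT file %s contains no gene sets", path)
    return GeneSetCollection(sets, descriptions)


def read_maf(path: str | Path) -> pd.DataFrame:
    """Load a MAF-style mutation table into a per-record DataFrame.

    Only the sample barcode is required; gene symbol and variant columns
    are carried along when present.  Lines starting with ``#`` are
    comments.  Returns columns ``sample_id``, ``gene_symbol``,
    ``variant_classification``, ``variant_type``.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if MAF_SAMPLE_COLUMN not in df.columns:
        raise ValueError(f"MAF file {path} lacks required column {MAF_SAMPLE_COLUMN!r}")
    out = pd.DataFrame({"sample_id": df[MAF_SAMPLE_COLUMN].astype(str)})
    for col, src in (
        ("gene_symbol", "Hugo_Symbol"),
        ("variant_classification", "Variant_Classification"),
        ("variant_type", "Variant_Type"),
    ):
        out[col] = df[src].astype(str) if src in df.columns else ""
    if len(out) and (out["sample_id"].str.len() == 0).any():
        raise ValueError("MAF record with empty sample id")
    return out


_NUMERIC_COHORT = ("os_time", "os_event", "dfs_time", "dfs_event", "purity", "tmb")


def read_cohort(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Load and validate a sample-level clinical/covariate table.

    ``column_map`` renames user columns onto canonical roles
    (:data:`CANONICAL_COHORT_COLUMNS`); unmapped columns are kept as
    generic covariates.  Validation: survival times ≥ 0, event indicators
    in {0, 1}, purity in (0, 1]; NaN is allowed everywhere and means
    "not recorded".
    """
    df = pd.read_csv(path, sep=_sep_for(path))
    if column_map:
        df = df.rename(columns=dict(column_map))
    if "sample_id" not in df.columns:
        raise ValueError("cohort table lacks a 'sample_id' column")
    df["sample_id"] = df["sample_id"].astype(str)
    dups = _list_duplicates(list(df["sample_id"]))
    if dups:
        raise ValueError(f"duplicate sample ids in cohort table: {dups}")
    df = df.set_index("sample_id")
    for col in df.columns:
        if col in _NUMERIC_COHORT or df[col].dtype.kind in "ifb":
            df[col] = pd.to_numeric(df[col], errors="coerce" if col not in _NUMERIC_COHORT else "raise")
    validate_cohort(df)
    return df


def validate_cohort(df: pd.DataFrame) -> None:
    for col in ("os_time", "dfs_time"):
        if col in df.columns:
            bad = df.index[df[col].dropna().lt(0).reindex(df.index, fill_value=False)]
            if len(bad):
                raise ValueError(f"negative {col} for samples {list(bad)}")
    for col in ("os_event", "dfs_event"):
        if col in df.columns:
            vals = df[col].dropna()
            if not vals.isin((0, 1)).all():
                bad = list(vals.index[~vals.isin((0, 1))])
                raise ValueError(f"{col} outside {{0,1}} for samples {bad}")
    if "purity" in df.columns:
        p = df["purity"].dropna()
        bad = list(p.index[(p <= 0) | (p > 1)])
        if bad:
            raise ValueError(f"purity outside (0,1] for samples {bad}")


SCORE_COLUMNS = ("depth2", "depth2_purity_adjusted", "n_genes_used")


def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    """Write a per-sample score table (blank adjusted score when absent)."""
    out = scores.copy()
    if "depth2_purity_adjusted" not in out.columns:
        out["depth2_purity_adjusted"] = np.nan
    cols = [c for c in SCORE_COLUMNS if c in out.columns]
    cols += [c for c in out.columns if c not in cols]
    out[cols].to_csv(path, sep=_sep_for(path), index_label="sample_id")


def read_scores(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep_for(path))
    if "sample_id" not in df.columns or "depth2" not in df.columns:
        raise ValueError("score table needs 'sample_id' and 'depth2' columns")
    df["sample_id"] = df["sample_id"].astype(str)
    return df.set_index("sample_id")
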