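"""Readers and writers for the on-disk formats.

Expression matrices, interaction tables and clinical tables are TSV;
gene sets are GMT; ground truth and reports are JSON.  Gene identifiers
are opaque strings throughout.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable

import pandas as pd

RNA_CLASSES = ("mRNA", "lncRNA", "miRNA")


class FormatError(ValueError):
    """A file does not conform to its declared format."""


@dataclasses.dataclass
class ExpressionMatrix:
    """Gene x sample numeric matrix tagged with an RNA class.

    Duplicate gene IDs are permitted (collapsing them is a cohort
    preprocessing step); duplicate sample IDs are not.
    """

    values: pd.DataFrame
    rna_class: str

    def __post_init__(self) -> None:
        if self.rna_class not in RNA_CLASSES:
            raise ValueError(f"rna_class must be one of {RNA_CLASSES}, got {self.rna_class!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise FormatError(f"duplicate sample ID: {dup!r}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = [s for s in sample_ids if s in self.values.columns]
        return ExpressionMatrix(self.values[ids], self.rna_class)


def read_expression(path: str | Path, rna_class: str) -> ExpressionMatrix:
    """Read a gene x sample TSV (first column gene IDs, header sample IDs).

    Missing or non-numeric cells are errors; the offending row and column
    are named.  Duplicate gene IDs are kept as-is.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_ids = header[1:]
    seen: set[str] = set()
    for s in sample_ids:
        if s in seen:  # pandas would silently mangle these to s, s.1, ...
            raise FormatError(f"{path}: duplicate sample ID {s!r}")
        seen.add(s)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    df.columns = sample_ids
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = numeric.isna().stack()
        gene, sample = bad[bad].index[0]
        raise FormatError(
            f"{path}: non-numeric cell at gene {gene!r}, sample {sample!r}: "
            f"{df.loc[gene, sample]!r}"
        )
    numeric = numeric.astype(float)
    numeric.index.name = df.index.name or "gene"
    return ExpressionMatrix(numeric, rna_class)


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    out = m.values.copy()
    out.index.name = out.index.name or "gene"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_interactions(path: str | Path) -> pd.DataFrame:
    """Read a miRNA->target edge list TSV with columns miRNA_id, target_id.

    Exact duplicate rows collapse to one edge; an optional ``source``
    column is preserved on the first occurrence.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("miRNA_id", "target_id"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return df.drop_duplicates(subset=["miRNA_id", "target_id"]).reset_index(drop=True)


def write_interactions(edges: pd.DataFrame, path: str | Path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def targets_by_mirna(edges: pd.DataFrame) -> dict[str, set[str]]:
    """Group an edge list into per-miRNA target sets."""
    return {m: set(g["target_id"]) for m, g in edges.groupby("miRNA_id", sort=True)}


def mirnas_by_target(edges: pd.DataFrame) -> dict[str, set[str]]:
    """Group an edge list into per-target miRNA sets."""
    return {t: set(g["miRNA_id"]) for t, g in edges.groupby("target_id", sort=True)}


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set file into a term -> gene-set mapping.

    Each line is ``name<TAB>description<TAB>gene[<TAB>gene...]``; within-set
    duplicate genes are removed.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: expected >=3 tab-separated fields")
            name = fields[0]
            genes = {g for g in fields[2:] if g}
            if not genes:
                raise FormatError(f"{path}: line {lineno}: empty gene list for set {name!r}")
            sets[name] = genes
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path, descriptions: dict | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name in sets:
            genes = sorted(sets[name])
            fh.write("\t".join([name, descriptions.get(name, "na"), *genes]) + "\n")


def read_clinical(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: missing required column 'sample_id'")
    return df


def write_clinical(clin: pd.DataFrame, path: str | Path) -> None:
    clin.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def _json_default(o):
    import numpy as np

    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
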