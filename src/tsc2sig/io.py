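"""Readers and writers for the on-disk artifacts of the signature pipeline.

Every artifact is a tab-delimited UTF-8 text file with "." as the decimal
separator; there is deliberately no CSV/Excel autodetection.  Matrices are
stored genes-in-rows (RSEM-style), with the first column holding gene
identifiers and one column per sample.

Gene identifiers are treated as case-sensitive strings throughout; mapping
between mouse and human symbol conventions is done only through an explicit
ortholog map (see :mod:`tsc2sig.scoring`), never by case folding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RAW = "raw"
LOG2P1 = "log2p1"
_SCALES = (RAW, LOG2P1)


class ValidationError(ValueError):
    """An on-disk artifact or in-memory container violated an invariant."""


def _check_unique(ids: Iterable[str], what: str) -> list[str]:
    ids = [str(x) for x in ids]
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)
    return ids


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with an explicit scale tag.

    ``scale`` is ``"raw"`` for non-negative abundance values (FPKM-like or
    normalized-RSEM-like) and ``"log2p1"`` after the log2(x+1) transform.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale: str = RAW

    def __post_init__(self) -> None:
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.values = np.asarray(self.values, dtype=float)
        if self.scale not in _SCALES:
            raise ValidationError(f"unknown scale {self.scale!r}; expected one of {_SCALES}")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"shape mismatch: values {self.values.shape} vs "
                f"({len(self.gene_ids)} genes, {len(self.sample_ids)} samples)"
            )
        bad = ~np.isfinite(self.values)
        if bad.any():
            g, s = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-finite value at gene {self.gene_ids[g]!r}, sample {self.sample_ids[s]!r}"
            )
        if self.scale == RAW and (self.values < 0).any():
            g, s = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative raw expression {self.values[g, s]} at gene "
                f"{self.gene_ids[g]!r}, sample {self.sample_ids[s]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ExpressionMatrix(
            gene_ids=list(self.gene_ids),
            sample_ids=list(sample_ids),
            values=self.values[:, idx],
            scale=self.scale,
        )


def read_expression_matrix(path, scale: str = RAW) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column = gene IDs, header = sample IDs)."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: expected gene-ID column plus >=1 sample column")
    gene_ids = df.iloc[:, 0].tolist()
    sample_ids = [str(c) for c in df.columns[1:]]
    try:
        values = df.iloc[:, 1:].astype(float).to_numpy()
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric expression cell ({exc})") from exc
    return ExpressionMatrix(gene_ids=gene_ids, sample_ids=sample_ids, values=values, scale=scale)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    df = matrix.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Sample metadata

GENOTYPES = ("WT", "KO")
TREATMENTS = ("vehicle", "sirolimus")


def read_sample_table(path) -> pd.DataFrame:
    """Sample metadata: columns sample_id, genotype, treatment, optional pair_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "genotype", "treatment"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing sample-table columns {sorted(missing)}")
    if "pair_id" not in df.columns:
        df["pair_id"] = pd.NA
    validate_sample_table(df)
    return df[["sample_id", "genotype", "treatment", "pair_id"]]


def validate_sample_table(df: pd.DataFrame, matrix: ExpressionMatrix | None = None) -> None:
    _check_unique(df["sample_id"], "sample")
    bad_geno = set(df["genotype"]) - set(GENOTYPES)
    if bad_geno:
        raise ValidationError(f"unknown genotype values {sorted(bad_geno)}; expected {GENOTYPES}")
    bad_trt = set(df["treatment"]) - set(TREATMENTS)
    if bad_trt:
        raise ValidationError(f"unknown treatment values {sorted(bad_trt)}; expected {TREATMENTS}")
    if matrix is not None:
        absent = set(df["sample_id"]) - set(matrix.sample_ids)
        if absent:
            raise ValidationError(f"samples absent from expression matrix: {sorted(absent)}")


def write_sample_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Mutation tables (MAF dialect, three required columns)

MAF_SYNONYMS: Mapping[str, tuple[str, ...]] = {
    "tumor_id": ("tumor_id", "Tumor_Sample_Barcode", "sample_id"),
    "gene_symbol": ("gene_symbol", "Hugo_Symbol", "gene"),
    "variant_classification": ("variant_classification", "Variant_Classification"),
}


def read_mutation_table(path, synonyms: Mapping[str, tuple[str, ...]] = MAF_SYNONYMS) -> pd.DataFrame:
    """Read a MAF-dialect mutation TSV down to the three columns the pipeline uses.

    Unknown variant-classification strings are preserved verbatim; extra
    columns are ignored.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    out = {}
    for canonical, names in synonyms.items():
        found = [c for c in names if c in df.columns]
        if not found:
            raise ValidationError(
                f"{path}: missing column for {canonical!r}; accepted names: {list(names)}"
            )
        out[canonical] = df[found[0]]
    table = pd.DataFrame(out)
    if (table["tumor_id"].fillna("") == "").any() or (table["gene_symbol"].fillna("") == "").any():
        raise ValidationError(f"{path}: empty tumor_id or gene_symbol in mutation record")
    return table


def write_mutation_table(table: pd.DataFrame, path) -> None:
    table.rename(
        columns={
            "tumor_id": "Tumor_Sample_Barcode",
            "gene_symbol": "Hugo_Symbol",
            "variant_classification": "Variant_Classification",
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Signatures

_DIRECTION_TOKENS = {"up": 1, "down": -1, "+1": 1, "-1": -1, "1": 1}


@dataclass
class Signature:
    """Ordered map gene -> direction (+1 up in KO, -1 down in KO) with provenance."""

    genes: dict[str, int] = field(default_factory=dict)
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for g, d in self.genes.items():
            if d not in (1, -1):
                raise ValidationError(f"signature direction for {g!r} must be +1/-1, got {d!r}")

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def up_genes(self) -> list[str]:
        return [g for g, d in self.genes.items() if d == 1]

    @property
    def down_genes(self) -> list[str]:
        return [g for g, d in self.genes.items() if d == -1]


def read_signature(path) -> Signature:
    meta: dict[str, str] = {}
    genes: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    body = []
    for line in lines:
        if line.startswith("#"):
            if "=" in line:
                k, v = line.lstrip("# ").split("=", 1)
                meta[k.strip()] = v.strip()
        elif line.strip():
            body.append(line)
    if not body:
        raise ValidationError(f"{path}: empty signature file (no header row)")
    header = body[0].split("\t")
    if header[:2] != ["gene_id", "direction"]:
        raise ValidationError(f"{path}: expected header 'gene_id\\tdirection', got {header[:2]}")
    for line in body[1:]:
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValidationError(f"{path}: malformed signature row {line!r}")
        gene, token = fields[0], fields[1].strip()
        if token not in _DIRECTION_TOKENS:
            raise ValidationError(
                f"{path}: direction token {token!r} for {gene!r}; accepted: up/down/+1/-1"
            )
        if gene in genes:
            raise ValidationError(f"{path}: duplicate signature gene {gene!r}")
        genes[gene] = _DIRECTION_TOKENS[token]
    if not genes:
        logger.warning("%s: signature file contains a header but no genes", path)
    return Signature(genes=genes, meta=meta)


def write_signature(sig: Signature, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for k, v in sig.meta.items():
            fh.write(f"# {k} = {v}\n")
        fh.write("gene_id\tdirection\n")
        for g, d in sig.genes.items():
            fh.write(f"{g}\t{'+1' if d == 1 else '-1'}\n")


# ---------------------------------------------------------------------------
# Ortholog maps and annotation tables

def read_ortholog_map(path) -> pd.DataFrame:
    """Two-column TSV: mouse_gene, human_gene."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"mouse_gene", "human_gene"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing ortholog-map columns {sorted(missing)}")
    return df[["mouse_gene", "human_gene"]]


def write_ortholog_map(df: pd.DataFrame, path) -> None:
    df[["mouse_gene", "human_gene"]].to_csv(path, sep="\t", index=False)


def read_annotation_table(path) -> dict[str, set[str]]:
    """Annotation TSV (gene_id, category; one row per gene-category pair) -> gene -> categories."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"gene_id", "category"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing annotation columns {sorted(missing)}")
    if (df["category"].fillna("") == "").any():
        raise ValidationError(f"{path}: empty annotation category")
    out: dict[str, set[str]] = {}
    for gene, cat in zip(df["gene_id"], df["category"]):
        out.setdefault(gene, set()).add(cat)
    return out


def write_annotation_table(ann: Mapping[str, set[str]], path) -> None:
    rows = [(g, c) for g, cats in ann.items() for c in sorted(cats)]
    pd.DataFrame(rows, columns=["gene_id", "category"]).to_csv(path, sep="\t", index=False)
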