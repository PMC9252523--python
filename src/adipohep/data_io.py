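"""Readers and writers for the pipeline's external formats.

Formats: expression matrices (plain TSV or GCT 1.2) with a metadata
sidecar, GMT gene sets, survival TSVs and GWAS summary-statistic TSVs.
Writers emit canonical column order and round-trip floating point exactly
(shortest round-trip decimal representation, always >= 12 significant
digits where needed).
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .types import (
    ExpressionCohort,
    FormatError,
    GeneSet,
    GwasSummaryTable,
    SurvivalTable,
    ValidationError,
)

log = logging.getLogger(__name__)

_GCT_HEADER = "#1.2"


def _fmt(x: float) -> str:
    """Shortest decimal string that round-trips to the same float."""
    return repr(float(x))


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------


def _parse_matrix_body(
    gene_rows: list[tuple[str, list[str]]], sample_ids: list[str], path: Path
) -> tuple[tuple[str, ...], np.ndarray]:
    genes: list[str] = []
    seen: set[str] = set()
    values = np.empty((len(gene_rows), len(sample_ids)), dtype=float)
    for r, (gene, cells) in enumerate(gene_rows):
        gene = gene.strip()
        if gene in seen:
            raise FormatError(f"{path}: duplicate gene id {gene!r}")
        seen.add(gene)
        genes.append(gene)
        if len(cells) != len(sample_ids):
            raise FormatError(
                f"{path}: row {gene!r} has {len(cells)} values, expected {len(sample_ids)}"
            )
        for c, cell in enumerate(cells):
            try:
                v = float(cell)
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric cell at gene {gene!r}, sample {sample_ids[c]!r}: {cell!r}"
                ) from None
            if not np.isfinite(v) or v < 0:
                raise FormatError(
                    f"{path}: invalid (negative or non-finite) value at gene {gene!r}, "
                    f"sample {sample_ids[c]!r}: {cell!r}"
                )
            values[r, c] = v
    return tuple(genes), values


def _read_expression_tsv(path: Path) -> tuple[tuple[str, ...], tuple[str, ...], np.ndarray]:
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise FormatError(f"{path}: empty expression file")
    header = lines[0].split("\t")
    if header[0] != "gene_id":
        raise FormatError(f"{path}: first header column must be 'gene_id', got {header[0]!r}")
    sample_ids = [s.strip() for s in header[1:]]
    if len(set(sample_ids)) != len(sample_ids):
        dup = next(s for s in sample_ids if sample_ids.count(s) > 1)
        raise FormatError(f"{path}: duplicate sample id {dup!r}")
    rows = []
    for line in lines[1:]:
        if not line:
            continue
        parts = line.split("\t")
        rows.append((parts[0], parts[1:]))
    genes, values = _parse_matrix_body(rows, sample_ids, path)
    return genes, tuple(sample_ids), values


def _read_expression_gct(path: Path) -> tuple[tuple[str, ...], tuple[str, ...], np.ndarray]:
    lines = path.read_text(encoding="utf-8").splitlines()
    if len(lines) < 3 or lines[0].strip() != _GCT_HEADER:
        raise FormatError(f"{path}: not a GCT 1.2 file (missing '#1.2' header)")
    dims = lines[1].split("\t")
    try:
        n_genes, n_samples = int(dims[0]), int(dims[1])
    except (ValueError, IndexError):
        raise FormatError(f"{path}: malformed GCT dimension line {lines[1]!r}") from None
    header = lines[2].split("\t")
    if len(header) < 2 or header[0] != "Name":
        raise FormatError(f"{path}: malformed GCT column header")
    sample_ids = [s.strip() for s in header[2:]]
    if len(sample_ids) != n_samples:
        raise FormatError(
            f"{path}: GCT declares {n_samples} samples but header has {len(sample_ids)}"
        )
    body = [ln for ln in lines[3:] if ln]
    if len(body) != n_genes:
        raise FormatError(f"{path}: GCT declares {n_genes} genes but body has {len(body)} rows")
    rows = []
    for line in body:
        parts = line.split("\t")
        rows.append((parts[0], parts[2:]))  # skip Description column
    genes, values = _parse_matrix_body(rows, sample_ids, path)
    return genes, tuple(sample_ids), values


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sample metadata sidecar TSV: sample_id, cohort, sex."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "cohort"):
        if col not in df.columns:
            raise FormatError(f"{path}: metadata sidecar missing required column {col!r}")
    if "sex" not in df.columns:
        df["sex"] = "unknown"
    df["sex"] = df["sex"].fillna("unknown")
    return df


def read_expression(
    path: str | Path,
    format_hint: str | None = None,
    metadata_path: str | Path | None = None,
    default_cohort: str | None = None,
) -> ExpressionCohort:
    """Read an expression matrix (TSV or GCT 1.2) into an ``ExpressionCohort``.

    Cohort labels come from the metadata sidecar; with no sidecar,
    ``default_cohort`` must be given (cohort is required metadata). Sex
    defaults to ``unknown`` for samples the sidecar does not cover.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format_hint
    if fmt is None:
        with open(path, encoding="utf-8") as fh:
            fmt = "gct" if fh.readline().strip() == _GCT_HEADER else "tsv"
    if fmt == "gct":
        genes, samples, values = _read_expression_gct(path)
    elif fmt == "tsv":
        genes, samples, values = _read_expression_tsv(path)
    else:
        raise ValueError(f"unknown format hint {fmt!r} (expected 'tsv' or 'gct')")

    cohort: list[str] = []
    sex: list[str] = []
    if metadata_path is not None:
        meta = read_metadata(metadata_path).set_index("sample_id")
        for s in samples:
            if s in meta.index:
                cohort.append(str(meta.loc[s, "cohort"]))
                sex.append(str(meta.loc[s, "sex"]))
            elif default_cohort is not None:
                cohort.append(default_cohort)
                sex.append("unknown")
            else:
                raise ValidationError(
                    f"sample {s!r} has no cohort label (absent from metadata sidecar)"
                )
    elif default_cohort is not None:
        cohort = [default_cohort] * len(samples)
        sex = ["unknown"] * len(samples)
    else:
        raise ValidationError(
            "cohort labels are required: provide a metadata sidecar or default_cohort"
        )
    return ExpressionCohort(genes, samples, values, tuple(cohort), tuple(sex))


def write_expression(
    cohort: ExpressionCohort, path: str | Path, metadata_path: str | Path | None = None
) -> None:
    """Write the matrix as canonical TSV (and optionally its sidecar)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene_id\t" + "\t".join(cohort.sample_ids) + "\n")
        for g, row in zip(cohort.gene_ids, cohort.values):
            fh.write(g + "\t" + "\t".join(_fmt(v) for v in row) + "\n")
    if metadata_path is not None:
        cohort.metadata_frame().to_csv(metadata_path, sep="\t", index=False)


def write_expression_gct(cohort: ExpressionCohort, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_GCT_HEADER + "\n")
        fh.write(f"{cohort.n_genes}\t{cohort.n_samples}\n")
        fh.write("Name\tDescription\t" + "\t".join(cohort.sample_ids) + "\n")
        for g, row in zip(cohort.gene_ids, cohort.values):
            fh.write(g + "\tna\t" + "\t".join(_fmt(v) for v in row) + "\n")


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT file: one gene set per line, name <TAB> description <TAB> genes."""
    path = Path(path)
    sets: list[GeneSet] = []
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(
                f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3"
            )
        name, description, genes = fields[0], fields[1], [g for g in fields[2:] if g.strip()]
        gs = GeneSet.from_genes(name, genes, description)
        if len(gs) < len(genes):
            log.warning(
                "%s:%d: gene set %r contained %d duplicate gene(s); collapsed",
                path, lineno, name, len(genes) - len(gs),
            )
        sets.append(gs)
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description or "na", *gs.genes]) + "\n")


def packaged_signature() -> GeneSet:
    """The packaged 14-gene obesity signature."""
    with resources.as_file(resources.files("adipohep") / "data" / "obesity_14.gmt") as p:
        return read_gmt(p)[0]


# ---------------------------------------------------------------------------
# survival tables
# ---------------------------------------------------------------------------


def read_survival(path: str | Path) -> SurvivalTable:
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "time_days", "event"):
        if col not in df.columns:
            raise FormatError(f"{path}: survival table missing required column {col!r}")
    if "sex" not in df.columns:
        df["sex"] = "unknown"
    return SurvivalTable(df)


def write_survival(table: SurvivalTable, path: str | Path) -> None:
    cols = list(SurvivalTable.REQUIRED) + [
        c for c in table.df.columns if c not in SurvivalTable.REQUIRED
    ]
    out = table.df[cols].copy()
    out["time_days"] = out["time_days"].map(_fmt)
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------


def read_gwas(path: str | Path) -> GwasSummaryTable:
    """Read a GWAS summary TSV; invalid rows are dropped with a logged count."""
    df = pd.read_csv(path, sep="\t")
    table, n_dropped = GwasSummaryTable.clean(df)
    if n_dropped:
        log.warning("%s: dropped %d invalid GWAS row(s)", path, n_dropped)
    return table


def write_gwas(table: GwasSummaryTable, path: str | Path) -> None:
    out = table.df[list(GwasSummaryTable.REQUIRED)].copy()
    for col in ("eaf", "beta", "se", "pval"):
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else _fmt(v))
    out["n"] = out["n"].map(lambda v: "" if pd.isna(v) else str(int(v)))
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")
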