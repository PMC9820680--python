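"""Readers and writers for the pipeline's tabular interchange formats.

Formats are deliberately plain: TSV count matrices (either the
featureCounts layout with its annotation columns, or a bare gene-id +
sample-columns table), a CSV sample sheet, a 4-column TSV marker
reference, and a 2-column TSV ortholog map. Parsing is delegated to
pandas; this module enforces the domain contracts (integer counts, unique
identifiers, closed vocabularies) and reports violations by row/column.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import (
    CountMatrix,
    DEFAULT_POPULATIONS,
    MarkerEntry,
    MarkerReference,
    OrthologMap,
    SampleRecord,
    SampleSheet,
    ValidationError,
)

FEATURECOUNTS_ANNOTATION = ("Geneid", "Chr", "Start", "End", "Strand", "Length")


def _strip_sample_name(column: str) -> str:
    """featureCounts headers carry BAM paths; keep the file's basename stem."""
    base = os.path.basename(column)
    for ext in (".bam", ".sam", ".cram"):
        if base.endswith(ext):
            base = base[: -len(ext)]
    return base


def read_count_matrix(path: str | os.PathLike, dialect: str = "plain") -> CountMatrix:
    """Load a gene x sample count matrix.

    Parameters
    ----------
    path
        TSV file. For ``dialect="featurecounts"`` the header may be preceded
        by a ``#`` program line and must contain the six annotation columns
        (Geneid, Chr, Start, End, Strand, Length) followed by one column per
        sample; sample names are basename-stripped. ``dialect="plain"``
        expects a gene-id column followed by sample columns.
    """
    if dialect not in ("plain", "featurecounts"):
        raise ValidationError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: need a gene-id column plus >= 1 sample column")
    if dialect == "featurecounts":
        missing = [c for c in FEATURECOUNTS_ANNOTATION if c not in df.columns]
        if missing:
            raise ValidationError(
                f"{path}: featurecounts dialect is missing columns {missing}"
            )
        gene_ids = df["Geneid"].tolist()
        sample_cols = [c for c in df.columns if c not in FEATURECOUNTS_ANNOTATION]
        sample_ids = [_strip_sample_name(c) for c in sample_cols]
        if len(set(sample_ids)) != len(sample_ids):
            dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
            raise ValidationError(
                f"{path}: sample names collide after basename-stripping: {dupes}"
            )
        data = df[sample_cols]
    else:
        gene_ids = df.iloc[:, 0].tolist()
        sample_ids = list(df.columns[1:])
        data = df.iloc[:, 1:]

    if len(set(gene_ids)) != len(gene_ids):
        dupes = sorted({g for g in gene_ids if gene_ids.count(g) > 1})
        raise ValidationError(f"{path}: duplicate gene id(s): {dupes[:5]}")

    counts = np.empty((len(gene_ids), len(sample_ids)), dtype=np.int64)
    for j, col in enumerate(data.columns):
        values = pd.to_numeric(data[col], errors="coerce")
        bad = values.isna() | (np.mod(values.fillna(0), 1) != 0) | (values.fillna(0) < 0)
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"{path}: non-integer or negative count {data[col].iloc[i]!r} "
                f"at gene {gene_ids[i]!r}, sample column {sample_ids[j]!r}"
            )
        counts[:, j] = values.to_numpy(dtype=np.int64)
    return CountMatrix.from_counts(gene_ids, sample_ids, counts)


def write_count_matrix(counts: CountMatrix, path: str | os.PathLike) -> None:
    """Write in the plain dialect (gene_id column + sample columns)."""
    df = counts.to_frame()
    df.insert(0, "gene_id", list(counts.gene_ids))
    df.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | os.PathLike) -> SampleSheet:
    """Load the CSV sample sheet (sample_id, source, site, subject_id)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    required = ["sample_id", "source", "site", "subject_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: sample sheet is missing columns {missing}")
    records = tuple(
        SampleRecord(r.sample_id, r.source, r.site, r.subject_id)
        for r in df[required].itertuples(index=False)
    )
    return SampleSheet(records)


def write_sample_sheet(sheet: SampleSheet, path: str | os.PathLike) -> None:
    sheet.to_frame().to_csv(path, index=False)


def read_marker_reference(
    path: str | os.PathLike,
    populations: Sequence[str] = DEFAULT_POPULATIONS,
) -> MarkerReference:
    """Load the marker reference TSV (gene_id, population, subpopulation,
    significant). Populations outside ``populations`` are rejected; pass an
    extended tuple to accept additional ones."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["gene_id", "population", "subpopulation", "significant"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: marker reference is missing columns {missing}")
    entries = []
    for r in df[required].itertuples(index=False):
        flag = str(r.significant).strip().lower()
        if flag not in ("true", "false", "1", "0"):
            raise ValidationError(
                f"{path}: significant flag {r.significant!r} for gene {r.gene_id!r} "
                "must be true/false"
            )
        entries.append(
            MarkerEntry(r.gene_id, r.population, r.subpopulation, flag in ("true", "1"))
        )
    return MarkerReference(tuple(entries), tuple(populations))


def write_marker_reference(reference: MarkerReference, path: str | os.PathLike) -> None:
    df = reference.to_frame()
    df["significant"] = df["significant"].map({True: "true", False: "false"})
    df.to_csv(path, sep="\t", index=False)


def read_ortholog_map(path: str | os.PathLike) -> OrthologMap:
    """Load the 2-column TSV of study -> reference gene id pairs."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["study_gene_id", "reference_gene_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: ortholog map is missing columns {missing}")
    return OrthologMap(tuple(df[required].itertuples(index=False, name=None)))


def write_ortholog_map(orthologs: OrthologMap, path: str | os.PathLike) -> None:
    orthologs.to_frame().to_csv(path, sep="\t", index=False)


def read_differential_results(path: str | os.PathLike):
    """Load a DE result TSV written by the pipeline back into domain objects."""
    from .model import DifferentialResult

    df = pd.read_csv(path, sep="\t")
    return [
        DifferentialResult(
            str(r.gene_id),
            float(r.log2_fc),
            float(r.p_value),
            float(r.fdr),
            bool(r.significant),
            str(r.direction),
        )
        for r in df.itertuples(index=False)
    ]


def write_differential_results(results, path: str | os.PathLike) -> None:
    from .model import differential_results_to_frame

    differential_results_to_frame(results).to_csv(path, sep="\t", index=False)


def is_accession_id(gene_id: str) -> bool:
    """Accession-style ids (Ensembl ENS... with digits) vs symbol-style."""
    return gene_id.upper().startswith("ENS") and any(c.isdigit() for c in gene_id)


def canonical_gene_id(gene_id: str, symbol_case_insensitive: bool = True) -> str:
    """Exact matching for accession ids; optionally case-folded for symbols."""
    if symbol_case_insensitive and not is_accession_id(gene_id):
        return gene_id.upper()
    return gene_id


def canonicalize(ids: Iterable[str], symbol_case_insensitive: bool = True) -> list[str]:
    return [canonical_gene_id(g, symbol_case_insensitive) for g in ids]
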