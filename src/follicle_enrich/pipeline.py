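"""Orchestration of the full analysis and rendering of its summary report.

``run_all`` executes filter -> TMM normalization -> the three contrasts
(all samples, forelock only, mane only) -> marker projection, writing
machine-readable artifacts (TSV/JSON) into the output directory. The
markdown report is rendered strictly from those artifacts — it re-reads
the files it cites rather than recomputing, so the human-readable numbers
cannot drift from the machine-readable ones.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import io as fio
from .diffabund import ContrastOutcome, run_contrast
from .model import (
    ContrastSpec,
    CountMatrix,
    ValidationError,
    enrichment_calls_to_frame,
)
from .preprocess import compute_tmm_factors, filter_low_expression
from .projection import project


@dataclass(frozen=True)
class RunConfig:
    """Paths and parameters for a full pipeline run."""

    counts: str
    sheet: str
    reference: str
    orthologs: str
    out_dir: str
    dialect: str = "plain"
    min_rpm: float = 1.0
    min_samples: int = 2
    trim_m: float = 0.30
    trim_a: float = 0.05
    reference_sample: str | None = None
    alpha: float = 0.05
    conclusive_threshold: float = 0.75
    renormalize_per_contrast: bool = False
    sites: tuple[str, ...] = ("forelock", "mane")

    def validate(self) -> None:
        for label in ("counts", "sheet", "reference", "orthologs"):
            path = getattr(self, label)
            if not os.path.exists(path):
                raise ValidationError(f"{label} file does not exist: {path}")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "sites" in raw:
            raw["sites"] = tuple(raw["sites"])
        return cls(**raw)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def protein_coding_detection_pct(n_detected: int, n_annotated: int) -> int:
    """Percent of annotated protein-coding genes detected, nearest integer."""
    if n_annotated <= 0:
        raise ValidationError("annotated protein-coding gene count must be positive")
    return int(round(100.0 * n_detected / n_annotated))


def detection_summary(
    filtered: CountMatrix,
    biotypes: Mapping[str, str],
    n_annotated_protein_coding: int,
) -> dict:
    """Detected-gene bookkeeping: totals, per-biotype counts, and the share
    of annotated protein-coding genes detected (genes absent from the
    biotype mapping count as 'other')."""
    per_biotype: dict[str, int] = {}
    for g in filtered.gene_ids:
        per_biotype[biotypes.get(g, "other")] = per_biotype.get(biotypes.get(g, "other"), 0) + 1
    n_pc = per_biotype.get("protein_coding", 0)
    return {
        "n_detected": filtered.n_genes,
        "per_biotype": dict(sorted(per_biotype.items())),
        "n_detected_protein_coding": n_pc,
        "n_annotated_protein_coding": int(n_annotated_protein_coding),
        "protein_coding_pct": protein_coding_detection_pct(
            n_pc, n_annotated_protein_coding
        ),
    }


def _stage(name: str):
    """Wrap stage errors with the stage name for actionable failures."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


class _StageError(RuntimeError):
    pass


def run_all(config: RunConfig) -> Path:
    """Execute the whole analysis; returns the artifact directory.

    Deterministic given identical inputs: all stages are closed-form or
    exhaustive, so reruns produce byte-identical artifacts.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log: dict = {
        "parameters": {
            k: getattr(config, k)
            for k in (
                "dialect",
                "min_rpm",
                "min_samples",
                "trim_m",
                "trim_a",
                "reference_sample",
                "alpha",
                "conclusive_threshold",
                "renormalize_per_contrast",
            )
        },
        "input_hashes": {
            k: _sha256(getattr(config, k))
            for k in ("counts", "sheet", "reference", "orthologs")
        },
        "stages": [],
    }

    with _stage("load"):
        counts = fio.read_count_matrix(config.counts, config.dialect)
        sheet = fio.read_sample_sheet(config.sheet)
        sheet.check_covers(counts)
        reference = fio.read_marker_reference(config.reference)
        orthologs = fio.read_ortholog_map(config.orthologs)
    log["stages"].append({"stage": "load", "n_genes": counts.n_genes, "n_samples": counts.n_samples})

    with _stage("filter"):
        filtered, filter_report = filter_low_expression(
            counts, config.min_rpm, config.min_samples
        )
    (out / "filter_report.json").write_text(
        json.dumps(filter_report.__dict__, indent=2) + "\n"
    )
    log["stages"].append({"stage": "filter", "n_retained": filtered.n_genes})

    with _stage("normalize"):
        factors = compute_tmm_factors(
            filtered,
            reference=config.reference_sample,
            trim_m=config.trim_m,
            trim_a=config.trim_a,
        )
    factors.to_frame().to_csv(out / "tmm_factors.tsv", sep="\t", index=False)
    log["stages"].append(
        {"stage": "normalize", "reference_sample": factors.reference_sample}
    )

    contrasts = [ContrastSpec.plucked_vs_biopsy(None)] + [
        ContrastSpec.plucked_vs_biopsy(site) for site in config.sites
    ]
    outcomes: list[ContrastOutcome] = []
    summary_rows = []
    for spec in contrasts:
        with _stage(f"contrast:{spec.label}"):
            per_contrast_factors = None if config.renormalize_per_contrast else factors
            outcome = run_contrast(
                filtered, sheet, spec, factors=per_contrast_factors, alpha=config.alpha
            )
        outcomes.append(outcome)
        fio.write_differential_results(outcome.results, out / f"de_{spec.label}.tsv")
        summary_rows.append(
            {
                "contrast": spec.label,
                "n_lower_abundance": outcome.n_plucked_higher,
                "n_higher_abundance": outcome.n_biopsy_higher,
                "dispersion": outcome.dispersion.common_dispersion,
            }
        )
        log["stages"].append({"stage": f"contrast:{spec.label}", **summary_rows[-1]})
    pd.DataFrame(summary_rows).to_csv(out / "contrast_summary.tsv", sep="\t", index=False)

    with _stage("projection"):
        proj = project(
            list(outcomes[0].results),
            orthologs,
            reference,
            conclusive_threshold=config.conclusive_threshold,
        )
    (out / "venn.json").write_text(
        json.dumps(
            {
                "regions": proj.venn.as_dict(),
                "region_genes": {k: list(v) for k, v in proj.region_genes.items()},
                "unmapped_study_ids": list(proj.mapping.unmapped_study_ids),
                "ambiguous_ids": list(proj.mapping.ambiguous_ids),
            },
            indent=2,
        )
        + "\n"
    )
    markers_df = pd.DataFrame(
        [(g, pop) for pop, genes in proj.markers.markers.items() for g in genes],
        columns=["gene_id", "population"],
    )
    markers_df.to_csv(out / "markers.tsv", sep="\t", index=False)
    enrichment_calls_to_frame(list(proj.calls) + list(proj.subpopulation_calls)).to_csv(
        out / "calls.tsv", sep="\t", index=False
    )
    log["stages"].append(
        {"stage": "projection", "n_markers": proj.markers.total}
    )

    (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str) + "\n")
    render_report(out)
    return out


@dataclass(frozen=True)
class SyntheticRun:
    """In-memory result of the pipeline on one synthetic cohort."""

    outcome: ContrastOutcome
    projection: object  # ProjectionResult
    truth: object  # SimulationTruth
    filter_report: object

    def population_calls(self) -> dict[str, str]:
        return {c.population: c.call for c in self.projection.calls}

    def subpopulation_calls(self) -> dict[tuple[str, str], str]:
        return {
            (c.population, c.subpopulation): c.call
            for c in self.projection.subpopulation_calls
        }


def run_synthetic(
    config=None,
    seed: int | None = None,
    alpha: float = 0.05,
    conclusive_threshold: float = 0.75,
) -> SyntheticRun:
    """Generate a synthetic cohort and push it through the whole pipeline
    (filter -> TMM -> all-samples contrast -> projection), in memory."""
    from .simulate import SimulationConfig, generate_dataset

    if config is None:
        config = SimulationConfig()
    counts, sheet, reference, orthologs, ref_expr, ref_sig, truth = generate_dataset(
        config, seed
    )
    filtered, filter_report = filter_low_expression(counts)
    factors = compute_tmm_factors(filtered)
    outcome = run_contrast(
        filtered, sheet, ContrastSpec.plucked_vs_biopsy(), factors=factors, alpha=alpha
    )
    proj = project(
        list(outcome.results),
        orthologs,
        reference,
        ref_expressed=ref_expr,
        ref_significant=ref_sig,
        conclusive_threshold=conclusive_threshold,
    )
    return SyntheticRun(outcome, proj, truth, filter_report)


def render_report(out_dir: str | os.PathLike) -> Path:
    """Render report.md purely from the artifacts in ``out_dir``."""
    out = Path(out_dir)
    filter_report = json.loads((out / "filter_report.json").read_text())
    summary = pd.read_csv(out / "contrast_summary.tsv", sep="\t")
    venn = json.loads((out / "venn.json").read_text())["regions"]
    calls = pd.read_csv(out / "calls.tsv", sep="\t", keep_default_na=False)

    lines = ["# Plucked hair vs skin biopsy — enrichment report", ""]
    lines += [
        "## Expressed-gene filter",
        "",
        f"- genes in: {filter_report['n_input_genes']}",
        f"- genes retained (RPM >= {filter_report['min_rpm']} in >= "
        f"{filter_report['min_samples']} samples): {filter_report['n_retained_genes']}",
        "",
        "## Differentially abundant genes per contrast",
        "",
        "| Comparison | Lower abundance | Higher abundance |",
        "|---|---|---|",
    ]
    for row in summary.itertuples(index=False):
        lines.append(
            f"| {row.contrast} | {row.n_lower_abundance} | {row.n_higher_abundance} |"
        )
    lines += [
        "",
        "(orientation: 'higher' = higher in skin biopsies)",
        "",
        "## Gene-set overlap with the single-cell reference",
        "",
    ]
    for region, n in venn.items():
        lines.append(f"- {region}: {n}")
    lines += ["", "## Cell-population enrichment calls", ""]
    lines += [
        "| Population | Subpopulation | n markers | biopsy higher | plucked higher | Call |",
        "|---|---|---|---|---|---|",
    ]
    for row in calls.itertuples(index=False):
        call = row.call + (" (predominant)" if row.predominant else "")
        lines.append(
            f"| {row.population} | {row.subpopulation or '-'} | {row.n_markers} "
            f"| {row.n_biopsy_higher} | {row.n_plucked_higher} | {call} |"
        )
    path = out / "report.md"
    path.write_text("\n".join(lines) + "\n")
    return path
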