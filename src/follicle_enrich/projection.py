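"""Projection of bulk differential-abundance results onto a single-cell
marker reference: ortholog mapping, the expressed/significant Venn
partition of the two gene universes, unique-marker extraction, and
per-population enrichment calls with subpopulation refinement.

The logic mirrors how a cell population leaves a signature in bulk data:
a gene significantly expressed in exactly one reference population is a
marker; the direction of its abundance difference between sampling
methods (plucked hair vs skin biopsy) is one vote for where that
population is enriched. A population's verdict is the majority direction
of its markers, called conclusive when the majority reaches the
``conclusive_threshold`` (default 0.75).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .model import (
    DifferentialResult,
    EnrichmentCall,
    MarkerReference,
    MarkerSet,
    OrthologMap,
    ValidationError,
    VennPartition,
)


@dataclass(frozen=True)
class MappingReport:
    """One-to-one ortholog pairs plus the ids dropped on the way."""

    mapped: tuple[tuple[str, str], ...]
    unmapped_study_ids: tuple[str, ...]
    ambiguous_ids: tuple[str, ...]

    def as_mapping(self) -> dict[str, str]:
        return dict(self.mapped)


def map_orthologs(study_genes: Iterable[str], orthologs: OrthologMap) -> MappingReport:
    """Retain only one-to-one study->reference pairs for the given genes.

    Study ids participating in many-to-one or one-to-many relations are
    dropped and reported as ambiguous; study ids with no map row are
    reported as unmapped.
    """
    study_genes = list(study_genes)
    fwd: dict[str, set[str]] = {}
    rev: dict[str, set[str]] = {}
    for s, r in orthologs.pairs:
        fwd.setdefault(s, set()).add(r)
        rev.setdefault(r, set()).add(s)

    mapped, unmapped, ambiguous = [], [], []
    for g in study_genes:
        targets = fwd.get(g)
        if not targets:
            unmapped.append(g)
            continue
        if len(targets) > 1:
            ambiguous.append(g)
            continue
        (ref,) = targets
        if len(rev[ref]) > 1:
            ambiguous.append(g)
            continue
        mapped.append((g, ref))
    return MappingReport(tuple(mapped), tuple(unmapped), tuple(ambiguous))


def classify_venn(
    study_expressed: Iterable[str],
    study_significant: Iterable[str],
    ref_expressed: Iterable[str],
    ref_significant: Iterable[str],
) -> tuple[VennPartition, dict[str, tuple[str, ...]]]:
    """Assign every gene of the joint universe to exactly one region.

    All ids must already be in the reference namespace (post ortholog
    mapping). Significant sets must be subsets of the corresponding
    expressed sets. The genes carried forward to marker extraction are
    exactly the ``both_expr_sig_both`` region.
    """
    study_expressed = set(study_expressed)
    study_significant = set(study_significant)
    ref_expressed = set(ref_expressed)
    ref_significant = set(ref_significant)
    for name, sig, expr in (
        ("study", study_significant, study_expressed),
        ("reference", ref_significant, ref_expressed),
    ):
        stray = sig - expr
        if stray:
            raise ValidationError(
                f"{name} significant gene(s) not in the expressed set: "
                f"{sorted(stray)[:5]}"
            )

    regions: dict[str, list[str]] = {
        "study_only_nonsig": [],
        "ref_only_nonsig": [],
        "both_nonsig": [],
        "study_only_sig": [],
        "ref_only_sig": [],
        "both_expr_sig_study_only": [],
        "both_expr_sig_ref_only": [],
        "both_expr_sig_both": [],
    }
    for g in study_expressed | ref_expressed:
        in_study, in_ref = g in study_expressed, g in ref_expressed
        sig_s, sig_r = g in study_significant, g in ref_significant
        if in_study and not in_ref:
            regions["study_only_sig" if sig_s else "study_only_nonsig"].append(g)
        elif in_ref and not in_study:
            regions["ref_only_sig" if sig_r else "ref_only_nonsig"].append(g)
        elif sig_s and sig_r:
            regions["both_expr_sig_both"].append(g)
        elif sig_s:
            regions["both_expr_sig_study_only"].append(g)
        elif sig_r:
            regions["both_expr_sig_ref_only"].append(g)
        else:
            regions["both_nonsig"].append(g)

    lists = {k: tuple(sorted(v)) for k, v in regions.items()}
    partition = VennPartition(**{k: len(v) for k, v in lists.items()})
    return partition, lists


def carried_forward_count(
    n_both_expressed_sig_any: int, n_sig_study_only: int, n_sig_ref_only: int
) -> int:
    """Bookkeeping of the both-expressed region: genes significant in both
    datasets = those significant in at least one minus those significant in
    only one. Negative results indicate inconsistent region counts."""
    n = n_both_expressed_sig_any - n_sig_study_only - n_sig_ref_only
    if n < 0:
        raise ValidationError(
            "inconsistent region counts: significant-in-one regions exceed the "
            "both-expressed significant total"
        )
    return n


def extract_unique_markers(
    carried_genes: Iterable[str], reference: MarkerReference
) -> MarkerSet:
    """Keep genes significant in exactly one population; genes significant
    in two or more populations are excluded (and counted)."""
    sig_pops: dict[str, set[str]] = {}
    for e in reference.entries:
        if e.significant:
            sig_pops.setdefault(e.gene_id, set()).add(e.population)

    markers: dict[str, list[str]] = {}
    n_multi = 0
    n_none = 0
    for g in carried_genes:
        pops = sig_pops.get(g, set())
        if len(pops) == 1:
            (pop,) = pops
            markers.setdefault(pop, []).append(g)
        elif len(pops) > 1:
            n_multi += 1
        else:
            n_none += 1
    return MarkerSet(
        markers={p: tuple(sorted(g)) for p, g in sorted(markers.items())},
        n_excluded_multi_population=n_multi,
        n_without_significant_population=n_none,
    )


def _tally(
    genes: Sequence[str], directions: Mapping[str, str]
) -> tuple[int, int]:
    n_b = n_p = 0
    for g in genes:
        if g not in directions:
            raise ValidationError(f"marker gene {g!r} has no differential result")
        d = directions[g]
        if d == "biopsy_higher":
            n_b += 1
        elif d == "plucked_higher":
            n_p += 1
        else:
            raise ValidationError(
                f"marker gene {g!r} has direction 'none'; markers must be significant"
            )
    return n_b, n_p


def _directions(de: Iterable[DifferentialResult]) -> dict[str, str]:
    return {r.gene_id: r.direction for r in de}


def call_enrichment(
    markers: MarkerSet,
    de: Iterable[DifferentialResult],
    conclusive_threshold: float = 0.75,
    populations: Sequence[str] | None = None,
) -> list[EnrichmentCall]:
    """Majority-direction verdict per population.

    A call is conclusive when the majority fraction reaches
    ``conclusive_threshold``; otherwise it is ``inconclusive``. Populations
    listed in ``populations`` but holding no markers get ``no_call``.
    """
    directions = _directions(de)
    pops = list(populations) if populations is not None else list(markers.markers)
    for p in markers.markers:
        if p not in pops:
            pops.append(p)
    calls = []
    for pop in pops:
        genes = markers.markers.get(pop, ())
        n_b, n_p = _tally(genes, directions)
        n = n_b + n_p
        if n == 0:
            calls.append(
                EnrichmentCall(pop, 0, 0, 0, "no_call", concordance=0.0)
            )
            continue
        conc = max(n_b, n_p) / n
        if n_b / n >= conclusive_threshold:
            call = "biopsy_enriched"
        elif n_p / n >= conclusive_threshold:
            call = "plucked_enriched"
        else:
            call = "inconclusive"
        calls.append(
            EnrichmentCall(pop, n, n_b, n_p, call, concordance=conc)
        )
    return calls


def refine_subpopulations(
    population: str,
    markers: MarkerSet,
    reference: MarkerReference,
    de: Iterable[DifferentialResult],
    conclusive_threshold: float = 0.75,
) -> list[EnrichmentCall]:
    """Split a population's markers by subpopulation and re-tally.

    Subpopulation calls use a simple majority; when the majority is below
    ``conclusive_threshold`` the call is retained but flagged
    ``predominant`` (a softer verdict). Markers lacking a subpopulation
    annotation fall into an ``unassigned`` bucket.
    """
    genes = markers.markers.get(population, ())
    if not reference.subpopulations_of(population):
        raise ValidationError(
            f"population {population!r} has no subpopulations in the reference"
        )
    directions = _directions(de)
    buckets: dict[str, list[str]] = {}
    for g in genes:
        sub = reference.subpopulation_of(g, population) or "unassigned"
        buckets.setdefault(sub, []).append(g)

    calls = []
    for sub in sorted(buckets):
        sub_genes = buckets[sub]
        n_b, n_p = _tally(sub_genes, directions)
        n = n_b + n_p
        conc = max(n_b, n_p) / n
        if n_b > n_p:
            call = "biopsy_enriched"
        elif n_p > n_b:
            call = "plucked_enriched"
        else:
            call = "inconclusive"
        calls.append(
            EnrichmentCall(
                population,
                n,
                n_b,
                n_p,
                call,
                concordance=conc,
                subpopulation=sub,
                predominant=(call != "inconclusive" and conc < conclusive_threshold),
            )
        )
    return calls


@dataclass(frozen=True)
class ProjectionResult:
    """Everything the projection step produces, including audit trails."""

    venn: VennPartition
    region_genes: Mapping[str, tuple[str, ...]]
    markers: MarkerSet
    calls: tuple[EnrichmentCall, ...]
    subpopulation_calls: tuple[EnrichmentCall, ...]
    mapping: MappingReport


def project(
    de_results: Sequence[DifferentialResult],
    orthologs: OrthologMap,
    reference: MarkerReference,
    ref_expressed: Iterable[str] | None = None,
    ref_significant: Iterable[str] | None = None,
    conclusive_threshold: float = 0.75,
) -> ProjectionResult:
    """Full projection: map orthologs, partition the gene universes, extract
    unique markers, call population enrichment, refine subpopulations.

    ``ref_expressed`` / ``ref_significant`` default to the reference table's
    own notions (any entry / any significant entry).
    """
    if ref_expressed is None:
        ref_expressed = reference.gene_ids
    if ref_significant is None:
        ref_significant = reference.significant_gene_ids

    mapping = map_orthologs([r.gene_id for r in de_results], orthologs)
    to_ref = mapping.as_mapping()
    study_expressed = {to_ref[r.gene_id] for r in de_results if r.gene_id in to_ref}
    study_significant = {
        to_ref[r.gene_id] for r in de_results if r.gene_id in to_ref and r.significant
    }
    venn, region_genes = classify_venn(
        study_expressed, study_significant, ref_expressed, ref_significant
    )
    markers = extract_unique_markers(region_genes["both_expr_sig_both"], reference)

    # DE directions keyed by reference-namespace ids
    de_ref = [
        DifferentialResult(
            to_ref[r.gene_id], r.log2_fc, r.p_value, r.fdr, r.significant, r.direction
        )
        for r in de_results
        if r.gene_id in to_ref
    ]
    calls = call_enrichment(
        markers, de_ref, conclusive_threshold, populations=reference.populations
    )
    sub_calls: list[EnrichmentCall] = []
    for pop in reference.populations:
        if reference.subpopulations_of(pop) and markers.markers.get(pop):
            sub_calls.extend(
                refine_subpopulations(pop, markers, reference, de_ref, conclusive_threshold)
            )
    return ProjectionResult(
        venn=venn,
        region_genes=region_genes,
        markers=markers,
        calls=tuple(calls),
        subpopulation_calls=tuple(sub_calls),
        mapping=mapping,
    )
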