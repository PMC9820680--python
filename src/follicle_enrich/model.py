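"""Domain types shared across the pipeline.

The analysis contrasts bulk RNA-seq from two skin sampling methods —
plucked hair, which carries mostly hair-follicle-associated cells, and
punch biopsy, which captures the whole tissue including interfollicular
populations — and projects per-gene differential-abundance results onto a
single-cell-derived marker reference to call which cell populations each
sampling method enriches.

Conventions used throughout:

* ``source`` is one of ``plucked`` / ``biopsy``; ``site`` is ``forelock`` /
  ``mane``.
* log2 fold changes are oriented biopsy over plucked: positive values mean
  higher abundance in skin biopsies.
* Library sizes are fixed when a count matrix is loaded (column sums over
  all genes) and are never recomputed after filtering, so "reads per
  million" always refers to sequencing depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

SOURCES = ("plucked", "biopsy")
SITES = ("forelock", "mane")

#: The seven main skin cell populations of the murine marker reference.
DEFAULT_POPULATIONS = (
    "permanent_epidermis_keratinocyte",
    "fibroblast",
    "anagen_hf_keratinocyte",
    "vascular",
    "neural_crest",
    "immune",
    "miscellaneous",
)


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


@dataclass(frozen=True, eq=False)
class CountMatrix:
    """Gene x sample matrix of non-negative integer read counts.

    ``library_sizes`` are the column sums at load time and are preserved
    unchanged through filtering; depth-based quantities (RPM) therefore
    always refer to the full sequencing depth of each sample.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    counts: np.ndarray  # (n_genes, n_samples) int64
    library_sizes: np.ndarray  # (n_samples,) int64

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise ValidationError("counts must be integer-valued")
            counts = counts.astype(np.int64)
        if counts.size and counts.min() < 0:
            raise ValidationError("counts must be non-negative")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        lib = np.asarray(self.library_sizes, dtype=np.int64)
        if lib.shape != (len(self.sample_ids),):
            raise ValidationError("library_sizes length does not match samples")
        object.__setattr__(self, "counts", np.ascontiguousarray(counts, dtype=np.int64))
        object.__setattr__(self, "library_sizes", lib)

    @classmethod
    def from_counts(
        cls, gene_ids: Sequence[str], sample_ids: Sequence[str], counts: np.ndarray
    ) -> "CountMatrix":
        """Build a matrix whose library sizes are the column sums of ``counts``."""
        counts = np.asarray(counts)
        return cls(
            tuple(gene_ids),
            tuple(sample_ids),
            counts,
            counts.sum(axis=0).astype(np.int64),
        )

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, CountMatrix)
            and self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
            and np.array_equal(self.library_sizes, other.library_sizes)
        )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id {sample_id!r}") from None

    def subset_genes(self, keep: np.ndarray) -> "CountMatrix":
        """Row subset by boolean mask or integer index; library sizes unchanged."""
        keep = np.asarray(keep)
        idx = np.flatnonzero(keep) if keep.dtype == bool else keep
        return CountMatrix(
            tuple(self.gene_ids[i] for i in idx),
            self.sample_ids,
            self.counts[idx, :],
            self.library_sizes,
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        idx = [self.sample_index(s) for s in sample_ids]
        return CountMatrix(
            self.gene_ids,
            tuple(sample_ids),
            self.counts[:, idx],
            self.library_sizes[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.gene_ids), columns=list(self.sample_ids)
        )


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    source: str
    site: str
    subject_id: str


@dataclass(frozen=True)
class SampleSheet:
    """Per-sample metadata: sampling method (source), body site, and subject."""

    records: tuple[SampleRecord, ...]

    def __post_init__(self) -> None:
        ids = [r.sample_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate sample_id(s): {dupes}")
        for r in self.records:
            if r.source not in SOURCES:
                raise ValidationError(
                    f"sample {r.sample_id!r}: source {r.source!r} not in {SOURCES}"
                )
            if r.site not in SITES:
                raise ValidationError(
                    f"sample {r.sample_id!r}: site {r.site!r} not in {SITES}"
                )

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(r.sample_id for r in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def select(self, predicate: Callable[[SampleRecord], bool]) -> tuple[str, ...]:
        return tuple(r.sample_id for r in self.records if predicate(r))

    def check_covers(self, counts: CountMatrix) -> None:
        """Every count-matrix sample must appear in the sheet."""
        missing = set(counts.sample_ids) - set(self.sample_ids)
        if missing:
            raise ValidationError(
                f"sample sheet is missing count-matrix samples: {sorted(missing)}"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.sample_id, r.source, r.site, r.subject_id) for r in self.records],
            columns=["sample_id", "source", "site", "subject_id"],
        )


@dataclass(frozen=True, eq=False)
class NormalizationFactors:
    """TMM scaling factors; effective library size = raw depth x factor."""

    sample_ids: tuple[str, ...]
    factor: np.ndarray  # per-sample positive real, geometric mean 1
    effective_library_size: np.ndarray
    reference_sample: str

    def __post_init__(self) -> None:
        f = np.asarray(self.factor, dtype=float)
        if not np.all(np.isfinite(f)) or np.any(f <= 0):
            raise ValidationError("TMM factors must be finite and strictly positive")
        gm = float(np.exp(np.mean(np.log(f))))
        if abs(gm - 1.0) > 1e-8:
            raise ValidationError(f"TMM factors must have geometric mean 1, got {gm!r}")
        object.__setattr__(self, "factor", f)
        object.__setattr__(
            self, "effective_library_size", np.asarray(self.effective_library_size, float)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": list(self.sample_ids),
                "factor": self.factor,
                "effective_library_size": self.effective_library_size,
            }
        )


DIRECTIONS = ("biopsy_higher", "plucked_higher", "none")


@dataclass(frozen=True)
class DifferentialResult:
    """Per-gene differential-abundance outcome.

    Sign convention: ``log2_fc > 0`` means higher abundance in skin
    biopsies, negative means higher in plucked hair.
    """

    gene_id: str
    log2_fc: float
    p_value: float
    fdr: float
    significant: bool
    direction: str

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValidationError(f"invalid direction {self.direction!r}")
        expected = "none"
        if self.significant:
            expected = "biopsy_higher" if self.log2_fc > 0 else "plucked_higher"
        if self.direction != expected:
            raise ValidationError(
                f"gene {self.gene_id}: direction {self.direction!r} inconsistent "
                f"with significant={self.significant}, log2_fc={self.log2_fc}"
            )


def differential_results_to_frame(results: Sequence[DifferentialResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.gene_id, r.log2_fc, r.p_value, r.fdr, r.significant, r.direction)
            for r in results
        ],
        columns=["gene_id", "log2_fc", "p_value", "fdr", "significant", "direction"],
    )


@dataclass(frozen=True)
class MarkerEntry:
    gene_id: str
    population: str
    subpopulation: str  # empty string when unannotated
    significant: bool


@dataclass(frozen=True)
class MarkerReference:
    """Reference-species genes annotated with the cell population(s) in which
    they are significantly expressed, optionally refined to subpopulations."""

    entries: tuple[MarkerEntry, ...]
    populations: tuple[str, ...] = DEFAULT_POPULATIONS

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        subpop_parent: dict[str, str] = {}
        for e in self.entries:
            if e.population not in self.populations:
                raise ValidationError(
                    f"gene {e.gene_id!r}: population {e.population!r} not in the "
                    f"declared set {self.populations}"
                )
            key = (e.gene_id, e.population)
            if key in seen:
                raise ValidationError(f"duplicate (gene, population) row: {key}")
            seen.add(key)
            if e.subpopulation:
                parent = subpop_parent.setdefault(e.subpopulation, e.population)
                if parent != e.population:
                    raise ValidationError(
                        f"subpopulation {e.subpopulation!r} appears under two parent "
                        f"populations: {parent!r} and {e.population!r}"
                    )

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def gene_ids(self) -> frozenset[str]:
        """All genes with any entry — 'expressed' in the reference."""
        return frozenset(e.gene_id for e in self.entries)

    @property
    def significant_gene_ids(self) -> frozenset[str]:
        """Genes flagged significant in at least one population."""
        return frozenset(e.gene_id for e in self.entries if e.significant)

    def significant_populations(self, gene_id: str) -> tuple[str, ...]:
        return tuple(
            sorted({e.population for e in self.entries if e.gene_id == gene_id and e.significant})
        )

    def subpopulation_of(self, gene_id: str, population: str) -> str:
        for e in self.entries:
            if e.gene_id == gene_id and e.population == population and e.significant:
                return e.subpopulation
        return ""

    def subpopulations_of(self, population: str) -> tuple[str, ...]:
        return tuple(
            sorted({e.subpopulation for e in self.entries if e.population == population and e.subpopulation})
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.gene_id, e.population, e.subpopulation, e.significant) for e in self.entries],
            columns=["gene_id", "population", "subpopulation", "significant"],
        )


@dataclass(frozen=True)
class OrthologMap:
    """Raw study-species -> reference-species gene id pairs (may be ambiguous;
    one-to-one filtering happens in the projection step)."""

    pairs: tuple[tuple[str, str], ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["study_gene_id", "reference_gene_id"])


@dataclass(frozen=True)
class FilterReport:
    n_input_genes: int
    n_retained_genes: int
    min_rpm: float
    min_samples: int

    def __post_init__(self) -> None:
        if self.n_retained_genes > self.n_input_genes:
            raise ValidationError("retained more genes than were supplied")


@dataclass(frozen=True)
class DispersionEstimate:
    """Common negative-binomial dispersion phi (variance = mu + phi mu^2)."""

    common_dispersion: float
    n_genes_used: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.common_dispersion) or self.common_dispersion < 0:
            raise ValidationError("dispersion must be finite and >= 0")


@dataclass(frozen=True)
class ContrastSpec:
    """Two disjoint sample groups selected from the sheet by predicates.

    Orientation: ``group_a`` is the plucked-hair side, ``group_b`` the
    biopsy side, so fold changes are reported biopsy over plucked.
    """

    group_a: Callable[[SampleRecord], bool]
    group_b: Callable[[SampleRecord], bool]
    label: str

    @staticmethod
    def plucked_vs_biopsy(site: str | None = None) -> "ContrastSpec":
        def in_site(r: SampleRecord) -> bool:
            return site is None or r.site == site

        label = "all_plucked_vs_all_biopsy" if site is None else f"{site}_plucked_vs_{site}_biopsy"
        return ContrastSpec(
            group_a=lambda r: r.source == "plucked" and in_site(r),
            group_b=lambda r: r.source == "biopsy" and in_site(r),
            label=label,
        )

    def resolve(self, sheet: SampleSheet) -> tuple[tuple[str, ...], tuple[str, ...]]:
        a = sheet.select(self.group_a)
        b = sheet.select(self.group_b)
        if set(a) & set(b):
            raise ValidationError(f"contrast {self.label!r}: groups overlap")
        if len(a) < 2 or len(b) < 2:
            raise ValidationError(
                f"contrast {self.label!r}: each group needs >= 2 samples "
                f"(got {len(a)} and {len(b)})"
            )
        return a, b


VENN_REGIONS = (
    "study_only_nonsig",
    "ref_only_nonsig",
    "both_nonsig",
    "study_only_sig",
    "ref_only_sig",
    "both_expr_sig_study_only",
    "both_expr_sig_ref_only",
    "both_expr_sig_both",
)


@dataclass(frozen=True)
class VennPartition:
    """Disjoint region counts of the expressed/significant overlap between the
    study (bulk) and reference (single-cell) gene sets."""

    study_only_nonsig: int
    ref_only_nonsig: int
    both_nonsig: int
    study_only_sig: int
    ref_only_sig: int
    both_expr_sig_study_only: int
    both_expr_sig_ref_only: int
    both_expr_sig_both: int

    def as_dict(self) -> dict[str, int]:
        return {r: getattr(self, r) for r in VENN_REGIONS}

    @property
    def n_both_expressed(self) -> int:
        return (
            self.both_nonsig
            + self.both_expr_sig_study_only
            + self.both_expr_sig_ref_only
            + self.both_expr_sig_both
        )

    @property
    def n_universe(self) -> int:
        return sum(self.as_dict().values())


@dataclass(frozen=True)
class MarkerSet:
    """Unique markers: population -> genes significant in that population only."""

    markers: Mapping[str, tuple[str, ...]]
    n_excluded_multi_population: int = 0
    n_without_significant_population: int = 0

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for pop, genes in self.markers.items():
            for g in genes:
                if g in seen:
                    raise ValidationError(
                        f"gene {g!r} listed under both {seen[g]!r} and {pop!r}"
                    )
                seen[g] = pop

    @property
    def total(self) -> int:
        return sum(len(g) for g in self.markers.values())

    def population_of(self, gene_id: str) -> str | None:
        for pop, genes in self.markers.items():
            if gene_id in genes:
                return pop
        return None


CALLS = ("biopsy_enriched", "plucked_enriched", "inconclusive", "no_call")


@dataclass(frozen=True)
class EnrichmentCall:
    """Direction-concordance verdict for one population (or subpopulation)."""

    population: str
    n_markers: int
    n_biopsy_higher: int
    n_plucked_higher: int
    call: str
    concordance: float
    subpopulation: str = ""
    predominant: bool = False

    def __post_init__(self) -> None:
        if self.call not in CALLS:
            raise ValidationError(f"invalid call {self.call!r}")
        if self.n_biopsy_higher + self.n_plucked_higher != self.n_markers:
            raise ValidationError(
                f"{self.population}: direction tallies "
                f"{self.n_biopsy_higher}+{self.n_plucked_higher} != n_markers {self.n_markers}"
            )
        if (self.call == "no_call") != (self.n_markers == 0):
            raise ValidationError("call is no_call iff the population has no markers")


def enrichment_calls_to_frame(calls: Sequence[EnrichmentCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                c.population,
                c.subpopulation,
                c.n_markers,
                c.n_biopsy_higher,
                c.n_plucked_higher,
                c.concordance,
                c.call,
                c.predominant,
            )
            for c in calls
        ],
        columns=[
            "population",
            "subpopulation",
            "n_markers",
            "n_biopsy_higher",
            "n_plucked_higher",
            "concordance",
            "call",
            "predominant",
        ],
    )


__all__ = [
    "CALLS",
    "ContrastSpec",
    "CountMatrix",
    "DEFAULT_POPULATIONS",
    "DIRECTIONS",
    "DifferentialResult",
    "DispersionEstimate",
    "EnrichmentCall",
    "FilterReport",
    "MarkerEntry",
    "MarkerReference",
    "MarkerSet",
    "NormalizationFactors",
    "OrthologMap",
    "SITES",
    "SOURCES",
    "SampleRecord",
    "SampleSheet",
    "ValidationError",
    "VennPartition",
    "VENN_REGIONS",
    "differential_results_to_frame",
    "enrichment_calls_to_frame",
    "replace",
]
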