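"""Mixture-structured synthetic data for the whole pipeline.

Bulk RNA-seq of skin-derived material is modeled as a mixture of cell
populations whose proportions depend on the sampling method: plucked hair
carries mostly follicle-associated cells (anagen hair-follicle
keratinocytes, melanocytes), while a punch biopsy captures interfollicular
tissue (epidermis keratinocytes, fibroblasts, vasculature, immune cells,
miscellaneous red-blood/muscle cells, Schwann cells). Every gene has a
baseline log-normal expression rate shared across populations; marker
genes are elevated ``marker_fold``-fold in their own population only.
Sample counts are negative binomial around library-size-scaled mixture
rates, so composition differences — not sequencing depth — are the only
systematic signal between sources.

The generator also emits the matching marker-reference table, ortholog
map and truth record, so parameter-recovery tests can compare pipeline
output against the known simulation design.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .model import (
    CountMatrix,
    MarkerEntry,
    MarkerReference,
    OrthologMap,
    SampleRecord,
    SampleSheet,
    ValidationError,
)

#: leaf groups of the mixture: the seven main populations, with the
#: neural-crest population split into its two subpopulations.
DEFAULT_LEAVES = (
    "permanent_epidermis_keratinocyte",
    "fibroblast",
    "anagen_hf_keratinocyte",
    "vascular",
    "schwann",
    "melanocyte",
    "immune",
    "miscellaneous",
)

LEAF_PARENT = {
    "schwann": "neural_crest",
    "melanocyte": "neural_crest",
}

# Source-dependent mixing proportions over the leaf groups. Plucked hair is
# almost entirely follicle material (anagen HF keratinocytes plus melanocytes
# riding along with the shaft); biopsies are dominated by interfollicular
# populations. The polarization is deliberate — plucked shafts and whole-skin
# punches are drastically different materials — and gives every population's
# markers a bulk abundance shift of ~2x or more between sources, i.e. effect
# sizes of the magnitude the sampling-method contrast is about.
DEFAULT_COMPOSITIONS: dict[str, dict[str, float]] = {
    "plucked": {
        "permanent_epidermis_keratinocyte": 0.005,
        "fibroblast": 0.005,
        "anagen_hf_keratinocyte": 0.60,
        "vascular": 0.005,
        "schwann": 0.005,
        "melanocyte": 0.37,
        "immune": 0.005,
        "miscellaneous": 0.005,
    },
    "biopsy": {
        "permanent_epidermis_keratinocyte": 0.16,
        "fibroblast": 0.16,
        "anagen_hf_keratinocyte": 0.03,
        "vascular": 0.14,
        "schwann": 0.18,
        "melanocyte": 0.03,
        "immune": 0.15,
        "miscellaneous": 0.15,
    },
}

# 7 + 7 design: four subjects, biopsy and plucked samples from forelock
# (subjects 1-4) and mane (subjects 1-3) of the same animals.
DEFAULT_DESIGN = tuple(
    (source, site, f"horse{subject}")
    for source in ("plucked", "biopsy")
    for site, subjects in (("forelock", (1, 2, 3, 4)), ("mane", (1, 2, 3)))
    for subject in subjects
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the real design: 14 samples (7 plucked + 7 biopsy from
    4 subjects), ~1M reads per sample, NB dispersion 0.1, 10 unique marker
    genes per leaf population elevated 8-fold in their own population, and
    source compositions shifted toward follicle populations in plucked hair.
    """

    n_genes: int = 5000
    leaves: tuple[str, ...] = DEFAULT_LEAVES
    markers_per_population: int = 10
    marker_fold: float = 8.0
    base_log_mean: float = 0.0
    base_log_sd: float = 1.2
    dispersion: float = 0.1
    library_size_range: tuple[int, int] = (800_000, 1_200_000)
    design: tuple[tuple[str, str, str], ...] = DEFAULT_DESIGN
    compositions: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_COMPOSITIONS
    )
    fraction_multi_population_markers: float = 0.1
    fraction_unmapped_orthologs: float = 0.1
    ref_expressed_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.marker_fold < 1:
            raise ValidationError("marker_fold must be >= 1")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be >= 0")
        if self.markers_per_population * len(self.leaves) > self.n_genes:
            raise ValidationError(
                "more marker genes requested than genes in the simulation"
            )
        for source, comp in self.compositions.items():
            if set(comp) != set(self.leaves):
                raise ValidationError(
                    f"composition for {source!r} must cover exactly the leaves"
                )
            vec = np.array([comp[l] for l in self.leaves], float)
            if np.any(vec < 0) or abs(vec.sum() - 1.0) > 1e-9:
                raise ValidationError(
                    f"composition for {source!r} must be >= 0 and sum to 1"
                )

    def rng(self, stream: int, seed: int | None = None) -> np.random.Generator:
        base = self.seed if seed is None else seed
        return np.random.default_rng(np.random.SeedSequence([int(base), stream]))


def parent_population(leaf: str) -> str:
    return LEAF_PARENT.get(leaf, leaf)


@dataclass(frozen=True)
class SimulationTruth:
    """What the generator actually did, for parameter-recovery checks."""

    marker_population: Mapping[str, str]  # gene -> leaf population of origin
    compositions: Mapping[str, Mapping[str, float]]
    expected_direction: Mapping[str, str]  # leaf -> biopsy_higher | plucked_higher
    expected_calls: Mapping[str, str]  # parent population -> expected verdict
    expected_subpopulation_calls: Mapping[tuple[str, str], str]

    def as_dict(self) -> dict:
        return {
            "marker_population": dict(self.marker_population),
            "compositions": {s: dict(c) for s, c in self.compositions.items()},
            "expected_direction": dict(self.expected_direction),
            "expected_calls": dict(self.expected_calls),
            "expected_subpopulation_calls": {
                f"{p}/{s}": c for (p, s), c in self.expected_subpopulation_calls.items()
            },
        }


def _expected_truth(
    config: SimulationConfig, marker_population: Mapping[str, str]
) -> SimulationTruth:
    """Derive expected directions and calls from the composition vectors.

    A leaf's markers are expected higher in the source where the leaf's
    proportion is larger; a parent population's expected call applies the
    pipeline's own 0.75-majority rule to those expected marker directions
    (so a parent whose subpopulations pull both ways is expected
    inconclusive).
    """
    comp_p = config.compositions["plucked"]
    comp_b = config.compositions["biopsy"]
    direction = {}
    for leaf in config.leaves:
        if comp_p[leaf] > comp_b[leaf]:
            direction[leaf] = "plucked_higher"
        elif comp_b[leaf] > comp_p[leaf]:
            direction[leaf] = "biopsy_higher"
        else:
            direction[leaf] = "none"

    n_per = config.markers_per_population
    expected_calls: dict[str, str] = {}
    parents = sorted({parent_population(l) for l in config.leaves})
    for parent in parents:
        votes = {"biopsy_higher": 0, "plucked_higher": 0}
        for leaf in config.leaves:
            if parent_population(leaf) == parent and direction[leaf] != "none":
                votes[direction[leaf]] += n_per
        n = sum(votes.values())
        if n == 0:
            expected_calls[parent] = "no_call"
        elif votes["biopsy_higher"] / n >= 0.75:
            expected_calls[parent] = "biopsy_enriched"
        elif votes["plucked_higher"] / n >= 0.75:
            expected_calls[parent] = "plucked_enriched"
        else:
            expected_calls[parent] = "inconclusive"

    sub_calls = {}
    for leaf, parent in LEAF_PARENT.items():
        if leaf in config.leaves and direction[leaf] != "none":
            sub_calls[(parent, leaf)] = (
                "biopsy_enriched" if direction[leaf] == "biopsy_higher" else "plucked_enriched"
            )
    return SimulationTruth(
        marker_population=dict(marker_population),
        compositions={s: dict(c) for s, c in config.compositions.items()},
        expected_direction=direction,
        expected_calls=expected_calls,
        expected_subpopulation_calls=sub_calls,
    )


def generate_profiles(
    config: SimulationConfig, seed: int | None = None
) -> tuple[np.ndarray, list[str], SimulationTruth]:
    """Per-leaf expression-rate profiles.

    Returns ``(rates, gene_ids, truth)`` where ``rates`` is a
    leaves x genes matrix: a shared log-normal baseline per gene, with each
    marker gene's rate multiplied by ``marker_fold`` in its own leaf only.
    Deterministic given (config, seed).
    """
    rng = config.rng(1, seed)
    gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]
    base = rng.lognormal(config.base_log_mean, config.base_log_sd, config.n_genes)
    rates = np.tile(base, (len(config.leaves), 1))

    marker_population: dict[str, str] = {}
    order = rng.permutation(config.n_genes)
    k = config.markers_per_population
    for li, leaf in enumerate(config.leaves):
        for g in order[li * k : (li + 1) * k]:
            rates[li, g] *= config.marker_fold
            marker_population[gene_ids[g]] = leaf
    return rates, gene_ids, _expected_truth(config, marker_population)


def generate_bulk_counts(
    profiles: np.ndarray,
    gene_ids: Sequence[str],
    config: SimulationConfig,
    seed: int | None = None,
) -> tuple[CountMatrix, SampleSheet]:
    """Draw NB bulk counts for the configured design.

    Each sample's expected counts are its library size times the
    source-specific mixture of leaf profiles, normalized over genes so
    depth is composition-independent; counts are NB(mean, dispersion)
    (Poisson when dispersion = 0).
    """
    rng = config.rng(2, seed)
    records = []
    columns = []
    lo, hi = config.library_size_range
    for source, site, subject in config.design:
        sample_id = f"{source}_{site}_{subject}"
        records.append(SampleRecord(sample_id, source, site, subject))
        comp = np.array(
            [config.compositions[source][l] for l in config.leaves], float
        )
        mix = comp @ profiles  # per-gene mixture rate
        lib = int(rng.integers(lo, hi + 1))
        mean = lib * mix / mix.sum()
        if config.dispersion == 0:
            col = rng.poisson(mean)
        else:
            lam = rng.gamma(1.0 / config.dispersion, config.dispersion * mean)
            col = rng.poisson(lam)
        columns.append(col)
    counts = np.column_stack(columns).astype(np.int64)
    matrix = CountMatrix.from_counts(list(gene_ids), [r.sample_id for r in records], counts)
    return matrix, SampleSheet(tuple(records))


def generate_reference_tables(
    truth: SimulationTruth,
    gene_ids: Sequence[str],
    config: SimulationConfig,
    seed: int | None = None,
) -> tuple[MarkerReference, OrthologMap, frozenset[str], frozenset[str]]:
    """Marker reference, ortholog map, and reference expressed/significant sets.

    True markers are emitted as significant under their (parent) population,
    subpopulation leaves keeping their leaf name as subpopulation label. A
    configured fraction of non-marker genes is emitted as significant under
    two populations to exercise the unique-marker exclusion rule. The
    ortholog map is the identity minus a configured unmapped fraction
    (never dropping true markers' map rows by design would hide the rule,
    so markers may be lost too). Reference 'expressed' genes are the
    markers plus a random fraction of the remaining genes.
    """
    rng = config.rng(3, seed)
    marker_genes = set(truth.marker_population)
    non_markers = [g for g in gene_ids if g not in marker_genes]

    entries = [
        MarkerEntry(
            gene_id=g,
            population=parent_population(leaf),
            subpopulation=leaf if leaf in LEAF_PARENT else "",
            significant=True,
        )
        for g, leaf in sorted(truth.marker_population.items())
    ]

    n_multi = int(round(config.fraction_multi_population_markers * len(marker_genes)))
    multi_genes = list(rng.choice(non_markers, size=n_multi, replace=False)) if n_multi else []
    parents = sorted({parent_population(l) for l in config.leaves})
    for g in multi_genes:
        pops = rng.choice(parents, size=2, replace=False)
        for pop in pops:
            entries.append(MarkerEntry(str(g), str(pop), "", True))

    # nonsignificant 'expressed in the reference' backdrop
    backdrop_pool = [g for g in non_markers if g not in set(multi_genes)]
    n_backdrop = int(round(config.ref_expressed_fraction * len(backdrop_pool)))
    backdrop = rng.choice(backdrop_pool, size=n_backdrop, replace=False)
    for g in backdrop:
        pop = rng.choice(parents)
        entries.append(MarkerEntry(str(g), str(pop), "", False))

    reference = MarkerReference(tuple(entries))

    keep = rng.random(len(gene_ids)) >= config.fraction_unmapped_orthologs
    pairs = tuple((g, g) for g, k in zip(gene_ids, keep) if k)
    orthologs = OrthologMap(pairs)
    return reference, orthologs, reference.gene_ids, reference.significant_gene_ids


def generate_dataset(config: SimulationConfig, seed: int | None = None):
    """Convenience wrapper: profiles -> counts + sheet + reference tables.

    Returns (counts, sheet, reference, orthologs, ref_expressed,
    ref_significant, truth).
    """
    profiles, gene_ids, truth = generate_profiles(config, seed)
    counts, sheet = generate_bulk_counts(profiles, gene_ids, config, seed)
    reference, orthologs, ref_expr, ref_sig = generate_reference_tables(
        truth, gene_ids, config, seed
    )
    return counts, sheet, reference, orthologs, ref_expr, ref_sig, truth


def null_config(config: SimulationConfig | None = None) -> SimulationConfig:
    """Same cohort with identical compositions for both sources (global null)."""
    config = config or SimulationConfig()
    shared = dict(config.compositions["biopsy"])
    return replace(config, compositions={"plucked": shared, "biopsy": shared})
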