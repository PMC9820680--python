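import numpy as np
import pytest

from follicle_enrich.model import (
    CountMatrix,
    DifferentialResult,
    MarkerEntry,
    MarkerReference,
    NormalizationFactors,
    SampleRecord,
    SampleSheet,
)


@pytest.fixture
def tiny_counts() -> CountMatrix:
    """2 genes x 2 samples, counts ((1, 2), (3, 4))."""
    return CountMatrix.from_counts(
        ["gA", "gB"], ["s1", "s2"], np.array([[1, 2], [3, 4]])
    )


@pytest.fixture
def paired_sheet() -> SampleSheet:
    """7 + 7 design: 4 forelock + 3 mane samples per source, 4 subjects."""
    records = []
    for source in ("plucked", "biopsy"):
        for site, subjects in (("forelock", [1, 2, 3, 4]), ("mane", [1, 2, 3])):
            for s in subjects:
                records.append(
                    SampleRecord(f"{source}_{site}_{s}", source, site, f"horse{s}")
                )
    return SampleSheet(tuple(records))


@pytest.fixture
def unit_factors():
    def make(counts: CountMatrix) -> NormalizationFactors:
        return NormalizationFactors(
            counts.sample_ids,
            np.ones(counts.n_samples),
            counts.library_sizes.astype(float),
            counts.sample_ids[0],
        )

    return make


def de_result(gene, lfc, p=1e-4, fdr=1e-3, significant=True):
    if not significant:
        return DifferentialResult(gene, lfc, p, fdr, False, "none")
    direction = "biopsy_higher" if lfc > 0 else "plucked_higher"
    return DifferentialResult(gene, lfc, p, fdr, True, direction)


@pytest.fixture
def seven_population_reference() -> MarkerReference:
    """Reference whose unique-marker tallies mirror the real study:
    epidermis 5, fibroblast 13, anagen HF 9, vascular 6, neural crest 5
    (2 Schwann + 3 melanocyte), immune 2, miscellaneous 2 — 42 in all."""
    tallies = {
        "permanent_epidermis_keratinocyte": 5,
        "fibroblast": 13,
        "anagen_hf_keratinocyte": 9,
        "vascular": 6,
        "immune": 2,
        "miscellaneous": 2,
    }
    entries = []
    for pop, n in tallies.items():
        for i in range(n):
            entries.append(MarkerEntry(f"{pop}_m{i}", pop, "", True))
    for gene, sub in (
        ("CNP", "schwann"),
        ("MPZ", "schwann"),
        ("ATP6V1G1", "melanocyte"),
        ("NPY", "melanocyte"),
        ("PMEL", "melanocyte"),
    ):
        entries.append(MarkerEntry(gene, "neural_crest", sub, True))
    return MarkerReference(tuple(entries))
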