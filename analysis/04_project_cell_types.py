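#!/usr/bin/env python
"""Project the all-samples DE results onto the marker reference: ortholog
mapping, the expressed/significant Venn partition, unique-marker
extraction, per-population enrichment calls and the neural-crest
Schwann/melanocyte refinement. Calls are checked against the simulation
truth. Small tables go to results/."""

import json
from pathlib import Path

import pandas as pd

from follicle_enrich import io as fio
from follicle_enrich.model import enrichment_calls_to_frame
from follicle_enrich.projection import project

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "scratch" / "cohort"
PIPELINE = ROOT / "scratch" / "pipeline"
RESULTS = ROOT / "results"


def main() -> None:
    de = fio.read_differential_results(PIPELINE / "de_all_plucked_vs_all_biopsy.tsv")
    reference = fio.read_marker_reference(COHORT / "markers.tsv")
    orthologs = fio.read_ortholog_map(COHORT / "orthologs.tsv")
    truth = json.loads((COHORT / "truth.json").read_text())

    result = project(de, orthologs, reference)

    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "venn_regions.json").write_text(
        json.dumps(result.venn.as_dict(), indent=2) + "\n"
    )
    pd.DataFrame(
        [(g, pop) for pop, genes in result.markers.markers.items() for g in genes],
        columns=["gene_id", "population"],
    ).to_csv(RESULTS / "unique_markers.tsv", sep="\t", index=False)
    calls = enrichment_calls_to_frame(
        list(result.calls) + list(result.subpopulation_calls)
    )
    calls.to_csv(RESULTS / "enrichment_calls.tsv", sep="\t", index=False)

    print(f"Venn: {result.venn.as_dict()}")
    print(f"unique markers recovered: {result.markers.total}")
    expected = truth["expected_calls"]
    for c in result.calls:
        mark = "OK" if c.call == expected.get(c.population) else "MISMATCH"
        print(
            f"{c.population}: {c.n_biopsy_higher}/{c.n_markers} biopsy-higher "
            f"-> {c.call} [{mark}, expected {expected.get(c.population)}]"
        )
    for c in result.subpopulation_calls:
        print(
            f"  {c.population}/{c.subpopulation}: "
            f"{c.n_biopsy_higher}-{c.n_plucked_higher} -> {c.call}"
            + (" (predominant)" if c.predominant else "")
        )


if __name__ == "__main__":
    main()
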