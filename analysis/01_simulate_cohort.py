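#!/usr/bin/env python
"""Generate the default synthetic cohort: 14 bulk RNA-seq samples (7 plucked
hair + 7 skin biopsies from 4 subjects), 5,000 genes, NB dispersion 0.1,
with 10 unique marker genes per cell population and source compositions
polarized toward follicle populations in plucked hair.

Raw tables (counts, sheet, marker reference, ortholog map, truth) are
written to scratch/cohort/ — they are inputs for the later scripts, not
results. A small design summary lands in results/.
"""

import json
from pathlib import Path

from follicle_enrich import io as fio
from follicle_enrich.simulate import SimulationConfig, generate_dataset

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"


def main() -> None:
    config = SimulationConfig(seed=1)
    counts, sheet, reference, orthologs, _, _, truth = generate_dataset(config)

    COHORT.mkdir(parents=True, exist_ok=True)
    fio.write_count_matrix(counts, COHORT / "counts.tsv")
    fio.write_sample_sheet(sheet, COHORT / "sheet.csv")
    fio.write_marker_reference(reference, COHORT / "markers.tsv")
    fio.write_ortholog_map(orthologs, COHORT / "orthologs.tsv")
    (COHORT / "truth.json").write_text(json.dumps(truth.as_dict(), indent=2) + "\n")

    RESULTS.mkdir(exist_ok=True)
    design = {
        "n_genes": config.n_genes,
        "n_samples": counts.n_samples,
        "library_size_range": config.library_size_range,
        "dispersion": config.dispersion,
        "marker_fold": config.marker_fold,
        "markers_per_population": config.markers_per_population,
        "compositions": {s: dict(c) for s, c in config.compositions.items()},
        "seed": config.seed,
    }
    (RESULTS / "cohort_design.json").write_text(json.dumps(design, indent=2) + "\n")

    print(f"cohort: {counts.n_genes} genes x {counts.n_samples} samples -> {COHORT}")
    print(f"true markers: {len(truth.marker_population)}; "
          f"expected calls: {truth.expected_calls}")


if __name__ == "__main__":
    main()
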