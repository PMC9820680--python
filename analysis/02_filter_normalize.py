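#!/usr/bin/env python
"""Low-expression filtering (>= 1 RPM in >= 2 samples) and TMM
normalization of the synthetic cohort. Writes the per-sample factors to
results/ and reports what survived the filter."""

import json
from pathlib import Path

from follicle_enrich import io as fio
from follicle_enrich.preprocess import compute_tmm_factors, filter_low_expression

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"


def main() -> None:
    counts = fio.read_count_matrix(COHORT / "counts.tsv")
    filtered, report = filter_low_expression(counts)
    factors = compute_tmm_factors(filtered)

    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "filter_report.json").write_text(
        json.dumps(report.__dict__, indent=2) + "\n"
    )
    factors.to_frame().to_csv(RESULTS / "tmm_factors.tsv", sep="\t", index=False)
    fio.write_count_matrix(filtered, COHORT / "counts.filtered.tsv")

    print(f"retained {report.n_retained_genes}/{report.n_input_genes} genes")
    print(f"TMM reference sample: {factors.reference_sample}; "
          f"factor range [{factors.factor.min():.4f}, {factors.factor.max():.4f}]")


if __name__ == "__main__":
    main()
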