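#!/usr/bin/env python
"""Repeat the whole pipeline over independent synthetic cohorts and score
how often the enrichment calls recover the simulated composition shifts;
also measure null calibration (raw p < 0.05 rate under identical
compositions). Uses fewer replicates than the full acceptance run to stay
interactive; scripts/acceptance.py is the definitive version."""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from follicle_enrich.diffabund import run_contrast
from follicle_enrich.model import ContrastSpec
from follicle_enrich.pipeline import run_synthetic
from follicle_enrich.preprocess import filter_low_expression
from follicle_enrich.simulate import SimulationConfig, generate_dataset, null_config

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
N_RECOVERY_SEEDS = 10
N_NULL_SEEDS = 5


def main() -> None:
    rows = []
    for seed in range(N_RECOVERY_SEEDS):
        run = run_synthetic(SimulationConfig(), seed=seed)
        calls = run.population_calls()
        subs = run.subpopulation_calls()
        expected = run.truth.expected_calls
        rows.append(
            {
                "seed": seed,
                "n_significant": run.outcome.n_biopsy_higher + run.outcome.n_plucked_higher,
                "n_markers": run.projection.markers.total,
                "populations_correct": sum(
                    calls.get(p) == e for p, e in expected.items()
                ),
                "populations_total": len(expected),
                "subpopulations_correct": sum(
                    subs.get(k) == e
                    for k, e in run.truth.expected_subpopulation_calls.items()
                ),
            }
        )
    recovery = pd.DataFrame(rows)

    n_rej = n_tot = 0
    for seed in range(N_NULL_SEEDS):
        cfg = null_config(SimulationConfig(n_genes=2000))
        counts, sheet, *_ = generate_dataset(cfg, seed=seed)
        filtered, _ = filter_low_expression(counts)
        outcome = run_contrast(filtered, sheet, ContrastSpec.plucked_vs_biopsy())
        p = np.array([r.p_value for r in outcome.results])
        n_rej += int((p < 0.05).sum())
        n_tot += p.size

    RESULTS.mkdir(exist_ok=True)
    recovery.to_csv(RESULTS / "recovery_by_seed.tsv", sep="\t", index=False)
    summary = {
        "population_recovery_pct": round(
            100 * recovery.populations_correct.sum() / recovery.populations_total.sum(), 2
        ),
        "subpopulation_recovery_pct": round(
            100 * recovery.subpopulations_correct.sum() / (2 * len(recovery)), 2
        ),
        "null_rejection_rate_pct": round(100 * n_rej / n_tot, 3),
        "n_recovery_seeds": N_RECOVERY_SEEDS,
        "n_null_tests": n_tot,
    }
    (RESULTS / "evaluation_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    print(recovery.to_string(index=False))
    print(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
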