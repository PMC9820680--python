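# follicle-enrich

Which skin cell populations does each RNA-seq sampling method actually
capture? Plucking a hair collects the follicle and little else; a punch
biopsy collects whole skin. This package contrasts bulk RNA-seq gene
abundance between the two sampling methods and projects the results onto
a single-cell-derived marker reference to call, population by population,
which method enriches it — the kind of evidence needed before choosing
the non-invasive plucked-hair method for studies of hair growth,
pigmentation, or follicle disease.

It is written for transcriptomics practitioners: the inputs are an
ordinary gene × sample count matrix (featureCounts or plain TSV), a
sample sheet, a marker reference table, and an ortholog map; the outputs
are per-gene differential-abundance tables, gene-set overlap (Venn)
partitions, unique-marker sets, and per-population enrichment calls.

## Method core

* **Filtering**: keep genes with ≥ 1 read per million in ≥ 2 samples
  (library sizes fixed at load time).
* **TMM normalization**, re-implemented from the estimator's definition:
  per-gene log-ratios M_g against a reference sample, doubly trimmed
  (30% by M, 5% by average log expression A), averaged with
  precision weights w_g = [(N_k−y_gk)/(N_k y_gk) + (N_r−y_gr)/(N_r y_gr)]⁻¹;
  factor = 2^(Σ wM/Σ w), geometric mean rescaled to 1.
* **Differential abundance**: conditional negative-binomial exact test on
  library-equalized pseudo-counts — group sums are NB(nμ, φ/n); given the
  total t, the two-sided p sums the probabilities of all splits no more
  likely than the observed one. Common dispersion φ (var = μ + φμ²) by a
  median method-of-moments estimator; Benjamini–Hochberg FDR < 0.05.
  Positive log2 fold changes mean higher abundance in skin biopsies.
* **Marker projection**: one-to-one ortholog mapping, an eight-region
  expressed/significant Venn partition of the two gene universes, markers
  = genes significant in exactly one reference population, and a
  majority-direction enrichment call per population (conclusive at ≥ 0.75
  concordance), with subpopulation refinement (e.g. neural crest →
  Schwann vs melanocyte).
* **Synthetic cohorts**: NB counts from population-specific expression
  profiles mixed in source-dependent proportions, with matching marker
  reference, ortholog map, and ground truth — every stage is testable
  without any external download.

See `docs/methods.md` for assumptions, parameter defaults, and limits.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
cohort (5,000 genes, 7 plucked + 7 biopsy samples, NB dispersion 0.1,
10 markers per population elevated 8-fold in their own population):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_filter_normalize.py
python analysis/03_differential_abundance.py
python analysis/04_project_cell_types.py
python analysis/05_evaluate_recovery.py
```

Output of steps 3–4 (seed 1):

```
all_plucked_vs_all_biopsy: 42 higher / 27 lower in biopsies (phi = 0.0980)
forelock_plucked_vs_forelock_biopsy: 15 higher / 20 lower in biopsies (phi = 0.0965)
mane_plucked_vs_mane_biopsy: 12 higher / 19 lower in biopsies (phi = 0.0950)
unique markers recovered: 57
permanent_epidermis_keratinocyte: 5/5 biopsy-higher -> biopsy_enriched [OK]
fibroblast: 7/7 biopsy-higher -> biopsy_enriched [OK]
anagen_hf_keratinocyte: 0/9 biopsy-higher -> plucked_enriched [OK]
vascular: 8/8 biopsy-higher -> biopsy_enriched [OK]
neural_crest: 7/16 biopsy-higher -> inconclusive [OK]
immune: 6/6 biopsy-higher -> biopsy_enriched [OK]
miscellaneous: 6/6 biopsy-higher -> biopsy_enriched [OK]
  neural_crest/melanocyte: 0-9 -> plucked_enriched
  neural_crest/schwann: 7-0 -> biopsy_enriched
```

Reading: the exact test finds 69 significant genes in the all-samples
contrast at an estimated dispersion of 0.098 (truth: 0.1); 57 of them are
unique markers of one population. Every population's call matches the
simulated composition shift — anagen hair-follicle keratinocytes enriched
in plucked hair, interfollicular populations in biopsies — and the
neural-crest population, whose two subpopulations pull in opposite
directions, is correctly inconclusive at the parent level and resolves
into biopsy-enriched Schwann cells and plucked-enriched melanocytes.

The same pipeline runs from the shell on any dataset:

```bash
follicle-enrich simulate --seed 1 --out-dir cohort/
follicle-enrich run-all --config run.yaml   # filter -> TMM -> 3 contrasts -> projection
follicle-enrich de --counts counts.tsv --sheet sheet.csv --contrast plucked-vs-biopsy:mane --out de.tsv
follicle-enrich project --de de.tsv --orthologs orthologs.tsv --reference markers.tsv --out-dir proj/
```

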