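import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from follicle_enrich.model import (
    DifferentialResult,
    MarkerEntry,
    MarkerReference,
    MarkerSet,
    OrthologMap,
    ValidationError,
)
from follicle_enrich.projection import (
    call_enrichment,
    carried_forward_count,
    classify_venn,
    extract_unique_markers,
    map_orthologs,
    project,
    refine_subpopulations,
)

from conftest import de_result
from _oracles import venn_region_oracle


class TestOrthologMapping:
    def test_identity_map(self):
        rep = map_orthologs(["a", "b", "c"], OrthologMap((("a", "a"), ("b", "b"), ("c", "c"))))
        assert rep.mapped == (("a", "a"), ("b", "b"), ("c", "c"))
        assert rep.unmapped_study_ids == rep.ambiguous_ids == ()

    def test_missing_row_reported_unmapped(self):
        rep = map_orthologs(["a", "b"], OrthologMap((("a", "A"),)))
        assert rep.mapped == (("a", "A"),)
        assert rep.unmapped_study_ids == ("b",)

    def test_many_to_one_dropped_both_sides(self):
        rep = map_orthologs(["a", "b"], OrthologMap((("a", "X"), ("b", "X"))))
        assert rep.mapped == ()
        assert set(rep.ambiguous_ids) == {"a", "b"}

    def test_one_to_many_dropped(self):
        rep = map_orthologs(["a"], OrthologMap((("a", "X"), ("a", "Y"))))
        assert rep.mapped == ()
        assert rep.ambiguous_ids == ("a",)


class TestVenn:
    def test_hand_enumerated_five_gene_example(self):
        partition, lists = classify_venn(
            study_expressed={"a", "b", "c", "d"},
            study_significant={"a", "b"},
            ref_expressed={"b", "c", "e"},
            ref_significant={"b", "c"},
        )
        assert lists["both_expr_sig_both"] == ("b",)
        assert lists["both_expr_sig_ref_only"] == ("c",)
        assert lists["both_expr_sig_study_only"] == ()
        assert lists["study_only_sig"] == ("a",)
        assert lists["study_only_nonsig"] == ("d",)
        assert lists["ref_only_nonsig"] == ("e",)
        assert partition.n_universe == 5

    def test_empty_sets(self):
        partition, _ = classify_venn(set(), set(), set(), set())
        assert partition.n_universe == 0

    def test_significant_outside_expressed_rejected(self):
        with pytest.raises(ValidationError, match="ghost"):
            classify_venn({"a"}, {"ghost"}, set(), set())

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_partition_is_disjoint_and_exhaustive(self, seed):
        rng = np.random.default_rng(seed)
        universe = [f"g{i}" for i in range(40)]
        se = {g for g in universe if rng.random() < 0.6}
        re_ = {g for g in universe if rng.random() < 0.6}
        ss = {g for g in se if rng.random() < 0.5}
        rs = {g for g in re_ if rng.random() < 0.5}
        partition, lists = classify_venn(se, ss, re_, rs)
        everything = [g for genes in lists.values() for g in genes]
        assert len(everything) == len(set(everything)) == len(se | re_)
        for region, genes in lists.items():
            for g in genes:
                assert venn_region_oracle(g, se, ss, re_, rs) == region

    def test_printed_region_bookkeeping(self):
        assert carried_forward_count(4914, 2870, 1400) == 644
        with pytest.raises(ValidationError, match="inconsistent"):
            carried_forward_count(10, 8, 8)


class TestUniqueMarkers:
    def test_single_population_gene_is_marker(self):
        ref = MarkerReference((MarkerEntry("X", "anagen_hf_keratinocyte", "", True),))
        ms = extract_unique_markers(["X"], ref)
        assert ms.markers == {"anagen_hf_keratinocyte": ("X",)}

    def test_multi_population_gene_excluded(self):
        ref = MarkerReference(
            (
                MarkerEntry("X", "anagen_hf_keratinocyte", "", True),
                MarkerEntry("X", "permanent_epidermis_keratinocyte", "", True),
            )
        )
        ms = extract_unique_markers(["X"], ref)
        assert ms.total == 0
        assert ms.n_excluded_multi_population == 1

    def test_study_tally_reproduced(self, seven_population_reference):
        ms = extract_unique_markers(
            sorted(seven_population_reference.gene_ids), seven_population_reference
        )
        per_pop = sorted(len(g) for g in ms.markers.values())
        assert per_pop == [2, 2, 5, 5, 6, 9, 13]
        assert ms.total == 42

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_no_gene_under_two_populations(self, seed):
        rng = np.random.default_rng(seed)
        pops = ["immune", "vascular", "fibroblast"]
        entries = []
        for i in range(30):
            for pop in pops:
                if rng.random() < 0.4:
                    entries.append(MarkerEntry(f"g{i}", pop, "", bool(rng.random() < 0.7)))
        ref = MarkerReference(tuple(entries))
        ms = extract_unique_markers([f"g{i}" for i in range(30)], ref)
        seen = [g for genes in ms.markers.values() for g in genes]
        assert len(seen) == len(set(seen))
        for pop, genes in ms.markers.items():
            for g in genes:
                assert ref.significant_populations(g) == (pop,)


def tally_de(markers_by_pop):
    """Build DE results realizing given (n_biopsy_higher, n_plucked_higher)."""
    de, markers = [], {}
    for pop, (n_b, n_p) in markers_by_pop.items():
        genes = []
        for i in range(n_b):
            g = f"{pop}_b{i}"
            de.append(de_result(g, +1.0))
            genes.append(g)
        for i in range(n_p):
            g = f"{pop}_p{i}"
            de.append(de_result(g, -1.0))
            genes.append(g)
        markers[pop] = tuple(genes)
    return MarkerSet(markers=markers), de


class TestEnrichmentCalls:
    def test_printed_tallies_reproduce_verbal_conclusions(self):
        markers, de = tally_de(
            {
                "permanent_epidermis_keratinocyte": (5, 0),
                "fibroblast": (10, 3),
                "vascular": (5, 1),
                "anagen_hf_keratinocyte": (1, 8),
                "immune": (2, 0),
                "miscellaneous": (2, 0),
                "neural_crest": (3, 2),
            }
        )
        calls = {c.population: c for c in call_enrichment(markers, de)}
        assert calls["permanent_epidermis_keratinocyte"].call == "biopsy_enriched"
        assert calls["fibroblast"].call == "biopsy_enriched"
        assert calls["vascular"].call == "biopsy_enriched"
        assert calls["anagen_hf_keratinocyte"].call == "plucked_enriched"
        assert calls["anagen_hf_keratinocyte"].concordance == pytest.approx(8 / 9)
        assert calls["immune"].call == "biopsy_enriched"
        assert calls["miscellaneous"].call == "biopsy_enriched"
        assert calls["neural_crest"].call == "inconclusive"
        assert calls["neural_crest"].concordance == pytest.approx(0.6)

    def test_population_without_markers_gets_no_call(self):
        markers, de = tally_de({"immune": (2, 0)})
        calls = {c.population: c.call for c in call_enrichment(markers, de, populations=["immune", "vascular"])}
        assert calls["vascular"] == "no_call"

    def test_invariant_to_marker_and_de_order(self):
        markers, de = tally_de({"immune": (3, 1), "vascular": (1, 4)})
        fwd = call_enrichment(markers, de)
        rev = call_enrichment(markers, list(reversed(de)))
        assert fwd == rev

    def test_missing_de_result_names_gene(self):
        markers = MarkerSet(markers={"immune": ("orphan",)})
        with pytest.raises(ValidationError, match="orphan"):
            call_enrichment(markers, [])

    def test_nonsignificant_marker_rejected(self):
        markers = MarkerSet(markers={"immune": ("g1",)})
        with pytest.raises(ValidationError, match="direction"):
            call_enrichment(markers, [de_result("g1", 0.5, significant=False)])

    def test_source_relabelling_flips_calls(self):
        markers, de = tally_de({"immune": (3, 1), "anagen_hf_keratinocyte": (0, 5)})
        flipped = [
            DifferentialResult(
                r.gene_id,
                -r.log2_fc,
                r.p_value,
                r.fdr,
                r.significant,
                {"biopsy_higher": "plucked_higher", "plucked_higher": "biopsy_higher"}[r.direction],
            )
            for r in de
        ]
        fwd = {c.population: c for c in call_enrichment(markers, de)}
        rev = {c.population: c for c in call_enrichment(markers, flipped)}
        flip = {"biopsy_enriched": "plucked_enriched", "plucked_enriched": "biopsy_enriched",
                "inconclusive": "inconclusive", "no_call": "no_call"}
        for pop in fwd:
            assert rev[pop].call == flip[fwd[pop].call]
            assert rev[pop].concordance == fwd[pop].concordance


class TestSubpopulations:
    def make_reference(self):
        return MarkerReference(
            (
                MarkerEntry("CNP", "neural_crest", "schwann", True),
                MarkerEntry("MPZ", "neural_crest", "schwann", True),
                MarkerEntry("ATP6V1G1", "neural_crest", "melanocyte", True),
                MarkerEntry("NPY", "neural_crest", "melanocyte", True),
                MarkerEntry("PMEL", "neural_crest", "melanocyte", True),
            )
        )

    def test_schwann_vs_melanocyte_refinement(self):
        ref = self.make_reference()
        markers = MarkerSet(markers={"neural_crest": ("CNP", "MPZ", "ATP6V1G1", "NPY", "PMEL")})
        de = [
            de_result("CNP", 1.2),
            de_result("MPZ", 0.8),
            de_result("ATP6V1G1", -0.5),
            de_result("NPY", -1.1),
            de_result("PMEL", -0.9),
        ]
        calls = {c.subpopulation: c for c in refine_subpopulations("neural_crest", markers, ref, de)}
        assert calls["schwann"].call == "biopsy_enriched"
        assert calls["schwann"].n_markers == 2 and not calls["schwann"].predominant
        assert calls["melanocyte"].call == "plucked_enriched"
        # tallies across subpopulations sum to the parent's tally
        parent = call_enrichment(markers, de)[0]
        assert sum(c.n_markers for c in calls.values()) == parent.n_markers
        assert sum(c.n_biopsy_higher for c in calls.values()) == parent.n_biopsy_higher

    def test_majority_below_threshold_is_predominant(self):
        ref = MarkerReference(
            tuple(MarkerEntry(f"m{i}", "neural_crest", "melanocyte", True) for i in range(3))
        )
        markers = MarkerSet(markers={"neural_crest": ("m0", "m1", "m2")})
        de = [de_result("m0", -1.0), de_result("m1", -1.0), de_result("m2", 1.0)]
        (call,) = refine_subpopulations("neural_crest", markers, ref, de)
        assert call.call == "plucked_enriched" and call.predominant
        assert call.concordance == pytest.approx(2 / 3)

    def test_single_marker_follows_its_direction(self):
        ref = MarkerReference((MarkerEntry("m", "neural_crest", "schwann", True),))
        markers = MarkerSet(markers={"neural_crest": ("m",)})
        (call,) = refine_subpopulations("neural_crest", markers, ref, [de_result("m", 2.0)])
        assert call.call == "biopsy_enriched" and call.concordance == 1.0

    def test_unannotated_marker_goes_to_unassigned_bucket(self):
        ref = MarkerReference(
            (
                MarkerEntry("m", "neural_crest", "schwann", True),
                MarkerEntry("x", "neural_crest", "", True),
            )
        )
        markers = MarkerSet(markers={"neural_crest": ("m", "x")})
        de = [de_result("m", 1.0), de_result("x", -1.0)]
        calls = {c.subpopulation: c.call for c in refine_subpopulations("neural_crest", markers, ref, de)}
        assert calls == {"schwann": "biopsy_enriched", "unassigned": "plucked_enriched"}

    def test_population_without_subpopulations_rejected(self):
        ref = MarkerReference((MarkerEntry("m", "immune", "", True),))
        markers = MarkerSet(markers={"immune": ("m",)})
        with pytest.raises(ValidationError, match="no subpopulations"):
            refine_subpopulations("immune", markers, ref, [de_result("m", 1.0)])


class TestProject:
    def test_minimal_single_population_pipeline(self):
        ref = MarkerReference((MarkerEntry("M", "immune", "", True),))
        de = [de_result("M", -2.0), de_result("N", 0.1, significant=False)]
        result = project(de, OrthologMap((("M", "M"), ("N", "N"))), ref)
        calls = {c.population: c.call for c in result.calls}
        assert calls["immune"] == "plucked_enriched"
        assert result.venn.both_expr_sig_both == 1

    def test_empty_significance_gives_all_no_call(self):
        ref = MarkerReference((MarkerEntry("M", "immune", "", True),))
        de = [de_result("M", 0.0, significant=False)]
        result = project(de, OrthologMap((("M", "M"),)), ref)
        assert all(c.call == "no_call" for c in result.calls)

    def test_unmapped_genes_reported_not_classified(self):
        ref = MarkerReference((MarkerEntry("M", "immune", "", True),))
        de = [de_result("M", -2.0), de_result("lost", 1.0)]
        result = project(de, OrthologMap((("M", "M"),)), ref)
        assert result.mapping.unmapped_study_ids == ("lost",)
        assert "lost" not in {g for v in result.region_genes.values() for g in v}
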