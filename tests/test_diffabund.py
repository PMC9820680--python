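import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import follicle_enrich as fe
from follicle_enrich.diffabund import (
    ContrastOutcome,
    bh_fdr,
    equalize_counts,
    estimate_common_dispersion,
    exact_test_pvalues,
    nb_exact_test,
    run_contrast,
)
from follicle_enrich.model import (
    ContrastSpec,
    CountMatrix,
    DispersionEstimate,
    NormalizationFactors,
    SampleRecord,
    SampleSheet,
    ValidationError,
)

from _oracles import bh_stepup_oracle, binomial_exact_oracle, nb_exact_oracle


def nb_counts(rng, mu, phi, shape):
    if phi == 0:
        return rng.poisson(mu, shape)
    lam = rng.gamma(1 / phi, phi * mu, shape)
    return rng.poisson(lam)


def make_matrix(counts):
    counts = np.asarray(counts)
    return CountMatrix.from_counts(
        [f"g{i}" for i in range(counts.shape[0])],
        [f"s{j}" for j in range(counts.shape[1])],
        counts,
    )


def unit_factors_for(cm):
    return NormalizationFactors(
        cm.sample_ids, np.ones(cm.n_samples), cm.library_sizes.astype(float), cm.sample_ids[0]
    )


def two_group_sheet(n_a, n_b):
    recs = [
        SampleRecord(f"s{j}", "plucked" if j < n_a else "biopsy", "mane", f"h{j}")
        for j in range(n_a + n_b)
    ]
    return SampleSheet(tuple(recs))


class TestDispersion:
    def test_zero_within_group_variance_floors_at_zero(self):
        counts = np.tile([[10, 10, 10, 10]], (20, 1))
        cm = make_matrix(counts)
        est = estimate_common_dispersion(
            cm, (("s0", "s1"), ("s2", "s3")), unit_factors_for(cm)
        )
        assert est.common_dispersion == 0.0

    def test_poisson_counts_give_near_zero_dispersion(self):
        rng = np.random.default_rng(10)
        mu = rng.uniform(20, 200, 2000)
        cm = make_matrix(rng.poisson(mu[:, None], (2000, 8)))
        est = estimate_common_dispersion(
            cm, (cm.sample_ids[:4], cm.sample_ids[4:]), unit_factors_for(cm)
        )
        assert est.common_dispersion <= 0.02

    @pytest.mark.parametrize("seed", range(10))
    def test_recovers_true_dispersion(self, seed):
        rng = np.random.default_rng(seed)
        mu = rng.uniform(20, 200, 2000)
        cm = make_matrix(nb_counts(rng, mu[:, None], 0.1, (2000, 8)))
        est = estimate_common_dispersion(
            cm, (cm.sample_ids[:4], cm.sample_ids[4:]), unit_factors_for(cm)
        )
        assert 0.07 <= est.common_dispersion <= 0.13

    def test_all_sparse_matrix_rejected(self):
        counts = np.zeros((5, 4), dtype=int)
        counts[0, 0] = 1  # pooled mean 0.25 < 1 for every gene
        cm = make_matrix(counts)
        with pytest.raises(ValidationError, match="sparse"):
            estimate_common_dispersion(
                cm, (cm.sample_ids[:2], cm.sample_ids[2:]), unit_factors_for(cm)
            )


class TestExactTest:
    def test_balanced_split_is_modal(self):
        for phi in (0.0, 0.1, 1.0):
            assert nb_exact_test(5, 5, 1, 1, phi) == 1.0

    def test_poisson_limit_matches_binomial_closed_form(self):
        assert nb_exact_test(0, 20, 1, 1, 0.0) == pytest.approx(2 * 0.5**20, rel=1e-12)

    def test_zero_total_gives_p_one(self):
        assert nb_exact_test(0, 0, 3, 4, 0.2) == 1.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            nb_exact_test(1, 2, 1, 1, -0.5)
        with pytest.raises(ValidationError):
            nb_exact_test(-1, 2, 1, 1, 0.1)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.integers(0, 60),
        st.integers(0, 60),
        st.integers(1, 8),
        st.integers(1, 8),
        st.sampled_from([0.0, 0.05, 0.2, 1.0]),
    )
    def test_symmetry(self, s_a, s_b, n_a, n_b, phi):
        p1 = nb_exact_test(s_a, s_b, n_a, n_b, phi)
        p2 = nb_exact_test(s_b, s_a, n_b, n_a, phi)
        assert p1 == pytest.approx(p2, rel=1e-12)

    @pytest.mark.parametrize("n_a,n_b", [(1, 1), (2, 3), (7, 7)])
    def test_poisson_case_equals_binomial_enumeration(self, n_a, n_b):
        for t in range(0, 51, 5):
            for s_a in range(t + 1):
                assert nb_exact_test(s_a, t - s_a, n_a, n_b, 0.0) == pytest.approx(
                    binomial_exact_oracle(s_a, t - s_a, n_a, n_b), abs=1e-12
                )

    @pytest.mark.parametrize("phi", [0.05, 0.3, 1.5])
    def test_nb_case_equals_enumeration_oracle(self, phi):
        for t in (1, 7, 20, 41):
            for s_a in range(0, t + 1, 3):
                assert nb_exact_test(s_a, t - s_a, 3, 4, phi) == pytest.approx(
                    nb_exact_oracle(s_a, t - s_a, 3, 4, phi), abs=1e-12
                )

    def test_more_imbalance_never_increases_p(self):
        for phi in (0.0, 0.1, 0.7):
            t = 60
            p = [nb_exact_test(x, t - x, 2, 2, phi) for x in range(t // 2, -1, -1)]
            assert all(p[i + 1] <= p[i] + 1e-12 for i in range(len(p) - 1))

    def test_vectorized_agrees_with_scalar(self):
        rng = np.random.default_rng(3)
        sa = rng.integers(0, 400, 50)
        sb = rng.integers(0, 400, 50)
        batch = exact_test_pvalues(sa, sb, 7, 7, 0.1)
        singles = [nb_exact_test(int(a), int(b), 7, 7, 0.1) for a, b in zip(sa, sb)]
        assert np.allclose(batch, singles, atol=1e-12)


class TestBhFdr:
    def test_stepup_worked_example(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_identical_and_single_p_are_fixed_points(self):
        assert np.allclose(bh_fdr([0.5, 0.5, 0.5]), 0.5)
        assert bh_fdr([0.2]).tolist() == [0.2]

    def test_empty_vector(self):
        assert bh_fdr(np.array([])).size == 0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=40))
    def test_matches_brute_force_stepup(self, pvals):
        assert np.allclose(bh_fdr(pvals), bh_stepup_oracle(pvals), atol=1e-12)

    def test_monotone_in_p_value_rank(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(1e-6, 1, 200)
        fdr = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(fdr[order]) >= -1e-15)


class TestRunContrast:
    def test_null_input_identical_group_means(self):
        counts = np.tile([[30], [80], [140]], (1, 8))
        cm = make_matrix(counts)
        sheet = two_group_sheet(4, 4)
        out = run_contrast(cm, sheet, ContrastSpec.plucked_vs_biopsy())
        assert out.n_biopsy_higher == out.n_plucked_higher == 0
        assert all(r.log2_fc == 0 for r in out.results)
        assert all(r.p_value == 1.0 for r in out.results)

    def test_swapping_group_labels_negates_fold_changes(self):
        rng = np.random.default_rng(5)
        counts = nb_counts(rng, rng.uniform(20, 150, 300)[:, None], 0.05, (300, 8))
        cm = make_matrix(counts)
        sheet = two_group_sheet(4, 4)
        fwd = run_contrast(cm, sheet, ContrastSpec.plucked_vs_biopsy())
        swapped = ContrastSpec(
            group_a=lambda r: r.source == "biopsy",
            group_b=lambda r: r.source == "plucked",
            label="swapped",
        )
        rev = run_contrast(cm, sheet, swapped)
        assert np.allclose(
            [r.log2_fc for r in fwd.results], [-r.log2_fc for r in rev.results]
        )
        assert np.allclose(
            [r.p_value for r in fwd.results], [r.p_value for r in rev.results], atol=1e-12
        )

    @pytest.mark.parametrize("seed", range(12))
    def test_eightfold_gene_detected_with_correct_sign(self, seed):
        """An 8x biopsy-elevated gene should be called biopsy_higher in
        nearly all replicates (spec'd at >= 95% over many seeds)."""
        rng = np.random.default_rng(seed)
        mu = rng.uniform(30, 150, 200)
        counts = nb_counts(rng, mu[:, None], 0.05, (200, 14)).astype(float)
        counts[0, 7:] = nb_counts(rng, 8 * mu[0], 0.05, 7)
        cm = make_matrix(counts.astype(int))
        out = run_contrast(cm, two_group_sheet(7, 7), ContrastSpec.plucked_vs_biopsy())
        focal = out.results[0]
        assert focal.significant and focal.direction == "biopsy_higher"

    def test_overlapping_groups_rejected(self):
        cm = make_matrix(np.ones((5, 4), dtype=int) * 10)
        sheet = two_group_sheet(2, 2)
        overlapping = ContrastSpec(
            group_a=lambda r: True, group_b=lambda r: r.source == "biopsy", label="bad"
        )
        with pytest.raises(ValidationError, match="overlap"):
            run_contrast(cm, sheet, overlapping)

    def test_single_replicate_group_rejected(self):
        cm = make_matrix(np.ones((5, 8), dtype=int) * 10)
        sheet = two_group_sheet(1, 7)
        with pytest.raises(ValidationError, match=">= 2 samples"):
            run_contrast(cm, sheet, ContrastSpec.plucked_vs_biopsy())


def test_equalize_counts_matches_depth():
    counts = np.array([[10, 40], [90, 360]])
    eq = equalize_counts(counts, np.array([100.0, 400.0]), target=200.0)
    assert eq.tolist() == [[20, 20], [180, 180]]
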