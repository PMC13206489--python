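import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dynlr.bn_model import ThetaModel, genotype, locus_genotype_arrays
from dynlr.pmf_engine import (
    AliasingError,
    DiscretePMF,
    GridError,
    PMFCache,
    alpha_from_threshold,
    bin_index,
    convolve_direct,
    convolve_fft,
    count_loci_subsets,
    equal_genotype_mass,
    n_genotypes,
    single_locus_pmf,
    threshold_from_alpha,
)
from dynlr.popsim import synthetic_frequency_table
from tests.conftest import make_table


def pmf_from_masses(placements, delta=0.001, length=4096, loci=("X",)):
    mass = np.zeros(length)
    for bin_, value in placements:
        mass[bin_] = value
    return DiscretePMF(delta=delta, mass=mass, loci=frozenset(loci))


class TestBinning:
    def test_round_half_away_from_zero(self):
        assert bin_index(0.0015, 0.001) == 2
        assert bin_index(0.0005, 0.001) == 1

    def test_presnap_absorbs_float_noise(self):
        # 0.602059991... / 0.001 lands a hair under 602.06; exact bin targets
        # like 3 * 0.001 / 0.001 must not fall to 2 through representation.
        assert bin_index(0.003, 0.001) == 3
        assert bin_index(np.log10(4.0), 0.001) == 602


class TestEqualGenotypeMass:
    def test_hwe_values(self, toy_table, model_hwe):
        hom = genotype("COIN", "10", "10", toy_table)
        het = genotype("COIN", "10", "11", toy_table)
        assert equal_genotype_mass(hom, toy_table, model_hwe) == pytest.approx(0.0625)
        assert equal_genotype_mass(het, toy_table, model_hwe) == pytest.approx(0.25)

    def test_two_allele_locus_total(self, toy_table, model_hwe):
        pmf = single_locus_pmf("COIN", toy_table, model_hwe)
        assert pmf.total_mass == pytest.approx(0.375)


class TestSingleLocusPMF:
    def test_coin_locus_bins_and_clumping(self, toy_table, model_hwe):
        # two homozygotes (LR 4, log10 ~ 0.602) clump into bin 602; the
        # heterozygote (LR 2) sits alone in bin 301.
        pmf = single_locus_pmf("COIN", toy_table, model_hwe)
        assert pmf.mass[602] == pytest.approx(0.125)
        assert pmf.mass[301] == pytest.approx(0.25)
        assert np.count_nonzero(pmf.mass) == 2

    def test_ten_allele_ladder_has_55_genotypes(self, model):
        table = make_table(
            {"TEN": (tuple(str(i) for i in range(10)), (0.1,) * 10)}
        )
        arrays = locus_genotype_arrays("TEN", table, model)
        assert n_genotypes(10) == 55
        assert len(arrays["prob"]) == 55
        assert np.all(arrays["prob"] * arrays["cond"] > 0)

    @pytest.mark.parametrize("theta", [0.0, 0.01])
    def test_total_mass_is_subprobability(self, table6, theta):
        model = ThetaModel(theta)
        for locus in table6.loci:
            assert single_locus_pmf(locus, table6, model).total_mass <= 1 + 1e-9

    def test_grid_too_small_raises_aliasing(self, toy_table, model):
        with pytest.raises(AliasingError):
            single_locus_pmf("SKEW", toy_table, model, length=256)


class TestConvolution:
    def test_direct_empty_input_is_identity_element(self):
        pmf = convolve_direct([], length=1024)
        assert pmf.mass[0] == 1.0
        assert pmf.total_mass == 1.0

    def test_single_input_returned_unchanged(self, toy_table, model):
        pmf = single_locus_pmf("COIN", toy_table, model)
        assert convolve_fft([pmf]) is pmf
        assert convolve_direct([pmf]) is pmf

    def test_two_coin_loci_match_brute_force_enumeration(self, model_hwe):
        table = make_table(
            {
                "C1": (("10", "11"), (0.5, 0.5)),
                "C2": (("10", "11"), (0.5, 0.5)),
            }
        )
        pmfs = [single_locus_pmf(l, table, model_hwe) for l in table.loci]
        conv = convolve_fft(pmfs)
        # brute force over the 3x3 genotype pairs
        expected = np.zeros(conv.length)
        for (b1, m1) in [(301, 0.25), (602, 0.125)]:
            for (b2, m2) in [(301, 0.25), (602, 0.125)]:
                expected[b1 + b2] += m1 * m2
        np.testing.assert_allclose(conv.mass, expected, atol=1e-12)
        assert conv.total_mass == pytest.approx(0.375**2)

    @pytest.mark.parametrize("size", [2, 3])
    def test_fft_equals_direct_on_subsets(self, table6, model, size):
        singles = {l: single_locus_pmf(l, table6, model) for l in table6.loci}
        for subset in itertools.combinations(table6.loci[:4], size):
            fft = convolve_fft([singles[l] for l in subset])
            direct = convolve_direct([singles[l] for l in subset])
            assert np.abs(fft.mass - direct.mass).max() < 1e-10
            assert fft.loci == frozenset(subset)

    def test_subprobability_product_law(self, table6, model):
        singles = [single_locus_pmf(l, table6, model) for l in table6.loci]
        conv = convolve_fft(singles)
        product = np.prod([p.total_mass for p in singles])
        assert conv.total_mass == pytest.approx(product, abs=1e-9)

    def test_conditional_mean_additivity(self, table6, model):
        singles = [single_locus_pmf(l, table6, model) for l in table6.loci[:4]]
        conv = convolve_fft(singles)
        mean_sum = sum(p.conditional_moments()[0] for p in singles)
        mean_conv = conv.conditional_moments()[0]
        assert abs(mean_conv - mean_sum) <= len(singles) * conv.delta

    def test_mismatched_grids_rejected(self, toy_table, model):
        a = single_locus_pmf("COIN", toy_table, model, delta=0.001)
        b = single_locus_pmf("TRI", toy_table, model, delta=0.002)
        with pytest.raises(GridError):
            convolve_fft([a, b])

    def test_aliasing_guard_on_combined_support(self, toy_table, model):
        a = single_locus_pmf("SKEW", toy_table, model, length=4096)
        with pytest.raises(AliasingError):
            convolve_fft([a] * 3, length=4096)


class TestTailConversions:
    def test_threshold_zero_returns_total_mass(self, toy_table, model_hwe):
        pmf = single_locus_pmf("COIN", toy_table, model_hwe)
        assert alpha_from_threshold(pmf, 0.0) == pytest.approx(pmf.total_mass)

    def test_beyond_support_returns_zero(self, toy_table, model_hwe):
        pmf = single_locus_pmf("COIN", toy_table, model_hwe)
        assert alpha_from_threshold(pmf, 3.0) == 0.0

    def test_coin_locus_tail_at_half(self, toy_table, model_hwe):
        pmf = single_locus_pmf("COIN", toy_table, model_hwe)
        assert alpha_from_threshold(pmf, 0.5) == pytest.approx(0.125)

    def test_threshold_from_alpha_examples(self, toy_table, model_hwe):
        pmf = single_locus_pmf("COIN", toy_table, model_hwe)
        assert threshold_from_alpha(pmf, pmf.total_mass) == 0.0
        # smallest bin whose tail is within budget: the bin right above the
        # heterozygote spike at 0.301 (tail there is 0.125 <= 0.2, while the
        # tail one bin lower still includes the 0.25 spike)
        assert threshold_from_alpha(pmf, 0.2) == pytest.approx(0.302)
        assert alpha_from_threshold(pmf, 0.302) == pytest.approx(0.125)

    def test_nonpositive_alpha_rejected(self, toy_table, model_hwe):
        pmf = single_locus_pmf("COIN", toy_table, model_hwe)
        with pytest.raises(ValueError):
            threshold_from_alpha(pmf, 0.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_round_trip_bracket(self, seed):
        rng = np.random.default_rng(seed)
        mass = np.zeros(2048)
        bins = rng.choice(2048, size=40, replace=False)
        mass[bins] = rng.random(40)
        mass /= mass.sum() * 2  # sub-probability
        pmf = DiscretePMF(delta=0.001, mass=mass, loci=frozenset({"R"}))
        for alpha in [1e-4, 1e-3, 1e-2, 0.1]:
            thr = threshold_from_alpha(pmf, alpha)
            assert alpha_from_threshold(pmf, thr) <= alpha
            if thr > 0:
                assert alpha_from_threshold(pmf, thr - pmf.delta) > alpha

    @given(
        data=st.data(),
        alpha=st.floats(min_value=1e-6, max_value=0.9),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_round_trip_holds_for_arbitrary_subprobability_pmfs(
        self, data, alpha
    ):
        bins = data.draw(
            st.lists(
                st.tuples(
                    st.integers(min_value=0, max_value=1023),
                    st.floats(min_value=1e-6, max_value=1.0),
                ),
                min_size=1,
                max_size=20,
                unique_by=lambda t: t[0],
            )
        )
        mass = np.zeros(1024)
        for b, v in bins:
            mass[b] = v
        mass /= max(mass.sum() / 0.999, 1.0)  # keep sub-probability
        pmf = DiscretePMF(delta=0.001, mass=mass, loci=frozenset({"H"}))
        thr = threshold_from_alpha(pmf, alpha)
        assert alpha_from_threshold(pmf, thr) <= alpha
        if thr > 0:
            assert alpha_from_threshold(pmf, thr - pmf.delta) > alpha

    def test_tail_monotone_in_threshold(self, table6, model):
        pmf = single_locus_pmf(table6.loci[0], table6, model)
        thresholds = np.linspace(0, 5, 60)
        tails = [alpha_from_threshold(pmf, t) for t in thresholds]
        assert all(a >= b - 1e-15 for a, b in zip(tails, tails[1:]))

    def test_threshold_monotone_in_alpha(self, table6, model):
        pmf = convolve_fft(
            [single_locus_pmf(l, table6, model) for l in table6.loci[:3]]
        )
        alphas = np.logspace(-9, -1, 30)
        thresholds = [threshold_from_alpha(pmf, a) for a in alphas]
        assert all(t1 >= t2 - 1e-15 for t1, t2 in zip(thresholds, thresholds[1:]))


class TestCache:
    def test_cache_hit_reuses_convolution(self, table6, model):
        cache = PMFCache(table6, model)
        first = cache.pmf(["L01", "L02"])
        second = cache.pmf(("L02", "L01"))  # order-insensitive key
        assert first is second
        assert cache.stats == {"hits": 1, "misses": 1, "cached_sets": 1}

    def test_thresholds_cached_per_loci_set_and_alpha(self, table6, model):
        cache = PMFCache(table6, model)
        t1 = cache.threshold(["L01", "L03"], 1e-6)
        t2 = cache.threshold(["L03", "L01"], 1e-6)
        assert t1 == t2

    def test_empty_loci_set_rejected(self, table6, model):
        with pytest.raises(ValueError):
            PMFCache(table6, model).pmf([])


class TestCombinatorics:
    def test_subset_counts(self):
        assert count_loci_subsets(24, 4, 4) == 10626
        assert count_loci_subsets(24, 3, 24) == 16776915
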