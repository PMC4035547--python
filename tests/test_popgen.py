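"""Closed-form pool genetics: distributions, variances, noise, attenuation, LD."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from poolassoc import (
    InfeasibleLDError,
    LocusModel,
    attenuation_factor,
    binomial_noise_variance,
    explained_variance,
    genetic_variance_individual,
    genetic_variance_pool,
    haplotype_frequencies,
    harmonic_mean_depth,
    mating_table,
    poisson_missing_prob,
    pool_genotype_probs,
)
from poolassoc.popgen import POOL_FREQUENCIES


def enumerate_pool_probs(p):
    """Brute-force oracle: enumerate all 2^4 outcomes of four allele draws."""
    probs = np.zeros(5)
    for draws in itertools.product([0, 1], repeat=4):
        pr = np.prod([p if d else 1 - p for d in draws])
        probs[sum(draws)] += pr
    return probs


class TestPoolGenotypeDistribution:
    @pytest.mark.parametrize(
        "p, expected",
        [
            (0.0, (1, 0, 0, 0, 0)),
            (0.5, (0.0625, 0.25, 0.375, 0.25, 0.0625)),
            (0.1, (0.6561, 0.2916, 0.0486, 0.0036, 0.0001)),
            (1.0, (0, 0, 0, 0, 1)),
        ],
    )
    def test_examples(self, p, expected):
        dist = pool_genotype_probs(p)
        np.testing.assert_allclose(dist.probs, expected, atol=1e-12)
        np.testing.assert_array_equal(dist.support, POOL_FREQUENCIES)

    @given(st.floats(0.0, 1.0))
    @settings(max_examples=200, derandomize=True)
    def test_matches_enumeration_and_normalizes(self, p):
        probs = pool_genotype_probs(p).probs
        np.testing.assert_allclose(probs, enumerate_pool_probs(p), atol=1e-12)
        assert abs(probs.sum() - 1.0) < 1e-12
        assert np.all(probs >= 0)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            pool_genotype_probs(1.5)

    def test_moments(self):
        dist = pool_genotype_probs(0.3)
        assert dist.mean() == pytest.approx(0.3, abs=1e-12)
        assert dist.var() == pytest.approx(0.3 * 0.7 / 4, abs=1e-12)


class TestMatingTable:
    def test_six_rows_sum_to_one(self):
        rows = mating_table(0.37)
        assert len(rows) == 6
        assert sum(r.mating_freq for r in rows) == pytest.approx(1.0, abs=1e-12)

    def test_half_frequency_case(self):
        rows = mating_table(0.5)
        by_label = {r.mating: r for r in rows}
        assert by_label["aa x aa"].mating_freq == pytest.approx(0.0625)
        assert by_label["aa x aa"].pool_freq == 0.0
        assert by_label["aa x AA"].pool_freq == 0.5
        assert by_label["Aa x Aa"].pool_freq == 0.5

    def test_fixed_population(self):
        rows = mating_table(1.0)
        assert [r.mating_freq for r in rows] == [0, 0, 0, 0, 0, 1]
        assert rows[-1].mating == "AA x AA"

    @given(st.floats(0.0, 1.0))
    @settings(max_examples=200, derandomize=True)
    def test_aggregation_reproduces_pool_distribution(self, p):
        rows = mating_table(p)
        agg = np.zeros(5)
        for row in rows:
            agg[int(round(row.pool_freq * 4))] += row.mating_freq
        np.testing.assert_allclose(agg, pool_genotype_probs(p).probs, atol=1e-12)


class TestVariances:
    @pytest.mark.parametrize(
        "p, a, expected",
        [(0.5, 1.0, 0.5), (0.0, 2.0, 0.0), (1.0, 2.0, 0.0), (0.3, 0.5, 0.105)],
    )
    def test_individual(self, p, a, expected):
        model = LocusModel.from_allele_effect(p=p, a=a)
        assert genetic_variance_individual(model) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "p, a, expected",
        [(0.5, 1.0, (0.25, 0.0625)), (0.1, 1.0, (0.09, 0.0225))],
    )
    def test_pool(self, p, a, expected):
        model = LocusModel.from_allele_effect(p=p, a=a)
        value_var, freq_var = genetic_variance_pool(model)
        assert value_var == pytest.approx(expected[0])
        assert freq_var == pytest.approx(expected[1])

    def test_pool_value_variance_from_distribution(self):
        # independent route: b^2 * var of the exact pool-frequency distribution
        model = LocusModel(p=0.3, b=1.7)
        value_var, freq_var = genetic_variance_pool(model)
        dist_var = pool_genotype_probs(0.3).var()
        assert freq_var == pytest.approx(dist_var, abs=1e-12)
        assert value_var == pytest.approx(model.b**2 * dist_var, abs=1e-12)

    @given(st.floats(0.0, 1.0), st.floats(-3.0, 3.0))
    @settings(max_examples=100, derandomize=True)
    def test_pool_is_half_individual(self, p, a):
        model = LocusModel.from_allele_effect(p=p, a=a)
        assert genetic_variance_pool(model)[0] == pytest.approx(
            genetic_variance_individual(model) / 2.0, abs=1e-12
        )

    def test_zero_effect(self):
        assert genetic_variance_pool(LocusModel(p=0.4, b=0.0))[0] == 0.0


class TestBinomialNoise:
    @pytest.mark.parametrize(
        "p, depth, expected",
        [(0.5, 3, 0.0625), (0.0, 10, 0.0), (0.3, 7, 0.0225)],
    )
    def test_examples(self, p, depth, expected):
        assert binomial_noise_variance(p, depth) == pytest.approx(expected)

    @given(st.floats(0.0, 1.0), st.integers(1, 100))
    @settings(max_examples=200, derandomize=True)
    def test_weighted_enumeration_oracle(self, p, depth):
        # independent route: Pr(k)-weighted g(1-g)/S_T over the five pool genotypes
        probs = enumerate_pool_probs(p)
        g = POOL_FREQUENCIES
        expected = float(np.sum(g * (1 - g) * probs)) / depth
        assert binomial_noise_variance(p, depth) == pytest.approx(
            expected, abs=1e-12
        )

    def test_rejects_zero_depth(self):
        with pytest.raises(ValueError):
            binomial_noise_variance(0.5, 0)


class TestAttenuation:
    def test_known_depths(self):
        assert attenuation_factor(3) == 0.5
        assert attenuation_factor(30) == pytest.approx(1 / 1.1)
        assert attenuation_factor(1e12) == pytest.approx(1.0, abs=1e-9)

    def test_strictly_increasing(self):
        depths = np.linspace(0.5, 100, 400)
        values = np.array([attenuation_factor(d) for d in depths])
        assert np.all(np.diff(values) > 0)
        assert np.all((values > 0) & (values < 1))

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            attenuation_factor(0.0)

    def test_consistent_with_variance_ratio(self):
        # attenuation = var(g) / (var(g) + binomial noise), any p
        for p in (0.1, 0.3, 0.5):
            for depth in (3, 7, 15, 30):
                var_g = p * (1 - p) / 4
                ratio = var_g / (var_g + binomial_noise_variance(p, depth))
                assert attenuation_factor(depth) == pytest.approx(ratio)


class TestHarmonicMeanDepth:
    def test_examples(self):
        depth, excluded = harmonic_mean_depth([5, 5, 5])
        assert depth == pytest.approx(5.0)
        assert excluded == 0
        depth, excluded = harmonic_mean_depth([3, 3, 6])
        assert depth == pytest.approx(3.6)
        assert excluded == 0
        assert harmonic_mean_depth([0, 4, 4]) == (4.0, 1)

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            harmonic_mean_depth([0, 0])

    def test_at_most_arithmetic_mean(self):
        rng = np.random.default_rng(5)
        depths = rng.integers(1, 40, size=50)
        assert harmonic_mean_depth(depths).depth <= depths.mean() + 1e-12


class TestExplainedVariance:
    @pytest.mark.parametrize(
        "p, expected", [(0.1, 0.0014), (0.3, 0.0032), (0.5, 0.0039)]
    )
    def test_reference_values(self, p, expected):
        model = LocusModel(p=p, b=1.0, sigma_e=4.0)
        assert explained_variance(model) == pytest.approx(expected, abs=1e-4)

    def test_monotone_in_effect_and_noise(self):
        base = dict(p=0.3, sigma_e=4.0)
        values_b = [explained_variance(LocusModel(b=b, **base)) for b in (0.5, 1, 2, 4)]
        assert values_b == sorted(values_b) and len(set(values_b)) == 4
        values_s = [
            explained_variance(LocusModel(p=0.3, b=1.0, sigma_e=s))
            for s in (1, 2, 4, 10)
        ]
        assert values_s == sorted(values_s, reverse=True)

    def test_rejects_zero_noise(self):
        with pytest.raises(ValueError):
            explained_variance(LocusModel(p=0.3, b=1.0, sigma_e=0.0))


class TestHaplotypeFrequencies:
    def test_perfect_ld(self):
        two = haplotype_frequencies(0.5, 0.5, 1.0)
        np.testing.assert_allclose(two.haplotype_probs, [0.5, 0, 0, 0.5], atol=1e-12)

    def test_linkage_equilibrium(self):
        two = haplotype_frequencies(0.3, 0.3, 0.0)
        np.testing.assert_allclose(
            two.haplotype_probs, [0.09, 0.21, 0.21, 0.49], atol=1e-12
        )

    def test_intermediate_ld(self):
        two = haplotype_frequencies(0.3, 0.3, 0.7)
        assert two.D == pytest.approx(0.147)
        np.testing.assert_allclose(
            two.haplotype_probs, [0.237, 0.063, 0.063, 0.637], atol=1e-12
        )
        assert two.recomputed_r() == pytest.approx(0.7, abs=1e-9)

    def test_infeasible_r_names_haplotype(self):
        with pytest.raises(InfeasibleLDError, match="x12"):
            haplotype_frequencies(0.05, 0.5, 0.9)
        with pytest.raises(InfeasibleLDError, match="x1[12]|x2[12]"):
            haplotype_frequencies(0.5, 0.05, -0.9)

    @given(
        st.floats(0.01, 0.99),
        st.floats(0.01, 0.99),
        st.floats(-1.0, 1.0),
    )
    @settings(max_examples=300, derandomize=True)
    def test_round_trip_and_marginals(self, p1, q1, r):
        try:
            two = haplotype_frequencies(p1, q1, r)
        except InfeasibleLDError:
            return
        x = two.haplotype_probs
        assert abs(x.sum() - 1.0) < 1e-12
        assert np.all(x >= 0)
        assert x[0] + x[1] == pytest.approx(p1, abs=1e-12)
        assert x[0] + x[2] == pytest.approx(q1, abs=1e-12)
        assert two.recomputed_r() == pytest.approx(r, abs=1e-9)


class TestPoissonMissing:
    def test_zero_read_probabilities(self):
        # e^-lambda, i.e. ~0.7 %, 0.2 %, 0.1 % at mean depth 5, 6, 7
        assert poisson_missing_prob(5) == pytest.approx(np.exp(-5))
        assert round(100 * poisson_missing_prob(5), 1) == 0.7
        assert round(100 * poisson_missing_prob(6), 1) == 0.2
        assert round(100 * poisson_missing_prob(7), 1) == 0.1

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            poisson_missing_prob(0)
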