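"""Quantum-population operators: observation, rotation, mutation, stability."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ceqea.entropy import EntropyProfile
from ceqea.quantum import (
    BinaryMask,
    QubitChromosome,
    StabilityScores,
    init_population,
    mutation_probability,
    observe,
    phase_flip,
    rotate,
    rotation_sign,
    stability_scores,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_chromosome(n, rng):
    theta = rng.uniform(0, 2 * np.pi, n)
    return QubitChromosome(np.cos(theta), np.sin(theta))


class TestChromosome:
    def test_init_population_is_unbiased_superposition(self):
        pop = init_population(5, 10)
        assert len(pop) == 5
        for chrom in pop:
            np.testing.assert_allclose(chrom.alpha**2 + chrom.beta**2, 1.0, atol=1e-12)
            np.testing.assert_allclose(chrom.p_one, 0.5, atol=1e-12)

    def test_fresh_population_observes_half_the_tokens(self, rng):
        # mean retained ~ Binomial(n, 1/2) over repeated observations
        n = 20
        chrom = init_population(2, n)[0]
        counts = [observe(chrom, rng, force_first=False).retained_count for _ in range(1000)]
        se = np.sqrt(n * 0.25 / 1000)
        assert abs(np.mean(counts) - n / 2) < 4 * se

    def test_too_small_population_rejected(self):
        with pytest.raises(ValueError):
            init_population(1, 10)

    def test_array_round_trip(self, rng):
        chrom = random_chromosome(6, rng)
        back = QubitChromosome.from_array(chrom.to_array())
        np.testing.assert_allclose(back.alpha, chrom.alpha)
        np.testing.assert_allclose(back.beta, chrom.beta)


class TestObservation:
    def test_deterministic_qubits(self, rng):
        n = 8
        sure_zero = QubitChromosome(np.ones(n), np.zeros(n))
        sure_one = QubitChromosome(np.zeros(n), np.ones(n))
        assert observe(sure_zero, rng, force_first=False).retained_count == 0
        assert observe(sure_one, rng, force_first=False).retained_count == n

    def test_observation_frequency_matches_beta_squared(self, rng):
        # P(1) = beta^2 within 3 binomial sigma at 1e5 draws
        p1 = 0.75
        chrom = QubitChromosome(np.array([0.5]), np.array([np.sqrt(p1)]))
        draws = 100_000
        ones = sum(int(observe(chrom, rng, force_first=False).bits[0]) for _ in range(draws))
        sigma = np.sqrt(draws * p1 * (1 - p1))
        assert abs(ones - draws * p1) < 3 * sigma

    def test_force_first_always_retains_class_token(self, rng):
        chrom = QubitChromosome(np.ones(5), np.zeros(5))  # would observe all zeros
        for _ in range(20):
            assert observe(chrom, rng, force_first=True).bits[0] == 1


class TestRotation:
    @pytest.mark.parametrize(
        "bit, best, worse, expected",
        [
            (0, 1, True, +1),
            (0, 1, False, -1),
            (1, 0, False, +1),
            (1, 0, True, -1),
            (0, 0, True, 0),
            (0, 0, False, 0),
            (1, 1, True, 0),
            (1, 1, False, 0),
        ],
    )
    def test_sign_table_all_eight_cases(self, bit, best, worse, expected):
        f, fstar = (0.2, 0.9) if worse else (0.9, 0.2)
        assert rotation_sign(bit, best, f, fstar) == expected

    def test_identity_when_masks_agree(self, rng):
        chrom = random_chromosome(7, rng)
        mask = observe(chrom, rng, force_first=False)
        out = rotate(chrom, mask, mask, 0.3, 0.9, 0.05)
        np.testing.assert_allclose(out.alpha, chrom.alpha, atol=1e-12)
        np.testing.assert_allclose(out.beta, chrom.beta, atol=1e-12)

    def test_quarter_rotation_swaps_basis_state(self):
        chrom = QubitChromosome(np.array([1.0]), np.array([0.0]))
        own = BinaryMask(np.array([0], dtype=np.int8))
        best = BinaryMask(np.array([1], dtype=np.int8))
        out = rotate(chrom, own, best, 0.1, 0.9, np.pi / 2)  # sign +1
        np.testing.assert_allclose(out.alpha[0], 0.0, atol=1e-12)
        np.testing.assert_allclose(out.beta[0], 1.0, atol=1e-12)

    def test_normalization_preserved_over_random_cases(self, rng):
        for _ in range(1000):
            n = int(rng.integers(1, 12))
            chrom = random_chromosome(n, rng)
            own = BinaryMask(rng.integers(0, 2, n).astype(np.int8))
            best = BinaryMask(rng.integers(0, 2, n).astype(np.int8))
            out = rotate(chrom, own, best, rng.random(), rng.random(), rng.uniform(0, 1.5))
            np.testing.assert_allclose(out.alpha**2 + out.beta**2, 1.0, atol=1e-9)

    def test_positive_sign_increases_retention_probability(self, rng):
        # for positive-amplitude qubits and steps < pi/2
        for theta in np.linspace(0.05, np.pi / 2 - 0.05, 12):
            chrom = QubitChromosome(np.array([np.cos(theta)]), np.array([np.sin(theta)]))
            own = BinaryMask(np.array([0], dtype=np.int8))
            best = BinaryMask(np.array([1], dtype=np.int8))
            up = rotate(chrom, own, best, 0.1, 0.9, 0.05)  # sign +1
            down = rotate(chrom, best, own, 0.1, 0.9, 0.05)  # (1,0) worse -> -1
            assert up.p_one[0] > chrom.p_one[0]
            assert down.p_one[0] < chrom.p_one[0]

    def test_length_mismatch_rejected(self, rng):
        chrom = random_chromosome(5, rng)
        with pytest.raises(ValueError):
            rotate(chrom, BinaryMask(np.ones(4, dtype=np.int8)), BinaryMask(np.ones(5, dtype=np.int8)), 0, 1, 0.05)


class TestPhaseFlip:
    def test_negates_second_amplitude(self):
        chrom = QubitChromosome(np.array([0.6]), np.array([0.8]))
        out = phase_flip(chrom, 0)
        assert out.alpha[0] == pytest.approx(0.6)
        assert out.beta[0] == pytest.approx(-0.8)

    def test_involution_and_probability_invariance(self, rng):
        chrom = random_chromosome(4, rng)
        twice = phase_flip(phase_flip(chrom, 2), 2)
        np.testing.assert_allclose(twice.beta, chrom.beta)
        np.testing.assert_allclose(phase_flip(chrom, 2).p_one, chrom.p_one)

    def test_out_of_range_position(self, rng):
        with pytest.raises(IndexError):
            phase_flip(random_chromosome(4, rng), 4)


class TestMutationProbability:
    def test_best_individual_never_mutates(self):
        prof = EntropyProfile(1.0, 2.0)
        assert mutation_probability(0.15, 0.9, 0.9, prof, 1.0) == 0.0

    def test_reference_product(self):
        prof = EntropyProfile(2.0, 4.0)
        assert mutation_probability(0.15, 0.5, 1.0, prof, 1.0) == pytest.approx(0.0375)

    def test_zero_stability_blocks_mutation(self):
        prof = EntropyProfile(0.0, 2.0)
        assert mutation_probability(0.15, 0.0, 1.0, prof, 0.0) == 0.0

    def test_zero_max_fitness_fallback_drops_fitness_factor(self):
        prof = EntropyProfile(1.0, 2.0)
        assert mutation_probability(0.2, 0.0, 0.0, prof, 1.0) == pytest.approx(0.1)

    @given(
        st.floats(min_value=0, max_value=0.3),
        st.floats(min_value=0, max_value=1),
        st.floats(min_value=0, max_value=1),
        st.floats(min_value=0, max_value=1),
    )
    @settings(deadline=None, derandomize=True)
    def test_bounded_by_base_rate(self, eta, frac, hnorm, s):
        prof = EntropyProfile(hnorm * 2.0, 2.0)
        p = mutation_probability(eta, frac, 1.0, prof, s)
        assert 0.0 <= p <= eta + 1e-12


class TestStabilityScores:
    def test_unanimous_selection(self):
        masks = [BinaryMask(np.array([1, 1, 0], dtype=np.int8))] * 3
        scores = stability_scores([masks])
        np.testing.assert_allclose(scores.scores, [1.0, 1.0, 0.0])

    def test_cross_client_average(self):
        # client A: 3 of 4 masks select the token; client B: 1 of 2
        a = [BinaryMask(np.array([1], dtype=np.int8))] * 3 + [BinaryMask(np.array([0], dtype=np.int8))]
        b = [BinaryMask(np.array([1], dtype=np.int8)), BinaryMask(np.array([0], dtype=np.int8))]
        scores = stability_scores([a, b])
        assert scores.scores[0] == pytest.approx(0.625)

    def test_empty_clients_excluded_then_fallback(self):
        a = [BinaryMask(np.array([1, 0], dtype=np.int8))]
        scores = stability_scores([a, []])
        np.testing.assert_allclose(scores.scores, [1.0, 0.0])
        fallback = stability_scores([[], []], n_tokens=4)
        np.testing.assert_allclose(fallback.scores, 1.0)

    def test_scores_stay_in_unit_interval(self):
        with pytest.raises(ValueError):
            StabilityScores(np.array([1.2]))
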