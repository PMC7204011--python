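import numpy as np
import pytest

from dotprint import (
    DecayCurve,
    ProteinSequence,
    RepeatSpec,
    decay_experiment,
    fit_exponential,
    insertion_experiment,
    make_tandem_protein,
    mutate_once,
    shuffle_alphabet_mc,
    substitution_probabilities,
)
from dotprint.alphabet import AMINO_ACIDS
from dotprint.evolve import InsertionCurve, ReplacementMap, _map_score

from .oracles import identity_markov_expectation


class TestMutateOnce:
    def test_forced_change_on_single_residue(self, blosum62, rng):
        for _ in range(20):
            out = mutate_once(ProteinSequence("a", "A"), blosum62, rng)
            assert out.residues != "A"

    def test_deterministic_under_seed(self, blosum62):
        seq = ProteinSequence("s", "MKTAYIAKQRQISFVK")
        a = mutate_once(seq, blosum62, np.random.default_rng(42))
        b = mutate_once(seq, blosum62, np.random.default_rng(42))
        assert a.residues == b.residues

    def test_substitution_probabilities_follow_blosum(self, blosum62, rng):
        """From W, the half-bit back-transform prefers Y (M=2) over P (M=-4)
        by a factor of 2^3 = 8; check empirical frequencies against the
        exact categorical probabilities."""
        probs = substitution_probabilities(blosum62)
        w = AMINO_ACIDS.index("W")
        p_y, p_p = probs[w, AMINO_ACIDS.index("Y")], probs[w, AMINO_ACIDS.index("P")]
        assert p_y / p_p == pytest.approx(2 ** ((2 - (-4)) / 2))
        draws = 20000
        seq = ProteinSequence("w", "W")
        got = [mutate_once(seq, blosum62, rng, probs).residues for _ in range(draws)]
        freq_y = got.count("Y") / draws
        freq_p = got.count("P") / draws
        assert freq_y == pytest.approx(p_y, abs=4 * np.sqrt(p_y / draws))
        assert freq_p == pytest.approx(p_p, abs=4 * np.sqrt(max(p_p, 1e-4) / draws))
        assert freq_y > freq_p

    def test_probability_rows_normalized_no_self(self, blosum62):
        probs = substitution_probabilities(blosum62)
        assert probs.shape == (20, 20)
        assert np.allclose(probs.sum(axis=1), 1.0)
        assert np.allclose(np.diag(probs), 0.0)


class TestDecay:
    def test_zero_rounds_curve(self, blosum62):
        seq = ProteinSequence("s", "MKTAYIAKQRQISFVK")
        curve = decay_experiment(seq, blosum62, rounds=0, replicates=1,
                                 rng=np.random.default_rng(0))
        assert curve.mean_jx.tolist() == [1.0]
        assert curve.mean_identity.tolist() == [100.0]

    def test_jx_nonincreasing_within_noise(self, blosum62):
        rng = np.random.default_rng(5)
        spec = RepeatSpec(unit_length=30, copies=4, unit_divergence=(0.3, 0.5), flank_length=0)
        seq, _ = make_tandem_protein(spec, blosum62, rng)
        curve = decay_experiment(seq, blosum62, replicates=50, rng=rng, measure_every=8)
        diffs = np.diff(curve.mean_jx)
        assert (diffs <= 0.05).all()

    def test_identity_matches_markov_oracle(self, blosum62):
        """Measured mean identity equals the exact per-site Markov-chain
        expectation (which includes reversions) within 3 standard errors."""
        rng = np.random.default_rng(11)
        seq = ProteinSequence("s", "".join(rng.choice(list(AMINO_ACIDS), size=60)))
        reps = 60
        curve = decay_experiment(seq, blosum62, rounds=60, replicates=reps,
                                 rng=rng, measure_every=60)
        expected = identity_markov_expectation(seq.residues, blosum62, 60)
        # per-replicate identity is an average of 60 near-Bernoulli sites
        se = 100 * np.sqrt(0.4 * 0.6 / 60) / np.sqrt(reps)
        assert curve.mean_identity[-1] == pytest.approx(expected, abs=3 * se)

    def test_reproducible_under_seed(self, blosum62):
        seq = ProteinSequence("s", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ")
        kwargs = dict(rounds=10, replicates=3, measure_every=5)
        a = decay_experiment(seq, blosum62, rng=np.random.default_rng(7), **kwargs)
        b = decay_experiment(seq, blosum62, rng=np.random.default_rng(7), **kwargs)
        assert np.array_equal(a.mean_jx, b.mean_jx)
        assert np.array_equal(a.mean_identity, b.mean_identity)


class TestExponentialFit:
    @staticmethod
    def synthetic_curve(b, z, noise=0.0, rng=None):
        j = np.exp(-b * z)
        if noise:
            j = j + rng.normal(0, noise, size=z.size)
        return DecayCurve(steps=np.arange(z.size + 1),
                          mean_jx=np.concatenate([[1.0], j]),
                          mean_identity=np.concatenate([[100.0], 100.0 - z]),
                          replicates=1)

    def test_noiseless_recovery(self):
        z = np.arange(1.0, 31.0)
        fit = fit_exponential(self.synthetic_curve(0.1, z))
        assert fit.b == pytest.approx(0.1, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.clean

    def test_half_life_consistency(self):
        z = np.arange(1.0, 31.0)
        b = np.log(2) / 8.2
        fit = fit_exponential(self.synthetic_curve(b, z))
        assert fit.z50 == pytest.approx(8.2, rel=1e-6)

    def test_noisy_recovery(self):
        rng = np.random.default_rng(3)
        z = np.arange(1.0, 31.0)
        fit = fit_exponential(self.synthetic_curve(0.1, z, noise=0.01, rng=rng))
        assert 0.08 <= fit.b <= 0.12
        assert fit.r_squared >= 0.98

    @pytest.mark.parametrize("b", [0.02, 0.05, 0.1, 0.2])
    def test_parameter_grid_recovery(self, b):
        rng = np.random.default_rng(int(b * 1000))
        z = np.linspace(1, 60, 40)
        fit = fit_exponential(self.synthetic_curve(b, z, noise=0.02, rng=rng))
        assert fit.b == pytest.approx(b, rel=0.15)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_exponential(self.synthetic_curve(0.1, np.arange(1.0, 4.0)))

    def test_non_decaying_curve_flagged(self):
        z = np.arange(1.0, 11.0)
        curve = DecayCurve(steps=np.arange(11), mean_jx=np.concatenate([[1.0], np.full(10, 1.0)]),
                           mean_identity=np.concatenate([[100.0], 100.0 - z]), replicates=1)
        fit = fit_exponential(curve)
        assert not fit.clean or fit.b < 1e-6


class TestInsertion:
    def test_zero_insertions_full_similarity(self, blosum62, tandem_exact):
        curve = insertion_experiment(tandem_exact, blosum62, max_fraction=0.03,
                                     replicates=2, rng=np.random.default_rng(0))
        assert curve.mean_jx[0] == 1.0
        assert curve.rate_percent[0] == 0.0

    def test_jx_decreases_with_insertions(self, blosum62, tandem_exact):
        curve = insertion_experiment(tandem_exact, blosum62, max_fraction=0.06,
                                     replicates=10, rng=np.random.default_rng(1))
        assert (np.diff(curve.mean_jx) <= 0.05).all()
        assert curve.mean_jx[-1] < curve.mean_jx[0]

    def test_half_loss_rate_units_and_interpolation(self):
        # 4 insertions into a 417-residue chain is a 0.96% insertion rate
        counts = np.arange(5)
        curve = InsertionCurve(n_inserted=counts,
                               rate_percent=100.0 * counts / 417,
                               mean_jx=np.array([1.0, 0.9, 0.7, 0.6, 0.5]),
                               replicates=1)
        assert curve.rate_percent[4] == pytest.approx(0.959, abs=1e-3)
        assert curve.half_loss_rate == pytest.approx(100 * 4 / 417, abs=1e-6)
        # interpolated crossing between measurements
        curve2 = InsertionCurve(n_inserted=np.arange(3),
                                rate_percent=np.array([0.0, 1.0, 2.0]),
                                mean_jx=np.array([1.0, 0.8, 0.4]),
                                replicates=1)
        assert curve2.half_loss_rate == pytest.approx(1.75)


class TestAlphabetShuffle:
    def test_map_is_always_bijection(self, blosum62, rng):
        seq = ProteinSequence("s", "".join(rng.choice(list(AMINO_ACIDS), size=50)))
        for _ in range(3):
            res = shuffle_alphabet_mc(seq, blosum62, steps=200, restarts=2, rng=rng)
            assert sorted(res.map.mapping) == sorted(AMINO_ACIDS)
            assert sorted(res.map.mapping.values()) == sorted(AMINO_ACIDS)

    def test_reported_score_matches_mapping(self, blosum62, rng):
        seq = ProteinSequence("s", "".join(rng.choice(list(AMINO_ACIDS), size=40)))
        res = shuffle_alphabet_mc(seq, blosum62, steps=300, restarts=2, rng=rng)
        mapped = res.map.apply(seq)
        manual = sum(
            blosum62.score(x, y) for x, y in zip(mapped.residues, seq.residues)
        ) / len(seq)
        assert res.map.similarity_score == pytest.approx(manual)

    def test_non_bijection_rejected(self):
        mapping = {a: "A" for a in AMINO_ACIDS}
        with pytest.raises(ValueError):
            ReplacementMap(mapping=mapping, similarity_score=0.0)

    def test_pattern_survives_shuffling(self, blosum62):
        """On a strongly repetitive chain the optimized map erases sequence
        identity while the dot-plot pattern remains recognizable."""
        rng = np.random.default_rng(8)
        spec = RepeatSpec(unit_length=25, copies=6, unit_divergence=0.05, flank_length=5)
        seq, _ = make_tandem_protein(spec, blosum62, rng)
        res = shuffle_alphabet_mc(seq, blosum62, steps=2000, restarts=3, rng=rng)
        assert res.identity_percent <= 10.0
        assert res.jaccard >= 0.1

    def test_swap_moves_preserve_score_bookkeeping(self, blosum62, rng):
        # the score function itself: identity map scores the mean diagonal
        codes = rng.choice(20, size=30)
        seq = ProteinSequence("s", "".join(AMINO_ACIDS[c] for c in codes))
        comp = np.bincount(codes, minlength=20).astype(float)
        ident = np.arange(20)
        score = _map_score(ident, comp, blosum62.standard_block.astype(float), 30)
        manual = np.mean([blosum62.score(c, c) for c in seq.residues])
        assert score == pytest.approx(manual)
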