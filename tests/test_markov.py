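import math
from collections import Counter, defaultdict

import numpy as np
import pytest

from rsgkit.markov import (
    TransitionModel,
    conditional_entropy_rate,
    log_likelihood,
    score_participant,
    score_sequence,
    select_order,
)
from rsgkit.sequences import ParticipantRecord
from tests.conftest import make_blocks


def naive_counts(seq, k):
    """Independent dict-based subsequence counting."""
    counts = defaultdict(Counter)
    for i in range(len(seq) - k):
        counts[tuple(seq[i : i + k])][seq[i + k]] += 1
    return counts


def naive_log_likelihood(seq, k):
    """Brute-force per-position product of the self-fit probabilities."""
    counts = naive_counts(seq, k)
    total = 0.0
    for i in range(len(seq) - k):
        ctx = tuple(seq[i : i + k])
        c = counts[ctx]
        total += math.log(c[seq[i + k]] / sum(c.values()))
    return total


def random_seq(rng, n):
    return list(np.where(rng.integers(0, 2, n) == 0, "H", "T"))


class TestFit:
    def test_context_counts_example(self):
        # H-H occurs 4x, followed 3x by T and once by H -> P(T|HH)=0.75
        seq = list("HHTHHTHHTHHH")
        m = TransitionModel.fit(seq, 2)
        assert m.count(("H", "H"), "T") == 3
        assert m.count(("H", "H"), "H") == 1
        assert m.probability(("H", "H"), "T") == pytest.approx(0.75)
        assert m.probability(("H", "H"), "H") == pytest.approx(0.25)

    def test_alternation_deterministic_at_k1(self):
        m = TransitionModel.fit(list("HTHTHTHT"), 1)
        assert m.probability(("H",), "T") == 1.0
        assert m.probability(("T",), "H") == 1.0
        assert m.total_transitions == 7  # the 7 length-2 subsequences

    def test_constant_sequence_k0(self):
        m = TransitionModel.fit(["H"] * 10, 0)
        assert m.probability((), "H") == 1.0
        assert m.probability((), "T") == 0.0

    def test_counts_match_naive_oracle(self):
        rng = np.random.default_rng(3)
        for k in (0, 1, 2, 3):
            seq = random_seq(rng, 60)
            oracle = naive_counts(seq, k)
            m = TransitionModel.fit(seq, k)
            for ctx, c in oracle.items():
                for sym in "HT":
                    assert m.count(ctx, sym) == c[sym]
            assert m.total_transitions == len(seq) - k

    def test_normalization(self):
        rng = np.random.default_rng(4)
        seq = random_seq(rng, 200)
        for k in range(5):
            m = TransitionModel.fit(seq, k)
            probs = m.probability_table
            observed = m.context_totals > 0
            assert np.allclose(probs[observed].sum(axis=1), 1.0, atol=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            TransitionModel.fit(list("HT"), 2)


class TestLogLikelihood:
    def test_deterministic_alternation_is_zero(self):
        m = TransitionModel.fit(list("HT" * 20), 1)
        assert log_likelihood(m) == 0.0

    def test_fair_coin_closed_form(self):
        m = TransitionModel.fair_coin(0)
        seq = list("HTTHHTHT")
        assert log_likelihood(m, seq) == pytest.approx(8 * math.log(0.5))

    def test_self_fit_matches_brute_force(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            seq = random_seq(rng, 30)
            for k in (0, 1, 2):
                m = TransitionModel.fit(seq, k)
                assert log_likelihood(m) == pytest.approx(
                    naive_log_likelihood(seq, k), abs=1e-10
                )
                # scoring the training sequence position-by-position agrees too
                assert log_likelihood(m, seq) == pytest.approx(
                    naive_log_likelihood(seq, k), abs=1e-10
                )

    def test_zero_probability_foreign_sequence(self):
        m = TransitionModel.fit(list("HHHHHH"), 0)
        with pytest.warns(UserWarning, match="zero probability"):
            assert log_likelihood(m, list("HHT")) == float("-inf")


class TestSelectOrder:
    def test_constant_sequence_selects_zero(self):
        sel = select_order(["H"] * 200, k_max=5)
        assert sel.selected_order == 0
        assert all(ll == 0.0 for ll in sel.log_likelihoods)

    def test_alternation_selects_one(self):
        sel = select_order(list("HT" * 100), k_max=5)
        assert sel.selected_order == 1
        # frozen hand computation: BIC(0) = 2*200*ln2 + ln200, BIC(1) = 2*ln199
        assert sel.bic_values[0] == pytest.approx(2 * 200 * math.log(2) + math.log(200))
        assert sel.bic_values[1] == pytest.approx(2 * math.log(199))

    def test_n_params_doubles(self):
        sel = select_order(random_seq(np.random.default_rng(0), 100), k_max=4)
        assert sel.n_params == [1, 2, 4, 8, 16]

    def test_k_max_too_large_rejected(self):
        with pytest.raises(ValueError):
            select_order(list("HTHT"), k_max=4)

    def test_common_set_monotone_vs_refit_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            seq = random_seq(rng, 30)
            k_max = 3
            sel = select_order(seq, k_max=k_max, common_prediction_set=True)
            # brute-force refit restricted to positions k_max..n-1
            def restricted_ll(k):
                counts = defaultdict(Counter)
                for i in range(k_max - k, len(seq) - k):
                    counts[tuple(seq[i : i + k])][seq[i + k]] += 1
                tot = 0.0
                for i in range(k_max - k, len(seq) - k):
                    ctx = tuple(seq[i : i + k])
                    tot += math.log(counts[ctx][seq[i + k]] / sum(counts[ctx].values()))
                return tot

            for k in range(k_max + 1):
                assert sel.log_likelihoods[k] == pytest.approx(restricted_ll(k), abs=1e-10)
            assert all(
                a <= b + 1e-10
                for a, b in zip(sel.log_likelihoods, sel.log_likelihoods[1:])
            )


class TestConditionalEntropyRate:
    def test_fair_coin_is_one_bit(self):
        for k in (0, 1, 3):
            assert conditional_entropy_rate(TransitionModel.fair_coin(k)) == 1.0

    def test_deterministic_is_zero_bits(self):
        probs = np.array([[1.0, 0.0], [0.0, 1.0]])
        m = TransitionModel.from_probabilities(probs)
        assert conditional_entropy_rate(m) == 0.0

    def test_single_context_closed_form(self):
        m = TransitionModel.from_probabilities(np.array([[0.75, 0.25]]))
        assert conditional_entropy_rate(m) == pytest.approx(0.811278, abs=1e-6)

    def test_bounds_and_zero_iff_deterministic(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            seq = random_seq(rng, 100)
            m = TransitionModel.fit(seq, 3)
            h = conditional_entropy_rate(m)
            assert 0.0 <= h <= 1.0
            probs = m.probability_table[m.context_totals > 0]
            deterministic = np.all((probs == 0) | (probs == 1))
            assert (h == 0.0) == bool(deterministic)

    def test_empty_model_rejected(self):
        m = TransitionModel(order_k=1, count_table=np.zeros((2, 2)))
        with pytest.raises(ValueError):
            conditional_entropy_rate(m)


class TestScoreParticipant:
    def test_constant_blocks(self):
        rec = ParticipantRecord("c", "FC", make_blocks(["H" * 50] * 5))
        scores = score_participant(rec)
        assert scores.mean_entropy_bits == 0.0
        assert scores.mean_optimal_order == 0.0

    def test_fair_blocks_entropy_range(self, fair_participant):
        # plug-in bias at 8 contexts x ~25 transitions is small and downward
        scores = score_participant(fair_participant)
        assert 0.90 <= scores.mean_entropy_bits < 1.00

    def test_short_block_becomes_missing(self):
        blocks = make_blocks(["HTHTHTHTHT"] * 4 + ["HT"])
        rec = ParticipantRecord("s", "ER", blocks)
        with pytest.warns(UserWarning, match="missing"):
            scores = score_participant(rec, fixed_k=3, k_max=3)
        assert np.isnan(scores.per_block_entropy_bits[4])
        assert not np.isnan(scores.mean_entropy_bits)

    def test_means_are_block_means(self, fair_participant):
        scores = score_participant(fair_participant)
        assert scores.mean_entropy_bits == pytest.approx(
            np.mean(scores.per_block_entropy_bits)
        )
        assert scores.mean_optimal_order == pytest.approx(
            np.mean(scores.per_block_optimal_order)
        )


class TestFixedKSafety:
    def test_overfit_order_keeps_entropy(self):
        # data of true order 1: the k=3 estimate converges to the k=1 limit,
        # because conditioning on extra irrelevant history loses no entropy
        from rsgkit.simulate import GeneratorSpec, gen_sequence, repeat_transition_table

        spec = GeneratorSpec(
            kind="markov",
            order_k=1,
            transition_table=repeat_transition_table(0.75),
            n_blocks=1,
            block_length=100_000,
            fail_rate=0.0,
            seed=123,
        )
        seq = gen_sequence(spec)[0].symbols
        h1 = conditional_entropy_rate(TransitionModel.fit(seq, 1))
        h3 = conditional_entropy_rate(TransitionModel.fit(seq, 3))
        assert abs(h3 - h1) < 0.01
        assert h1 == pytest.approx(0.811278, abs=0.01)
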