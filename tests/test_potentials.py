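import math

import numpy as np
import pytest

from mirhairpin import (
    PotentialSet,
    Sequence,
    TrainingError,
    fold,
    score_distance_dependent,
    score_distance_specific,
    score_position_specific,
    train_potentials,
)
from mirhairpin.potentials import PotentialTable, encode_words

from .conftest import random_rna
from .oracles import boltzmann_table, count_word_pairs


def seqs(*strings):
    return [Sequence(f"s{i}", s) for i, s in enumerate(strings)]


def constant_table(scheme, k, n_bins, c):
    return PotentialTable(scheme=scheme, k=k, n_bins=n_bins,
                          entries=np.full((4 ** k, 4 ** k, n_bins), float(c)),
                          epsilon=1.0, provenance="test")


class TestEncodeWords:
    def test_known_codes(self):
        np.testing.assert_array_equal(encode_words("ACGU", 1), [0, 1, 2, 3])
        np.testing.assert_array_equal(encode_words("ACGU", 2), [1, 6, 11])

    def test_too_short_gives_empty(self):
        assert len(encode_words("AC", 3)) == 0


class TestTrainPotentials:
    def test_identical_sets_give_all_zero(self):
        both = seqs("ACGUACGUACGU", "GGGCCCAAAUUU")
        t = train_potentials(both, both, "distance_specific", k=2, n_bins=1)
        np.testing.assert_allclose(t.entries, 0.0)

    def test_word_pair_absent_from_both_sets_is_zero(self):
        pos = seqs("AAAAAA")
        neg = seqs("CCCCCC")
        t = train_potentials(pos, neg, "distance_specific", k=1, n_bins=1)
        # (G, G) never occurs on either side: eps/eps -> 0
        assert t.entries[2, 2, 0] == 0.0
        # (A, A) occurs only in positives -> favourable (negative energy)
        assert t.entries[0, 0, 0] < 0.0

    def test_matches_hand_counted_boltzmann_inversion(self):
        pos = seqs("ACGUACGUACGU", "GGCAAUUGGCAA")
        neg = seqs("AAAACCCCGGGG", "UUUUGGGGCCCC")
        eps = 1e-3
        t = train_potentials(pos, neg, "distance_specific", k=1, n_bins=1,
                             epsilon=eps)
        pc, nc = {}, {}
        for s in pos:
            for key, v in count_word_pairs(s.residues, 1, 1, False).items():
                pc[key] = pc.get(key, 0) + v
        for s in neg:
            for key, v in count_word_pairs(s.residues, 1, 1, False).items():
                nc[key] = nc.get(key, 0) + v
        oracle = boltzmann_table(pc, nc, eps)
        code = {"A": 0, "C": 1, "G": 2, "U": 3}
        for (wa, wb, b), expected in oracle.items():
            assert t.entries[code[wa], code[wb], b] == pytest.approx(expected)

    def test_empty_class_raises(self):
        with pytest.raises(TrainingError):
            train_potentials([], seqs("ACGU"), "distance_specific", 1, 1)

    def test_k_longer_than_shortest_sequence_raises(self):
        with pytest.raises(TrainingError):
            train_potentials(seqs("ACG"), seqs("ACGUACGU"),
                             "distance_specific", k=4, n_bins=1)

    def test_antisymmetry_under_class_swap(self):
        pos = seqs("ACGUACGUGGCC", "GGGAAACCCAAA")
        neg = seqs("AAAAUUUUGGGG", "CACACACACACA")
        fwd = train_potentials(pos, neg, "distance_dependent", k=1, n_bins=20)
        rev = train_potentials(neg, pos, "distance_dependent", k=1, n_bins=20)
        np.testing.assert_allclose(fwd.entries, -rev.entries, atol=1e-12)

    def test_duplicating_training_sequences_changes_nothing(self):
        pos = seqs("ACGUACGUGGCC")
        neg = seqs("AAAAUUUUGGGG")
        a = train_potentials(pos, neg, "distance_specific", k=2, n_bins=1)
        b = train_potentials(pos * 3, neg * 3, "distance_specific", k=2, n_bins=1)
        np.testing.assert_allclose(a.entries, b.entries)


class TestScoreDistanceSpecific:
    def test_all_zero_table_scores_zero(self):
        t = constant_table("distance_specific", 1, 1, 0.0)
        assert score_distance_specific(Sequence("a", "ACGUAC"), t) == 0.0

    def test_constant_table_scores_constant(self):
        t = constant_table("distance_specific", 2, 1, 1.75)
        assert score_distance_specific(Sequence("a", "ACGUACGU"), t) == pytest.approx(1.75)

    def test_mean_over_all_15_pairs_matches_double_loop(self, rng):
        t = PotentialTable(
            scheme="distance_specific", k=1, n_bins=1,
            entries=rng.normal(size=(4, 4, 1)), epsilon=1.0, provenance="t",
        )
        s = "GCAUGC"
        code = {"A": 0, "C": 1, "G": 2, "U": 3}
        acc = [t.entries[code[s[i]], code[s[j]], 0]
               for i in range(6) for j in range(i + 1, 6)]
        assert len(acc) == 15
        assert score_distance_specific(Sequence("a", s), t) == pytest.approx(
            float(np.mean(acc)))


class TestScorePositionSpecific:
    def test_zero_pairs_gives_all_zero(self, trained_tables):
        seq = Sequence("a", "A" * 20)
        ss = fold(seq, engine="fallback")
        out = score_position_specific(seq, ss, trained_tables.position_specific)
        np.testing.assert_allclose(out, 0.0)

    def test_all_zero_table_gives_all_zero(self):
        t = constant_table("position_specific", 2, 34, 0.0)
        seq = Sequence("a", "GGGGGAAAAACCCCC")
        ss = fold(seq, engine="fallback")
        np.testing.assert_allclose(score_position_specific(seq, ss, t), 0.0)

    def test_per_bin_means_match_brute_tally(self, rng):
        t = PotentialTable(
            scheme="position_specific", k=2, n_bins=34,
            entries=rng.normal(size=(16, 16, 34)), epsilon=1.0, provenance="t",
        )
        seq = Sequence("a", "GGGGGGAAAAAACCCCCC")
        ss = fold(seq, engine="fallback")
        L = len(seq)
        sums = np.zeros(34)
        counts = np.zeros(34)
        code = {"A": 0, "C": 1, "G": 2, "U": 3}

        def enc2(w):
            return code[w[0]] * 4 + code[w[1]]

        for i, j in ss.pairs:
            if i + 1 > L or j - 1 < 1:
                continue
            b = min(34 * i // L, 33)
            wa = enc2(seq.residues[i - 1 : i + 1])
            wb = enc2(seq.residues[j - 2 : j])
            sums[b] += t.entries[wa, wb, b]
            counts[b] += 1
        expected = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
        np.testing.assert_allclose(
            score_position_specific(seq, ss, t), expected, atol=1e-12)


class TestScoreDistanceDependent:
    def _tables(self, c):
        return {k: constant_table("distance_dependent", k, 20, c)
                for k in (1, 2, 3)}

    def test_all_zero_tables(self):
        out = score_distance_dependent(Sequence("a", "ACGU" * 10), self._tables(0.0))
        assert out.shape == (26,)
        np.testing.assert_allclose(out, 0.0)

    def test_constant_tables(self):
        # 40 nt: every one of the 20 relative-distance bins is occupied
        out = score_distance_dependent(Sequence("a", "ACGU" * 10), self._tables(2.5))
        np.testing.assert_allclose(out[:20], 2.5)   # pooled bin scores
        np.testing.assert_allclose(out[20:23], 2.5)  # per-k means
        np.testing.assert_allclose(out[23:], 0.0)    # per-k std devs

    def test_matches_exhaustive_pooled_tally(self, rng):
        tables = {
            k: PotentialTable(
                scheme="distance_dependent", k=k, n_bins=20,
                entries=rng.normal(size=(4 ** k, 4 ** k, 20)),
                epsilon=1.0, provenance="t")
            for k in (1, 2, 3)
        }
        s = random_rna(rng, 30)
        L = len(s)
        code = {"A": 0, "C": 1, "G": 2, "U": 3}

        def enc(w):
            v = 0
            for ch in w:
                v = v * 4 + code[ch]
            return v

        pooled = {b: [] for b in range(20)}
        per_k = {}
        for k in (1, 2, 3):
            words = [s[i : i + k] for i in range(L - k + 1)]
            vals = []
            binned = {b: [] for b in range(20)}
            for a in range(len(words)):
                for b2 in range(a + 1, len(words)):
                    bin_ = min(20 * (b2 - a) // L, 19)
                    e = tables[k].entries[enc(words[a]), enc(words[b2]), bin_]
                    vals.append(e)
                    binned[bin_].append(e)
                    pooled[bin_].append(e)
            bin_means = [np.mean(binned[b]) for b in range(20) if binned[b]]
            per_k[k] = (np.mean(vals), np.std(bin_means))
        expected = np.concatenate([
            [np.mean(pooled[b]) if pooled[b] else 0.0 for b in range(20)],
            [per_k[k][0] for k in (1, 2, 3)],
            [per_k[k][1] for k in (1, 2, 3)],
        ])
        got = score_distance_dependent(Sequence("a", s), tables)
        np.testing.assert_allclose(got, expected, atol=1e-10)


class TestSeparationProperty:
    def test_planted_enrichment_scores_positives_lower(self, rng):
        # positives are G-rich, negatives A-rich: the (G,G) pair entry must be
        # favourable and the positive-class mean score lower
        pos = [Sequence(f"p{i}", "".join(
            rng.choice(list("ACGU"), p=[0.1, 0.1, 0.7, 0.1], size=30)))
            for i in range(30)]
        neg = [Sequence(f"n{i}", "".join(
            rng.choice(list("ACGU"), p=[0.7, 0.1, 0.1, 0.1], size=30)))
            for i in range(30)]
        t = train_potentials(pos, neg, "distance_specific", k=1, n_bins=1)
        assert t.entries[2, 2, 0] < 0.0
        pos_mean = np.mean([score_distance_specific(s, t) for s in pos])
        neg_mean = np.mean([score_distance_specific(s, t) for s in neg])
        assert pos_mean < neg_mean


class TestPotentialSet:
    def test_train_covers_all_schemes(self, trained_tables):
        assert trained_tables.position_specific.scheme == "position_specific"
        assert sorted(trained_tables.distance_specific) == [1, 2, 3, 4, 5]
        assert sorted(trained_tables.distance_dependent) == [1, 2, 3]
        for k, t in trained_tables.distance_dependent.items():
            assert t.n_bins == 20 and t.k == k
        assert np.all(np.isfinite(trained_tables.position_specific.entries))

    def test_position_specific_requires_structure(self):
        with pytest.raises(TrainingError):
            train_potentials(seqs("ACGUACGUACGU"), seqs("GGGCCCAAAUUU"),
                             "position_specific", k=2, n_bins=34)
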