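from collections import Counter

import numpy as np
import pytest

from transfacpred.features import (
    AAC_NAMES,
    DPC_NAMES,
    aac,
    class_composition,
    combine_aac_dpc,
    dpc,
    feature_matrix,
    one_hot,
)
from transfacpred.seqio import NATURAL_AA, TF, NON_TF, LabeledDataset, SequenceRecord
from transfacpred.simulate import GeneratorConfig, generate_dataset
from tests.conftest import random_sequence


def naive_aac(seq: str) -> np.ndarray:
    """Dictionary-counting oracle for the composition vector."""
    counts = Counter(seq)
    return np.array([counts.get(a, 0) / len(seq) for a in NATURAL_AA])


def naive_dpc(seq: str, j: int = 1) -> np.ndarray:
    """Dictionary-counting oracle for the dipeptide vector."""
    counts = Counter(seq[p] + seq[p + j] for p in range(len(seq) - j))
    pairs = [a + b for a in NATURAL_AA for b in NATURAL_AA]
    return np.array([counts.get(p, 0) / (len(seq) - j) for p in pairs])


class TestAAC:
    def test_homopolymer(self):
        v = aac(SequenceRecord("P", "AAAA"))
        assert v[0] == 1.0 and v[1:].sum() == 0.0

    def test_all_twenty_residues_once(self):
        v = aac(SequenceRecord("P", NATURAL_AA))
        assert np.allclose(v, 0.05)

    def test_length_and_scale(self, toy_records):
        for rec in toy_records:
            frac = aac(rec)
            assert frac.shape == (20,)
            assert np.allclose(aac(rec, scale="percent"), 100 * frac)

    def test_nonnatural_residue_rejected(self):
        with pytest.raises(ValueError, match="filter_nonnatural"):
            aac(SequenceRecord("P", "ACDX"))

    def test_permutation_invariance(self, rng):
        seq = random_sequence(rng, 80)
        shuffled = "".join(rng.permutation(list(seq)))
        assert np.array_equal(aac(SequenceRecord("A", seq)), aac(SequenceRecord("B", shuffled)))


class TestDPC:
    def test_two_residue_sequence(self):
        v = dpc(SequenceRecord("P", "AA"))
        assert v[0] == 1.0 and v.sum() == 1.0

    def test_adjacent_pair_counts(self):
        # ACAC: pairs AC, CA, AC over L-1 = 3
        v = dpc(SequenceRecord("P", "ACAC"))
        names = dict(zip(DPC_NAMES, v))
        assert names["AC"] == pytest.approx(2 / 3)
        assert names["CA"] == pytest.approx(1 / 3)

    def test_length_400(self, toy_records):
        assert dpc(toy_records[0]).shape == (400,)

    def test_gap_parameter(self):
        # ACDE at j=2: pairs AD, CE over L-2 = 2
        v = dict(zip(DPC_NAMES, dpc(SequenceRecord("P", "ACDE"), order_j=2)))
        assert v["AD"] == 0.5 and v["CE"] == 0.5

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            dpc(SequenceRecord("P", "A"), order_j=1)

    def test_not_permutation_invariant(self):
        a = dpc(SequenceRecord("A", "AACC"))
        b = dpc(SequenceRecord("B", "ACAC"))
        assert not np.array_equal(a, b)


class TestOracleEquivalence:
    def test_aac_and_dpc_match_naive_counting_on_random_sequences(self, rng):
        for _ in range(100):
            seq = random_sequence(rng, int(rng.integers(2, 51)))
            rec = SequenceRecord("Q", seq)
            assert np.array_equal(aac(rec), naive_aac(seq))
            assert np.array_equal(dpc(rec), naive_dpc(seq))

    def test_normalization(self, rng):
        for _ in range(20):
            rec = SequenceRecord("Q", random_sequence(rng, int(rng.integers(5, 200))))
            assert abs(aac(rec).sum() - 1.0) < 1e-9
            assert abs(dpc(rec).sum() - 1.0) < 1e-9


class TestCombine:
    def test_length_420_aac_first(self):
        rec = SequenceRecord("P", "ACDEFG")
        v = combine_aac_dpc(aac(rec), dpc(rec))
        assert v.shape == (420,)
        assert np.array_equal(v[:20], aac(rec))
        assert np.array_equal(v[20:], dpc(rec))

    def test_zero_dpc_block_leaves_aac_unchanged(self):
        a = aac(SequenceRecord("P", "ACD"))
        v = combine_aac_dpc(a, np.zeros(400))
        assert np.array_equal(v[:20], a) and v[20:].sum() == 0

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            combine_aac_dpc(np.zeros(21), np.zeros(400))


class TestOneHot:
    def test_alanine_row(self):
        m = one_hot(SequenceRecord("P", "A"), max_len=1)
        assert m.shape == (1, 21)
        assert m[0, 0] == 1 and m.sum() == 1

    def test_unknown_symbol_is_all_zero(self):
        m = one_hot(SequenceRecord("P", "X"), max_len=1)
        assert m.sum() == 0

    def test_padding_and_truncation(self):
        m = one_hot(SequenceRecord("P", "AC"), max_len=4)
        assert m[2:].sum() == 0
        t = one_hot(SequenceRecord("P", "ACDEFG"), max_len=3)
        assert t.shape == (3, 21) and t.sum() == 3

    def test_row_sums_and_total_ones(self, rng):
        seq = random_sequence(rng, 50) + "XB"
        m = one_hot(SequenceRecord("P", seq), max_len=60)
        assert set(m.sum(axis=1)) <= {0, 1}
        assert m.sum() == 50

    def test_dummy_slot_never_set(self, rng):
        m = one_hot(SequenceRecord("P", random_sequence(rng, 100) + "XZU"), max_len=200)
        assert m[:, 20].sum() == 0


class TestFeatureMatrix:
    def test_shapes_and_names(self, toy_records):
        X = feature_matrix(toy_records, kind="aac_dpc")
        assert X.shape == (3, 420)
        assert list(X.columns[:20]) == list(AAC_NAMES)
        assert list(X.index) == [r.id for r in toy_records]


class TestClassComposition:
    def test_single_sequence_class(self):
        ds = LabeledDataset(
            [SequenceRecord("a", "AA"), SequenceRecord("b", "CC")], [TF, NON_TF]
        )
        cc = class_composition(ds)
        assert cc.loc[TF, "A"] == 100.0 and cc.loc[NON_TF, "C"] == 100.0

    def test_unweighted_mean_over_sequences(self):
        ds = LabeledDataset(
            [SequenceRecord("a", "AA"), SequenceRecord("b", "CC"),
             SequenceRecord("n", "DD")],
            [TF, TF, NON_TF],
        )
        cc = class_composition(ds)
        assert cc.loc[TF, "A"] == 50.0 and cc.loc[TF, "C"] == 50.0

    def test_biased_generator_classes_separate(self):
        ds = generate_dataset(
            GeneratorConfig(n_pos=500, n_neg=500, family_size=1, seed=11)
        )
        cc = class_composition(ds)
        for res in "EPQRS":
            assert cc.loc[TF, res] > cc.loc[NON_TF, res]
        for res in "AGIV":
            assert cc.loc[NON_TF, res] > cc.loc[TF, res]
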