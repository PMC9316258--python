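import numpy as np
import pytest

import sagpred as sp
from sagpred.encodings import ACC, KMER, PC_PSEAAC, EncodingError

from oracles import (
    acc_oracle,
    kmer_oracle,
    load_raw_property_values,
    pseaac_oracle,
    random_protein,
)


class TestPropertyTable:
    def test_default_scales_are_standardized(self):
        table = sp.default_property_table()
        assert table.names == ["hydrophobicity", "hydrophilicity", "side_chain_mass"]
        assert np.allclose(table.matrix.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(table.matrix.std(axis=1, ddof=0), 1.0, atol=1e-12)

    def test_constant_scale_rejected(self):
        values = {"flat": {aa: 1.0 for aa in sp.ALPHABET}}
        with pytest.raises(ValueError, match="constant"):
            sp.PropertyTable(["flat"], values)


class TestKmer:
    def test_homopolymer_concentrates_on_one_component(self):
        v = sp.encode_kmer("AAA", k=2)
        assert v.shape == (400,)
        assert v[0] == 1.0 and v.sum() == 1.0  # "AA" is the first label

    def test_two_window_sequence(self):
        v = sp.encode_kmer("ACA", k=2)
        labels = sp.feature_labels(sp.EncodingSpec(encoders=(KMER,)))
        assert v[labels.index("kmer:AC")] == 0.5
        assert v[labels.index("kmer:CA")] == 0.5

    def test_matches_naive_counting_oracle(self, rng):
        seq = random_protein(rng, 200)
        assert np.abs(sp.encode_kmer(seq, 2) - kmer_oracle(seq, 2)).max() < 1e-10

    def test_too_short_sequence_identifies_record(self):
        with pytest.raises(EncodingError, match="myrec"):
            sp.encode_kmer("A", k=2, record_id="myrec")


class TestPcPseAAC:
    def test_homopolymer_has_zero_order_factors(self):
        v = sp.encode_pc_pseaac("A" * 30)
        assert v.shape == (22,)
        assert v[0] == 1.0
        assert np.all(v[1:] == 0.0)

    def test_matches_formula_oracle(self):
        v = sp.encode_pc_pseaac("ACDEFGHIKL")
        assert np.abs(v - pseaac_oracle("ACDEFGHIKL", lam=2, w=0.05)).max() < 1e-10

    def test_matches_formula_oracle_on_random_sequences(self, rng):
        for _ in range(5):
            seq = random_protein(rng, int(rng.integers(20, 120)))
            got = sp.encode_pc_pseaac(seq)
            assert np.abs(got - pseaac_oracle(seq, 2, 0.05)).max() < 1e-10

    def test_sums_to_one_and_nonnegative(self, rng):
        for _ in range(5):
            v = sp.encode_pc_pseaac(random_protein(rng, 60))
            assert v.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(v >= 0)

    def test_tiny_weight_reduces_to_composition(self, rng):
        seq = random_protein(rng, 80)
        v = sp.encode_pc_pseaac(seq, lam=2, w=1e-12)
        comp = np.array([seq.count(aa) / len(seq) for aa in sp.ALPHABET])
        assert np.allclose(v[:20], comp, atol=1e-9)
        assert np.allclose(v[20:], 0.0, atol=1e-9)

    def test_length_precondition(self):
        with pytest.raises(EncodingError, match="lambda"):
            sp.encode_pc_pseaac("AC", lam=2)


class TestACC:
    def test_homopolymer_gives_all_zero_covariances(self):
        v = sp.encode_acc("W" * 40)
        assert v.shape == (27,)
        assert np.allclose(v, 0.0, atol=1e-15)  # constant tracks: only fp residue

    def test_matches_double_loop_oracle(self, rng):
        seq = random_protein(rng, 100)
        assert np.abs(sp.encode_acc(seq) - acc_oracle(seq, lag=3)).max() < 1e-10

    def test_invariant_to_constant_property_shift(self, rng):
        # adding a constant to a raw track changes nothing after per-sequence
        # centering (tables built without standardization to isolate the effect)
        names, raw = load_raw_property_values()
        shifted = {n: {aa: v + 7.5 for aa, v in raw[n].items()} for n in names}
        t1 = sp.PropertyTable(names, raw, normalize=False)
        t2 = sp.PropertyTable(names, shifted, normalize=False)
        seq = random_protein(rng, 60)
        assert np.allclose(sp.encode_acc(seq, props=t1), sp.encode_acc(seq, props=t2))

    def test_length_precondition(self):
        with pytest.raises(EncodingError, match="LAG"):
            sp.encode_acc("ACD", lag=3)


class TestFusion:
    WIDTHS = {
        (KMER,): 400,
        (PC_PSEAAC,): 22,
        (ACC,): 27,
        (KMER, PC_PSEAAC): 422,
        (KMER, ACC): 427,
        (ACC, PC_PSEAAC): 49,
        (ACC, KMER, PC_PSEAAC): 449,
    }

    @pytest.mark.parametrize("encoders,width", sorted(WIDTHS.items()))
    def test_dimensionality_of_every_combination(self, encoders, width, rng):
        spec = sp.EncodingSpec(encoders=encoders)
        assert sp.dimensionality(spec) == width
        records = [
            sp.ProteinRecord(f"r{i}", "", random_protein(rng, 60)) for i in range(3)
        ]
        feats = sp.encode_matrix(records, spec)
        assert feats.shape == (3, width)
        assert len(feats.col_names) == width

    def test_fusion_is_concatenation_in_spec_order(self, rng):
        seq = random_protein(rng, 70)
        fused = sp.encode_sequence(seq, sp.EncodingSpec(encoders=(ACC, KMER)))
        assert np.array_equal(fused[:27], sp.encode_acc(seq))
        assert np.array_equal(fused[27:], sp.encode_kmer(seq))

    def test_batch_error_lists_offending_ids(self):
        records = [
            sp.ProteinRecord("ok", "", "ACDEFGHIKL" * 4),
            sp.ProteinRecord("bad", "", "AC"),
        ]
        with pytest.raises(EncodingError, match="bad"):
            sp.encode_matrix(records, sp.EncodingSpec())

    def test_encoders_are_pure_functions(self, rng):
        seq = random_protein(rng, 90)
        spec = sp.EncodingSpec(encoders=(KMER, PC_PSEAAC, ACC))
        a = sp.encode_sequence(seq, spec)
        b = sp.encode_sequence(seq, spec)
        assert a.tobytes() == b.tobytes()

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            sp.EncodingSpec(encoders=())
        with pytest.raises(ValueError):
            sp.EncodingSpec(w=1.5)
        with pytest.raises(ValueError):
            sp.EncodingSpec(encoders=("kmer", "dna"))
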