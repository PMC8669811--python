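import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.base import clone
from sklearn.pipeline import FeatureUnion

from aipkit.encoders import (
    DEFAULT_CODON_TABLE,
    DIPEPTIDES,
    AACEncoder,
    CodonTable,
    DDEEncoder,
    FeatureMatrix,
    GGapDipeptideEncoder,
    combine,
    encode_aac,
    encode_dde,
    encode_features,
    encode_gdc,
)
from aipkit.peptide_io import ALPHABET, PeptideRecord, PeptideSet

SEQ = st.text(alphabet=ALPHABET, min_size=5, max_size=12)


def _set(*seqs: str) -> PeptideSet:
    return PeptideSet([PeptideRecord(f"P{i}", s) for i, s in enumerate(seqs)])


# ---------------------------------------------------------------- oracles

def brute_gap_pairs(seq: str, g: int) -> dict[str, int]:
    """Enumerate (i, i+g) residue pairs by hand."""
    counts: dict[str, int] = {}
    for i in range(len(seq) - g):
        pair = seq[i] + seq[i + g]
        counts[pair] = counts.get(pair, 0) + 1
    return counts


def brute_dde(seq: str, table: CodonTable) -> np.ndarray:
    """Independent loop-and-dict evaluation of DC, TM, TV, DDE."""
    L = len(seq)
    out = np.empty(400)
    for v, dip in enumerate(DIPEPTIDES):
        n_j = sum(
            1 for i in range(L - 1) if seq[i] + seq[i + 1] == dip
        )
        dc = n_j / (L - 1)
        tm = (table.codon_counts[dip[0]] / table.cn) * (
            table.codon_counts[dip[1]] / table.cn
        )
        tv = tm * (1 - tm) / (L - 1)
        out[v] = (dc - tm) / math.sqrt(tv)
    return out


# -------------------------------------------------------------------- AAC

class TestAAC:
    def test_simple_composition(self):
        fm = encode_aac(_set("AAAAC"))
        assert fm.values[0, 0] == pytest.approx(0.8)
        assert fm.values[0, 1] == pytest.approx(0.2)
        assert np.count_nonzero(fm.values[0]) == 2

    def test_full_alphabet_uniform(self):
        fm = encode_aac(_set(ALPHABET))
        assert np.allclose(fm.values[0], 0.05)

    def test_single_residue_type(self):
        fm = encode_aac(_set("GGGGG"))
        g_col = fm.feature_names.index("AAC:G")
        assert fm.values[0, g_col] == 1.0

    def test_dimension_and_names(self):
        fm = encode_aac(_set("ACDEF"))
        assert fm.n_features == 20
        assert fm.feature_names == [f"AAC:{a}" for a in ALPHABET]

    def test_empty_set_errors(self):
        with pytest.raises(ValueError, match="empty"):
            encode_aac(PeptideSet([]))

    @given(seq=SEQ)
    def test_rows_are_distributions(self, seq):
        row = AACEncoder().fit_transform([seq])[0]
        assert (row >= 0).all()
        assert row.sum() == pytest.approx(1.0, abs=1e-12)


# -------------------------------------------------------------------- GDC

class TestGDC:
    def test_gap1_hand_enumeration(self):
        fm = encode_gdc(_set("AAC"), g=1)
        assert fm.values[0, fm.feature_names.index("GDC1:AA")] == 0.5
        assert fm.values[0, fm.feature_names.index("GDC1:AC")] == 0.5
        assert fm.values[0].sum() == 1.0

    def test_gap2_hand_enumeration(self):
        fm = encode_gdc(_set("ACDE"), g=2)
        assert fm.values[0, fm.feature_names.index("GDC2:AD")] == 0.5
        assert fm.values[0, fm.feature_names.index("GDC2:CE")] == 0.5

    def test_gap4_minimum_length_sequence(self):
        # L=5 with g=4 leaves exactly one pair: the termini
        fm = encode_gdc(_set("ACDEF"), g=4)
        assert fm.values[0, fm.feature_names.index("GDC4:AF")] == 1.0
        assert np.count_nonzero(fm.values[0]) == 1

    def test_too_short_sequence_names_record(self):
        with pytest.raises(ValueError, match="P0"):
            encode_gdc(_set("ACDE"), g=4)

    def test_dimension(self):
        assert encode_gdc(_set("ACDEF"), g=1).n_features == 400

    @pytest.mark.parametrize("g", [1, 2, 3, 4])
    @given(seq=SEQ)
    def test_matches_brute_force_enumerator(self, g, seq):
        enc = GGapDipeptideEncoder(g=g)
        row = enc.fit_transform([seq])[0]
        expected = brute_gap_pairs(seq, g)
        total = len(seq) - g
        for v, dip in enumerate(DIPEPTIDES):
            assert row[v] == pytest.approx(
                expected.get(dip, 0) / total, abs=1e-12
            )

    @given(seq=SEQ, g=st.integers(1, 4))
    def test_rows_are_distributions(self, seq, g):
        row = GGapDipeptideEncoder(g=g).fit_transform([seq])[0]
        assert (row >= 0).all()
        assert row.sum() == pytest.approx(1.0, abs=1e-12)

    def test_invalid_g(self):
        with pytest.raises(ValueError, match="g must be"):
            GGapDipeptideEncoder(g=5).fit_transform(["ACDEFGH"])


# -------------------------------------------------------------------- DDE

class TestDDE:
    def test_codon_table_theoretical_mean(self):
        tm = DEFAULT_CODON_TABLE.theoretical_means()
        assert tm[0] == pytest.approx((4 / 61) * (4 / 61), abs=1e-15)
        assert DEFAULT_CODON_TABLE.cn == 61

    def test_homopolymer_closed_form(self):
        # DC(AA)=1, L=5: DDE(AA) = (1 - TM)/sqrt(TM(1-TM)/4)
        tm = (4 / 61) ** 2
        expected = (1 - tm) / math.sqrt(tm * (1 - tm) / 4)
        fm = encode_dde(_set("AAAAA"))
        assert fm.values[0, 0] == pytest.approx(expected, abs=1e-10)

    def test_absent_dipeptide_is_negative(self):
        fm = encode_dde(_set("AAAAA"))
        # every dipeptide other than AA has DC=0, hence DDE < 0
        assert (np.delete(fm.values[0], 0) < 0).all()

    def test_dc_normalisation_via_reconstruction(self):
        # invert the standardisation and check DC sums to 1
        seq = "ACDEFGAC"
        fm = encode_dde(_set(seq))
        tm = DEFAULT_CODON_TABLE.theoretical_means()
        tv = tm * (1 - tm) / (len(seq) - 1)
        dc = fm.values[0] * np.sqrt(tv) + tm
        assert dc.sum() == pytest.approx(1.0, abs=1e-10)

    def test_depends_only_on_dipeptide_counts_and_length(self):
        # ACAGA and AGACA share the adjacent-pair multiset {AC,CA,AG,GA}
        fm = encode_dde(_set("ACAGA", "AGACA"))
        assert np.array_equal(fm.values[0], fm.values[1])

    @given(seq=SEQ)
    def test_matches_brute_force(self, seq):
        row = DDEEncoder().fit_transform([seq])[0]
        assert np.allclose(row, brute_dde(seq, DEFAULT_CODON_TABLE),
                           atol=1e-10, rtol=0)

    def test_length_one_errors(self):
        with pytest.raises(ValueError, match="length"):
            DDEEncoder().fit_transform(["A"])

    def test_custom_codon_table_changes_expectation(self):
        uniform = CodonTable({aa: 3 for aa in ALPHABET})
        default = encode_dde(_set("ACDEF"))
        custom = encode_dde(_set("ACDEF"), codons=uniform)
        assert not np.allclose(default.values, custom.values)

    def test_codon_table_missing_residue(self):
        with pytest.raises(ValueError, match="missing"):
            CodonTable({"A": 4})


# ---------------------------------------------------------------- combine

class TestCombine:
    def test_aac_dde_gdc1_is_820_columns(self, tiny_set):
        fm = encode_features(tiny_set, ("aac", "dde", "gdc1"))
        assert fm.n_features == 20 + 400 + 400
        assert fm.feature_names[0] == "AAC:A"
        assert fm.feature_names[20] == "DDE:AA"
        assert fm.feature_names[420] == "GDC1:AA"
        assert fm.labels is not None

    def test_pairwise_combination_shape(self, tiny_set):
        fm = combine([encode_aac(tiny_set), encode_dde(tiny_set)])
        assert fm.values.shape == (4, 420)

    def test_single_block_identity(self, tiny_set):
        aac = encode_aac(tiny_set)
        fm = combine([aac])
        assert np.array_equal(fm.values, aac.values)
        assert fm.feature_names == aac.feature_names

    def test_sample_order_mismatch_errors(self, tiny_set):
        aac = encode_aac(tiny_set)
        shuffled = FeatureMatrix(
            aac.values[::-1], aac.feature_names, aac.sample_ids[::-1]
        )
        with pytest.raises(ValueError, match="sample"):
            combine([aac, shuffled])

    def test_unknown_encoder_name(self, tiny_set):
        with pytest.raises(ValueError, match="unknown encoder"):
            encode_features(tiny_set, ("aac", "ctriad"))


# ------------------------------------------------- container & estimators

class TestFeatureMatrix:
    def test_tsv_round_trip_lossless(self, tmp_path, tiny_set):
        fm = encode_features(tiny_set, ("aac", "dde"))
        path = fm.to_tsv(tmp_path / "features.tsv")
        back = FeatureMatrix.from_tsv(path)
        assert back.feature_names == fm.feature_names
        assert back.sample_ids == fm.sample_ids
        assert np.array_equal(back.values, fm.values)
        assert np.array_equal(back.labels, fm.labels)

    def test_select_by_name_preserves_order(self, tiny_set):
        fm = encode_aac(tiny_set)
        sub = fm.select(["AAC:C", "AAC:A"])
        assert sub.feature_names == ["AAC:C", "AAC:A"]
        assert np.array_equal(sub.values[:, 1], fm.values[:, 0])

    def test_duplicate_feature_names_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            FeatureMatrix(np.zeros((1, 2)), ["a", "a"], ["s"])


class TestSklearnInterop:
    def test_encoders_are_deterministic(self, tiny_set):
        enc = DDEEncoder()
        a = enc.fit_transform(tiny_set)
        b = enc.fit_transform(tiny_set)
        assert np.array_equal(a, b)

    def test_clone_and_get_params(self):
        enc = GGapDipeptideEncoder(g=3)
        assert clone(enc).get_params()["g"] == 3

    def test_feature_union_concatenates_channels(self, tiny_set):
        union = FeatureUnion(
            [("aac", AACEncoder()), ("gdc1", GGapDipeptideEncoder(g=1))]
        )
        X = union.fit_transform(tiny_set.sequences)
        assert X.shape == (4, 420)
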