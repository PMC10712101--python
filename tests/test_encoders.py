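import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kglupred import encoders
from kglupred.encoders import (
    FeatureBlock,
    PssmProfile,
    SecondaryStructureAnnotation,
    assemble,
    encode_be,
    encode_blosum62,
    encode_cksaap,
    encode_ctdc,
    encode_eaac,
    encode_pssm_window,
    encode_structure,
    minmax_apply,
    minmax_fit,
    parse_pssm,
    write_pssm,
)
from kglupred.residues import ALPHABET22, STANDARD20, ctd_groups

from conftest import random_window

window_strategy = st.text(alphabet=ALPHABET22, min_size=33, max_size=33)


@pytest.mark.parametrize(
    "encoder,width",
    [
        (encode_be, 726),
        (encode_eaac, 580),
        (encode_cksaap, 484),
        (encode_ctdc, 39),
        (encode_blosum62, 660),
    ],
)
def test_dimensional_contracts(rng, encoder, width):
    for _ in range(5):
        w = random_window(rng, alphabet=ALPHABET22)
        assert encoder(w).shape == (width,)


class TestBinaryEncoding:
    def test_exactly_one_hot_per_residue(self, windows33):
        for w in windows33:
            v = encode_be(w).reshape(33, 22)
            assert (v.sum(axis=1) == 1).all()
            assert set(np.unique(v)) <= {0.0, 1.0}

    def test_placeholder_column(self):
        v = encode_be("X" * 33).reshape(33, 22)
        assert (v[:, 21] == 1).all()
        assert v.sum() == 33

    def test_index_arithmetic(self):
        w = "AC" + "G" * 31
        v = encode_be(w)
        assert v[0] == 1  # A at block 0, offset 0
        assert v[22 + 1] == 1  # C at block 1, offset 1

    def test_invalid_character(self):
        with pytest.raises(ValueError):
            encode_be("B" * 33)


class TestEaac:
    def test_homopolymer(self):
        v = encode_eaac("A" * 33, win_size=5).reshape(29, 20)
        assert (v[:, 0] == 1.0).all()
        assert v.sum() == 29

    def test_hand_count_first_window(self):
        v = encode_eaac("ACDEF" + "X" * 28, win_size=5).reshape(29, 20)
        expected = np.zeros(20)
        for aa in "ACDEF":
            expected[STANDARD20.index(aa)] = 0.2
        np.testing.assert_allclose(v[0], expected)

    def test_u_and_x_excluded_from_numerators(self):
        assert encode_eaac("U" * 33).sum() == 0
        assert encode_eaac("X" * 33).sum() == 0

    def test_invalid_win_size(self):
        with pytest.raises(ValueError):
            encode_eaac("A" * 33, win_size=0)
        with pytest.raises(ValueError):
            encode_eaac("A" * 33, win_size=34)


def brute_force_cksaap(seq, k):
    """Exhaustive enumeration of k-spaced ordered pairs."""
    counts = {}
    for i in range(len(seq)):
        j = i + k + 1
        if j < len(seq):
            counts[(seq[i], seq[j])] = counts.get((seq[i], seq[j]), 0) + 1
    total = len(seq) - k - 1
    out = np.zeros(484)
    for (a, b), c in counts.items():
        out[ALPHABET22.index(a) * 22 + ALPHABET22.index(b)] = c / total
    return out


class TestCksaap:
    def test_homopolymer_k0(self):
        v = encode_cksaap("A" * 33, k=0)
        assert v[0] == 1.0
        assert v.sum() == 1.0

    @pytest.mark.parametrize("k", [0, 1, 3, 7])
    def test_matches_brute_force_enumeration(self, rng, k):
        for _ in range(10):
            w = random_window(rng, alphabet=ALPHABET22)
            np.testing.assert_allclose(encode_cksaap(w, k), brute_force_cksaap(w, k))

    @settings(derandomize=True, max_examples=40)
    @given(window_strategy, st.integers(0, 31))
    def test_sums_to_one_and_nonnegative(self, w, k):
        v = encode_cksaap(w, k)
        assert np.isclose(v.sum(), 1.0)
        assert (v >= 0).all()

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            encode_cksaap("A" * 33, k=32)


class TestCtdc:
    def test_single_group_window(self):
        # all residues in the hydrophobic group of the first hydrophobicity partition
        v = encode_ctdc("C" * 16 + "K" + "L" * 16)
        groups = ctd_groups()["hydrophobicity_PRAM900101"]
        # K is polar (group 1), C/L hydrophobic (group 3) in that partition
        np.testing.assert_allclose(v[:3], [1 / 33, 0.0, 32 / 33])

    def test_triples_sum_to_one(self, windows33):
        for w in windows33:
            if all(c in "UX" for c in w):
                continue
            v = encode_ctdc(w).reshape(13, 3)
            np.testing.assert_allclose(v.sum(axis=1), 1.0)

    def test_hand_tally_charge(self):
        w = "KRDE" + "A" * 29
        v = encode_ctdc(w).reshape(13, 3)
        props = list(ctd_groups())
        charge = v[props.index("charge")]
        # K,R positive; 29 A + nothing else neutral... A*29 plus none; D,E negative
        np.testing.assert_allclose(charge, [2 / 33, 29 / 33, 2 / 33])

    def test_placeholders_excluded_from_n(self):
        v = encode_ctdc("K" + "X" * 32).reshape(13, 3)
        np.testing.assert_allclose(v.sum(axis=1), 1.0)

    def test_all_placeholder_window_rejected(self):
        with pytest.raises(ValueError):
            encode_ctdc("X" * 33)


class TestBlosum62:
    # the published BLOSUM62 row for tryptophan, in ACDEFGHIKLMNPQRSTVWY order
    W_ROW = [-3, -2, -4, -3, 1, -2, -2, -3, -3, -2, -1, -4, -4, -2, -3, -3, -2, -3, 11, 2]

    def test_placeholder_window_is_zero(self):
        assert not encode_blosum62("X" * 33).any()
        assert not encode_blosum62("U" * 33).any()

    def test_tryptophan_row_matches_published_matrix(self):
        v = encode_blosum62("W" * 33).reshape(33, 20)
        np.testing.assert_array_equal(v[0], self.W_ROW)
        assert v[0][STANDARD20.index("W")] == 11

    def test_width(self, windows33):
        assert encode_blosum62(windows33[0]).shape == (660,)


class TestStructure:
    def test_output_length_66(self):
        ann = SecondaryStructureAnnotation("p", "C" * 50)
        assert encode_structure(ann, 25).shape == (66,)

    def test_all_coil_is_zero(self):
        ann = SecondaryStructureAnnotation("p", "C" * 50)
        assert not encode_structure(ann, 25).any()

    def test_codebook_prefix(self):
        ann = SecondaryStructureAnnotation("p", "CHE" + "C" * 40)
        v = encode_structure(ann, 17)  # window starts exactly at residue 1
        assert list(v[:6]) == [0, 0, 0, 1, 1, 0]

    def test_boundary_padding_is_11(self):
        ann = SecondaryStructureAnnotation("p", "C" * 20)
        v = encode_structure(ann, 1).reshape(33, 2)
        assert (v[:16] == 1).all()  # left pad = X = 11
        assert (v[16:] != 1).any()

    def test_o_normalized_to_e(self):
        ann = SecondaryStructureAnnotation("p", "O" * 10)
        assert ann.ss_string == "E" * 10

    def test_invalid_letters_rejected(self):
        with pytest.raises(ValueError):
            SecondaryStructureAnnotation("p", "CHQ")


PSSM_FIXTURE = """
Last position-specific scoring matrix computed, weighted observed percentages rounded down

            A   R   N   D   C   Q   E   G   H   I   L   K   M   F   P   S   T   W   Y   V   A   R   N   D   C   Q   E   G   H   I   L   K   M   F   P   S   T   W   Y   V
    1 M    -1  -2  -3  -4  -2  -1  -2  -3  -2   1   2  -2   8   0  -3  -2  -1  -2  -1   1    0   0   0   0   0   0   0   0   0   0   0   0 100   0   0   0   0   0   0   0  0.50 0.20
    2 K    -1   2   0  -1  -4   1   1  -2  -1  -3  -3   5  -2  -4  -1   0  -1  -3  -2  -3    0  10   0   0   0   5   5   0   0   0   0  80   0   0   0   0   0   0   0   0  0.75 0.30
"""


class TestPssm:
    def test_parse_fixture_exact_cells(self, tmp_path):
        p = tmp_path / "prot1.pssm"
        p.write_text(PSSM_FIXTURE)
        profile = parse_pssm(p)
        assert profile.protein_id == "prot1"
        assert profile.matrix.shape == (2, 20)
        assert profile.residue_order == "ARNDCQEGHILKMFPSTWYV"
        assert profile.sequence == "MK"
        assert profile.matrix[0, 12] == 8  # M column of row 1
        assert profile.matrix[1, 11] == 5  # K column of row 2
        assert profile.matrix[0, 0] == -1

    def test_out_of_range_values_warn(self, tmp_path, caplog):
        text = PSSM_FIXTURE.replace("   8 ", "  19 ")
        p = tmp_path / "x.pssm"
        p.write_text(text)
        with caplog.at_level("WARNING"):
            profile = parse_pssm(p)
        assert profile.matrix.max() == 19
        assert "outside" in caplog.text

    def test_malformed_row_rejected(self, tmp_path):
        p = tmp_path / "x.pssm"
        p.write_text("    1 M   -1  bad  -3\n")
        with pytest.raises(ValueError):
            parse_pssm(p)

    def test_write_parse_round_trip(self, tmp_path, rng):
        matrix = rng.integers(-15, 14, size=(7, 20)).astype(float)
        profile = PssmProfile("p1", matrix, "ARNDCQEGHILKMFPSTWYV", "MKVLAAK")
        path = tmp_path / "p1.pssm"
        write_pssm(profile, path)
        back = parse_pssm(path)
        np.testing.assert_array_equal(back.matrix, matrix)
        assert back.sequence == "MKVLAAK"

    def test_window_boundary_padding(self, rng):
        matrix = rng.integers(-5, 6, size=(40, 20)).astype(float)
        profile = PssmProfile("p", matrix, "ARNDCQEGHILKMFPSTWYV")
        v = encode_pssm_window(profile, 1).reshape(33, 20)
        assert not v[:16].any()
        np.testing.assert_array_equal(v[16], matrix[0])

    def test_interior_window_equals_slice(self, rng):
        matrix = rng.integers(-5, 6, size=(80, 20)).astype(float)
        profile = PssmProfile("p", matrix, "ARNDCQEGHILKMFPSTWYV")
        v = encode_pssm_window(profile, 40).reshape(33, 20)
        np.testing.assert_array_equal(v, matrix[23:56])

    def test_position_out_of_range(self, rng):
        profile = PssmProfile("p", np.zeros((10, 20)), "ARNDCQEGHILKMFPSTWYV")
        with pytest.raises(ValueError):
            encode_pssm_window(profile, 11)


def _block(name, width, n_rows=4, seed=0):
    rng = np.random.default_rng(seed)
    return FeatureBlock(name, [f"c{i}" for i in range(width)], rng.random((n_rows, width)))


class TestAssemble:
    ROW_KEYS = [("p", i + 1) for i in range(4)]
    LABELS = [0, 1, 0, 1]

    def test_partial_width(self):
        fm = assemble([_block("BE", 726), _block("CKSAAP", 484)], self.ROW_KEYS, self.LABELS)
        assert fm.values.shape == (4, 1210)

    def test_blocks_reordered_canonically(self):
        fm = assemble([_block("PSSM", 660), _block("BE", 726)], self.ROW_KEYS, self.LABELS)
        assert fm.block_names == ["BE", "PSSM"]

    def test_full_width_and_unique_labels(self):
        widths = {"BE": 726, "EAAC": 580, "CKSAAP": 484, "CTDC": 39,
                  "BLOSUM62": 660, "STRUCT": 66, "PSSM": 660}
        fm = assemble([_block(n, w) for n, w in widths.items()], self.ROW_KEYS, self.LABELS)
        assert fm.values.shape == (4, 3215)
        assert len(set(fm.column_labels)) == 3215

    def test_duplicate_block_rejected(self):
        with pytest.raises(ValueError):
            assemble([_block("BE", 726), _block("BE", 726)], self.ROW_KEYS, self.LABELS)

    def test_row_misalignment_rejected(self):
        with pytest.raises(ValueError):
            assemble([_block("BE", 726, n_rows=3)], self.ROW_KEYS, self.LABELS)

    def test_csv_round_trip(self, tmp_path):
        fm = assemble([_block("BE", 5), _block("CTDC", 3)], self.ROW_KEYS, self.LABELS)
        path = tmp_path / "fm.csv"
        fm.to_csv(path)
        back = encoders.FeatureMatrix.from_csv(path)
        np.testing.assert_allclose(back.values, fm.values)
        assert back.column_labels == fm.column_labels
        assert back.row_keys == fm.row_keys


class TestMinMax:
    def test_endpoints_map_to_unit_interval(self):
        X = np.array([[-15.0], [13.0]])
        params = minmax_fit(X)
        np.testing.assert_allclose(minmax_apply(X, params).ravel(), [0.0, 1.0])

    def test_constant_column_maps_to_zero(self):
        X = np.full((5, 2), 3.0)
        assert not minmax_apply(X, minmax_fit(X)).any()

    def test_no_clipping_outside_training_range(self):
        train = np.array([[0.0], [2.0]])
        params = minmax_fit(train)
        out = minmax_apply(np.array([[3.0], [-1.0]]), params)
        np.testing.assert_allclose(out.ravel(), [1.5, -0.5])

    def test_training_matrix_spans_unit_interval(self, rng):
        X = rng.normal(size=(20, 6)) * 10
        scaled = minmax_apply(X, minmax_fit(X))
        np.testing.assert_allclose(scaled.min(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(scaled.max(axis=0), 1.0, atol=1e-12)

    def test_width_mismatch_rejected(self):
        params = minmax_fit(np.zeros((3, 4)))
        with pytest.raises(ValueError):
            minmax_apply(np.zeros((3, 5)), params)

    def test_json_round_trip(self, tmp_path, rng):
        params = minmax_fit(rng.random((6, 3)))
        path = tmp_path / "scaler.json"
        params.to_json(path)
        back = encoders.ScalerParams.from_json(path)
        np.testing.assert_array_equal(back.minimum, params.minimum)
        np.testing.assert_array_equal(back.maximum, params.maximum)
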