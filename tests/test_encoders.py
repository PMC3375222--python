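from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sumohydro.alphabet import ALPHABET, AMINO_ACIDS, LETTER_INDEX, PAD
from sumohydro.dataset import LabeledDataset, NEGATIVE, POSITIVE
from sumohydro.encoders import (
    DEFAULT_KNN_K,
    EncodingError,
    HYDROPHOBICITY,
    PssmProfile,
    ZSCALES,
    encode_binary,
    encode_cksaap,
    encode_dataset,
    encode_hydrobinary,
    encode_knn,
    encode_pssm,
    encode_reduced,
    encode_zscales,
    hydrophobicity,
    knn_distance,
    normalized_blosum,
    parse_pssm,
    scheme_dimension,
)

from conftest import make_fragment, random_fragment


@st.composite
def fragments(draw):
    from sumohydro.dataset import Fragment

    left_pad = draw(st.integers(0, 12))
    right_pad = draw(st.integers(0, 12))
    left = "".join(
        draw(st.lists(st.sampled_from(AMINO_ACIDS),
                      min_size=12 - left_pad, max_size=12 - left_pad))
    )
    right = "".join(
        draw(st.lists(st.sampled_from(AMINO_ACIDS),
                      min_size=12 - right_pad, max_size=12 - right_pad))
    )
    residues = PAD * left_pad + left + "K" + right + PAD * right_pad
    return Fragment(residues, NEGATIVE, (f"hyp:{residues}", 13))


class TestBinary:
    def test_block_for_A_is_first_slot(self):
        f = make_fragment("AAKAA")
        vec = encode_binary(f)
        # position 11 (offset -1) holds A -> block 11 has a 1 at slot 0
        assert vec[11 * 21 + 0] == 1.0
        assert vec[11 * 21 + 1 : 12 * 21].sum() == 0.0

    def test_dimension_and_sum(self, rng):
        for _ in range(20):
            vec = encode_binary(random_fragment(rng))
            assert vec.shape == (504,)
            assert vec.sum() == 24.0

    def test_index_arithmetic_vs_naive_loop(self, rng):
        f = random_fragment(rng)
        vec = encode_binary(f)
        letters = f.residues[:12] + f.residues[13:]
        naive = np.zeros(504)
        for i, letter in enumerate(letters):
            naive[i * 21 + LETTER_INDEX[letter]] = 1.0
        np.testing.assert_array_equal(vec, naive)

    def test_all_A_flanks(self):
        f = make_fragment("A" * 12 + "K" + "A" * 12)
        vec = encode_binary(f)
        assert set(np.flatnonzero(vec)) == {i * 21 for i in range(24)}

    @given(fragments())
    @settings(max_examples=50, deadline=None)
    def test_one_hot_conservation(self, f):
        assert encode_binary(f).sum() == 24.0


class TestCksaap:
    def test_per_k_sums(self, rng):
        f = random_fragment(rng)
        vec = encode_cksaap(f, k_max=4)
        for k in range(5):
            assert vec[k * 441 : (k + 1) * 441].sum() == 25 - k - 1

    def test_all_A_flanks_k0(self):
        f = make_fragment("A" * 12 + "K" + "A" * 12)
        vec = encode_cksaap(f, k_max=0)
        a, k = LETTER_INDEX["A"], LETTER_INDEX["K"]
        counts = {(a, a): vec[a * 21 + a], (a, k): vec[a * 21 + k], (k, a): vec[k * 21 + a]}
        assert counts == {(a, a): 22.0, (a, k): 1.0, (k, a): 1.0}
        assert vec.sum() == 24.0

    def test_brute_force_oracle(self, rng):
        f = random_fragment(rng)
        k_max = 3
        vec = encode_cksaap(f, k_max=k_max)
        naive = np.zeros(441 * (k_max + 1))
        for k in range(k_max + 1):
            for i in range(25 - k - 1):
                x, y = f.residues[i], f.residues[i + k + 1]
                naive[k * 441 + LETTER_INDEX[x] * 21 + LETTER_INDEX[y]] += 1
        np.testing.assert_array_equal(vec, naive)

    def test_total_dimension(self, rng):
        assert encode_cksaap(random_fragment(rng), k_max=4).shape == (2205,)

    def test_negative_kmax_rejected(self, rng):
        with pytest.raises(EncodingError):
            encode_cksaap(random_fragment(rng), k_max=-1)

    @given(fragments(), st.integers(0, 4))
    @settings(max_examples=30, deadline=None)
    def test_counts_sum_property(self, f, k_max):
        vec = encode_cksaap(f, k_max=k_max)
        assert vec.sum() == sum(25 - k - 1 for k in range(k_max + 1))


class TestReduced:
    def test_v_and_l_share_group_in_both_variants(self):
        for variant in ("six", "nine"):
            fv = encode_reduced(make_fragment("VVKVV"), variant)
            fl = encode_reduced(make_fragment("LLKLL"), variant)
            np.testing.assert_array_equal(fv, fl)

    def test_g_and_c_share_group_only_under_six(self):
        fg6 = encode_reduced(make_fragment("GGKGG"), "six")
        fc6 = encode_reduced(make_fragment("CCKCC"), "six")
        np.testing.assert_array_equal(fg6, fc6)
        fg9 = encode_reduced(make_fragment("GGKGG"), "nine")
        fc9 = encode_reduced(make_fragment("CCKCC"), "nine")
        assert not np.array_equal(fg9, fc9)

    @pytest.mark.parametrize("variant,dim", [("six", 144), ("nine", 216)])
    def test_dimension_and_sum(self, rng, variant, dim):
        vec = encode_reduced(random_fragment(rng), variant)
        assert vec.shape == (dim,)
        assert vec.sum() == 24.0

    def test_unknown_variant(self, rng):
        with pytest.raises(EncodingError, match="variant"):
            encode_reduced(random_fragment(rng), "twelve")


class TestZscales:
    def test_table_values_A(self):
        assert ZSCALES["A"] == (0.24, -2.32, 0.60, -0.14, 1.30)

    def test_table_values_W(self):
        assert ZSCALES["W"] == (-4.36, 3.94, 0.59, 3.44, -1.59)

    def test_dimension(self, rng):
        assert encode_zscales(random_fragment(rng)).shape == (120,)

    def test_padding_contributes_zeros(self):
        f = make_fragment("AAKAA")  # 10 O's each side
        vec = encode_zscales(f).reshape(24, 5)
        np.testing.assert_array_equal(vec[:10], 0.0)
        np.testing.assert_array_equal(vec[14:], 0.0)
        np.testing.assert_array_equal(vec[10], ZSCALES["A"])


class TestHydrophobicity:
    @pytest.mark.parametrize(
        "letter,value",
        [("A", 1.81), ("I", 4.92), ("R", -14.92), ("K", -5.55), ("O", 0.0)],
    )
    def test_scale_values(self, letter, value):
        assert hydrophobicity(letter) == value

    def test_unknown_letter(self):
        with pytest.raises(EncodingError):
            hydrophobicity("B")

    def test_all_21_letters_covered(self):
        assert set(HYDROPHOBICITY) == set(ALPHABET)


class TestHydrobinary:
    def test_dimension(self, rng):
        for _ in range(10):
            assert encode_hydrobinary(random_fragment(rng)).shape == (508,)

    def test_center_contribution_is_K(self, rng):
        vec = encode_hydrobinary(random_fragment(rng))
        assert vec[505] == -5.55

    def test_hydrophobic_tail_values(self):
        # E at -1, I at +1, D at +2 around the centre K
        f = make_fragment("AEKID")
        np.testing.assert_allclose(
            encode_hydrobinary(f)[504:], [-6.81, -5.55, 4.92, -8.72]
        )

    def test_prefix_is_binary_encoding(self, rng):
        f = random_fragment(rng)
        np.testing.assert_array_equal(encode_hydrobinary(f)[:504], encode_binary(f))


class TestPssm:
    def _profile(self, rng, seq):
        scores = rng.integers(-10, 11, size=(len(seq), 20)).astype(float)
        return PssmProfile(protein_id="P1", residues=seq, scores=scores)

    def test_full_window_copied_verbatim(self, rng):
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=30))
        seq = seq[:14] + "K" + seq[15:]
        prof = self._profile(rng, seq)
        from sumohydro.dataset import ProteinRecord, extract_fragment

        frag = extract_fragment(ProteinRecord("P1", seq), 15)
        vec = encode_pssm(frag, prof)
        assert vec.shape == (500,)
        np.testing.assert_array_equal(vec.reshape(25, 20), prof.scores[2:27])

    def test_n_terminal_padding_zeros(self, rng):
        seq = "K" + "".join(rng.choice(list(AMINO_ACIDS), size=29))
        prof = self._profile(rng, seq)
        from sumohydro.dataset import ProteinRecord, extract_fragment

        frag = extract_fragment(ProteinRecord("P1", seq), 1)
        vec = encode_pssm(frag, prof).reshape(25, 20)
        np.testing.assert_array_equal(vec[:12], 0.0)
        np.testing.assert_array_equal(vec[12:], prof.scores[:13])

    def test_toy_profile_vs_naive_loop(self, rng):
        seq = "AKC"
        prof = self._profile(rng, seq)
        from sumohydro.dataset import ProteinRecord, extract_fragment

        frag = extract_fragment(ProteinRecord("P1", seq), 2)
        vec = encode_pssm(frag, prof).reshape(25, 20)
        for i in range(25):
            p = 2 - 12 + i
            expected = prof.scores[p - 1] if 1 <= p <= 3 else np.zeros(20)
            np.testing.assert_array_equal(vec[i], expected)

    def test_residue_mismatch_errors(self, rng):
        seq = "AKC"
        prof = PssmProfile("P1", "AKA", rng.integers(-5, 6, (3, 20)).astype(float))
        from sumohydro.dataset import ProteinRecord, extract_fragment

        frag = extract_fragment(ProteinRecord("P1", seq), 2)
        with pytest.raises(EncodingError, match="mismatch"):
            encode_pssm(frag, prof)

    def test_parse_ncbi_ascii(self, tmp_path):
        text = (
            "\n"
            "Last position-specific scoring matrix computed\n"
            "            A   R   N   D   C   Q   E   G   H   I   L   K   M   F   P   S   T   W   Y   V"
            "   A   R   N   D   C   Q   E   G   H   I   L   K   M   F   P   S   T   W   Y   V\n"
            "    1 A     4  -1  -2  -2   0  -1  -1   0  -2  -1  -1  -1  -1  -2  -1   1   0  -3  -2   0"
            "  90  1  0  0  0  1  1  0  0  1  1  1  0  0  1  1  1  0  0  1\n"
            "    2 K    -1   2   0  -1  -3   1   1  -2  -1  -3  -2   5  -1  -3  -1   0  -1  -3  -2  -2"
            "   1  2  0  1  0  1  1  0  0  1  1 85  0  0  1  1  1  0  0  1\n"
            "\n"
            "                      K         Lambda\n"
        )
        p = tmp_path / "P1.pssm"
        p.write_text(text)
        prof = parse_pssm(p, "P1")
        assert prof.residues == "AK"
        # NCBI column A maps to our alphabetical column 0
        assert prof.scores[0, 0] == 4.0
        # our column for K (alphabetical index 8) holds the NCBI K column
        assert prof.scores[1, LETTER_INDEX["K"]] == 5.0


class TestKnnDistance:
    def test_identical_self_maxima(self, rng):
        a = random_fragment(rng)
        b = random_fragment(rng)
        assert knn_distance(a, a) <= knn_distance(a, b)

    def test_padding_self_similarity(self):
        # K surrounded by 12 O's each side: all 24 O/O pairs are maximally
        # similar; only the centre K/K pair (BLOSUM62 5 -> (5+4)/15) adds distance
        f = make_fragment("K")
        assert knn_distance(f, f) == pytest.approx((1 - 9 / 15) / 25)

    def test_hand_computed_oracle(self):
        # 5-mer windows; BLOSUM62: A/A=4, C/W=-2, K/K=5, D/D=6, E/F=-3,
        # min=-4, max=11 -> normalized (v+4)/15; padding O/O similarity = 1
        a = make_fragment("ACKDE", window=5)
        b = make_fragment("AWKDF", window=5)
        expected = np.mean([1 - 8 / 15, 1 - 2 / 15, 1 - 9 / 15, 1 - 10 / 15, 1 - 1 / 15])
        assert knn_distance(a, b) == pytest.approx(expected)
        assert expected == pytest.approx(0.6)

    def test_symmetry_and_bounds(self, rng):
        for _ in range(10):
            a, b = random_fragment(rng), random_fragment(rng)
            d = knn_distance(a, b)
            assert 0.0 <= d <= 1.0
            assert d == pytest.approx(knn_distance(b, a))

    def test_length_mismatch(self):
        with pytest.raises(EncodingError):
            knn_distance(make_fragment("K", window=5), make_fragment("K", window=25))

    def test_normalized_blosum_properties(self):
        sim = normalized_blosum()
        assert sim.shape == (21, 21)
        np.testing.assert_array_equal(sim, sim.T)
        assert sim.min() == 0.0 and sim.max() == 1.0
        assert sim[20, 20] == 1.0
        assert sim[20, :20].sum() == 0.0


class TestEncodeKnn:
    def _refs(self, rng, n, label):
        return [random_fragment(rng, label=label, source=(f"{label}r{i}", 13)) for i in range(n)]

    def test_equidistant_gives_ones(self):
        pos = [make_fragment("AAKAA", source=(f"p{i}", 3)) for i in range(3)]
        neg = [make_fragment("AAKAA", source=(f"n{i}", 3), label=0) for i in range(3)]
        q = make_fragment("CCKCC", source=("q", 3))
        feats = encode_knn(q, pos, neg, k_list=(1, 3))
        np.testing.assert_allclose(feats, 1.0)

    def test_identical_positive_pulls_below_one(self, rng):
        pos = self._refs(rng, 3, POSITIVE)
        neg = self._refs(rng, 3, NEGATIVE)
        from sumohydro.dataset import Fragment

        q = Fragment(pos[0].residues, POSITIVE, ("query", 13))
        feats = encode_knn(q, pos, neg, k_list=(1,), exclude_self=False)
        assert feats[0] < 1.0

    def test_brute_force_oracle(self, rng):
        pos = self._refs(rng, 3, POSITIVE)
        neg = self._refs(rng, 3, NEGATIVE)
        q = random_fragment(rng, source=("query", 13))
        feats = encode_knn(q, pos, neg, k_list=(1, 3))
        for ki, k in enumerate((1, 3)):
            dp = sorted(knn_distance(q, r) for r in pos)
            dn = sorted(knn_distance(q, r) for r in neg)
            expected = np.mean(dp[:k]) / np.mean(dn[:k])
            assert feats[ki] == pytest.approx(expected)

    def test_reference_order_invariance(self, rng):
        pos = self._refs(rng, 5, POSITIVE)
        neg = self._refs(rng, 5, NEGATIVE)
        q = random_fragment(rng, source=("query", 13))
        a = encode_knn(q, pos, neg, k_list=(1, 3, 5))
        b = encode_knn(q, pos[::-1], neg[::-1], k_list=(1, 3, 5))
        np.testing.assert_allclose(a, b)

    def test_too_small_reference(self, rng):
        pos = self._refs(rng, 2, POSITIVE)
        neg = self._refs(rng, 5, NEGATIVE)
        with pytest.raises(EncodingError, match="too small"):
            encode_knn(random_fragment(rng), pos, neg, k_list=(5,))

    def test_self_exclusion_by_source(self, rng):
        pos = self._refs(rng, 4, POSITIVE)
        neg = self._refs(rng, 4, NEGATIVE)
        q = pos[0]
        with_self = encode_knn(q, pos, neg, k_list=(1,), exclude_self=False)
        without = encode_knn(q, pos, neg, k_list=(1,), exclude_self=True)
        assert with_self[0] <= without[0]


class TestEncodeDataset:
    def test_binary_matrix_shape(self, toy_dataset):
        X, y = encode_dataset(toy_dataset, "binary")
        assert X.shape == (25, 504)
        assert y.sum() == 5

    def test_determinism(self, toy_dataset):
        X1, _ = encode_dataset(toy_dataset, "hydrobinary")
        X2, _ = encode_dataset(toy_dataset, "hydrobinary")
        np.testing.assert_array_equal(X1, X2)

    def test_knn_leave_self_out(self, rng):
        frags = [
            random_fragment(rng, label=POSITIVE, source=(f"p{i}", 13)) for i in range(16)
        ] + [
            random_fragment(rng, label=NEGATIVE, source=(f"n{i}", 13)) for i in range(16)
        ]
        ds = LabeledDataset(frags)
        X, y = encode_dataset(ds, "knn", k_list=(1,))
        # with self-exclusion a reference positive never matches itself: D_p > 0
        assert np.all(X[:16, 0] > 0)

    def test_row_order_matches_dataset(self, toy_dataset):
        X, _ = encode_dataset(toy_dataset, "binary")
        for i, f in enumerate(toy_dataset):
            np.testing.assert_array_equal(X[i], encode_binary(f))

    def test_unknown_scheme(self, toy_dataset):
        with pytest.raises(EncodingError, match="unknown scheme"):
            encode_dataset(toy_dataset, "quantum")


class TestDimensionContracts:
    @pytest.mark.parametrize(
        "scheme,dim",
        [
            ("binary", 504),
            ("cksaap", 2205),
            ("six_letter", 144),
            ("nine_letter", 216),
            ("zscales", 120),
            ("hydrobinary", 508),
            ("pssm", 500),
            ("knn", 6),
        ],
    )
    def test_contract(self, scheme, dim):
        assert scheme_dimension(scheme) == dim

    def test_knn_dimension_follows_k_list(self):
        assert scheme_dimension("knn", k_list=(1, 3)) == 2

    def test_cksaap_dimension_follows_k_max(self):
        assert scheme_dimension("cksaap", k_max=0) == 441
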