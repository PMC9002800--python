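"""Unit and property tests for the quinary pattern encoder."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from quintex.encoder import (
    DEFAULT_SCALES,
    NeighborhoodSpec,
    ThresholdRule,
    code_table,
    encode_image,
    lqp_basic_code,
    per_channel_dim,
    quinary_level,
    riu2_code,
    riu4_code,
    riu4_index,
    sample_circle,
    split_subpatterns,
    transition_count,
)


class TestQuinaryLevel:
    @pytest.mark.parametrize(
        "diff,expected",
        [
            (0.0, 0),
            (2.0, 2),  # diff == tau2 -> level 2
            (1.0, 1),  # diff == tau1 -> level 1
            (-1.0, 0),  # diff == -tau1 -> level 0
            (-2.0, -1),  # diff == -tau2 -> level -1
            (-2.5, -2),
            (1.5, 1),
            (5.0, 2),
        ],
    )
    def test_boundaries(self, diff, expected):
        assert quinary_level(diff, tau1=1.0, tau2=2.0) == expected

    def test_degenerate_thresholds_use_sign(self):
        # zero centre intensity collapses the bands: 0 stays 0, signs go extreme
        assert quinary_level(0.0, 0.0, 0.0) == 0
        assert quinary_level(3.0, 0.0, 0.0) == 2
        assert quinary_level(-3.0, 0.0, 0.0) == -2

    def test_vectorized_matches_scalar(self, rng):
        diffs = rng.normal(0, 3, 100)
        vec = quinary_level(diffs, 1.0, 2.0)
        assert [quinary_level(d, 1.0, 2.0) for d in diffs] == list(vec)


class TestSubpatterns:
    def test_exhaustive_partition_of_nonzero_levels(self):
        # over all 5^4 level strings: rows are disjoint and cover level != 0
        levels_alphabet = [-2, -1, 0, 1, 2]
        from itertools import product

        for levels in product(levels_alphabet, repeat=4):
            bits = split_subpatterns(list(levels))
            assert bits.shape == (4, 4)
            col_sums = bits.sum(axis=0)
            expected = np.array([1 if l != 0 else 0 for l in levels])
            assert (col_sums == expected).all()
            # row i marks exactly the positions with the matching level
            for row, target in zip(bits, (2, 1, -1, -2)):
                assert (row == (np.array(levels) == target)).all()


class TestTransitionCount:
    @pytest.mark.parametrize(
        "bits,expected",
        [
            ("00000000", 0),
            ("11111111", 0),
            ("00111100", 2),
            ("11001110", 4),
            ("01010101", 8),
            ("10", 2),
        ],
    )
    def test_circular_count(self, bits, expected):
        assert transition_count(bits) == expected


class TestWorkedExamples:
    """The descriptor's published 8-bit worked examples."""

    @pytest.mark.parametrize(
        "bits,code",
        [
            ("00111100", 4),
            ("00001111", 4),
            ("11001110", 15),
            ("11101100", 15),
            ("11111111", 8),  # T=0, popcount
            ("00000000", 0),
            ("01010101", 18),  # fully alternating -> unified code
        ],
    )
    def test_riu4(self, bits, code):
        assert riu4_code(bits) == code

    @pytest.mark.parametrize(
        "bits,code",
        [("00111100", 4), ("11001110", 9), ("11111111", 8), ("00000000", 0)],
    )
    def test_riu2(self, bits, code):
        assert riu2_code(bits) == code

    @pytest.mark.parametrize("bits,code", [("00111100", 60), ("00001111", 15), ("00000000", 0)])
    def test_basic(self, bits, code):
        assert lqp_basic_code(bits) == code


class TestDimensionality:
    @pytest.mark.parametrize("P,dim", [(8, 19), (10, 28), (14, 52), (18, 84)])
    def test_per_channel_dim(self, P, dim):
        assert per_channel_dim(P) == dim
        # matches ceil((P^2 + 11) / 4) for the even P used here
        assert dim == -(-(P**2 + 11) // 4)

    def test_default_configuration_has_656_channels(self):
        assert 4 * sum(per_channel_dim(s.n_points) for s in DEFAULT_SCALES) == 656

    @pytest.mark.parametrize("P", [8, 10, 14, 18])
    def test_index_is_bijective(self, P):
        """Eq-style two-run index maps {(X,Y)} 1:1 onto 1..floor((P-2)^2/4)."""
        pairs = [
            (x, y)
            for x in range(1, P)
            for y in range(x, P)
            if x + y <= P - 2
        ]
        indices = [riu4_index(x, y, P) for x, y in pairs]
        assert sorted(indices) == list(range(1, (P - 2) ** 2 // 4 + 1))


def _rotations(bits: str):
    return {bits[i:] + bits[:i] for i in range(len(bits))}


class TestRotationInvariance:
    @pytest.mark.parametrize("P", [8, 10])
    def test_exhaustive_cyclic_shifts(self, P):
        lut = code_table(P)
        v = np.arange(1 << P, dtype=np.uint32)
        rot = ((v >> 1) | (v << (P - 1))) & ((1 << P) - 1)
        assert (lut[rot] == lut).all()

    @pytest.mark.parametrize("P", [8, 10])
    def test_emitted_codes_cover_alphabet(self, P):
        lut = code_table(P)
        assert set(np.unique(lut)) == set(range(per_channel_dim(P)))

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=(1 << 18) - 1), st.integers(0, 17))
    def test_random_shifts_p18(self, value, shift):
        bits = format(value, "018b")
        shifted = bits[shift:] + bits[:shift]
        assert riu4_code(bits) == riu4_code(shifted)


def _oracle_class(bits: str):
    """Brute-force canonical class: what a code must distinguish."""
    T = transition_count(bits)
    if T <= 2:
        return ("uniform", bits.count("1"))
    if T == 4:
        # run lengths of ones in the canonical (minimal) rotation
        runs = tuple(sorted(len(r) for r in min(_rotations(bits)).strip("0").split("0") if r))
        return ("two-run", runs)
    return ("other",)


class TestCompleteness:
    @pytest.mark.parametrize("P", [8, 10])
    def test_codes_partition_exactly_by_canonical_class(self, P):
        """Two strings share a riu4 code iff they share the canonical class."""
        lut = code_table(P)
        class_to_code = {}
        for v in range(1 << P):
            bits = format(v, f"0{P}b")
            cls = _oracle_class(bits)
            code = int(lut[v])
            assert class_to_code.setdefault(cls, code) == code
        codes = sorted({c for c in class_to_code.values()})
        assert codes == list(range(per_channel_dim(P)))

    def test_scalar_riu4_agrees_with_table(self, rng):
        for P in (10, 14, 18):
            lut = code_table(P)
            for v in rng.integers(0, 1 << P, 100):
                assert riu4_code(format(v, f"0{P}b")) == lut[v]


class TestSampleCircle:
    def test_constant_image(self):
        img = np.full((16, 16), 7.0)
        vals, ok = sample_circle(img, None, (8, 8), NeighborhoodSpec(2, 10))
        assert ok and np.allclose(vals, 7.0)

    def test_near_edge_is_invalid(self):
        img = np.zeros((16, 16))
        mask = np.zeros((16, 16), bool)
        mask[4:12, 4:12] = True
        vals, ok = sample_circle(img, mask, (5, 8), NeighborhoodSpec(2, 10))
        assert not ok

    def test_ramp_p4_bilinear_values(self):
        # P=4, R=1: samples at the four diagonals of the centre
        img = np.tile(np.arange(8.0), (8, 1))  # intensity == column
        vals, ok = sample_circle(img, None, (4, 4), NeighborhoodSpec(1, 4))
        s = np.sqrt(0.5)
        assert ok
        assert np.allclose(vals, [4 - s, 4 + s, 4 + s, 4 - s])


class TestEncodeImage:
    def test_constant_image_is_all_code_zero(self):
        codes = encode_image(np.full((40, 40), 55.0), None)
        assert codes.valid.any()
        for s in range(codes.n_scales):
            for i in range(4):
                plane, valid = codes.plane(s, i)
                assert (plane[valid] == 0).all()

    def test_rotation_by_180_preserves_code_multisets(self, phantom):
        image, _ = phantom
        a = encode_image(image, None, variant="riu4")
        b = encode_image(image[::-1, ::-1].copy(), None, variant="riu4")
        for s in range(a.n_scales):
            for i in range(4):
                pa, va = a.plane(s, i)
                pb, vb = b.plane(s, i)
                assert va.sum() == vb.sum()
                assert np.array_equal(
                    np.bincount(pa[va], minlength=a.channel_dims[s]),
                    np.bincount(pb[vb], minlength=b.channel_dims[s]),
                )

    def test_riu2_agrees_with_riu4_on_uniform_patterns(self, phantom):
        image, mask = phantom
        spec = (NeighborhoodSpec(2, 10),)
        a = encode_image(image, mask, spec, variant="riu4")
        b = encode_image(image, mask, spec, variant="riu2")
        P = 10
        for i in range(4):
            pa, va = a.plane(0, i)
            pb, vb = b.plane(0, i)
            assert np.array_equal(va, vb)
            uniform = pa[va] <= P  # riu4 codes 0..P are exactly the T<=2 class
            assert np.array_equal(pa[va][uniform], pb[vb][uniform])
            assert (pb[vb][~uniform] == P + 1).all()

    def test_codes_partition_valid_pixels(self, encoded_phantom):
        codes = encoded_phantom
        for s in range(codes.n_scales):
            for i in range(4):
                plane, valid = codes.plane(s, i)
                counts = np.bincount(plane[valid], minlength=codes.channel_dims[s])
                assert counts.sum() == valid.sum()

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            encode_image(np.ones((20, 20)), np.zeros((20, 20), bool))

    def test_all_pixels_too_close_to_mask_edge_raises(self):
        mask = np.zeros((24, 24), bool)
        mask[10:13, 10:13] = True  # too small for R=8 support
        with pytest.raises(ValueError):
            encode_image(np.ones((24, 24)), mask, (NeighborhoodSpec(8, 18),))

    def test_threshold_rule_validation(self):
        with pytest.raises(ValueError):
            ThresholdRule(0.07, 0.02)
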