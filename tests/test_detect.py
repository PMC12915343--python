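"""Classical detection: HSB conversion, gating, particles, merging."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nodulequant import detect, simulate
from nodulequant.core_io import (
    FluorClass,
    HSBGate,
    ImageRGB,
    RunConfig,
    default_gates,
    detection_from_mask,
)
from .conftest import make_uniform_image
from .oracles import flood_components, hsb_of_pixel


class TestRgbToHsb:
    @pytest.mark.parametrize("color,hue,sat,bri", [
        ((255, 0, 0), 0.0, 1.0, 1.0),       # pure red
        ((0, 255, 255), 0.5, 1.0, 1.0),     # pure cyan
        ((100, 100, 100), 0.0, 0.0, 100 / 255),  # achromatic convention
        ((0, 0, 0), 0.0, 0.0, 0.0),         # black: sat defined as 0
    ])
    def test_reference_colors(self, color, hue, sat, bri):
        planes = detect.rgb_to_hsb(make_uniform_image(color, 2, 2))
        assert planes.hue[0, 0] == pytest.approx(hue, abs=1e-12)
        assert planes.sat[0, 0] == pytest.approx(sat, abs=1e-12)
        assert planes.bri[0, 0] == pytest.approx(bri, abs=1e-12)

    @settings(deadline=None, max_examples=60)
    @given(st.tuples(st.integers(0, 255), st.integers(0, 255), st.integers(0, 255)))
    def test_matches_colorsys_oracle(self, rgb):
        planes = detect.rgb_to_hsb(make_uniform_image(rgb, 1, 1))
        h, s, v = hsb_of_pixel(*rgb)
        assert planes.hue[0, 0] == pytest.approx(h, abs=1e-9)
        assert planes.sat[0, 0] == pytest.approx(s, abs=1e-9)
        assert planes.bri[0, 0] == pytest.approx(v, abs=1e-9)


class TestAdjustIntensity:
    def test_identity(self):
        img = make_uniform_image((3, 200, 77), 4, 4)
        out = detect.adjust_intensity(img, 0, 255)
        assert np.array_equal(out.pixels, img.pixels)

    def test_endpoint_maps_to_max(self):
        img = make_uniform_image((128, 128, 128))
        assert detect.adjust_intensity(img, 0, 128).pixels[0, 0, 0] == 255

    def test_round_half_away_midpoint(self):
        # 255*64/128 = 127.5 -> 128 under half-away-from-zero (exact
        # rational oracle: Fraction(255*64, 128) == 255/2)
        exact = Fraction(255 * 64, 128)
        assert exact == Fraction(255, 2)
        img = make_uniform_image((64, 64, 64))
        assert detect.adjust_intensity(img, 0, 128).pixels[0, 0, 0] == 128

    @settings(deadline=None, max_examples=40)
    @given(v=st.integers(0, 255), lo=st.integers(0, 100), hi=st.integers(101, 255))
    def test_matches_exact_rational_arithmetic(self, v, lo, hi):
        exact = Fraction(255 * (v - lo), hi - lo)
        # half-away rounding of a Fraction
        q, r = divmod(abs(exact.numerator), exact.denominator)
        rounded = q + (1 if 2 * r >= exact.denominator else 0)
        if exact < 0:
            rounded = -rounded
        expected = min(255, max(0, rounded))
        img = make_uniform_image((v, v, v))
        assert detect.adjust_intensity(img, lo, hi).pixels[0, 0, 0] == expected

    def test_bad_bounds(self):
        with pytest.raises(ValueError):
            detect.adjust_intensity(make_uniform_image((0, 0, 0)), 10, 10)


class TestGateMask:
    def test_cyan_pixel_passes_default_gate(self):
        planes = detect.rgb_to_hsb(make_uniform_image((0, 255, 255)))
        gate = default_gates()[FluorClass.CYAN]
        assert detect.gate_mask(planes, gate).all()

    def test_black_fails_any_brightness_gate(self):
        planes = detect.rgb_to_hsb(make_uniform_image((0, 0, 0)))
        for gate in default_gates().values():
            assert not detect.gate_mask(planes, gate).any()

    def test_wrapped_red_gate(self):
        gate = HSBGate(FluorClass.RED, 0.92, 0.06, 0.3, 0.15)
        planes = detect.rgb_to_hsb(make_uniform_image((255, 0, 31)))  # hue ~0.98
        assert planes.hue[0, 0] > 0.92
        assert detect.gate_mask(planes, gate).all()
        planes2 = detect.rgb_to_hsb(make_uniform_image((255, 31, 0)))  # hue ~0.02
        assert detect.gate_mask(planes2, gate).all()


class TestExtractParticles:
    def _two_squares(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[2:5, 2:5] = True
        mask[10:13, 10:13] = True
        return mask

    def test_counts_components(self):
        dets = detect.extract_particles(self._two_squares(), FluorClass.CYAN, 5, 1000)
        assert len(dets) == 2
        assert all(len(d.mask) == 9 for d in dets)
        assert dets[0].det_id == 0 and dets[1].det_id == 1

    def test_size_filter(self):
        assert detect.extract_particles(self._two_squares(), FluorClass.CYAN, 10, 1000) == []

    def test_max_area_filter(self):
        assert detect.extract_particles(self._two_squares(), FluorClass.CYAN, 1, 8) == []

    def test_diagonal_touch_is_one_component(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[1:4, 1:4] = True
        mask[4:7, 4:7] = True  # touches only at corner (3,3)-(4,4)
        dets = detect.extract_particles(mask, FluorClass.RED, 1, 1000)
        assert len(dets) == 1
        assert len(dets[0].mask) == 18

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 10_000))
    def test_matches_flood_fill_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((25, 25)) < 0.35
        dets = detect.extract_particles(mask, FluorClass.CYAN, 1, 10_000)
        oracle = flood_components(mask)
        assert len(dets) == len(oracle)
        assert {d.mask for d in dets} == set(oracle)


class TestConfidence:
    def test_score_is_mean_brightness(self):
        arr = np.zeros((2, 2, 3), dtype=np.uint8)
        arr[0, 0] = (51, 51, 51)    # bri 0.2
        arr[0, 1] = (153, 153, 153)  # bri 0.6
        planes = detect.rgb_to_hsb(ImageRGB(arr))
        det = detection_from_mask(0, FluorClass.CYAN, [(0, 0), (0, 1)], 1.0)
        assert detect.score_confidence(det, planes) == pytest.approx(0.4)

    def test_filter_boundary_inclusive(self):
        dets = [detection_from_mask(i, FluorClass.CYAN, [(0, i)], c)
                for i, c in enumerate([0.2, 0.3, 0.5])]
        kept = detect.filter_confidence(dets, 0.3)
        assert [d.confidence for d in kept] == [0.3, 0.5]

    def test_filter_zero_is_identity(self):
        dets = [detection_from_mask(i, FluorClass.CYAN, [(0, i)], c)
                for i, c in enumerate([0.1, 0.9])]
        assert detect.filter_confidence(dets, 0.0) == dets

    def test_filter_one_drops_everything_below(self):
        dets = [detection_from_mask(0, FluorClass.CYAN, [(0, 0)], 0.99)]
        assert detect.filter_confidence(dets, 1.0) == []

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.floats(0, 1), max_size=12),
           st.floats(0, 1), st.floats(0, 1))
    def test_monotone_in_threshold(self, confs, t1, t2):
        t1, t2 = min(t1, t2), max(t1, t2)
        dets = [detection_from_mask(i, FluorClass.RED, [(0, i)], c)
                for i, c in enumerate(confs)]
        assert len(detect.filter_confidence(dets, t2)) <= len(detect.filter_confidence(dets, t1))


class TestMergeMixed:
    def _det(self, i, fc, pixels, conf=0.8):
        return detection_from_mask(i, fc, pixels, conf)

    def test_identical_masks_merge(self):
        pix = [(r, c) for r in range(3) for c in range(3)]
        out = detect.merge_mixed([
            self._det(0, FluorClass.CYAN, pix, 0.6),
            self._det(1, FluorClass.YELLOW, pix, 0.9),
        ], 0.5)
        assert len(out) == 1
        m = out[0]
        assert m.fluor_class is FluorClass.MIXED
        assert m.partner_classes == {FluorClass.CYAN, FluorClass.YELLOW}
        assert m.confidence == 0.9
        assert m.mask == frozenset(pix)

    def test_disjoint_unchanged(self):
        a = self._det(0, FluorClass.CYAN, [(0, 0)])
        b = self._det(1, FluorClass.YELLOW, [(5, 5)])
        assert detect.merge_mixed([a, b], 0.5) == [a, b]

    def test_same_class_never_merges(self):
        pix = [(0, 0), (0, 1)]
        a = self._det(0, FluorClass.CYAN, pix)
        b = self._det(1, FluorClass.CYAN, pix)
        assert len(detect.merge_mixed([a, b], 0.5)) == 2

    def test_overlap_boundary(self):
        # 10-px mask sharing 5 px with a 40-px mask: 5/10 = 0.5 >= 0.5
        small = [(0, c) for c in range(10)]
        big = [(r, c) for r in range(1, 5) for c in range(10)]
        big = big[:35] + small[:5]
        out = detect.merge_mixed([
            self._det(0, FluorClass.YELLOW, small),
            self._det(1, FluorClass.RED, big),
        ], 0.5)
        assert len(out) == 1 and out[0].fluor_class is FluorClass.MIXED

    def test_below_boundary_no_merge(self):
        small = [(0, c) for c in range(10)]
        big = [(r, c) for r in range(1, 5) for c in range(10)] + small[:4]
        out = detect.merge_mixed([
            self._det(0, FluorClass.YELLOW, small),
            self._det(1, FluorClass.RED, big),
        ], 0.5)
        assert len(out) == 2

    def test_transitive_three_way(self):
        pix = [(r, c) for r in range(2) for c in range(2)]
        out = detect.merge_mixed([
            self._det(0, FluorClass.CYAN, pix),
            self._det(1, FluorClass.YELLOW, pix),
            self._det(2, FluorClass.RED, pix),
        ], 0.5)
        assert len(out) == 1
        assert out[0].partner_classes == {FluorClass.CYAN, FluorClass.YELLOW, FluorClass.RED}

    def test_idempotent(self):
        pix = [(r, c) for r in range(3) for c in range(3)]
        dets = [
            self._det(0, FluorClass.CYAN, pix),
            self._det(1, FluorClass.YELLOW, pix),
            self._det(2, FluorClass.RED, [(9, 9), (9, 8)]),
        ]
        once = detect.merge_mixed(dets, 0.5)
        twice = detect.merge_mixed(once, 0.5)
        assert [(d.fluor_class, d.mask) for d in once] == \
               [(d.fluor_class, d.mask) for d in twice]


class TestClassicalPipeline:
    def test_gate_soundness_on_simulated_image(self, clean_render, run_config):
        """Every pixel of every classical detection passes its class gate."""
        _, image, _ = clean_render
        planes = detect.rgb_to_hsb(image)
        dets = detect.detect_classical(image, run_config)
        gates = run_config.gates
        for d in dets:
            gate = gates[d.fluor_class]
            for r, c in d.mask:
                assert bool(gate.passes(planes.hue[r, c], planes.sat[r, c],
                                        planes.bri[r, c]))

    def test_clean_counts_match_truth(self, clean_render, run_config):
        """Noise-free, well-separated nodules are counted exactly per class."""
        _, image, truth = clean_render
        dets = detect.detect_classical(image, run_config)
        for fc in (FluorClass.CYAN, FluorClass.YELLOW, FluorClass.RED):
            n_true = sum(1 for n in truth.nodules if n.fluor_class is fc)
            n_det = sum(1 for d in dets if d.fluor_class is fc)
            assert n_det == n_true == 5
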