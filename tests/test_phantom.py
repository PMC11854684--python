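"""Synthetic retina and ghost-image rendering."""

import math

import numpy as np
import pytest
from skimage.transform import rotate as sk_rotate

from ghostgrade.errors import InvalidParameterError, OutOfBoundsError
from ghostgrade.phantom import (
    DEFAULT_DIRECTION_MIX,
    GRADE_BANDS,
    TrajectoryTruth,
    generate_cohort,
    generate_vessel_phantom,
    render_ghost_image,
    sample_cohort,
)


class TestVesselPhantom:
    def test_reproducible_and_seed_sensitive(self, phantom):
        again = generate_vessel_phantom((512, 512), seed=7)
        assert np.array_equal(phantom.canvas, again.canvas)
        other = generate_vessel_phantom((512, 512), seed=8)
        assert np.mean(phantom.canvas != other.canvas) >= 0.01

    def test_anatomy(self, phantom):
        assert phantom.canvas.min() >= 0 and phantom.canvas.max() <= 1
        assert len(phantom.bifurcations) >= 10
        x, y = phantom.disc_center
        r = phantom.disc_diameter_px / 2
        h, w = phantom.canvas.shape
        assert r <= x <= w - r and r <= y <= h - r
        # disc is a bright region, macula a darker one
        assert phantom.canvas[int(y), int(x)] > np.median(phantom.canvas)
        mx, my = phantom.macula_center
        assert phantom.canvas[int(my), int(mx)] < np.median(phantom.canvas)

    def test_too_small_canvas_rejected(self):
        with pytest.raises(InvalidParameterError):
            generate_vessel_phantom((128, 128), seed=0)


class TestRenderGhostImage:
    def test_identity_transform(self, phantom, single_image):
        assert np.allclose(single_image.pixels, phantom.canvas)

    def test_double_is_mean_of_symmetric_copies(self, phantom, double_image):
        # copies sit at +-(dx/2, 0) about the original position, so the
        # composite at (y, x) is the mean of the phantom at x -+ 12
        rng = np.random.default_rng(0)
        h, w = phantom.canvas.shape
        ys = rng.integers(40, h - 40, size=200)
        xs = rng.integers(40, w - 40, size=200)
        expected = 0.5 * (phantom.canvas[ys, xs - 12] + phantom.canvas[ys, xs + 12])
        assert np.allclose(double_image.pixels[ys, xs], expected, atol=1e-9)

    def test_rotation_split_evenly_across_copies(self, phantom):
        truth = TrajectoryTruth(
            "rotary", (0.0, 0.0), 6.0, 2, (0.5, 0.5), 0.0, amplitude_grade=2
        )
        img = render_ghost_image(phantom, truth)
        expected = 0.5 * (
            sk_rotate(phantom.canvas, 3.0, center=phantom.macula_center, order=1, mode="edge")
            + sk_rotate(phantom.canvas, -3.0, center=phantom.macula_center, order=1, mode="edge")
        )
        # compare away from borders where edge handling differs
        assert np.allclose(img.pixels[50:-50, 50:-50], expected[50:-50, 50:-50], atol=1e-9)

    def test_energy_conservation(self, phantom, double_image, triple_image):
        for img in (double_image, triple_image):
            assert abs(img.pixels.mean() - phantom.canvas.mean()) <= 0.02 * phantom.canvas.mean()

    def test_weight_length_mismatch_rejected(self, phantom):
        truth = TrajectoryTruth("horizontal", (24, 0), 0.0, 1, (0.5, 0.5), 0.0, amplitude_grade=1)
        with pytest.raises(InvalidParameterError):
            render_ghost_image(phantom, truth)

    def test_off_canvas_displacement_rejected(self, phantom):
        truth = TrajectoryTruth(
            "horizontal", (200.0, 0.0), 0.0, 2, (0.5, 0.5), 0.0, amplitude_grade=3
        )
        with pytest.raises(OutOfBoundsError):
            render_ghost_image(phantom, truth)

    def test_truth_class_consistency_enforced(self):
        # 'none' must coincide with sub-floor motion and a single copy
        bad = TrajectoryTruth("none", (24.0, 0.0), 0.0, 2, (0.5, 0.5), 0.0)
        with pytest.raises(InvalidParameterError):
            bad.validate()


class TestCohortSampling:
    def test_no_overcall_when_disabled(self):
        truths, records = sample_cohort(50, seed=1, p_over=0.0, p_missrot=0.0)
        for t, r in zip(truths, records):
            if t.amplitude_grade > 0:
                assert r.clinical_amplitude == t.amplitude_grade
                if t.direction_class != "none":
                    assert r.clinical_direction == t.direction_class

    def test_overcall_rate_binomial(self):
        truths, records = sample_cohort(1000, seed=2, p_over=0.2, p_missrot=0.0)
        eligible = [
            (t, r) for t, r in zip(truths, records) if 0 < t.amplitude_grade < 3
        ]
        over = sum(r.clinical_amplitude == t.amplitude_grade + 1 for t, r in eligible)
        assert len(eligible) > 200
        assert abs(over / len(eligible) - 0.2) <= 0.04

    def test_rotary_undercall_rate(self):
        truths, records = sample_cohort(1000, seed=3, p_over=0.0, p_missrot=0.5)
        rot = [(t, r) for t, r in zip(truths, records) if t.direction_class == "rotary"]
        miss = sum(r.clinical_direction != "rotary" for t, r in rot)
        assert len(rot) > 30
        assert abs(miss / len(rot) - 0.5) <= 0.15

    def test_clinical_direction_mix_multinomial(self):
        # clinical examination distribution of the emulated cohort:
        # 23 horizontal, 5 vertical, 10 rotary, 15 combined of 53 eyes
        mix = {
            "horizontal": 23 / 53,
            "vertical": 5 / 53,
            "rotary": 10 / 53,
            "combined": 15 / 53,
            "none": 0.0,
        }
        n = 1000
        truths, _ = sample_cohort(n, seed=4, mix=mix, p_over=0.0, p_missrot=0.0)
        for cls, p in mix.items():
            count = sum(t.direction_class == cls for t in truths)
            bound = 1.96 * math.sqrt(n * p * (1 - p)) if p > 0 else 0.5
            assert abs(count - n * p) <= bound + 1e-9

    def test_incomplete_mix_rejected(self):
        with pytest.raises(InvalidParameterError):
            sample_cohort(10, seed=0, mix={"horizontal": 1.0})

    def test_grade_bands_avoid_cutpoints(self):
        for lo, hi in GRADE_BANDS.values():
            for cut in (0.15, 0.40):
                assert hi <= 0.9 * cut + 1e-9 or lo >= 1.1 * cut - 1e-9

    def test_generate_cohort_deterministic(self):
        a = generate_cohort(3, seed=11)
        b = generate_cohort(3, seed=11)
        for ia, ib in zip(a[0], b[0]):
            assert np.array_equal(ia.pixels, ib.pixels)
        assert [t.displacement_px for t in a[1]] == [t.displacement_px for t in b[1]]
        assert [r.clinical_amplitude for r in a[2]] == [r.clinical_amplitude for r in b[2]]
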