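"""Ghost displacement, torsion, landmark and disc-geometry estimators."""

import math

import numpy as np
import pytest
from sklearn.base import clone

from ghostgrade.errors import (
    DegenerateInputError,
    InsufficientLandmarksError,
    InvalidParameterError,
)
from ghostgrade.images import FundusImage
from ghostgrade.phantom import TrajectoryTruth, generate_vessel_phantom, render_ghost_image
from ghostgrade.quantify import (
    ESTIMATE_COLUMNS,
    AutocorrDisplacementEstimator,
    GhostQuantifier,
    LandmarkDisplacementEstimator,
    estimate_disc_geometry,
    estimate_displacement_autocorr,
    estimate_rotation,
    match_landmarks,
    quantify_image,
)


def vector_error(est, truth):
    """Distance between offset vectors up to global negation (the sign of a
    ghost offset is not physically defined)."""
    ex, ey = est
    tx, ty = truth
    return min(math.hypot(ex - tx, ey - ty), math.hypot(ex + tx, ey + ty))


class TestAutocorrelation:
    def test_double_image_recovered(self, double_image):
        est = estimate_displacement_autocorr(double_image)
        assert est.n_images == 2
        assert vector_error((est.dx_px, est.dy_px), (24, 0)) <= 1.0
        assert 0 <= est.peak_strength <= 1

    def test_single_image_reports_no_ghost(self, single_image):
        est = estimate_displacement_autocorr(single_image)
        assert (est.dx_px, est.dy_px, est.n_images) == (0.0, 0.0, 1)

    def test_triple_image_recovered(self, triple_image):
        est = estimate_displacement_autocorr(triple_image)
        assert est.n_images == 3
        assert vector_error((est.dx_px, est.dy_px), (12, 12)) <= 1.0

    def test_degenerate_and_small_inputs_rejected(self):
        with pytest.raises(DegenerateInputError):
            estimate_displacement_autocorr(np.full((256, 256), 0.5))
        with pytest.raises(InvalidParameterError):
            estimate_displacement_autocorr(np.random.default_rng(0).random((64, 64)))

    def test_shift_equivariance_of_single_exposure(self, phantom):
        # translating the whole (single-exposure) content must not create
        # a ghost: the autocorrelation only sees relative structure
        rolled = np.roll(phantom.canvas, (30, 20), axis=(0, 1))
        est = estimate_displacement_autocorr(rolled)
        assert (est.dx_px, est.dy_px, est.n_images) == (0.0, 0.0, 1)

    def test_sign_convention_dominant_component_nonnegative(
        self, double_image, vertical_double_image, triple_image
    ):
        for img in (double_image, vertical_double_image, triple_image):
            est = estimate_displacement_autocorr(img)
            dominant = est.dx_px if abs(est.dx_px) >= abs(est.dy_px) else est.dy_px
            assert dominant >= 0


class TestRotation:
    def test_rotation_recovered(self, rotary_image):
        assert abs(estimate_rotation(rotary_image) - 6.0) <= 0.5

    def test_no_rotation_reports_zero(self, single_image, double_image):
        assert estimate_rotation(single_image) == 0.0
        assert estimate_rotation(double_image) == 0.0

    def test_negative_rotation_reports_magnitude(self, phantom):
        # +theta and -theta produce identical symmetric composites, so the
        # estimator reports the nonnegative magnitude by convention
        truth = TrajectoryTruth("rotary", (0, 0), -4.0, 2, (0.5, 0.5), 0.0, amplitude_grade=1)
        img = render_ghost_image(phantom, truth)
        assert abs(estimate_rotation(img) - 4.0) <= 0.5

    def test_annulus_must_fit(self, double_image):
        with pytest.raises(InvalidParameterError):
            estimate_rotation(double_image, center=(10.0, 10.0))


class TestLandmarks:
    def test_vertical_double_recovered(self, vertical_double_image):
        est = match_landmarks(vertical_double_image)
        assert est.n_images == 2
        assert vector_error((est.dx_px, est.dy_px), (0, 20)) <= 2.0

    def test_single_exposure_no_consensus(self, single_image):
        est = match_landmarks(single_image)
        assert (est.dx_px, est.dy_px, est.n_images) == (0.0, 0.0, 1)

    def test_triple_consensus(self, triple_image):
        est = match_landmarks(triple_image)
        assert est.n_images == 3
        assert vector_error((est.dx_px, est.dy_px), (12, 12)) <= 2.0

    def test_insufficient_landmarks(self):
        # a single straight vessel has no bifurcations at all
        canvas = np.full((256, 256), 0.55)
        canvas[:, 126:130] = 0.25
        with pytest.raises(InsufficientLandmarksError):
            match_landmarks(canvas)


class TestDiscGeometry:
    def test_phantom_disc_found(self, phantom, single_image):
        (cx, cy), d = estimate_disc_geometry(single_image)
        tx, ty = phantom.disc_center
        assert math.hypot(cx - tx, cy - ty) <= 5.0
        assert abs(d - phantom.disc_diameter_px) <= 0.15 * phantom.disc_diameter_px

    def test_uniform_image_falls_back_with_warning(self):
        with pytest.warns(UserWarning):
            (_, _), d = estimate_disc_geometry(np.full((256, 256), 0.5))
        assert d == pytest.approx(0.08 * 256)

    def test_double_exposure_disc_near_true_center(self, phantom, double_image):
        (cx, cy), _ = estimate_disc_geometry(double_image)
        tx, ty = phantom.disc_center
        assert math.hypot(cx - tx, cy - ty) <= 0.5 * 24


class TestSklearnInterface:
    @pytest.mark.parametrize(
        "est",
        [
            AutocorrDisplacementEstimator(),
            LandmarkDisplacementEstimator(),
            GhostQuantifier(),
        ],
        ids=["autocorr", "landmark", "quantifier"],
    )
    def test_fit_transform_contract(self, est, double_image):
        est = clone(est)
        params = est.get_params()
        est.set_params(**params)
        out = est.fit([double_image]).transform([double_image])
        assert est.is_fitted_ and est.n_images_in_ == 1
        assert list(out.columns) == ESTIMATE_COLUMNS
        assert len(out) == 1
        assert out.loc[0, "n_images"] == 2

    def test_invalid_params_rejected_at_fit(self, double_image):
        with pytest.raises(InvalidParameterError):
            AutocorrDisplacementEstimator(peak_threshold=1.5).fit([double_image])


class TestCombinedQuantification:
    def test_translation_and_rotation_merged(self, double_image, rotary_image):
        q = quantify_image(double_image)
        assert q.rotation_deg == 0.0 and q.n_images == 2
        q = quantify_image(rotary_image)
        assert q.displacement_px == 0.0
        assert abs(q.rotation_deg - 6.0) <= 0.5
        assert q.n_images == 2  # torsional ghost implies a second copy
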