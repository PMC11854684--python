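"""Ordinal grading of ghost-image measurements.

Maps a :class:`~ghostgrade.quantify.DisplacementEstimate` to the clinical
0-3 amplitude scale (0 = no visible nystagmus, 3 = large amplitude) and to
a direction class in {horizontal, vertical, rotary, combined, undetected}.

Amplitude is normalised by the optic-disc diameter — the standard fundus
yardstick (~1.5 mm) — which removes magnification and resolution
dependence.  The grade cut-points (0.15 and 0.40 disc diameters) and the
direction angle bins (30/60 degrees from horizontal) are configurable
defaults chosen so that the canonical exemplar ladder of small / medium /
large ghost separations is reproduced on matched phantoms; no published
numeric cut-points exist for this scale.

A torsion-only image is graded by the arc length swept at the mid radius of
the measurement annulus, converted to the same disc-diameter scale.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional, Sequence

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import DegenerateInputError, InvalidParameterError
from .images import FundusImage
from .quantify import (
    DISPLACEMENT_FLOOR_PX,
    PEAK_THRESHOLD,
    ROTATION_FLOOR_DEG,
    DisplacementEstimate,
    estimate_disc_geometry,
    quantify_image,
)

#: Grade cut-points in disc diameters: grade 1 below CUT_SMALL, grade 2 in
#: [CUT_SMALL, CUT_LARGE), grade 3 at or above CUT_LARGE.
CUT_SMALL = 0.15
CUT_LARGE = 0.40

#: Direction angle bins (degrees from horizontal, folded to [0, 90]).
ANGLE_HORIZONTAL = 30.0
ANGLE_VERTICAL = 60.0

#: Annulus mid radius as a fraction of the shorter image side; converts a
#: torsional offset to an arc length comparable with linear displacement.
ANNULUS_MID_FRACTION = 0.30

GRADE_COLUMNS = [
    "eye_id",
    "arm",
    "amplitude_grade",
    "direction_class",
    "normalized_displacement",
    "rotation_deg",
]


@dataclasses.dataclass
class PhotoGrade:
    """The ordinal photographic assessment of one eye."""

    eye_id: str
    amplitude_grade: int
    direction_class: str
    arm: str  # "quantitative" or "qualitative"
    normalized_displacement: float  # in disc diameters
    rotation_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude_grade not in (0, 1, 2, 3):
            raise InvalidParameterError("amplitude_grade must be in {0,1,2,3}")
        if (self.amplitude_grade == 0) != (self.direction_class == "undetected"):
            raise InvalidParameterError(
                "grade 0 and direction 'undetected' must coincide"
            )
        if self.normalized_displacement < 0:
            raise InvalidParameterError("normalized_displacement must be >= 0")

    def as_row(self) -> dict:
        return {
            "eye_id": self.eye_id,
            "arm": self.arm,
            "amplitude_grade": self.amplitude_grade,
            "direction_class": self.direction_class,
            "normalized_displacement": self.normalized_displacement,
            "rotation_deg": self.rotation_deg,
        }


def _normalized_amplitude(
    estimate: DisplacementEstimate,
    disc_diameter_px: float,
    displacement_floor: float,
    rotation_floor: float,
    annulus_mid_radius_px: Optional[float],
) -> float:
    """Ghost amplitude in disc diameters: linear offset, or torsional arc."""
    linear = estimate.displacement_px
    if linear >= displacement_floor:
        return linear / disc_diameter_px
    if abs(estimate.rotation_deg) >= rotation_floor:
        if annulus_mid_radius_px is None:
            raise InvalidParameterError(
                "annulus_mid_radius_px is required to grade a torsion-only estimate"
            )
        arc = math.radians(abs(estimate.rotation_deg)) * annulus_mid_radius_px
        return arc / disc_diameter_px
    return 0.0


def amplitude_grade(
    estimate: DisplacementEstimate,
    disc_diameter_px: float,
    cut_small: float = CUT_SMALL,
    cut_large: float = CUT_LARGE,
    displacement_floor: float = DISPLACEMENT_FLOOR_PX,
    rotation_floor: float = ROTATION_FLOOR_DEG,
    annulus_mid_radius_px: Optional[float] = None,
) -> int:
    """Grade the ghost amplitude 0-3 in disc diameters.

    Intervals are half-open, lower-inclusive on the upper bin: a normalised
    displacement exactly at ``cut_small`` grades 2, exactly at ``cut_large``
    grades 3.  Below the detectability floors the grade is 0.
    """
    if disc_diameter_px <= 0:
        raise InvalidParameterError("disc_diameter_px must be positive")
    if not (0 < cut_small < cut_large):
        raise InvalidParameterError("grade cut-points must be positive and ordered")
    d = _normalized_amplitude(
        estimate, disc_diameter_px, displacement_floor, rotation_floor, annulus_mid_radius_px
    )
    if d == 0.0:
        return 0
    if d < cut_small:
        return 1
    if d < cut_large:
        return 2
    return 3


def classify_direction(
    estimate: DisplacementEstimate,
    displacement_floor: float = DISPLACEMENT_FLOOR_PX,
    rotation_floor: float = ROTATION_FLOOR_DEG,
    angle_horizontal: float = ANGLE_HORIZONTAL,
    angle_vertical: float = ANGLE_VERTICAL,
) -> str:
    """Classify the nystagmus direction from the ghost-offset orientation.

    The linear offset angle is folded to [0, 90] degrees from horizontal:
    within ``angle_horizontal`` of the horizontal axis → horizontal, within
    ``90 - angle_vertical`` of the vertical axis → vertical, else combined.
    Torsion above floor with no linear component → rotary; torsion plus a
    linear component → combined (the multi-component class).  Below both
    floors → undetected.
    """
    if not (0 < angle_horizontal <= angle_vertical < 90):
        raise InvalidParameterError("angle bins must satisfy 0 < low <= high < 90")
    linear = estimate.displacement_px >= displacement_floor
    rotary = abs(estimate.rotation_deg) >= rotation_floor
    if not linear and not rotary:
        return "undetected"
    if not linear:
        return "rotary"
    alpha = math.degrees(math.atan2(abs(estimate.dy_px), abs(estimate.dx_px)))
    if rotary:
        return "combined"
    if alpha <= angle_horizontal:
        return "horizontal"
    if alpha >= angle_vertical:
        return "vertical"
    return "combined"


def grade_estimate(
    estimate: DisplacementEstimate,
    disc_diameter_px: float,
    arm: str = "quantitative",
    annulus_mid_radius_px: Optional[float] = None,
    cut_small: float = CUT_SMALL,
    cut_large: float = CUT_LARGE,
    displacement_floor: float = DISPLACEMENT_FLOOR_PX,
    rotation_floor: float = ROTATION_FLOOR_DEG,
    angle_horizontal: float = ANGLE_HORIZONTAL,
    angle_vertical: float = ANGLE_VERTICAL,
) -> PhotoGrade:
    """Combine amplitude grading and direction classification for one eye."""
    grade = amplitude_grade(
        estimate,
        disc_diameter_px,
        cut_small=cut_small,
        cut_large=cut_large,
        displacement_floor=displacement_floor,
        rotation_floor=rotation_floor,
        annulus_mid_radius_px=annulus_mid_radius_px,
    )
    direction = classify_direction(
        estimate,
        displacement_floor=displacement_floor,
        rotation_floor=rotation_floor,
        angle_horizontal=angle_horizontal,
        angle_vertical=angle_vertical,
    )
    if grade == 0:
        direction = "undetected"
    elif direction == "undetected":
        grade = 0
    d = _normalized_amplitude(
        estimate, disc_diameter_px, displacement_floor, rotation_floor, annulus_mid_radius_px
    )
    return PhotoGrade(
        eye_id=estimate.eye_id,
        amplitude_grade=grade,
        direction_class=direction,
        arm=arm,
        normalized_displacement=d,
        rotation_deg=estimate.rotation_deg,
    )


def qualitative_emulation(
    image: FundusImage,
    disc_diameter_px: Optional[float] = None,
    peak_threshold: float = 0.15,
    threshold_scale: float = 0.8,
    cut_small: float = CUT_SMALL,
    cut_large: float = CUT_LARGE,
) -> PhotoGrade:
    """Emulate a by-eye grader: coarser detection, biased cut-points.

    Runs the quantitative estimator without sub-pixel refinement at a lower
    peak threshold, and scales the grade cut-points by ``threshold_scale``
    (default 0.8, i.e. 20% lower): a by-eye grader saturates earlier, which
    reproduces the tendency of qualitative assessment to assign the large
    grade more often than pixel measurement does.
    """
    est = quantify_image(
        image,
        peak_threshold=peak_threshold,
        subpixel=False,
    )
    if disc_diameter_px is None:
        if image.disc_diameter_px is not None:
            disc_diameter_px = image.disc_diameter_px
        else:
            _, disc_diameter_px = estimate_disc_geometry(image)
    r_mid = ANNULUS_MID_FRACTION * min(image.shape)
    return grade_estimate(
        est,
        disc_diameter_px,
        arm="qualitative",
        annulus_mid_radius_px=r_mid,
        cut_small=threshold_scale * cut_small,
        cut_large=threshold_scale * cut_large,
    )


def quantitative_grade(
    image: FundusImage,
    disc_diameter_px: Optional[float] = None,
    **params,
) -> PhotoGrade:
    """Full quantitative arm on one image: measure, normalise, grade."""
    est = quantify_image(image)
    if disc_diameter_px is None:
        if image.disc_diameter_px is not None:
            disc_diameter_px = image.disc_diameter_px
        else:
            _, disc_diameter_px = estimate_disc_geometry(image)
    r_mid = ANNULUS_MID_FRACTION * min(image.shape)
    return grade_estimate(
        est, disc_diameter_px, arm="quantitative", annulus_mid_radius_px=r_mid, **params
    )


class PhotoGrader(BaseEstimator, TransformerMixin):
    """Sklearn-style grader: images in, tidy grade table out.

    Parameters mirror the grading defaults; ``arm`` selects the
    quantitative pipeline or the qualitative emulation.  ``transform``
    accepts a sequence of :class:`FundusImage` and returns a DataFrame with
    columns ``eye_id, arm, amplitude_grade, direction_class,
    normalized_displacement, rotation_deg``.
    """

    def __init__(
        self,
        arm: str = "quantitative",
        cut_small: float = CUT_SMALL,
        cut_large: float = CUT_LARGE,
        angle_horizontal: float = ANGLE_HORIZONTAL,
        angle_vertical: float = ANGLE_VERTICAL,
    ):
        self.arm = arm
        self.cut_small = cut_small
        self.cut_large = cut_large
        self.angle_horizontal = angle_horizontal
        self.angle_vertical = angle_vertical

    def fit(self, X: Sequence[FundusImage], y=None) -> "PhotoGrader":
        if self.arm not in ("quantitative", "qualitative"):
            raise InvalidParameterError("arm must be quantitative or qualitative")
        if not (0 < self.cut_small < self.cut_large):
            raise InvalidParameterError("grade cut-points must be positive and ordered")
        self.n_images_in_ = len(X)
        self.is_fitted_ = True
        return self

    def _grade_one(self, image: FundusImage) -> PhotoGrade:
        if self.arm == "qualitative":
            return qualitative_emulation(
                image, cut_small=self.cut_small, cut_large=self.cut_large
            )
        return quantitative_grade(
            image,
            cut_small=self.cut_small,
            cut_large=self.cut_large,
            angle_horizontal=self.angle_horizontal,
            angle_vertical=self.angle_vertical,
        )

    def transform(self, X: Sequence[FundusImage]) -> pd.DataFrame:
        rows = [self._grade_one(img).as_row() for img in X]
        return pd.DataFrame(rows, columns=GRADE_COLUMNS)
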