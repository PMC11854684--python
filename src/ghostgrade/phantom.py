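"""Synthetic fundus photographs with controlled ghost-image structure.

The study conditions this generator emulates: a non-mydriatic fundus
photograph of an eye with nystagmus shows the retina duplicated into two
or three discrete "ghost" copies, because the eye dwells at distinct
foveation positions during the (milliseconds) exposure.  The composite is
modelled as an exposure-weighted sum of rigidly transformed copies of a
still retina — discrete foveation positions, not continuous motion blur.

A phantom retina consists of a bright optic disc, a darker macula at the
fixation centre, and a dark random binary-branching vessel tree rooted at
the disc with monotonically decreasing caliber; vessel bifurcations are the
anatomical landmarks the landmark-matching estimator relies on.

Torsional (rotary) nystagmus rotates the globe about the line of sight, so
rotation is applied about the macula (fixation) centre, which is placed at
the canvas centre.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage.draw import polygon
from skimage.transform import rotate as _sk_rotate

from .errors import InvalidParameterError, OutOfBoundsError
from .images import FundusImage

# Direction classes as recorded clinically / photographically.
DIRECTION_CLASSES = ("horizontal", "vertical", "rotary", "combined")
#: Truth classes add "none": an eye whose photograph shows no ghost (e.g.
#: latent nystagmus photographed with both eyes open).
TRUTH_CLASSES = DIRECTION_CLASSES + ("none",)

#: Default direction mix, anchored to the photographic (quantitative)
#: direction distribution of the study cohort: 17 horizontal, 3 vertical,
#: 4 rotary, 11 combined, 18 with no ghost, of 53 eyes.
DEFAULT_DIRECTION_MIX: Dict[str, float] = {
    "horizontal": 17 / 53,
    "vertical": 3 / 53,
    "rotary": 4 / 53,
    "combined": 11 / 53,
    "none": 18 / 53,
}

#: Amplitude-grade distribution among detected eyes (quantitative arm:
#: 5 small, 12 medium, 17 large of 34 graded eyes).
DEFAULT_GRADE_MIX: Dict[int, float] = {1: 5 / 34, 2: 12 / 34, 3: 17 / 34}

#: Normalised-displacement sampling band per grade, in disc diameters.
#: Bands sit >= 10% away from the grade cut-points (0.15, 0.40) so that a
#: noise-free eye is always recoverable to its generating grade.
GRADE_BANDS: Dict[int, Tuple[float, float]] = {
    1: (0.110, 0.135),
    2: (0.165, 0.360),
    3: (0.440, 0.700),
}

#: Detectability floors (see quantify): below these an image reads as a
#: single exposure.
DISPLACEMENT_FLOOR_PX = 3.0
ROTATION_FLOOR_DEG = 1.5

#: Fraction of the canvas width occupied by the optic disc (≈11% matches a
#: 45-degree-field fundus photograph where the ~1.5 mm disc spans ~11% of
#: the ~13.5 mm field).
DISC_FRACTION = 0.11

#: Annulus used for torsion estimation; its mid radius converts rotation
#: to an arc length comparable with linear displacement.
ANNULUS_MID_FRACTION = 0.30

DEFAULT_BRANCHING: Dict[str, float | int | tuple] = {
    "n_trunks": 5,
    "initial_width": 4.5,
    "width_decay": 0.78,
    "segment_length": (28.0, 52.0),
    "branch_angle": (18.0, 38.0),
    "max_depth": 5,
    "jitter_deg": 9.0,
    "darkness": 0.32,
}


@dataclasses.dataclass
class VesselPhantom:
    """A synthetic still retina: canvas in [0,1] plus geometry and landmarks."""

    canvas: np.ndarray
    disc_center: Tuple[float, float]  # (x, y)
    disc_diameter_px: float
    macula_center: Tuple[float, float]  # (x, y) — fixation centre
    seed: int
    bifurcations: np.ndarray = dataclasses.field(default_factory=lambda: np.empty((0, 2)))

    def __post_init__(self) -> None:
        c = np.asarray(self.canvas, dtype=float)
        if c.min() < -1e-9 or c.max() > 1 + 1e-9:
            raise InvalidParameterError("canvas intensities must lie in [0, 1]")
        self.canvas = np.clip(c, 0.0, 1.0)
        if self.disc_diameter_px <= 0:
            raise InvalidParameterError("disc_diameter_px must be positive")
        h, w = self.canvas.shape
        x, y = self.disc_center
        r = self.disc_diameter_px / 2.0
        if not (r <= x <= w - r and r <= y <= h - r):
            raise InvalidParameterError("optic disc must lie fully inside the canvas")


@dataclasses.dataclass
class TrajectoryTruth:
    """Ground-truth nystagmus parameters behind one synthetic photograph.

    ``displacement_px`` is the adjacent-copy offset ``(dx, dy)`` in image
    coordinates; ``rotation_deg`` is the adjacent-copy torsion about the
    fixation centre (counterclockwise positive).  ``n_images`` is the number
    of discrete foveation copies (1, 2 or 3); ``exposure_weights`` are their
    relative dwell times and must sum to 1.
    """

    direction_class: str
    displacement_px: Tuple[float, float] = (0.0, 0.0)
    rotation_deg: float = 0.0
    n_images: int = 1
    exposure_weights: Tuple[float, ...] = (1.0,)
    noise_sigma: float = 0.0
    amplitude_grade: int = 0  # generating grade (0 for class "none")
    eye_id: str = ""

    def validate(self) -> None:
        if self.direction_class not in TRUTH_CLASSES:
            raise InvalidParameterError(f"unknown direction class {self.direction_class!r}")
        if self.n_images not in (1, 2, 3):
            raise InvalidParameterError("n_images must be 1, 2 or 3")
        w = np.asarray(self.exposure_weights, dtype=float)
        if len(w) != self.n_images:
            raise InvalidParameterError("exposure_weights length must equal n_images")
        if np.any(w < 0):
            raise InvalidParameterError("exposure_weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise InvalidParameterError("exposure_weights must sum to 1 (within 1e-9)")
        if self.noise_sigma < 0:
            raise InvalidParameterError("noise_sigma must be nonnegative")
        mag = math.hypot(*self.displacement_px)
        undetectable = (
            mag < DISPLACEMENT_FLOOR_PX
            and abs(self.rotation_deg) < ROTATION_FLOOR_DEG
            and self.n_images == 1
        )
        if (self.direction_class == "none") != undetectable:
            raise InvalidParameterError(
                "direction_class 'none' must coincide with sub-floor displacement, "
                "sub-floor rotation and n_images == 1"
            )


@dataclasses.dataclass
class SyntheticClinicalRecord:
    """A clinician's record for one eye: direction class and amplitude 1-3.

    Clinical examination always detects the nystagmus (inclusion criterion of
    the emulated study), so the amplitude is never 0.
    """

    eye_id: str
    clinical_direction: str
    clinical_amplitude: int

    def __post_init__(self) -> None:
        if self.clinical_direction not in DIRECTION_CLASSES:
            raise InvalidParameterError(
                f"clinical_direction must be one of {DIRECTION_CLASSES}"
            )
        if self.clinical_amplitude not in (1, 2, 3):
            raise InvalidParameterError("clinical_amplitude must be 1, 2 or 3")


# ---------------------------------------------------------------------------
# Phantom generation


def _draw_segment(mask: np.ndarray, p0: np.ndarray, p1: np.ndarray, width: float) -> None:
    """Rasterise a thick line segment into a boolean mask."""
    d = p1 - p0
    n = np.array([-d[1], d[0]])
    norm = np.hypot(*n)
    if norm == 0:
        return
    n = n / norm * max(width, 1.0) / 2.0
    corners = np.array([p0 + n, p1 + n, p1 - n, p0 - n])
    rr, cc = polygon(corners[:, 1], corners[:, 0], shape=mask.shape)
    mask[rr, cc] = True


def generate_vessel_phantom(
    size_px: Tuple[int, int] = (512, 512),
    seed: int = 0,
    branching: Optional[Dict] = None,
) -> VesselPhantom:
    """Generate a synthetic still retina.

    Parameters
    ----------
    size_px:
        Canvas size as ``(height, width)``; both must be >= 256 so the disc
        and the torsion annulus fit.
    seed:
        Seeds every random draw; identical ``(size_px, seed, branching)``
        yield a bit-identical canvas.
    branching:
        Overrides for :data:`DEFAULT_BRANCHING` (trunk count, initial vessel
        width in px, per-branch width decay, segment length range, branch
        half-angle range in degrees, maximum depth, angular jitter,
        vessel darkness).

    Returns
    -------
    VesselPhantom
        With a bright disc, darker macula at the canvas centre, and a dark
        binary-branching vessel tree with at least 10 bifurcations.
    """
    h, w = int(size_px[0]), int(size_px[1])
    if h < 256 or w < 256:
        raise InvalidParameterError("canvas must be at least 256x256 to contain the disc")
    params = dict(DEFAULT_BRANCHING)
    if branching:
        params.update(branching)
    for key in ("n_trunks", "initial_width", "width_decay", "max_depth", "darkness"):
        if not params[key] or params[key] <= 0:  # type: ignore[operator]
            raise InvalidParameterError(f"branching parameter {key!r} must be positive")

    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    cx, cy = w / 2.0, h / 2.0

    # Gentle vignetted background.
    rnorm = np.hypot(xx - cx, yy - cy) / math.hypot(cx, cy)
    canvas = 0.52 - 0.18 * rnorm**2

    # Bright optic disc, nasal to the fixation centre.
    disc_d = DISC_FRACTION * w
    disc_x, disc_y = 0.28 * w, 0.5 * h
    rd = np.hypot(xx - disc_x, yy - disc_y) / (disc_d / 2.0)
    canvas += 0.34 * np.exp(-(rd**4))

    # Darker macula at the fixation centre.
    rm = np.hypot(xx - cx, yy - cy) / (0.45 * disc_d)
    canvas -= 0.10 * np.exp(-(rm**2))

    # Random binary-branching vessel tree rooted at the disc.
    mask = np.zeros((h, w), dtype=bool)
    bifurcations: List[Tuple[float, float]] = []
    seg_lo, seg_hi = params["segment_length"]  # type: ignore[misc]
    ang_lo, ang_hi = params["branch_angle"]  # type: ignore[misc]
    jitter = float(params["jitter_deg"])  # type: ignore[arg-type]
    margin = 10.0

    trunk_base = rng.uniform(0, 360)
    stack: List[Tuple[np.ndarray, float, float, int]] = []
    n_trunks = int(params["n_trunks"])  # type: ignore[arg-type]
    for k in range(n_trunks):
        ang = trunk_base + 360.0 * k / n_trunks + rng.uniform(-15, 15)
        start = np.array([disc_x, disc_y]) + (disc_d / 2.2) * np.array(
            [math.cos(math.radians(ang)), math.sin(math.radians(ang))]
        )
        stack.append((start, ang, float(params["initial_width"]), 0))  # type: ignore[arg-type]

    while stack:
        pos, ang, width, depth = stack.pop()
        length = rng.uniform(seg_lo, seg_hi)
        ang = ang + rng.uniform(-jitter, jitter)
        end = pos + length * np.array(
            [math.cos(math.radians(ang)), math.sin(math.radians(ang))]
        )
        if not (margin <= end[0] <= w - margin and margin <= end[1] <= h - margin):
            continue
        _draw_segment(mask, pos, end, width)
        child_w = width * float(params["width_decay"])  # type: ignore[arg-type]
        if depth < int(params["max_depth"]) and child_w >= 1.0:  # type: ignore[arg-type]
            half = rng.uniform(ang_lo, ang_hi)
            bifurcations.append((end[0], end[1]))
            stack.append((end, ang + half, child_w, depth + 1))
            stack.append((end, ang - half, child_w, depth + 1))

    vessels = ndimage.gaussian_filter(mask.astype(float), 0.8)
    canvas -= float(params["darkness"]) * vessels  # type: ignore[arg-type]
    canvas = np.clip(canvas, 0.0, 1.0)

    return VesselPhantom(
        canvas=canvas,
        disc_center=(disc_x, disc_y),
        disc_diameter_px=disc_d,
        macula_center=(cx, cy),
        seed=seed,
        bifurcations=np.asarray(bifurcations, dtype=float),
    )


# ---------------------------------------------------------------------------
# Ghost-image rendering


def render_ghost_image(
    phantom: VesselPhantom,
    truth: TrajectoryTruth,
    noise_seed: int = 0,
    max_offset_fraction: float = 0.1,
) -> FundusImage:
    """Compose a ghost image as an exposure-weighted sum of transformed copies.

    Copies are placed symmetrically about the original position: copy *i*
    (of *n*) is displaced by ``(i - (n-1)/2) * (dx, dy)`` and rotated by
    ``(i - (n-1)/2) * rotation_deg`` about the macula centre, so adjacent
    copies are exactly ``(dx, dy)`` and ``rotation_deg`` apart.  Gaussian
    pixel noise of standard deviation ``noise_sigma`` is added and the
    result is clipped to ``[0, 1]``.
    """
    truth.validate()
    h, w = phantom.canvas.shape
    n = truth.n_images
    dx, dy = truth.displacement_px
    positions = [i - (n - 1) / 2.0 for i in range(n)]
    max_p = max(abs(p) for p in positions)
    if max_p * abs(dx) > max_offset_fraction * w or max_p * abs(dy) > max_offset_fraction * h:
        raise OutOfBoundsError(
            "displacement pushes a ghost copy more than "
            f"{max_offset_fraction:.0%} off-canvas"
        )

    out = np.zeros_like(phantom.canvas)
    for p, weight in zip(positions, truth.exposure_weights):
        copy = phantom.canvas
        if p != 0 and truth.rotation_deg != 0:
            copy = _sk_rotate(
                copy,
                angle=p * truth.rotation_deg,
                center=phantom.macula_center,
                order=1,
                mode="edge",
                preserve_range=True,
            )
        if p != 0 and (dx != 0 or dy != 0):
            copy = ndimage.shift(copy, shift=(p * dy, p * dx), order=1, mode="nearest")
        out = out + weight * copy

    if truth.noise_sigma > 0:
        rng = np.random.default_rng(noise_seed)
        out = out + rng.normal(0.0, truth.noise_sigma, size=out.shape)

    return FundusImage(
        pixels=np.clip(out, 0.0, 1.0),
        disc_center=phantom.disc_center,
        disc_diameter_px=phantom.disc_diameter_px,
        eye_id=truth.eye_id,
    )


# ---------------------------------------------------------------------------
# Cohort simulation


def _validate_mix(mix: Dict[str, float]) -> None:
    missing = set(TRUTH_CLASSES) - set(mix)
    if missing:
        raise InvalidParameterError(f"class mix omits required classes: {sorted(missing)}")
    total = sum(mix[c] for c in TRUTH_CLASSES)
    if abs(total - 1.0) > 1e-6:
        raise InvalidParameterError("class-mix proportions must sum to 1")
    if any(mix[c] < 0 for c in TRUTH_CLASSES):
        raise InvalidParameterError("class-mix proportions must be nonnegative")


def _linear_class_of(dx: float, dy: float) -> str:
    """Direction class of a pure linear offset (axis bins 30/60 degrees)."""
    if dx == 0 and dy == 0:
        return "horizontal"
    alpha = math.degrees(math.atan2(abs(dy), abs(dx)))
    if alpha <= 30:
        return "horizontal"
    if alpha >= 60:
        return "vertical"
    return "combined"


def sample_cohort(
    n_eyes: int,
    seed: int,
    mix: Optional[Dict[str, float]] = None,
    grade_mix: Optional[Dict[int, float]] = None,
    p_over: float = 0.2,
    p_missrot: float = 0.5,
    noise_sigma: float = 0.01,
    image_size: Tuple[int, int] = (512, 512),
) -> Tuple[List[TrajectoryTruth], List[SyntheticClinicalRecord]]:
    """Draw ground-truth trajectories and noisy clinical records (no rendering).

    The clinician-noise model encodes the study's stated discrepancies:
    with probability ``p_over`` the clinical amplitude exceeds the true
    grade by 1 (capped at 3) — clinicians tend to overestimate amplitude —
    and with probability ``p_missrot`` a true torsional component is
    recorded as its linear projection (torsion is under-called at the
    slit lamp relative to the photograph).  Eyes of true class "none"
    (no ghost on the photograph, e.g. latent nystagmus) are still recorded
    clinically as small horizontal nystagmus.
    """
    if n_eyes < 1:
        raise InvalidParameterError("n_eyes must be >= 1")
    if not (0 <= p_over <= 1 and 0 <= p_missrot <= 1):
        raise InvalidParameterError("noise probabilities must lie in [0, 1]")
    mix = dict(DEFAULT_DIRECTION_MIX) if mix is None else dict(mix)
    _validate_mix(mix)
    grade_mix = dict(DEFAULT_GRADE_MIX) if grade_mix is None else dict(grade_mix)
    if abs(sum(grade_mix.values()) - 1.0) > 1e-6:
        raise InvalidParameterError("grade-mix proportions must sum to 1")

    h, w = image_size
    disc_d = DISC_FRACTION * w
    r_mid = ANNULUS_MID_FRACTION * min(h, w)
    rng = np.random.default_rng(seed)
    classes = list(TRUTH_CLASSES)
    class_p = np.array([mix[c] for c in classes])
    grades = sorted(grade_mix)
    grade_p = np.array([grade_mix[g] for g in grades])

    truths: List[TrajectoryTruth] = []
    records: List[SyntheticClinicalRecord] = []
    for i in range(n_eyes):
        eye_id = f"eye{i:04d}"
        cls = classes[rng.choice(len(classes), p=class_p)]
        if cls == "none":
            truth = TrajectoryTruth(
                direction_class="none",
                displacement_px=(0.0, 0.0),
                rotation_deg=0.0,
                n_images=1,
                exposure_weights=(1.0,),
                noise_sigma=noise_sigma,
                amplitude_grade=0,
                eye_id=eye_id,
            )
            has_rot = False
            dx = dy = 0.0
            clin_dir, clin_amp = "horizontal", 1
        else:
            g = int(grades[rng.choice(len(grades), p=grade_p)])
            d_norm = rng.uniform(*GRADE_BANDS[g])
            has_rot = False
            dx = dy = 0.0
            rot = 0.0
            if cls == "rotary":
                # all amplitude carried by torsion: arc at the annulus mid
                # radius equals the grade-band displacement.
                rot = math.degrees(d_norm * disc_d / r_mid)
                has_rot = True
            else:
                if cls == "horizontal":
                    theta = math.radians(rng.uniform(-18, 18))
                elif cls == "vertical":
                    theta = math.radians(90 + rng.uniform(-18, 18))
                else:  # combined: diagonal linear (multidirectional) offset
                    theta = math.radians(45 + rng.uniform(-8, 8))
                mag = d_norm * disc_d
                dx, dy = mag * math.cos(theta), mag * math.sin(theta)
            n_images = int(rng.choice((2, 3), p=(0.7, 0.3)))
            weights = tuple([1.0 / n_images] * n_images)
            truth = TrajectoryTruth(
                direction_class=cls,
                displacement_px=(dx, dy),
                rotation_deg=rot,
                n_images=n_images,
                exposure_weights=weights,
                noise_sigma=noise_sigma,
                amplitude_grade=g,
                eye_id=eye_id,
            )
            clin_dir = cls
            clin_amp = g
        # clinical direction: drop a torsional component with p_missrot
        u_missrot, u_over = rng.random(), rng.random()
        if has_rot and u_missrot < p_missrot:
            clin_dir = _linear_class_of(dx, dy)
        if truth.amplitude_grade > 0 and u_over < p_over:
            clin_amp = min(3, truth.amplitude_grade + 1)
        truths.append(truth)
        records.append(
            SyntheticClinicalRecord(
                eye_id=eye_id, clinical_direction=clin_dir, clinical_amplitude=clin_amp
            )
        )
    return truths, records


def generate_cohort(
    n_eyes: int,
    seed: int,
    mix: Optional[Dict[str, float]] = None,
    image_size: Tuple[int, int] = (512, 512),
    **kwargs,
) -> Tuple[List[FundusImage], List[TrajectoryTruth], List[SyntheticClinicalRecord]]:
    """Sample a cohort and render one ghost image per eye.

    Fully deterministic in ``(seed, parameters)``: the cohort draw, the
    per-eye phantom seeds and the per-eye noise seeds all derive from
    ``seed``.
    """
    truths, records = sample_cohort(
        n_eyes, seed, mix=mix, image_size=image_size, **kwargs
    )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xFD]))
    images: List[FundusImage] = []
    for truth in truths:
        phantom_seed = int(rng.integers(0, 2**31 - 1))
        noise_seed = int(rng.integers(0, 2**31 - 1))
        phantom = generate_vessel_phantom(image_size, seed=phantom_seed)
        images.append(render_ghost_image(phantom, truth, noise_seed=noise_seed))
    return images, truths, records
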