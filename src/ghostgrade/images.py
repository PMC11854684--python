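"""Fundus image container and raster I/O.

All measurements in the package are made on :class:`FundusImage`, a 2-D
intensity grid in ``[0, 1]`` plus the pixel geometry needed to normalise
displacements (optic-disc centre and diameter).  Coordinates follow the
image convention: origin top-left, 0-based, ``x`` rightward (columns),
``y`` downward (rows).  Angles are in degrees, counterclockwise positive
as the image is displayed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
from PIL import Image

from .errors import InvalidParameterError

#: ITU-R BT.601 luma weights used to collapse RGB input to grayscale.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


@dataclasses.dataclass
class FundusImage:
    """A fundus photograph plus pixel-geometry metadata.

    Parameters
    ----------
    pixels:
        2-D float array with values in ``[0, 1]``.
    disc_center:
        Optic-disc centre as ``(x, y)`` in pixels, if known.
    disc_diameter_px:
        Optic-disc diameter in pixels, if known.  The disc diameter is the
        standard anatomical yardstick (~1.5 mm) used to normalise ghost
        displacement.
    eye_id:
        Identifier used to join photographic and clinical records.
    laterality:
        ``"OD"`` (right), ``"OS"`` (left) or ``"unknown"``.
    session_date:
        ISO-8601 date of acquisition, if known.
    """

    pixels: np.ndarray
    disc_center: Optional[Tuple[float, float]] = None
    disc_diameter_px: Optional[float] = None
    eye_id: str = ""
    laterality: str = "unknown"
    session_date: Optional[str] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise InvalidParameterError("pixels must be a 2-D grayscale array")
        if not np.all(np.isfinite(px)):
            raise InvalidParameterError("pixels must be finite")
        if px.size and (px.min() < -1e-9 or px.max() > 1 + 1e-9):
            raise InvalidParameterError("pixels must lie in [0, 1]")
        self.pixels = np.clip(px, 0.0, 1.0)
        if self.disc_diameter_px is not None and self.disc_diameter_px <= 0:
            raise InvalidParameterError("disc_diameter_px must be positive")
        if self.laterality not in ("OD", "OS", "unknown"):
            raise InvalidParameterError("laterality must be OD, OS or unknown")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape  # (rows, cols)


def to_grayscale(arr: np.ndarray) -> np.ndarray:
    """Collapse an (H, W[, 3|4]) uint8/float array to float grayscale in [0, 1]."""
    a = np.asarray(arr)
    if a.dtype.kind in "ui":
        a = a.astype(float) / np.iinfo(arr.dtype).max
    else:
        a = a.astype(float)
    if a.ndim == 3:
        a = a[..., :3] @ np.asarray(LUMA_WEIGHTS)
    return np.clip(a, 0.0, 1.0)


def load_image(path: str | Path, eye_id: str = "", laterality: str = "unknown") -> FundusImage:
    """Read PNG/TIFF/JPEG into a :class:`FundusImage` (grayscale, [0, 1])."""
    with Image.open(path) as im:
        arr = np.asarray(im)
    gray = to_grayscale(arr)
    name = eye_id or Path(path).stem
    return FundusImage(pixels=gray, eye_id=name, laterality=laterality)


def save_image(image: FundusImage | np.ndarray, path: str | Path) -> None:
    """Write an image as 8-bit grayscale PNG (or other format by extension)."""
    px = image.pixels if isinstance(image, FundusImage) else np.asarray(image, dtype=float)
    u8 = np.clip(np.round(px * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(u8, mode="L").save(path)
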