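"""Per-well fluorescence scoring.

The score of a well is the number of pixels that remain positive after
(1) subtracting a background level estimated as the mean intensity over a
centered rectangle covering a fixed fraction (default 80%) of the image's
height and width, (2) a linear contrast adjustment ``v = v * alpha + beta``,
and (3) thresholding.  The score is a proxy for the reporter-positive
(retinal) projected area of the organoid in the well.

All arithmetic is in floating point on the 0-255 intensity scale; 16-bit
inputs are divided by 257 first so the pixel threshold means the same thing
at both bit depths.  Residuals are clipped below at 0 before contrast and
the contrast output is clipped to [0, 255] (8-bit saturation semantics).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .plate_io import ValidationError, WellImage

__all__ = [
    "ScoringParams",
    "OrganoidScore",
    "estimate_background",
    "apply_pipeline",
    "compute_score",
    "score_to_area_fraction",
]

POSITIVE_VALUE = 255  # mask value for suprathreshold pixels


@dataclass(frozen=True)
class ScoringParams:
    """Tunables of the pixel pipeline.

    rect_fraction : fraction (0, 1] of each image dimension covered by the
        centered background-estimation rectangle (default 0.8).
    alpha : contrast gain (> 0), applied to the background-subtracted value.
    beta : contrast offset, added after the gain.
    pixel_threshold : per-pixel cutoff in (0, 255]; pixels whose adjusted
        value is >= this become positive (255) in the mask.
    """

    rect_fraction: float = 0.8
    alpha: float = 1.0
    beta: float = 0.0
    pixel_threshold: float = 50.0

    def __post_init__(self) -> None:
        if not 0 < self.rect_fraction <= 1:
            raise ValidationError(f"rect_fraction must be in (0,1]: {self.rect_fraction}")
        if self.alpha <= 0:
            raise ValidationError(f"alpha must be > 0: {self.alpha}")
        if not 0 < self.pixel_threshold <= 255:
            raise ValidationError(
                f"pixel_threshold must be in (0,255]: {self.pixel_threshold}"
            )


@dataclass
class OrganoidScore:
    """Per-well scoring result: positive-pixel count plus provenance."""

    plate_id: str
    well_id: str
    score: int
    background: float
    height: int
    width: int
    params_used: ScoringParams = field(default_factory=ScoringParams)
    label: str | None = None

    @property
    def area_px(self) -> int:
        return self.height * self.width

    def __post_init__(self) -> None:
        if not 0 <= self.score <= self.area_px:
            raise ValidationError(
                f"score {self.score} outside [0, {self.area_px}]"
            )


def _rect_dim(dim: int, fraction: float) -> int:
    # round half away from zero, at least one pixel
    return max(1, int(math.floor(fraction * dim + 0.5)))


def _central_rect(pixels: np.ndarray, rect_fraction: float) -> np.ndarray:
    h, w = pixels.shape
    rh, rw = _rect_dim(h, rect_fraction), _rect_dim(w, rect_fraction)
    # when the leftover margin is odd the extra row/column goes bottom/right
    top, left = (h - rh) // 2, (w - rw) // 2
    return pixels[top : top + rh, left : left + rw]


def _to_8bit_scale(image: WellImage) -> np.ndarray:
    arr = np.asarray(image.pixels, dtype=np.float64)
    if image.bit_depth == 16:
        arr = arr / 257.0
    return arr


def estimate_background(image: WellImage, rect_fraction: float = 0.8) -> float:
    """Mean intensity over the centered background rectangle, at native scale.

    The rectangle's dimensions are ``max(1, round(rect_fraction * dim))``
    in each axis, centered; odd leftover margins put the extra row at the
    bottom and the extra column at the right.
    """
    if not 0 < rect_fraction <= 1:
        raise ValidationError(f"rect_fraction must be in (0,1]: {rect_fraction}")
    rect = _central_rect(np.asarray(image.pixels, dtype=np.float64), rect_fraction)
    return float(rect.mean())


def apply_pipeline(image: WellImage, params: ScoringParams) -> np.ndarray:
    """Run background subtraction, contrast and threshold; return the mask.

    The mask has the input's shape with values in {0, 255}: per pixel,
    ``v = clip(p - background, 0, inf); v = clip(v*alpha + beta, 0, 255)``
    and the pixel is positive iff ``v >= pixel_threshold``.
    """
    arr = _to_8bit_scale(image)
    background = _central_rect(arr, params.rect_fraction).mean()
    v = np.clip(arr - background, 0.0, None)
    v = np.clip(v * params.alpha + params.beta, 0.0, 255.0)
    return np.where(v >= params.pixel_threshold, POSITIVE_VALUE, 0).astype(np.uint8)


def compute_score(image: WellImage, params: ScoringParams | None = None) -> OrganoidScore:
    """Score one well: the count of positive pixels in the pipeline mask."""
    if params is None:
        params = ScoringParams()
    arr = _to_8bit_scale(image)
    background = float(_central_rect(arr, params.rect_fraction).mean())
    mask = apply_pipeline(image, params)
    return OrganoidScore(
        plate_id=image.plate_id,
        well_id=image.well_id,
        score=int(np.count_nonzero(mask == POSITIVE_VALUE)),
        background=background,
        height=image.height,
        width=image.width,
        params_used=params,
    )


def score_to_area_fraction(score: int, organoid_area_px: int) -> float:
    """Express a score as a fraction of the organoid's projected area.

    A threshold of a few hundred pixels typically corresponds to ~1% of
    the projected area of an organoid at the default imaging scale.
    Values above 1 are reported as-is (the caller supplied an area smaller
    than the score).
    """
    if organoid_area_px <= 0:
        raise ValidationError(f"organoid_area_px must be positive: {organoid_area_px}")
    if score < 0:
        raise ValidationError(f"score must be non-negative: {score}")
    return score / organoid_area_px
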