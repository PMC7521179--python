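"""Synthetic well images, plates, and labeled score sets with ground truth.

The generator emulates what a widefield fluorescence scan of one organoid
per well looks like: a dim, roughly circular organoid body on a darker
background, with bright reporter-positive patches covering a small fraction
(~1-10%) of the organoid's projected area in positive wells, plus additive
Gaussian noise and an optional smooth background gradient.  Plate-level
generation supports a column-dependent positive probability to emulate
spatial edge effects (e.g. a temperature gradient across the incubator).

Disk rasterization is the "center-in-circle" rule: a pixel belongs to the
disk iff its center satisfies dx^2 + dy^2 <= r^2, so ground-truth areas are
integer-exact and implementation-independent (a radius-5 disk has 81 pixels).

Randomness is reproducible well-by-well: a plate seed spawns one child seed
per well index, so regenerating a plate reproduces every well bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .calibration import NEGATIVE, POSITIVE, LabeledScoreSet
from .plate_io import ALL_WELLS, PlateSet, ValidationError, WellImage

__all__ = [
    "SyntheticWellSpec",
    "GroundTruth",
    "default_positive_spec",
    "default_negative_spec",
    "render_well",
    "sample_plate_labels",
    "generate_plate",
    "sample_scores",
]


@dataclass(frozen=True)
class SyntheticWellSpec:
    """Recipe for one synthetic well image.

    patches: list of ((row, col), radius_px, intensity) for fluorescent
    areas; their centers must lie inside the organoid disk, which is
    centered in the image.  ``gradient`` is an optional (direction,
    amplitude) linear background ramp with direction 'x' (left to right)
    or 'y' (top to bottom), spanning 0..amplitude across the image.
    """

    image_size: tuple[int, int] = (512, 512)
    organoid_radius_px: int = 150
    organoid_intensity: float = 40.0
    patches: tuple = ()
    background_level: float = 10.0
    gradient: tuple[str, float] | None = None
    noise_sd: float = 0.0
    bit_depth: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size
        if self.organoid_radius_px <= 0:
            raise ValidationError("organoid radius must be positive")
        if 2 * self.organoid_radius_px >= min(h, w):
            raise ValidationError("organoid disk must fit within the image")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        for (py, px), radius, _ in self.patches:
            if radius <= 0:
                raise ValidationError("patch radius must be positive")
            if (py - cy) ** 2 + (px - cx) ** 2 > self.organoid_radius_px**2:
                raise ValidationError(
                    f"patch center ({py}, {px}) lies outside the organoid disk"
                )


@dataclass
class GroundTruth:
    """Exact pixel-level truth for one synthetic well."""

    positive_area_px: int
    organoid_area_px: int
    label: str
    seed: int
    well_id: str = ""

    def __post_init__(self) -> None:
        if self.positive_area_px > self.organoid_area_px:
            raise ValidationError("positive area cannot exceed organoid area")


def _disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def default_positive_spec(
    image_size: tuple[int, int] = (512, 512),
    organoid_radius_px: int | None = None,
    noise_sd: float = 3.0,
    patch_intensity: float = 100.0,
) -> SyntheticWellSpec:
    """A positive well at default geometry: two bright patches totalling
    roughly 8% of the organoid's projected area."""
    h, w = image_size
    r = organoid_radius_px if organoid_radius_px is not None else int(0.29 * min(h, w))
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    pr = max(2, round(0.2 * r))
    offset = round(0.45 * r)
    patches = (
        ((cy - offset, cx - offset), pr, patch_intensity),
        ((cy + offset, cx + offset), pr, patch_intensity),
    )
    return SyntheticWellSpec(
        image_size=image_size,
        organoid_radius_px=r,
        patches=patches,
        noise_sd=noise_sd,
    )


def default_negative_spec(
    image_size: tuple[int, int] = (512, 512),
    organoid_radius_px: int | None = None,
    noise_sd: float = 3.0,
) -> SyntheticWellSpec:
    """A negative well: the dim organoid body only, no fluorescent patches."""
    h, w = image_size
    r = organoid_radius_px if organoid_radius_px is not None else int(0.29 * min(h, w))
    return SyntheticWellSpec(
        image_size=image_size, organoid_radius_px=r, noise_sd=noise_sd
    )


def render_well(
    spec: SyntheticWellSpec, plate_id: str = "", well_id: str = "A1"
) -> tuple[WellImage, GroundTruth]:
    """Rasterize one synthetic well; deterministic given ``spec.seed``.

    Pixel value = background (+ gradient) + organoid_intensity inside the
    organoid disk + patch intensity inside each patch + N(0, noise_sd),
    clipped to the bit range.  Ground-truth areas are exact pixel counts
    of the rasterized disks (patch overlaps counted once).
    """
    h, w = spec.image_size
    center = ((h - 1) / 2.0, (w - 1) / 2.0)
    img = np.full((h, w), float(spec.background_level))
    if spec.gradient is not None:
        direction, amplitude = spec.gradient
        if direction == "x":
            ramp = np.linspace(0.0, amplitude, w)[None, :]
        elif direction == "y":
            ramp = np.linspace(0.0, amplitude, h)[:, None]
        else:
            raise ValidationError(f"gradient direction must be 'x' or 'y': {direction}")
        img = img + ramp

    organoid = _disk_mask((h, w), center, spec.organoid_radius_px)
    img[organoid] += spec.organoid_intensity

    patch_union = np.zeros((h, w), dtype=bool)
    for patch_center, radius, intensity in spec.patches:
        m = _disk_mask((h, w), patch_center, radius)
        img[m] += intensity
        patch_union |= m

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd, size=(h, w))

    vmax = 2**spec.bit_depth - 1
    img = np.clip(img, 0.0, vmax)
    well = WellImage(
        pixels=img, bit_depth=spec.bit_depth, plate_id=plate_id, well_id=well_id
    )
    truth = GroundTruth(
        positive_area_px=int(patch_union.sum()),
        organoid_area_px=int(organoid.sum()),
        label=POSITIVE if spec.patches else NEGATIVE,
        seed=spec.seed,
        well_id=well.well_id,
    )
    return well, truth


def _column_rates(
    positive_rate: float, edge_gradient: Sequence[float] | None
) -> np.ndarray:
    if not 0 <= positive_rate <= 1:
        raise ValidationError(f"positive_rate must be in [0,1]: {positive_rate}")
    mult = np.ones(12) if edge_gradient is None else np.asarray(edge_gradient, float)
    if mult.shape != (12,) or (mult < 0).any():
        raise ValidationError("edge_gradient must be 12 non-negative column multipliers")
    return np.clip(positive_rate * mult, 0.0, 1.0)


def sample_plate_labels(
    n_wells: int,
    positive_rate: float,
    edge_gradient: Sequence[float] | None = None,
    seed: int = 0,
) -> dict[str, str]:
    """Draw positive/negative labels for the first ``n_wells`` coordinates.

    Each well is independently positive with its column-adjusted
    probability ``clip(positive_rate * edge_gradient[column], 0, 1)``.
    This is the label layer of :func:`generate_plate`, usable on its own
    for plate-statistics simulations that do not need pixel data.
    """
    if not 1 <= n_wells <= 96:
        raise ValidationError(f"n_wells must be in 1..96: {n_wells}")
    rates = _column_rates(positive_rate, edge_gradient)
    rng = np.random.default_rng(seed)
    labels: dict[str, str] = {}
    for well in ALL_WELLS[:n_wells]:
        col = int(well[1:]) - 1
        labels[well] = POSITIVE if rng.random() < rates[col] else NEGATIVE
    return labels


def generate_plate(
    n_wells: int = 96,
    positive_rate: float = 0.25,
    positive_spec: SyntheticWellSpec | None = None,
    negative_spec: SyntheticWellSpec | None = None,
    edge_gradient: Sequence[float] | None = None,
    seed: int = 0,
    plate_id: str = "SIM1",
) -> tuple[PlateSet, list[GroundTruth]]:
    """Generate a synthetic plate of rendered wells plus its ground truth.

    Positive wells are rendered from ``positive_spec`` (which must carry at
    least one patch), negative wells from ``negative_spec`` (no patches).
    Per-well noise seeds are spawned from ``seed`` by well index, so any
    single well can be reproduced without rendering the whole plate.
    """
    if positive_spec is None:
        positive_spec = default_positive_spec()
    if negative_spec is None:
        negative_spec = default_negative_spec(
            image_size=positive_spec.image_size,
            organoid_radius_px=positive_spec.organoid_radius_px,
            noise_sd=positive_spec.noise_sd,
        )
    if not positive_spec.patches:
        raise ValidationError("positive_spec must have at least one patch")
    if negative_spec.patches:
        raise ValidationError("negative_spec must have no patches")

    labels = sample_plate_labels(n_wells, positive_rate, edge_gradient, seed)
    child_seeds = np.random.SeedSequence(seed).spawn(n_wells)
    wells: dict[str, WellImage] = {}
    truths: list[GroundTruth] = []
    for i, well_id in enumerate(ALL_WELLS[:n_wells]):
        spec = positive_spec if labels[well_id] == POSITIVE else negative_spec
        well_seed = int(child_seeds[i].generate_state(1)[0] % (2**31))
        img, truth = render_well(
            replace(spec, seed=well_seed), plate_id=plate_id, well_id=well_id
        )
        wells[well_id] = img
        truths.append(truth)
    missing = list(ALL_WELLS[n_wells:])
    return PlateSet(plate_id=plate_id, wells=wells, missing_wells=missing), truths


def sample_scores(
    n_pos: int,
    n_neg: int,
    pos_dist: tuple = ("lognormal", 7.0, 0.6),
    neg_dist: tuple = ("lognormal", 4.0, 1.0),
    seed: int = 0,
) -> LabeledScoreSet:
    """Draw a labeled score set from named distribution families.

    Stands in for a manually classified calibration set of a few hundred
    organoids.  Families: ``("lognormal", mu, sigma)`` with median e^mu,
    or ``("gamma", shape, scale)``.  Deterministic given ``seed``.
    """
    if n_pos < 0 or n_neg < 0 or n_pos + n_neg < 1:
        raise ValidationError("need n_pos + n_neg >= 1 with non-negative counts")
    rng = np.random.default_rng(seed)

    def draw(dist: tuple, n: int) -> np.ndarray:
        family, *params = dist
        if family == "lognormal":
            mu, sigma = params
            return rng.lognormal(mu, sigma, size=n)
        if family == "gamma":
            shape, scale = params
            return rng.gamma(shape, scale, size=n)
        raise ValidationError(f"unknown distribution family: {family!r}")

    pos = draw(pos_dist, n_pos)
    neg = draw(neg_dist, n_neg)
    return LabeledScoreSet(
        scores=[float(s) for s in pos] + [float(s) for s in neg],
        labels=[POSITIVE] * n_pos + [NEGATIVE] * n_neg,
        source=f"synthetic(seed={seed})",
    )
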