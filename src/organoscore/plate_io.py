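"""Reading well images and plate manifests; writing tabular results.

A 96-well plate has rows A-H and columns 1-12.  Well IDs are accepted in
both zero-padded (``A01``) and bare (``A1``) form and canonicalized to the
bare form internally, since microscope exporters differ on padding.
Pixel coordinates are 0-based, row-major, origin at the top-left corner.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile
from PIL import Image

__all__ = [
    "WellImage",
    "PlateSet",
    "ROWS",
    "COLUMNS",
    "ALL_WELLS",
    "normalize_well_id",
    "well_to_coords",
    "read_well_image",
    "write_well_image",
    "discover_plate",
    "write_scores",
    "read_scores",
]

ROWS = "ABCDEFGH"
COLUMNS = tuple(range(1, 13))
#: the 96 canonical well IDs in plate-reading order (A1..A12, B1..., H12)
ALL_WELLS = tuple(f"{r}{c}" for r in ROWS for c in COLUMNS)

_WELL_RE = re.compile(r"^([A-Ha-h])(0?[1-9]|1[0-2])$")

_CHANNEL_INDEX = {"red": 0, "green": 1, "blue": 2}


class PlateIOError(IOError):
    """Raised when an image or manifest cannot be read or written."""


class ValidationError(ValueError):
    """Raised when inputs violate a documented precondition."""


def normalize_well_id(well_id: str) -> str:
    """Canonicalize a 96-well ID ('A01' or 'a1' -> 'A1').

    Raises :class:`ValidationError` for anything outside rows A-H /
    columns 1-12.
    """
    m = _WELL_RE.match(well_id.strip())
    if m is None:
        raise ValidationError(f"not a valid 96-well coordinate: {well_id!r}")
    return f"{m.group(1).upper()}{int(m.group(2))}"


def well_to_coords(well_id: str) -> tuple[int, int]:
    """Return the 0-based (row, column) grid indices of a well ID."""
    w = normalize_well_id(well_id)
    return ROWS.index(w[0]), int(w[1:]) - 1


@dataclass
class WellImage:
    """A single-channel intensity image of one well.

    Parameters
    ----------
    pixels : ndarray
        2-D non-negative intensity grid at native bit depth.
    bit_depth : int
        8 or 16; every intensity must lie in ``[0, 2**bit_depth - 1]``.
    plate_id, well_id : str
        Plate identity and a valid 96-well coordinate.
    channel : str
        Free-text channel label (e.g. ``"green"`` for a GFP reporter).
    """

    pixels: np.ndarray
    bit_depth: int
    plate_id: str = ""
    well_id: str = "A1"
    channel: str = "green"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValidationError("pixels must be a non-empty 2-D array")
        if self.bit_depth not in (8, 16):
            raise ValidationError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        lo, hi = self.pixels.min(), self.pixels.max()
        if lo < 0 or hi > 2**self.bit_depth - 1:
            raise ValidationError(
                f"intensities [{lo}, {hi}] outside [0, {2**self.bit_depth - 1}]"
            )
        self.well_id = normalize_well_id(self.well_id)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class PlateSet:
    """All well images found for one plate, plus the coordinates not found."""

    plate_id: str
    wells: dict[str, WellImage] = field(default_factory=dict)
    missing_wells: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        covered = set(self.wells) | set(self.missing_wells)
        if covered != set(ALL_WELLS) or len(self.wells) + len(self.missing_wells) != 96:
            raise ValidationError(
                "wells and missing_wells must partition the 96 coordinates"
            )


def _select_channel(arr: np.ndarray, channel_policy: str) -> np.ndarray:
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        try:
            idx = _CHANNEL_INDEX[channel_policy]
        except KeyError:
            raise ValidationError(
                f"unknown channel policy {channel_policy!r}; expected one of "
                f"{sorted(_CHANNEL_INDEX)}"
            ) from None
        return arr[:, :, idx]
    raise ValidationError(f"unsupported image shape {arr.shape}")


def read_well_image(
    path: str | Path,
    channel_policy: str = "green",
    plate_id: str = "",
    well_id: str = "A1",
) -> WellImage:
    """Read a TIFF or PNG well image as a single-channel :class:`WellImage`.

    RGB inputs are reduced to the configured channel (default green, the
    GFP reporter channel).  Bit depth is taken from the file's dtype.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        elif suffix == ".png":
            arr = np.asarray(Image.open(path))
        else:
            raise PlateIOError(f"unsupported image format: {path}")
    except (OSError, ValueError) as exc:
        raise PlateIOError(f"cannot read image {path}: {exc}") from exc
    if arr.size == 0:
        raise ValidationError(f"zero-sized image: {path}")
    arr = _select_channel(arr, channel_policy)
    bit_depth = 16 if arr.dtype.itemsize >= 2 else 8
    return WellImage(
        pixels=arr,
        bit_depth=bit_depth,
        plate_id=plate_id,
        well_id=well_id,
        channel=channel_policy,
    )


def write_well_image(image: WellImage, path: str | Path) -> None:
    """Write a :class:`WellImage` as grayscale TIFF or PNG at native depth."""
    path = Path(path)
    dtype = np.uint16 if image.bit_depth == 16 else np.uint8
    arr = np.asarray(np.rint(image.pixels), dtype=dtype)
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            tifffile.imwrite(path, arr)
        elif suffix == ".png":
            Image.fromarray(arr).save(path)
        else:
            raise PlateIOError(f"unsupported image format: {path}")
    except OSError as exc:
        raise PlateIOError(f"cannot write image {path}: {exc}") from exc


#: default filename pattern: "{plate}_{well}.{ext}" with ext in tif/tiff/png
DEFAULT_PATTERN = (
    r"^(?P<plate>.+)_(?P<well>[A-Ha-h](?:0?[1-9]|1[0-2]))\.(?:tif|tiff|png)$"
)


def discover_plate(
    directory: str | Path,
    pattern: str = DEFAULT_PATTERN,
    channel_policy: str = "green",
    plate_id: str | None = None,
) -> PlateSet:
    """Scan a folder for well images of one plate.

    ``pattern`` is a regex with named groups ``plate`` and ``well``.
    Every matching file is assigned to its canonical well; two files that
    map to the same well are rejected.  The result is independent of
    directory listing order.  The source path of each image is kept in
    the returned set's ``paths`` attribute.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise PlateIOError(f"not a directory: {directory}")
    rx = re.compile(pattern)
    if "plate" not in rx.groupindex or "well" not in rx.groupindex:
        raise ValidationError("pattern must define named groups 'plate' and 'well'")

    assignments: dict[str, Path] = {}
    plate_ids: set[str] = set()
    for path in sorted(directory.iterdir()):
        m = rx.match(path.name)
        if m is None:
            continue
        pid = m.group("plate")
        if plate_id is not None and pid != plate_id:
            continue
        well = normalize_well_id(m.group("well"))
        if well in assignments:
            raise ValidationError(
                f"well {well} assigned twice: {assignments[well]} and {path}"
            )
        assignments[well] = path
        plate_ids.add(pid)

    if not assignments:
        raise PlateIOError(f"no files matching pattern in {directory}")
    if len(plate_ids) > 1:
        raise ValidationError(
            f"multiple plate IDs in one folder: {sorted(plate_ids)}; "
            "pass plate_id= to select one"
        )
    pid = plate_ids.pop()
    wells: dict[str, WellImage] = {}
    for well, path in assignments.items():
        wells[well] = read_well_image(
            path, channel_policy=channel_policy, plate_id=pid, well_id=well
        )
    missing = [w for w in ALL_WELLS if w not in assignments]
    ps = PlateSet(plate_id=pid, wells=wells, missing_wells=missing)
    ps.paths = dict(assignments)  # type: ignore[attr-defined]
    return ps


_SCORE_FIELDS = ["plate_id", "well_id", "score", "background", "label", "height", "width"]


def _sort_key(record: Mapping[str, object]) -> tuple:
    row, col = well_to_coords(str(record["well_id"]))
    return (str(record["plate_id"]), row, col)


def write_scores(
    results: Sequence,
    path: str | Path,
    labels: Sequence[str] | None = None,
    json_mirror: bool = False,
) -> None:
    """Write per-organoid scores as CSV (one row per well, header always).

    Rows are ordered by (plate, row letter, column number).  ``labels`` is
    an optional parallel list of positive/negative classifications.  With
    ``json_mirror=True`` the same records are also written next to the CSV
    with a ``.json`` extension.
    """
    if labels is not None and len(labels) != len(results):
        raise ValidationError("labels must be parallel to results")
    records = []
    for i, r in enumerate(results):
        records.append(
            {
                "plate_id": r.plate_id,
                "well_id": r.well_id,
                "score": r.score,
                "background": r.background,
                "label": labels[i] if labels is not None else getattr(r, "label", ""),
                "height": r.height,
                "width": r.width,
            }
        )
    records.sort(key=_sort_key)
    path = Path(path)
    try:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=_SCORE_FIELDS)
            writer.writeheader()
            writer.writerows(records)
    except OSError as exc:
        raise PlateIOError(f"cannot write {path}: {exc}") from exc
    if json_mirror:
        path.with_suffix(".json").write_text(json.dumps(records, indent=1))


def read_scores(path: str | Path) -> list[dict]:
    """Re-parse a score CSV written by :func:`write_scores`."""
    out: list[dict] = []
    try:
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                row["score"] = int(row["score"])
                row["background"] = float(row["background"])
                row["height"] = int(row["height"])
                row["width"] = int(row["width"])
                out.append(row)
    except OSError as exc:
        raise PlateIOError(f"cannot read {path}: {exc}") from exc
    return out
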