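"""Reading and writing microscopy images, label masks, and batch file lists.

Bright-field and fluorescence frames arrive either as 8-bit PNGs or as
12/16-bit camera TIFFs.  Twelve-bit data is stored in 16-bit containers by
every major acquisition stack, so it is reported here as ``bit_depth=16``
with the true data maximum recorded separately.  Conversion to 8-bit uses
channel-specific black and white points supplied by the user.

Batch processing is driven by CSV *file lists*: a required ``bf`` column of
image paths and an optional ``mask`` column of paired label-mask paths.
Relative paths are resolved against the CSV's own directory, so lists are
portable across machines.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile


class FormatError(ValueError):
    """Unreadable file or a file whose layout violates a precondition."""


class ValidationError(ValueError):
    """Well-formed input whose content violates an invariant."""


@dataclass
class IntensityImage:
    """A single-channel 2D image with an explicit container bit depth.

    ``pixels`` holds non-negative intensities; ``bit_depth`` is the container
    depth (8 or 16), and ``data_max`` records the observed maximum so that
    12-bit data inside a 16-bit container remains identifiable.
    """

    pixels: np.ndarray
    bit_depth: int
    data_max: int = field(default=0)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValidationError("image must be 2D with positive dimensions")
        if self.bit_depth not in (8, 12, 16):
            raise ValidationError(f"unsupported bit depth {self.bit_depth}")
        if self.pixels.size and self.pixels.min() < 0:
            raise ValidationError("negative intensities")
        if self.pixels.size and self.pixels.max() > 2**self.bit_depth - 1:
            raise ValidationError(
                f"intensity exceeds {self.bit_depth}-bit range"
            )
        if not self.data_max:
            self.data_max = int(self.pixels.max(initial=0))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class FileList:
    """Ordered (image_path, mask_path) pairs; mask paths optional."""

    rows: list[tuple[Path, Path | None]]

    def __post_init__(self) -> None:
        from collections import Counter

        counts = Counter(p for p, _ in self.rows)
        dupes = [p for p, c in counts.items() if c > 1]
        if dupes:
            raise ValidationError(f"duplicate image paths in file list: {sorted(map(str, dupes))}")

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def image_paths(self) -> list[Path]:
        return [p for p, _ in self.rows]

    def mask_paths(self) -> list[Path | None]:
        return [m for _, m in self.rows]


def read_image(path: str | Path) -> IntensityImage:
    """Read a single-channel PNG or TIFF as an :class:`IntensityImage`.

    Bit depth is inferred from the container dtype: uint8 -> 8, uint16 -> 16.
    Multi-channel (RGB/RGBA) files are rejected.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend specific
        raise FormatError(f"cannot read image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected single-channel 2D image, got shape {arr.shape}")
    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    else:
        raise FormatError(f"{path}: unsupported dtype {arr.dtype}")
    return IntensityImage(pixels=arr, bit_depth=depth)


def to_8bit(img: IntensityImage, black_point: float, white_point: float) -> IntensityImage:
    """Linear 8-bit conversion with channel-specific black/white points.

    ``out = round(255 * clip((v - black) / (white - black), 0, 1))``.
    """
    if white_point <= black_point:
        raise ValidationError(
            f"white_point ({white_point}) must exceed black_point ({black_point})"
        )
    v = img.pixels.astype(np.float64)
    scaled = np.clip((v - black_point) / (white_point - black_point), 0.0, 1.0)
    out = np.rint(255.0 * scaled).astype(np.uint8)
    return IntensityImage(pixels=out, bit_depth=8)


def read_file_list(path: str | Path) -> FileList:
    """Parse a CSV file list with columns ``bf`` and optional ``mask``.

    Row order is preserved; relative paths resolve against the CSV's folder.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "bf" not in reader.fieldnames:
            raise FormatError(f"{path}: file list must have a 'bf' column")
        has_mask = "mask" in reader.fieldnames
        base = path.parent
        rows: list[tuple[Path, Path | None]] = []
        for rec in reader:
            img = Path(rec["bf"])
            if not img.is_absolute():
                img = base / img
            mask: Path | None = None
            if has_mask and rec.get("mask"):
                mask = Path(rec["mask"])
                if not mask.is_absolute():
                    mask = base / mask
            rows.append((img, mask))
    return FileList(rows=rows)


def write_file_list(fl: FileList, path: str | Path) -> None:
    """Write a file list CSV (inverse of :func:`read_file_list`)."""
    path = Path(path)
    has_mask = any(m is not None for _, m in fl.rows)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["bf", "mask"] if has_mask else ["bf"])
        for img, mask in fl.rows:
            if has_mask:
                writer.writerow([str(img), "" if mask is None else str(mask)])
            else:
                writer.writerow([str(img)])


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write an integer label mask; PNG for <=255 labels, 16-bit TIFF above.

    Round-trips exactly through :func:`read_image` (label values preserved).
    """
    path = Path(path)
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValidationError("mask must be 2D")
    if mask.min(initial=0) < 0:
        raise ValidationError("labels must be non-negative")
    top = int(mask.max(initial=0))
    if path.suffix.lower() in (".tif", ".tiff"):
        if top > 65535:
            raise FormatError(f"{top} exceeds 16-bit container for {path}")
        tifffile.imwrite(path, mask.astype(np.uint16))
    else:
        if top > 255:
            if top > 65535:
                raise FormatError(f"{top} exceeds 16-bit container for {path}")
            raise FormatError(
                f"{top} labels overflow 8-bit PNG {path}; use a .tif path"
            )
        iio.imwrite(path, mask.astype(np.uint8))


def read_mask(path: str | Path) -> np.ndarray:
    """Read a label mask written by :func:`write_mask` as an integer array."""
    return read_image(path).pixels.astype(np.int64)
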