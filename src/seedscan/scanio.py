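"""Scan image I/O, dpi calibration, and file-name tag parsing.

Scans arrive as TIFF (1-bit or 8-bit grayscale; RGB tolerated) or PNG files
whose names encode collection metadata in an underscore-delimited "tag":

    SITE_TRAP_DATE_SPECIES_FILL_REPn.tif

e.g. ``S05_T12_2019-10-01_TSHE_filled_rep1.tif``.  SPECIES and FILL may be
``NA`` when unknown.  Coordinates follow raster convention: origin at the
top-left pixel corner, x rightward, y downward, 0-based; pixel (row, col)
occupies the unit square [col, col+1) x [row, row+1).
"""

from __future__ import annotations

import datetime as _dt
import os
import re
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import tifffile
from PIL import Image

__all__ = [
    "ScanImage",
    "ScanMetadata",
    "ScanIOError",
    "TagParseError",
    "read_scan",
    "write_scan",
    "parse_tag",
    "pixel_size_mm",
    "DARK_ON_LIGHT",
    "LIGHT_ON_DARK",
]

DARK_ON_LIGHT = "dark_on_light"
LIGHT_ON_DARK = "light_on_dark"

_FILL_VALUES = ("filled", "unfilled", "unknown")


class ScanIOError(ValueError):
    """Raised for unreadable scan files or missing calibration."""


class TagParseError(ValueError):
    """Raised when a file-name tag does not match the documented grammar."""


@dataclass
class ScanImage:
    """A calibrated pixel grid from one scanner pass."""

    pixels: np.ndarray  # 2-D integer array, values in 0..255 or {0,1}
    dpi: float = 600.0
    polarity: str = DARK_ON_LIGHT
    source_tag: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ScanIOError("pixels must be a non-empty 2-D array")
        if self.dpi <= 0:
            raise ScanIOError(f"dpi must be positive, got {self.dpi}")
        if self.polarity not in (DARK_ON_LIGHT, LIGHT_ON_DARK):
            raise ScanIOError(f"unknown polarity {self.polarity!r}")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ScanIOError("intensities must lie in [0, 255]")

    @property
    def height_px(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width_px(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def is_binary(self) -> bool:
        vals = np.unique(self.pixels)
        return np.isin(vals, (0, 1)).all() or np.isin(vals, (0, 255)).all()

    def pixel_size_mm(self) -> float:
        return pixel_size_mm(self.dpi)


@dataclass
class ScanMetadata:
    """Collection metadata parsed from a scan file-name tag."""

    site: str
    trap_id: str = "NA"
    collection_date: Optional[_dt.date] = None
    species_label: Optional[str] = None
    fill_status: str = "unknown"
    replicate_index: int = 1
    source_tag: str = ""

    def __post_init__(self) -> None:
        if not self.site:
            raise TagParseError("site must be non-empty")
        if self.replicate_index < 1:
            raise TagParseError("replicate_index must be >= 1")

    @property
    def batch_id(self) -> str:
        """Identity of the physical seed batch: site+trap+date+fill."""
        date = self.collection_date.isoformat() if self.collection_date else "NA"
        return f"{self.site}_{self.trap_id}_{date}_{self.fill_status}"


def pixel_size_mm(dpi: float) -> float:
    """Side length of one pixel in millimetres: 25.4 / dpi."""
    if dpi <= 0:
        raise ValueError(f"dpi must be positive, got {dpi}")
    return 25.4 / dpi


def _luminance(arr: np.ndarray) -> np.ndarray:
    # ITU-R 601 weights, rounded to nearest integer intensity
    lum = 0.299 * arr[..., 0] + 0.587 * arr[..., 1] + 0.114 * arr[..., 2]
    return np.rint(lum).astype(np.uint8)


def _tiff_dpi(page: "tifffile.TiffPage") -> Optional[float]:
    tags = page.tags
    if "XResolution" not in tags:
        return None
    num, den = tags["XResolution"].value
    if den == 0 or num == 0:
        return None
    res = num / den
    unit = tags["ResolutionUnit"].value if "ResolutionUnit" in tags else 2
    unit = getattr(unit, "value", unit)
    if unit == 1:  # "no absolute unit" — resolution tag is meaningless
        return None
    if unit == 3:  # pixels per centimetre
        res *= 2.54
    return float(res)


def read_scan(
    path: str | os.PathLike,
    dpi_override: Optional[float] = None,
    polarity: str = DARK_ON_LIGHT,
) -> ScanImage:
    """Read a TIFF or PNG scan into a :class:`ScanImage`.

    dpi precedence: ``dpi_override`` if given, else embedded resolution
    metadata.  1-bit images are promoted to {0, 1}; RGB is converted to
    luminance.  Missing dpi with no override raises :class:`ScanIOError`.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise ScanIOError(f"scan file not found: {path}")
    ext = os.path.splitext(path)[1].lower()
    dpi_meta: Optional[float] = None
    try:
        if ext in (".tif", ".tiff"):
            with tifffile.TiffFile(path) as tf:
                page = tf.pages[0]
                arr = page.asarray()
                dpi_meta = _tiff_dpi(page)
        else:
            with Image.open(path) as im:
                info_dpi = im.info.get("dpi")
                if info_dpi and info_dpi[0]:
                    dpi_meta = float(info_dpi[0])
                arr = np.asarray(im)
    except ScanIOError:
        raise
    except Exception as exc:  # noqa: BLE001 - wrap decoder errors uniformly
        raise ScanIOError(f"could not decode scan {path}: {exc}") from exc

    if arr.ndim == 3:
        arr = _luminance(arr)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    arr = np.ascontiguousarray(arr)

    dpi = dpi_override if dpi_override is not None else dpi_meta
    if dpi is None:
        raise ScanIOError(
            f"no dpi metadata in {path} and no dpi_override given"
        )
    return ScanImage(
        pixels=arr,
        dpi=float(dpi),
        polarity=polarity,
        source_tag=os.path.basename(path),
    )


def write_scan(image: ScanImage, path: str | os.PathLike) -> None:
    """Write a scan as TIFF (or PNG) preserving pixel values and dpi."""
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    arr = image.pixels.astype(np.uint8)
    if ext in (".tif", ".tiff"):
        tifffile.imwrite(
            path,
            arr,
            resolution=(image.dpi, image.dpi),
            resolutionunit="INCH",
        )
    else:
        im = Image.fromarray(arr)
        im.save(path, dpi=(image.dpi, image.dpi))


_TAG_RE = re.compile(
    r"^(?P<site>[^_]+)_(?P<trap>[^_]+)_(?P<date>\d{4}-\d{2}-\d{2})"
    r"_(?P<species>[^_]+)_(?P<fill>[^_]+)_rep(?P<rep>\d+)$"
)

_GRAMMAR = "SITE_TRAP_DATE_SPECIES_FILL_REPn (e.g. S05_T12_2019-10-01_TSHE_filled_rep1.tif)"


def parse_tag(filename: str, mode: str = "strict") -> ScanMetadata:
    """Parse collection metadata from a scan file name.

    ``mode='strict'`` requires the full grammar; ``mode='site-only'``
    extracts just the leading site field and defaults the rest.
    """
    base = os.path.basename(filename)
    stem = os.path.splitext(base)[0]
    m = _TAG_RE.match(stem)
    if m is None:
        if mode == "site-only":
            site = stem.split("_")[0]
            if not site:
                raise TagParseError(f"empty site field in {filename!r}")
            return ScanMetadata(site=site, source_tag=base)
        raise TagParseError(
            f"file name {filename!r} does not match the tag grammar {_GRAMMAR}"
        )
    species = m.group("species")
    fill = m.group("fill")
    if fill not in _FILL_VALUES and fill != "NA":
        raise TagParseError(
            f"fill field {fill!r} in {filename!r} must be one of "
            f"{_FILL_VALUES} or NA"
        )
    return ScanMetadata(
        site=m.group("site"),
        trap_id=m.group("trap"),
        collection_date=_dt.date.fromisoformat(m.group("date")),
        species_label=None if species == "NA" else species,
        fill_status="unknown" if fill == "NA" else fill,
        replicate_index=int(m.group("rep")),
        source_tag=base,
    )


def format_tag(meta: ScanMetadata, ext: str = ".tif") -> str:
    """Inverse of :func:`parse_tag` for strict-grammar names."""
    date = meta.collection_date.isoformat() if meta.collection_date else "NA"
    species = meta.species_label if meta.species_label else "NA"
    return (
        f"{meta.site}_{meta.trap_id}_{date}_{species}"
        f"_{meta.fill_status}_rep{meta.replicate_index}{ext}"
    )
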