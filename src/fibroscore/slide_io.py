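"""Reading and writing section images and compartment masks.

Supported slide formats: tiled TIFF (micron calibration in the resolution
tags), Zarr arrays (calibration in an ``mpp`` attribute), and PNG (no
standard calibration — an explicit ``mpp`` override is required).  Masks
are single-channel PNG or Zarr rasters with the fixed label convention
0=background, 1=epidermis, 2=dermis, 3=subcutis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
import zarr
from PIL import Image

from fibroscore.errors import CalibrationError, GeometryError, SchemaError

log = logging.getLogger(__name__)

VALID_MASK_LABELS = frozenset({0, 1, 2, 3})


@dataclass
class SlideRef:
    """In-memory RGB raster with spatial calibration."""

    pixels: np.ndarray  # (H, W, 3) uint8
    mpp: float
    source_format: str  # tiff | png | zarr
    path: str | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class DermisMask:
    """Validated compartment label mask."""

    labels: np.ndarray  # (H, W) uint8
    path: str | None = None

    def label_counts(self) -> dict[int, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts)}


def _mpp_from_tiff(page) -> float | None:
    tags = page.tags
    xres = tags.get("XResolution")
    unit = tags.get("ResolutionUnit")
    if xres is None or unit is None:
        return None
    num, den = xres.value
    if num == 0:
        return None
    pixels_per_unit = num / den
    unit_name = getattr(unit.value, "name", str(unit.value)).upper()
    if "CENTIMETER" in unit_name or unit.value == 3:
        return 1e4 / pixels_per_unit
    if "INCH" in unit_name or unit.value == 2:
        return 25400.0 / pixels_per_unit
    return None


def read_slide(path, mpp: float | None = None) -> SlideRef:
    """Read a TIFF/PNG/Zarr slide, resolving microns-per-pixel.

    ``mpp`` overrides any stored calibration; for PNG (which has no
    standard micron tag) it is mandatory.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"slide not found: {p}")
    suffix = p.suffix.lower()
    if suffix in (".tif", ".tiff"):
        with tifffile.TiffFile(p) as tf:
            page = tf.pages[0]
            pixels = page.asarray()
            stored = _mpp_from_tiff(page)
        fmt = "tiff"
    elif suffix == ".png":
        pixels = np.asarray(Image.open(p).convert("RGB"))
        stored = None
        fmt = "png"
    elif suffix == ".zarr" or p.is_dir():
        arr = zarr.open(str(p), mode="r")
        pixels = np.asarray(arr)
        stored = arr.attrs.get("mpp")
        fmt = "zarr"
    else:
        raise SchemaError(f"unsupported slide format: {suffix!r} (tiff/png/zarr)")
    resolved = mpp if mpp is not None else stored
    if resolved is None:
        raise CalibrationError(
            f"{p}: no microns-per-pixel calibration stored and no override given"
        )
    if resolved <= 0:
        raise CalibrationError(f"mpp must be > 0, got {resolved}")
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise SchemaError(f"slide must be RGB (H, W, 3), got shape {pixels.shape}")
    return SlideRef(pixels=pixels, mpp=float(resolved), source_format=fmt, path=str(p))


def read_mask(path, slide: SlideRef) -> DermisMask:
    """Read and validate a compartment mask against its slide."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"mask not found: {p}")
    if p.suffix.lower() == ".png":
        labels = np.asarray(Image.open(p).convert("L"))
    elif p.suffix.lower() == ".zarr" or p.is_dir():
        labels = np.asarray(zarr.open(str(p), mode="r"))
    else:
        raise SchemaError(f"unsupported mask format: {p.suffix!r} (png/zarr)")
    if labels.shape != slide.shape:
        raise GeometryError(
            f"mask shape {labels.shape} does not match slide shape {slide.shape}"
        )
    found = set(np.unique(labels).tolist())
    unknown = found - VALID_MASK_LABELS
    if unknown:
        raise SchemaError(f"mask contains unknown labels {sorted(unknown)}; allowed 0-3")
    mask = DermisMask(labels=labels.astype(np.uint8), path=str(p))
    log.info("mask %s label counts: %s", p, mask.label_counts())
    return mask


def write_slide_tiff(path, image: np.ndarray, mpp: float) -> None:
    """Write a tiled TIFF with mpp encoded in centimeter resolution tags."""
    tifffile.imwrite(
        path,
        image,
        tile=(256, 256),
        resolution=(1e4 / mpp, 1e4 / mpp),
        resolutionunit="CENTIMETER",
    )


def write_slide_zarr(path, image: np.ndarray, mpp: float) -> None:
    arr = zarr.open(
        str(path), mode="w", shape=image.shape, chunks=(256, 256, 3), dtype="u1"
    )
    arr[:] = image
    arr.attrs["mpp"] = float(mpp)


def write_mask_png(path, labels: np.ndarray) -> None:
    Image.fromarray(labels.astype(np.uint8), mode="L").save(path)


def write_mask_zarr(path, labels: np.ndarray) -> None:
    arr = zarr.open(
        str(path), mode="w", shape=labels.shape, chunks=(512, 512), dtype="u1"
    )
    arr[:] = labels.astype(np.uint8)
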