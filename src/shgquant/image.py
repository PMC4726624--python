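"""Core raster types and multichannel TIFF I/O.

A biopsy mosaic is a pair of registered single-channel rasters: the SHG
channel (fibrillar collagen contrast) and the CARS channel (lipid / CH2
contrast), plus the physical pixel pitch in micrometres per pixel. All
filter radii elsewhere in the package are given in micrometres and
converted to pixels here, so the analysis is independent of the objective
and mosaic downsampling used during acquisition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "MosaicImage",
    "BinaryMask",
    "read_mosaic",
    "write_mosaic",
    "read_mask",
    "write_mask",
    "um_to_px",
]

_DTYPES = {8: np.uint8, 16: np.uint16, 32: np.float32}

MASK_LABELS = ("sample", "portal", "capsule", "excluded", "parenchyma")


@dataclass
class MosaicImage:
    """Two registered channels of a stitched biopsy mosaic.

    Parameters
    ----------
    shg, cars : ndarray
        2-D nonnegative intensity rasters of identical shape.
    pixel_size_um : float
        Isotropic physical pitch per pixel in micrometres. Must be > 0 and
        is never inferred: acquisition metadata or an explicit value is
        required.
    bit_depth : int
        8, 16 (unsigned integer rasters) or 32 (float rasters).
    """

    shg: np.ndarray
    cars: np.ndarray
    pixel_size_um: float
    bit_depth: int = 16

    def __post_init__(self):
        self.shg = np.asarray(self.shg)
        self.cars = np.asarray(self.cars)
        if self.shg.ndim != 2 or self.cars.ndim != 2:
            raise ValueError("channels must be 2-D rasters")
        if self.shg.shape != self.cars.shape:
            raise ValueError(
                f"SHG and CARS shapes differ: {self.shg.shape} vs {self.cars.shape}"
            )
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.bit_depth not in _DTYPES:
            raise ValueError(f"bit_depth must be one of {sorted(_DTYPES)}")
        for name, ch in (("shg", self.shg), ("cars", self.cars)):
            if ch.size and float(np.min(ch)) < 0:
                raise ValueError(f"{name} contains negative intensities")
            if self.bit_depth in (8, 16):
                top = 2 ** self.bit_depth - 1
                if ch.size and float(np.max(ch)) > top:
                    raise ValueError(
                        f"{name} exceeds the {self.bit_depth}-bit range [0, {top}]"
                    )

    @property
    def shape(self) -> tuple[int, int]:
        return self.shg.shape

    @property
    def dtype(self):
        return _DTYPES[self.bit_depth]


@dataclass
class BinaryMask:
    """A boolean raster tied to a mosaic, tagged with its anatomical role."""

    pixels: np.ndarray
    label: str = "sample"

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2-D")
        if self.label not in MASK_LABELS:
            raise ValueError(f"label must be one of {MASK_LABELS}")

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())

    def area_um2(self, pixel_size_um: float) -> float:
        return self.area_px * pixel_size_um**2


def um_to_px(length_um: float, pixel_size_um: float) -> int:
    """Convert a physical length to a pixel count.

    Rounds half-up and never returns less than 1 px, so a physically
    meaningful radius always yields a usable kernel.
    """
    if not (length_um > 0 and pixel_size_um > 0):
        raise ValueError("length_um and pixel_size_um must be > 0")
    return max(1, int(math.floor(length_um / pixel_size_um + 0.5)))


def write_mosaic(img: MosaicImage, path) -> None:
    """Write a mosaic as a 2-channel grayscale TIFF (channel 0 = SHG).

    The pixel pitch is stored both in the ImageDescription metadata
    (``pixel_size_um``) and the standard TIFF resolution tags.
    """
    stack = np.stack([img.shg, img.cars]).astype(img.dtype)
    px_per_cm = 1e4 / img.pixel_size_um
    tifffile.imwrite(
        str(path),
        stack,
        photometric="minisblack",
        metadata={"pixel_size_um": img.pixel_size_um, "axes": "CYX"},
        resolution=(px_per_cm, px_per_cm),
        resolutionunit="CENTIMETER",
    )


def _pitch_from_tags(page) -> float | None:
    tags = page.tags
    if "XResolution" not in tags or "ResolutionUnit" not in tags:
        return None
    num, den = tags["XResolution"].value
    if num == 0:
        return None
    px_per_unit = num / den
    unit = int(tags["ResolutionUnit"].value)
    if unit == 3:  # centimetre
        return 1e4 / px_per_unit
    if unit == 2:  # inch
        return 25400.0 / px_per_unit
    return None


def read_mosaic(path, pixel_size_um: float | None = None,
                channel_order: tuple[str, str] = ("shg", "cars")) -> MosaicImage:
    """Read a 2-channel grayscale TIFF into a :class:`MosaicImage`.

    Channel 0 maps to SHG and channel 1 to CARS by default; pass
    ``channel_order=("cars", "shg")`` for files saved the other way round.
    The pixel pitch is taken from (in priority order) the explicit
    argument, the ImageDescription metadata, or the TIFF resolution tags;
    if none is available an error is raised rather than assuming 1 um/px.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if set(channel_order) != {"shg", "cars"}:
        raise ValueError("channel_order must be a permutation of ('shg', 'cars')")
    with tifffile.TiffFile(str(path)) as tif:
        arr = tif.series[0].asarray()
        meta = tif.shaped_metadata
        pitch = pixel_size_um
        if pitch is None and meta:
            pitch = meta[0].get("pixel_size_um")
        if pitch is None:
            pitch = _pitch_from_tags(tif.pages[0])
    if arr.ndim == 2:
        raise ValueError(f"expected a 2-channel TIFF, got 1 channel in {path.name}")
    if arr.ndim != 3:
        raise ValueError(f"unsupported TIFF layout with shape {arr.shape}")
    if arr.shape[0] == 2:
        channels = arr
    elif arr.shape[-1] == 2:
        channels = np.moveaxis(arr, -1, 0)
    else:
        n = arr.shape[0] if arr.shape[0] < arr.shape[-1] else arr.shape[-1]
        raise ValueError(f"expected a 2-channel TIFF, got {n} channels in {path.name}")
    if pitch is None:
        raise ValueError(
            f"no pixel size for {path.name}: supply pixel_size_um explicitly "
            "or store it in the TIFF metadata/resolution tags"
        )
    by_name = dict(zip(channel_order, channels))
    if channels.dtype == np.uint8:
        depth = 8
    elif channels.dtype == np.uint16:
        depth = 16
    else:
        depth = 32
        by_name = {k: v.astype(np.float32) for k, v in by_name.items()}
    return MosaicImage(shg=by_name["shg"], cars=by_name["cars"],
                       pixel_size_um=float(pitch), bit_depth=depth)


def write_mask(mask: BinaryMask | np.ndarray, path) -> None:
    """Write a binary mask as a single-channel 8-bit TIFF (0/255)."""
    pixels = mask.pixels if isinstance(mask, BinaryMask) else np.asarray(mask, bool)
    tifffile.imwrite(str(path), (pixels.astype(np.uint8) * 255),
                     photometric="minisblack")


def read_mask(path, label: str = "sample") -> BinaryMask:
    arr = tifffile.imread(str(path))
    return BinaryMask(pixels=arr > 0, label=label)
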