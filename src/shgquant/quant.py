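"""Background-subtracted intensity scoring over the parenchyma.

The per-biopsy readout is the mean SHG intensity over the parenchyma
(sample minus capsule and portal areas) after subtracting the mean signal
outside the specimen, and the analogous CARS mean as a fat readout. The
fold-over-background statistic relates the raw parenchymal mean to that
background baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from .image import BinaryMask, MosaicImage
from .masks import SegmentationResult

__all__ = ["QuantResult", "estimate_background", "quantify"]


@dataclass
class QuantResult:
    """Per-biopsy quantification summary.

    ``mean_shg`` / ``mean_cars`` are background-subtracted parenchymal
    means, clamped at 0 (intensities are physical signal magnitudes).
    ``fold_over_background`` is the raw (pre-subtraction) parenchymal SHG
    mean divided by the SHG background, NaN when the background is 0.
    """

    background_shg: float
    background_cars: float
    mean_shg: float
    mean_cars: float
    fold_over_background: float
    sample_area_um2: float
    excluded_area_um2: float
    parenchyma_fraction: float

    def to_row(self) -> dict:
        return asdict(self)


def estimate_background(img: MosaicImage,
                        sample: BinaryMask | np.ndarray) -> tuple[float, float]:
    """Per-channel mean intensity outside the sample mask."""
    pixels = sample.pixels if isinstance(sample, BinaryMask) else np.asarray(sample, bool)
    outside = ~pixels
    if not outside.any():
        raise ValueError("sample mask covers the full frame: no background region")
    return (float(np.asarray(img.shg, np.float64)[outside].mean()),
            float(np.asarray(img.cars, np.float64)[outside].mean()))


def quantify(img: MosaicImage, seg: SegmentationResult) -> QuantResult:
    """Background-subtracted mean SHG/CARS over the parenchyma.

    Deterministic arithmetic on the given masks; raises when the
    parenchyma is empty.
    """
    par = seg.parenchyma.pixels
    if par.shape != img.shape:
        raise ValueError("mask shape does not match the image")
    if not par.any():
        raise ValueError("no parenchyma to quantify")
    bg_shg, bg_cars = estimate_background(img, seg.sample)
    raw_shg = float(np.asarray(img.shg, np.float64)[par].mean())
    raw_cars = float(np.asarray(img.cars, np.float64)[par].mean())
    px2 = img.pixel_size_um**2
    sample_area = seg.sample.area_px * px2
    excluded_area = seg.excluded.area_px * px2
    fold = raw_shg / bg_shg if bg_shg > 0 else math.nan
    return QuantResult(
        background_shg=bg_shg,
        background_cars=bg_cars,
        mean_shg=max(0.0, raw_shg - bg_shg),
        mean_cars=max(0.0, raw_cars - bg_cars),
        fold_over_background=fold,
        sample_area_um2=sample_area,
        excluded_area_um2=excluded_area,
        parenchyma_fraction=seg.parenchyma.area_px / seg.sample.area_px,
    )
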