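"""Death and fibrosis stain quantification.

Necrosis (7-AAD) and apoptosis (phosphatidylserine) channels are Otsu-
thresholded into masks; cells in late apoptosis also take up the necrosis
stain, so the apoptosis mask is removed from the necrosis mask by set
difference before comparing areas. DAPI uses the median intensity of a
150 x 250 um centre region of the maximum projection as a proxy for cell
number; vimentin and fibronectin report mean projected intensity.
"""

from __future__ import annotations

import dataclasses
from typing import Literal

import numpy as np
from skimage import filters

from .stack import ImageStack, ROISpec


@dataclasses.dataclass
class MaskPair:
    apoptosis: np.ndarray  # binary
    necrosis: np.ndarray  # binary

    def __post_init__(self) -> None:
        self.apoptosis = np.asarray(self.apoptosis, dtype=bool)
        self.necrosis = np.asarray(self.necrosis, dtype=bool)
        if self.apoptosis.shape != self.necrosis.shape:
            raise ValueError("masks must have the same shape")

    @property
    def necrosis_only(self) -> np.ndarray:
        """Necrosis mask with late-apoptotic cells removed (set difference)."""
        return self.necrosis & ~self.apoptosis

    def areas_px(self) -> dict[str, int]:
        return {
            "apoptosis": int(self.apoptosis.sum()),
            "necrosis": int(self.necrosis.sum()),
            "necrosis_only": int(self.necrosis_only.sum()),
        }

    def areas_um2(self, scale_um_per_px: float) -> dict[str, float]:
        return {k: v * scale_um_per_px**2 for k, v in self.areas_px().items()}


def project(stack: ImageStack, mode: Literal["max", "sum"] = "max") -> np.ndarray:
    """Pixelwise max (or sum) projection of a z-stack."""
    if stack.axes != "z":
        raise ValueError("projection expects a z-stack")
    pixels = np.asarray(stack.pixels, dtype=float)
    if mode == "max":
        return pixels.max(axis=0)
    if mode == "sum":
        return pixels.sum(axis=0)
    raise ValueError(f"unknown projection mode {mode!r}")


def threshold_mask(image: np.ndarray) -> np.ndarray:
    """Otsu-thresholded binary mask of a (non-constant) image."""
    image = np.asarray(image, dtype=float)
    if np.ptp(image) == 0:
        raise ValueError("constant image: Otsu threshold undefined")
    return image > filters.threshold_otsu(image)


def necrosis_apoptosis_ratio(pair: MaskPair) -> float:
    """Positive-area ratio of (necrosis minus apoptosis) to apoptosis."""
    areas = pair.areas_px()
    if areas["apoptosis"] == 0:
        raise ValueError("apoptosis mask is empty: ratio undefined")
    return areas["necrosis_only"] / areas["apoptosis"]


def roi_statistic(
    projection: np.ndarray,
    roi: ROISpec,
    scale_um_per_px: float,
    stat: Literal["median", "mean"],
) -> float:
    """Median or mean intensity over an ROI of a projection image."""
    rows, cols = roi.to_pixels(scale_um_per_px)
    h, w = projection.shape
    if rows.start < 0 or cols.start < 0 or rows.stop > h or cols.stop > w:
        raise ValueError("ROI outside projection bounds")
    region = np.asarray(projection, dtype=float)[rows, cols]
    if stat == "median":
        return float(np.median(region))
    if stat == "mean":
        return float(region.mean())
    raise ValueError(f"unknown statistic {stat!r}")
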