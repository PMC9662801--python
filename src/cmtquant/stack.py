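"""Image stacks and rectangular regions of interest.

``ImageStack`` is the pipeline's in-memory container for both z-stacks
(confocal fluorescence) and time-lapse videos (brightfield / calcium): a
(planes, y, x) array plus the axis meaning and the physical pixel scale.
``ROISpec`` describes a rectangle in micrometres; conversion to pixels is
half-open, 0-based, origin at the image top-left, with x the horizontal axis
connecting the two microtissue posts.
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path
from typing import Literal

import numpy as np
import tifffile

Role = Literal["center", "adjacent", "edge", "custom"]


@dataclasses.dataclass
class ImageStack:
    """Stack of equally shaped 2-D planes along a z or time axis."""

    pixels: np.ndarray  # (n_planes, height, width), nonnegative intensities
    axes: Literal["z", "t"]
    pixel_scale_um_per_px: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[None]
        if self.pixels.ndim != 3:
            raise ValueError(f"expected (planes, y, x) array, got shape {self.pixels.shape}")
        if self.pixels.shape[0] < 1:
            raise ValueError("stack needs at least one plane")
        if self.axes not in ("z", "t"):
            raise ValueError(f"axes must be 'z' or 't', got {self.axes!r}")
        if not (self.pixel_scale_um_per_px > 0):
            raise ValueError("pixel_scale_um_per_px must be positive")

    @property
    def n_planes(self) -> int:
        return self.pixels.shape[0]

    @property
    def plane_shape(self) -> tuple[int, int]:
        return self.pixels.shape[1], self.pixels.shape[2]

    def __len__(self) -> int:
        return self.n_planes

    def __getitem__(self, i: int) -> np.ndarray:
        return self.pixels[i]


@dataclasses.dataclass(frozen=True)
class ROISpec:
    """Axis-aligned rectangle in micrometres with a named role.

    ``origin_um`` is the (x, y) position of the top-left corner; ``size_um``
    is (width, height). Standard roles follow the study layout: a
    299 x 199 um center region over the injury, a 139 x 299 um adjacent
    region, a 100 x 100 um edge region, and 150 x 250 um center crops for
    stain statistics.
    """

    origin_um: tuple[float, float]
    size_um: tuple[float, float]
    role: Role = "custom"

    def __post_init__(self) -> None:
        w, h = self.size_um
        if not (w > 0 and h > 0):
            raise ValueError(f"ROI size must be positive, got {self.size_um}")
        if self.role not in ("center", "adjacent", "edge", "custom"):
            raise ValueError(f"unknown ROI role {self.role!r}")

    def to_pixels(self, scale_um_per_px: float) -> tuple[slice, slice]:
        """Half-open (row_slice, col_slice) of this ROI at the given scale."""
        x0 = int(round(self.origin_um[0] / scale_um_per_px))
        y0 = int(round(self.origin_um[1] / scale_um_per_px))
        w = int(round(self.size_um[0] / scale_um_per_px))
        h = int(round(self.size_um[1] / scale_um_per_px))
        return slice(y0, y0 + h), slice(x0, x0 + w)


def centered_roi(
    image_shape_px: tuple[int, int],
    size_um: tuple[float, float],
    scale_um_per_px: float,
    role: Role = "center",
) -> ROISpec:
    """ROI of the given physical size centred in an image."""
    h_px, w_px = image_shape_px
    w_um, h_um = size_um
    x0 = (w_px * scale_um_per_px - w_um) / 2.0
    y0 = (h_px * scale_um_per_px - h_um) / 2.0
    return ROISpec(origin_um=(x0, y0), size_um=size_um, role=role)


def _numeric_key(path: Path) -> tuple:
    """Sort key ordering frame files by the integers embedded in their names."""
    parts = re.split(r"(\d+)", path.name)
    return tuple(int(p) if p.isdigit() else p for p in parts)


def read_stack(path: str | Path, scale_um_per_px: float, axes: Literal["z", "t"] = "t") -> ImageStack:
    """Read a multi-page TIFF, or a directory of numbered TIFF frames, as a stack.

    Directory frames are ordered by the numeric components of their file
    names (``frame2.tif`` before ``frame10.tif``). Intensities are preserved
    bit-exactly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file or directory: {path}")
    if path.is_dir():
        frames = sorted(
            [p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff")],
            key=_numeric_key,
        )
        if not frames:
            raise FileNotFoundError(f"no TIFF frames in directory {path}")
        planes = [tifffile.imread(f) for f in frames]
        shapes = {p.shape for p in planes}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent frame shapes in {path}: {sorted(shapes)}")
        pixels = np.stack(planes)
    else:
        pixels = tifffile.imread(path)
    return ImageStack(pixels=pixels, axes=axes, pixel_scale_um_per_px=scale_um_per_px)


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as a multi-page TIFF (lossless for integer data)."""
    # explicit photometric: a 3-plane stack must not be guessed as RGB
    tifffile.imwrite(Path(path), stack.pixels, photometric="minisblack")


def crop_roi(stack: ImageStack, roi: ROISpec) -> ImageStack:
    """Crop every plane to an ROI; pixel values are a pure subset of the input."""
    rows, cols = roi.to_pixels(stack.pixel_scale_um_per_px)
    h, w = stack.plane_shape
    if rows.start < 0 or cols.start < 0 or rows.stop > h or cols.stop > w:
        raise ValueError(
            f"ROI {roi} maps to rows {rows.start}:{rows.stop}, cols {cols.start}:{cols.stop} "
            f"outside the {h}x{w} image"
        )
    return ImageStack(
        pixels=stack.pixels[:, rows, cols].copy(),
        axes=stack.axes,
        pixel_scale_um_per_px=stack.pixel_scale_um_per_px,
    )
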