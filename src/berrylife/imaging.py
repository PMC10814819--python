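"""Image loading, grayscale/CIELAB conversion and region-of-interest extraction.

Fruit-surface photographs are reduced to fixed-size square regions of
interest (ROIs); texture features are computed on the grayscale ROI and
color features are per-ROI means of per-pixel CIELAB values (sRGB
companding, D65/2-degree white).  Grayscale conversion uses ITU-R BT.601
luma weights (0.299, 0.587, 0.114).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from PIL import Image
from skimage.color import rgb2lab

#: BT.601 luma weights for RGB -> grayscale.
GRAY_WEIGHTS = np.array([0.299, 0.587, 0.114])

ROIMode = Literal["manual", "seeded_random", "grid"]


@dataclass
class RGBImage:
    """An 8-bit RGB photograph with sample metadata.

    Pixels are H x W x 3 uint8; ``surface`` is ``"outer"`` or ``"inner"``,
    ``storage_day`` the day label, ``replicate_id`` a free-form sample id.
    """

    pixels: np.ndarray
    surface: str = "outer"
    storage_day: int = 0
    replicate_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected H x W x 3 pixels, got shape {px.shape}")
        if px.shape[0] < 15 or px.shape[1] < 15:
            raise ValueError("image must be at least 15 x 15 pixels")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("channel values must lie in [0, 255]")
        self.pixels = px.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass
class GrayImage:
    """Real-valued grayscale image in [0, 255] (pre-quantization)."""

    pixels: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class ROISpec:
    """A square ROI: 0-based top-left corner, half-open extent ``size``."""

    row: int
    col: int
    size: int = 15

    def slices(self) -> tuple[slice, slice]:
        return slice(self.row, self.row + self.size), slice(self.col, self.col + self.size)

    def overlaps(self, other: "ROISpec") -> bool:
        return (
            self.row < other.row + other.size
            and other.row < self.row + self.size
            and self.col < other.col + other.size
            and other.col < self.col + self.size
        )


@dataclass(frozen=True)
class ColorFeatures:
    """Per-ROI mean CIELAB coordinates."""

    L_star: float
    a_star: float
    b_star: float


def load_image(path, surface: str = "outer", day: int = 0, replicate: str = "") -> RGBImage:
    """Load a JPEG/PNG file as an :class:`RGBImage`.

    Grayscale files are accepted and replicated to three channels (with a
    warning); an alpha channel is dropped.
    """
    try:
        with Image.open(path) as im:
            if im.mode in ("L", "I;16", "I"):
                warnings.warn(
                    f"{path}: grayscale image, replicating to 3 channels", stacklevel=2
                )
                im = im.convert("L")
                arr = np.asarray(im, dtype=np.uint8)
                px = np.repeat(arr[:, :, None], 3, axis=2)
            else:
                px = np.asarray(im.convert("RGB"), dtype=np.uint8)
    except OSError as exc:
        raise OSError(f"cannot read image file {path!r}: {exc}") from exc
    return RGBImage(px, surface=surface, storage_day=day, replicate_id=replicate)


def to_grayscale(img: RGBImage) -> GrayImage:
    """BT.601 luminance: 0.299 R + 0.587 G + 0.114 B, real-valued."""
    return GrayImage(np.asarray(img.pixels, dtype=float) @ GRAY_WEIGHTS)


def rgb_to_lab(img: RGBImage, roi: ROISpec | None = None) -> ColorFeatures:
    """Mean CIELAB coordinates over an ROI (whole image if ``roi`` is None).

    Conversion is per-pixel sRGB -> XYZ -> L*a*b* under the D65/2-degree
    reference white; the ROI color is the mean of per-pixel Lab values.
    """
    px = img.pixels
    if roi is not None:
        _validate_roi(roi, img.shape)
        rs, cs = roi.slices()
        px = px[rs, cs]
    lab = rgb2lab(px)
    L, a, b = lab.reshape(-1, 3).mean(axis=0)
    return ColorFeatures(float(L), float(a), float(b))


def _validate_roi(roi: ROISpec, shape: tuple[int, int]) -> None:
    h, w = shape
    if roi.row < 0 or roi.col < 0 or roi.row + roi.size > h or roi.col + roi.size > w:
        raise ValueError(f"ROI {roi} exceeds image bounds {h} x {w}")


def extract_rois(
    img: RGBImage,
    n: int = 8,
    size: int = 15,
    mode: ROIMode = "seeded_random",
    coords: Sequence[tuple[int, int]] | None = None,
    seed: int | None = None,
) -> list[ROISpec]:
    """Select ``n`` non-overlapping ``size`` x ``size`` ROIs.

    Modes: ``manual`` uses the supplied (row, col) corners; ``grid`` tiles
    row-major from the top-left; ``seeded_random`` places ROIs by uniform
    rejection sampling, reproducible given ``seed``.
    """
    h, w = img.shape
    if n * size * size > h * w:
        raise ValueError(f"cannot fit {n} ROIs of {size}x{size} in a {h}x{w} image")

    if mode == "manual":
        if coords is None:
            raise ValueError("manual mode requires coords")
        rois = [ROISpec(r, c, size) for r, c in coords]
        for roi in rois:
            _validate_roi(roi, (h, w))
        for i, a in enumerate(rois):
            for b in rois[i + 1:]:
                if a.overlaps(b):
                    raise ValueError(f"manual ROIs overlap: {a} and {b}")
        if len(rois) != n:
            raise ValueError(f"expected {n} coords, got {len(rois)}")
        return rois

    if mode == "grid":
        rois = []
        for r in range(0, h - size + 1, size):
            for c in range(0, w - size + 1, size):
                rois.append(ROISpec(r, c, size))
                if len(rois) == n:
                    return rois
        raise ValueError(f"grid mode cannot place {n} ROIs of {size}x{size} in {h}x{w}")

    if mode == "seeded_random":
        rng = np.random.default_rng(seed)
        placed: list[ROISpec] = []
        # rejection sampling with a generous budget; dense packings should
        # use grid mode instead
        for _ in range(10000 * n):
            cand = ROISpec(
                int(rng.integers(0, h - size + 1)),
                int(rng.integers(0, w - size + 1)),
                size,
            )
            if not any(cand.overlaps(p) for p in placed):
                placed.append(cand)
                if len(placed) == n:
                    return placed
        raise ValueError(
            f"could not place {n} non-overlapping ROIs by rejection sampling "
            f"(placed {len(placed)}); try grid mode"
        )

    raise ValueError(f"unknown ROI mode {mode!r}")


def roi_table(path: str, rois: Sequence[ROISpec]):
    """Provenance rows (path, roi_index, row, col, size) for a ROI list."""
    import pandas as pd

    return pd.DataFrame(
        [
            {"path": path, "roi_index": i, "row": r.row, "col": r.col, "size": r.size}
            for i, r in enumerate(rois)
        ]
    )
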