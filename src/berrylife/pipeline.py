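"""Glue: turn images into tidy per-ROI / per-fruit feature tables."""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from . import imaging, texture
from .imaging import RGBImage
from .texture import FEATURE_NAMES, TextureConfig


def extract_feature_table(
    images: Iterable[RGBImage],
    n_rois: int = 8,
    roi_size: int = 15,
    roi_mode: str = "seeded_random",
    seed: int = 0,
    config: TextureConfig = TextureConfig(),
) -> pd.DataFrame:
    """Per-ROI 18-feature rows for a collection of labeled images.

    Each row carries replicate, surface, day and roi_index plus the 18
    canonical feature names.  ROI placement is reproducible given ``seed``
    (each image gets a seed offset by its position in the sequence).
    """
    rows = []
    for k, img in enumerate(images):
        gray = imaging.to_grayscale(img)
        rois = imaging.extract_rois(
            img, n=n_rois, size=roi_size, mode=roi_mode, seed=seed + k
        )
        for idx, roi in enumerate(rois):
            rs, cs = roi.slices()
            color = imaging.rgb_to_lab(img, roi)
            feats = texture.feature_vector(gray.pixels[rs, cs], color, config)
            rows.append(
                {
                    "replicate": img.replicate_id,
                    "surface": img.surface,
                    "day": img.storage_day,
                    "roi_index": idx,
                    **feats,
                }
            )
    return pd.DataFrame(rows)


def aggregate_per_fruit(roi_table: pd.DataFrame) -> pd.DataFrame:
    """Mean the per-ROI features within each (day, replicate, surface) fruit.

    Classification can be run at either granularity: ROI-level (each ROI a
    sample) or fruit-level (one averaged row per fruit); this produces the
    latter.
    """
    keys = ["day", "replicate", "surface"]
    return roi_table.groupby(keys, as_index=False)[FEATURE_NAMES].mean()
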