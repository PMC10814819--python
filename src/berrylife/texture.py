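"""Grayscale texture features: first-order statistics, GLCM and run-length.

The 15 grayscale features follow the classical Haralick (co-occurrence)
and Galloway (run-length) definitions:

first-order   mean, standard_deviation, skewness, kurtosis, energy
GLCM          contrast, homogeneity, correlation, dissimilarity,
              angular_second_moment
run-length    SRE, LRE, GLN, RLN, RP

Conventions fixed here so that every value is exactly reproducible:

- moments are population moments; kurtosis is Pearson (non-excess);
  a constant patch has skewness = kurtosis = 0 by convention;
- ``energy`` is first-order histogram uniformity (sum of squared bin
  probabilities of the quantized patch); ``angular_second_moment`` is the
  analogous co-occurrence uniformity — the two are distinct features;
- GLCM correlation is 0 when either marginal is degenerate;
- quantization is uniform binning of 8-bit values: q = floor(v * G / 256).

Appending the per-ROI CIELAB means (L*, a*, b*) gives the full 18-feature
vector used for day discrimination and regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .imaging import ColorFeatures

#: Canonical 18 feature names, in reporting order.
FEATURE_NAMES = [
    "mean",
    "standard_deviation",
    "skewness",
    "kurtosis",
    "energy",
    "contrast",
    "homogeneity",
    "correlation",
    "dissimilarity",
    "angular_second_moment",
    "SRE",
    "LRE",
    "GLN",
    "RLN",
    "RP",
    "L_star",
    "a_star",
    "b_star",
]

#: Distance-1 offsets at 0, 45, 90 and 135 degrees (dr, dc).
DEFAULT_OFFSETS: tuple[tuple[int, int], ...] = ((0, 1), (-1, 1), (-1, 0), (-1, -1))

#: Horizontal and vertical scan directions for run-length analysis.
DEFAULT_DIRECTIONS: tuple[int, ...] = (0, 90)

DEFAULT_LEVELS = 16


@dataclass
class GrayROI:
    """A grayscale patch; ``levels`` is set once the patch is quantized."""

    pixels: np.ndarray
    levels: int | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("GrayROI requires a non-empty 2-D patch")


@dataclass
class GLCM:
    """Normalized gray-level co-occurrence matrix."""

    P: np.ndarray
    offsets: tuple[tuple[int, int], ...]
    symmetric: bool


@dataclass
class RunLengthMatrix:
    """Run counts R[level, length-1] accumulated over scan directions."""

    R: np.ndarray
    n_runs: int
    n_pixels: int
    directions: tuple[int, ...]


@dataclass(frozen=True)
class TextureConfig:
    """Quantization and direction settings shared by a whole analysis."""

    levels: int = DEFAULT_LEVELS
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS
    symmetric: bool = True
    directions: tuple[int, ...] = DEFAULT_DIRECTIONS


def quantize(roi: GrayROI | np.ndarray, levels: int = DEFAULT_LEVELS) -> GrayROI:
    """Uniformly bin 8-bit intensities into ``levels`` gray levels."""
    if levels < 2:
        raise ValueError(f"levels must be >= 2, got {levels}")
    px = roi.pixels if isinstance(roi, GrayROI) else np.asarray(roi)
    if px.min() < 0 or px.max() > 255:
        raise ValueError("raw intensities must lie in [0, 255]")
    q = np.minimum(np.floor(px * levels / 256.0).astype(np.int64), levels - 1)
    return GrayROI(q, levels=levels)


def first_order_features(
    roi: GrayROI, levels: int = DEFAULT_LEVELS
) -> dict[str, float]:
    """Mean, population SD, skewness, Pearson kurtosis, histogram energy.

    Moments are computed on the raw (unquantized) intensities; energy on
    the quantized histogram, so it is 1 exactly for a flat patch.
    """
    v = np.asarray(roi.pixels, dtype=float).ravel()
    mean = v.mean()
    sd = v.std()  # population
    if sd == 0.0:
        skew = kurt = 0.0
    else:
        z = (v - mean) / sd
        skew = float(np.mean(z**3))
        kurt = float(np.mean(z**4))
    q = roi if roi.levels is not None else quantize(roi, levels)
    counts = np.bincount(q.pixels.ravel(), minlength=q.levels)
    p = counts / counts.sum()
    energy = float(np.sum(p**2))
    return {
        "mean": float(mean),
        "standard_deviation": float(sd),
        "skewness": skew,
        "kurtosis": kurt,
        "energy": energy,
    }


def compute_glcm(
    roi: GrayROI,
    offsets: Iterable[tuple[int, int]] = DEFAULT_OFFSETS,
    symmetric: bool = True,
) -> GLCM:
    """Joint probability of gray-level pairs at the given pixel offsets.

    Pair counts from all offsets are accumulated into one matrix before
    normalization; in symmetric mode each pair is counted in both orders.
    """
    if roi.levels is None:
        raise ValueError("ROI must be quantized before GLCM computation")
    px = roi.pixels
    g = roi.levels
    offsets = tuple(tuple(o) for o in offsets)
    if any(o == (0, 0) for o in offsets):
        raise ValueError("offsets must be nonzero")
    counts = np.zeros((g, g), dtype=float)
    h, w = px.shape
    total = 0
    for dr, dc in offsets:
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        if r0 >= r1 or c0 >= c1:
            continue
        a = px[r0:r1, c0:c1]
        b = px[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        np.add.at(counts, (a.ravel(), b.ravel()), 1.0)
        total += a.size
    if total == 0:
        raise ValueError("no in-bounds pixel pairs: ROI smaller than offset reach")
    if symmetric:
        counts = counts + counts.T
    return GLCM(counts / counts.sum(), offsets=offsets, symmetric=symmetric)


def glcm_features(M: GLCM) -> dict[str, float]:
    """Contrast, homogeneity, correlation, dissimilarity and ASM of a GLCM."""
    P = M.P
    g = P.shape[0]
    i, j = np.meshgrid(np.arange(g), np.arange(g), indexing="ij")
    diff = i - j
    contrast = float(np.sum(diff**2 * P))
    homogeneity = float(np.sum(P / (1.0 + diff**2)))
    dissimilarity = float(np.sum(np.abs(diff) * P))
    asm = float(np.sum(P**2))
    pi = P.sum(axis=1)
    pj = P.sum(axis=0)
    mu_i = float(np.sum(np.arange(g) * pi))
    mu_j = float(np.sum(np.arange(g) * pj))
    var_i = float(np.sum((np.arange(g) - mu_i) ** 2 * pi))
    var_j = float(np.sum((np.arange(g) - mu_j) ** 2 * pj))
    denom = np.sqrt(var_i * var_j)
    if denom == 0.0:
        correlation = 0.0  # degenerate marginal: convention
    else:
        correlation = float(np.sum((i - mu_i) * (j - mu_j) * P) / denom)
    return {
        "contrast": contrast,
        "homogeneity": homogeneity,
        "correlation": correlation,
        "dissimilarity": dissimilarity,
        "angular_second_moment": asm,
    }


def _runs_1d(line: np.ndarray) -> list[tuple[int, int]]:
    """Maximal (level, length) runs of one scan line."""
    runs = []
    start = 0
    for k in range(1, len(line) + 1):
        if k == len(line) or line[k] != line[start]:
            runs.append((int(line[start]), k - start))
            start = k
    return runs


def compute_rlm(
    roi: GrayROI, directions: Iterable[int] = DEFAULT_DIRECTIONS
) -> RunLengthMatrix:
    """Run-length matrix over horizontal (0 deg) and/or vertical (90 deg) scans.

    Each scan line decomposes into maximal runs of equal level; counts are
    accumulated over directions.  ``n_pixels`` is pixels-per-direction times
    the number of directions, so RP stays in (0, 1].
    """
    if roi.levels is None:
        raise ValueError("ROI must be quantized before run-length computation")
    directions = tuple(directions)
    if not directions or any(d not in (0, 90) for d in directions):
        raise ValueError("directions must be a non-empty subset of {0, 90}")
    px = roi.pixels
    g = roi.levels
    lmax = max(px.shape)
    R = np.zeros((g, lmax), dtype=float)
    n_runs = 0
    for d in directions:
        lines = px if d == 0 else px.T
        for line in lines:
            for level, length in _runs_1d(line):
                R[level, length - 1] += 1
                n_runs += 1
    return RunLengthMatrix(
        R, n_runs=n_runs, n_pixels=px.size * len(directions), directions=directions
    )


def rlm_features(R: RunLengthMatrix) -> dict[str, float]:
    """Galloway run-length statistics: SRE, LRE, GLN, RLN, RP."""
    if R.n_runs == 0:
        raise ValueError("run-length matrix has no runs")
    mat = R.R
    lengths = np.arange(1, mat.shape[1] + 1, dtype=float)
    nr = R.n_runs
    sre = float(np.sum(mat / lengths**2) / nr)
    lre = float(np.sum(mat * lengths**2) / nr)
    gln = float(np.sum(mat.sum(axis=1) ** 2) / nr)
    rln = float(np.sum(mat.sum(axis=0) ** 2) / nr)
    rp = float(nr / R.n_pixels)
    return {"SRE": sre, "LRE": lre, "GLN": gln, "RLN": rln, "RP": rp}


def feature_vector(
    roi_gray: GrayROI | np.ndarray,
    color: ColorFeatures,
    config: TextureConfig = TextureConfig(),
) -> dict[str, float]:
    """The 18-feature vector of one ROI: 15 grayscale features + (L*, a*, b*)."""
    raw = roi_gray if isinstance(roi_gray, GrayROI) else GrayROI(np.asarray(roi_gray))
    q = quantize(raw, config.levels)
    feats: dict[str, float] = {}
    feats.update(first_order_features(GrayROI(raw.pixels, levels=None), config.levels))
    feats.update(glcm_features(compute_glcm(q, config.offsets, config.symmetric)))
    feats.update(rlm_features(compute_rlm(q, config.directions)))
    feats["L_star"] = color.L_star
    feats["a_star"] = color.a_star
    feats["b_star"] = color.b_star
    return {name: feats[name] for name in FEATURE_NAMES}
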