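"""Deterministic synthetic data with storage-driven drift.

Emulates an 11-day cold-storage study of strawberries sampled on days
1, 4, 6, 8 and 11 with 12 replicate fruits per day: surface photographs
whose texture coarsens and color drifts with storage, a physicochemical /
spectrophotometric table whose per-day anchors follow the measured
trajectories (water activity, moisture, soluble solids, titratable
acidity, ascorbic acid, texture-analyzer attributes, hue, TPC/ABTS/FRAP
with correlated assay noise), and ATR-FTIR spectra built from Gaussian
peaks in 17 diagnostic bands with day-dependent amplitudes.

Everything is a pure function of :class:`SyntheticConfig` — the same
master seed reproduces every image, table row and spectrum bitwise.

Default anchors: hue, firmness/adhesiveness/cohesiveness and band
amplitudes use published per-day means and SDs for this storage design;
the remaining measurements use anchors consistent with the reported
qualitative trajectories (e.g. soluble solids jump between days 4 and 6,
acidity peaks on day 6 and is lowest on day 11), with SDs of roughly half
the day-to-day steps that are reported as significant.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter
from skimage.color import lab2rgb

from .imaging import RGBImage
from .spectra import DEFAULT_BANDS, Spectrum

DAYS = (1, 4, 6, 8, 11)

# --- per-day texture parameters (index order = DAYS) -----------------------
# correlation length shrinks and gray level falls with storage: the surface
# becomes darker and more fragmented (higher GLCM contrast, more short runs)
TEXTURE_DEFAULTS = {
    "correlation_length": (5.0, 4.5, 4.0, 3.0, 2.0),  # px
    "intensity_mean": (150.0, 145.0, 140.0, 130.0, 120.0),
    "intensity_sd": (30.0, 29.0, 28.0, 27.0, 26.0),
    "speckle_density": (3.0, 3.0, 4.0, 5.0, 6.0),  # spots per 100x100 px
}

# --- per-day CIELAB color targets; hue(outer) ~ 25 deg, hue(inner) ~ 45 deg
COLOR_DEFAULTS = {
    "outer": {
        "L": (35.0, 34.0, 33.0, 30.0, 32.0),
        "a": (42.0, 41.0, 40.0, 34.0, 34.0),
        "b": (19.6, 19.1, 18.6, 15.9, 15.9),
    },
    "inner": {
        "L": (55.0, 54.0, 53.0, 52.0, 48.0),
        "a": (22.0, 26.0, 24.0, 22.0, 20.0),
        "b": (22.0, 26.0, 24.0, 22.0, 20.0),
    },
}
COLOR_REPLICATE_SD = 1.5  # fruit-to-fruit jitter on each Lab coordinate

# --- physicochemical anchors: {column: (per-day means, per-day SDs)} -------
PHYSICO_DEFAULTS: dict[str, tuple[tuple[float, ...], tuple[float, ...]]] = {
    "aw": ((0.980, 0.970, 0.980, 0.980, 0.950), (0.005,) * 5),
    "moisture_pct": ((89.0, 90.0, 91.0, 92.0, 91.5), (0.8,) * 5),
    "tss_brix": ((6.5, 6.6, 8.0, 8.0, 8.1), (0.5,) * 5),
    "ta_pct": ((0.70, 0.71, 0.78, 0.70, 0.55), (0.04,) * 5),
    "ascorbic_pct": ((0.060, 0.045, 0.058, 0.050, 0.040), (0.004,) * 5),
    "firmness_n": ((4.70, 6.40, 4.24, 4.88, 5.07), (1.66, 1.91, 1.17, 1.20, 1.44)),
    "adhesiveness": (
        (-0.024, -0.023, -0.039, -0.031, -0.044),
        (0.018, 0.013, 0.013, 0.015, 0.019),
    ),
    "cohesiveness": ((0.26, 0.30, 0.25, 0.27, 0.34), (0.03, 0.04, 0.04, 0.03, 0.10)),
    "hue_outer_deg": (
        (24.86, 26.60, 25.74, 26.81, 25.26),
        (3.40, 4.46, 4.19, 4.71, 2.38),
    ),
    "hue_inner_deg": (
        (46.62, 44.45, 45.70, 45.36, 44.26),
        (2.04, 1.68, 1.61, 0.70, 6.74),
    ),
    "tpc_mg_gae_g": ((1.8, 2.2, 2.8, 2.5, 2.3), (0.20,) * 5),
    "abts_mg_te_g": ((2.5, 3.0, 3.8, 3.4, 3.1), (0.25,) * 5),
    "frap_mg_fe2_g": ((8.0, 10.0, 13.0, 12.0, 11.0), (1.0,) * 5),
}

ASSAY_COLUMNS = ("tpc_mg_gae_g", "abts_mg_te_g", "frap_mg_fe2_g")
ASSAY_CORRELATION = 0.8  # target Pearson r between assay noise components

# --- FTIR band amplitude anchors (per-day mean, SD) keyed by band name -----
# two unmeasured cells (day 1 of 3645-3600, day 11 of 680-610) are filled
# with the mean of that band's measured days
BAND_DEFAULTS: dict[str, tuple[tuple[float, ...], tuple[float, ...]]] = {
    "3645-3600": ((0.01625, 0.020, 0.011, 0.023, 0.011), (0.003, 0.003, 0.003, 0.009, 0.003)),
    "3380": ((0.006, 0.004, 0.007, 0.006, 0.005), (0.001, 0.002, 0.001, 0.001, 0.001)),
    "2918-2920": ((0.317, 0.251, 0.370, 0.292, 0.279), (0.040, 0.070, 0.063, 0.072, 0.062)),
    "2850-2855": ((0.181, 0.134, 0.210, 0.174, 0.202), (0.030, 0.048, 0.053, 0.040, 0.038)),
    "1730-1742": ((0.111, 0.100, 0.109, 0.104, 0.093), (0.014, 0.021, 0.030, 0.017, 0.016)),
    "1632-1647": ((0.171, 0.184, 0.188, 0.197, 0.190), (0.012, 0.012, 0.010, 0.023, 0.013)),
    "1510-1520": ((0.010, 0.007, 0.017, 0.012, 0.011), (0.005, 0.003, 0.006, 0.004, 0.003)),
    "1420-1457": ((0.020, 0.019, 0.012, 0.017, 0.019), (0.006, 0.006, 0.003, 0.005, 0.004)),
    "1351-1378": ((0.017, 0.006, 0.018, 0.015, 0.021), (0.004, 0.004, 0.004, 0.005, 0.003)),
    "1245-1230": ((0.046, 0.035, 0.047, 0.043, 0.054), (0.006, 0.007, 0.012, 0.014, 0.009)),
    "1149-1155": ((0.023, 0.021, 0.026, 0.020, 0.022), (0.009, 0.008, 0.004, 0.010, 0.011)),
    "1105": ((0.058, 0.052, 0.054, 0.053, 0.056), (0.011, 0.012, 0.007, 0.009, 0.010)),
    "1050-1055": ((0.011, 0.006, 0.011, 0.008, 0.015), (0.003, 0.003, 0.004, 0.001, 0.002)),
    "1022-1028": ((0.068, 0.054, 0.060, 0.064, 0.081), (0.013, 0.013, 0.015, 0.018, 0.008)),
    "750-720": ((0.004, 0.003, 0.002, 0.003, 0.002), (0.002, 0.001, 0.001, 0.001, 0.001)),
    "680-610": ((0.001, 0.002, 0.001, 0.001, 0.00125), (0.001, 0.002, 0.003, 0.001, 0.001)),
    "523": ((0.009, 0.010, 0.010, 0.009, 0.008), (0.002, 0.003, 0.003, 0.002, 0.002)),
}

SPECTRUM_NOISE_SD = 0.0005  # white noise added to every grid point


@dataclass
class SyntheticConfig:
    """All generative parameters; the dataset is a pure function of this."""

    master_seed: int = 0
    days: tuple[int, ...] = DAYS
    n_replicates: int = 12
    n_rois: int = 8
    roi_size: int = 15
    image_shape: tuple[int, int] = (192, 256)  # H, W
    levels: int = 16
    texture: dict = field(default_factory=lambda: {k: v for k, v in TEXTURE_DEFAULTS.items()})
    color: dict = field(default_factory=lambda: json.loads(json.dumps(COLOR_DEFAULTS)))
    color_replicate_sd: float = COLOR_REPLICATE_SD
    physico: dict = field(default_factory=lambda: {k: v for k, v in PHYSICO_DEFAULTS.items()})
    assay_correlation: float = ASSAY_CORRELATION
    bands: dict = field(default_factory=lambda: {k: v for k, v in BAND_DEFAULTS.items()})
    spectrum_noise_sd: float = SPECTRUM_NOISE_SD

    def day_index(self, day: int) -> int:
        if day not in self.days:
            raise ValueError(f"unknown storage day {day}; configured days: {self.days}")
        return self.days.index(day)


def _rng(cfg: SyntheticConfig, *keys) -> np.random.Generator:
    """Deterministic generator from the master seed plus context keys."""
    ints = [cfg.master_seed]
    for k in keys:
        ints.append(zlib.crc32(str(k).encode()) if isinstance(k, str) else int(k))
    return np.random.default_rng(np.random.SeedSequence(ints))


def generate_surface_image(
    cfg: SyntheticConfig, day: int, replicate: str, surface: str = "outer"
) -> RGBImage:
    """One synthetic fruit-surface photograph.

    A seeded Gaussian noise field is smoothed with the day's correlation
    length, rescaled to the day's intensity moments, dark achene-like
    speckle spots are stamped in, and the relative intensity field modulates
    an RGB base color obtained from the day's CIELAB target (with
    fruit-to-fruit jitter).
    """
    i = cfg.day_index(day)
    if surface not in cfg.color:
        raise ValueError(f"unknown surface {surface!r}")
    rng = _rng(cfg, day, replicate, surface)
    h, w = cfg.image_shape

    corr = cfg.texture["correlation_length"][i]
    mean = cfg.texture["intensity_mean"][i]
    sd = cfg.texture["intensity_sd"][i]
    density = cfg.texture["speckle_density"][i]

    field_ = gaussian_filter(rng.standard_normal((h, w)), sigma=corr, mode="reflect")
    fsd = field_.std()
    if fsd > 0:
        field_ = (field_ - field_.mean()) / fsd
    gray = mean + sd * field_

    n_speckles = int(round(density * h * w / 10000.0))
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(n_speckles):
        cy, cx = rng.integers(0, h), rng.integers(0, w)
        r = rng.uniform(1.5, 3.0)
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        gray[disk] *= 0.45
    gray = np.clip(gray, 1.0, 255.0)

    col = cfg.color[surface]
    jitter = rng.normal(0.0, cfg.color_replicate_sd, size=3)
    lab = np.array([col["L"][i], col["a"][i], col["b"][i]]) + jitter
    base = lab2rgb(lab.reshape(1, 1, 3)).reshape(3)

    scale = gray / mean
    rgb = np.clip(base[None, None, :] * scale[:, :, None], 0.0, 1.0)
    px = np.round(rgb * 255.0).astype(np.uint8)
    return RGBImage(px, surface=surface, storage_day=day, replicate_id=replicate)


def generate_physico_table(cfg: SyntheticConfig, n_replicates: int | None = None) -> pd.DataFrame:
    """Replicate x measurement table with day-dependent anchors.

    The TPC/ABTS/FRAP assays share a latent noise component so their
    within-day noise correlates at ``cfg.assay_correlation``.
    """
    n = n_replicates if n_replicates is not None else cfg.n_replicates
    rng = _rng(cfg, "physico")
    rho = cfg.assay_correlation
    rows = []
    for day in cfg.days:
        i = cfg.day_index(day)
        for rep in range(n):
            row: dict = {"day": day, "replicate": f"r{rep:02d}"}
            z = rng.standard_normal()  # shared assay latent
            for col, (means, sds) in cfg.physico.items():
                eps = rng.standard_normal()
                if col in ASSAY_COLUMNS:
                    noise = np.sqrt(rho) * z + np.sqrt(1.0 - rho) * eps
                else:
                    noise = eps
                row[col] = means[i] + sds[i] * noise
            rows.append(row)
    return pd.DataFrame(rows)


def generate_spectra(cfg: SyntheticConfig, n_replicates: int | None = None) -> list[Spectrum]:
    """ATR-FTIR spectra on a 4000–500 cm^-1 grid (step 2, 1751 points).

    Each of the 17 diagnostic bands contributes a Gaussian peak centered in
    its window with a day-dependent amplitude; white noise is added on top.
    """
    n = n_replicates if n_replicates is not None else cfg.n_replicates
    grid = np.arange(4000.0, 499.0, -2.0)  # 4000 .. 500 inclusive
    centers = {b.name: (b.lo + b.hi) / 2.0 for b in DEFAULT_BANDS}
    widths = {b.name: max((b.hi - b.lo) / 4.0, 4.0) for b in DEFAULT_BANDS}
    out = []
    for day in cfg.days:
        i = cfg.day_index(day)
        for rep in range(n):
            rng = _rng(cfg, "spectrum", day, rep)
            absorb = np.zeros_like(grid)
            for name, (means, sds) in cfg.bands.items():
                amp = max(rng.normal(means[i], sds[i]), 0.0)
                absorb += amp * np.exp(-((grid - centers[name]) ** 2) / (2 * widths[name] ** 2))
            absorb += rng.normal(0.0, cfg.spectrum_noise_sd, size=grid.shape)
            out.append(Spectrum(grid.copy(), absorb, day=day, replicate=f"r{rep:02d}"))
    return out


def generate_images(
    cfg: SyntheticConfig,
    surfaces: tuple[str, ...] = ("outer", "inner"),
    days: tuple[int, ...] | None = None,
) -> list[RGBImage]:
    """All replicate images for the requested days and surfaces."""
    days = days if days is not None else cfg.days
    return [
        generate_surface_image(cfg, day, f"r{rep:02d}", surface)
        for day in days
        for rep in range(cfg.n_replicates)
        for surface in surfaces
    ]


def write_dataset(cfg: SyntheticConfig, outdir) -> dict[str, Path]:
    """Write the full synthetic dataset (images, manifest, tables, spectra).

    Returns the paths written.  This is the file-level entry point used by
    the examples; analyses can equally consume the in-memory objects.
    """
    outdir = Path(outdir)
    img_dir = outdir / "images"
    spc_dir = outdir / "spectra"
    img_dir.mkdir(parents=True, exist_ok=True)
    spc_dir.mkdir(parents=True, exist_ok=True)

    manifest_rows = []
    for img in generate_images(cfg):
        name = f"day{img.storage_day:02d}_{img.replicate_id}_{img.surface}.png"
        Image.fromarray(img.pixels).save(img_dir / name)
        manifest_rows.append(
            {
                "path": str(Path("images") / name),
                "surface": img.surface,
                "day": img.storage_day,
                "replicate": img.replicate_id,
            }
        )
    manifest = outdir / "manifest.csv"
    pd.DataFrame(manifest_rows).to_csv(manifest, index=False)

    physico = outdir / "physico.csv"
    generate_physico_table(cfg).to_csv(physico, index=False)

    for s in generate_spectra(cfg):
        fname = spc_dir / f"day{s.day:02d}_{s.replicate}.csv"
        pd.DataFrame({"wavenumber": s.wavenumbers, "absorbance": s.absorbance}).to_csv(
            fname, index=False, header=False
        )

    cfg_path = outdir / "config.json"
    cfg_path.write_text(json.dumps(asdict(cfg), indent=2, default=list))
    return {"manifest": manifest, "physico": physico, "images": img_dir,
            "spectra": spc_dir, "config": cfg_path}
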