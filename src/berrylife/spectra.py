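"""ATR-FTIR band-intensity summaries and per-day band tables.

A spectrum is absorbance on a descending wavenumber grid (cm^-1).  Band
intensity is the peak height (maximum absorbance) within a named
wavenumber window by default, or the window mean.  The default band set
covers 17 diagnostic regions between 523 and 3645 cm^-1 spanning O-H,
C-H, C=O, aromatic-ring and glycosidic-bond vibrations of water,
carbohydrates, organic acids and phenolics in fruit tissue; single-peak
labels (3380, 1105, 523 cm^-1) are widened to +/- 5 cm^-1 windows.

No baseline correction is applied by default; a linear baseline
subtraction over the full range is available behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .chemo_stats import anova_posthoc

logger = logging.getLogger(__name__)

_SINGLETON_HALF_WIDTH = 5.0  # cm^-1, window half-width for single-peak labels


@dataclass
class Spectrum:
    """Absorbance vs wavenumber (descending grid), with sample labels."""

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    day: int = 0
    replicate: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        if w.shape != a.shape or w.ndim != 1:
            raise ValueError("wavenumbers and absorbance must be equal-length 1-D")
        order = np.argsort(-w, kind="stable")
        self.wavenumbers = w[order]
        self.absorbance = a[order]
        d = np.diff(self.wavenumbers)
        if np.any(d == 0):
            logger.warning(
                "spectrum day=%s rep=%s: duplicate wavenumbers kept", self.day, self.replicate
            )


@dataclass(frozen=True)
class BandDefinition:
    """A named wavenumber window [lo, hi] with an assignment note."""

    name: str
    lo: float
    hi: float
    assignment: str = ""

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"band {self.name}: lo must be < hi")


#: 17 diagnostic absorbance regions (label, lo, hi, assignment).
DEFAULT_BANDS: tuple[BandDefinition, ...] = tuple(
    BandDefinition(name, lo, hi, note)
    for name, lo, hi, note in [
        ("3645-3600", 3600, 3645, "O-H stretch, phenolic compounds"),
        ("3380", 3375, 3385, "O-H stretch: water, organic acids, carbohydrates"),
        ("2918-2920", 2918, 2920, "asymmetric C-H stretch (CH3/CH2)"),
        ("2850-2855", 2850, 2855, "symmetric C-H stretch (CH3/CH2)"),
        ("1730-1742", 1730, 1742, "C=O stretch, esters (fragrance volatiles)"),
        ("1632-1647", 1632, 1647, "O-H bending; moisture content"),
        ("1510-1520", 1510, 1520, "aromatic C=C-C stretch (phenolics)"),
        ("1420-1457", 1420, 1457, "O-H bend + C-H rock; CH2 scissoring"),
        ("1351-1378", 1351, 1378, "citric acid"),
        ("1245-1230", 1230, 1245, "C-O stretch: carbohydrates, phenolics"),
        ("1149-1155", 1149, 1155, "C-H deformation in carbohydrates"),
        ("1105", 1100, 1110, "C-O / C-C stretch in carbohydrates"),
        ("1050-1055", 1050, 1055, "sucrose"),
        ("1022-1028", 1022, 1028, "glucose pyranose ring"),
        ("750-720", 720, 750, "CH2 rocking"),
        ("680-610", 610, 680, "alkyne C-H bending"),
        ("523", 518, 528, "C-C-C / C-O-C glycosidic bending"),
    ]
)


def read_spectrum(path, day: int = 0, replicate: str = "") -> Spectrum:
    """Parse a two-column (wavenumber, absorbance) text/CSV file."""
    try:
        df = pd.read_csv(path, header=None, comment="#")
        arr = df.iloc[:, :2].to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric rows in spectrum file {path!r}: {exc}") from exc
    return Spectrum(arr[:, 0], arr[:, 1], day=day, replicate=replicate)


def baseline_correct(s: Spectrum) -> Spectrum:
    """Subtract the straight line through the two endpoints of the spectrum."""
    w, a = s.wavenumbers, s.absorbance
    slope = (a[-1] - a[0]) / (w[-1] - w[0])
    base = a[0] + slope * (w - w[0])
    return Spectrum(w.copy(), a - base, day=s.day, replicate=s.replicate)


def band_intensity(s: Spectrum, band: BandDefinition, statistic: str = "peak_max") -> float:
    """Band intensity: peak height (default) or mean absorbance in the window."""
    mask = (s.wavenumbers >= band.lo) & (s.wavenumbers <= band.hi)
    if not mask.any():
        raise ValueError(
            f"band {band.name} [{band.lo}, {band.hi}] contains no grid point of the spectrum"
        )
    vals = s.absorbance[mask]
    if statistic == "peak_max":
        return float(vals.max())
    if statistic == "mean":
        return float(vals.mean())
    raise ValueError(f"unknown statistic {statistic!r}")


def band_table(
    spectra: Sequence[Spectrum],
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
    alpha: float = 0.05,
    statistic: str = "peak_max",
) -> pd.DataFrame:
    """Per-band, per-day mean ± SD of band intensities with compact letters.

    Rows are bands, columns are days; each cell holds mean, SD and the
    Tukey-HSD letter for that day.  Bands missing from some spectra give
    missing (NaN) cells, never zeros.  The output is invariant to the input
    order of the spectra.
    """
    days = sorted({s.day for s in spectra})
    if len(days) < 2:
        raise ValueError("need spectra from >= 2 days")
    rows = []
    for band in bands:
        per_day: dict[int, list[float]] = {d: [] for d in days}
        for s in sorted(spectra, key=lambda s: (s.day, s.replicate)):
            try:
                per_day[s.day].append(band_intensity(s, band, statistic))
            except ValueError:
                continue
        groups = [per_day[d] for d in days]
        usable = [g for g in groups if len(g) >= 2]
        letters: dict[int, str] = {d: "" for d in days}
        if len(usable) >= 2:
            present_days = [d for d in days if len(per_day[d]) >= 2]
            _, _, cld = anova_posthoc(
                [per_day[d] for d in present_days],
                alpha=alpha,
                group_names=[str(d) for d in present_days],
            )
            letters.update(dict(zip(present_days, cld.letters)))
        for d in days:
            g = per_day[d]
            rows.append(
                {
                    "band": band.name,
                    "day": d,
                    "mean": np.mean(g) if g else np.nan,
                    "sd": np.std(g, ddof=1) if len(g) >= 2 else np.nan,
                    "n": len(g),
                    "letters": letters[d],
                }
            )
    tidy = pd.DataFrame(rows)
    return tidy


def band_table_wide(tidy: pd.DataFrame, value: str = "mean") -> pd.DataFrame:
    """Pivot a tidy band table to bands x days (layout of a printed table)."""
    wide = tidy.pivot(index="band", columns="day", values=value)
    order = [b.name for b in DEFAULT_BANDS if b.name in set(tidy["band"])]
    extra = [b for b in wide.index if b not in order]
    return wide.reindex(order + extra)
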