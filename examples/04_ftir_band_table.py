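"""Summarize ATR-FTIR spectra into a band-intensity table across days.

Peak heights in 17 diagnostic wavenumber windows are averaged per storage
day; Tukey-HSD compact letters mark which days differ (days sharing a
letter are statistically indistinguishable at alpha = 0.05).
"""

from berrylife.spectra import band_table, band_table_wide
from berrylife.synthetic import SyntheticConfig, generate_spectra

spectra = generate_spectra(SyntheticConfig(master_seed=1))
tidy = band_table(spectra)

wide_mean = band_table_wide(tidy, "mean").round(3)
wide_letters = band_table_wide(tidy, "letters")
print("mean band intensity (rows: bands in cm^-1, columns: storage day):")
print(wide_mean.to_string())
print("\ncompact letters (per band, across days):")
print(wide_letters.to_string())
print(
    "\ne.g. the C-H stretching bands near 2920/2850 cm^-1 peak on day 6, "
    "mirroring the sugar increase at mid-storage."
)
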