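"""Extract the 18 per-ROI features from one fruit-surface image.

Eight non-overlapping 15x15 ROIs are sampled from the photograph; each
yields 15 grayscale texture features (first-order moments, co-occurrence
and run-length statistics) plus the mean CIELAB color (L*, a*, b*).
"""

from berrylife import imaging, texture
from berrylife.synthetic import SyntheticConfig, generate_surface_image

cfg = SyntheticConfig(master_seed=1)
img = generate_surface_image(cfg, day=11, replicate="r00", surface="outer")
gray = imaging.to_grayscale(img)
rois = imaging.extract_rois(img, n=8, size=15, mode="seeded_random", seed=1)

roi = rois[0]
rs, cs = roi.slices()
color = imaging.rgb_to_lab(img, roi)
fv = texture.feature_vector(gray.pixels[rs, cs], color)

print(f"day-11 outer surface, ROI at (row={roi.row}, col={roi.col}):")
for name, value in fv.items():
    print(f"  {name:22s} {value: .4f}")
print(
    "\nhigh contrast / low homogeneity marks a fragmented, aged surface; "
    "L*, a*, b* give the ROI's mean color (dark red here)."
)
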