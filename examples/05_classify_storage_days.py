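"""Discriminate storage days 1 / 6 / 11 with the ten-classifier roster.

Inner-surface lightness (mean L* over the fruit's ROIs) and the FRAP assay
form the feature pair; classifiers are compared by repeated stratified
K-fold accuracy, and the winner's decision surface is computed on the
PCA-score plane.
"""

import pandas as pd

from berrylife import chemometrics, pipeline, synthetic
from berrylife.synthetic import SyntheticConfig

cfg = SyntheticConfig(master_seed=1)
days = (1, 6, 11)

inner = synthetic.generate_images(cfg, surfaces=("inner",), days=days)
fruit = (
    pipeline.aggregate_per_fruit(pipeline.extract_feature_table(inner, seed=1))
    .sort_values(["day", "replicate"]).reset_index(drop=True)
)
phys = synthetic.generate_physico_table(cfg)
phys = phys[phys.day.isin(days)].sort_values(["day", "replicate"]).reset_index(drop=True)

X = pd.DataFrame({"L_star_inner": fruit["L_star"], "frap": phys["frap_mg_fe2_g"].to_numpy()})
y = fruit["day"].to_numpy()

results = chemometrics.evaluate_classifiers(X, y, seed=1)
print("classifier leaderboard (pooled repeated 5-fold accuracy):")
for res in results:
    counts = ", ".join(
        f"day {d}: {c}/{t}"
        for d, c, t in zip(res.class_labels, res.correct_per_class, res.total_per_class)
    )
    print(f"  {res.classifier:20s} {res.overall_accuracy_pct:5.1f}%   ({counts})")

best = results[0]
model = chemometrics.make_classifier(best.classifier, seed=1)
pca = chemometrics.pca2(X.to_numpy())
model.fit(pca.scores, y)
xx, yy, grid = chemometrics.decision_surface(model, pca.scores, grid_step=0.05)
print(
    f"\nbest: {best.classifier} at {best.overall_accuracy_pct:.1f}%; "
    f"decision surface computed on a {grid.shape[0]} x {grid.shape[1]} PCA-score grid"
)
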