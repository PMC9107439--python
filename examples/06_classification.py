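"""The discriminative protocol: CNN vs feature-GLM vs motion-GLM.

Each diagnostic group is compared against neurotypicals on a single
stratified 80/20 split and scored by PR-AUC on the held-out subjects.
The CNN sees the 14x1 RGB fingerprints; the feature GLM the 42 raw
network means; the motion GLM only mean framewise displacement.
"""

import numpy as np

from ieco import (
    CnnSpec,
    SplitSpec,
    assemble_dataset,
    encode_all,
    make_atlas,
    scale_features,
    simulate_cohort,
    study_cohort_spec,
    train_cnn,
    train_glm,
)
from ieco.pipeline import cohort_feature_table

atlas = make_atlas(seed=0)
spec = study_cohort_spec(effect=2.0, n_per_group=40, seed=0)
subjects = simulate_cohort(spec, atlas)
table, qc = cohort_feature_table(subjects, atlas, spec)
images = encode_all(scale_features(table))
merged = table.data[["subject_id", "group"]].merge(
    qc[["subject_id", "mean_fd"]], on="subject_id"
)

print(f"{len(table.data)} subjects retained; PR-AUC medians over 5 split seeds:")
print(f"{'model':12s} {'SCH':>6s} {'BIP':>6s} {'ADHD':>6s}")
rows = {"cnn": {}, "glm": {}, "glm-motion": {}}
for diagnosis in ("SCH", "BIP", "ADHD"):
    cnn = [train_cnn(images, (diagnosis, "TYP"), CnnSpec(seed=s), SplitSpec(seed=s)).pr_auc
           for s in range(5)]
    X, y, sids = assemble_dataset(table, (diagnosis, "TYP"))
    glm = [train_glm(X, y, sids, (diagnosis, "TYP"), SplitSpec(seed=s)).pr_auc
           for s in range(5)]
    sel = merged["group"].isin([diagnosis, "TYP"])
    fd = merged.loc[sel, "mean_fd"].to_numpy()
    ym = (merged.loc[sel, "group"] == diagnosis).to_numpy(int)
    mot = [train_glm(fd, ym, split=SplitSpec(seed=s), model_name="glm_motion").pr_auc
           for s in range(5)]
    rows["cnn"][diagnosis] = np.median(cnn)
    rows["glm"][diagnosis] = np.median(glm)
    rows["glm-motion"][diagnosis] = np.median(mot)
for model, vals in rows.items():
    print(f"{model:12s} " + " ".join(f"{100*vals[d]:5.1f}%" for d in ("SCH", "BIP", "ADHD")))
# With 2x injected effects the image-based classifiers are near-ceiling,
# while the motion-only baseline — groups differ only weakly in how much
# they move — stays far behind, as expected for a nuisance signal.
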