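"""From metric maps to color fingerprints, group images and the heatmap.

Network means are min-max scaled to [0, 255] and fused as RGB
(red = ECM, green = fALFF, blue = ReHo), giving one 14-band strip per
subject.  Group averages, diagnosis-minus-reference difference images
and the numeric difference heatmap summarise the cohort.  PNGs and TSVs
land in ./example_output/.
"""

from pathlib import Path

from ieco import make_atlas, simulate_cohort, study_cohort_spec
from ieco.encoding import (
    difference_heatmap,
    encode_all,
    group_images,
    save_color_image,
    save_heatmap_figure,
    scale_features,
)
from ieco.pipeline import cohort_feature_table

atlas = make_atlas(seed=0)
spec = study_cohort_spec(effect=2.0, n_per_group=8, seed=0)
subjects = simulate_cohort(spec, atlas)
table, qc = cohort_feature_table(subjects, atlas, spec)
print(f"{len(table.data)} of {len(subjects)} subjects retained after QC")

scaled = scale_features(table)  # global per-metric min/max
images = encode_all(scaled)
print(f"encoded {len(images)} fingerprints of {images[0].pixels.shape[0]} bands each")

out = Path("example_output")
out.mkdir(exist_ok=True)
groups = group_images(images, reference_group="TYP")
for gi in groups:
    stem = f"{gi.kind}_{gi.group}" + (f"_vs_{gi.reference}" if gi.reference else "")
    save_color_image(gi, out / f"{stem}.png")

heatmap = difference_heatmap(groups)
heatmap.to_csv(out / "difference_heatmap.tsv", sep="\t")
save_heatmap_figure(heatmap, out / "difference_heatmap.png")

print("\nlargest scaled differences vs TYP (signed, in 0-255 units):")
flat = heatmap.abs().stack(["group", "metric"], future_stack=True).sort_values(ascending=False)
for (net, grp, met), _ in flat.head(5).items():
    print(f"  {grp} {met:6s} {net:22s} {heatmap.loc[net, (grp, met)]:+7.1f}")
print(f"\nwrote images and heatmap to {out}/")
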