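"""Feature aggregation, min-max scaling, RGB fusion and group imaging."""

import numpy as np
import pandas as pd
import pytest

from conftest import random_feature_table
from ieco.encoding import (
    METRICS,
    FeatureTable,
    aggregate_rois,
    build_feature_table,
    difference_heatmap,
    encode_all,
    encode_subject,
    flag_ecm_degenerate,
    group_images,
    scale_features,
)
from ieco.metrics import MetricMap
from ieco.synthetic import SyntheticAtlas


def toy_atlas():
    vol = np.zeros((4, 4, 4), dtype=int)
    vol[:2] = 1
    vol[2:] = 2
    return SyntheticAtlas(label_volume=vol, label_names=["NetA", "NetB"])


def toy_maps(atlas, fill=None):
    maps = {}
    for i, m in enumerate(METRICS):
        vals = np.full(atlas.label_volume.shape, float(i + 1) if fill is None else fill)
        maps[m] = MetricMap(values=vals, metric_name=m, mask=atlas.mask)
    return maps


# ------------------------------------------------------------- aggregation


def test_aggregate_constant_map():
    atlas = toy_atlas()
    row = aggregate_rois(toy_maps(atlas), atlas)
    assert row["ECM_NetA"] == 1.0
    assert row["ReHo_NetB"] == 3.0
    assert len(row) == 6


def test_aggregate_is_arithmetic_mean():
    atlas = toy_atlas()
    maps = toy_maps(atlas)
    vals = maps["fALFF"].values
    vals[atlas.label_volume == 1] = 0.0
    idx = np.argwhere(atlas.label_volume == 1)
    for v, (i, j, k) in zip([1.0, 2.0, 3.0], idx[:3]):
        vals[i, j, k] = v
    expected = vals[atlas.label_volume == 1].mean()
    row = aggregate_rois(maps, atlas)
    assert row["fALFF_NetA"] == pytest.approx(expected)


def test_aggregate_excludes_degenerate_voxels():
    atlas = toy_atlas()
    maps = toy_maps(atlas)
    maps["ECM"].values[0, 0, 0] = 99.0
    maps["ECM"].degenerate_mask[0, 0, 0] = True
    row = aggregate_rois(maps, atlas)
    assert row["ECM_NetA"] == pytest.approx(1.0)  # outlier excluded


def test_aggregate_all_degenerate_label_raises():
    atlas = toy_atlas()
    maps = toy_maps(atlas)
    maps["ReHo"].degenerate_mask[atlas.label_volume == 2] = True
    with pytest.raises(ValueError, match="NetB.*ReHo"):
        aggregate_rois(maps, atlas)


# ---------------------------------------------------------- ecm degeneracy


def test_flag_ecm_degenerate_rules():
    rng = np.random.default_rng(0)
    table = random_feature_table(rng, n_per_group=2)
    assert flag_ecm_degenerate(table) == []
    df = table.data.copy()
    df.loc[1, "ECM_Net3"] = 0.0
    df.loc[2, "ECM_Net1"] = 1e-12  # strictly nonzero -> kept
    t2 = FeatureTable(data=df, network_names=table.network_names)
    assert flag_ecm_degenerate(t2) == [df.loc[1, "subject_id"]]


# ----------------------------------------------------------------- scaling


def test_scaling_formula_endpoints():
    df = pd.DataFrame(
        {
            "subject_id": ["a", "b", "c"],
            "group": ["g"] * 3,
            **{f"{m}_N": [2.0, 4.0, 6.0] for m in METRICS},
        }
    )
    table = FeatureTable(data=df, network_names=["N"])
    scaled = scale_features(table)
    for m in METRICS:
        assert list(scaled.scaled[f"{m}_N"]) == [0.0, 127.5, 255.0]


def test_scaling_is_idempotent():
    rng = np.random.default_rng(1)
    table = random_feature_table(rng)
    s1 = scale_features(table)
    t2 = FeatureTable(data=s1.scaled, network_names=table.network_names)
    s2 = scale_features(t2)
    assert np.allclose(
        s1.scaled.drop(columns=["subject_id", "group"]).to_numpy(dtype=float),
        s2.scaled.drop(columns=["subject_id", "group"]).to_numpy(dtype=float),
    )


def test_scaling_degenerate_scope_raises():
    df = pd.DataFrame(
        {
            "subject_id": ["a", "b"],
            "group": ["g", "g"],
            **{f"{m}_N": [1.0, 1.0] for m in METRICS},
        }
    )
    with pytest.raises(ValueError, match="degenerate"):
        scale_features(FeatureTable(data=df, network_names=["N"]))


def test_per_subject_scope_uses_each_strip_fully():
    rng = np.random.default_rng(2)
    table = random_feature_table(rng)
    scaled = scale_features(table, scope="per_subject_per_variable")
    for m in METRICS:
        block = scaled.scaled[scaled.metric_columns(m)].to_numpy(dtype=float)
        assert np.allclose(block.min(axis=1), 0.0)
        assert np.allclose(block.max(axis=1), 255.0)


# ---------------------------------------------------------------- encoding


def test_encode_channel_assignment_and_roundtrip():
    rng = np.random.default_rng(3)
    table = scale_features(random_feature_table(rng))
    sid = table.data["subject_id"].iloc[0]
    img = encode_subject(table, sid)
    assert img.pixels.shape == (5, 3)
    row = table.scaled[table.scaled["subject_id"] == sid].iloc[0]
    for ci, m in enumerate(METRICS):
        scaled_vals = row[table.metric_columns(m)].to_numpy(dtype=float)
        # decode(encode(x)) within 0.5 of the scaled value (8-bit rounding)
        assert np.all(np.abs(img.decode()[:, ci] - scaled_vals) <= 0.5)


def test_encode_pure_red_is_ecm_only():
    df = pd.DataFrame(
        {
            "subject_id": ["a", "b"],
            "group": ["g", "g"],
            "ECM_N": [1.0, 0.0],
            "fALFF_N": [0.0, 1.0],
            "ReHo_N": [0.0, 1.0],
        }
    )
    table = scale_features(FeatureTable(data=df, network_names=["N"]))
    img = encode_subject(table, "a")
    assert tuple(img.pixels[0]) == (255, 0, 0)  # pure red band
    img_b = encode_subject(table, "b")
    assert tuple(img_b.pixels[0]) == (0, 255, 255)


def test_channel_isolation():
    """Perturbing only ECM inputs changes only the red channel."""
    rng = np.random.default_rng(4)
    table = random_feature_table(rng)
    base = scale_features(table)
    sid = table.data["subject_id"].iloc[0]
    img0 = encode_subject(base, sid)

    df = table.data.copy()
    cols = table.metric_columns("ECM")
    df.loc[df["subject_id"] == sid, cols] = df.loc[df["subject_id"] == sid, cols] * 0.5
    pert = scale_features(FeatureTable(data=df, network_names=table.network_names))
    img1 = encode_subject(pert, sid)
    assert not np.array_equal(img0.pixels[:, 0], img1.pixels[:, 0])
    assert np.array_equal(img0.pixels[:, 1:], img1.pixels[:, 1:])


def test_encode_missing_value_raises():
    rng = np.random.default_rng(5)
    table = scale_features(random_feature_table(rng))
    table.scaled.loc[0, "ECM_Net1"] = np.nan
    with pytest.raises(ValueError, match="missing"):
        encode_subject(table, table.data["subject_id"].iloc[0])


# ------------------------------------------------------------ group images


def test_group_average_is_pixel_mean():
    rng = np.random.default_rng(6)
    table = scale_features(random_feature_table(rng, n_per_group=4))
    imgs = encode_all(table)
    out = group_images(imgs, reference_group="TYP")
    for gi in out:
        if gi.kind != "average":
            continue
        members = [im.pixels.astype(float) for im in imgs if im.group == gi.group]
        assert np.allclose(gi.pixels, np.mean(members, axis=0))


def test_identical_subjects_average_to_themselves():
    df = pd.DataFrame(
        {
            "subject_id": ["a", "b", "c"],
            "group": ["g1", "g1", "g2"],
            **{f"{m}_N": [3.0, 3.0, 9.0] for m in METRICS},
        }
    )
    table = scale_features(FeatureTable(data=df, network_names=["N"]))
    imgs = encode_all(table)
    out = group_images(imgs, reference_group="g2")
    avg = next(g for g in out if g.kind == "average" and g.group == "g1")
    assert np.allclose(avg.pixels, imgs[0].pixels.astype(float))


def test_difference_antisymmetry():
    rng = np.random.default_rng(7)
    table = scale_features(random_feature_table(rng, groups=("TYP", "SCH")))
    imgs = encode_all(table)
    d_ab = next(g for g in group_images(imgs, "TYP") if g.kind == "difference")
    d_ba = next(g for g in group_images(imgs, "SCH") if g.kind == "difference")
    assert np.allclose(d_ab.pixels, -d_ba.pixels)


def test_self_difference_is_zero():
    rng = np.random.default_rng(8)
    table = scale_features(random_feature_table(rng, groups=("TYP",)))
    imgs = encode_all(table)
    out = group_images(imgs, reference_group="TYP")
    assert all(g.kind == "average" for g in out)  # no non-reference group


def test_heatmap_matches_difference_channels():
    rng = np.random.default_rng(9)
    table = scale_features(random_feature_table(rng, groups=("TYP", "SCH", "BIP")))
    out = group_images(encode_all(table), "TYP")
    hm = difference_heatmap(out)
    for gi in out:
        if gi.kind != "difference":
            continue
        for ci, m in enumerate(METRICS):
            assert np.allclose(hm[(gi.group, m)].to_numpy(), gi.pixels[:, ci])


def test_feature_table_roundtrips_through_tsv(tmp_path):
    rng = np.random.default_rng(10)
    table = random_feature_table(rng)
    path = tmp_path / "features.tsv"
    table.to_tsv(path)
    back = FeatureTable(data=pd.read_csv(path, sep="\t"), network_names=table.network_names)
    assert np.allclose(
        back.data.drop(columns=["subject_id", "group"]).to_numpy(),
        table.data.drop(columns=["subject_id", "group"]).to_numpy(),
    )


def test_save_color_image_writes_png(tmp_path):
    from ieco.encoding import save_color_image

    rng = np.random.default_rng(11)
    table = scale_features(random_feature_table(rng))
    img = encode_all(table)[0]
    p = tmp_path / "strip.png"
    save_color_image(img, p)
    from PIL import Image

    with Image.open(p) as im:
        assert im.size == (20, 5 * 20)
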