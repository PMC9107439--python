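"""Network-level feature aggregation and RGB color fingerprints.

The three voxelwise metric maps are averaged per functional network,
min–max scaled to [0, 255] and fused with an additive RGB model:
eigenvector centrality drives the red channel, fALFF the green channel
and ReHo the blue channel.  Each subject becomes a K-band color strip
(K = 14 for the default atlas); group averages, group-minus-reference
difference images and a numeric difference heatmap summarise cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .metrics import MetricMap
from .synthetic import SyntheticAtlas

__all__ = [
    "METRICS",
    "FeatureTable",
    "SubjectColorImage",
    "GroupImage",
    "aggregate_rois",
    "build_feature_table",
    "flag_ecm_degenerate",
    "scale_features",
    "encode_subject",
    "encode_all",
    "group_images",
    "difference_heatmap",
    "save_color_image",
    "save_heatmap_figure",
]

# channel order: red, green, blue
METRICS = ("ECM", "fALFF", "ReHo")

SCALE_SCOPES = ("per_variable_global", "per_subject_per_variable")


def _col(metric: str, network: str) -> str:
    return f"{metric}_{network}"


@dataclass
class FeatureTable:
    """Subjects x (metric, network) table of raw network means.

    ``data`` holds columns subject_id, group and one ``{metric}_{network}``
    column per metric and network; ``scaled`` (same layout) holds the
    [0, 255] min-max scaled values once :func:`scale_features` has run.
    """

    data: pd.DataFrame
    network_names: List[str]
    scaled: Optional[pd.DataFrame] = None
    scale_scope: Optional[str] = None

    def __post_init__(self) -> None:
        missing = [
            _col(m, n)
            for m in METRICS
            for n in self.network_names
            if _col(m, n) not in self.data.columns
        ]
        if missing:
            raise ValueError(f"feature table missing columns: {missing[:5]} ...")

    @property
    def k(self) -> int:
        return len(self.network_names)

    def metric_columns(self, metric: str) -> List[str]:
        return [_col(metric, n) for n in self.network_names]

    def metric_values(self, metric: str, scaled: bool = False) -> pd.DataFrame:
        src = self.scaled if scaled else self.data
        if scaled and self.scaled is None:
            raise ValueError("table has not been scaled; run scale_features first")
        return src[self.metric_columns(metric)]

    def subjects(self) -> pd.Series:
        return self.data["subject_id"]

    def to_tsv(self, path, scaled: bool = False) -> None:
        src = self.scaled if scaled else self.data
        src.to_csv(path, sep="\t", index=False)


@dataclass
class SubjectColorImage:
    """K x 1 RGB strip, one color band per functional network."""

    pixels: np.ndarray  # (K, 3) uint8
    band_order: List[str]
    subject_id: str
    group: Optional[str] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.shape != (len(self.band_order), 3):
            raise ValueError("pixels must be (K, 3) matching band_order")

    def decode(self) -> np.ndarray:
        """Scaled feature values recovered from the 8-bit image."""
        return self.pixels.astype(float)


@dataclass
class GroupImage:
    """Group-average or group-difference strip in real-valued RGB space."""

    pixels: np.ndarray  # (K, 3) float; for differences, signed values
    band_order: List[str]
    group: str
    kind: str  # "average" | "difference"
    reference: Optional[str] = None


def aggregate_rois(
    metric_maps: Dict[str, MetricMap],
    atlas: SyntheticAtlas,
) -> Dict[str, float]:
    """One feature-table row: mean over in-label, non-degenerate voxels.

    ``metric_maps`` maps each of "ECM", "fALFF", "ReHo" to its MetricMap.
    """
    missing = [m for m in METRICS if m not in metric_maps]
    if missing:
        raise ValueError(f"missing metric maps: {missing}")
    row: Dict[str, float] = {}
    for metric in METRICS:
        mp = metric_maps[metric]
        if mp.values.shape != atlas.label_volume.shape:
            raise ValueError(f"{metric} map and atlas have different grids")
        usable = mp.mask & ~mp.degenerate_mask
        for label, name in enumerate(atlas.label_names, start=1):
            sel = (atlas.label_volume == label) & usable
            if not sel.any():
                raise ValueError(
                    f"network {label} ({name}) has no usable voxels for metric {metric}"
                )
            row[_col(metric, name)] = float(mp.values[sel].mean())
    return row


def build_feature_table(
    rows: Iterable[Dict[str, float]],
    subject_ids: Sequence[str],
    groups: Sequence[str],
    network_names: Sequence[str],
) -> FeatureTable:
    df = pd.DataFrame(list(rows))
    df.insert(0, "subject_id", list(subject_ids))
    df.insert(1, "group", list(groups))
    return FeatureTable(data=df, network_names=list(network_names))


def flag_ecm_degenerate(table: FeatureTable) -> List[str]:
    """Subjects with a network-level ECM value of exactly 0 (excluded
    because centrality could not be computed for at least one region)."""
    ecm = table.metric_values("ECM")
    bad = (ecm == 0).any(axis=1)
    return list(table.data.loc[bad.values, "subject_id"])


def scale_features(table: FeatureTable, scope: str = "per_variable_global") -> FeatureTable:
    """Min–max scale raw values to [0, 255]: x~ = 255 (x - min)/(max - min).

    ``per_variable_global``: min/max per metric over all subjects and
    networks (preserves between-subject contrast).
    ``per_subject_per_variable``: min/max per subject per metric across
    its K networks (each strip uses the full dynamic range).
    """
    if scope not in SCALE_SCOPES:
        raise ValueError(f"scope must be one of {SCALE_SCOPES}")
    scaled = table.data.copy()
    for metric in METRICS:
        cols = table.metric_columns(metric)
        block = table.data[cols].to_numpy(dtype=float)
        if scope == "per_variable_global":
            lo, hi = block.min(), block.max()
            if hi <= lo:
                raise ValueError(f"degenerate scaling scope: metric {metric} is constant")
            scaled[cols] = 255.0 * (block - lo) / (hi - lo)
        else:
            lo = block.min(axis=1, keepdims=True)
            hi = block.max(axis=1, keepdims=True)
            flat = (hi <= lo).ravel()
            if flat.any():
                subs = list(table.data.loc[flat, "subject_id"])
                raise ValueError(
                    f"degenerate scaling scope: metric {metric} constant for subjects {subs}"
                )
            scaled[cols] = 255.0 * (block - lo) / (hi - lo)
    return FeatureTable(
        data=table.data,
        network_names=table.network_names,
        scaled=scaled,
        scale_scope=scope,
    )


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=float) + 0.5)


def encode_subject(table: FeatureTable, subject_id: str) -> SubjectColorImage:
    """Fuse a subject's scaled (ECM, fALFF, ReHo) values into a K-band
    RGB strip; rounding half-up to 8 bits happens only here."""
    if table.scaled is None:
        raise ValueError("table has not been scaled; run scale_features first")
    sel = table.scaled["subject_id"] == subject_id
    if not sel.any():
        raise ValueError(f"subject {subject_id} not in table")
    row = table.scaled.loc[sel].iloc[0]
    pix = np.empty((table.k, 3))
    for ci, metric in enumerate(METRICS):
        vals = row[table.metric_columns(metric)].to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValueError(f"subject {subject_id}: missing scaled {metric} values")
        pix[:, ci] = vals
    return SubjectColorImage(
        pixels=_round_half_up(pix).astype(np.uint8),
        band_order=list(table.network_names),
        subject_id=subject_id,
        group=str(row["group"]),
    )


def encode_all(table: FeatureTable) -> List[SubjectColorImage]:
    return [encode_subject(table, sid) for sid in table.subjects()]


def group_images(
    images: Sequence[SubjectColorImage],
    reference_group: str = "TYP",
) -> List[GroupImage]:
    """Average image per group plus signed difference images versus the
    reference group (real-valued pixel space; clipping only at export)."""
    if not images:
        raise ValueError("no subject images")
    bands = images[0].band_order
    for im in images:
        if im.band_order != bands:
            raise ValueError("all images must share band order")
        if im.group is None:
            raise ValueError(f"subject {im.subject_id} has no group label")
    groups = sorted({im.group for im in images}, key=lambda g: (g != reference_group, g))
    if reference_group not in groups:
        raise ValueError(f"reference group {reference_group} has no subjects")

    averages: Dict[str, np.ndarray] = {}
    out: List[GroupImage] = []
    for g in groups:
        members = [im.pixels.astype(float) for im in images if im.group == g]
        averages[g] = np.mean(members, axis=0)
        out.append(GroupImage(pixels=averages[g], band_order=bands, group=g, kind="average"))
    for g in groups:
        if g == reference_group:
            continue
        out.append(
            GroupImage(
                pixels=averages[g] - averages[reference_group],
                band_order=bands,
                group=g,
                kind="difference",
                reference=reference_group,
            )
        )
    return out


def difference_heatmap(images: Sequence[GroupImage]) -> pd.DataFrame:
    """Networks x (group, metric) matrix of signed scaled differences.

    Each cell is the signed mean difference of one metric in one network
    for one group versus the reference — numerically identical to the
    corresponding channel of that group's difference image.
    """
    diffs = [im for im in images if im.kind == "difference"]
    if not diffs:
        raise ValueError("need at least one difference image")
    bands = diffs[0].band_order
    cols = {}
    for im in diffs:
        for ci, metric in enumerate(METRICS):
            cols[(im.group, metric)] = im.pixels[:, ci]
    df = pd.DataFrame(cols, index=bands)
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["group", "metric"])
    df.index.name = "network"
    return df


def save_color_image(
    image: Union[SubjectColorImage, GroupImage],
    path: Union[str, Path],
    scale: int = 20,
    difference_mode: str = "absolute",
) -> None:
    """Export a strip as PNG with nearest-neighbour upscaling.

    Group-difference images are signed; ``difference_mode`` selects the
    rendering: "absolute" (|d|), "clip" (negative -> 0) or "symmetric"
    (128 + d/2, so no difference renders mid-grey).
    """
    from PIL import Image

    pix = np.asarray(image.pixels, dtype=float)
    if isinstance(image, GroupImage) and image.kind == "difference":
        if difference_mode == "absolute":
            pix = np.abs(pix)
        elif difference_mode == "clip":
            pix = np.clip(pix, 0, None)
        elif difference_mode == "symmetric":
            pix = 128.0 + pix / 2.0
        else:
            raise ValueError("difference_mode must be absolute, clip or symmetric")
    arr = np.clip(_round_half_up(pix), 0, 255).astype(np.uint8)[:, None, :]  # (K, 1, 3)
    im = Image.fromarray(arr, mode="RGB")
    im = im.resize((scale, arr.shape[0] * scale), resample=Image.NEAREST)
    im.save(str(path))


def save_heatmap_figure(heatmap: pd.DataFrame, path: Union[str, Path]) -> None:
    """Render the difference heatmap with a diverging colormap."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vmax = float(np.abs(heatmap.to_numpy()).max()) or 1.0
    fig, ax = plt.subplots(figsize=(1.2 + 0.5 * heatmap.shape[1], 0.4 * heatmap.shape[0] + 1.5))
    im = ax.imshow(heatmap.to_numpy(), cmap="RdBu_r", vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_xticks(range(heatmap.shape[1]))
    ax.set_xticklabels([f"{g}\n{m}" for g, m in heatmap.columns], fontsize=7)
    ax.set_yticks(range(heatmap.shape[0]))
    ax.set_yticklabels(heatmap.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="scaled difference vs reference")
    fig.tight_layout()
    fig.savefig(str(path), dpi=150)
    plt.close(fig)
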