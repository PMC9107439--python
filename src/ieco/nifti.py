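"""Reading and writing the package's on-disk formats.

NIfTI via nibabel (repetition time carried in the 4th pixdim), motion
parameters as 6-column whitespace text, censor vectors as one 0/1 per
line, label tables and feature tables as TSV.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Optional, Tuple, Union

import nibabel as nib
import numpy as np
import pandas as pd

from .metrics import BoldSeries, MetricMap
from .motion import MotionTrace
from .synthetic import SyntheticAtlas

PathLike = Union[str, Path]


def save_bold(data: np.ndarray, repetition_time: float, voxel_size: float,
              path: PathLike) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine=np.diag([voxel_size] * 3 + [1.0]))
    img.header.set_zooms((voxel_size,) * 3 + (repetition_time,))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def load_bold(path: PathLike, mask_path: Optional[PathLike] = None,
              censor_path: Optional[PathLike] = None,
              repetition_time: Optional[float] = None) -> BoldSeries:
    """Load a 4D NIfTI as a BoldSeries; TR from the header unless given."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected 4D BOLD, got shape {data.shape}")
    tr = repetition_time if repetition_time is not None else float(img.header.get_zooms()[3])
    if tr <= 0:
        raise ValueError(f"{path}: no usable repetition time in header; pass repetition_time")
    if mask_path is not None:
        mask = np.asanyarray(nib.load(str(mask_path)).dataobj) > 0
    else:
        mask = np.ones(data.shape[:3], dtype=bool)
    censor = load_censor(censor_path) if censor_path is not None else None
    return BoldSeries(data=data, mask=mask, repetition_time=tr, censor=censor)


def save_metric_map(m: MetricMap, path: PathLike, voxel_size: float = 3.0,
                    degenerate_path: Optional[PathLike] = None) -> None:
    aff = np.diag([voxel_size] * 3 + [1.0])
    nib.save(nib.Nifti1Image(m.values.astype(np.float32), aff), str(path))
    if degenerate_path is not None:
        nib.save(nib.Nifti1Image(m.degenerate_mask.astype(np.uint8), aff), str(degenerate_path))


def save_atlas(atlas: SyntheticAtlas, nii_path: PathLike, tsv_path: PathLike) -> None:
    aff = np.diag([atlas.voxel_size] * 3 + [1.0])
    nib.save(nib.Nifti1Image(atlas.label_volume.astype(np.int16), aff), str(nii_path))
    pd.DataFrame(
        {"label": np.arange(1, atlas.k + 1), "name": atlas.label_names}
    ).to_csv(tsv_path, sep="\t", index=False)


def load_atlas(nii_path: PathLike, tsv_path: Optional[PathLike] = None) -> SyntheticAtlas:
    img = nib.load(str(nii_path))
    vol = np.asanyarray(img.dataobj).astype(int)
    k = int(vol.max())
    if tsv_path is not None:
        table = pd.read_csv(tsv_path, sep="\t")
        names = [str(n) for n in table.sort_values("label")["name"]]
    else:
        names = [f"Network{i:02d}" for i in range(1, k + 1)]
    voxel_size = float(img.header.get_zooms()[0])
    return SyntheticAtlas(label_volume=vol, label_names=names, voxel_size=voxel_size)


def load_motion(path: PathLike, sphere_radius: float = 50.0) -> MotionTrace:
    return MotionTrace(params=np.loadtxt(str(path)), sphere_radius=sphere_radius)


def save_censor(censor: np.ndarray, path: PathLike) -> None:
    np.savetxt(str(path), np.asarray(censor, dtype=int), fmt="%d")


def load_censor(path: PathLike) -> np.ndarray:
    return np.loadtxt(str(path)).astype(bool)


def load_participants(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"subject_id", "group"} <= set(df.columns):
        raise ValueError(f"{path}: participants TSV needs subject_id and group columns")
    return df
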