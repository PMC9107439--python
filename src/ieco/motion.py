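"""Head-motion quality control: framewise displacement, frame censoring
and subject-level exclusion.

Framewise displacement (FD) follows the scrubbing convention of summing
absolute backward differences of the six rigid-body parameters, with
rotations (radians) projected onto a 50 mm sphere.  Frames with
FD > 0.5 mm are censored; subjects exceeding 2 mm of absolute translation
and/or with more than 20% of frames above the FD threshold are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = ["MotionTrace", "QCReport", "framewise_displacement", "apply_qc"]


@dataclass
class MotionTrace:
    """T x 6 rigid-body parameters: 3 translations (mm), 3 rotations (rad)."""

    params: np.ndarray
    sphere_radius: float = 50.0

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError("motion parameters must be a T x 6 array")
        if self.params.shape[0] < 2:
            raise ValueError("need at least 2 timepoints of motion parameters")
        if np.isnan(self.params).any():
            raise ValueError("motion parameters contain NaN")
        if self.sphere_radius <= 0:
            raise ValueError("sphere_radius must be positive")

    @property
    def translations(self) -> np.ndarray:
        return self.params[:, :3]

    @property
    def rotations(self) -> np.ndarray:
        return self.params[:, 3:]


@dataclass
class QCReport:
    """Per-run motion QC summary."""

    fd: np.ndarray
    censor: np.ndarray  # True = keep
    mean_fd: float
    max_abs_motion: float
    excluded: bool
    reason: str


def framewise_displacement(trace: MotionTrace) -> np.ndarray:
    """FD_t = sum |delta translations| + sphere_radius * sum |delta rotations|.

    The first frame has no predecessor and is assigned FD 0.
    """
    d = np.abs(np.diff(trace.params, axis=0))
    fd = d[:, :3].sum(axis=1) + trace.sphere_radius * d[:, 3:].sum(axis=1)
    return np.concatenate(([0.0], fd))


def apply_qc(
    fd: np.ndarray,
    censor_threshold: float = 0.5,
    max_motion: float = 2.0,
    max_bad_fraction: float = 0.20,
    trace: Optional[MotionTrace] = None,
    motion_mode: str = "max_abs",
) -> QCReport:
    """Censor high-FD frames and decide subject-level exclusion.

    A subject is excluded when the maximum absolute translation exceeds
    ``max_motion`` (mm) and/or when more than ``max_bad_fraction`` of
    frames have FD above ``censor_threshold``.  The translation check
    needs the original trace; without one only the FD rule applies.
    ``motion_mode='peak_to_peak'`` uses the translation range instead of
    the maximum excursion from the reference frame.
    """
    fd = np.asarray(fd, dtype=float)
    if fd.ndim != 1 or len(fd) == 0:
        raise ValueError("fd must be a non-empty 1D array")
    censor = fd <= censor_threshold
    bad_fraction = float((~censor).mean())

    max_abs_motion = 0.0
    if trace is not None:
        t = trace.translations
        if motion_mode == "peak_to_peak":
            max_abs_motion = float(np.max(t.max(axis=0) - t.min(axis=0)))
        else:
            max_abs_motion = float(np.max(np.abs(t)))

    reasons = []
    if max_abs_motion > max_motion:
        reasons.append(f"max translation {max_abs_motion:.2f} mm > {max_motion} mm")
    if bad_fraction > max_bad_fraction:
        reasons.append(
            f"{100 * bad_fraction:.1f}% of frames above FD {censor_threshold} mm "
            f"(limit {100 * max_bad_fraction:.0f}%)"
        )
    return QCReport(
        fd=fd,
        censor=censor,
        mean_fd=float(fd.mean()),
        max_abs_motion=max_abs_motion,
        excluded=bool(reasons),
        reason="; ".join(reasons) if reasons else "passed",
    )
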