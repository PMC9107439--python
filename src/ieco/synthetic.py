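"""Synthetic resting-state cohorts with controllable network-level effects.

Emulates the structure of a four-group clinical resting-state study
(neurotypicals plus three diagnostic groups): a K-network atlas, 4D BOLD
per subject, rigid-body motion traces and a participants table.  Group
effects are injected per network through three multipliers, each designed
to move exactly one of the three downstream metrics:

* ``low_freq_power`` — redistributes a fixed per-voxel sinusoid energy
  budget between an in-band (0.05 Hz) and an out-of-band (0.2 Hz) tone,
  moving fALFF while leaving total variance (hence ReHo and ECM) alone.
* ``local_coupling`` — weight of a neighborhood-shared broadband field
  (spatially smoothed noise), moving regional homogeneity while barely
  touching the global correlation structure that centrality sees.
* ``hub_strength`` — how strongly the network's fixed-amplitude shared
  carrier mixes with a latent global "hub" series (variance-preserving
  rotation), moving eigenvector centrality without changing the
  carrier's variance, hence without moving ReHo.

All broadband components carry exactly half their variance inside the
0.01–0.1 Hz band so that weight changes do not leak into fALFF.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .metrics import BoldSeries

__all__ = [
    "SyntheticAtlas",
    "GroupEffects",
    "MotionProfile",
    "CohortSpec",
    "SyntheticSubject",
    "make_atlas",
    "simulate_cohort",
    "study_cohort_spec",
    "write_cohort",
    "STANFORD_NETWORK_NAMES",
]

# The 14 functional networks of the Stanford FIND resting-state atlas,
# used as default labels when k=14.
STANFORD_NETWORK_NAMES = [
    "AnteriorSalience",
    "Auditory",
    "BasalGanglia",
    "DorsalDMN",
    "HigherVisual",
    "Language",
    "LeftExecutiveControl",
    "PosteriorSalience",
    "Precuneus",
    "PrimaryVisual",
    "RightExecutiveControl",
    "Sensorimotor",
    "VentralDMN",
    "Visuospatial",
]

MIN_BLOCK = 3  # voxels per axis so a full 27-voxel ReHo neighbourhood fits


@dataclass
class SyntheticAtlas:
    """Integer-labelled network atlas (0 = background, 1..K networks)."""

    label_volume: np.ndarray
    label_names: List[str]
    voxel_size: float = 3.0

    def __post_init__(self) -> None:
        self.label_volume = np.asarray(self.label_volume, dtype=int)
        labels = np.unique(self.label_volume)
        labels = labels[labels > 0]
        k = len(self.label_names)
        if not np.array_equal(labels, np.arange(1, k + 1)):
            raise ValueError("labels must be contiguous integers 1..K matching label_names")

    @property
    def k(self) -> int:
        return len(self.label_names)

    @property
    def mask(self) -> np.ndarray:
        return self.label_volume > 0


@dataclass
class GroupEffects:
    """Per-network multipliers (scalar broadcasts to all K networks)."""

    local_coupling: Union[float, np.ndarray] = 1.0
    low_freq_power: Union[float, np.ndarray] = 1.0
    hub_strength: Union[float, np.ndarray] = 1.0

    def per_network(self, k: int) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        out = []
        for m in (self.local_coupling, self.low_freq_power, self.hub_strength):
            arr = np.broadcast_to(np.asarray(m, dtype=float), (k,)).copy()
            if (arr < 0).any():
                raise ValueError("effect multipliers must be >= 0")
            out.append(arr)
        return tuple(out)  # type: ignore[return-value]


@dataclass
class MotionProfile:
    """Mean/SD (mm) of a subject's typical per-frame translation step."""

    step_mean: float = 0.06
    step_sd: float = 0.02


@dataclass
class CohortSpec:
    """Cohort layout, acquisition parameters and injected group effects.

    Defaults mirror a typical resting-state acquisition: TR = 2 s,
    128 volumes, voxel time series with mean 100 and unit noise SD.
    """

    group_labels: Sequence[str] = ("TYP", "SCH", "BIP", "ADHD")
    n_per_group: Union[int, Dict[str, int]] = 40
    n_timepoints: int = 128
    repetition_time: float = 2.0
    effects: Dict[str, GroupEffects] = field(default_factory=dict)
    motion_profiles: Dict[str, MotionProfile] = field(default_factory=dict)
    seed: int = 0
    # signal-model constants (study conditions, not per-run dials)
    baseline: float = 100.0
    sin_amplitude: float = 1.0
    coupling_amplitude: float = 0.8
    network_amplitude: float = 0.5
    hub_mixing: float = 0.4
    noise_sd: float = 1.0
    freq_in_band: float = 0.05
    freq_out_band: float = 0.2
    band: Tuple[float, float] = (0.01, 0.1)

    def __post_init__(self) -> None:
        if self.n_timepoints < 64:
            raise ValueError("n_timepoints must be >= 64")
        if self.repetition_time <= 0:
            raise ValueError("repetition_time must be positive")
        nyq = 1.0 / (2.0 * self.repetition_time)
        for f in (self.freq_in_band, self.freq_out_band):
            if f >= nyq:
                raise ValueError(
                    f"injected sinusoid at {f} Hz is not below the Nyquist frequency {nyq} Hz "
                    f"for repetition_time={self.repetition_time} s"
                )

    def group_size(self, group: str) -> int:
        if isinstance(self.n_per_group, dict):
            return self.n_per_group[group]
        return self.n_per_group


@dataclass
class SyntheticSubject:
    """One simulated participant: BOLD, motion trace and group label."""

    bold: np.ndarray
    motion_params: np.ndarray
    group: str
    subject_id: str

    def __post_init__(self) -> None:
        if np.isnan(self.bold).any():
            raise ValueError("BOLD contains NaN")
        if self.motion_params.shape != (self.bold.shape[3], 6):
            raise ValueError("motion_params must have one row per timepoint")

    def bold_series(self, atlas: SyntheticAtlas, repetition_time: float,
                    censor: Optional[np.ndarray] = None) -> BoldSeries:
        return BoldSeries(
            data=self.bold,
            mask=atlas.mask,
            repetition_time=repetition_time,
            censor=censor,
        )


def _block_arrangement(k: int, shape: Sequence[int]) -> Tuple[int, int, int]:
    """Smallest grid of >=3-voxel blocks holding at least k blocks."""
    maxes = [s // MIN_BLOCK for s in shape]
    best = None
    for nx, ny, nz in itertools.product(*(range(1, m + 1) for m in maxes)):
        prod = nx * ny * nz
        if prod < k:
            continue
        key = (prod, max(nx, ny, nz))
        if best is None or key < best[0]:
            best = (key, (nx, ny, nz))
    if best is None:
        need = int(np.ceil(k ** (1 / 3))) * MIN_BLOCK
        raise ValueError(
            f"grid {tuple(shape)} too small for {k} networks of "
            f"{MIN_BLOCK}x{MIN_BLOCK}x{MIN_BLOCK} voxels; "
            f"minimum shape about ({need}, {need}, {need})"
        )
    return best[1]


def make_atlas(
    k_networks: int = 14,
    grid_shape: Sequence[int] = (12, 12, 14),
    seed: int = 0,
    voxel_size: float = 3.0,
) -> SyntheticAtlas:
    """Axis-aligned block atlas with ``k_networks`` contiguous labels.

    The grid is split into near-equal blocks of at least 3 voxels per
    axis; the first ``k_networks`` blocks (in seed-shuffled order) get
    labels 1..K, any leftover blocks stay background.  Each label is a
    contiguous block of >= 27 voxels, so every network interior supports
    a full 27-voxel ReHo neighbourhood.
    """
    if k_networks < 1:
        raise ValueError("k_networks must be >= 1")
    shape = tuple(int(s) for s in grid_shape)
    n_blocks = _block_arrangement(k_networks, shape)
    edges = [np.linspace(0, s, n + 1).astype(int) for s, n in zip(shape, n_blocks)]

    blocks = list(itertools.product(*(range(n) for n in n_blocks)))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(blocks))

    vol = np.zeros(shape, dtype=int)
    for label, bi in enumerate(order[:k_networks], start=1):
        i, j, k = blocks[bi]
        vol[
            edges[0][i]:edges[0][i + 1],
            edges[1][j]:edges[1][j + 1],
            edges[2][k]:edges[2][k + 1],
        ] = label

    if k_networks == 14:
        names = list(STANFORD_NETWORK_NAMES)
    else:
        names = [f"Network{i:02d}" for i in range(1, k_networks + 1)]
    return SyntheticAtlas(label_volume=vol, label_names=names, voxel_size=voxel_size)


def _balanced_noise(rng: np.random.Generator, n: int, tr: float,
                    band: Tuple[float, float], size: int = 1) -> np.ndarray:
    """Unit-variance Gaussian noise with exactly half its power in-band.

    White noise is split in the frequency domain into its in-band and
    out-of-band parts, each rescaled to variance 1/2 and re-summed, so
    re-weighting this component never shifts a voxel's fALFF.
    """
    freqs = np.fft.rfftfreq(n, d=tr)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    out_band = ~in_band & (freqs > 0)
    if n % 2 == 0:
        out_band[-1] = False  # drop Nyquist so both halves are sign-symmetric
    z = rng.standard_normal((size, n))
    Z = np.fft.rfft(z, axis=1)
    x_in = np.fft.irfft(Z * in_band, n=n, axis=1)
    x_out = np.fft.irfft(Z * out_band, n=n, axis=1)
    x_in /= x_in.std(axis=1, keepdims=True)
    x_out /= x_out.std(axis=1, keepdims=True)
    out = (x_in + x_out) / np.sqrt(2.0)
    return out[0] if size == 1 else out


def _subject_rng(seed: int, group_index: int, subject_index: int) -> np.random.Generator:
    # independent substream per subject; adding groups/subjects later
    # never reshuffles existing ones
    return np.random.default_rng(np.random.SeedSequence([seed, group_index, subject_index]))


def _smoothed_field(rng: np.random.Generator, shape, T: int, tr: float,
                    band: Tuple[float, float]) -> np.ndarray:
    """Neighborhood-shared noise: a spatially box-smoothed (3x3x3) white
    field, renormalised per voxel to unit variance.  Adjacent voxels
    share most of their smoothing kernel, so the field raises local
    concordance without building long-range correlation."""
    from scipy.ndimage import uniform_filter

    nvox = int(np.prod(shape))
    field = _balanced_noise(rng, T, tr, band, size=nvox).reshape(shape + (T,))
    field = uniform_filter(field, size=(3, 3, 3, 1), mode="nearest")
    sd = field.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return field / sd


def simulate_cohort(spec: CohortSpec, atlas: SyntheticAtlas) -> List[SyntheticSubject]:
    """Simulate all subjects of a cohort; bit-reproducible from the seed.

    Per voxel v of network n the BOLD model is

        bold = baseline
             + A_sin * [sqrt(p) sin(2 pi f_in t + phi1_v)
                        + sqrt(1-p) sin(2 pi f_out t + phi2_v)]
             + A_net * u_n(t)
             + A_loc * m_local * s_v(t)
             + noise_sd * eps_v(t)

    with p = m_lfp^2 / (1 + m_lfp^2) the in-band share of the sinusoid
    budget, u_n = sqrt(1-b^2) e_n + b h the fixed-amplitude network
    carrier rotated toward the global hub series h by
    b = hub_mixing * m_hub (clipped at 0.95), s_v a neighborhood-shared
    smoothed field, and per-voxel tone phases and noise.  Motion is a
    random walk whose per-frame step scale is drawn from the group's
    motion profile.
    """
    k = atlas.k
    T = spec.n_timepoints
    tr = spec.repetition_time
    t = np.arange(T) * tr
    subjects: List[SyntheticSubject] = []

    for gi, group in enumerate(spec.group_labels):
        eff = spec.effects.get(group, GroupEffects())
        m_loc, m_lfp, m_hub = eff.per_network(k)
        profile = spec.motion_profiles.get(group, MotionProfile())
        for si in range(spec.group_size(group)):
            rng = _subject_rng(spec.seed, gi, si)
            h = _balanced_noise(rng, T, tr, spec.band)
            e = _balanced_noise(rng, T, tr, spec.band, size=k)
            local = _smoothed_field(rng, atlas.label_volume.shape, T, tr, spec.band)

            bold = np.full(atlas.label_volume.shape + (T,), spec.baseline, dtype=float)
            for n in range(k):
                sel = atlas.label_volume == n + 1
                nv = int(sel.sum())
                b = min(spec.hub_mixing * m_hub[n], 0.95)
                u = np.sqrt(1.0 - b * b) * e[n] + b * h
                p = m_lfp[n] ** 2 / (1.0 + m_lfp[n] ** 2)
                phi1 = rng.uniform(0, 2 * np.pi, nv)[:, None]
                phi2 = rng.uniform(0, 2 * np.pi, nv)[:, None]
                tones = spec.sin_amplitude * (
                    np.sqrt(p) * np.sin(2 * np.pi * spec.freq_in_band * t + phi1)
                    + np.sqrt(1.0 - p) * np.sin(2 * np.pi * spec.freq_out_band * t + phi2)
                )
                eps = spec.noise_sd * _balanced_noise(rng, T, tr, spec.band, size=nv)
                bold[sel] += (
                    tones
                    + spec.network_amplitude * u
                    + spec.coupling_amplitude * m_loc[n] * local[sel]
                    + eps
                )

            # background voxels: independent noise only
            bg = atlas.label_volume == 0
            if bg.any():
                bold[bg] += spec.noise_sd * _balanced_noise(rng, T, tr, spec.band, size=int(bg.sum()))

            motion = _simulate_motion(rng, T, profile)
            subjects.append(
                SyntheticSubject(
                    bold=bold,
                    motion_params=motion,
                    group=group,
                    subject_id=f"sub-{group}{si + 1:03d}",
                )
            )
    return subjects


def _simulate_motion(rng: np.random.Generator, T: int, profile: MotionProfile) -> np.ndarray:
    """Random-walk rigid-body parameters with group-dependent step scale."""
    severity = max(float(rng.normal(profile.step_mean, profile.step_sd)), 0.0)
    # split the severity budget between translations and sphere-projected rotations
    s_trans = severity * np.sqrt(np.pi / 2.0) / 3.0
    s_rot = s_trans / 50.0
    steps = np.concatenate(
        [rng.normal(0, s_trans, (T - 1, 3)), rng.normal(0, s_rot, (T - 1, 3))],
        axis=1,
    )
    params = np.zeros((T, 6))
    params[1:] = np.cumsum(steps, axis=0)
    return params


def study_cohort_spec(
    effect: float = 2.0,
    n_per_group: Union[int, Dict[str, int]] = 40,
    n_timepoints: int = 128,
    repetition_time: float = 2.0,
    seed: int = 0,
) -> CohortSpec:
    """The default four-group study: TYP baseline plus three diagnostic
    groups with network-specific effects of strength ``effect``.

    The patterns echo the qualitative picture of psychotic-spectrum
    resting-state findings: schizophrenia- and bipolar-like groups get
    widespread effects (higher local coupling and hub centrality in some
    networks, lower low-frequency power in others), the ADHD-like group
    a sparse, local one.  ``effect=1`` is an exact null cohort.
    """
    m, inv = effect, 1.0 / effect

    def pattern(networks, value, k=14):
        arr = np.ones(k)
        arr[np.asarray(networks) - 1] = value
        return arr

    effects = {
        "TYP": GroupEffects(),
        "SCH": GroupEffects(
            local_coupling=pattern([1, 2, 3, 8, 13], m),
            low_freq_power=pattern([2, 6, 9, 12, 13, 14], inv),
            hub_strength=pattern([5, 8, 11, 13, 14], m),
        ),
        "BIP": GroupEffects(
            local_coupling=pattern([10], m),
            low_freq_power=pattern([1, 4, 6, 7, 9, 11, 12, 14], inv),
            hub_strength=pattern([1, 2, 3], m),
        ),
        "ADHD": GroupEffects(
            local_coupling=pattern([7, 11], m),
        ),
    }
    # group means differ by well under one between-subject SD: head motion
    # separates diagnoses only weakly, so the motion-only baseline stays
    # far behind classifiers that see the BOLD-derived features
    motion = {
        "TYP": MotionProfile(0.10, 0.05),
        "SCH": MotionProfile(0.13, 0.05),
        "BIP": MotionProfile(0.12, 0.05),
        "ADHD": MotionProfile(0.13, 0.05),
    }
    return CohortSpec(
        group_labels=("TYP", "SCH", "BIP", "ADHD"),
        n_per_group=n_per_group,
        n_timepoints=n_timepoints,
        repetition_time=repetition_time,
        effects=effects,
        motion_profiles=motion,
        seed=seed,
    )


def write_cohort(
    subjects: Sequence[SyntheticSubject],
    atlas: SyntheticAtlas,
    spec: CohortSpec,
    outdir: Union[str, Path],
) -> None:
    """Write a cohort to disk in standard neuroimaging formats.

    Per subject a 4D NIfTI (TR in the header) and a 6-column motion text
    file; plus the atlas NIfTI, a label TSV and a participants TSV.
    """
    from . import nifti as _io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _io.save_atlas(atlas, outdir / "atlas.nii", outdir / "atlas_labels.tsv")
    rows = []
    for sub in subjects:
        _io.save_bold(
            sub.bold, spec.repetition_time, atlas.voxel_size,
            outdir / f"{sub.subject_id}_bold.nii",
        )
        np.savetxt(outdir / f"{sub.subject_id}_motion.1D", sub.motion_params, fmt="%.6f")
        rows.append((sub.subject_id, sub.group))
    with open(outdir / "participants.tsv", "w") as f:
        f.write("subject_id\tgroup\n")
        for sid, grp in rows:
            f.write(f"{sid}\t{grp}\n")
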