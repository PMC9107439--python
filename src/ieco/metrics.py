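"""Voxelwise resting-state metrics: ReHo, fALFF and eigenvector centrality.

All three operate on a :class:`BoldSeries` (masked 4D BOLD + repetition
time) and return a :class:`MetricMap` (3D field over the mask plus a
degenerate-voxel flag volume).

* ReHo — Kendall's coefficient of concordance (W) between a voxel's time
  series and its spatial neighbours, Fisher-z transformed.
* fALFF — fraction of the spectral content of a voxel's series that lies
  in the low-frequency band (default 0.01–0.1 Hz).
* ECM — eigenvector centrality of the voxel-by-voxel similarity matrix
  A = (1 + r)/2 (r = Pearson correlation), computed matrix-free.

Frame censoring (motion scrubbing) is applied to the rank/correlation
based metrics (ReHo, ECM) but never to fALFF, which needs an unbroken
time axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "BoldSeries",
    "MetricMap",
    "SpectralSettings",
    "fisher_z",
    "kendalls_w",
    "compute_reho",
    "compute_falff",
    "compute_ecm",
    "bandpass",
]

FISHER_EPS = 1e-7

# neighbourhood stencils: offsets around the centre voxel, centre included
_NEIGHBORHOODS = {7: 1, 19: 2, 27: 3}


def _offsets(n_neighbors: int) -> np.ndarray:
    """Offsets of the 7/19/27-voxel cubic neighbourhood (centre included)."""
    if n_neighbors not in _NEIGHBORHOODS:
        raise ValueError(f"neighborhood must be one of {sorted(_NEIGHBORHOODS)}, got {n_neighbors}")
    max_l1 = _NEIGHBORHOODS[n_neighbors]
    offs = [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if abs(i) + abs(j) + abs(k) <= max_l1
    ]
    return np.asarray(offs, dtype=int)


@dataclass
class BoldSeries:
    """A masked 4D BOLD series.

    Parameters
    ----------
    data : (x, y, z, t) array of BOLD values.
    mask : (x, y, z) boolean array selecting brain voxels.
    repetition_time : sampling interval TR in seconds.
    censor : optional boolean keep-vector over timepoints (True = keep).
    """

    data: np.ndarray
    mask: np.ndarray
    repetition_time: float
    censor: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 4:
            raise ValueError("data must be 4D (x, y, z, t)")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape must equal the spatial shape of data")
        if self.repetition_time <= 0:
            raise ValueError("repetition_time must be positive")
        if self.censor is not None:
            self.censor = np.asarray(self.censor, dtype=bool)
            if self.censor.shape != (self.data.shape[3],):
                raise ValueError("censor length must equal the number of timepoints")
            if self.censor.sum() < 2:
                raise ValueError("fewer than 2 retained timepoints after censoring")
        if self.data.shape[3] < 2:
            raise ValueError("need at least 2 timepoints")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def nyquist(self) -> float:
        return 1.0 / (2.0 * self.repetition_time)

    def censored_data(self) -> np.ndarray:
        """Data with censored frames dropped (for ReHo/ECM)."""
        if self.censor is None:
            return self.data
        return self.data[..., self.censor]


@dataclass
class MetricMap:
    """One 3D scalar field over the mask, plus degenerate-voxel flags."""

    values: np.ndarray
    metric_name: str
    mask: np.ndarray
    degenerate_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.degenerate_mask is None:
            self.degenerate_mask = np.zeros(self.values.shape, dtype=bool)

    def masked_values(self, include_degenerate: bool = False) -> np.ndarray:
        sel = self.mask if include_degenerate else (self.mask & ~self.degenerate_mask)
        return self.values[sel]


@dataclass
class SpectralSettings:
    """Frequency band and edge-bin policy for fALFF.

    ``spectrum`` selects the periodogram ("power", default) or the raw
    modulus of the FFT coefficients ("amplitude").  ``prefilter_band``
    optionally band-passes the series before the spectral ratio is taken
    (which drives the ratio toward 1 and is off by default).
    """

    band_low: float = 0.01
    band_high: float = 0.1
    exclude_dc: bool = True
    exclude_nyquist: bool = True
    spectrum: str = "power"
    prefilter_band: Optional[tuple] = None

    def validate(self, nyquist: float) -> None:
        if not (0 < self.band_low < self.band_high):
            raise ValueError("need 0 < band_low < band_high")
        if self.band_high >= nyquist:
            raise ValueError(
                f"band_high={self.band_high} Hz is not below the Nyquist frequency {nyquist} Hz"
            )
        if self.spectrum not in ("power", "amplitude"):
            raise ValueError("spectrum must be 'power' or 'amplitude'")


def fisher_z(rho):
    """Fisher z-transform rho_tilde = 0.5 * ln((1 + rho) / (1 - rho)).

    Values with |rho| within 1e-7 of 1 are clamped before the transform so
    perfect concordance maps to a large finite value instead of infinity.
    """
    r = np.asarray(rho, dtype=float)
    if np.any(np.abs(r) > 1):
        raise ValueError("rho must lie in [-1, 1]")
    r = np.clip(r, -1 + FISHER_EPS, 1 - FISHER_EPS)
    out = 0.5 * np.log((1 + r) / (1 - r))
    return float(out) if np.isscalar(rho) or out.ndim == 0 else out


def _rank_tie_term(ranks: np.ndarray) -> np.ndarray:
    """Tie correction sum T = sum(t^3 - t) per series, from mid-ranks.

    ranks: (m, n) mid-ranks per series. Returns (m,) tie terms.
    """
    m, n = ranks.shape
    T = np.zeros(m)
    for j in range(m):
        _, counts = np.unique(ranks[j], return_counts=True)
        T[j] = np.sum(counts**3 - counts)
    return T


def kendalls_w(series_set: np.ndarray) -> float:
    """Kendall's coefficient of concordance W of m series of length n.

    Series are ranked along time with mid-ranks for ties; W uses the
    tie-corrected rank-sum formula

        W = 12 S / (m^2 (n^3 - n) - m * sum_j T_j)

    with S the sum of squared deviations of the per-timepoint rank sums
    from their mean and T_j = sum(t^3 - t) over tie groups of series j.
    Returns NaN when every series is constant (W undefined).
    """
    x = np.asarray(series_set, dtype=float)
    if x.ndim != 2:
        raise ValueError("series_set must be 2D (m series x n timepoints)")
    m, n = x.shape
    if m < 2 or n < 2:
        raise ValueError("need at least 2 series of at least 2 timepoints")
    ranks = rankdata(x, axis=1, method="average")
    R = ranks.sum(axis=0)
    S = float(np.sum((R - R.mean()) ** 2))
    T = _rank_tie_term(ranks)
    denom = m * m * (n**3 - n) - m * float(T.sum())
    if denom <= 0:
        return float("nan")
    return 12.0 * S / denom


def compute_reho(bold: BoldSeries, neighborhood: int = 27, strict: bool = False) -> MetricMap:
    """Regional homogeneity: Fisher-z of Kendall's W over each voxel's
    cubic neighbourhood (default 27 voxels = the voxel and its nearest 26).

    Censored frames are dropped before ranking.  At mask edges only the
    in-mask neighbours contribute (m < 27); with ``strict=True`` voxels
    without a full neighbourhood are marked degenerate instead.  Voxels
    with fewer than 2 usable series, or where all series are constant,
    are degenerate (value 0, flagged).
    """
    if not bold.mask.any():
        raise ValueError("empty mask")
    offs = _offsets(neighborhood)
    data = bold.censored_data()
    nx, ny, nz, n = data.shape
    if n < 2:
        raise ValueError("need at least 2 retained timepoints")
    mask = bold.mask

    ranks = rankdata(data[mask], axis=1, method="average")  # (V, n)
    # per-series tie terms; vectorised via sorting
    sr = np.sort(ranks, axis=1)
    breaks = np.diff(sr, axis=1) != 0
    tie_T = np.empty(ranks.shape[0])
    for i in range(ranks.shape[0]):
        # run lengths of equal mid-ranks
        idx = np.flatnonzero(breaks[i])
        bounds = np.concatenate(([0], idx + 1, [n]))
        t = np.diff(bounds).astype(float)
        tie_T[i] = np.sum(t**3 - t)

    # padded volumes for shift-and-add accumulation
    pr = np.zeros((nx + 2, ny + 2, nz + 2, n))
    pm = np.zeros((nx + 2, ny + 2, nz + 2), dtype=bool)
    pt = np.zeros((nx + 2, ny + 2, nz + 2))
    pr[1:-1, 1:-1, 1:-1][mask] = ranks
    pm[1:-1, 1:-1, 1:-1] = mask
    pt[1:-1, 1:-1, 1:-1][mask] = tie_T

    rank_sum = np.zeros((nx, ny, nz, n))
    m_count = np.zeros((nx, ny, nz))
    tie_sum = np.zeros((nx, ny, nz))
    for di, dj, dk in offs:
        sl = (slice(1 + di, nx + 1 + di), slice(1 + dj, ny + 1 + dj), slice(1 + dk, nz + 1 + dk))
        inm = pm[sl]
        rank_sum += pr[sl] * inm[..., None]
        m_count += inm
        tie_sum += pt[sl] * inm

    m = m_count[mask]  # series count per voxel
    R = rank_sum[mask]
    S = np.sum((R - R.mean(axis=1, keepdims=True)) ** 2, axis=1)
    denom = m * m * (n**3 - n) - m * tie_sum[mask]

    degenerate = (m < 2) | (denom <= 0)
    if strict:
        degenerate |= m < neighborhood
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(degenerate, 0.0, 12.0 * S / np.where(denom > 0, denom, 1.0))
    w = np.clip(w, 0.0, 1.0)
    z = fisher_z(np.where(degenerate, 0.0, w))

    values = np.zeros((nx, ny, nz))
    deg = np.zeros((nx, ny, nz), dtype=bool)
    values[mask] = np.where(degenerate, 0.0, z)
    deg[mask] = degenerate
    return MetricMap(values=values, metric_name="ReHo", mask=mask.copy(), degenerate_mask=deg)


def compute_falff(bold: BoldSeries, settings: Optional[SpectralSettings] = None) -> MetricMap:
    """Fractional ALFF: in-band share of the spectral content per voxel.

    The mean-removed series is transformed to a periodogram via the FFT;
    fALFF is the sum of spectral values at frequencies within
    [band_low, band_high] divided by the sum over all frequencies in
    (0, Nyquist], excluding DC and (by default) the Nyquist bin.  The
    non-censored series is used so the time axis stays continuous.
    Constant series have a zero denominator and are marked degenerate.
    """
    settings = settings or SpectralSettings()
    settings.validate(bold.nyquist)
    if not bold.mask.any():
        raise ValueError("empty mask")
    data = bold.data  # never censored
    n = data.shape[3]
    if n < 32:
        raise ValueError("need at least 32 timepoints for spectral estimation")
    mask = bold.mask
    x = data[mask]
    x = x - x.mean(axis=1, keepdims=True)
    if settings.prefilter_band is not None:
        lo, hi = settings.prefilter_band
        x = _bandpass_rows(x, n, bold.repetition_time, lo, hi)

    freqs = np.fft.rfftfreq(n, d=bold.repetition_time)
    spec = np.abs(np.fft.rfft(x, axis=1))
    if settings.spectrum == "power":
        spec = spec**2

    keep = freqs > 0
    if settings.exclude_nyquist and n % 2 == 0:
        keep[-1] = False
    band = keep & (freqs >= settings.band_low) & (freqs <= settings.band_high)
    if not band.any():
        raise ValueError("no frequency bins fall inside the requested band")

    num = spec[:, band].sum(axis=1)
    den = spec[:, keep].sum(axis=1)
    degenerate = den <= 0
    vals = np.where(degenerate, 0.0, num / np.where(den > 0, den, 1.0))

    values = np.zeros(mask.shape)
    deg = np.zeros(mask.shape, dtype=bool)
    values[mask] = vals
    deg[mask] = degenerate
    return MetricMap(values=values, metric_name="fALFF", mask=mask.copy(), degenerate_mask=deg)


def compute_ecm(bold: BoldSeries, tol: float = 1e-6, max_iter: int = 100) -> MetricMap:
    """Fast eigenvector centrality over in-mask voxels.

    Centrality is the principal eigenvector of the similarity matrix
    A = (1 + r_ij)/2 with r the Pearson correlation between voxel time
    series.  A is never materialised: with M the row-demeaned, unit-norm
    voxel-by-time matrix, A v = (M (M^T v) + sum(v) 1) / 2.  Power
    iteration starts from the uniform vector, renormalises each step and
    stops when the max absolute change drops below ``tol``.

    Zero-variance voxels get centrality 0 and a degenerate flag; the
    result is nonnegative with unit Euclidean norm over the remaining
    voxels.  Censored frames are dropped before correlation.
    """
    if not bold.mask.any():
        raise ValueError("empty mask")
    data = bold.censored_data()
    mask = bold.mask
    X = data[mask]
    X = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(X, axis=1)
    valid = norms > 0
    if valid.sum() < 2:
        raise ValueError("need at least 2 non-constant in-mask voxels")
    M = X[valid] / norms[valid, None]
    nv = M.shape[0]

    v = np.full(nv, 1.0 / np.sqrt(nv))
    for _ in range(max_iter):
        av = 0.5 * (M @ (M.T @ v) + v.sum())
        av /= np.linalg.norm(av)
        delta = np.max(np.abs(av - v))
        v = av
        if delta < tol:
            break
    else:
        raise RuntimeError(
            f"fast-ECM power iteration did not converge in {max_iter} iterations "
            f"(last residual {delta:.3e})"
        )
    v = np.abs(v)  # Perron vector is nonnegative; guard sign noise
    v /= np.linalg.norm(v)

    full = np.zeros(valid.shape[0])
    full[valid] = v
    values = np.zeros(mask.shape)
    deg = np.zeros(mask.shape, dtype=bool)
    values[mask] = full
    deg[mask] = ~valid
    return MetricMap(values=values, metric_name="ECM", mask=mask.copy(), degenerate_mask=deg)


def _bandpass_rows(x: np.ndarray, n: int, tr: float, lo: float, hi: float) -> np.ndarray:
    freqs = np.fft.rfftfreq(n, d=tr)
    X = np.fft.rfft(x, axis=-1)
    X[:, (freqs < lo) | (freqs > hi)] = 0
    return np.fft.irfft(X, n=n, axis=-1)


def bandpass(bold: BoldSeries, band_low: float = 0.01, band_high: float = 0.1) -> BoldSeries:
    """Frequency-domain band-pass: zero FFT coefficients outside the band.

    The mean (DC) is removed; the censor vector and TR carry over.
    """
    if not (0 < band_low < band_high < bold.nyquist):
        raise ValueError("band must satisfy 0 < low < high < Nyquist")
    shape = bold.data.shape
    flat = bold.data.reshape(-1, shape[3])
    flat = flat - flat.mean(axis=1, keepdims=True)
    out = _bandpass_rows(flat, shape[3], bold.repetition_time, band_low, band_high)
    return BoldSeries(
        data=out.reshape(shape),
        mask=bold.mask.copy(),
        repetition_time=bold.repetition_time,
        censor=None if bold.censor is None else bold.censor.copy(),
    )
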