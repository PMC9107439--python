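"""Unit and oracle tests for the three voxelwise metrics."""

import numpy as np
import pytest
from scipy.stats import rankdata

from ieco.metrics import (
    BoldSeries,
    SpectralSettings,
    bandpass,
    compute_ecm,
    compute_falff,
    compute_reho,
    fisher_z,
    kendalls_w,
)


# ---------------------------------------------------------------- oracles


def naive_kendalls_w(series):
    """Textbook rank-sum W with mid-ranks and tie correction, written as
    an explicit loop, independent of the package implementation."""
    series = np.asarray(series, dtype=float)
    m, n = series.shape
    ranks = np.array([rankdata(s) for s in series])
    R = ranks.sum(axis=0)
    S = sum((r - R.mean()) ** 2 for r in R)
    T = 0.0
    for j in range(m):
        _, counts = np.unique(ranks[j], return_counts=True)
        T += sum(c**3 - c for c in counts)
    denom = m * m * (n**3 - n) - m * T
    return 12.0 * S / denom if denom > 0 else float("nan")


# ---------------------------------------------------------------- fisher z


@pytest.mark.parametrize(
    "rho,expected",
    [(0.0, 0.0), (0.5, 0.5 * np.log(3)), (0.9, 0.5 * np.log(19))],
)
def test_fisher_z_closed_form(rho, expected):
    assert fisher_z(rho) == pytest.approx(expected, abs=1e-12)


def test_fisher_z_clamps_at_unity_and_is_monotone():
    z1 = fisher_z(1.0)
    assert np.isfinite(z1)
    assert z1 == pytest.approx(0.5 * np.log((2 - 1e-7) / 1e-7))
    grid = np.linspace(-0.999, 0.999, 101)
    assert np.all(np.diff(fisher_z(grid)) > 0)


def test_fisher_z_rejects_out_of_domain():
    with pytest.raises(ValueError):
        fisher_z(1.5)


# ------------------------------------------------------------- kendalls w


def test_kendalls_w_perfect_concordance():
    base = np.arange(20, dtype=float)
    assert kendalls_w(np.tile(base, (27, 1))) == pytest.approx(1.0)


def test_kendalls_w_reversed_pair_is_zero():
    x = np.arange(10, dtype=float)
    assert kendalls_w(np.vstack([x, x[::-1]])) == pytest.approx(0.0, abs=1e-12)


def test_kendalls_w_matches_bruteforce_oracle():
    rng = np.random.default_rng(42)
    for _ in range(20):
        m = rng.integers(2, 8)
        n = rng.integers(3, 12)
        x = rng.standard_normal((m, n))
        if rng.random() < 0.5:  # inject ties
            x = np.round(x)
        w = kendalls_w(x)
        expected = naive_kendalls_w(x)
        if np.isnan(expected):
            assert np.isnan(w)
        else:
            assert w == pytest.approx(expected, abs=1e-12)
            assert 0.0 <= w <= 1.0 + 1e-12


def test_kendalls_w_all_constant_is_undefined():
    assert np.isnan(kendalls_w(np.ones((5, 8))))


# ------------------------------------------------------------------- reho


def _bold(data, tr=2.0, mask=None, censor=None):
    data = np.asarray(data, dtype=float)
    if mask is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    return BoldSeries(data=data, mask=mask, repetition_time=tr, censor=censor)


def test_reho_shared_time_course_saturates():
    t = np.linspace(0, 1, 30)
    data = np.tile(np.sin(2 * np.pi * t), (3, 3, 3, 1))
    m = compute_reho(_bold(data))
    assert np.allclose(m.masked_values(), fisher_z(1.0))


def test_reho_matches_naive_triple_loop():
    rng = np.random.default_rng(7)
    data = rng.standard_normal((4, 4, 4, 15))
    m = compute_reho(_bold(data))
    shape = data.shape[:3]
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                neigh = []
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        for dk in (-1, 0, 1):
                            a, b, c = i + di, j + dj, k + dk
                            if 0 <= a < shape[0] and 0 <= b < shape[1] and 0 <= c < shape[2]:
                                neigh.append(data[a, b, c])
                expected = fisher_z(naive_kendalls_w(np.array(neigh)))
                assert m.values[i, j, k] == pytest.approx(expected, abs=1e-6)


def test_reho_white_noise_null_mean():
    """On independent voxels the mean W over full 27-voxel neighbourhoods
    sits at the null expectation 1/27 (checked within 3 SE)."""
    rng = np.random.default_rng(3)
    data = rng.standard_normal((9, 9, 9, 200))
    m = compute_reho(_bold(data), strict=True)
    w = np.tanh(m.masked_values())  # invert the Fisher transform
    assert len(w) >= 200
    se = w.std(ddof=1) / np.sqrt(len(w))
    assert abs(w.mean() - 1 / 27) < 3 * se


def test_reho_respects_censoring():
    rng = np.random.default_rng(11)
    data = rng.standard_normal((3, 3, 3, 40))
    censor = np.ones(40, dtype=bool)
    censor[[5, 17, 30]] = False
    m_censored = compute_reho(_bold(data, censor=censor))
    m_manual = compute_reho(_bold(data[..., censor]))
    assert np.allclose(m_censored.values, m_manual.values)


def test_reho_empty_mask_raises():
    with pytest.raises(ValueError):
        compute_reho(_bold(np.zeros((2, 2, 2, 10)), mask=np.zeros((2, 2, 2), bool)))


# ------------------------------------------------------------------ falff


def _sinusoid_volume(freq, tr=2.0, T=128, shape=(2, 2, 2)):
    t = np.arange(T) * tr
    x = np.sin(2 * np.pi * freq * t)
    return np.tile(x, shape + (1,))


def test_falff_in_band_sinusoid_near_one():
    m = compute_falff(_bold(_sinusoid_volume(0.05)))
    assert np.all(m.masked_values() >= 0.99)


def test_falff_out_of_band_sinusoid_near_zero():
    m = compute_falff(_bold(_sinusoid_volume(0.2)))
    assert np.all(m.masked_values() <= 0.01)


def test_falff_scale_invariance_exact():
    rng = np.random.default_rng(5)
    data = rng.standard_normal((3, 3, 3, 64))
    a = compute_falff(_bold(data))
    b = compute_falff(_bold(3.7 * data + 100.0))
    assert np.allclose(a.values, b.values)


def test_falff_white_noise_matches_bin_fraction():
    """For white noise the expected fALFF equals the in-band share of the
    retained frequency bins."""
    rng = np.random.default_rng(9)
    T, tr = 256, 2.0
    data = rng.standard_normal((6, 6, 6, T))
    m = compute_falff(_bold(data, tr=tr))
    freqs = np.fft.rfftfreq(T, d=tr)
    keep = freqs > 0
    keep[-1] = False
    frac = ((freqs >= 0.01) & (freqs <= 0.1) & keep).sum() / keep.sum()
    v = m.masked_values()
    se = v.std(ddof=1) / np.sqrt(len(v))
    assert abs(v.mean() - frac) < 3 * se


def test_falff_constant_series_degenerate():
    data = np.ones((2, 2, 2, 64))
    m = compute_falff(_bold(data))
    assert m.degenerate_mask.all()


def test_falff_values_bounded():
    rng = np.random.default_rng(13)
    m = compute_falff(_bold(rng.standard_normal((4, 4, 4, 64))))
    v = m.masked_values()
    assert np.all((v >= 0) & (v <= 1))


def test_falff_band_outside_nyquist_rejected():
    with pytest.raises(ValueError):
        compute_falff(
            _bold(np.random.default_rng(0).standard_normal((2, 2, 2, 64))),
            SpectralSettings(band_low=0.01, band_high=0.4),  # Nyquist is 0.25
        )


def test_falff_ignores_censor_vector():
    """Spectral estimation must use the unbroken series even when frames
    are censored for the rank/correlation metrics."""
    rng = np.random.default_rng(21)
    data = rng.standard_normal((2, 2, 2, 64))
    censor = np.ones(64, dtype=bool)
    censor[::7] = False
    a = compute_falff(_bold(data))
    b = compute_falff(_bold(data, censor=censor))
    assert np.allclose(a.values, b.values)


# -------------------------------------------------------------------- ecm


def test_ecm_matches_dense_eigendecomposition():
    rng = np.random.default_rng(17)
    data = rng.standard_normal((40, 1, 1, 60))
    m = compute_ecm(_bold(data), tol=1e-10)
    X = data[:, 0, 0, :]
    r = np.corrcoef(X)
    A = (1 + r) / 2
    evals, evecs = np.linalg.eigh(A)
    v = np.abs(evecs[:, -1])
    got = m.values[:, 0, 0]
    cosine = np.dot(got, v) / (np.linalg.norm(got) * np.linalg.norm(v))
    assert cosine >= 1 - 1e-6


def test_ecm_identical_series_uniform():
    t = np.linspace(0, 4 * np.pi, 50)
    data = np.tile(np.sin(t), (3, 3, 3, 1))
    m = compute_ecm(_bold(data))
    n = 27
    assert np.allclose(m.masked_values(), 1 / np.sqrt(n), atol=1e-6)


def test_ecm_affine_invariance():
    rng = np.random.default_rng(19)
    data = rng.standard_normal((3, 3, 3, 50))
    scale = rng.uniform(0.5, 2.0, (3, 3, 3, 1))
    shift = rng.uniform(-5, 5, (3, 3, 3, 1))
    a = compute_ecm(_bold(data), tol=1e-10)
    b = compute_ecm(_bold(scale * data + shift), tol=1e-10)
    assert np.allclose(a.values, b.values, atol=1e-6)


def test_ecm_zero_variance_voxel_flagged():
    rng = np.random.default_rng(23)
    data = rng.standard_normal((2, 2, 2, 40))
    data[0, 0, 0] = 5.0  # constant voxel
    m = compute_ecm(_bold(data))
    assert m.degenerate_mask[0, 0, 0]
    assert m.values[0, 0, 0] == 0.0
    v = m.masked_values()
    assert np.all(v >= 0)
    assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-9)


def test_ecm_nonconvergence_reports_residual():
    rng = np.random.default_rng(29)
    data = rng.standard_normal((3, 3, 3, 30))
    with pytest.raises(RuntimeError, match="residual"):
        compute_ecm(_bold(data), tol=1e-15, max_iter=2)


# --------------------------------------------------------------- bandpass


def test_bandpass_separates_components():
    tr, T = 2.0, 128
    t = np.arange(T) * tr
    lo = np.sin(2 * np.pi * 0.05 * t)
    hi = np.sin(2 * np.pi * 0.2 * t)
    data = np.tile(lo + hi, (2, 2, 2, 1))
    out = bandpass(_bold(data, tr=tr), 0.01, 0.1)
    r = np.corrcoef(out.data[0, 0, 0], lo)[0, 1]
    assert r >= 0.99


def test_bandpass_identity_on_passband():
    tr, T = 2.0, 128
    t = np.arange(T) * tr
    # exact FFT bin inside the band
    x = np.sin(2 * np.pi * (4 / (T * tr)) * t)
    data = np.tile(x, (2, 2, 2, 1))
    out = bandpass(_bold(data, tr=tr), 0.01, 0.1)
    assert np.max(np.abs(out.data - (data - data.mean(-1, keepdims=True)))) <= 1e-8


def test_bandpass_constant_series_zeroed():
    data = np.full((2, 2, 2, 64), 7.0)
    out = bandpass(_bold(data), 0.01, 0.1)
    assert np.allclose(out.data, 0.0, atol=1e-10)


def test_bandpass_invalid_band_rejected():
    data = np.zeros((2, 2, 2, 64))
    with pytest.raises(ValueError):
        bandpass(_bold(data), 0.1, 0.01)


# --------------------------------------------------- cross-metric properties


def test_all_metrics_scale_invariant_on_shared_input():
    rng = np.random.default_rng(31)
    data = rng.standard_normal((3, 3, 3, 64))
    pos_scale = rng.uniform(0.5, 3.0, (3, 3, 3, 1))
    shifted = pos_scale * data + 10.0
    for op in (compute_reho, compute_falff, compute_ecm):
        a = op(_bold(data))
        b = op(_bold(shifted))
        assert np.allclose(a.values, b.values, atol=1e-6), op.__name__
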