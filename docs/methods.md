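# Methods

This note records the models, parameter choices and numerical policies
behind `ieco`, and what the synthetic cohort does and does not emulate.

## Voxelwise metrics

**ReHo.** For each in-mask voxel, Kendall's coefficient of concordance
is computed over the voxel and the in-mask members of its cubic
neighbourhood (27 voxels by default; 7/19 available):

    W = 12 S / (m² (n³ − n) − m Σ_j T_j)

with m the number of series, n the number of retained timepoints, S the
sum of squared deviations of per-timepoint rank sums, and
T_j = Σ(t³ − t) over tie groups of series j (mid-ranks). Ties rarely
occur in continuous BOLD but the correction keeps the statistic exact
when they do (e.g. quantised or constant series). W is then Fisher
z-transformed, ρ̃ = ½ ln((1+ρ)/(1−ρ)), with |ρ| clamped to 1 − 1e−7 so
perfect concordance stays finite. Edge policy: by default voxels with a
partial neighbourhood use their m < 27 in-mask neighbours (m is part of
the formula, so the statistic remains exact); `strict=True` instead
flags them degenerate, which is the right instrument when comparing
against the 1/m null expectation. Voxels with fewer than two usable
series, or where the tie-corrected denominator vanishes (all series
constant), are flagged degenerate and carry value 0.

**fALFF.** The mean-removed series is transformed with an FFT and the
periodogram (squared modulus) summed over 0.01–0.1 Hz, divided by the
sum over all frequencies in (0, Nyquist], excluding DC and, by default,
the Nyquist bin. The power spectrum is the default because the ratio of
summed squared coefficients concentrates an off-bin sinusoid's leakage
far better than raw amplitudes, making the band-selectivity of the
measure sharp (an in-band tone scores > 0.99 even when its frequency
falls between FFT bins); the raw amplitude spectrum is available via
`SpectralSettings(spectrum="amplitude")`. fALFF always uses the
non-censored series: dropping frames breaks the uniform sampling the
FFT assumes, whereas the rank- and correlation-based metrics are
unaffected by frame deletion. A `prefilter_band` option band-passes the
series before the ratio (this drives fALFF toward 1 and is off by
default; it exists because preprocessing conventions differ on whether
spectra are taken pre- or post-filtering).

**ECM.** Centrality is the principal eigenvector of A = (1 + r)/2 over
in-mask voxels; the (1+r)/2 shift guarantees nonnegativity, so the
Perron–Frobenius theorem gives a unique nonnegative principal
eigenvector. A is never formed: with M the row-demeaned unit-norm
voxel×time matrix, A·v = (M(Mᵀv) + Σv·1)/2, and power iteration from
the uniform vector with per-step Euclidean normalisation stops when the
maximum absolute change drops below 1e−6 (default; 100 iterations max,
non-convergence raises with the last residual). Because A's spectral
gap is large (the all-ones component dominates), convergence takes a
handful of iterations in practice. Zero-variance voxels are excluded
from M, assigned centrality 0 and flagged degenerate; the returned
vector has unit norm over the remaining voxels.

## Motion QC

FD_t = Σ|Δ translations| + 50 mm · Σ|Δ rotations| (first frame 0); the
50 mm sphere radius is the common convention and is configurable.
Frames with FD > 0.5 mm are censored. A subject is excluded when the
maximum absolute translation from the reference frame exceeds 2 mm
(read as "> 2 mm of motion"; a peak-to-peak mode exists since the
phrase is ambiguous, and rotations are not counted by default) and/or
more than 20% of frames are censored.

## Encoding

Network means are taken over in-label, non-degenerate voxels. Subjects
with a network-level ECM mean of exactly 0 are excluded (strict
equality: a zero can only arise from a fully degenerate network, not
from rounding). Min–max scaling x̃ = 255(x − min)/(max − min) defaults
to the `per_variable_global` scope — one min/max per metric over all
subjects and networks — because a literal per-subject-per-variable-
per-network scope would make every cell its own scope and the formula
degenerate, and global scaling preserves the between-subject contrast
the classifiers need. The `per_subject_per_variable` scope (each strip
stretched to full range) is also implemented. Rounding to 8 bits
(half-up) happens only at image export; averages, differences and the
heatmap all use real-valued pixels, and difference images keep their
signs (export offers absolute, clip-at-zero and symmetric-about-128
renderings, since a signed image has no canonical RGB form).

## Group statistics

Per metric, a one-way MANOVA with the K network means as response:
Wilks' lambda Λ = det(W)/det(W+B) from the within/between scatter
matrices, mapped to an F statistic by Rao's approximation (exact for
two groups, where it coincides with Hotelling's T²). Comparisons are
pairwise — each diagnosis versus the reference — matching how such
results are reported per diagnosis; an omnibus mode over all groups
exists. Tests run on raw network means: the p-values are invariant to
any common affine rescaling of the responses, so globally scaled values
would give identical results. Post-hoc per-network one-way ANOVAs are
uncorrected by default (descriptive localisation), with an optional
Benjamini–Hochberg flag.

## Classification

A single stratified 80/20 split (seed-controlled) — no cross-validation,
because the protocol being implemented uses one split; a repeated-splits
loop over seeds reports dispersion, which matters at n ≈ 100 where a
single split is high-variance. The CNN is a purpose-built numpy engine:
rescale 1/255 → conv 1×3 along the band axis (8 filters, ReLU, valid
padding) → flatten → dense-4 ReLU → sigmoid, trained with Adam
(lr 1e−3) on binary cross-entropy, 100 epochs, batch 8. The filter
count, epochs and batch size are free parameters (defaults chosen for
stable training at n ≈ 100 subjects); with a few hundred parameters the
model trains on CPU in well under a second and is bit-reproducible from
its seed (gradients are verified against numerical differentiation in
the test suite). The logistic baselines standardise features on the
training partition (the MLE is invariant to affine feature rescaling);
if the training data is perfectly separable the unpenalised MLE does
not exist, which is detected (a fitted hyperplane classifying the
training set perfectly) and handled by refitting with a minimal ridge
of 1e−3, recorded in the report.

PR-AUC sweeps thresholds over the distinct scores in descending order
(ties grouped) and sums (R_i − R_{i−1})·P_i — the step-wise
average-precision estimator, chosen over trapezoidal integration
because linear interpolation in PR space is optimistic. Constant scores
therefore give exactly the positive prevalence.

## The synthetic cohort

The generator emulates the *structure* of a four-group clinical
resting-state study: a K-network atlas, per-subject 4D BOLD with TR in
the header, six-column motion traces, and a participants table. Per
voxel of network n:

    bold = 100 + A_sin [√p sin(2πf_in t + φ₁ᵥ) + √(1−p) sin(2πf_out t + φ₂ᵥ)]
         + A_net u_n + A_loc m_local s_v + σ ε_v

* `p = m_lfp²/(1+m_lfp²)`: the **low_freq_power** multiplier
  redistributes a fixed per-voxel sinusoid energy budget between an
  in-band tone (0.05 Hz, the centre of the 0.01–0.1 Hz band) and an
  out-of-band tone (0.2 Hz), so fALFF moves while total variance — and
  hence ReHo and ECM — stays put. Phases are per-voxel, so the tones
  carry no spatial correlation. Tones at or above Nyquist are a
  configuration error (TR must be < 2.5 s at the defaults).
* `s_v`: a **neighborhood-shared** field (white noise box-smoothed
  3×3×3, renormalised per voxel), weighted by the **local_coupling**
  multiplier. Adjacent voxels share most of their kernel, so the field
  drives ReHo; because the correlated blocks are only neighbourhood-
  sized, its footprint on the global correlation structure (ECM) is
  small.
* `u_n = √(1−b²) e_n + b h` with `b = 0.4·m_hub` (clipped at 0.95): a
  fixed-amplitude network carrier rotated toward a latent global hub
  series. The **hub_strength** multiplier raises a network's
  correlation with the rest of the brain (ECM) without changing the
  carrier's variance, hence without moving ReHo or fALFF. A
  variance-preserving rotation was chosen over additively mixing a hub
  network's time course into other networks, because an additive hub
  term inflates within-network concordance and destroys the
  one-multiplier-one-metric property the recovery tests rely on.
* All broadband components (e_n, h, s_v, ε_v) are spectrally balanced —
  exactly half their power inside 0.01–0.1 Hz — so re-weighting any of
  them leaves fALFF untouched.
* Amplitude defaults A_sin = 1.0, A_net = 0.5, A_loc = 0.8, σ = 1.0
  place the null cohort at fALFF ≈ 0.5, within-network W ≈ 0.2 and a
  mildly inter-correlated network graph — fALFF and ReHo mid-range and
  responsive in both directions.

Orthogonality is exact for low_freq_power and hub_strength and
approximate for local_coupling: raising a block's internal coupling
necessarily raises its centrality a little, a genuine property of
eigenvector centrality rather than a generator artefact. At the test
conditions (×2 in one network, n = 10/group, T = 128) the leakage stays
within 3 standard errors.

Motion is a random walk whose per-frame step scale is drawn per subject
from the group's (mean, SD) profile, split between translations and
sphere-projected rotations; BOLD and motion are independent, so motion
carries group information but no imaging confound. The default group
profiles differ by well under one between-subject SD, making motion a
weak classifier relative to the imaging features — deliberately, since
a motion-dominated cohort would make the comparison of classifiers
uninformative. The default study spec gives the schizophrenia- and
bipolar-like groups widespread effects (lower low-frequency power,
higher coupling and hub strength in several networks) and the ADHD-like
group a sparse local one, echoing the qualitative pattern such cohorts
show.

Randomness: one master seed expands to per-subject `SeedSequence([seed,
group_index, subject_index])` substreams, so enlarging the cohort never
reshuffles existing subjects, and identical (spec, seed) is
bit-identical.

**What the generator does not emulate:** hemodynamic response shapes,
physiological (cardiac/respiratory) noise, scanner drift, anatomical
geometry (networks are axis-aligned blocks) or motion-induced image
artefacts. Passing tests therefore demonstrate that the pipeline
recovers injected effects of the stated kinds under clean conditions —
not that it is robust to the full noise structure of real acquisitions,
where preprocessing quality dominates.

## Problem sizes

The default verification cohort uses a 12×12×14 voxel grid
(~1 700 in-mask voxels), 14 networks, T = 128, TR = 2 s and 40 subjects
per group — large enough for stable MANOVAs (N > K + 2 per comparison)
and meaningful 80/20 splits, small enough that the full pipeline runs
in well under a minute per cohort on one CPU. Statistical calibration
checks (type-I error, power) sample network means directly from
multivariate normals, since only the test statistics, not the imaging
pipeline, are under test there.

## Known limitations

* The ECM exclusion rule (any network mean exactly 0) can in principle
  fire on a real dataset only via fully degenerate networks; with the
  synthetic generator it never triggers, so that code path is exercised
  by constructed tables in the tests.
* MANOVA requires non-singular within-group scatter; with K = 14
  responses this needs comfortably more than 16 subjects per
  comparison, and the error message says so.
* The CNN engine implements exactly the one architecture the protocol
  specifies; it is not a general deep-learning layer library.
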