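# Methods

## Signal models and pixel-wise fitting

Five magnetization preparations are supported, all read out identically, so
one frame stack per preparation reaches the fitter together with its time
axis: explicit inversion times (T₁), echo times (T₂) or spin-lock durations
(T₁ρ), or — for the adiabatic-pulse-train preparations (adiabatic T₁ρ,
T_RAFF) — pulse count × per-pulse duration. Pulse-power settings
(γB₁ᵐᵃˣ, pulse family) are carried as protocol metadata and never enter any
computation: the package models relaxation of already-prepared
magnetization, not pulse physics.

Two models cover the five preparations:

* **Inversion recovery** S(TI) = A·(1 − 2e^(−TI/T₁)). Acquisitions are
  magnitude-valued, so the default fit is of |A·(1 − 2e^(−TI/T₁))| against
  the magnitude data. An optional polarity-restoration mode sign-flips the
  samples acquired before the signal null and fits the signed model; the
  null sample itself is tried on both sides of the zero crossing and the
  split with the lower residual wins. Both modes recover the generating
  parameters exactly on noiseless data. T₁ is initialized from the null
  condition TI_null = T₁·ln 2 using the minimum-|S| frame; A from the
  longest-TI frame.
* **Mono-exponential decay** S(t) = A·e^(−t/T), initialized by ordinary
  least squares on (t, ln S) over the strictly positive samples; a pixel
  with fewer than two positive samples is invalid, never an exception.

Each masked pixel is fitted independently with bounded trust-region least
squares (relative parameter tolerance 1e-8, at most 200 function
evaluations, analytic Jacobian for the decay model). The output is
deterministic and independent of pixel visit order.

**Bounds and validity.** T is constrained to [min(0.1, 10⁻³·t_max),
50·t_max] and A to (0, 10·max intensity]. The lower T bound is 0.1 ms for
every millisecond-scale protocol in the study; the 10⁻³·t_max alternative
keeps the rule covariant if a caller supplies a time axis in other units
(the whole fit is unit-covariant: rescaling the time axis rescales T
identically). A fit that converges onto any bound is recorded as invalid —
in practice this catches background-adjacent pixels whose signal carries no
decay information. Invalid pixels carry NaN in all maps. Goodness of fit is
R² = 1 − SS_res/SS_tot over the pixel's own samples; a pixel with zero
signal variance has no defined R² and is invalid. No published
pixel-exclusion rule exists for this analysis, so validity is purely an
artifact of fit health, and the ROI summaries use valid pixels only.

A closed-form two-point solver T = (t₂−t₁)/ln(S₁/S₂) is provided as an
exact helper for the two-sample case; the iterative fitter requires at
least three samples.

Foreground masks, when not supplied, threshold the first frame at a
fraction (default 0.1) of its 99th intensity percentile; the percentile
rather than the maximum makes the rule robust to isolated bright noise.

## Optical densitometry

Detector counts of the stained-section sample image and of a blank-glass
reference image are dark-subtracted and divided by their exposure times;
the rate ratio is the transmittance and OD = −log₁₀(transmittance).
Choices worth recording:

* **Log base.** Base 10, the standard absorbance convention; the published
  OD range (~0.26–3.10) is consistent with decadic absorbance for realistic
  stain densities. A natural-log mode exists behind a flag.
* **Exposure compensation.** Sample and reference need not share exposure
  times — normalizing to counts/s cancels them exactly, which is also an
  invariant test.
* **Saturation.** Pixels at the detector's full scale are flagged before
  normalization and propagate to invalid OD rather than biasing ROI means.
* **Edge cases.** Transmittance ≤ 0 (opaque or dead pixels) is invalid;
  transmittance slightly above 1 (shot noise on unstained regions) clamps
  to OD 0 and stays valid, so blank regions average to zero instead of
  being censored toward positive OD.

ROI summaries (mean, SD with ddof = 1, n) use valid pixels only and the
label conventions 1 = articular, 2 = viable, 3 = necrotic.

## Cohort statistics

**Percent difference.** The difference statistic behind the published
viable-vs-necrotic columns is never written out in the source tables; of
the candidate definitions, only the symmetric form
100·(a − b)/((a + b)/2) reproduces the printed columns (e.g. 167.9% for OD
means 2.98 vs 0.26, 64.5% for T₂ 106.6 vs 54.6). Percent-of-smaller and
percent-of-larger variants do not, and were rejected. The function is
antisymmetric and bounded in (−200, 200) for positive inputs.

**Printed-precision tolerance.** Reproducing a printed difference cell from
printed inputs is limited by the inputs' own rounding. For inputs printed
with half-width h, the worst-case shift of the percent difference is
(|∂d/∂v| + |∂d/∂n|)·h = 400·h/(v + n). For the millisecond-scale parameters
(h = 0.05) this is below 0.1 pp everywhere, but T₁ is printed to 0.01 s
(h = 0.005 s), which supports deviations up to ~0.7 pp; and indeed direct
recomputation of the T₁ column differs from the printed cells by up to
0.36 pp. Table-reproduction tests therefore use this per-cell bound,
floored at 0.1 pp — tightening it further would be asserting digits the
inputs do not carry.

**Regressions.** Plain OLS throughout (slope, intercept, R² = 1 −
SS_res/SS_tot; constant y is defined to give slope 0, R² 0; constant x is
an error). The OD time-course fits exclude the week-6 specimen by default —
its lesion contained no histologically evident chondronecrosis, so its
(small) OD drop is not a necrosis measurement; exclusion is a per-specimen
flag, not a hard-coded week. On the published means this yields viable
R² = 0.129, necrotic R² = 0.993 and percent-difference R² = 0.989; the
published captions attach 0.989 to the necrotic fit and 0.993 to the
percent-difference fit, i.e. swapped relative to direct OLS on the printed
means (or computed from unrounded source data). The package reports both
fits as computed and does not force either printed value. The pooled
relaxation-vs-OD regression uses every non-null (week, parameter) pair
(29 points), giving slope ≈ 0.216 against the printed 0.21; its computed
R² is 0.25 (the printed 0.39 is not recoverable from the printed pairs
under any obvious inclusion subset — parameter and week inclusion are
configurable so the sensitivity is easy to probe). Missing measurements
(the week-3 T₂ series was invalid at acquisition) propagate as nulls
through every table, never as zeros.

## Synthetic cohort

The phantom is a stylized condyle cross-section: a half-disc seated on the
lower image edge, an articular band along its curved surface, viable
epiphyseal cartilage inside, and an elliptical necrotic lesion that must
lie entirely within the epiphyseal compartment — lesions never involve the
avascular articular cartilage, and the generator enforces that as a hard
error. Default geometry is 256×256 pixels at 160 µm (matching the study's
matrix and resolution range), scaled proportionally for smaller images.
Compartment ground truth defaults to the published per-ROI means
(T₁ converted to ms internally; reported in seconds), so a noiseless run of
the full pipeline must return exactly the published-means tables — the
forward/inverse consistency property at the heart of the test suite.

* **MRI noise** is Rician: magnitude of (S + N(0,σ)) + i·N(0,σ), the
  physically standard model for magnitude images; the implementation is
  guarded by the analytic background mean σ√(π/2). The acquisitions' true
  SNR is unreported, so the noisy-condition runs use σ = A/50 (2% of the
  amplitude), a calibration choice that puts the per-pixel scatter of the
  fitted times in the few-percent range of the published ROI SDs.
* **Histology noise** is Poisson counting on a Beer–Lambert forward model:
  reference counts = photon budget × exposure, sample counts attenuated by
  10^(−OD) per pixel, constant dark offset on both. Defaults (2×10⁴
  counts/s budget, 1 s reference and 10 s sample exposures — the longer
  sample exposure emulating exposure compensation for the dense stain)
  give ROI-mean OD errors of ~10⁻³ a.u.
* **Cohort structure**: six specimens; large incisions at weeks 3/5/9,
  small at 4/6/10; no T₂ truth or series for week 3; week 6 flagged as
  lacking histological necrosis. All randomness flows from a single seed
  through `numpy.random.SeedSequence`, so runs are bit-reproducible.

What the phantom does **not** emulate — and therefore what passing tests do
not establish about real specimens: partial-volume mixing at compartment
boundaries (truth is piecewise constant), depth- and orientation-dependent
relaxation within cartilage, B₀/B₁ inhomogeneity, readout-related blurring
or slice effects, spatially correlated noise, ossification fronts or bone
signal, and any registration error between MRI and histology sections
(labels are shared by construction). The tests establish that the
estimation pipeline is unbiased and stable under the assumed noise models,
not that those models exhaust real acquisitions.

## Problem sizes

The cohort-wide analyses run at 96×96 (≈3 000 fitted pixels per map, 29
maps) and the end-to-end acceptance checks at 64×64; single-map examples
and oracle comparisons use 48×48 or synthetic pixel rows. These sizes keep
every ROI in the hundreds-to-thousands of pixels, large enough for stable
ROI statistics while keeping a full-suite run to a couple of minutes.
Fitting cost is linear in pixel count, so scaling to the full 256×256
matrix changes runtimes, not results.

## Known limitations

* The magnitude inversion-recovery objective is non-smooth at the signal
  null; with very high noise the fitted null can sit one sample off,
  which the validity flag does not detect. The polarity-restoration mode
  shares the limitation in its split search.
* Mono-exponential fits of decays sampled only over a small fraction of T
  (e.g. adiabatic T₁ρ ≈ 413 ms sampled to 96 ms) amplify noise into the
  estimate; ROI means inherit a slight upward skew under noise (~2 pp in
  the difference tables at σ = A/50).
* OD at very low transmitted counts is biased by the log of small Poisson
  counts and by exclusion of zero-count pixels; the default photon budget
  keeps this below ~10⁻² a.u. at OD ≈ 3.
* No hypothesis testing is provided; the source analysis reports none, and
  n = 1 specimen per time point would not support it.
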