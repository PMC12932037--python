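# Methods

This note documents the models, conventions and design choices behind
`marrowmrs`. It is written for a reader who wants to know exactly what the
package computes and what its synthetic-data experiments do and do not show.

## Spectral model

A voxel spectrum is a sum of a water resonance (4.7 ppm) and ten fat
resonances (0.90 methyl, 1.30 methylene, 1.60 beta-carboxyl, 2.03
alpha-olefinic, 2.25 alpha-carboxyl, 2.77 diacyl, 4.15/4.30 glycerol CH2,
5.21 glycerol CH, 5.31 olefinic ppm). Each peak is a pseudo-Voigt
absorption line

    P(f) = LSF * L(f0, LW) + (1 - LSF) * G(f0, LW),

with both the Lorentzian and the Gaussian area-normalized and sharing the
same FWHM `LW`. Tying the two component widths means the fitted `LW` is the
profile's FWHM for any shape fraction, so the conversion `R2* = pi * LW`
applies to the pseudo-Voigt linewidth directly. Water uses `LSF = 0.5` (a
compromise robust to sclerotic broadening); fat peaks use `LSF = 0.2`.
Full Voigt (convolution) lineshapes and J-coupling evolution are out of
scope.

Fat amplitudes follow the generic-triglyceride proton-count rules, linear in
the chain length `CL`, the number of double bonds `ndb` and the number of
methylene-interrupted double bonds `nmidb` (methyl 9; methylene
`6(CL-4) - 8 ndb + 2 nmidb`; beta-carboxyl 6; alpha-olefinic
`4(ndb - nmidb)`; alpha-carboxyl 6; diacyl `2 nmidb`; glycerol 2/2/1;
olefinic `2 ndb`). The coefficients are configuration data
(`ResonanceModel.from_json`) and deliberately user-overridable; the
validity checks are the linearity and boundary properties, not specific
coefficient values. Default composition: `CL = 17.5`, `ndb = 2.7`,
`nmidb = 0.7`, typical of marrow triglyceride.

Fat frequencies are rigidly linked: every fat peak keeps a fixed ppm offset
from the methyl peak; only the methyl and water frequencies are free in
fitting. The chemical-shift axis is referenced to water at 4.7 ppm with the
carrier on water; ppm-to-Hz conversion uses the transmitter frequency
(default 127.73 MHz, a 3T system).

Relaxation-group structure (defaults): unique T1 for methyl, methylene, the
2.03+2.25 ppm "composite" pair, diacyl, olefinic and water; unique T2 for
methylene, composite and water; linewidths for water, methylene and one
shared "other fat" group. Every fat peak not listed inherits the methylene
relaxation groups — at 3T the crowded fat peaks cannot support independent
relaxation times, so methylene serves as the common fat reference.

## Signal equations

Stimulated-echo (multi-TE) amplitude: `A0 * exp(-TE/T2)`, with `A0` the
T2-corrected amplitude (proton density). Inversion recovery (multi-TI)
amplitude: `A0 * (1 - 2*beta*exp(-TI/T1) + exp(-TR/T1))` with a shared
inversion efficiency `beta` for all resonances (the adiabatic pulse inverts
uniformly across the spectral band; see the Bloch check below). The finite-TR
term is kept exactly as written, so the long-TI limit is `1 + exp(-TR/T1)`.
The STEAM amplitude factor (half of a spin echo) and TM decay are not
modelled: amplitudes are defined at the observed scale, and every derived
quantity (PDFF, relaxation times) is invariant to a global scale.

PDFF is `sum(F0,n) / (W0 + sum(F0,n))` over the T2-corrected amplitudes;
all fat-model peaks, including glycerol, enter the numerator.

## Synthetic data

The generator synthesizes the time-domain counterpart of the model: each
resonance contributes a complex decay `LSF*exp(-pi*LW*t) +
(1-LSF)*exp(-(pi*LW*t)^2 / (4 ln 2))` times `exp(2i*pi*df*t)`, weighted by
the TE or TI factor. The Gaussian decay constant makes the frequency-domain
FWHM exactly `LW`, keeping the signal equations consistent between generator and
fitter; the DFT of a synthetic FID and the fitter's forward model agree to
machine precision on the same grid, and agree with the continuous
closed-form absorption lineshapes to grid tolerance (~3e-4 of the peak)
after the standard half-first-point correction.

Protocol defaults follow the acquisition design: TE ∈ {20, 25, 30, 35, 40,
50, 60, 80, 100} ms at TR 3500 ms; TI ∈ {15, 70, 150, 300, 500, 1000, 2500,
4000} ms at TE 20 ms, TR 5000 ms; TM 10 ms; 2048 complex points at 2400 Hz;
6 averages per contrast, stored separately so registration and combination
stay testable.

Noise is additive complex white Gaussian. Because no noise magnitude is
part of the study design, SNR is a configuration knob, defined as the
magnitude of the **methylene** peak of the TE = 20 ms spectrum divided by
the spectral noise std; every experiment in the tests and analysis scripts
states its SNR explicitly (50 for fitting experiments, following a
realistic marrow acquisition). Multi-channel acquisition multiplies the
clean FID by complex channel sensitivities (drawn once per study from the
seed) and adds channel noise with a configurable correlation matrix.
Per-average frequency/phase drift multiplies each average by
`exp(i(2*pi*df*t + dphi))`; the analysis scripts use 1.5 Hz / 10 deg (1 SD),
a plausible scanner drift scale. All randomness flows through one seed and
is recorded in a truth record sufficient to regenerate a dataset
bit-for-bit.

Tissue presets: the volunteer presets carry the cohort-mean vertebral (L5)
and femoral-head values (e.g. L5: water T1 1368 ms, T2 27 ms, R2* 142 Hz;
methylene T1 369 ms, T2 68 ms, R2* 124 Hz; PDFF 30%; inversion efficiency
0.93). Patient presets (active, treated, fat-restored, normal-appearing)
are chosen inside the reported in-vivo ranges (water T1 1121–2206 ms, water
T2 14–73 ms, disease-state-appropriate PDFF); the shared "other fat"
linewidth, never reported separately, defaults to 50 Hz. These are single
representative points, not distributions.

What the generator does **not** emulate: eddy currents, B0 inhomogeneity
across the voxel, motion, lipid sidebands, chemical-shift displacement,
J-coupling modulation, baselines from macromolecules, or non-Gaussian
artefacts. Passing the recovery tests therefore shows the estimator chain
is correct and well-calibrated under its own model class — not that in-vivo
accuracy would match.

## Preprocessing

Whitened-SVD coil combination: the channel noise covariance is estimated
from the trailing quarter of the FID (pooled over averages), channels are
whitened by its inverse Cholesky factor, and the rank-1 SVD of the whitened
channel-by-time matrix yields the combined FID. The covariance is
regularized (`+1e-8 * trace/n` on the diagonal) when its condition number
exceeds 1e8, and a covariance at numerical-noise level (noiseless data) is
replaced by the identity — whitening against rounding noise would rescale
each contrast by an arbitrary factor. Phase convention: the combined FID's
first point is rotated real-positive (the fitter estimates zero-order phase
anyway, so any fixed convention works).

Spectral registration: per-average frequency/phase offsets relative to the
first average are estimated by time-domain least squares over the first 200
ms of the FID, initialized by the FFT peak of `x * conj(ref)` (which
oscillates at the frequency offset) to avoid local minima. The 200 ms
window is a deliberate choice: marrow FIDs (linewidths ~40–50 Hz) decay
within tens of ms, and longer windows admit noise-dominated samples whose
gradient contribution degrades the estimate (both averages are noisy, so
noise-only samples are not information-free). Registration is applied
within a contrast only, before averaging; cross-contrast alignment is
intentionally not performed.

## Fitting

All fits are bounded nonlinear least squares (`scipy.optimize.least_squares`,
trust-region reflective) on the concatenated real and imaginary parts of
the complex spectrum, restricted to a window covering the peak span ±200 Hz.
The forward model is evaluated as the DFT of the synthesized time-domain
signal, making it exactly consistent with the generator. Bounds: T1 ∈ [50,
5000] ms, T2 ∈ [5, 300] ms, LW ∈ [1, 200] Hz, beta ∈ [0.5, 1], frequency
offsets ±30 Hz, amplitudes ≥ 0. Zero-order phase is fitted per spectrum and
limited to ±90°, so that a 180° rotation can never be absorbed by the phase
term — polarity stays with the explicit sign decision of the
inversion-recovery algorithm. First-order phase is fixed at zero (the
synthetic data are phase-perfect; the parameter is exposed in config).
Convergence: relative cost/step tolerances 1e-12, at most 2000 residual
evaluations for final fits (intermediate fits of the sign schedule use
looser 1e-8 tolerances — they only rank polarity candidates).

Amplitude parameterization: the water amplitude is free; fat amplitudes are
`scale * protons(CL, ndb, nmidb)`. In the joint multi-TE fit one fat scale
suffices because the explicit `exp(-TE/T2)` factors carry all differential
weighting. A single spectrum at fixed TE (the initial fit) and the TI
series (acquired at TE 20 ms) carry an unknown per-T2-group echo decay in
their effective amplitudes, so those fits use one fat scale per T2 group,
which keeps the proton-count ratios exact within each group.

Pipeline: (1) fit the TE = 20 ms spectrum with (ndb, nmidb) free; (2) pool
the cohort's initial fits and invert the amplitude rules for a common
composition by bounded linear least squares (anchoring each T2 group's
scale on its composition-independent peaks), then freeze it; (3) joint
multi-TE fit (subset 20–50 ms or all echoes — both variants are exposed;
on synthetic data without J-coupling they agree); (4) joint multi-TI fit.

Sequential polarity restoration (multi-TI): input spectra are first
normalized "upright" (dominant peak positive), mimicking individually
phased in-vivo spectra whose true polarity is unknown. The algorithm
assumes the shortest TI inverted and the longest upright, fits that pair
jointly, then adds the remaining TIs in ascending order: each new spectrum
enters the joint fit both as presented and rotated by 180°, and the
lower-cost candidate fixes its sign (ties, which essentially never occur
off the null point, resolve to the sign of the nearest earlier TI). The
final joint fit over all TIs returns per-group T1 and the shared beta.

## CRLB quality control

Cramér–Rao lower bounds come from the Fisher information `J^T J / sigma^2`,
with `J` the numerical Jacobian of the stacked real/imaginary model at the
solution and `sigma` the per-point spectral noise std, estimated from the
signal-free region using first differences (plain std there is biased high
by the smooth Lorentzian dispersion tails; differencing suppresses them).
A parameter is withheld ("censored", with the reason retained) when its
relative CRLB exceeds 25% or when every peak it belongs to has amplitude
below 1% of the largest peak (water or methylene); a singular information
matrix censors the affected parameters as unidentifiable. Derived
per-resonance amplitude bounds inherit the bound of their shared scale. The
calibration test checks the amplitude CRLB of a single Lorentzian against
the Monte-Carlo SD of the estimator over 200 noise seeds.

## Dixon bias simulation

RF-spoiled gradient-echo signals are simulated in idealized conditions
(perfect spoiling, no field map): each species contributes the Ernst
steady-state amplitude `sin(a)(1-E1)/(1-E1 cos a)`, `E1 = exp(-TR/T1)`,
times `exp(2i*pi*df*TE)` per fat spectral component and optional
`exp(-TE/T2*)` decay. The fat-water shift uses 420 Hz for 3.4 ppm — the
in/opposed-phase convention the TE = 2.46/3.69 ms echo pair was designed
around. (One protocol source prints the first echo as 2.48 ms; the package
defaults to 2.46 ms with `DIXON_TE_MS` overridable.) The nine-peak marrow
fat spectrum is derived from the package's own triglyceride rules with the
glycerol CH2 lines merged, normalized to unit sum, and overridable; the
single-peak model puts all fat at 1.3 ppm. Generation arms: nine-peak fat
with R2*, single peak with R2*, single peak without R2*.

Two-point estimator: the default solves the two complex echo equations
`S_k = W + F c_k` exactly (the idealized complex-based reconstruction) and
reports `|F| / (|F| + |W|)`. This resolves the dominant species and is
monotone over the whole 1–100% range, matching the closed-form Ernst-ratio
curve `FF_app = r x / (1 + (r-1) x)` to 1e-10 in the single-peak no-R2*
arm. The classical magnitude arithmetic (`water = (|IP|+|OP|)/2`,
`fat = (|IP|-|OP|)/2`) is available as `mode="magnitude"`; it folds
fractions above ~`1/(1+r)` and is kept for comparison, not as the default.

Multi-echo estimator: magnitude fit of `|W + F c(TE)| * exp(-TE * R2*)`
over the six echoes (1.13–6.78 ms), with the fat phasor `c(TE)` from the
assumed spectral model and one effective R2* — a simple stand-in for a
vendor hybrid pipeline, not a reimplementation of it. The fit starts from
both the water-dominant and fat-dominant points and reports near-degenerate
fat-water-swap solutions. Note a structural fact this exposes: with a
single-peak fat model the magnitude fit is *exactly* swap-degenerate
(`|W + F c| = |F + W c|` when `|c| = 1`), so the multi-echo estimator is
only meaningful with a multi-peak fat spectrum — which is why the
estimator-comparison experiments pair the multi-echo arm with nine-peak
generation.

Comparisons between estimators isolate T1 weighting (no R2*, each estimator
under its own assumed fat spectrum). With R2* decay or spectral-model
mismatch included, the naive two-point curve happens to cross the identity
near FF ≈ 60–70% where its bias momentarily vanishes; at such a crossing a
pointwise "closer to identity" comparison is vacuous for any estimator with
nonzero bias, so the package makes the T1-isolated comparison and reports
the full compounded curves separately (analysis/03).

Monte-Carlo curves: for each true FF on a 1..100% grid, complex Gaussian
noise (SNR defined as the noiseless pure-water in-phase magnitude over the
noise std) is drawn per iteration, the estimator applied, and the mean with
2.5/97.5 percentiles recorded. The acceptance-scale noise runs use 10,000
iterations; the analysis driver uses 1,000 per grid point to keep its
runtime modest, and states so in its output.

## Repeatability statistics

Bland–Altman analysis uses arithmetic differences for PDFF (a bounded
percentage) and log-ratio differences for strictly positive parameters
(T1, T2, R2*), with bias ± 1.96 SD limits of agreement and a paired t-test
on the bias. The ensemble coefficient of variation for positive data pools
squared within-subject log differences: `s^2 = sum(d^2) / (2n)`,
`CoV = 100 * sqrt(exp(s^2) - 1)`; it equals the per-measurement CV for
small CVs and is invariant to rescaling. Group comparisons run the gated
sequence — Shapiro–Wilk per group and Levene across groups, one-way ANOVA
only if all groups are normal and homoscedastic, Tukey HSD only if the
ANOVA rejects at p < 0.05 — with no correction beyond Tukey. These are
standard library routines (scipy) behind a thin reporting layer.

## Bloch inversion check

A piecewise-constant rotation integrator (no relaxation) evaluates the
frequency profile of the hyperbolic-secant inversion pulse (default: 10 ms,
peak gamma-B1 800 Hz, beta 800 s^-1, mu 4.9). Across ±400 Hz — covering
the full water/fat spectral span at 3T — the pulse achieves Mz ≤ -0.98,
flat to within 1%, supporting the fitter's single shared inversion
efficiency across resonances.

## Problem sizes

Defaults used by the test-suite experiments, chosen to characterize the
estimators well at desk scale: 100 noise seeds for the PDFF consistency
check, 200 seeds for CRLB calibration, 30 seeds for registration and
combination statistics, 10,000 Monte-Carlo iterations for the noise-bias
extremes, 1,000 per grid point in the analysis driver's bias curves. The
sequential TI algorithm and all noiseless recovery checks run on the full
protocol grids (9 TEs, 8 TIs, 2048 points).

## Known limitations

* The fitter's forward model matches the generator's model class; no
  baseline, lipid-sideband or J-coupling mismatch is exercised, so the
  TE-subset comparison (20–50 ms vs all) agrees trivially on synthetic data.
* The composition inversion assumes the cohort shares one (ndb, nmidb);
  heterogeneous cohorts are averaged, as in the in-vivo design.
* CRLBs use the estimated noise level and a numerical Jacobian; for
  parameters at bounds they are not meaningful (such parameters should be
  considered censored).
* The multi-echo PDFF stand-in fits magnitudes with a single effective R2*
  and no field map, and therefore inherits magnitude-fitting's noise floor
  and swap behaviour near 50% fat fraction.
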