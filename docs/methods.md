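# Methods

This note documents the models, parameter choices and numerical decisions
behind `phosphoshift`, and what the synthetic validation does and does not
establish about real data.

## Forward chemistry

A voxel's biochemical state is (pH, m, Ion): intracellular pH, the MgATP
bound fraction m ∈ [0, 1] under fast two-site exchange, and a
dimensionless ionic-strength surrogate.  Pi follows the phosphate
titration curve between its protonated (3.275 ppm) and deprotonated
(5.685 ppm) limits with pKa 6.77; each ATP resonance mixes linearly
between free-ATP endpoints (γ, α, β) = (−2.72, −7.57, −18.95) ppm and
MgATP endpoints (−2.48, −7.52, −16.15) ppm and carries linearized pH and
ionic-strength sensitivities.  All shifts are referenced to PCr = 0 ppm,
downfield positive.

These constants are configurable (plain-text key=value files) and were
chosen to be literature-plausible while respecting the qualitative
sensitivity orderings that motivate the joint-shift analysis: pH acts
strongest on Pi and γ-ATP, then β, then α; Mg acts strongest on β, then γ,
then α; the ionic term acts on γ and β far more than on α.  Absolute
accuracy of the constants is not load-bearing for the package's validation,
which is parameter *recovery* under the same constants.

Two deliberate modeling choices:

* **Separable affine coupling.**  pH-dependent Mg binding (a pH-dependent
  K_D) is not modeled; pH, Mg and Ion enter each ATP shift additively.
* **Ion units.**  The surrogate has no absolute scale, so the coefficient
  magnitudes (γ 1.0, α 0.1, β 0.3, Pi 0.1 ppm per Ion unit) fix its units.
  They are set so that one look-up grid step of each state variable moves
  the shift triple by a commensurate amount; with much smaller γ/β
  coefficients the nearest-neighbour inversion trades several Ion steps to
  absorb Mg/pH quantization residuals and Ion becomes effectively
  non-identifiable at the grid resolution.  Only relative Ion differences
  are meaningful.

Mg is reported as a bound fraction, not a free concentration; a K_D-based
conversion is deliberately out of scope.

## Synthetic cohorts

The generator emulates the structure the analysis assumes: 11 patients —
8 HGG (7 IDH-WT, 1 IDH-mut) carrying a contrast-enhancing core (CE) with
an edema shell (EDM), 2 LGG (IDH-mut) carrying a non-enhancing compartment
(NCE), and 1 unclassified patient handled like the pleomorphic case
(tumor present, excluded from compartment groups, shown separately in the
IDH grouping).  Geometry is an ellipsoidal brain mask with an offset
ellipsoidal tumor on a 6×6×6 grid by default — the smallest structure
that supports ROI statistics at interactive runtimes; the acquisition
defaults otherwise mirror a 7 T FID-MRSI protocol (Δf = 5000 Hz, 1024
points, 120.76 MHz).

Default compartment biochemistry: NAWM (7.00, 0.80, 0.15), EDM
(7.05, 0.82, 0.15), CE (7.15, 0.90, 0.15), NCE (7.05, 0.91, 0.13).  This
encodes the qualitative pattern of interest — downfield Pi/γ shifts
growing from NAWM through NCE to CE, β-ATP comparably shifted in the LGG
and HGG tumor compartments (ground-truth |Δδβ| ≈ 0.007 ppm), and lower
Ion in the LGG/IDH-mut tumors.  Patient-level Gaussian jitter
(SD 0.02 pH, 0.003 Mg, 0.005 Ion) provides between-patient variability
small enough not to scramble that pattern.

Each metabolite is a Lorentzian singlet (no J-multiplets); the spectral
model comprises PCr, γ/α/β-ATP, intra- and extracellular Pi, PE, PC, GPC,
GPE, DPG, MPL, NAD(H) and UDPG with literature-typical positions,
relative amplitudes and dampings of 20–60 Hz.  Per-compartment amplitude
tables are configurable but default to a single table: the analysis reads
only shifts, and no reliable per-compartment amplitude ratios were
available to encode.  Per-voxel B0 offsets are smoothed uniform draws of
±0.05 ppm; per-voxel amplitude scaling is lognormal (SD 0.2 in log units).

The noise default (complex-channel SD 0.45 in units of the PCr t = 0
amplitude) is calibrated so that *direct* (unfiltered) quantification puts
the worst-of-four amplitude CRLBs astride the 35 % QA gate — the regime in
which the gate does real work.  With the default low-rank filter in the
chain, most voxels pass.

Randomness is organised as counter-derived sub-seeds
(master seed, patient index, stage), so extending the cohort never
perturbs existing patients' draws, and equal seeds give bit-identical
datasets.

**What passing these conditions does not show:** real spectra have
non-Lorentzian lineshapes, baseline from bone/membrane phosphorus,
J-coupling of the ATP multiplets, spatially varying amplitude ratios,
partial-volume mixtures at compartment borders, and segmentation error.
The synthetic validation establishes the correctness of the estimation
machinery, not in-vivo accuracy of the biochemical values.

## Preprocessing

Fixed order: Casorati low-rank filter → spatial zero-filling → 15-Hz
Gaussian apodization.

* **Low-rank:** global truncated SVD of the in-mask (voxels × time)
  matrix, default rank 8.  This is a *projection chosen from the data*,
  hence not a linear operator like the other steps, and it biases even
  noiseless data whose true rank exceeds 8 (per-voxel B0 offsets make the
  Casorati matrix formally full-rank); at the default settings the
  measured shift bias is negligible.  Equivalence with any particular
  published low-rank variant is not claimed.
* **Zero-filling:** k-space padding (fftshift convention; even grids pad
  the extra coefficient on the negative-frequency side) with amplitude-
  preserving scaling; factor 2 ("one-fold") by default.
* **Apodization:** w(t) = exp(−(π·lw·t)²/(4 ln 2)) so that `lw` is the
  *added* Gaussian FWHM in Hz (verified by a spectral-linewidth test:
  10 Hz ⊕ 15 Hz → √(10²+15²) Hz).

**Quantification grid.**  Shifts are quantified on the acquired grid by
default, not the zero-filled grid.  Fourier interpolation blends FIDs
across compartment borders; measured on a noiseless cohort this
partial-volume mixing biases CE ROI means by up to ~0.09 ppm on δβ, an
order of magnitude above the look-up resolution.  The zero-filled option
(`fit_on_zero_filled=True`) remains available to match display grids.

## Quantification and CRLBs

Bounded trust-region least squares (analytic Jacobian) on the complex
residual, starting from the prior table shifted by the voxel's detected
PCr offset, with a linear least-squares refinement of starting amplitudes
and the shared zero-order phase.  Shift windows are ±0.5 ppm, widened to
±1.0 ppm for the mobile Pi and β-ATP lines (both spectrally isolated) and
narrowed to ±0.1/±0.2 ppm for ePi/DPG, which sit inside Pi's travel range:
without that pin, the optimizer can land on a label-permuted solution of
identical residual.  Non-convergence is reported as a flag, not an
exception, and such voxels fail QA.

When the data were apodized, the same known window multiplies the fit
model: the lineshape parameters keep their unapodized meaning and shifts
stay unbiased even for overlapping lines (the alternative — absorbing the
Gaussian into the Lorentzian damping — leaves residual shift bias that can
exceed the Ion resolution).  The noise SD used for CRLB scaling is
estimated from the pre-apodization FID tail (final 25 %, real and
imaginary pooled), since the window annihilates tail noise.

CRLBs: Cov ⪰ σ²·(Re JᴴJ)⁻¹ with J the complex model Jacobian at the fit
and σ the per-channel noise SD; the shared phase enters once.  The Fisher
matrix is unit-normalized before a conditioning check (condition > 1e12 →
non-identifiable, e.g. duplicate resonances).  Amplitude bounds are
reported as % of amplitude, shift bounds in ppm.  A Monte-Carlo check
(300 realizations, amplitude-SNR 20) validates the amplitude CRLB within
15 %; an RMS-vs-CRLB check at noise calibrated for ≈0.01 ppm shift CRLBs
validates the shift bounds within a factor 2.  For windowed fits the
white-noise Fisher matrix is an approximation (apodized noise is not
stationary); all quantitative CRLB validation uses unwindowed fits.

## QA, ROIs, grouping

A voxel passes QA iff the amplitude CRLBs of Pi, γ-, α- and β-ATP are all
*strictly below* the threshold (default 35 %; equality fails), the fit
converged, and no CRLB is missing.  ROI values are unweighted arithmetic
means of PCr-referenced shifts over passing voxels; an ROI with no
passing voxels is reported missing, never zero.  WHT is the union of the
patient's tumor compartments.  Grouping scheme 1 compares HGG-CE,
HGG-EDM, LGG-NCE and NAWM (the unclassified patient contributes only to
NAWM); scheme 2 compares IDH-WT vs IDH-mut whole-tumor means with the
unclassified patient reported separately.

## Look-up inversion

The table evaluates the forward model on a grid of pH 6.0–7.8 × Mg 0–1 ×
Ion 0–0.4, step 0.01 each (181×101×41 nodes), storing α-referenced
triples; α-referencing insulates the inversion from PCr-reference errors.
Inversion is exhaustive nearest-neighbour under the unweighted Euclidean
metric — chosen over interpolation for determinism and testability — with
ties broken toward the lowest pH, then Mg, then Ion.  A residual above
0.1 ppm flags the result out-of-model.  A Jacobian-conditioning report
flags nodes where axes become numerically confounded (none with the
default constants).  Because this package's table is built from its own
forward model, look-up pH and Henderson–Hasselbalch pH agree by
construction (at reference Ion, to grid resolution); the systematic
offsets seen between independently calibrated in-vitro tables and in-vivo
conditions cannot arise here and are not emulated.

## Statistics

Pairwise group comparisons: paired t within-patient (CE vs EDM), Welch t
for independent arms with n ≥ 5 each, Mann–Whitney otherwise (exact null
for min(n) ≤ 8; the enumerable 4-vs-4 extreme case p = 2/70 is asserted).
Significance flags (`*` p < 0.05, `**` p < 0.001) additionally require
post-hoc power > 0.8, computed from the observed effect size via
noncentral-t (t tests) or a normal approximation of U (Mann–Whitney).
Post-hoc power is descriptive, not inferential; its practical role is to
block confident claims from tiny groups — a 2-vs-8 Mann–Whitney cannot
reach power 0.8 at any effect size, so n = 2 groups are never flagged.
Raw p-values are reported per comparison by default (a Holm adjustment is
available but off), matching how such small exploratory cohorts are
usually reported.  Degenerate paired data (zero variance, nonzero mean)
report the limit p = 0 with a warning.

## Problem sizes and determinism

Default validation sizes: 6×6×6 patient grids (~88 brain voxels each),
11-patient cohorts, 100-voxel CRLB-calibration phantoms, 300 Monte-Carlo
noise realizations, 10⁴ null replicates for test calibration, 500 random
states for look-up recovery.  Every stochastic quantity is seeded;
pipeline reruns with equal config and seed produce byte-identical tables.

## Known limitations

* Lorentzian-only lineshape; no Voigt, baseline or multiplet modeling.
* The low-rank stage's interaction with very high noise is unmodeled in
  the CRLBs (noise estimated after filtering is treated as white).
* Post-zero-fill quantification is supported but biased at compartment
  borders (measured above); use the acquired grid for quantitative work.
* The look-up table shares constants with the generator; recovering the
  generator's truth validates the inversion machinery, not the constants.
* Compartment amplitude tables are placeholders (shifts carry the
  analysis); no NOE, coil-combination or k-space acquisition effects.
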