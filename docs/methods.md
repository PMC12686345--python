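# Methods

## Scientific setting

Pancreatic ductal adenocarcinoma stroma contains cancer-associated
fibroblasts (CAFs) in at least two functional states: inflammatory iCAFs
(IL-6-high, lipid-metabolism-enriched) and myofibroblastic myCAFs
(α-SMA/collagen-high). Both can be induced in vitro from human primary
pancreatic stellate cells (HPaSC). Label-free Raman microspectroscopy of
fixed cells resolves these states chemically: iCAFs carry stronger
lipid-associated CH-stretch bands (2,811, 2,896, 2,910, 2,950 cm⁻¹) and a
stronger DNA band at 481 cm⁻¹, myCAFs a stronger guanine band at 680 cm⁻¹
and elevated nucleotide bands (830, 992, 1,175 cm⁻¹) relative to HPaSC,
while HPaSC keeps the strongest amide-I bands (1,638, 1,700 cm⁻¹).

This package implements that classification workflow end to end: synthetic
hyperspectral cell maps with the assumed statistical structure, spectral
preprocessing, partial least squares discriminant analysis (PLS-DA) with
variable-importance (VIP) band selection, and the full evaluation protocol.
Because the original raw spectra are not publicly deposited, the synthetic
generator is first-class, tested code: it defines the study conditions
under which every downstream claim is checked.

## Synthetic data generator

One simulated experiment is 8 HPaSC, 10 iCAF and 12 myCAF cells, each
mapped on an approximately square raster of 100 pixels (1 spectrum per
pixel; the 1 µm pitch is metadata only), on a 300–5,000 cm⁻¹ grid at
1 cm⁻¹ spacing (4,701 channels). The instrument's sampling density is not
publicly specified; the integer grid is a package choice that makes band
lookup exact.

Each spectrum is

```
y(w) = Σ_j A_j m_j g_j(w) + P g_PFA(w) + b(w) + ε(w)
```

* `g_j`: Gaussian line shapes at the literature band positions, FWHM
  12 cm⁻¹ in the fingerprint region, 40 cm⁻¹ for CH stretches,
  60 cm⁻¹ for the OH stretch (plausible widths for a 600-groove grating;
  line widths are not published, and all are config-exposed).
* `A_j`: class-specific mean amplitudes encoding the contrast directions
  listed above. No biological band lies inside the Raman-silent region
  (1,800–2,800 cm⁻¹); `PeakSpec` enforces this.
* `m_j`: one log-normal multiplier (mean 1) per peak per **cell** — the
  between-cell level of the variance hierarchy. The default CV is 0.08;
  iCAF uses 0.25 for peaks in the 700–800 and 1,200–1,400 cm⁻¹ windows,
  where that class is reported to be most variable; the CH-stretch cluster
  uses per-class CVs (0.20 / 0.112 / 0.138) chosen so the total
  post-normalization SD of the 2,896 cm⁻¹ band approaches the published
  0.667 / 0.575 / 0.474.
* `P`: the 1,040 cm⁻¹ paraformaldehyde (PFA) internal-standard amplitude,
  log-normal per pixel with mean 50 counts and CV 8 %. The mean anchors
  the arbitrary intensity scale and is deliberately large relative to the
  pixel noise: an internal standard that cannot be measured precisely makes
  ratio normalization meaningless.
* `b(w)`: a per-pixel random cubic polynomial (autofluorescence), with
  coefficient SDs scaled to roughly 20 % of typical peak height.
* `ε(w)`: additive white Gaussian noise, SD 3 counts per channel — the
  within-cell level of the hierarchy.

A fixed `SimConfig` (including seed) reproduces the dataset bit-for-bit.

### Calibration of the 2,896 cm⁻¹ band

Published statistics pin the post-normalization 2,896 cm⁻¹ band means to
4.082 / 5.042 / 3.659 (HPaSC / iCAF / myCAF). Calibration proceeds in two
deterministic steps:

1. **Closed form.** Amplitudes are expressed in normalized units times the
   expected PFA band mean, corrected for the Jensen bias of dividing by a
   stochastic denominator (`E[1/P] = exp(σ_ln²)/E[P]`) and — for the
   2,896 band — for the leakage of the neighbouring CH peaks into the
   2,896 ± 2 cm⁻¹ window (2,910 cm⁻¹ contributes ≈ 0.71× its amplitude
   there; ignoring this would overshoot the targets by ~50 %). Band
   response factors are computed from Savitzky–Golay-filtered unit peaks so
   smoothing attenuation is included.
2. **Forward-model refinement.** The baseline estimator interacts
   nonlinearly with the broad CH envelope and with pixel noise; no closed
   form captures that residual (~1–3 %). The 2,896 amplitude is therefore
   adjusted once by a two-point secant solve through the full pipeline:
   simulate one calibration cell per class at a fixed internal seed
   (cell-level variability off — its multiplier has mean 1 and cannot bias
   the mean, only inflate calibration variance; noise, baselines and PFA
   jitter on, with common random numbers across the two evaluations),
   preprocess with defaults, measure the band, solve linearly. The solve is
   deterministic and cached per process.

Across 20 independent seeds, class means land within 2 cluster-aware
standard errors (published SD / √n_cells) of the published values in 19–20
runs, and the acceptance suite asserts ≥ 18/20.

### What the generator does not emulate

No cosmic rays, detector etaloning or wavelength-dependent response; no
intracellular structure (nucleus vs cytoplasm), so within-cell variation is
pure noise rather than organelle chemistry; Gaussian-only line shapes;
statistically independent peak amplitudes within a cell. Passing tests
demonstrate that the analysis machinery is correct and well calibrated
under these assumptions — not that real CAF spectra are this separable.
In particular, spectrum-level splits on mapped cells share cells between
train and test; accuracy under that protocol is an upper-bound estimate,
which is why cell-level splitting is also provided (see Evaluation).

## Preprocessing

Order: baseline removal → Savitzky–Golay smoothing → internal-standard
normalization, independently per spectrum (no training statistics, hence no
train/test leakage through preprocessing). The published workflow names
only "polynomial fitting and smoothing" in vendor software and
normalization at 1,040 cm⁻¹; all specifics below are package choices,
config-exposed.

* **Baseline:** iterative modified polynomial, default order 5, relative
  tolerance 1e-4 on the fitted values, max 100 iterations, fitted on the
  domain scaled to [-1, 1] for conditioning. The default clipping level is
  `fit + SD(residual)` (noise-aware "improved modpoly"): plain
  `min(y, fit)` clipping converges to the *lower envelope* of the noise,
  and the resulting positive offset in the corrected spectra inflates
  band ratios — at the default noise level it distorted normalized band
  means by ~30 %. Plain clipping is available via
  `baseline_noise_aware=False`. Negative residual intensities are retained;
  clipping them would bias band statistics.
* **Smoothing:** Savitzky–Golay, window 11, polynomial order 3, polynomial
  endpoint interpolation. Exactly preserves polynomials up to the filter
  order.
* **Normalization:** divide by the mean intensity over 1,040 ± 2 cm⁻¹
  (closed window; a band rather than one channel for robustness to grid
  offset; `norm_half_width=0` gives single-channel behaviour). The band
  mean equals 1 exactly afterwards; scale invariance is tested.

## PLS-DA and VIP

NIPALS PLS2 on mean-centered spectra against one-hot class indicators,
2 components by default. Bands are **not** autoscaled: after
internal-standard normalization spectra share a physical intensity scale,
and autoscaling would inflate silent-region noise (an `autoscale` flag
exists). The NIPALS inner loop starts from the first response column, so
fits are deterministic without a random seed; weight-column signs are fixed
so the largest-magnitude entry is positive; inner tolerance 1e-10, max 500
iterations. Regression coefficients `B = W (PᵀW)⁻¹ Qᵀ` give direct
prediction; the classifier is the row-wise argmax of the continuous
response, ties toward the earliest class in `class_order` (the original
decision rule is unpublished; argmax is the standard choice).

VIP follows Wold's formulation with `SSYₐ = ‖tₐ‖² Σₖ q²ₖₐ` summed over all
response columns; Σⱼ VIPⱼ² = p is an algebraic identity used as a test
invariant. Discriminant bands are those with VIP strictly above the
threshold (default 1.0). The model consumes the entire spectrum including
the silent region; cropping to the fingerprint or CH windows is optional.

## Evaluation

* **Split:** stratified 70/30, deterministic given a seed. `spectrum` mode
  mirrors the published protocol; `cell` mode assigns whole cells to one
  side and is the recommended honest generalization test.
* **Metrics:** confusion matrix (rows = truth), per-class precision /
  recall / F1, overall accuracy. A class never predicted has undefined
  precision; it is reported as 0 with an explicit flag, never silently.
* **ROC/AUC:** one-vs-rest from the continuous PLS responses (not hard
  labels), tie-grouped thresholds, trapezoidal AUC — equal to the
  tie-adjusted Mann–Whitney concordance probability (asserted against
  exhaustive pair counting up to m = 50). The macro average is reported
  because the published single "AUC for all classes" does not state its
  averaging.
* **Cross-validation:** stratified k-fold (default 5) in either split mode;
  cell-mode folds never split a cell.
* **Band statistics:** per-class mean/SD of the band-mean intensity over
  center ± half-width, pairwise Student's equal-variance t-tests by
  default (Welch by flag), two-sided p-values, no multiple-testing
  correction by default (a Bonferroni flag exists). Zero-variance pairs
  are reported as degenerate, not p = 0.
* **Published-table reconstruction:** from the published diagonal counts
  and per-class precision/recall, per-class set sizes are
  `correct/recall` and `correct/precision`; both routes must give the same
  grand total (7,256) — used as a worked-example identity since the
  underlying spectra are unavailable.

## Pipeline

`run_pipeline` chains simulate/load → preprocess → split → train →
evaluate and writes fixed-key-order JSON plus CSV artifacts, so identical
configs replay bit-for-bit. One global seed is fanned out through
`SeedSequence` into independent substreams for simulation, splitting and
CV, keeping stages individually re-runnable. Every number in the report is
recomputable from the persisted preprocessed dataset and model archive
(verified by a replay test).

## Problem sizes and numerical choices

Acceptance-level checks run the full study design (3,000 spectra × 4,701
channels) over 20 seeds for the calibration and VIP-recovery rates; unit
tests use a reduced 3 × 3-cell, 20-pixel design. The baseline solver
vectorizes the modpoly iteration across spectra via one QR factorization
of the shared design matrix, compacting converged rows. Wavenumber
intervals are closed on both ends everywhere. CSV writers use 17
significant digits so write → read round-trips are exact.

## Known limitations

* Published headline numbers (95.24 % accuracy, AUC 0.99, CV mean 0.9368,
  the confusion diagonal) came from undeposited raw data and are not
  reproduced here; synthetic-data performance is checked against
  plausibility bands instead.
* The Table 1 band list is represented by a subset: near-duplicate entries
  (1,180 vs 1,175; 1,690 vs 1,700; 1,004 kept, 1,370 kept) closer than one
  default line width are merged into a single band.
* The literature lists both "922" and "992" for the myCAF-elevated
  benzene-ring band; this package uses 992.
* The between-cell vs within-cell variance split is an assumption; only
  its 2,896 cm⁻¹ consequences are pinned by published numbers.
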