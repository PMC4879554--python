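# Methods

This note documents the models, numerical choices and limitations of
`ramanclass` — what each stage assumes, which parameters matter, and
what the synthetic-data experiments do and do not demonstrate.

## Preprocessing

Two preprocessing paths serve two distinct purposes.

**Classification path** (input to PCA/LDA), applied per spectrum in
this fixed order:

1. *Background subtraction* (optional): an instrument/substrate
   background spectrum is linearly interpolated onto the sample axis
   and subtracted. Subtractive correction only; a multiplicative
   detector-response correction is out of scope.
2. *Savitzky–Golay first derivative*, window 3, polynomial order 1.
   At window 3 only orders ≤ 2 exist, and order 1 makes the filter the
   central-difference estimate; the derivative is reported in intensity
   per cm⁻¹ (`delta` = grid step). Endpoints use the filter's one-sided
   polynomial fit (`mode="interp"`). Differentiation suppresses the
   slowly varying fluorescence background that dominates raw biological
   Raman spectra. The filter requires a uniform axis; non-uniform
   spectra are resampled first.
3. *Region interpolation*: linear interpolation onto a uniform grid at
   1 cm⁻¹ over the analysis region — fingerprint 700–1800 (1101
   points), high-wavenumber 2800–3100, tissue 1200–1800 cm⁻¹. 1 cm⁻¹
   matches dispersive-system sampling and keeps the PCA dimensionality
   stable across studies.
4. *Vector normalization* to unit Euclidean norm, last, so unit norm
   holds on the analysis grid. This removes per-acquisition intensity
   scale (laser power, focus, pellet density) — which is also why the
   generator's multiplicative batch factor is invisible to the
   classifier, as it should be.

Negative intensities are allowed throughout (derivatives are signed by
construction); no clipping, despiking, wavenumber calibration or
EMSC/MSC correction is performed.

**Mean-spectrum path** (band interpretation): spectra are background-
subtracted and interpolated *without* derivatization, averaged
pointwise per group, baseline-corrected by subtracting a least-squares
polynomial of order 5 fitted to the whole region (no peak masking; the
fit uses a scaled domain, so it is well conditioned at order 5), SG-
smoothed (window 3, order 1 — a 3-point moving average), and vector-
normalized. Baseline correction is a projection, hence idempotent and
exact on polynomial inputs of the same order; averaging, baseline
correction and smoothing are all linear, so the group mean equals the
mean of individually processed spectra up to the final normalization.

## PC-LDA

The classifier is LDA on a screened subset of PCA scores:

* **PCA**: mean-centred, full SVD, default 10 factors (the cell-study
  setting; small sets are clamped to the admissible `n − 1` bound).
* **Factor screening**: per factor, a one-way ANOVA F-test of the
  scores across groups; factors with p < α (default 0.05) are kept.
  Kruskal–Wallis was considered as an alternative; ANOVA on scores is
  the standard chemometric screen and is what the package uses. The
  number of retained factors is capped at the largest integer strictly
  below half the smallest group size (an over-fitting guard, e.g.
  smallest group 16 → at most 7 factors); if more qualify, the
  smallest p-values win, ties broken by lower factor index. If *no*
  factor passes the screen — which happens on label-permuted null data
  — the single smallest-p factor is used so that a (chance-level)
  model can still be cross-validated.
* **LDA**: within-class scatter S_w and between-class scatter S_b in
  the selected-score space; discriminant axes are the leading
  generalized eigenvectors of (S_b, S_w), rescaled so the pooled
  within-class covariance is whitened. Classification assigns the
  nearest class mean in this space under the Euclidean metric, which
  equals the maximal linear discriminant score under equal priors.
  Equal priors are used despite unequal group sizes because the study
  design treats groups symmetrically. Ties break to the lowest class
  index in the model's label order (determinism). A singular S_w
  raises an error recommending fewer factors.
* **LOOCV** refits the *entire* chain — PCA, screening, LDA — on the
  n−1 retained spectra of every fold, so no information leaks from the
  held-out spectrum. (Refitting is the conservative choice; the
  original workflow is ambiguous on this point.) A brute-force
  refit-per-fold loop reproduces `loocv()` exactly; this equivalence is
  tested.
* **Frozen models** are serialized as versioned JSON (axis, mean,
  loadings, selection, discriminant axes, class means) so the standard
  model can be reapplied to independent test sets; prediction centres
  new spectra with the *training* mean and refuses axis mismatches.

Classification efficiency is 100 · trace / total of the confusion
matrix (rows true, columns predicted), with per-group values
100 · diagonal / row sum.

## Band analysis

Peaks of (difference) spectra are local extrema of either sign with
prominence above 3× the median absolute deviation of the spectrum — a
scale-free default that works on normalized data. Peaks are matched to
every literature band whose centre lies within ±8 cm⁻¹ (±15 cm⁻¹ for
the broad C–H stretch bands); the window covers reported intra-band
drift (1447 vs 1450 cm⁻¹) without cross-band confusion, and
one-to-many matches are deliberate (1660 cm⁻¹ reports both amide I and
ceramide). The breadth of the 2840–2880 cm⁻¹ lipid region is
quantified as the trapezoidal area in that window.

## Assays

* **D₀** is fitted from a clonogenic survival curve under the
  single-hit model SF(D) = exp(−D/D₀) by least squares on the log
  scale through the origin: slope = Σ D·ln SF / Σ D², D₀ = −1/slope.
  By construction SF(D₀) = 1/e ≈ 36.8 %, i.e. "the dose at which 37 %
  of cells survive". The fit is exactly covariant under dose rescaling.
  Zero survival points are rejected (log undefined); a linear-quadratic
  model is out of scope.
* **ΔΔCt**: fold change = 2^−[(Ct_t − Ct_r)_test − (Ct_t − Ct_r)_ctrl].

## Synthetic data generator

No spectra were deposited with the source study, so the generator
defines the test bed. Each spectrum is

    I(ν) = b · [ Σᵢ aᵢ L(ν; cᵢ, wᵢ) + baseline(ν) ] + ε(ν)

with unit-height Lorentzians L (the standard Raman line shape;
Gaussian/Voigt variants are not modelled), a polynomial fluorescence
baseline of degree ≤ 5 in the scaled region coordinate, a per-batch
lognormal intensity factor b (SD 0.1, 3 batches — mirroring biological
triplicates), per-spectrum band amplitudes aᵢ ~ Normal(mean, CV·mean)
clipped at zero with CV 0.03, and additive Gaussian noise ε with
per-channel SD 0.05 × the largest mean band amplitude.

ε is *correlated* across channels with a Gaussian kernel of σ = 7 cm⁻¹
(l2-normalized, so the per-channel SD is independent of σ). This
represents the spectrograph line-spread function combined with the
residual slowly varying fluctuations that survive detector-response
correction — the very nuisance the derivative step exists to suppress.
Channel-white noise would instead be *amplified* by differentiation
relative to the smooth band signal and is not what corrected,
accumulation-averaged spectra look like.

Class presets share a backbone of cellular bands and differ by which
bands are elevated (+0.25 over backbone amplitudes of 0.2–1.0):
recurrent → lipids (1272, 1305, 1447, 1660, 1725, 1746, 2850, 2880,
plus a 1673 ceramide shoulder); parent → DNA/protein (1008, 1095,
1340, 1560, 1610, 2900); non-responder tissue → 1313, 1320, 1340,
1367, 1485, 1579, 1750 on the 1200–1800 cm⁻¹ region. The SF268
recurrent preset deliberately inverts the DNA/protein shift (slightly
higher DNA, lower protein) to mimic the one atypical cell line. In the
8-group cell study every group additionally receives its own band-
centre jitter (uniform, ≤ 0.8 cm⁻¹ per band) as inter-sample
variation; the tissue study draws a configurable fraction (default
10 %) of each group from a 50/50 mixed profile, mimicking clonal-cell
overlap between outcome groups.

The free generator parameters (noise correlation length, amplitude CV,
jitter magnitude, the 3.5 cm⁻¹ half-width of the sharp phenylalanine
band) were calibrated once so that the default studies operate where
this kind of experiment is reported to live — leave-one-out efficiency
in the 90–98 % range with occasional misclassifications between
related groups, a controlled one-band shift of 4× the noise SD
recovered at ≥ 95 % median efficiency, and tissue classification in the
low-90s at 10 % overlap — and are fixed defaults thereafter.

**What passing tests show — and don't.** The generator reproduces the
statistical structure the pipeline assumes: smooth baselines dominated
by fluorescence, multiplicative intensity drift, band-level class
differences, modest within-class amplitude variation. It does not model
photon shot noise, photobleaching kinetics, cosmic-ray spikes,
wavenumber miscalibration, water/paraffin contamination, or the spatial
heterogeneity of real tissue. Success on synthetic data therefore
demonstrates the correctness and internal consistency of the analysis
chain at realistic effect sizes, not clinical performance on real
spectra.

## Problem sizes and determinism

The packaged studies use 30 spectra/group (8 groups) for cells and 45
per class for tissues, matching the reported designs; tests and the
acceptance script run reduced designs (10–30 spectra/group, 3–10
seeds) chosen to make every stochastic check stable at its stated
threshold. All generators are pure functions of (config, seed); the
pipeline itself is deterministic, so identical inputs and configuration
give bitwise-identical outputs.

## Known limitations

* The ANOVA screen assumes approximately normal scores within groups;
  heavy-tailed score distributions would favour a rank-based screen.
* Plain LDA requires more spectra than selected factors per group;
  regularized/shrinkage LDA is explicitly out of scope.
* The polynomial baseline fit uses no peak masking; very strong, broad
  peaks leak slightly into the baseline estimate (bounded in tests).
* Band annotation is nearest-window matching against a fixed table; it
  does not resolve genuinely overlapping assignments.
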