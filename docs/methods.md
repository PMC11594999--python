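# Methods

This note documents the models, conventions and calibration behind
`flimtex`, and what the synthetic tests do and do not establish about
real FLIM data.

## Data model and conventions

A *lifetime matrix* is a 2-D float64 array of per-pixel mean fluorescence
lifetimes in picoseconds.  Coordinates are 0-based with half-open
rectangles (`x` = column, `y` = row, origin top-left), so an ROI
`(x0, y0, x1, y1)` selects `values[y0:y1, x0:x1]`.  NaN marks pixels
without a lifetime estimate (e.g. masked plasma); it is legal in stored
matrices but rejected inside a declared ROI, because every statistic is
defined on a fully observed rectangle placed strictly inside the cell.
All feature computation happens after ROI extraction — extracellular
plasma never contaminates the statistics.

Matrices round-trip bit-exactly through tab-separated text (`repr` of
each float) and within float32 precision through single-channel TIFF.

## Histogram features

Per-ROI features are population moments (SD with divisor n, skewness
m₃/m₂^1.5 without small-sample correction), linear-interpolation
percentiles, and Shannon entropy of an equal-width histogram over the
ROI's own [min, max] range.  Entropy binning (default 32 bins, natural
log) is a free parameter: published absolute entropy values depend on an
unknowable binning, so entropies are comparable only within one
configuration, never across software.  A constant ROI reports SD 0,
entropy 0 and, by convention, skewness 0 (with a warning).

## riu2 Local Binary Patterns

Neighbour i of pixel (cx, cy) is sampled at
(cx + R·cos(2πi/P), cy − R·sin(2πi/P)) (y axis down); positions within
1e-9 of a pixel centre are snapped onto it so axis-aligned samples
reproduce pixel values exactly, and other positions use bilinear
interpolation.  The indicator s(x) returns 1 at x = 0 exactly.  The
uniformity U is the circular transition count including the wrap term;
uniform patterns (U ≤ 2) code as their popcount, all others as the
sentinel P + 1, giving P + 2 codes (26 at the default P = 24, R = 3).
Rotation invariance is obtained directly from the popcount rule rather
than minimum-over-shifts (equivalent for riu2, O(P) per pixel).

Borders of width ceil(R) are excluded rather than padded — padding would
fabricate texture.  "LBP mean/SD/skewness" are moments of the code
matrix (the mean equals the frequency-weighted histogram index, so both
readings coincide); "LBP entropy" is the Shannon entropy of the
26-bin histogram.

Grey-scale invariance is stated carefully: codes are invariant under
*any* strictly increasing transform only where samples fall on pixel
centres (e.g. P = 4, R = 1); with interpolated samples, invariance is
exact for positive affine maps, while nonlinear monotone maps can flip
near-tied comparisons.  The tests exercise each claim in the regime
where it holds.  The implementation is verified pixel-exactly against a
naive double-loop oracle and against scikit-image's `uniform` method.

## Fisher discriminant and validation

For two classes the direction maximizing J(w) = wᵀS_B w / wᵀS_W w is
w ∝ S_W⁻¹(μ₁ − μ₀); a singular S_W falls back to ridge regularization
(ε = 1e-8·trace(S_W)/d, recorded on the model).  The decision threshold
on the projection is placed where pooled-covariance Gaussian posteriors
with training priors are equal; predictions match scikit-learn's LDA
exactly on nondegenerate data (an independent cross-check, not the
implementation).

Stepwise selection uses partial Wilks' Λ F statistics with forward entry
and backward removal; defaults F-to-enter = 3.84 / F-to-remove = 2.71
(the classical defaults of legacy statistics packages).  Note these are
*per-candidate* α ≈ 0.05 thresholds: with k noise candidates the
familywise false-entry rate is ≈ 1 − 0.95ᵏ, so analyses that must keep
*any* noise feature out should raise F-to-enter (the selection-
reliability test uses F = 8, per-candidate α ≈ 0.005, for its
three-noise-feature scenario).  Collinear candidates are skipped via a
singularity guard, so a duplicated feature enters once.

Leave-one-out refits the *entire* procedure (including selection) per
fold; the unit is a cell or a patient (`loo_group="patient"` guards
against within-patient leakage).  Hold-out validation is stratified
50/50, 10 repeats by default, reporting accuracy and macro F-score
mean ± SD.  Patient-level analysis averages each patient's cell features
arithmetically before fitting.

## Group statistics

Mann–Whitney uses the exact U distribution when min(n₁,n₂) ≤ 8 without
ties, else the tie-corrected normal approximation (no continuity
correction, so the branches agree in the limit); Wilcoxon drops zero
differences, exact for n ≤ 12 without tied magnitudes.  Both are
verified against full enumeration.  The KS normality screen estimates
mean/SD from the sample, so the Lilliefors-corrected p-value is the
default; the uncorrected variant is kept for comparability with legacy
software.  No multiple-testing correction is applied by default;
Bonferroni/BH are available.

## Synthetic generator: what it emulates and how it is calibrated

The generator emulates three phenotypes on a plasma background
(400 ps, above all cytoplasm means): round control cells, round
non-sickled SCD cells with 0–3 bright dots (uniform over the range;
never in controls), and elongated bent-ellipse sickled cells (axis ratio
≥ 3) with a high-lifetime patch grown from a boundary seed covering
10–30 % of the cell.  The ROI is the largest greedily grown axis-aligned
rectangle strictly inside the footprint.

**Calibration contract.**  Class means/SDs (175.5/30.2, 193.9/28.1,
253.3/58.6 ps) are per-cell ROI pixel statistics.  Per cell, the noise
field is standardized to zero mean/unit SD over the ROI, the planted
offsets' ROI mean is absorbed into the base level, and their ROI
variance is given a capped share (80 %) of the variance budget — offsets
are rescaled if they would exceed it — with pixel noise receiving the
remainder.  Consequently each cell's ROI mean equals the class mean plus
a per-cell jitter (SD 8 ps) and a per-patient shift (SD 5 ps), and the
ROI pixel SD equals the class SD in expectation.  Two side effects are
deliberate: (i) raising a planted offset does not raise the 95th
percentile unless the planted mass reaches the top 5 % of ROI pixels
(the compensation slightly lowers it instead), so the p95-monotonicity
property is tested with three radius-4 dots where it genuinely holds;
(ii) the broad sickled patch is often rescaled into the SD budget and
then manifests as elevated SD/p95 rather than as a robust-threshold
focus — the foci detector is validated on the compact dots.

**Texture contrast.**  Real class differences in LBP features arise from
sub-resolution changes in the hemoglobin matrix that no generator can
copy from summary statistics; they are emulated with two per-class
knobs, each with per-cell log-normal jitter (σ = 0.15) and a smaller
per-patient factor (σ = 0.05): the spatial correlation length of the
noise field (σ_texture 0.70/0.78/0.90 px), which mainly moves LBP mean
(down) and entropy (up), and the amplitude of an additive large-scale
structure field (0.25/0.75/0.90 × class SD, correlation 6 px), which
mainly moves entropy and SD.  The two directions make the class contrast
genuinely two-dimensional so that a stepwise discriminant recovers both
LBP mean and LBP entropy, with cell-level accuracy around 0.9 and
patient-level near 1.0 at the default cohort scale.  These values were
tuned once against the generator itself; they are modelling choices, not
biological claims, and passing tests demonstrate the *pipeline*, not any
property of patient data.  In particular the absolute accuracies on
synthetic cohorts are not comparable to accuracies on real cohorts.

The `shot-like` noise option modulates noise amplitude by the square
root of the local mean level before re-standardization, for sensitivity
analyses.  All randomness flows from one seed through `SeedSequence`
substreams per patient and per cell, so any cell can be regenerated in
isolation and cohorts are bit-reproducible.

## Foci detection

Foci are 8-connected components above median + 3.5 × robust SD
(1.4826·MAD) with area ≥ 6 px.  The defaults were chosen by calibration
against the generator's placement log: over non-sickled cells they give
a detected/planted (within-ROI) ratio of ≈ 1.00 with zero false
positives on controls.  Dots planted outside the ROI are invisible by
construction; recovery is therefore always evaluated against the dots
whose centres fall inside the ROI.

## Problem sizes and numerical choices

The validation suite uses 200 cells per class for distributional
recovery, 20 replicate cohorts of 24 patients × 8 cells for the
end-to-end structural check, 10,000 samples per class for the Gaussian
Bayes-rate comparison and 100 runs for selection reliability — sizes at
which sampling error is well below the tested tolerances while the suite
stays fast.  Degenerate inputs fail loudly (single-class fits, constant
samples, all-zero differences, out-of-bounds ROIs) rather than
returning defaults, except where a convention is standard (skewness 0
for constant input, per-class F = 0 when nothing is predicted positive).

## Known limitations

The generator does not model optics (PSF), photon-counting statistics at
the TCSPC level, multi-cell scenes, or vendor file formats.  Sickled
ROIs are small (thin footprints), so their texture statistics are
noisier than round-cell statistics.  Entropy values are binning-relative.
The stepwise procedure inherits the known optimism of data-driven
selection; leave-one-out includes selection inside each fold precisely
to expose that optimism.
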