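# flimtex

Texture analysis of fluorescence lifetime imaging (FLIM) matrices of red
blood cells, for researchers studying hemoglobin S polymerization in
sickle cell disease (SCD).

Label-free FLIM assigns each pixel a mean fluorescence lifetime (here in
picoseconds).  In SCD, polymerizing hemoglobin changes the sub-resolution
arrangement of the cytoplasm, which alters the *texture* of the lifetime
matrix even in cells that look normal under the light microscope.  This
package implements the full analysis chain needed to quantify that:

* **Histogram features** per cell ROI: mean, SD, skewness, Shannon
  entropy, 5th/95th percentiles of the pixel lifetimes.
* **Rotation-invariant uniform Local Binary Patterns (riu2).**  For each
  pixel, P neighbours are sampled on a circle of radius R (bilinear
  interpolation) and thresholded against the centre:

  LBP(riu2)_{P,R} = Σᵢ s(gᵢ − g_c)  if U ≤ 2, else P + 1,

  where s(x) = 1 for x ≥ 0 and U counts circular 0↔1 transitions.  With
  the study geometry P = 24, R = 3 this yields 26 possible codes; the
  code histogram and its mean/SD/skewness/entropy are the texture
  descriptors.
* **Fisher linear discriminant** maximizing J(w) = wᵀS_B w / wᵀS_W w,
  with classical stepwise feature selection (partial Wilks' Λ
  F-statistics), leave-one-out validation at cell or patient level, and
  repeated stratified 50/50 hold-out with macro F-score.
* **Nonparametric group statistics**: Mann–Whitney U (exact for small
  samples), Wilcoxon signed-rank, Kolmogorov–Smirnov normality screen
  with Lilliefors correction.
* **A calibrated synthetic cohort generator** emulating three phenotypes
  — control cytoplasm (mean ≈ 175.5 ps), non-sickled SCD cells
  (≈ 193.9 ps, 0–3 bright dots), sickled cells (≈ 253.3 ps, elongated
  footprint plus a membrane-adherent high-lifetime patch) — so the whole
  pipeline is testable without patient data.
* **Foci detection**: robust-threshold connected-component counting of
  high-lifetime dots, validated against the generator's planted ground
  truth.

## Worked example

`examples/simulate_and_classify.py` generates 12 control and 12 SCD
"patients" with 8 round cells each, extracts the four LBP summary
features and classifies at both analysis levels:

```
192 cells from 24 patients
stepwise-selected features: ['lbp_entropy', 'lbp_mean']
cell-level LOO accuracy:    90.1%  (n=192)
patient-level LOO accuracy: 100.0%  (n=24)
```

The stepwise discriminant recovers LBP entropy and LBP mean as the
informative texture features, and averaging each patient's cells before
classification raises accuracy — the structural result of the cell-level
vs patient-level analysis.  The other example scripts demonstrate the
LBP transform on one cell (`lbp_demo.py`), the table-shaped group
comparison (`group_comparison.py`) and foci counting
(`foci_counting.py`).

A thin CLI wraps the same functions:

```sh
flimtex run --seed 7 --out runs/demo          # simulate → features → classify → compare → foci
flimtex simulate --out runs/sim --seed 1      # matrices + manifest only
flimtex classify --features runs/demo/features.tsv --level patient
```

## Layout

```
src/flimtex/      io, features, lbp, discriminant, groupstats, foci,
                  synthetic, pipeline, cli
tests/            pytest suite incl. brute-force oracles (tests/_oracles.py)
examples/         narrative scripts, one per capability
docs/methods.md   models, calibration and design choices in detail
```
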