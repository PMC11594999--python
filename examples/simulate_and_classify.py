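"""Generate a synthetic cohort and classify control vs SCD patients.

Builds a cohort of 12 control subjects and 12 SCD patients (8 round cells
each), extracts the four LBP summary features per cell, then runs the
stepwise Fisher discriminant with leave-one-out validation twice: on
single cells and on per-patient feature means.  Averaging cells per
patient shrinks within-class spread, so patient-level accuracy should
exceed cell-level accuracy — the structural result this pipeline exists
to reproduce.
"""

import numpy as np

from flimtex import generate_cohort
from flimtex.discriminant import aggregate_per_patient, loo_validate, stepwise_select
from flimtex.pipeline import feature_table

FEATS = ["lbp_mean", "lbp_sd", "lbp_skewness", "lbp_entropy"]

cohort = generate_cohort(
    n_per_group={"control": 12, "scd": 12},
    cells_per_patient={"control": 8, "nonsickled": 8, "sickled": 0},
    seed=1,
)
df = feature_table(cohort.cells)
print(f"{len(df)} cells from {df['patient_id'].nunique()} patients")

X, y = df[FEATS].to_numpy(), df["group"].to_numpy()
selected, _ = stepwise_select(X, y, feature_names=FEATS)
print("stepwise-selected features:", selected)

cell = loo_validate(X, y, stepwise=True, feature_names=FEATS)
pat = aggregate_per_patient(df[["patient_id", "group"] + FEATS])
patient = loo_validate(
    pat[FEATS].to_numpy(), pat["group"].to_numpy(), stepwise=True, feature_names=FEATS
)
print(f"cell-level LOO accuracy:    {100 * cell.accuracy_loo:.1f}%  (n={len(df)})")
print(f"patient-level LOO accuracy: {100 * patient.accuracy_loo:.1f}%  (n={len(pat)})")
print("Patient averaging should raise accuracy by shrinking within-class variance.")
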