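"""Table-shaped nonparametric comparison of the three cell phenotypes.

Generates a small cohort including sickled cells, computes the 8 per-cell
features and prints the cell-level comparison table: group means with
Mann-Whitney p-values for control vs non-sickled and non-sickled vs
sickled.  Raw lifetime statistics separate sickled cells strongly (the
polymerization patch raises mean and SD), while the LBP features also
separate the *visually identical* control and non-sickled classes.
"""

import pandas as pd

from flimtex import generate_cohort
from flimtex.pipeline import compare_groups, feature_table

cohort = generate_cohort(
    n_per_group={"control": 8, "scd": 8},
    cells_per_patient={"control": 6, "nonsickled": 6, "sickled": 3},
    seed=5,
)
df = feature_table(cohort.cells)
table = compare_groups(df, level="cell")
pd.set_option("display.float_format", lambda v: f"{v:.4g}")
print(table.to_string(index=False))
print("\nSmall p in 'p_control_vs_nonsickled' for lbp_* rows shows texture "
      "separating classes a human observer cannot distinguish.")
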