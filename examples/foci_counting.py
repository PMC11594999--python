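"""Detect high-lifetime foci (polymerization nuclei surrogates) per cell.

Generates cells of each phenotype and counts connected high-lifetime
regions in the ROI with the robust-threshold detector.  Control cells
carry none by construction; non-sickled SCD cells carry 0-3 planted dots;
sickled cells additionally carry a membrane-adherent patch.
"""

import numpy as np

from flimtex import detect_foci, generate_cell
from flimtex.io import extract_roi

for cls in ("control", "nonsickled", "sickled"):
    counts = []
    for s in range(40):
        matrix, record = generate_cell(cls, seed=300 + s)
        counts.append(detect_foci(extract_roi(matrix, record.roi)).count)
    print(f"{cls:11s}: mean {np.mean(counts):.2f} foci/cell "
          f"(range {min(counts)}-{max(counts)}) over 40 cells")
print("Counts are per-ROI; dots planted outside the analysis rectangle are "
      "invisible to the detector by design.  Sickled counts are low because "
      "the generator folds the broad patch into the cell's fixed pixel-SD "
      "budget, so the patch raises SD/p95 rather than crossing the robust "
      "threshold; the detector is validated on the compact dots.")
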