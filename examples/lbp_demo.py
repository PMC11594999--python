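"""Compute the riu2 LBP transform and descriptors of one synthetic cell.

Generates a single non-sickled SCD cell, extracts its ROI, applies the
rotation-invariant uniform LBP with the study geometry (P=24 neighbours,
radius 3 px) and prints the 26-bin descriptor and the four LBP summary
statistics used for classification.
"""

import numpy as np

from flimtex import LBPParams, generate_cell, lbp_histogram, lbp_stats, lbp_transform
from flimtex.io import extract_roi

matrix, record = generate_cell("nonsickled", seed=42)
roi = extract_roi(matrix, record.roi)
print(f"cell {record.cell_id}: ROI {roi.shape[1]}x{roi.shape[0]} px, "
      f"mean lifetime {roi.mean():.1f} ps, SD {roi.std():.1f} ps")

codes = lbp_transform(roi, LBPParams(P=24, R=3))
hist = lbp_histogram(codes)
stats = lbp_stats(codes)

print(f"code matrix {codes.codes.shape} (border of 3 px excluded), "
      f"codes span 0..{codes.codes.max()}")
top = np.argsort(hist.normalized)[::-1][:5]
print("five most frequent riu2 codes (code: share):")
for c in top:
    print(f"  {c:2d}: {hist.normalized[c]:.3f}")
print(f"LBP mean {stats.mean:.2f}, SD {stats.sd:.2f}, "
      f"skewness {stats.skewness:.2f}, entropy {stats.entropy:.3f}")
print("The LBP mean/entropy pair is what separates SCD from control "
      "cytoplasm texture downstream.")
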