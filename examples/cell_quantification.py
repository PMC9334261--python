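"""Devices per cell from flow cytometry via bead calibration.

Five bead populations with defined fluorophore counts define a log-log
calibration line; a cell sample's mean fluorescence intensity (MFI) is then
converted to molecules per cell.  Synthetic data are generated with a true
count of 9,200 devices/cell.
"""

import numpy as np

from nanowinch import count_from_mfi, fit_bead_calibration, gen_bead_table

beads, cell_mfi, _ = gen_bead_table(cv=0.05, seed=2024, true_count=9200.0)
print(beads.to_string(index=False))

line = fit_bead_calibration(beads)
print(f"\nlog10(molecules) = {line.slope:.4f} x log10(MFI) + {line.intercept:.4f} "
      f"(r^2 = {line.r_squared:.5f})")

counts = [count_from_mfi(line, m) for m in cell_mfi]
print(f"replicate estimates: {[f'{c:.0f}' for c in counts]}")
print(f"mean: {np.mean(counts):.0f} devices/cell (true value 9200)")
print("\nAt 5% measurement noise the pipeline recovers the configured count to a")
print("few percent - the precision the calibration-bead approach is designed for.")
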