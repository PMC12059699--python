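"""Neurite disintegration index on synthetic beta-III-Tubulin fields.

Generates vehicle (intact) and "treated" fields in which 10% of neurite
pixels are elevated into bright bead-like swellings, calibrates the
cell-line threshold (mean + 3 SD of vehicle neurite intensity) and reports
the disintegrated/total area index per condition.
"""

import numpy as np

from neurotoxiscore import neurite as nr
from neurotoxiscore import synthetic as syn

dmso = syn.make_neurite_images(syn.NeuriteImageSpec(seed=1), 5)
treated = syn.make_neurite_images(
    syn.NeuriteImageSpec(seed=2, fragmentation_fraction=0.10), 5)

masks = [nr.segment_neurite_area(f.image) for f in dmso]
calib = nr.calibrate_threshold(
    [(f.image, m) for f, m in zip(dmso, masks)], cell_line="demo")
print(f"calibrated intensity threshold: {calib.threshold:.1f} "
      f"(mean {calib.mean_intensity:.1f} + 3 x SD {calib.sd_intensity:.1f})")

for label, fields in (("DMSO", dmso), ("treated (f=0.10)", treated)):
    idx = [nr.disintegration_index(
        f.image, nr.segment_neurite_area(f.image), calib).index
        for f in fields]
    print(f"{label:18s} mean index {np.mean(idx):.4f}")
# The vehicle index sits near zero; the treated index recovers the 10% of
# neurite area occupied by high-intensity (disintegrated) swellings.
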