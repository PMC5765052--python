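"""Trabecular microarchitecture on a parallel-plate lattice phantom.

Plates 0.1 mm thick repeating every 0.4 mm have exact analytic outcomes
BV/TV = 0.25, Tb.Th = 0.1 mm, Tb.N = 2.5 /mm.  The pipeline thresholds the
gray volume at level 40 and measures inside a VOI spanning whole periods.
"""

import numpy as np

from skelemorph import phantoms, segmentation, trabecular
from skelemorph.voxgrid import BinaryMask

data = phantoms.generate(phantoms.PhantomSpec("plate_lattice", spacing=0.01))
mask = segmentation.threshold_mask(data.volume, level=40)
lo, hi = data.aux["voi_slices"]
voi = np.zeros(mask.shape, dtype=bool)
voi[lo:hi] = True
voi = BinaryMask(voi, mask.spacing, mask.origin)

res = trabecular.analyze(mask, voi)
print(f"BV/TV : {res.bv_tv:.4f}   (bone volume fraction; truth {data.truth['bv_tv']})")
print(f"Tb.Th : {res.tb_th:.4f} mm (mean maximal-sphere thickness; truth {data.truth['tb_th_mm']})")
print(f"Tb.N  : {res.tb_n:.4f} /mm (plate-model trabecular number; truth {data.truth['tb_n_per_mm']})")
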