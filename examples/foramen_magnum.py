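"""Foramen magnum morphometry on an elliptical aperture phantom.

The aperture's rim is measured in 3D: circumference as the boundary-loop
length on the surface mesh, transverse/sagittal diameters as 3D extents,
and area via the ellipse formula 1/4 * pi * Dt * Ds.
"""

import numpy as np

from skelemorph import craniofacial, phantoms

mesh = phantoms.aperture_plate_mesh(semi_transverse=2.0, semi_sagittal=1.0)
loop = craniofacial.foramen_boundary(mesh)
res = craniofacial.foramen_metrics(loop, transverse_axis=(0, 1, 0), sagittal_axis=(0, 0, 1))

print(f"circumference : {res.circumference_mm:.4f} mm (Ramanujan perimeter: 9.6884 mm)")
print(f"D_t           : {res.d_t:.4f} mm")
print(f"D_s           : {res.d_s:.4f} mm")
print(f"area          : {res.area_mm2:.4f} mm^2 (true ellipse area 2*pi = {2*np.pi:.4f})")
print("A narrowed foramen magnum shows up as reduced circumference and area.")
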