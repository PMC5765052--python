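"""Brain volume from MRI-style slice segmentations and skull bone volume
from a thresholded CT-style shell.

The ellipsoidal brain (semi-axes 8, 6, 5 mm) has analytic volume
4/3*pi*abc ~= 1005.3 mm^3; the skull shell (outer R=5, inner r=4.8 mm)
has volume 4/3*pi*(R^3 - r^3) ~= 60.35 mm^3.
"""

from skelemorph import craniofacial, phantoms

brain = phantoms.generate(phantoms.PhantomSpec("ellipsoid", spacing=(0.5, 0.05, 0.05)))
brain_vol = craniofacial.brain_volume(
    brain.aux["slice_masks"],
    slice_thickness_mm=brain.aux["slice_thickness_mm"],
    in_plane_spacing_mm=brain.aux["in_plane_spacing_mm"],
)
print(f"brain volume : {brain_vol:.1f} mm^3 (truth {brain.truth['volume_mm3']:.1f})")

skull = phantoms.generate(phantoms.PhantomSpec("skull_shell_aperture", spacing=0.05))
skull_vol = craniofacial.skull_volume(skull.volume, level=40)
print(f"skull volume : {skull_vol:.2f} mm^3 (truth {skull.truth['volume_mm3']:.2f})")
print("Both are computed exactly as in scans: slice-wise areas times slice")
print("thickness for MRI, thresholded largest-component voxel counting for CT.")
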