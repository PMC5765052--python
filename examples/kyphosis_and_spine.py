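"""Spinal morphometry: kyphosis index, body length, pedicle and lumbar
canal lengths.

The kyphosis index KI = chord / max-perpendicular-deviation of the dorsal
profile; a semicircular spine has KI = 2 and a straighter spine a larger
KI, so more kyphosis = lower index.
"""

from skelemorph import phantoms, spine
from skelemorph.voxgrid import LandmarkSet

for sagitta in (2.0, 5.0, 10.0):
    d = phantoms.generate(
        phantoms.PhantomSpec("vertebral_column", spacing=0.5,
                             params=dict(chord=20.0, sagitta=sagitta))
    )
    ki = spine.kyphosis_index(d.aux["profile"])
    canal = spine.l4l6_curved_length(d.aux["canal_seeds"])
    print(f"sagitta {sagitta:5.1f} mm -> KI {ki:6.3f} (truth {d.truth['kyphosis_index']:.3f}), "
          f"canal length {canal:.3f} mm (truth {d.truth['arc_length_mm']:.3f})")

body = spine.body_length(LandmarkSet({"nasal_tip": [0.0, 0.0],
                                      "first_caudal_base": [85.0, 0.0]}))
ped = spine.pedicle_length(LandmarkSet({
    "left_apex": [0, 0, 0.0], "left_base": [0, 0, 1.0],
    "right_apex": [1, 0, 0.0], "right_base": [1, 0, 1.2],
}))
print(f"body length {body:.1f} mm; mean L5 pedicle length {ped:.2f} mm")
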