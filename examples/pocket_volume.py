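"""Voxel-rule binding-pocket volume near a positioned reference.

Measures the openness of a nucleotide-site-like pocket: the volume of all
voxels with below-mean density within 5 Å of reference atoms placed at a
domain surface of a synthetic transporter map.
"""

from cryolig import build_scene, make_toy_transporter, pocket_volume
from cryolig.structure import AtomRecord

model = make_toy_transporter(60.0, seed=3)
scene, truth = build_scene(model, noise_sd=0.05, seed=3, separation=60.0)

# a pseudo-nucleotide positioned at the inner face of the left domain
reference = [
    AtomRecord("N", 1, "", "ATP", "P", "P", (-22.0, 0.0, -28.0)),
    AtomRecord("N", 1, "", "ATP", "O1", "O", (-20.5, 1.0, -28.0)),
]

result = pocket_volume(scene, reference, radius=5.0)
print(f"pocket voxels : {result.voxel_count}")
print(f"pocket volume : {result.volume:.0f} Å³ "
      f"(radius {result.radius} Å, rule '{result.rule}')")
print()
print("Larger volumes mean a more open site: more low-density (solvent-")
print("accessible) space surrounds the positioned nucleotide.")
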