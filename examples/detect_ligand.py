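"""Detect unmodeled ligand density in a synthetic transporter map.

Builds a wide-open two-domain transporter scene with a rod-shaped ligand
in the central cavity (plus 5% noise), then runs the full detection
pipeline: equal-volume display threshold, model masking, blob search,
four-criteria screen, rigid fit and 180° end-swap comparison.
"""

from cryolig import build_scene, make_toy_ligand, make_toy_transporter
from cryolig.config import PipelineConfig
from cryolig.pipeline import run_detection

model = make_toy_transporter(separation=60.0, seed=1)
ligand = make_toy_ligand(seed=1)
scene, truth = build_scene(model, ligand=ligand, noise_sd=0.05, seed=1,
                           separation=60.0)

config = PipelineConfig(display_target_volume=truth.display_volume)
report = run_detection(scene, model, ligand, config)

print(f"display level                : {report['protein_display_level']:.4f}")
print(f"blobs after masking          : {report['n_blobs']}")
print(f"ligand-bearing verdict       : {report['ligand_bearing']}")
best = report["best_candidate"]
print(f"fit CC / end-swapped CC      : {best['cc']:.3f} / {best['cc_flipped']:.3f}")
print(f"serious clashes of the pose  : {best['clashes']['n_serious']}")
print()
print("The verdict is True because exactly one blob at the protein display")
print("level is rod-shaped, drug-sized, and accepts a clash-free rigid fit;")
print("the larger of the two CCs identifies which end of the rod the")
print("ligand's fin-bearing end occupies (ground truth in this scene).")
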