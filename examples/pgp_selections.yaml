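# Demonstration selections for murine P-glycoprotein (single chain A,
# ~1276 residues). Domain boundaries are a modeling choice: adjust the
# ranges to your own model before using them for center-of-mass
# separations or pocket references. These approximate values bracket the
# two nucleotide-binding domains.
selections:
  NBD1: [["A", 395, 627]]
  NBD2: [["A", 1040, 1271]]
prune_cutoff: 2.0
pocket_radius: 5.0
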