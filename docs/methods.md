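# Methods

This note documents the models, conventions and numerical choices behind
cryolig, what the synthetic scenes do and do not emulate, and the known
limitations.

## Grid and map conventions

A `DensityMap` is a scalar field on a regular orthogonal grid. The
physical coordinate of voxel `(i, j, k)` is `origin + (i, j, k) ⊙
voxel_size` — a voxel-corner convention, 0-based, with X as the first
array axis. Every module shares this single convention; there is no
half-voxel offset anywhere.

MRC2014 files in modes 0/1/2 are read (mode 2 written); axis order is
normalized to X-fastest on read, so permuted `MAPC/MAPR/MAPS` files give
identical arrays. The voxel size is cell length divided by grid sampling
per axis. The origin is taken from the ORIGIN header words when any is
nonzero, otherwise `nstart × voxel_size` — covering both dialects in
circulation. Only orthogonal cells are supported (universal for
single-particle maps); anything else is rejected with an explicit error.

## Thresholding

Thresholding is closed (`value ≥ level`), which makes the equal-volume
level an exact order statistic: the level enclosing target volume `V` is
the m-th largest voxel value with `m = round(V / v_voxel)`. Ties at the
level are all included, so the realized volume can exceed the target by
the tied voxels — a deterministic, documented bias. The SD-multiple rule
is `level = mean + k·SD` with population SD over the whole box.

Note that `mean + k·SD` levels are **box-dependent**: padding a sparse
map with more empty voxels lowers both mean and SD and therefore the
level. All comparisons in the pipeline that use such levels (the ligand
reference envelope, fit scoring regions) use a fixed, stated grid
construction so the quantity is well defined; the reference-envelope
volume is only comparable between ligands rendered with the same
parameters.

## Map simulation

Atoms are rendered as isotropic 3-D Gaussians whose FWHM equals the
stated resolution (`σ = R / (2√(2 ln 2))`), weighted by atomic number by
default ("electron-count"; uniform weighting available for toy fixtures).
Kernels are normalized and truncated at 4σ (< 0.01% mass loss), so the
map integral equals the total weight. This is a deliberate simplification
of electron scattering-factor sums: any fixed kernel convention rescales
densities and thresholds consistently, and the convention is recorded in
the parameter echo of every output. B-factor-dependent widths and solvent
models are out of scope.

## Blob detection and the four criteria

Model-accounted density is removed by setting voxels within a mask radius
(default 3.0 Å — an explicit, reproducible stand-in for what is usually a
visual judgement) of any model heavy atom to the map minimum. Connected
components at the display level use 26-connectivity by default with a
10-voxel minimum (suppresses noise specks). Shape metrics come from
density-weighted PCA of voxel-center coordinates; extents are `2√λ` per
principal axis, and the rod criterion is a single elongation threshold
(default 2.0) — the simplest faithful operationalization of "roughly
rod-shaped", exposed in the configuration. The volume criterion compares
the blob volume to the ligand's reference envelope (its own 5 Å simulated
map at that map's `mean + 7·SD` level) within a configurable band,
default 0.5–2.0×, with the raw ratio always reported alongside the flag.
The clash criterion is evaluated on the *pre-minimization* rigid fit:
rotamer adjustment of neighboring side chains is out of scope, so a
handful of near-cutoff contacts that side-chain minimization would
resolve will count here.

## Rigid fitting

The scoring region is the simulated (posed) ligand map's own
`mean + k·SD` envelope on the experimental grid (k default 7), and the
score is the Pearson correlation about the mean over that region (the
non-mean-subtracted overlap is also computed and reported; which one
drives the search is configurable). The search scans a deterministic
super-Fibonacci quaternion lattice (default 576 rotations ≈ 24° covering
radius) with the ligand centroid pinned to the blob centroid, then
refines the best five scan poses over all six rigid parameters with
Nelder–Mead (scaled initial simplex ≈ 9° / 0.7 Å per coordinate; the
refined pose never scores below the scanned one). Refining several basins
matters because the 180° end-swap of an elongated ligand is
near-degenerate and can win a coarse scan. The end-swap itself is a 180°
rotation about the ligand's second principal axis through its posed
centroid; both CCs are reported and the larger orientation is preferred,
mirroring how such fits are adjudicated in practice.

For quasi-axially-symmetric ligands the roll angle about the long axis is
weakly determined at 5 Å resolution (and exactly degenerate for a ligand
with C2 symmetry), so pose-recovery quality is judged by posed-coordinate
RMS and long-axis tilt, not by raw rotation angle.

## Geometry

Centers of mass use standard atomic masses (geometric weighting
available; identical for single-element selections). Domain selections
are user configuration — residue ranges per chain — because domain
boundaries are a modeling choice, not a map property. Pocket volume
counts voxels strictly below the whole-box mean within the radius
(default 5 Å) of the reference atoms; the spatial index is required to
agree exactly with the brute-force double loop, and that equivalence is
tested. Matched RMSD pairs atoms by (chain, residue number, insertion
code, atom name), Cα-only by default (one pair per modeled residue),
superposes with Kabsch/SVD and iteratively prunes pairs deviating more
than the cutoff (default 2.0 Å) until the retained set is stable;
`max_iter=1` gives the single-pass variant. The report carries both the
retained-set RMSD and the all-pair RMSD in the final frame.

## FSC

`FSC(s) = Re Σ F₁·conj(F₂) / √(Σ|F₁|² Σ|F₂|²)` over shells one
reciprocal-voxel wide, assigned by rounded integer radius, up to Nyquist.
No masking or sharpening is applied before the transform. Resolution is
the reciprocal of the linearly interpolated frequency of the first
downward crossing of the criterion (0.143 by default); a curve that never
crosses is flagged Nyquist-limited. Empty shells are omitted and listed.

## Synthetic scenes

The generator emulates the data situation the pipeline exists for — not
the physics of image formation. A scene is a Cα+pseudo-side-chain trace
of a two-domain transporter (two four-helix bundles at a stated
center-of-mass separation, joined by crossing strands into an
inward-facing V with a central cavity), rendered at 5 Å / 1.043 Å voxels,
plus, optionally: a 14-atom rocket-shaped ligand (12-atom shaft at 1.5 Å
spacing, two fins at one end) at a seeded random clash-free orientation
in the cavity; a low-amplitude torus mimicking a detergent micelle; and
white Gaussian voxel noise with SD a stated fraction (default 5%) of the
noiseless signal peak. Each residue carries a CB atom so the rendered
protein density is comparable to a real chain rather than a bare
backbone. The recommended display volume recorded in the truth is the
protein envelope volume at the level where a fully occupied ligand is
enveloped like its simulated reference — the construction that makes the
volume criterion a like-for-like comparison, playing the role the known
molecular volume plays for a real particle.

All randomness flows from one master seed via `numpy.random.SeedSequence`
spawning, so scenes are exactly reproducible from their truth records.
What the scenes do **not** contain: CTF effects, colored noise, alignment
error, masking artifacts, partial occupancy mixed within one map, or real
protein folds. Passing the ensemble tests therefore demonstrates that the
decision procedure is correct and well-calibrated under its stated
assumptions, not that those assumptions hold for any particular
experimental map.

Default ensemble: five classes at separations {60, 56, 60, 55, 53} Å with
the ligand only in the first (widest) class — the configuration in which
a ligand-associated wide-open class coexists with ligand-free classes.

## Problem sizes

The test suite and the acceptance script run on 32³–64³ random grids,
~500-atom toy models on ~90×50×90 Å scenes, 576-rotation fits, and ten
master seeds for the Monte-Carlo checks — sizes chosen so the full
verification completes in about a minute on one core while keeping every
statistical bound meaningful.

## Known limitations

- The Gaussian kernel is not a scattering-factor model; absolute density
  values are arbitrary and only level *rules* (volume- or SD-based) are
  meaningful.
- SD-based levels depend on the box construction (see Thresholding).
- The clash criterion ignores side-chain flexibility (no rotamer
  relaxation).
- FSC shell binning assumes near-cubic grids (shells by integer radius in
  units of the largest-axis frequency step).
- Cross-model RMSD requires matching author numbering; sequence-alignment
  based matching for cross-species comparisons is out of scope.
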