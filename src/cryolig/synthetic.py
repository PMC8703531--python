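"""Ground-truthed synthetic scenes: a toy two-domain transporter with an
optional rod-shaped ligand in its central cavity.

The generator emulates the situation the pipeline is built for: an
inward-facing ABC-transporter-like particle imaged at intermediate (4-6 Å)
resolution, where the two nucleotide-binding domains (NBDs) sit at a
variable separation, a hydrophobic drug may occupy the central cavity at
sub-stoichiometric occupancy, the map carries additive white noise, and a
detergent micelle may add a low-density annulus around the transmembrane
belt. The protein is a Cα-trace pseudo-structure (two pseudo-helical
bundles joined by crossing strands forming a V); every quantity the
pipeline measures — COM separation, blob volume and shape, pose recovery —
depends only on the coordinates and the rendered density, so a real fold
is unnecessary.

All randomness flows from one master seed through numpy SeedSequence
spawning, so every scene is exactly reproducible from its truth record.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import BoundsError, DomainError
from .grid import DensityMap
from .mapcore import enclosed_volume, sd_threshold, threshold_for_volume
from .simulate import SimulationParams, simulate_map, simulate_on_grid
from .structure import AtomRecord, LigandAtoms, ModelStructure
from .fitting import LigandPose, super_fibonacci_rotations

__all__ = [
    "SceneTruth",
    "make_toy_transporter",
    "make_toy_ligand",
    "build_scene",
    "make_ensemble",
    "NBD1_SELECTION",
    "NBD2_SELECTION",
]

# Geometry of the toy transporter (construction frame):
# NBD bundles centered at (±separation/2, 0, NBD_Z); cavity between the
# crossing TM strands around CAVITY_CENTER.
NBD_Z = -28.0
CAVITY_CENTER = np.array([0.0, 0.0, 12.0])

# Reference-domain selections for COM separation on toy models.
from .geometry import DomainSelection  # noqa: E402  (avoids cycle at top)

NBD1_SELECTION = DomainSelection("NBD1", (("A", 1, 10_000),))
NBD2_SELECTION = DomainSelection("NBD2", (("B", 1, 10_000),))


@dataclass
class SceneTruth:
    """Everything needed to regenerate and to grade a synthetic scene."""

    seed: int
    domain_separation: float | None  # Å (None when not generated from a separation)
    ligand_present: bool
    ligand_rotation: list | None  # 3x3 nested list
    ligand_translation: list | None  # Å
    occupancy: float
    noise_sd: float  # fraction of noiseless signal peak
    resolution: float  # Å (FWHM)
    voxel_size: float  # Å
    micelle: bool
    display_volume: float  # Å³ recommended protein display volume
    n_model_atoms: int = 0

    def pose(self) -> LigandPose | None:
        if not self.ligand_present:
            return None
        return LigandPose(np.array(self.ligand_rotation), np.array(self.ligand_translation))

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SceneTruth":
        return cls(**json.loads(text))


def _helix_trace(n_res: int, center: np.ndarray, rng) -> tuple[np.ndarray, np.ndarray]:
    """Ideal Cα helix (rise 1.5 Å, 100°/residue, radius 2.3 Å) plus jitter.

    Returns (CA, CB) coordinate arrays: each residue carries one pseudo
    side-chain atom displaced radially outward, so the rendered density of
    the trace approximates a real helix rather than a bare backbone.
    """
    i = np.arange(n_res)
    theta = np.radians(100.0) * i
    z = 1.5 * i
    radial = np.stack([np.cos(theta), np.sin(theta), np.zeros_like(theta)], axis=1)
    ca = 2.3 * radial + np.stack([np.zeros(n_res), np.zeros(n_res), z], axis=1)
    cb = ca + 1.7 * radial
    mid = ca.mean(axis=0)
    ca = ca - mid + center + rng.normal(0.0, 0.05, size=ca.shape)
    cb = cb - mid + center + rng.normal(0.0, 0.05, size=cb.shape)
    return ca, cb


def make_toy_transporter(
    separation: float = 60.0,
    n_helices_per_domain: int = 4,
    seed: int = 0,
) -> ModelStructure:
    """Cα-trace pseudo-transporter with the stated NBD-COM separation.

    Chain A / chain B are the two reference domains ("NBDs", pseudo-helical
    bundles); chains C and D are crossing strands forming the inward-facing
    V, leaving a central cavity around ``CAVITY_CENTER``. The COM distance
    of chains A and B equals ``separation`` to well within 0.5 Å (exact up
    to the 0.05 Å coordinate jitter). Deterministic per seed.
    """
    if separation <= 0:
        raise DomainError("separation must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    atoms: list[AtomRecord] = []

    n_res_helix = 24
    ring_radius = 6.0
    for chain, sign in (("A", -1.0), ("B", 1.0)):
        center = np.array([sign * separation / 2.0, 0.0, NBD_Z])
        res = 1
        ca_all, cb_all = [], []
        for h in range(n_helices_per_domain):
            ang = 2.0 * math.pi * h / n_helices_per_domain
            hc = center + np.array(
                [ring_radius * math.cos(ang), ring_radius * math.sin(ang), 0.0]
            )
            ca, cb = _helix_trace(n_res_helix, hc, rng)
            ca_all.append(ca)
            cb_all.append(cb)
        ca_pts = np.concatenate(ca_all)
        cb_pts = np.concatenate(cb_all)
        # recenter so the chain COM (all atoms, equal masses) sits exactly
        # at the domain center
        shift = center - np.concatenate([ca_pts, cb_pts]).mean(axis=0)
        ca_pts += shift
        cb_pts += shift
        for p, q in zip(ca_pts, cb_pts):
            atoms.append(AtomRecord(chain, res, "", "GLY", "CA", "C", tuple(p)))
            atoms.append(AtomRecord(chain, res, "", "GLY", "CB", "C", tuple(q)))
            res += 1

    # crossing TM strands: from the top of each NBD up and across the midline
    half = separation / 2.0
    for chain, x0 in (("C", -half), ("D", half)):
        top = np.array([x0, 0.0, NBD_Z + 20.0])
        apex = np.array([-np.sign(x0) * 10.0, 0.0, 32.0])
        for strand, dy in ((0, -3.0), (1, 3.0)):
            a = top + np.array([0.0, dy, 0.0])
            b = apex + np.array([0.0, dy, 0.0])
            n_res_strand = max(int(np.linalg.norm(b - a) / 3.8) + 1, 2)
            ts = np.linspace(0.0, 1.0, n_res_strand)
            res = 1 + strand * 1000
            perp = np.array([0.0, 0.0, 1.0])
            for t in ts:
                p = a + t * (b - a) + rng.normal(0.0, 0.05, size=3)
                q = p + 1.7 * perp + rng.normal(0.0, 0.05, size=3)
                atoms.append(AtomRecord(chain, res, "", "GLY", "CA", "C", tuple(p)))
                atoms.append(AtomRecord(chain, res, "", "GLY", "CB", "C", tuple(q)))
                res += 1
    return ModelStructure(atoms, name=f"toy_transporter_sep{separation:g}")


def make_toy_ligand(
    n_shaft_atoms: int = 12,
    n_fin_atoms: int = 2,
    seed: int = 0,
) -> LigandAtoms:
    """Rocket-shaped toy ligand: a linear shaft with fins at one end.

    The shaft runs along +z with 1.5 Å atom spacing; ``n_fin_atoms`` (0 or
    2) branch sideways at the z=0 end, breaking end-to-end symmetry the way
    a drug's bulky substituents do. At 5 Å rendering resolution the
    simulated blob of the default ligand has elongation >= 2.
    """
    if n_shaft_atoms < 3:
        raise DomainError("n_shaft_atoms must be >= 3")
    if n_fin_atoms not in (0, 2):
        raise DomainError("n_fin_atoms must be 0 or 2")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    pts = [np.array([0.0, 0.0, 1.5 * i]) for i in range(n_shaft_atoms)]
    if n_fin_atoms == 2:
        pts.append(np.array([1.6, 0.0, -1.0]))
        pts.append(np.array([-1.6, 0.0, -1.0]))
    atoms = []
    for i, p in enumerate(pts):
        q = p + rng.normal(0.0, 0.005, size=3)
        atoms.append(AtomRecord("L", 1, "", "LIG", f"C{i + 1}", "C", tuple(q)))
    return LigandAtoms(atoms, label="toy_rocket")


def _random_rotation(rng) -> np.ndarray:
    """Uniform random rotation from a seeded generator (quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    x, y, z, w = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def build_scene(
    model: ModelStructure,
    ligand: LigandAtoms | None = None,
    pose: LigandPose | None = None,
    params: SimulationParams = SimulationParams(),
    noise_sd: float = 0.05,
    micelle: bool = False,
    occupancy: float = 1.0,
    seed: int = 0,
    separation: float | None = None,
) -> tuple[DensityMap, SceneTruth]:
    """Render a complete synthetic scene and its ground-truth record.

    map = simulate(model) + occupancy·simulate(posed ligand)
        [+ micelle annulus] + white noise of SD = noise_sd × signal peak.

    When a ligand is given without a pose, a seeded random orientation is
    placed at the cavity center. The truth records the pose, occupancy,
    noise level and the recommended protein display volume (the volume the
    noiseless protein envelope encloses at its own mean + 2·SD level).
    """
    ss = np.random.SeedSequence([seed, 303])
    rng_pose, rng_noise = (np.random.default_rng(s) for s in ss.spawn(2))

    coords = model.coords()
    lo = coords.min(axis=0) - params.padding
    hi = coords.max(axis=0) + params.padding
    dims = np.ceil((hi - lo) / params.voxel_size).astype(int) + 1
    template = DensityMap(np.zeros(tuple(dims)), (params.voxel_size,) * 3, tuple(lo))

    protein = simulate_on_grid(model, template, params)
    signal = protein.values.copy()

    truth_pose: LigandPose | None = None
    if ligand is not None:
        if pose is None:
            pose = _random_cavity_pose(ligand, model, rng_pose)
        posed = pose.apply(ligand.coords)
        if np.any(posed < lo) or np.any(posed > hi):
            raise BoundsError("ligand pose falls outside the scene box")
        lig_map = simulate_on_grid(ligand.transformed(pose.rotation, pose.translation),
                                   template, params)
        signal += occupancy * lig_map.values
        truth_pose = pose

    if micelle:
        signal += _micelle_annulus(template, amplitude=0.1 * signal.max())

    peak = float(signal.max())
    display_volume = _display_volume(
        DensityMap(protein.values, template.voxel_size, template.origin), params
    )
    values = signal + rng_noise.normal(0.0, noise_sd * peak, size=signal.shape)
    dmap = DensityMap(values, template.voxel_size, template.origin, name="scene")

    truth = SceneTruth(
        seed=seed,
        domain_separation=float(separation) if separation is not None else None,
        ligand_present=ligand is not None,
        ligand_rotation=truth_pose.rotation.tolist() if truth_pose else None,
        ligand_translation=truth_pose.translation.tolist() if truth_pose else None,
        occupancy=occupancy if ligand is not None else 0.0,
        noise_sd=noise_sd,
        resolution=params.resolution,
        voxel_size=params.voxel_size,
        micelle=micelle,
        display_volume=display_volume,
        n_model_atoms=len(model),
    )
    return dmap, truth


def _random_cavity_pose(
    ligand: LigandAtoms,
    model: ModelStructure,
    rng,
    clearance: float = 5.0,
    max_tries: int = 200,
) -> LigandPose:
    """Seeded random orientation at the cavity center, clash-free.

    Orientations that bring any ligand atom within ``clearance`` Å of a
    model atom are rejected and redrawn (a bound ligand cannot interpenetrate
    the protein); the sampling is deterministic given the generator state.
    """
    from scipy.spatial import cKDTree

    tree = cKDTree(model.coords())
    last = None
    for _ in range(max_tries):
        R = _random_rotation(rng)
        t = CAVITY_CENTER - R @ ligand.centroid
        pose = LigandPose(R, t)
        d, _i = tree.query(pose.apply(ligand.coords), k=1)
        last = pose
        if d.min() >= clearance:
            return pose
    return last  # pragma: no cover - cavity large enough in practice


def _display_volume(protein_map: DensityMap, params: SimulationParams) -> float:
    """Recommended display volume for a scene.

    Plays the role the known molecular volume plays for a real particle: it
    pins the display threshold to a meaningful contour independent of the
    noise realization. The contour is chosen so that a fully occupied
    ligand in the scene is enveloped the same way as its simulated
    reference map (at the reference map's own mean + 7·SD level) — the
    construction under which the candidate-ligand volume criterion is a
    like-for-like comparison.
    """
    ref = simulate_map(make_toy_ligand(seed=0), params)
    level = sd_threshold(ref, 7.0)
    return enclosed_volume(protein_map, level).enclosed_volume


def _micelle_annulus(template: DensityMap, amplitude: float,
                     center_z: float = 5.0, major_radius: float = 30.0,
                     minor_radius: float = 7.0) -> np.ndarray:
    """Soft torus of low density around the transmembrane belt."""
    centers = template.voxel_centers()
    x, y, z = centers[..., 0], centers[..., 1], centers[..., 2]
    rho = np.sqrt(x * x + y * y)
    d2 = (rho - major_radius) ** 2 + (z - center_z) ** 2
    return amplitude * np.exp(-d2 / (2.0 * (minor_radius / 2.0) ** 2))


def make_ensemble(
    separations=(60.0, 56.0, 60.0, 55.0, 53.0),
    ligand_in=(True, False, False, False, False),
    params: SimulationParams = SimulationParams(),
    noise_sd: float = 0.05,
    micelle: bool = False,
    seed: int = 0,
    outdir: str | Path | None = None,
):
    """Generate the default five-class ensemble (ligand only in class 1).

    Mirrors a 3D-classification outcome where the ligand-bearing class is
    the widest-open one: separations {60, 56, 60, 55, 53} Å with the
    ligand present only in the first class. Returns a list of
    (class label, ModelStructure, DensityMap, SceneTruth); when ``outdir``
    is given, also writes map (MRC2014), model (PDB), truth (JSON) per
    class plus a manifest TSV.
    """
    if len(separations) != len(ligand_in):
        raise DomainError("separations and ligand_in must have equal length")
    ss = np.random.SeedSequence([seed, 404])
    class_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(len(separations))]

    ligand = make_toy_ligand(seed=seed)
    out = []
    labels = [chr(ord("a") + i) for i in range(len(separations))]
    for label, sep, has_lig, cseed in zip(labels, separations, ligand_in, class_seeds):
        model = make_toy_transporter(separation=sep, seed=cseed)
        dmap, truth = build_scene(
            model,
            ligand=ligand if has_lig else None,
            params=params,
            noise_sd=noise_sd,
            micelle=micelle,
            seed=cseed,
            separation=sep,
        )
        dmap.name = f"class_{label}"
        out.append((label, model, dmap, truth))

    if outdir is not None:
        from .io import write_density_map
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rows = ["label\tmap\tmodel\ttruth\tseparation_A\tligand_present"]
        for label, model, dmap, truth in out:
            map_path = outdir / f"class_{label}.mrc"
            model_path = outdir / f"class_{label}.pdb"
            truth_path = outdir / f"class_{label}.truth.json"
            write_density_map(dmap, map_path)
            write_model_pdb(model, model_path)
            truth_path.write_text(truth.to_json() + "\n")
            rows.append(
                f"{label}\t{map_path.name}\t{model_path.name}\t{truth_path.name}"
                f"\t{truth.domain_separation:g}\t{int(truth.ligand_present)}"
            )
        (outdir / "manifest.tsv").write_text("\n".join(rows) + "\n")
    return out


def write_model_pdb(model: ModelStructure, path: str | Path) -> None:
    """Write a ModelStructure as minimal PDB ATOM records."""
    lines = []
    serial = 1
    for a in model.atoms:
        x, y, z = a.coord
        name = a.atom_name if len(a.atom_name) >= 4 else f" {a.atom_name:<3.3s}"
        lines.append(
            f"ATOM  {serial:5d} {name:<4.4s} {a.res_name:<3.3s} {a.chain:1.1s}"
            f"{a.res_number:4d}{a.icode:1.1s}   {x:8.3f}{y:8.3f}{z:8.3f}"
            f"{a.occupancy:6.2f}{0.0:6.2f}          {a.element:>2.2s}"
        )
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
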