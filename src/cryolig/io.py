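"""Reading and writing of the standard formats the pipeline touches.

Density maps are MRC2014 (.mrc/.map); modes 0/1/2 are read and mode 2
(32-bit float) is written. Atomic models come from PDB or mmCIF, ligands
from PDB or SDF V2000. Parsing is delegated to gemmi (maps and models)
and RDKit (SDF); this module normalizes everything into the cryolig
containers and enforces the conventions stated in :mod:`cryolig.grid`.
"""

from __future__ import annotations

import os
from pathlib import Path

import gemmi
import numpy as np

from .errors import (
    DegenerateLigandError,
    EmptyModelError,
    MapFormatError,
    UnsupportedFeatureError,
)
from .grid import DensityMap
from .structure import _ELEMENTS, AtomRecord, LigandAtoms, ModelStructure

__all__ = ["read_density_map", "write_density_map", "read_model", "read_ligand"]


# ---------------------------------------------------------------------------
# density maps

def read_density_map(path: str | os.PathLike) -> DensityMap:
    """Read an MRC/CCP4 map, normalizing axis order to X-fastest.

    voxel_size is cell length / grid sampling per axis. The origin is taken
    from the ORIGIN header words when any is nonzero, otherwise from
    nstart × voxel_size (the two dialects in circulation).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as e:
        raise MapFormatError(f"{path}: not a readable MRC/CCP4 file ({e})") from e

    mode = m.header_i32(4)
    if mode not in (0, 1, 2):
        raise MapFormatError(f"{path}: unsupported MODE field {mode} (need 0, 1 or 2)")
    mapc, mapr, maps_ = (m.header_i32(w) for w in (17, 18, 19))
    if sorted((mapc, mapr, maps_)) != [1, 2, 3]:
        raise MapFormatError(
            f"{path}: MAPC/MAPR/MAPS fields ({mapc},{mapr},{maps_}) are not a "
            "permutation of 1,2,3"
        )
    cell = m.grid.unit_cell
    if not (
        abs(cell.alpha - 90) < 1e-3 and abs(cell.beta - 90) < 1e-3
        and abs(cell.gamma - 90) < 1e-3
    ):
        raise UnsupportedFeatureError(
            f"{path}: non-orthogonal cell (alpha,beta,gamma = "
            f"{cell.alpha},{cell.beta},{cell.gamma}); only 90,90,90 supported"
        )

    # read origin words before setup (setup may rearrange nstart)
    origin_words = tuple(m.header_float(w) for w in (50, 51, 52))
    nstart_xyz = _nstart_xyz(m, mapc, mapr, maps_)

    m.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    values = np.array(m.grid, copy=True).astype(np.float64)
    mx, my, mz = (m.header_i32(w) for w in (8, 9, 10))
    for name, v in (("MX", mx), ("MY", my), ("MZ", mz)):
        if v < 1:
            raise MapFormatError(f"{path}: {name} field must be >= 1, got {v}")
    voxel = (cell.a / mx, cell.b / my, cell.c / mz)
    if any(v <= 0 for v in voxel):
        raise MapFormatError(f"{path}: CELLA field gives non-positive voxel size {voxel}")

    if any(abs(o) > 1e-9 for o in origin_words):
        origin = origin_words
    else:
        origin = tuple(n * v for n, v in zip(nstart_xyz, voxel))
    if not np.all(np.isfinite(values)):
        raise MapFormatError(f"{path}: data block contains non-finite values")
    return DensityMap(values, voxel, origin, name=path.stem)


def _nstart_xyz(m: gemmi.Ccp4Map, mapc: int, mapr: int, maps_: int) -> tuple[int, int, int]:
    """NXSTART/NYSTART/NZSTART reordered from file axes to x,y,z."""
    ns_file = [m.header_i32(w) for w in (5, 6, 7)]
    out = [0, 0, 0]
    for file_axis, xyz_axis in enumerate((mapc, mapr, maps_)):
        out[xyz_axis - 1] = ns_file[file_axis]
    return tuple(out)  # type: ignore[return-value]


def write_density_map(dmap: DensityMap, path: str | os.PathLike) -> None:
    """Write a map as MRC2014 mode 2 with recomputed header statistics."""
    path = Path(path)
    nx, ny, nz = dmap.dims
    grid = gemmi.FloatGrid(nx, ny, nz)
    vx, vy, vz = dmap.voxel_size
    grid.set_unit_cell(gemmi.UnitCell(nx * vx, ny * vy, nz * vz, 90, 90, 90))
    grid.spacegroup = gemmi.SpaceGroup("P1")
    np.array(grid, copy=False)[...] = dmap.values.astype(np.float32)
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()  # recomputes min/max/mean, sets mode 2
    for w, o in zip((50, 51, 52), dmap.origin):
        m.set_header_float(w, float(o))
    try:
        m.write_ccp4_map(str(path))
    except (RuntimeError, OSError) as e:
        raise IOError(f"cannot write map to {path}: {e}") from e


# ---------------------------------------------------------------------------
# atomic models

def read_model(path: str | os.PathLike) -> ModelStructure:
    """Read a PDB or mmCIF model into a ModelStructure.

    Only the first model of multi-model files is used. Alternate locations
    are resolved to the highest-occupancy conformer (ties: alphabetically
    first altloc id). Waters are retained but flagged. Unknown element
    symbols are inferred from the atom name.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as e:
        raise EmptyModelError(f"{path}: cannot parse structure ({e})") from e
    st.setup_entities()
    if len(st) == 0:
        raise EmptyModelError(f"{path}: no models in file")

    records: list[AtomRecord] = []
    model = st[0]
    for chain in model:
        for residue in chain:
            best: dict[str, gemmi.Atom] = {}
            for atom in residue:
                prev = best.get(atom.name)
                if prev is None:
                    best[atom.name] = atom
                elif (atom.occ, _altloc_rank(atom)) > (prev.occ, _altloc_rank(prev)):
                    # higher occupancy wins; on ties the alphabetically
                    # earlier altloc (ranked higher) is kept
                    best[atom.name] = atom
            for atom in best.values():
                elem = atom.element.name
                if elem in ("X", "") or elem not in _ELEMENTS:
                    elem = _element_from_atom_name(atom.name)
                records.append(
                    AtomRecord(
                        chain=chain.name,
                        res_number=residue.seqid.num,
                        icode=(residue.seqid.icode or "").strip(),
                        res_name=residue.name,
                        atom_name=atom.name,
                        element=elem,
                        coord=(atom.pos.x, atom.pos.y, atom.pos.z),
                        occupancy=min(max(atom.occ, 0.0), 1.0),
                        is_water=residue.is_water(),
                    )
                )
    if not records:
        raise EmptyModelError(f"{path}: no atoms parsed")
    return ModelStructure(records, name=path.stem)


def _altloc_rank(atom: gemmi.Atom) -> int:
    """Higher rank = preferred on occupancy ties (alphabetically earlier)."""
    alt = atom.altloc or "\x7f"
    return -ord(alt[0])


def _element_from_atom_name(name: str) -> str:
    stripped = "".join(c for c in name if c.isalpha())
    for cand in (stripped[:2].capitalize(), stripped[:1].upper()):
        if cand in _ELEMENTS:
            return cand
    return "C"


# ---------------------------------------------------------------------------
# ligands

def read_ligand(
    path: str | os.PathLike,
    include_hydrogens: bool = False,
    label: str | None = None,
) -> LigandAtoms:
    """Read ligand coordinates from a PDB or SDF (V2000) file.

    Heavy atoms only by default; pass ``include_hydrogens=True`` to keep H.
    """
    path = Path(path)
    if path.suffix.lower() in (".sdf", ".mol"):
        atoms = _read_sdf_atoms(path)
    else:
        model = read_model(path)
        atoms = model.atoms
    if not include_hydrogens:
        atoms = [a for a in atoms if a.element != "H"]
    if len(atoms) < 2:
        raise DegenerateLigandError(
            f"{path}: fewer than 2 heavy atoms ({len(atoms)})"
        )
    return LigandAtoms(atoms, label=label or path.stem)


def _read_sdf_atoms(path: Path) -> list[AtomRecord]:
    from rdkit import Chem  # optional dependency, only needed for SDF input

    mol = Chem.MolFromMolFile(str(path), removeHs=False, sanitize=False)
    if mol is None:
        raise DegenerateLigandError(f"{path}: RDKit could not parse SDF")
    conf = mol.GetConformer()
    records = []
    for i, atom in enumerate(mol.GetAtoms()):
        pos = conf.GetAtomPosition(i)
        records.append(
            AtomRecord(
                chain="L",
                res_number=1,
                icode="",
                res_name="LIG",
                atom_name=f"{atom.GetSymbol()}{i + 1}",
                element=atom.GetSymbol().capitalize(),
                coord=(pos.x, pos.y, pos.z),
            )
        )
    return records


def write_ligand_pdb(ligand: LigandAtoms, path: str | os.PathLike) -> None:
    """Write ligand atoms as PDB HETATM records (pose export)."""
    lines = []
    for i, a in enumerate(ligand.atoms, start=1):
        x, y, z = a.coord
        lines.append(
            f"HETATM{i:5d} {a.atom_name:<4.4s}{a.res_name:>4.4s} {a.chain:1.1s}"
            f"{a.res_number:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}"
            f"{0.0:6.2f}          {a.element:>2.2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
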