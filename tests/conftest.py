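"""Shared fixtures: raw MRC writing (header-level control), an ivacaftor
conformer built from its SMILES, and small deterministic random maps."""

from __future__ import annotations

import struct

import numpy as np
import pytest

from cryolig import DensityMap, LigandAtoms
from cryolig.structure import AtomRecord

IVACAFTOR_SMILES = "CC(C)(C)c1cc(c(cc1NC(=O)c1c[nH]c2ccccc2c1=O)O)C(C)(C)C"


def write_mrc_raw(
    path,
    data_xyz: np.ndarray,
    voxel: float = 1.5,
    mapc: int = 1,
    mapr: int = 2,
    maps: int = 3,
    origin=(0.0, 0.0, 0.0),
    nstart=(0, 0, 0),
    angles=(90.0, 90.0, 90.0),
    mode: int = 2,
) -> None:
    """Minimal MRC2014 writer with full header control (test oracle only)."""
    axmap = [mapc - 1, mapr - 1, maps - 1]  # file col/row/sec -> xyz axis
    n_file = [data_xyz.shape[a] for a in axmap]
    arr = np.transpose(data_xyz, (axmap[2], axmap[1], axmap[0]))
    h = bytearray(1024)
    struct.pack_into("<3i", h, 0, *n_file)
    struct.pack_into("<i", h, 12, mode)
    struct.pack_into("<3i", h, 16, *nstart)
    struct.pack_into("<3i", h, 28, *data_xyz.shape)
    struct.pack_into("<3f", h, 40, *(n * voxel for n in data_xyz.shape))
    struct.pack_into("<3f", h, 52, *angles)
    struct.pack_into("<3i", h, 64, mapc, mapr, maps)
    struct.pack_into(
        "<3f", h, 76, float(data_xyz.min()), float(data_xyz.max()), float(data_xyz.mean())
    )
    struct.pack_into("<i", h, 88, 1)
    struct.pack_into("<3f", h, 196, *origin)
    h[208:212] = b"MAP "
    h[212:216] = bytes([0x44, 0x44, 0, 0])
    with open(path, "wb") as fh:
        fh.write(h)
        if mode == 2:
            fh.write(arr.astype("<f4").tobytes())
        elif mode == 1:
            fh.write(arr.astype("<i2").tobytes())
        elif mode == 0:
            fh.write(arr.astype("<i1").tobytes())
        else:
            raise ValueError(mode)


@pytest.fixture
def random_map():
    def make(seed: int = 0, dims=(16, 16, 16), voxel=1.0, origin=(0.0, 0.0, 0.0)):
        rng = np.random.default_rng(seed)
        return DensityMap(rng.normal(size=dims), (voxel,) * 3, origin)

    return make


def build_ivacaftor() -> LigandAtoms:
    """29-heavy-atom ivacaftor conformer embedded from SMILES (seeded)."""
    from rdkit import Chem
    from rdkit.Chem import AllChem

    mol = Chem.MolFromSmiles(IVACAFTOR_SMILES)
    AllChem.EmbedMolecule(mol, randomSeed=7)
    conf = mol.GetConformer()
    atoms = [
        AtomRecord(
            "L", 1, "", "IVA", f"{a.GetSymbol()}{i + 1}", a.GetSymbol(),
            tuple(conf.GetAtomPosition(i)),
        )
        for i, a in enumerate(mol.GetAtoms())
    ]
    return LigandAtoms(atoms, label="ivacaftor")


@pytest.fixture(scope="session")
def ivacaftor() -> LigandAtoms:
    return build_ivacaftor()
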