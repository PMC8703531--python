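"""Atomic-model containers: atoms, models, ligands.

These are deliberately thin, array-friendly records: the heavy lifting on
coordinates happens in numpy, while parsing of PDB/mmCIF/SDF lives in
:mod:`cryolig.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

from .errors import DegenerateLigandError, DomainError, SelectionError

__all__ = ["AtomRecord", "ModelStructure", "LigandAtoms"]

# Periodic-table whitelist (symbols as gemmi normalizes them).
_ELEMENTS = frozenset(
    gemmi.Element(z).name for z in range(1, 119) if gemmi.Element(z).name != "X"
)


def atomic_mass(element: str) -> float:
    """Standard atomic mass (u) of an element symbol."""
    return float(gemmi.Element(element).weight)


def atomic_number(element: str) -> int:
    return int(gemmi.Element(element).atomic_number)


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity plus Cartesian coordinates in Å."""

    chain: str
    res_number: int
    icode: str
    res_name: str
    atom_name: str
    element: str
    coord: tuple[float, float, float]
    occupancy: float = 1.0
    is_water: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.occupancy <= 1.0):
            raise DomainError(f"occupancy must be in [0, 1], got {self.occupancy}")
        if self.element not in _ELEMENTS:
            raise DomainError(f"unrecognized element symbol {self.element!r}")
        if not np.all(np.isfinite(self.coord)):
            raise DomainError("atom coordinates must be finite")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Identity used for matching atoms across models."""
        return (self.chain, self.res_number, self.icode, self.atom_name)


class ModelStructure:
    """A parsed atomic model: a flat atom list plus a chain/residue index."""

    def __init__(self, atoms: list[AtomRecord], name: str = ""):
        if len(atoms) == 0:
            raise DomainError("a ModelStructure needs at least one atom")
        seen: set[tuple[str, int, str, str]] = set()
        for a in atoms:
            if a.key in seen:
                raise DomainError(f"duplicate atom identity {a.key}")
            seen.add(a.key)
        self.atoms = list(atoms)
        self.name = name

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self, heavy_only: bool = False, exclude_water: bool = False) -> np.ndarray:
        sel = self.select(heavy_only=heavy_only, exclude_water=exclude_water)
        return np.array([a.coord for a in sel], dtype=float)

    def select(
        self,
        chain: str | None = None,
        res_range: tuple[int, int] | None = None,
        atom_name: str | None = None,
        heavy_only: bool = False,
        exclude_water: bool = False,
    ) -> list[AtomRecord]:
        out = []
        for a in self.atoms:
            if chain is not None and a.chain != chain:
                continue
            if res_range is not None and not (res_range[0] <= a.res_number <= res_range[1]):
                continue
            if atom_name is not None and a.atom_name != atom_name:
                continue
            if heavy_only and a.element == "H":
                continue
            if exclude_water and a.is_water:
                continue
            out.append(a)
        return out

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain, None)
        return list(seen)

    def atom_index(self) -> dict[tuple[str, int, str, str], AtomRecord]:
        return {a.key: a for a in self.atoms}


class LigandAtoms:
    """Ligand coordinates (heavy atoms by default) for simulation and fitting."""

    def __init__(self, atoms: list[AtomRecord], label: str = "ligand"):
        if len(atoms) < 2:
            raise DegenerateLigandError(
                f"a ligand needs at least 2 atoms, got {len(atoms)}"
            )
        coords = np.array([a.coord for a in atoms])
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() < 1e-9:
            raise DomainError("ligand contains duplicate coordinates")
        self.atoms = list(atoms)
        self.label = label

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    def principal_axes(self) -> np.ndarray:
        """Rows = principal axes of the atom cloud, by descending variance.

        Deterministic sign convention: each axis is flipped so that its
        largest-magnitude component is positive; handedness is then restored
        by flipping the last axis if needed.
        """
        c = self.coords - self.centroid
        cov = c.T @ c / len(self.atoms)
        w, v = np.linalg.eigh(cov)
        axes = v[:, ::-1].T  # descending eigenvalue order
        for i in range(3):
            j = int(np.argmax(np.abs(axes[i])))
            if axes[i, j] < 0:
                axes[i] = -axes[i]
        if np.linalg.det(axes) < 0:
            axes[2] = -axes[2]
        return axes

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "LigandAtoms":
        """Return a copy with coordinates mapped through x -> R x + t."""
        new_coords = (np.asarray(rotation) @ self.coords.T).T + np.asarray(translation)
        atoms = [
            AtomRecord(
                a.chain, a.res_number, a.icode, a.res_name, a.atom_name,
                a.element, tuple(c), a.occupancy, a.is_water,
            )
            for a, c in zip(self.atoms, new_coords)
        ]
        return LigandAtoms(atoms, self.label)
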