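"""Conformational geometry: domain separations, pocket volumes, pruned RMSD.

These are the quantities used to compare conformational classes of a
two-domain transporter: the distance between the centers of mass of the
two nucleotide-binding domains (NBDs), the openness of a nucleotide site
measured as the volume of low-density voxels near a positioned nucleotide,
and the matched-Cα RMSD between two models with iterative outlier pruning
(reported in the "X Å over N pairs within cutoff, Y Å overall M pairs"
convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import DomainError, SelectionError
from .grid import DensityMap
from .mapcore import map_stats
from .structure import AtomRecord, LigandAtoms, ModelStructure, atomic_mass

__all__ = [
    "DomainSelection",
    "PocketVolumeResult",
    "RmsdReport",
    "center_of_mass",
    "domain_separation",
    "pocket_volume",
    "matched_rmsd",
    "kabsch",
]


@dataclass(frozen=True)
class DomainSelection:
    """A labelled set of inclusive (chain, first residue, last residue) ranges."""

    label: str
    ranges: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        if not self.ranges:
            raise DomainError(f"selection {self.label!r} has no ranges")
        for chain, start, end in self.ranges:
            if start > end:
                raise DomainError(
                    f"selection {self.label!r}: range {chain}:{start}-{end} inverted"
                )

    def atoms(self, model: ModelStructure) -> list[AtomRecord]:
        out = []
        for chain, start, end in self.ranges:
            out.extend(model.select(chain=chain, res_range=(start, end)))
        return out


@dataclass(frozen=True)
class PocketVolumeResult:
    volume: float  # Å³
    voxel_count: int
    radius: float  # Å
    rule: str  # density rule applied


@dataclass(frozen=True)
class RmsdReport:
    """Matched-atom RMSD with iterative superpose-and-prune.

    rmsd_retained / n_retained describe the final retained pair set;
    rmsd_all / n_matched describe all matched pairs evaluated in the final
    superposition frame ("X Å over N pairs within cutoff, Y Å overall M").
    """

    n_matched: int
    rmsd_all: float
    n_retained: int
    rmsd_retained: float
    prune_cutoff: float
    iterations: int
    pruning_failed: bool = False

    def summary(self) -> str:
        return (
            f"rmsd {self.rmsd_retained:.2f} Å over {self.n_retained} atom pairs "
            f"within {self.prune_cutoff:g} Å, {self.rmsd_all:.2f} Å overall "
            f"{self.n_matched} atom pairs"
        )


def center_of_mass(
    model: ModelStructure,
    selection: DomainSelection,
    weighting: str = "mass",
) -> np.ndarray:
    """Weighted mean coordinate of the selected atoms.

    ``mass`` uses standard atomic masses; ``geometric`` weights all atoms
    equally (the two coincide when all elements are identical).
    """
    if weighting not in ("mass", "geometric"):
        raise DomainError(f"unknown weighting {weighting!r}")
    atoms = selection.atoms(model)
    if not atoms:
        raise SelectionError(f"selection {selection.label!r} matched no atoms")
    coords = np.array([a.coord for a in atoms])
    if weighting == "mass":
        w = np.array([atomic_mass(a.element) for a in atoms])
    else:
        w = np.ones(len(atoms))
    return (coords * w[:, None]).sum(axis=0) / w.sum()


def domain_separation(
    model: ModelStructure,
    sel_a: DomainSelection,
    sel_b: DomainSelection,
    weighting: str = "mass",
) -> float:
    """Euclidean distance (Å) between two domains' centers of mass."""
    ca = center_of_mass(model, sel_a, weighting)
    cb = center_of_mass(model, sel_b, weighting)
    return float(np.linalg.norm(ca - cb))


def pocket_volume(
    dmap: DensityMap,
    ref_atoms,
    radius: float = 5.0,
    rule: str = "below-mean",
) -> PocketVolumeResult:
    """Volume of low-density voxels near reference (e.g. nucleotide) atoms.

    Counts voxels whose center lies within ``radius`` Å of any reference
    atom and whose value is strictly below the whole-box mean; volume is
    count × voxel volume. A proxy for the openness of a binding site.
    """
    if radius <= 0:
        raise DomainError("radius must be > 0")
    if rule != "below-mean":
        raise DomainError(f"unknown pocket rule {rule!r}")
    if isinstance(ref_atoms, LigandAtoms):
        coords = ref_atoms.coords
    elif isinstance(ref_atoms, np.ndarray):
        coords = np.atleast_2d(ref_atoms)
    else:
        coords = np.array([a.coord for a in ref_atoms], float)
    if coords.size == 0:
        raise SelectionError("pocket reference selection is empty")
    mean, _ = map_stats(dmap)
    centers = dmap.voxel_centers().reshape(-1, 3)
    tree = cKDTree(coords)
    d, _i = tree.query(centers, k=1, distance_upper_bound=radius)
    near = d <= radius
    low = dmap.values.ravel() < mean
    count = int(np.count_nonzero(near & low))
    return PocketVolumeResult(
        volume=count * dmap.voxel_volume,
        voxel_count=count,
        radius=radius,
        rule=rule,
    )


# ---------------------------------------------------------------------------
# superposition and pruned RMSD

def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation t minimizing |R Q + t - P|².

    Returns (R, t) such that Q is superposed onto P.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (Q - cq).T @ (P - cp)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cp - R @ cq
    return R, t


def matched_rmsd(
    model_a: ModelStructure,
    model_b: ModelStructure,
    atom_name: str = "CA",
    prune_cutoff: float = 2.0,
    max_iter: int = 20,
) -> RmsdReport:
    """Matched-atom RMSD of B onto A with iterative superpose-and-prune.

    Atoms are matched by (chain, residue number, insertion code, atom
    name), restricted to ``atom_name`` (Cα by default, i.e. one pair per
    modeled residue). Each iteration superposes B onto A over the retained
    pairs, then prunes pairs deviating by more than ``prune_cutoff``; the
    loop stops when the retained set is stable or after ``max_iter``
    rounds. ``max_iter=1`` gives the single-pass variant.
    """
    if prune_cutoff <= 0:
        raise DomainError("prune_cutoff must be > 0")
    index_b = {
        a.key: a for a in model_b.atoms if a.atom_name == atom_name and not a.is_water
    }
    pairs_a, pairs_b = [], []
    for a in model_a.atoms:
        if a.atom_name != atom_name or a.is_water:
            continue
        b = index_b.get(a.key)
        if b is not None:
            pairs_a.append(a.coord)
            pairs_b.append(b.coord)
    n_matched = len(pairs_a)
    if n_matched < 3:
        raise DomainError(f"need >= 3 matched atom pairs, got {n_matched}")
    P = np.array(pairs_a)
    Q = np.array(pairs_b)

    retained = np.ones(n_matched, dtype=bool)
    iterations = 0
    for _ in range(max_iter):
        iterations += 1
        R, t = kabsch(P[retained], Q[retained])
        dev = np.linalg.norm((R @ Q.T).T + t - P, axis=1)
        new_retained = dev <= prune_cutoff
        if new_retained.sum() < 3:
            # pruning collapsed: report the all-pair superposition
            R, t = kabsch(P, Q)
            dev = np.linalg.norm((R @ Q.T).T + t - P, axis=1)
            rmsd_all = float(np.sqrt((dev ** 2).mean()))
            return RmsdReport(
                n_matched=n_matched,
                rmsd_all=rmsd_all,
                n_retained=n_matched,
                rmsd_retained=rmsd_all,
                prune_cutoff=prune_cutoff,
                iterations=iterations,
                pruning_failed=True,
            )
        if np.array_equal(new_retained, retained):
            break
        retained = new_retained

    R, t = kabsch(P[retained], Q[retained])
    dev = np.linalg.norm((R @ Q.T).T + t - P, axis=1)
    rmsd_retained = float(np.sqrt((dev[retained] ** 2).mean()))
    rmsd_all = float(np.sqrt((dev ** 2).mean()))
    return RmsdReport(
        n_matched=n_matched,
        rmsd_all=rmsd_all,
        n_retained=int(retained.sum()),
        rmsd_retained=rmsd_retained,
        prune_cutoff=prune_cutoff,
        iterations=iterations,
    )
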