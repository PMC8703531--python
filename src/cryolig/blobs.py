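"""Unmodeled-density detection and candidate-ligand criteria.

Workflow: choose a protein display level (typically by enclosed volume),
zero out everything the refined model already accounts for (voxels within
a mask radius of any model heavy atom), find connected components of what
remains, and test each against four criteria for a bound drug:

(i)   visible at the protein display level (the blob exists at that level),
(ii)  roughly rod-shaped (elongation of the density-weighted PCA extents),
(iii) continuous volume comparable to the volume expected for the ligand
      at the working resolution,
(iv)  once a pose is fitted, no serious steric clashes with the model.

Criterion (iv) is marked not-evaluated until a fitted pose is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import DomainError
from .grid import DensityMap
from .mapcore import enclosed_volume, sd_threshold
from .simulate import SimulationParams, simulate_map
from .structure import LigandAtoms, ModelStructure

__all__ = [
    "Blob",
    "CriteriaReport",
    "mask_modeled_density",
    "find_blobs",
    "expected_ligand_volume",
    "evaluate_criteria",
]

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class Blob:
    """One connected component of above-level density."""

    voxel_indices: np.ndarray  # (n, 3) integer grid indices
    voxel_count: int
    volume: float  # Å³
    centroid: np.ndarray  # Å, density-weighted
    principal_extents: np.ndarray  # Å, descending (2*sqrt(eigenvalue))
    elongation: float  # first / second extent, >= 1
    max_density: float
    mean_density: float

    def to_dict(self) -> dict:
        return {
            "voxel_count": self.voxel_count,
            "volume_A3": self.volume,
            "centroid_A": [float(c) for c in self.centroid],
            "principal_extents_A": [float(e) for e in self.principal_extents],
            "elongation": self.elongation,
            "max_density": self.max_density,
            "mean_density": self.mean_density,
        }


@dataclass
class CriteriaReport:
    """Outcome of the four candidate-ligand criteria for one blob."""

    c1_visible_at_protein_level: bool
    c2_rod_shaped: bool
    c3_volume_match: bool
    c4_no_serious_clashes: Optional[bool]  # None = not evaluated (no pose yet)
    elongation: float
    rod_min_elongation: float
    volume_ratio: float  # blob volume / expected ligand volume
    volume_band: tuple[float, float]
    n_serious_clashes: Optional[int] = None

    @property
    def all_passed(self) -> bool:
        """True when every evaluated criterion passed (c4 must be evaluated)."""
        return bool(
            self.c1_visible_at_protein_level
            and self.c2_rod_shaped
            and self.c3_volume_match
            and self.c4_no_serious_clashes
        )

    @property
    def geometric_pass(self) -> bool:
        """Criteria (i)-(iii) — the pre-fitting screen."""
        return bool(
            self.c1_visible_at_protein_level
            and self.c2_rod_shaped
            and self.c3_volume_match
        )

    def to_dict(self) -> dict:
        return {
            "c1_visible_at_protein_level": self.c1_visible_at_protein_level,
            "c2_rod_shaped": self.c2_rod_shaped,
            "c3_volume_match": self.c3_volume_match,
            "c4_no_serious_clashes": (
                "not-evaluated" if self.c4_no_serious_clashes is None
                else self.c4_no_serious_clashes
            ),
            "elongation": self.elongation,
            "rod_min_elongation": self.rod_min_elongation,
            "volume_ratio": self.volume_ratio,
            "volume_band": list(self.volume_band),
            "n_serious_clashes": self.n_serious_clashes,
        }


def blobs_to_tsv(blobs: list["Blob"]) -> str:
    """Blob metrics as a TSV table (one row per blob, volume-sorted)."""
    rows = ["voxel_count\tvolume_A3\tcentroid_x\tcentroid_y\tcentroid_z"
            "\telongation\tmax_density\tmean_density"]
    for b in blobs:
        cx, cy, cz = b.centroid
        rows.append(
            f"{b.voxel_count}\t{b.volume:.2f}\t{cx:.2f}\t{cy:.2f}\t{cz:.2f}"
            f"\t{b.elongation:.3f}\t{b.max_density:.6g}\t{b.mean_density:.6g}"
        )
    return "\n".join(rows) + "\n"


def mask_modeled_density(
    dmap: DensityMap,
    model: ModelStructure,
    mask_radius: float = 3.0,
) -> tuple[DensityMap, int]:
    """Zero out (to the map minimum) density accounted for by the model.

    Voxels whose center lies within ``mask_radius`` Å of any model heavy
    atom are set to the map minimum. Returns the masked map and the number
    of voxels masked. Idempotent.
    """
    if mask_radius <= 0:
        raise DomainError("mask_radius must be > 0")
    coords = model.coords(heavy_only=True)
    if coords.size == 0:
        raise DomainError("model has no heavy atoms to mask around")
    out = dmap.copy()
    centers = out.voxel_centers().reshape(-1, 3)
    tree = cKDTree(coords)
    d, _ = tree.query(centers, k=1, distance_upper_bound=mask_radius)
    hit = np.isfinite(d)
    out.values.ravel()[hit] = float(dmap.values.min())
    return out, int(np.count_nonzero(hit))


def find_blobs(
    dmap: DensityMap,
    level: float,
    connectivity: int = 26,
    min_voxels: int = 10,
) -> list[Blob]:
    """Connected components of {value >= level}, sorted by volume descending.

    Components smaller than ``min_voxels`` are dropped. Shape metrics come
    from density-weighted PCA of the voxel-center coordinates; extents are
    2*sqrt(eigenvalue) per axis, in descending order.
    """
    if not np.isfinite(level):
        raise DomainError("level must be finite")
    if min_voxels < 1:
        raise DomainError("min_voxels must be >= 1")
    if connectivity not in _STRUCTURES:
        raise DomainError(f"connectivity must be one of 6, 18, 26, got {connectivity}")
    above = dmap.values >= level
    labels, n = ndimage.label(above, structure=_STRUCTURES[connectivity])
    blobs: list[Blob] = []
    for lab in range(1, n + 1):
        idx = np.argwhere(labels == lab)
        if len(idx) < min_voxels:
            continue
        vals = dmap.values[idx[:, 0], idx[:, 1], idx[:, 2]]
        coords = dmap.index_to_coord(idx)
        w = vals / vals.sum()
        centroid = (coords * w[:, None]).sum(axis=0)
        c = coords - centroid
        cov = (c * w[:, None]).T @ c
        eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        eigvals = np.clip(eigvals, 0.0, None)
        extents = 2.0 * np.sqrt(eigvals)
        elong = float(extents[0] / extents[1]) if extents[1] > 1e-12 else float("inf")
        blobs.append(
            Blob(
                voxel_indices=idx,
                voxel_count=len(idx),
                volume=len(idx) * dmap.voxel_volume,
                centroid=centroid,
                principal_extents=extents,
                elongation=max(elong, 1.0),
                max_density=float(vals.max()),
                mean_density=float(vals.mean()),
            )
        )
    blobs.sort(key=lambda b: (-b.volume, tuple(b.centroid)))
    return blobs


def expected_ligand_volume(
    ligand: LigandAtoms,
    params: SimulationParams = SimulationParams(),
    k: float = 7.0,
) -> float:
    """Reference envelope volume (Å³) expected for the ligand.

    The ligand is rendered at the working resolution and enveloped at its
    own mean + k·SD level (the display rule used for simulated ligand
    maps); the enclosed volume is the criterion-(iii) reference.
    """
    sim = simulate_map(ligand, params)
    level = sd_threshold(sim, k)
    return enclosed_volume(sim, level).enclosed_volume


def evaluate_criteria(
    blob: Blob,
    ligand: LigandAtoms,
    params: SimulationParams = SimulationParams(),
    k: float = 7.0,
    rod_min_elongation: float = 2.0,
    volume_band: tuple[float, float] = (0.5, 2.0),
    pose=None,
    model: ModelStructure | None = None,
    serious_clash_cutoff: float = 2.0,
    reference_volume: float | None = None,
) -> CriteriaReport:
    """Evaluate the four candidate-ligand criteria for one blob.

    The blob must come from ``find_blobs`` at the protein display level, so
    criterion (i) is structural (the blob exists). Criterion (iv) is only
    evaluated when both ``pose`` and ``model`` are supplied; otherwise it is
    reported as not-evaluated.
    """
    if reference_volume is None:
        reference_volume = expected_ligand_volume(ligand, params, k)
    ratio = blob.volume / reference_volume if reference_volume > 0 else float("inf")
    c4: Optional[bool] = None
    n_serious: Optional[int] = None
    if pose is not None and model is not None:
        from .fitting import clash_check

        report = clash_check(pose, ligand, model, serious_cutoff=serious_clash_cutoff)
        n_serious = report.n_serious
        c4 = report.n_serious == 0
    return CriteriaReport(
        c1_visible_at_protein_level=blob.voxel_count > 0,
        c2_rod_shaped=blob.elongation >= rod_min_elongation,
        c3_volume_match=volume_band[0] <= ratio <= volume_band[1],
        c4_no_serious_clashes=c4,
        elongation=blob.elongation,
        rod_min_elongation=rod_min_elongation,
        volume_ratio=ratio,
        volume_band=volume_band,
        n_serious_clashes=n_serious,
    )
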