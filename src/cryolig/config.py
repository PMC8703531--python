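"""Pipeline configuration: one validated record, echoed into every report.

Defaults follow the published workflow this pipeline generalizes: display
threshold chosen to enclose 153,000 Å³; ligands simulated at 5 Å
resolution and enveloped at their own mean + 7·SD level; pocket volumes
from below-mean voxels within 5 Å of a positioned nucleotide; RMSD
pruning at 2 Å.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import DomainError

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    display_target_volume: float = 153_000.0  # Å³
    sim_resolution: float = 5.0  # Å (FWHM)
    sim_voxel_size: float = 1.043  # Å
    sd_multiplier: float = 7.0
    mask_radius: float = 3.0  # Å
    connectivity: int = 26
    min_voxels: int = 10
    rod_min_elongation: float = 2.0
    volume_band: tuple[float, float] = (0.5, 2.0)
    n_rotations: int = 576
    local_refine: bool = True
    serious_clash_cutoff: float = 2.0  # Å
    contact_cutoff: float = 4.5  # Å
    pocket_radius: float = 5.0  # Å
    prune_cutoff: float = 2.0  # Å
    weighting: str = "electron-count"
    cc_about_mean: bool = True
    selections: dict = field(default_factory=dict)  # label -> [[chain, start, end], ...]
    seed: int = 0

    def __post_init__(self) -> None:
        self.volume_band = tuple(self.volume_band)  # type: ignore[assignment]
        checks = [
            (self.display_target_volume > 0, "display_target_volume must be > 0"),
            (self.sim_resolution > 0, "sim_resolution must be > 0"),
            (self.sim_voxel_size > 0, "sim_voxel_size must be > 0"),
            (self.mask_radius > 0, "mask_radius must be > 0"),
            (self.connectivity in (6, 18, 26), "connectivity must be 6, 18 or 26"),
            (self.min_voxels >= 1, "min_voxels must be >= 1"),
            (self.rod_min_elongation >= 1, "rod_min_elongation must be >= 1"),
            (len(self.volume_band) == 2 and 0 < self.volume_band[0] < self.volume_band[1],
             "volume_band must be (low, high) with 0 < low < high"),
            (self.n_rotations >= 1, "n_rotations must be >= 1"),
            (self.serious_clash_cutoff > 0, "serious_clash_cutoff must be > 0"),
            (self.contact_cutoff > 0, "contact_cutoff must be > 0"),
            (self.pocket_radius > 0, "pocket_radius must be > 0"),
            (self.prune_cutoff > 0, "prune_cutoff must be > 0"),
            (self.weighting in ("uniform", "electron-count"),
             "weighting must be 'uniform' or 'electron-count'"),
        ]
        for ok, msg in checks:
            if not ok:
                raise DomainError(msg)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise DomainError(f"{path}: config must be a YAML mapping")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise DomainError(f"{path}: unknown config keys {sorted(unknown)}")
        data.update(overrides)
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["volume_band"] = list(self.volume_band)
        return d

    def sim_params(self):
        from .simulate import SimulationParams

        return SimulationParams(
            resolution=self.sim_resolution,
            voxel_size=self.sim_voxel_size,
            weighting=self.weighting,
        )
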