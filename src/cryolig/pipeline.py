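"""End-to-end orchestration: detection and geometry runs with JSON reports.

``run_detection`` chains the full unmodeled-density workflow on one map +
model + ligand; ``run_geometry`` computes domain separations, pairwise
pruned RMSDs and pocket volumes across models/maps. Both return plain
dictionaries that serialize to JSON and echo the effective configuration,
so every number in a report is reproducible by calling the underlying
operation directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__ as _version
from .blobs import evaluate_criteria, expected_ligand_volume, find_blobs, mask_modeled_density
from .config import PipelineConfig
from .errors import CryoligError
from .fitting import LigandPose, clash_check, contact_residues, flip_compare, rigid_fit
from .geometry import DomainSelection, domain_separation, matched_rmsd, pocket_volume
from .grid import DensityMap
from .io import read_density_map, read_ligand, read_model
from .mapcore import threshold_for_volume
from .structure import LigandAtoms, ModelStructure

__all__ = ["run_detection", "run_geometry", "selections_from_config"]


def _load_map(src) -> DensityMap:
    return src if isinstance(src, DensityMap) else read_density_map(src)


def _load_model(src) -> ModelStructure:
    return src if isinstance(src, ModelStructure) else read_model(src)


def _load_ligand(src) -> LigandAtoms:
    return src if isinstance(src, LigandAtoms) else read_ligand(src)


def run_detection(map_src, model_src, ligand_src,
                  config: PipelineConfig = PipelineConfig()) -> dict:
    """Full unmodeled-density detection on one map.

    Stages: display threshold by enclosed volume → mask model-accounted
    density → blob search → four-criteria evaluation per blob → rigid fit,
    flip comparison, clash check and contact listing for the best
    geometric candidate. The better-scoring of the fitted pose and its
    180° end-swap is reported as the final pose (both CCs are reported).
    """
    dmap = _load_map(map_src)
    model = _load_model(model_src)
    ligand = _load_ligand(ligand_src)
    params = config.sim_params()

    thr = threshold_for_volume(dmap, config.display_target_volume)
    masked, n_masked = mask_modeled_density(dmap, model, config.mask_radius)
    blobs = find_blobs(masked, thr.level, config.connectivity, config.min_voxels)
    ref_volume = expected_ligand_volume(ligand, params, config.sd_multiplier)

    blob_reports = []
    candidates = []
    for blob in blobs:
        crit = evaluate_criteria(
            blob, ligand, params, config.sd_multiplier,
            config.rod_min_elongation, config.volume_band,
            reference_volume=ref_volume,
        )
        blob_reports.append({"blob": blob.to_dict(), "criteria": crit.to_dict()})
        if crit.geometric_pass:
            candidates.append((blob, crit))

    report: dict = {
        "map": dmap.name,
        "tool_version": _version,
        "protein_display_level": thr.level,
        "display_enclosed_volume_A3": thr.enclosed_volume,
        "n_masked_voxels": n_masked,
        "expected_ligand_volume_A3": ref_volume,
        "n_blobs": len(blobs),
        "blobs": blob_reports,
        "ligand_bearing": False,
        "best_candidate": None,
        "config": config.to_dict(),
    }

    if not candidates:
        return report

    blob, crit = candidates[0]  # blobs arrive volume-sorted
    pose = rigid_fit(
        ligand, dmap, blob, params, config.sd_multiplier,
        config.n_rotations, config.local_refine, config.cc_about_mean,
    )
    cc_pose, cc_flip = flip_compare(
        ligand, dmap, pose, params, config.sd_multiplier, config.cc_about_mean
    )
    flipped = cc_flip > cc_pose
    if flipped:
        from .fitting import apply_end_swap

        pose = apply_end_swap(ligand, pose)
        pose.cc = cc_flip
    clashes = clash_check(pose, ligand, model, config.serious_clash_cutoff)
    contacts = contact_residues(pose, ligand, model, config.contact_cutoff)
    final_crit = evaluate_criteria(
        blob, ligand, params, config.sd_multiplier,
        config.rod_min_elongation, config.volume_band,
        pose=pose, model=model,
        serious_clash_cutoff=config.serious_clash_cutoff,
        reference_volume=ref_volume,
    )
    report["ligand_bearing"] = bool(final_crit.all_passed)
    report["best_candidate"] = {
        "blob": blob.to_dict(),
        "criteria": final_crit.to_dict(),
        "pose": pose.to_dict(),
        "cc": max(cc_pose, cc_flip),
        "cc_flipped": min(cc_pose, cc_flip),
        "end_swap_applied": bool(flipped),
        "clashes": clashes.to_dict(),
        "contacts": [
            {"chain": c, "res_number": n, "res_name": r, "min_distance_A": d}
            for c, n, r, d in contacts
        ],
    }
    return report


def selections_from_config(config: PipelineConfig) -> dict[str, DomainSelection]:
    out = {}
    for label, ranges in config.selections.items():
        out[label] = DomainSelection(
            label, tuple((str(c), int(a), int(b)) for c, a, b in ranges)
        )
    return out


def run_geometry(model_srcs, map_srcs=(),
                 config: PipelineConfig = PipelineConfig(),
                 separation_pair: tuple[str, str] = ("NBD1", "NBD2"),
                 pocket_reference: str | None = None) -> dict:
    """Geometry report: separations per model, RMSD per model pair,
    pocket volume per map.

    ``separation_pair`` names two selections in the config; the pocket
    reference selection (when given) is taken from the first model and
    used against every map.
    """
    models = [_load_model(m) for m in model_srcs]
    maps = [_load_map(m) for m in map_srcs]
    sels = selections_from_config(config)

    report: dict = {"tool_version": _version, "config": config.to_dict(),
                    "models": [m.name for m in models]}

    a, b = separation_pair
    if a in sels and b in sels:
        report["separations_A"] = [
            domain_separation(m, sels[a], sels[b]) for m in models
        ]
    rmsd_entries = []
    for i in range(len(models)):
        for j in range(i + 1, len(models)):
            r = matched_rmsd(models[i], models[j],
                             prune_cutoff=config.prune_cutoff)
            rmsd_entries.append({
                "model_a": models[i].name, "model_b": models[j].name,
                "n_matched": r.n_matched, "rmsd_all_A": r.rmsd_all,
                "n_retained": r.n_retained, "rmsd_retained_A": r.rmsd_retained,
                "summary": r.summary(),
            })
    report["rmsd"] = rmsd_entries

    if pocket_reference is not None and maps:
        if pocket_reference not in sels:
            raise CryoligError(f"no selection named {pocket_reference!r} in config")
        ref_atoms = sels[pocket_reference].atoms(models[0])
        report["pocket_volumes"] = [
            {
                "map": m.name,
                **pocket_volume(m, ref_atoms, config.pocket_radius).__dict__,
            }
            for m in maps
        ]
    return report


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
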