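"""End-to-end report workflows over conformational ensembles and pose sets.

Two pipelines mirror the two halves of the analysis: the *conformation
report* (RMSF, helicity, inter-region contact time, circuit-topology census /
density / per-residue profile, clustering with representative selection) and
the *pose report* (region binding fractions, motif blockade, typed
interaction tallies).  Both are driven by a single TOML config, echo every
threshold into their output provenance, and are deterministic for a fixed
config and seed.
"""

from __future__ import annotations

import json
import tomllib
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .contacts import ContactCriteria, group_contact_fraction, residue_contacts
from .io import read_pdb, read_pose_set
from .interface import (
    InteractionWindows,
    motif_status,
    region_binding_fractions,
    type_interactions,
)
from .metrics import (
    gromos_cluster,
    helicity_profile,
    rmsf_profile,
    select_representatives,
)
from .sequence import RegionMap, load_region_map_toml
from .topology import (
    local_inverse_parallel_profile,
    topology_census,
    topology_density,
    sample_frames,
)

__all__ = [
    "load_config",
    "run_conformation_report",
    "run_pose_report",
    "write_report",
]


class StageError(RuntimeError):
    """An analysis stage failed; the message names the stage."""


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def _criteria_from(config: dict[str, Any]) -> ContactCriteria:
    cc = config.get("contacts", {})
    return ContactCriteria(
        cutoff=float(cc.get("cutoff", 4.5)),
        min_atom_pairs=int(cc.get("min_atom_pairs", 5)),
        neighbor_exclusion=int(cc.get("neighbor_exclusion", 3)),
        strict_per_side=bool(cc.get("strict_per_side", False)),
    )


def _round_floats(obj, ndigits: int = 6):
    """Stable rounding so report JSON is byte-identical across reruns."""
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist(), ndigits)
    return obj


def write_report(report: dict[str, Any], path: str | Path) -> None:
    payload = json.dumps(_round_floats(report), indent=2, sort_keys=True)
    Path(path).write_text(payload + "\n")


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage label
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def run_conformation_report(config: dict[str, Any] | str | Path) -> dict[str, Any]:
    """RMSF + helicity + inter-region contact time + CT + clustering, as one bundle."""
    if not isinstance(config, dict):
        config = load_config(config)
    inp = config["input"]
    paths = inp["pdb"] if isinstance(inp["pdb"], list) else [inp["pdb"]]
    chain = inp.get("chain")
    criteria = _criteria_from(config)
    ct_cfg = config.get("ct", {})
    clu_cfg = config.get("clustering", {})
    hel_cfg = config.get("helicity", {})
    seed = int(config.get("output", {}).get("seed", 0))

    ensembles = [read_pdb(p) for p in paths]
    for k, ens in enumerate(ensembles):
        ens.replicate_id = f"rep{k + 1}"

    report: dict[str, Any] = {
        "report": "conformation",
        "version": __version__,
        "provenance": {
            "inputs": [str(p) for p in paths],
            "n_replicates": len(ensembles),
            "frames_per_replicate": [e.n_frames for e in ensembles],
            "contact_criteria": {
                "cutoff_A": criteria.cutoff,
                "min_atom_pairs": criteria.min_atom_pairs,
                "neighbor_exclusion": criteria.neighbor_exclusion,
                "strict_per_side": criteria.strict_per_side,
            },
            "ct_sample_interval_ns": ct_cfg.get("sample_interval_ns"),
            "cluster_cutoff_nm": clu_cfg.get("cutoff_nm", 0.9),
            "cluster_coverage": clu_cfg.get("coverage", 0.5),
            "stable_helix_threshold": hel_cfg.get("stable_threshold", 0.30),
            "seed": seed,
        },
    }

    rmsf = _stage("rmsf")(rmsf_profile)(ensembles[0], chain_id=chain)
    report["rmsf"] = {
        "residues": rmsf.residues,
        "values_nm": rmsf.values_nm,
        "selection": rmsf.atom_selection,
    }

    try:
        hel = helicity_profile(
            ensembles, chain_id=chain,
            stable_threshold=float(hel_cfg.get("stable_threshold", 0.30)),
        )
        report["helicity"] = {
            "content_percent": hel.content_percent,
            "content_std": hel.content_std,
            "per_replicate_percent": hel.per_replicate_percent,
            "stable_residues": hel.stable_residues,
            "probability": hel.probability,
        }
    except ValueError as exc:
        # Cα-only scaffolds without helix geometry are a legal input for the
        # contact/CT stages; record why helicity is absent rather than abort.
        report["helicity"] = {"skipped": str(exc)}

    groups = config.get("groups", {})
    if "nr" in groups and "cr" in groups:
        lo_a, hi_a = groups["nr"]
        lo_b, hi_b = groups["cr"]
        mean, std, per_rep = _stage("group_contact_fraction")(group_contact_fraction)(
            ensembles,
            set(range(int(lo_a), int(hi_a) + 1)),
            set(range(int(lo_b), int(hi_b) + 1)),
            criteria, chain,
        )
        report["nr_cr_contact"] = {
            "fraction_mean": mean,
            "fraction_std": std,
            "per_replicate": per_rep,
            "nr": [int(lo_a), int(hi_a)],
            "cr": [int(lo_b), int(hi_b)],
        }

    interval = ct_cfg.get("sample_interval_ns")
    interval = float(interval) if interval is not None else None
    censuses = []
    for ens in ensembles:
        for k in sample_frames(ens, interval):
            cm = residue_contacts(ens.frames[k], criteria, chain, frame_index=k)
            c = topology_census(cm)
            censuses.append((c.n_S, c.n_P, c.n_X, c.n_contacts))
    arr = np.asarray(censuses, dtype=float)
    report["ct_census"] = {
        "per_frame": [list(map(int, row)) for row in censuses],
        "mean_S": arr[:, 0].mean(),
        "mean_P": arr[:, 1].mean(),
        "mean_X": arr[:, 2].mean(),
        "mean_contacts": arr[:, 3].mean(),
    }
    hist, s_edges, px_edges, pts = _stage("topology_density")(topology_density)(
        ensembles, criteria, interval, chain,
        bins=int(ct_cfg.get("density_bins", 10)),
    )
    report["ct_density"] = {
        "hist": hist,
        "s_edges": s_edges,
        "px_edges": px_edges,
        "total_mass": float(hist.sum()),
    }
    profile = _stage("ct_profile")(local_inverse_parallel_profile)(
        ensembles, criteria, interval, chain,
        aggregation=ct_cfg.get("aggregation", "sum"),
    )
    report["ct_profile"] = {
        "residues": profile.residues,
        "mean": profile.mean,
        "sem": profile.sem,
        "n_frames": profile.n_frames,
    }

    solution = _stage("clustering")(gromos_cluster)(
        ensembles[0], cutoff_nm=float(clu_cfg.get("cutoff_nm", 0.9)), chain_id=chain,
    )
    reps = select_representatives(solution, float(clu_cfg.get("coverage", 0.5)))
    report["clustering"] = {
        "n_clusters": len(solution.sizes),
        "sizes": solution.sizes,
        "centers": solution.centers,
        "representatives": reps,
        "cutoff_nm": solution.cutoff_nm,
    }
    return report


def _region_map_from(config: dict[str, Any]) -> RegionMap:
    reg = config["regions"]
    if isinstance(reg, str):
        return load_region_map_toml(reg)
    rm = RegionMap(chain_length=int(reg["chain_length"]))
    for item in reg.get("interval", []):
        rm.add(item["name"], int(item["start"]), int(item["end"]),
               item.get("frame", "chain-local"))
    rm.validate_nr_cr()
    return rm


def run_pose_report(config: dict[str, Any] | str | Path) -> dict[str, Any]:
    """Region fractions, motif blockade and interaction-type tallies of a pose set."""
    if not isinstance(config, dict):
        config = load_config(config)
    inp = config["input"]
    ana = config.get("analysis", {})
    criteria = _criteria_from(config)
    pose_set = _stage("read_pose_set")(read_pose_set)(
        inp["directory"],
        receptor_chain=inp.get("receptor_chain", "A"),
        ligand_chain=inp.get("ligand_chain", "B"),
    )
    region_map = _region_map_from(config)
    dominance = float(ana.get("dominance", 0.8))
    summary = _stage("region_binding_fractions")(region_binding_fractions)(
        pose_set, region_map, criteria, dominance,
    )
    report: dict[str, Any] = {
        "report": "poses",
        "version": __version__,
        "provenance": {
            "directory": str(inp["directory"]),
            "n_poses": len(pose_set),
            "skipped": pose_set.skipped,
            "dominance": dominance,
            "blocked_fraction": float(ana.get("blocked_fraction", 0.5)),
            "exposure_threshold": float(ana.get("exposure_threshold", 0.25)),
            "contact_criteria": {
                "cutoff_A": criteria.cutoff,
                "min_atom_pairs": criteria.min_atom_pairs,
            },
            "seed": int(config.get("output", {}).get("seed", 0)),
        },
        "region_fractions": {
            "NR": summary.fraction_nr,
            "CR": summary.fraction_cr,
            "dual": summary.fraction_dual,
            "n_classified": summary.n_classified,
        },
    }
    if summary.n_classified == 0:
        report["region_fractions"] = {
            "NR": None, "CR": None, "dual": None,
            "n_classified": 0, "note": "no pose has a non-empty interface",
        }

    motifs = ana.get("motifs", {})
    blockade = {}
    statuses: dict[str, list[str]] = {}
    for name, (lo, hi) in motifs.items():
        st, frac = _stage(f"motif_status[{name}]")(motif_status)(
            pose_set, (int(lo), int(hi)), criteria,
            blocked_fraction=float(ana.get("blocked_fraction", 0.5)),
            exposure_threshold=float(ana.get("exposure_threshold", 0.25)),
            any_contact_mode=bool(ana.get("any_contact_mode", False)),
        )
        blockade[name] = frac
        statuses[name] = st
    report["motif_blockade"] = blockade
    report["motif_statuses"] = statuses

    tallies: dict[str, int] = {}
    per_pose = []
    windows = InteractionWindows()
    names = pose_set.names or [f"pose{k}" for k in range(len(pose_set))]
    for name, pose, rep in zip(names, pose_set.poses, summary.reports):
        recs = type_interactions(pose, windows, pose_set.receptor_chain,
                                 pose_set.ligand_chain)
        for r in recs:
            tallies[r.interaction_type] = tallies.get(r.interaction_type, 0) + 1
        per_pose.append({
            "pose": name,
            "region_class": rep.region_class,
            "n_interface_receptor": len(rep.receptor_residues),
            "n_interface_ligand": len(rep.ligand_residues),
            "n_interactions": len(recs),
            "interface_receptor": sorted(rep.receptor_residues),
            "interface_ligand": sorted(rep.ligand_residues),
        })
    report["interaction_tallies"] = tallies
    report["per_pose"] = per_pose
    return report


def pose_table(report: dict[str, Any]) -> pd.DataFrame:
    """Per-pose CSV-ready table from a pose report."""
    rows = [
        {k: (",".join(map(str, v)) if isinstance(v, list) else v)
         for k, v in item.items()}
        for item in report["per_pose"]
    ]
    return pd.DataFrame(rows)
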