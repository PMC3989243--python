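"""Full-study orchestration: convergence, order, structure, interactions,
landscape, clustering and binding-site discovery in one report bundle.

Binding sites are operationalized through contact persistence: a ligand copy
is site-forming when the set of residues it touches stays essentially the
same (Jaccard overlap >= 0.5 with its own most-frequent contact set) for at
least a persistence fraction of the analysis window, and copies whose stable
contact sets overlap are merged into one site.  Sites are ranked by mean
interaction energy (most negative first) when charges/LJ parameters are
available, else by contact density.
"""
from __future__ import annotations

import json
import shutil
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import interactions, landscape, order, secondary
from .model import Topology, Trajectory
from .pdbio import read_multimodel_pdb, write_series_table


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of a full analysis run.

    ``equilibrated_from`` selects the analysis window: a fraction below 1
    discards that share of the trajectory (0.5 keeps the last half), an
    integer >= 1 is taken as the first analyzed frame index.  Thresholds
    default to the geometric criteria used throughout the package.
    """

    traj_path: str | None = None
    ligand_resnames: tuple[str, ...] = ()
    equilibrated_from: float | int = 0.5
    temperature: float = 310.0
    fel_bins: tuple[int, int] = (40, 40)
    cluster_k: int = 3
    cluster_stride: int = 2
    seed: int = 0
    hbond_distance: float = 3.5
    hbond_angle: float = 150.0
    contact_cutoff: float = 3.5
    importance_threshold: float = 0.1
    p2_cutoff: float = 0.5
    persistence_fraction: float = 0.5
    output_dir: str = "oligodestab_report"

    def __post_init__(self):
        for name in ("hbond_distance", "contact_cutoff", "temperature"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        ef = self.equilibrated_from
        if not (0.0 <= ef < 1.0 or (float(ef).is_integer() and ef >= 1)):
            raise ValueError("equilibrated_from must be a fraction in [0, 1) "
                             "or a frame index >= 1")


@dataclass
class SiteGroup:
    site_id: int
    member_ligands: list[int]
    anchor_residues: list[tuple[str, int]]
    mean_energy: float | None
    sd_energy: float | None
    mean_contacts: float
    hbond_occupancies: dict[str, float] = field(default_factory=dict)
    stacking: list = field(default_factory=list)


def _jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def discover_sites(traj: Trajectory,
                   ligand_ids: list[int] | None = None,
                   frame_window: slice | None = None,
                   persistence_fraction: float = 0.5,
                   overlap_threshold: float = 0.5,
                   importance_threshold: float = 0.1,
                   contact_cutoff: float = 3.5) -> list[SiteGroup]:
    """Group persistently bound ligand copies into binding sites.

    Returns one :class:`SiteGroup` per site, ranked most favourable first
    (mean interaction energy when parameters allow, contact density
    otherwise).  Diffusing copies — no stable contact set — form no site.
    """
    top = traj.topology
    if ligand_ids is None:
        ligand_ids = top.ligand_molecule_ids
    if not ligand_ids:
        return []
    frames = traj.frames[frame_window] if frame_window else traj.frames
    nf = len(frames)

    mode_sets: dict[int, set] = {}
    persistent: list[int] = []
    for lig in ligand_ids:
        per_frame_sets = []
        freq: dict[tuple[str, int], int] = {}
        for fr in frames:
            contacted = interactions.ligand_contacts(fr, top, lig,
                                                     cutoff=contact_cutoff)
            residues = {(c, r) for c, r, _ in contacted}
            per_frame_sets.append(residues)
            for key in residues:
                freq[key] = freq.get(key, 0) + 1
        mode = {key for key, n in freq.items() if n / nf >= 0.5}
        mode_sets[lig] = mode
        if not mode:
            continue
        stable = sum(1 for s in per_frame_sets
                     if _jaccard(s, mode) >= overlap_threshold)
        if stable / nf >= persistence_fraction:
            persistent.append(lig)

    # merge copies whose stable contact sets overlap (connected components)
    groups: list[list[int]] = []
    for lig in persistent:
        merged = False
        for grp in groups:
            if any(_jaccard(mode_sets[lig], mode_sets[other]) >= overlap_threshold
                   for other in grp):
                grp.append(lig)
                merged = True
                break
        if not merged:
            groups.append([lig])

    protein_idx = np.flatnonzero(top.protein_mask)
    has_params = all(a.charge is not None and a.lj_epsilon is not None
                     and a.lj_rmin_half is not None for a in top.atoms)
    sites = []
    for members in groups:
        profile = interactions.contact_profile(
            traj, members, frame_window,
            probability_threshold=importance_threshold, cutoff=contact_cutoff)
        anchors = sorted(set(profile.important_backbone)
                         | set(profile.important_sidechain))
        density = float(profile.backbone_mean_contacts.sum()
                        + profile.sidechain_mean_contacts.sum())
        mean_e = sd_e = None
        if has_params:
            lig_idx = np.flatnonzero(np.isin(top.molecule_ids, members)
                                     & top.is_ligand_mask)
            window_traj = Trajectory(top, frames, timestep=traj.timestep,
                                     superposed=traj.superposed)
            trace = interactions.interaction_energy(window_traj, protein_idx,
                                                    lig_idx)
            mean_e, sd_e = trace.mean, trace.sd
        sites.append(SiteGroup(site_id=0, member_ligands=sorted(members),
                               anchor_residues=anchors, mean_energy=mean_e,
                               sd_energy=sd_e, mean_contacts=density))
    if has_params:
        sites.sort(key=lambda s: (s.mean_energy, -s.mean_contacts))
    else:
        sites.sort(key=lambda s: -s.mean_contacts)
    for i, s in enumerate(sites, start=1):
        s.site_id = i
        _site_hbond_occupancies(traj, frames, s)
    return sites


def _site_hbond_occupancies(traj: Trajectory, frames, site: SiteGroup,
                            top_n: int = 6) -> None:
    """Protein-ligand H-bond occupancies over the window for one site."""
    top = traj.topology
    counts: dict[tuple[int, int], int] = {}
    members = set(site.member_ligands)
    for fr in frames:
        seen = set()
        for b in interactions.detect_hbonds(fr, top, scope="all"):
            mol_d = top.molecule_ids[b.donor]
            mol_a = top.molecule_ids[b.acceptor]
            lig_d = top.is_ligand_mask[b.donor]
            lig_a = top.is_ligand_mask[b.acceptor]
            if lig_d == lig_a:
                continue  # protein-protein or ligand-ligand
            if (mol_d if lig_d else mol_a) not in members:
                continue
            seen.add((b.donor, b.acceptor))
        for key in seen:
            counts[key] = counts.get(key, 0) + 1
    nf = len(frames)
    items = sorted(counts.items(), key=lambda kv: -kv[1])[:top_n]
    occ = {}
    for (d, a), n in items:
        label = (f"{top.chain_ids[d]}:{top.residue_indices[d]}:{top.names[d]}"
                 f"->{top.chain_ids[a]}:{top.residue_indices[a]}:{top.names[a]}")
        occ[label] = n / nf
    site.hbond_occupancies = occ


def run_full_report(config: RunConfig,
                    trajectory: Trajectory | None = None) -> dict:
    """Run every analysis stage and write a CSV/JSON report bundle.

    Returns the summary dictionary (also written as ``summary.json``).  A
    stage failure aborts with the stage name and removes partial outputs.
    Fixed config and seed reproduce the bundle byte-for-byte.
    """
    outdir = Path(config.output_dir)
    created = not outdir.exists()
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                                for k, v in asdict(config).items()}}
    stage = "load"
    try:
        if trajectory is None:
            if config.traj_path is None:
                raise ValueError("RunConfig.traj_path or an in-memory "
                                 "trajectory is required")
            trajectory = read_multimodel_pdb(config.traj_path,
                                             config.ligand_resnames)
        n_frames = len(trajectory)
        ef = config.equilibrated_from
        start = int(ef) if ef >= 1 else int(np.floor(ef * n_frames))
        if start >= n_frames:
            raise ValueError("equilibrated window starts beyond the trajectory")
        window = slice(start, n_frames)
        top = trajectory.topology

        stage = "convergence"
        ca = np.flatnonzero(top.calpha_mask)
        fitted, rmsd = order.superpose_trajectory(trajectory, ca)
        assignment = secondary.assign_trajectory(trajectory)
        beta_series, beta_mean, beta_sd = secondary.beta_content(
            assignment, frame_window=window)
        hb_series = interactions.backbone_hbond_count_series(trajectory)
        times = trajectory.times()
        write_series_table(
            [{"time": t, "rmsd": r, "beta_content": b, "backbone_hbonds": h}
             for t, r, b, h in zip(times, rmsd, beta_series, hb_series)],
            outdir / "convergence.csv")
        summary["convergence"] = {
            "n_frames": n_frames, "window_start_frame": start,
            "beta_content_mean": beta_mean, "beta_content_sd": beta_sd,
            "backbone_hbonds_mean": float(hb_series[start:].mean()),
        }

        stage = "order"
        p2 = order.p2_series(trajectory)
        label, p2_mean, p2_sd = order.classify_order(p2[window],
                                                     cutoff=config.p2_cutoff)
        rmsf = order.rmsf_per_residue_chain_averaged(
            Trajectory(top, fitted.frames[start:] if start < n_frames - 1
                       else fitted.frames, timestep=trajectory.timestep,
                       superposed=True))
        write_series_table([{"time": t, "p2": v} for t, v in zip(times, p2)],
                           outdir / "p2.csv")
        write_series_table([{"residue": int(r), "rmsf": float(v)}
                            for r, v in zip(
                                np.unique(top.residue_indices[top.calpha_mask]),
                                rmsf)],
                           outdir / "rmsf.csv")
        summary["order"] = {"label": label, "p2_mean": p2_mean, "p2_sd": p2_sd}

        stage = "secondary_structure"
        content = secondary.ss_content(assignment)
        summary["secondary_structure"] = {
            name: {"mean": float(series[window].mean()),
                   "sd": float(series[window].std())}
            for name, series in (("coil", content.coil), ("turn", content.turn),
                                 ("beta", content.beta),
                                 ("helix", content.helix))}
        secondary.ss_timeline(assignment).to_csv(
            outdir / "ss_timeline.csv", index=False)

        stage = "free_energy_landscape"
        rg = order.rg_series(trajectory) / 10.0  # report Rg in nm
        grid = landscape.build_fel(beta_series[window], rg[window],
                                   bins=config.fel_bins,
                                   temperature=config.temperature)
        basins = landscape.find_basins(grid)
        rows = [{"beta_content": float(x), "rg_nm": float(y),
                 "delta_g": (float(grid.delta_g[i, j])
                             if np.isfinite(grid.delta_g[i, j]) else "inf")}
                for i, x in enumerate(grid.x_centers)
                for j, y in enumerate(grid.y_centers)]
        write_series_table(rows, outdir / "fel.csv")
        summary["fel"] = {"kT": grid.kt,
                          "basins": [[b.x_center, b.y_center, b.depth]
                                     for b in basins]}

        stage = "hbond_maps"
        chains = top.chains
        maps = {}
        for cx, cy in zip(chains, chains[1:]):
            m = interactions.hbond_map(trajectory, (cx, cy), window)
            maps[f"{cx}-{cy}"] = {"all_zero": m.all_zero,
                                  "total": float(m.raw_counts.sum())}
            np.savetxt(outdir / f"hbond_map_{cx}{cy}.csv", m.matrix,
                       delimiter=",", fmt="%.6f")
        summary["hbond_maps"] = maps

        stage = "clustering"
        clusters = landscape.cluster_frames(trajectory, ca, k=config.cluster_k,
                                            seed=config.seed,
                                            stride=config.cluster_stride)
        summary["clustering"] = {
            "k": clusters.k,
            "occupancies": sorted((float(o) for o in clusters.occupancies),
                                  reverse=True),
            "representatives": [int(r) for r in clusters.representatives]}

        stage = "site_discovery"
        sites = discover_sites(
            trajectory, frame_window=window,
            persistence_fraction=config.persistence_fraction,
            importance_threshold=config.importance_threshold,
            contact_cutoff=config.contact_cutoff)
        summary["sites"] = [
            {"site_id": s.site_id, "ligands": s.member_ligands,
             "anchors": [f"{c}:{r}" for c, r in s.anchor_residues],
             "mean_energy": s.mean_energy, "sd_energy": s.sd_energy,
             "mean_contacts": s.mean_contacts,
             "hbond_occupancies": s.hbond_occupancies}
            for s in sites]

        stage = "write_summary"
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        return summary
    except Exception as exc:
        if created:
            shutil.rmtree(outdir, ignore_errors=True)
        else:
            for f in outdir.glob("*"):
                if f.is_file():
                    f.unlink()
        raise StageError(stage, exc) from exc
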