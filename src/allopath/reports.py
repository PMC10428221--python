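"""Structural analytics and the consolidated pipeline runner.

Two small per-trajectory diagnostics accompany the network machinery:

* **ligand–residue contact fractions** — for each residue, the fraction of
  frames in which any ligand heavy atom comes within a cutoff (default
  4.5 A) of the residue's side-chain heavy atoms; a fraction of 1 means the
  contact persists through the whole trajectory;
* **pore integrity** — the per-frame Cα–Cα distances between a marker
  residue (G626 in hERG) on diagonally opposite subunits; collapse or
  dilation of the conduction pore shows up directly in these two series.

:func:`run_pipeline` chains the package's stages (simulate → nodes →
network → paths/betweenness; receptor clustering; rescoring; contacts)
from a single declarative YAML/dict configuration and writes a
machine-readable run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, ValidationError

from . import __version__
from .network import (AllostericNetworkModel, KernelParams, MISettings)
from .receptor_clustering import (ClusterSelection, cluster_trajectory)
from .rescoring import read_pose_table, rescore_ensemble
from .synthetic import (PlantedCovariance, PlantedPoseModel, PoseMode,
                        ToyChannelSpec, generate_pose_ensemble,
                        generate_toy_channel, generate_trajectory)
from .trajectory import System, extract_node_series, load_system
from .trajectory import _heavy, _residue_nodes  # shared atom conventions

logger = logging.getLogger(__name__)

__all__ = [
    "ContactFractionTable",
    "PoreIntegritySeries",
    "contact_fractions",
    "pore_integrity",
    "run_pipeline",
    "PipelineConfig",
    "StageError",
]


# ---------------------------------------------------------------------------
# contact fractions


@dataclass
class ContactFractionTable:
    table: pd.DataFrame       # columns: node label parts + fraction
    cutoff: float
    note: str = ("contact: min distance between any ligand heavy atom and "
                 "any residue side-chain heavy atom (CA for glycine) <= cutoff")


def contact_fractions(system: System, cutoff: float = 4.5,
                      ligand_selection: str | None = None) -> ContactFractionTable:
    """Per-residue fraction of frames with a ligand contact."""
    u = system.universe
    lig = _heavy(u.select_atoms(ligand_selection or system.ligand_selection))
    if lig.n_atoms == 0:
        raise ValueError("no ligand heavy atoms found")
    protein = u.select_atoms("protein")
    if protein.n_residues == 0:
        raise ValueError("no protein residues found")
    res_nodes = _residue_nodes(protein)

    counts = np.zeros(len(res_nodes), dtype=int)
    for f in system.frames:
        pos = u.trajectory[int(f)].positions
        lig_pos = pos[lig.ix]
        for i, (_, _ca, side_ix, _m) in enumerate(res_nodes):
            d = np.linalg.norm(pos[side_ix][:, None, :] - lig_pos[None, :, :],
                               axis=-1)
            if d.min() <= cutoff:
                counts[i] += 1
    frac = counts / len(system.frames)
    rows = [
        {"segid": nid[0], "resid": nid[1], "resname": nid[2],
         "contact_fraction": float(f)}
        for (nid, *_), f in zip(res_nodes, frac)
    ]
    return ContactFractionTable(table=pd.DataFrame(rows), cutoff=cutoff)


# ---------------------------------------------------------------------------
# pore integrity


@dataclass
class PoreIntegritySeries:
    distances: pd.DataFrame   # per frame, one column per diagonal pair
    mean: dict[str, float]
    sd: dict[str, float]
    marker: str


def pore_integrity(system: System, marker_resid: int,
                   marker_resname: str | None = None) -> PoreIntegritySeries:
    """Cα–Cα distances of the marker residue across diagonal subunit pairs.

    For a channel of n subunits (n even), subunit i is paired with subunit
    i + n/2: two pairs in a tetramer.
    """
    u = system.universe
    sel = f"name CA and resid {marker_resid}"
    if marker_resname:
        sel += f" and resname {marker_resname}"
    ca = u.select_atoms(sel)
    n_sub = ca.n_atoms
    if n_sub == 0:
        raise ValueError(f"marker residue {marker_resid} not found in any subunit")
    if n_sub % 2:
        raise ValueError(
            f"marker found in {n_sub} subunits; diagonal pairing needs an "
            "even subunit count")
    # order by segment to make the diagonal pairing deterministic
    order = np.argsort([str(s) for s in ca.segids], kind="stable")
    ix = ca.ix[order]
    pairs = [(i, i + n_sub // 2) for i in range(n_sub // 2)]

    rows = []
    for f in system.frames:
        pos = u.trajectory[int(f)].positions
        rows.append([float(np.linalg.norm(pos[ix[a]] - pos[ix[b]]))
                     for a, b in pairs])
    cols = [f"pair_{a + 1}_{b + 1}" for a, b in pairs]
    df = pd.DataFrame(rows, columns=cols)
    df.insert(0, "frame", system.frames)
    return PoreIntegritySeries(
        distances=df,
        mean={c: float(df[c].mean()) for c in cols},
        sd={c: float(df[c].std(ddof=0)) for c in cols},
        marker=f"resid {marker_resid} CA",
    )


# ---------------------------------------------------------------------------
# pipeline configuration (validated schema)


class SimulateConfig(BaseModel):
    n_subunits: int = 4
    residues_per_subunit: int = 10
    n_frames: int = 500
    rho_path: float = 0.9
    rho_background: float = 0.0
    noise_sd: float = 1.0
    path_subunit: int = 0         # the planted chain spans this subunit
    n_ligand_fragments: int = 0
    pose_modes: Optional[list[dict]] = None  # center/energy/n_poses/spread_sd


class KernelConfig(BaseModel):
    cutoff: float = 7.0
    d_cut: float = 10.0
    kernel_floor: float = 1e-5
    sigma: Optional[float] = None


class MIConfig(BaseModel):
    estimator: Literal["histogram", "gaussian"] = "histogram"
    mode: Literal["factorized", "joint"] = "factorized"
    bins: int = 10
    range_sd: float = 4.0
    min_samples: int = 100


class NetworkConfig(BaseModel):
    kernel: KernelConfig = Field(default_factory=KernelConfig)
    mi: MIConfig = Field(default_factory=MIConfig)
    exclude_adjacent: int = 0
    superpose: bool = False


class PathsConfig(BaseModel):
    source_center: int | str
    sink_center: int | str
    radius: float = 7.0
    occupancy_threshold: float = 0.70


class ClusterConfig(BaseModel):
    k: int = 10
    residue_ranges: Optional[list[tuple[str, int, int]]] = None
    seed: Optional[int] = None


class RescoreConfig(BaseModel):
    pose_table: Optional[str] = None   # defaults to the simulated table
    rmsd_threshold: float = 2.0
    kT: float = 0.593
    receptor_populations: Optional[dict[str, float]] = None
    use_cluster_populations: bool = False


class ContactsConfig(BaseModel):
    cutoff: float = 4.5


class InputsConfig(BaseModel):
    topology: str
    trajectory: Optional[str] = None
    frame_selection: Optional[str] = None
    ligand_map: Optional[dict[str, list[str]]] = None


class PipelineConfig(BaseModel):
    output_dir: str
    seed: int = 0
    stages: list[Literal["simulate", "network", "paths", "cluster",
                         "rescore", "contacts"]] = Field(
        default_factory=lambda: ["simulate", "network", "paths"])
    inputs: Optional[InputsConfig] = None
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    network: NetworkConfig = Field(default_factory=NetworkConfig)
    paths: Optional[PathsConfig] = None
    cluster: ClusterConfig = Field(default_factory=ClusterConfig)
    rescore: RescoreConfig = Field(default_factory=RescoreConfig)
    contacts: ContactsConfig = Field(default_factory=ContactsConfig)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"[stage:{stage}] {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(obj, path: Path) -> Path:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str))
    return path


def run_pipeline(config) -> dict:
    """Execute the configured stages and write outputs plus a run manifest.

    ``config`` may be a dict, a :class:`PipelineConfig`, or a path to a YAML
    file.  Returns a report dict with per-stage results and the manifest.
    """
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    if isinstance(config, dict):
        try:
            config = PipelineConfig.model_validate(config)
        except ValidationError as exc:
            raise ValueError(f"invalid pipeline configuration: {exc}") from exc

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    report: dict = {"stages": {}}

    topology = trajectory_path = None
    ligand_map = None
    frame_selection = None
    universe = None
    pose_table_path: Path | None = None
    cluster_populations: dict[str, float] | None = None

    if config.inputs is not None:
        topology = config.inputs.topology
        trajectory_path = config.inputs.trajectory
        frame_selection = config.inputs.frame_selection
        ligand_map = config.inputs.ligand_map

    # ---- simulate --------------------------------------------------------
    if "simulate" in config.stages:
        try:
            sim = config.simulate
            spec = ToyChannelSpec(
                n_subunits=sim.n_subunits,
                residues_per_subunit=sim.residues_per_subunit,
                n_ligand_fragments=sim.n_ligand_fragments)
            channel = generate_toy_channel(spec)
            first = sim.path_subunit * sim.residues_per_subunit
            path_nodes = tuple(range(first, first + sim.residues_per_subunit))
            cov = PlantedCovariance(path_nodes=path_nodes,
                                    rho_path=sim.rho_path,
                                    rho_background=sim.rho_background,
                                    noise_sd=sim.noise_sd)
            traj = generate_trajectory(channel, cov, sim.n_frames,
                                       seed=config.seed)
            top_p = outdir / "toy_topology.pdb"
            trj_p = outdir / "toy_trajectory.dcd"
            gt_p = outdir / "ground_truth.json"
            traj.write(top_p, trj_p, gt_p)
            written += [top_p, trj_p, gt_p]
            topology, trajectory_path = str(top_p), str(trj_p)
            universe = traj.to_universe()
            if spec.n_ligand_fragments:
                ligand_map = channel.ligand_fragment_map()

            if sim.pose_modes:
                modes = tuple(
                    PoseMode(center=np.asarray(m["center"], dtype=float),
                             energy=float(m["energy"]),
                             n_poses=int(m["n_poses"]),
                             spread_sd=float(m.get("spread_sd", 0.5)))
                    for m in sim.pose_modes)
                table, gt = generate_pose_ensemble(
                    PlantedPoseModel(modes=modes), seed=config.seed + 1)
                pose_table_path = outdir / "toy_poses.tsv"
                table.to_csv(pose_table_path, sep="\t", index=False)
                _write_json(gt, outdir / "toy_poses_ground_truth.json")
                written += [pose_table_path,
                            outdir / "toy_poses_ground_truth.json"]
            report["stages"]["simulate"] = {
                "n_nodes": spec.n_nodes, "n_frames": sim.n_frames,
                "path_nodes": list(path_nodes)}
        except Exception as exc:   # noqa: BLE001 - stage-tagged diagnostics
            raise StageError("simulate", exc) from exc

    needs_system = {"network", "paths", "cluster", "contacts"} & set(config.stages)
    system = None
    if needs_system:
        if topology is None and universe is None:
            raise ValueError("stages need a trajectory: provide 'inputs' or "
                             "run the 'simulate' stage")
        system = load_system(topology, trajectory_path,
                             frame_selection=frame_selection,
                             universe=universe)

    results = None
    if "network" in config.stages or "paths" in config.stages:
        try:
            net = config.network
            model = AllostericNetworkModel(
                extract_node_series(system, ligand_map=ligand_map,
                                    superpose=net.superpose),
                kernel_params=KernelParams(**net.kernel.model_dump()),
                mi_settings=MISettings(**net.mi.model_dump()),
                exclude_adjacent=net.exclude_adjacent)
            results = model.fit()
            labels = results.node_labels
            pd.DataFrame(results.contacts, index=labels, columns=labels) \
                .to_csv(outdir / "contact_map.csv")
            pd.DataFrame(results.mi.M_hat, index=labels, columns=labels) \
                .to_csv(outdir / "mi_normalized.csv")
            results.to_edge_list(outdir / "network_edges.tsv")
            results.to_graphml(outdir / "network.graphml")
            written += [outdir / "contact_map.csv",
                        outdir / "mi_normalized.csv",
                        outdir / "network_edges.tsv",
                        outdir / "network.graphml"]
            report["stages"]["network"] = {
                "n_nodes": results.graph.number_of_nodes(),
                "n_edges": results.graph.number_of_edges()}
        except StageError:
            raise
        except Exception as exc:
            raise StageError("network", exc) from exc

    if "paths" in config.stages:
        try:
            if config.paths is None:
                raise ValueError("'paths' stage requested but no [paths] "
                                 "section configured")
            p = config.paths
            src = results.detect_region(p.source_center, p.radius,
                                        p.occupancy_threshold)
            snk = results.detect_region(p.sink_center, p.radius,
                                        p.occupancy_threshold)
            snk -= src
            path_res = results.min_path(src, snk)
            btw = results.betweenness()
            path_report = {
                "source_region": sorted(results.label_of(i) for i in src),
                "sink_region": sorted(results.label_of(i) for i in snk),
                "d_min": path_res.d_min,
                "coupling_efficiency": path_res.coupling_efficiency(),
                "reachable": path_res.reachable,
                "best_path": [results.label_of(i)
                              for i in (path_res.best_path or [])],
                "n_co_minimal_paths": len(path_res.co_minimal_paths),
                "betweenness": {results.label_of(i): v
                                for i, v in sorted(btw.items())},
            }
            _write_json(path_report, outdir / "paths.json")
            written.append(outdir / "paths.json")
            report["stages"]["paths"] = {
                "d_min": path_res.d_min, "reachable": path_res.reachable,
                "best_path": path_report["best_path"]}
        except StageError:
            raise
        except Exception as exc:
            raise StageError("paths", exc) from exc

    if "cluster" in config.stages:
        try:
            cl = config.cluster
            if cl.residue_ranges is not None:
                selection = ClusterSelection(
                    residue_ranges=tuple(tuple(r) for r in cl.residue_ranges))
            else:
                selection = ClusterSelection()
            cset = cluster_trajectory(system.universe, selection,
                                      k=cl.k,
                                      seed=config.seed if cl.seed is None
                                      else cl.seed,
                                      frames=system.frames)
            cluster_populations = cset.populations_as_dict()
            pd.DataFrame({
                "item": np.arange(len(cset.assignments)),
                "original_frame": cset.provenance[:, 0],
                "rotation": cset.provenance[:, 1],
                "cluster": cset.assignments,
            }).to_csv(outdir / "receptor_clusters.csv", index=False)
            _write_json({"k": cset.k, "populations": cluster_populations,
                         "seed": cset.seed,
                         "symmetry_expansion": "cyclic subunit relabeling"},
                        outdir / "receptor_populations.json")
            written += [outdir / "receptor_clusters.csv",
                        outdir / "receptor_populations.json"]
            report["stages"]["cluster"] = {"k": cset.k,
                                           "populations": cluster_populations}
        except StageError:
            raise
        except Exception as exc:
            raise StageError("cluster", exc) from exc

    if "rescore" in config.stages:
        try:
            rs = config.rescore
            table_path = rs.pose_table or pose_table_path
            if table_path is None:
                raise ValueError("'rescore' stage needs rescore.pose_table or "
                                 "simulate.pose_modes")
            table = read_pose_table(table_path)
            pops = rs.receptor_populations
            if pops is None and rs.use_cluster_populations:
                pops = cluster_populations
            rankings = rescore_ensemble(table, receptor_populations=pops,
                                        rmsd_threshold=rs.rmsd_threshold,
                                        kT=rs.kT)
            summary = {}
            for method, ranking in rankings.items():
                safe = method.replace("'", "_prime")
                fname = f"ranking_{safe}.csv"
                ranking.table.to_csv(outdir / fname, index=False)
                written.append(outdir / fname)
                summary[method] = {
                    "top_receptor_cluster": str(ranking.top.receptor_cluster),
                    "top_ligand_state": str(ranking.top.ligand_state),
                    "top_cluster_id": int(ranking.top.cluster_id),
                    "top_energy": float(ranking.top.energy),
                }
            report["stages"]["rescore"] = summary
        except StageError:
            raise
        except Exception as exc:
            raise StageError("rescore", exc) from exc

    if "contacts" in config.stages:
        try:
            cf = contact_fractions(system, cutoff=config.contacts.cutoff)
            cf.table.to_csv(outdir / "contact_fractions.csv", index=False)
            written.append(outdir / "contact_fractions.csv")
            report["stages"]["contacts"] = {
                "n_residues": len(cf.table),
                "max_fraction": float(cf.table.contact_fraction.max())}
        except StageError:
            raise
        except Exception as exc:
            raise StageError("contacts", exc) from exc

    manifest = {
        "allopath_version": __version__,
        "seed": config.seed,
        "config": config.model_dump(),
        "outputs": {str(p.name): _sha256(p) for p in written},
    }
    _write_json(manifest, outdir / "manifest.json")
    report["manifest"] = manifest
    return report
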