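"""Desk-scale surrogate inputs with known ground truth.

Real studies of voltage-gated channel allostery rest on hundreds of
nanoseconds of all-atom MD and GPU docking runs.  This module replaces those
inputs with small synthetic analogues whose statistical structure is planted
and therefore known exactly: a pseudo-channel (a C\\ :sub:`n`-symmetric helical
bundle of "residues", each a CA/CB pair) whose side-chain displacements follow
a prescribed correlation structure, and docking-pose ensembles drawn from
explicit modes with known populations and energies.  Every downstream stage of
the package can then be tested against ground truth.

Displacements are drawn i.i.d. per frame (no autocorrelation) and the planted
covariance acts identically and independently on x, y and z, so closed-form
per-dimension checks of the mutual-information estimators are exact.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import MDAnalysis as mda
import numpy as np
import pandas as pd
from MDAnalysis.coordinates.memory import MemoryReader

__all__ = [
    "ToyChannelSpec",
    "ToyChannel",
    "ToyTrajectory",
    "PlantedCovariance",
    "PoseMode",
    "PlantedPoseModel",
    "generate_toy_channel",
    "generate_trajectory",
    "generate_pose_ensemble",
    "POSE_TABLE_FIXED_COLUMNS",
]

SEGMENT_IDS = "ABCDEFGHIJKLMNOP"


@dataclass(frozen=True)
class ToyChannelSpec:
    """Geometry of the pseudo-channel.

    The channel is a bundle of ``n_subunits`` identical helical rods arranged
    with exact cyclic symmetry about the pore (z) axis.  Within a rod,
    consecutive residues are ~5 A apart (always in contact under a 7 A
    cutoff), residues two apart are ~8.6 A (weak kernel tail) and residues
    three or more apart are beyond 10 A (no contact), so the residue chain is
    the natural contact path along each subunit.
    """

    n_subunits: int = 4
    residues_per_subunit: int = 10
    bundle_radius: float = 7.0     # rod axis distance from the pore axis (A)
    helix_radius: float = 1.8      # CA distance from the rod axis (A)
    rise_per_residue: float = 4.0  # z step between consecutive residues (A)
    twist_per_residue: float = 120.0  # degrees about the rod axis
    sidechain_offset: float = 1.5  # CB offset, radially outward (A)
    n_ligand_fragments: int = 0    # optional pore-lodged ligand nodes

    def __post_init__(self) -> None:
        if self.n_subunits < 1:
            raise ValueError("n_subunits must be >= 1")
        if self.n_subunits > len(SEGMENT_IDS):
            raise ValueError(f"n_subunits must be <= {len(SEGMENT_IDS)}")
        if self.residues_per_subunit < 2:
            raise ValueError("residues_per_subunit must be >= 2")
        for name in ("bundle_radius", "helix_radius", "rise_per_residue",
                     "sidechain_offset"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        if self.n_ligand_fragments < 0:
            raise ValueError("n_ligand_fragments must be >= 0")

    @property
    def n_residues(self) -> int:
        return self.n_subunits * self.residues_per_subunit

    @property
    def n_nodes(self) -> int:
        """Residue nodes plus one node per ligand fragment."""
        return self.n_residues + self.n_ligand_fragments


def _rotation_z(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


@dataclass
class ToyChannel:
    """Reference structure produced by :func:`generate_toy_channel`."""

    spec: ToyChannelSpec
    coordinates: np.ndarray          # (n_atoms, 3), A
    atom_names: list[str]
    resids: np.ndarray               # per-atom residue index (0-based)
    resnames: list[str]              # per-residue
    segids: list[str]                # per-residue
    sidechain_atom_indices: list[np.ndarray]  # per node: atoms carrying displacements

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_residues(self) -> int:
        return len(self.resnames)

    def ligand_fragment_map(self) -> dict[str, list[str]] | None:
        """Atom-name map of the toy ligand's fragments, if a ligand exists."""
        if self.spec.n_ligand_fragments == 0:
            return None
        return {
            f"frag{k + 1}": [f"C{2 * k + 1}", f"C{2 * k + 2}"]
            for k in range(self.spec.n_ligand_fragments)
        }

    def to_universe(self) -> mda.Universe:
        u = _make_universe(self)
        u.load_new(self.coordinates[None, :, :].astype(np.float32),
                   format=MemoryReader)
        return u

    def write_pdb(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_universe().atoms.write(str(path))
        return path


def _make_universe(channel: ToyChannel) -> mda.Universe:
    spec = channel.spec
    n_res = channel.n_residues
    seg_labels = sorted(set(channel.segids), key=channel.segids.index)
    seg_index = {s: i for i, s in enumerate(seg_labels)}
    u = mda.Universe.empty(
        n_atoms=channel.n_atoms,
        n_residues=n_res,
        n_segments=len(seg_labels),
        atom_resindex=channel.resids,
        residue_segindex=np.array([seg_index[s] for s in channel.segids]),
        trajectory=False,
    )
    u.add_TopologyAttr("names", channel.atom_names)
    u.add_TopologyAttr("resnames", channel.resnames)
    resids = []
    counts: dict[str, int] = {}
    for s in channel.segids:
        counts[s] = counts.get(s, 0) + 1
        resids.append(counts[s])
    u.add_TopologyAttr("resids", resids)
    u.add_TopologyAttr("segids", seg_labels)
    u.add_TopologyAttr("chainIDs",
                       [channel.segids[r][0] for r in channel.resids])
    u.add_TopologyAttr("masses", np.full(channel.n_atoms, 12.011))
    u.add_TopologyAttr("elements", ["C"] * channel.n_atoms)
    return u


def generate_toy_channel(spec: ToyChannelSpec) -> ToyChannel:
    """Build the C\\ :sub:`n`-symmetric reference structure.

    Subunit 0 is constructed explicitly; the others are exact rotations of it
    by multiples of 360/n about the pore axis, so inter-subunit RMSD after
    rotation is zero by construction.
    """
    coords: list[np.ndarray] = []
    names: list[str] = []
    resid_of_atom: list[int] = []
    resnames: list[str] = []
    segids: list[str] = []
    sidechain_atoms: list[np.ndarray] = []

    # subunit 0 template: CA on a helix about the rod axis, CB radially out
    ca0, cb0 = [], []
    for k in range(spec.residues_per_subunit):
        phi = np.deg2rad(spec.twist_per_residue * k)
        local = np.array([spec.helix_radius * np.cos(phi),
                          spec.helix_radius * np.sin(phi),
                          spec.rise_per_residue * k])
        ca = local + np.array([spec.bundle_radius, 0.0, 0.0])
        radial = ca[:2] / max(np.linalg.norm(ca[:2]), 1e-12)
        cb = ca + np.array([*(spec.sidechain_offset * radial), 0.0])
        ca0.append(ca)
        cb0.append(cb)

    resindex = 0
    atom_index = 0
    for s in range(spec.n_subunits):
        rot = _rotation_z(360.0 * s / spec.n_subunits)
        for k in range(spec.residues_per_subunit):
            coords.append(rot @ ca0[k])
            coords.append(rot @ cb0[k])
            names.extend(["CA", "CB"])
            resid_of_atom.extend([resindex, resindex])
            resnames.append("ALA")
            segids.append(SEGMENT_IDS[s])
            sidechain_atoms.append(np.array([atom_index + 1]))
            atom_index += 2
            resindex += 1

    # optional ligand: fragments of two atoms each, stacked on the pore axis
    if spec.n_ligand_fragments:
        z_mid = spec.rise_per_residue * (spec.residues_per_subunit - 1) / 2.0
        for k in range(spec.n_ligand_fragments):
            z = z_mid + 3.0 * (k - (spec.n_ligand_fragments - 1) / 2.0)
            frag_atoms = []
            for j, dx in enumerate((-0.7, 0.7)):
                coords.append(np.array([dx, 0.0, z]))
                names.append(f"C{2 * k + j + 1}")
                resid_of_atom.append(resindex)
                frag_atoms.append(atom_index)
                atom_index += 1
            sidechain_atoms.append(np.array(frag_atoms))
        # all fragment atoms share one LIG residue
        resnames.append("LIG")
        segids.append(SEGMENT_IDS[spec.n_subunits])
        resindex += 1

    channel = ToyChannel(
        spec=spec,
        coordinates=np.asarray(coords, dtype=float),
        atom_names=names,
        resids=np.asarray(resid_of_atom),
        resnames=resnames,
        segids=segids,
        sidechain_atom_indices=sidechain_atoms,
    )
    if not np.all(np.isfinite(channel.coordinates)):
        raise ValueError("generated coordinates are not finite")
    return channel


@dataclass(frozen=True)
class PlantedCovariance:
    """Correlation structure planted on side-chain displacements.

    ``path_nodes`` form a Markov chain: the correlation between path nodes at
    chain distance m is ``rho_path**m``, so consecutive nodes have correlation
    exactly ``rho_path`` and the matrix is positive definite by construction.
    Non-path nodes share a constant pairwise correlation ``rho_background``
    (default 0).  The same correlation matrix acts independently on each of
    x, y and z.
    """

    path_nodes: tuple[int, ...]
    rho_path: float = 0.9
    rho_background: float = 0.0
    noise_sd: float = 1.0
    repair_tolerance: float = 0.05  # max |negative eigenvalue| / max eigenvalue

    def __post_init__(self) -> None:
        if len(set(self.path_nodes)) != len(self.path_nodes):
            raise ValueError("path_nodes must be distinct")
        if not -1.0 < self.rho_path < 1.0:
            raise ValueError("rho_path must lie in (-1, 1)")
        if not -1.0 < self.rho_background < 1.0:
            raise ValueError("rho_background must lie in (-1, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")

    def correlation_matrix(self, n_nodes: int) -> tuple[np.ndarray, bool]:
        """Return (R, repaired) for ``n_nodes`` nodes.

        Non-PSD matrices (possible for rho_background < 0) are repaired by
        clipping negative eigenvalues at zero and renormalizing the diagonal;
        the repair is reported via the flag and a warning.  Negative
        eigenvalues larger than ``repair_tolerance`` times the top eigenvalue
        are considered beyond repair.
        """
        if max(self.path_nodes, default=-1) >= n_nodes:
            raise ValueError("path_nodes exceed the number of nodes")
        R = np.eye(n_nodes)
        on_path = np.zeros(n_nodes, dtype=bool)
        on_path[list(self.path_nodes)] = True
        background = np.where(~on_path)[0]
        for a in range(len(background)):
            for b in range(a + 1, len(background)):
                i, j = background[a], background[b]
                R[i, j] = R[j, i] = self.rho_background
        for a in range(len(self.path_nodes)):
            for b in range(a + 1, len(self.path_nodes)):
                i, j = self.path_nodes[a], self.path_nodes[b]
                R[i, j] = R[j, i] = self.rho_path ** (b - a)

        w = np.linalg.eigvalsh(R)
        repaired = False
        if w[0] < -1e-12:
            if abs(w[0]) > self.repair_tolerance * w[-1]:
                raise ValueError(
                    f"correlation matrix is non-PSD beyond repair tolerance "
                    f"(min eigenvalue {w[0]:.3g})")
            vals, vecs = np.linalg.eigh(R)
            R = (vecs * np.clip(vals, 0.0, None)) @ vecs.T
            d = np.sqrt(np.diag(R))
            R = R / np.outer(d, d)
            repaired = True
            warnings.warn("planted correlation matrix repaired by eigenvalue "
                          "clipping", stacklevel=2)
        return R, repaired


@dataclass
class ToyTrajectory:
    """Synthetic trajectory plus its ground-truth sidecar."""

    channel: ToyChannel
    coordinates: np.ndarray          # (n_frames, n_atoms, 3)
    displacements: np.ndarray        # (n_frames, n_nodes, 3) planted values
    ground_truth: dict

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    def to_universe(self) -> mda.Universe:
        u = _make_universe(self.channel)
        u.load_new(self.coordinates.astype(np.float32), format=MemoryReader)
        return u

    def write(self, topology_path: str | Path, trajectory_path: str | Path,
              ground_truth_path: str | Path | None = None) -> None:
        """Write PDB topology + DCD trajectory (+ JSON ground truth)."""
        self.channel.write_pdb(topology_path)
        u = self.to_universe()
        with mda.Writer(str(trajectory_path), n_atoms=u.atoms.n_atoms) as w:
            for _ in u.trajectory:
                w.write(u.atoms)
        if ground_truth_path is not None:
            Path(ground_truth_path).write_text(
                json.dumps(self.ground_truth, indent=2))


def generate_trajectory(channel: ToyChannel, cov: PlantedCovariance,
                        n_frames: int, seed: int) -> ToyTrajectory:
    """Draw frames as reference + correlated Gaussian side-chain displacements.

    Each node's displacement vector is added to its side-chain atoms only
    (CB, or the ligand-fragment atoms); backbone CA positions stay at the
    reference, so the contact map of the toy system is deterministic while the
    mutual-information structure is planted.  Frames are i.i.d.; the same seed
    reproduces the trajectory bit for bit.
    """
    if n_frames < 10:
        raise ValueError("n_frames must be >= 10")
    n_nodes = len(channel.sidechain_atom_indices)
    R, repaired = cov.correlation_matrix(n_nodes)
    vals, vecs = np.linalg.eigh(R)
    L = vecs * np.sqrt(np.clip(vals, 0.0, None))

    rng = np.random.default_rng(seed)
    z = rng.standard_normal((3, n_frames, n_nodes))
    disp = np.einsum("dfn,mn->fmd", z, L) * cov.noise_sd  # (frames, nodes, 3)

    coords = np.repeat(channel.coordinates[None, :, :], n_frames, axis=0)
    for node, atoms in enumerate(channel.sidechain_atom_indices):
        coords[:, atoms, :] += disp[:, node, None, :]

    ground_truth = {
        "path_nodes": list(cov.path_nodes),
        "rho_path": cov.rho_path,
        "rho_background": cov.rho_background,
        "noise_sd": cov.noise_sd,
        "n_frames": n_frames,
        "seed": seed,
        "covariance_repaired": repaired,
        "n_subunits": channel.spec.n_subunits,
        "residues_per_subunit": channel.spec.residues_per_subunit,
    }
    return ToyTrajectory(channel=channel, coordinates=coords,
                         displacements=disp, ground_truth=ground_truth)


# ---------------------------------------------------------------------------
# docking-pose ensembles

POSE_TABLE_FIXED_COLUMNS = ["pose_id", "receptor_cluster", "ligand_state",
                            "energy"]


@dataclass(frozen=True)
class PoseMode:
    """One planted binding mode: a coordinate center plus an energy level."""

    center: np.ndarray               # (n_atoms, 3)
    energy: float                    # kcal/mol
    n_poses: int
    spread_sd: float                 # A, isotropic scatter about the center

    def __post_init__(self) -> None:
        if self.n_poses < 1:
            raise ValueError("n_poses must be >= 1")
        if self.spread_sd <= 0:
            raise ValueError("spread_sd must be > 0")
        if not np.isfinite(self.energy):
            raise ValueError("energy must be finite")
        object.__setattr__(self, "center",
                           np.atleast_2d(np.asarray(self.center, dtype=float)))


@dataclass(frozen=True)
class PlantedPoseModel:
    modes: tuple[PoseMode, ...]
    receptor_cluster_id: str = "1"
    ligand_state_id: str = "Z(eea)"
    energy_jitter_sd: float = 0.05   # kcal/mol

    def __post_init__(self) -> None:
        if not self.modes:
            raise ValueError("at least one mode is required")
        shapes = {m.center.shape for m in self.modes}
        if len(shapes) != 1:
            raise ValueError("all modes must share the same atom count")


def generate_pose_ensemble(model: PlantedPoseModel,
                           seed: int) -> tuple[pd.DataFrame, dict]:
    """Sample a pose table from planted modes.

    Returns the table in the package's pose-table dialect (fixed columns
    ``pose_id, receptor_cluster, ligand_state, energy`` followed by
    ``x0,y0,z0,x1,...`` coordinate triplets) and a ground-truth dict mapping
    pose ids to their generating mode.
    """
    rng = np.random.default_rng(seed)
    n_atoms = model.modes[0].center.shape[0]
    rows = []
    membership: dict[str, int] = {}
    pose_counter = 0
    for mode_index, mode in enumerate(model.modes):
        for _ in range(mode.n_poses):
            pose_id = f"pose{pose_counter:05d}"
            pose_counter += 1
            energy = mode.energy + model.energy_jitter_sd * rng.standard_normal()
            xyz = mode.center + mode.spread_sd * rng.standard_normal((n_atoms, 3))
            rows.append([pose_id, model.receptor_cluster_id,
                         model.ligand_state_id, energy, *xyz.ravel()])
            membership[pose_id] = mode_index
    coord_cols = [f"{ax}{i}" for i in range(n_atoms) for ax in "xyz"]
    table = pd.DataFrame(rows, columns=POSE_TABLE_FIXED_COLUMNS + coord_cols)
    ground_truth = {
        "mode_of_pose": membership,
        "mode_energies": [m.energy for m in model.modes],
        "mode_populations": [m.n_poses / sum(m.n_poses for m in model.modes)
                             for m in model.modes],
        "seed": seed,
    }
    return table, ground_truth
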