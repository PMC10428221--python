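"""Trajectory ingestion and network-node extraction.

Network nodes are protein residues (anchored at their CA atom) and, when a
ligand is present, user-defined ligand fragments anchored at the fragment's
heavy-atom center of mass.  For every node the module extracts two per-frame
series: the anchor coordinate (used by the contact map and region detection)
and the side-chain center-of-mass displacement relative to its time mean
(the random variable entering the mutual-information estimator).

Side-chain COM is mass-weighted over heavy atoms beyond the backbone;
glycine, which has no heavy side-chain atom, falls back to its CA position so
every residue remains representable.  No superposition is applied by default;
an optional least-squares fit to the mean structure is available for inputs
with global drift and its use is recorded in the metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import MDAnalysis as mda
import numpy as np

from .geometry import superpose_frames

logger = logging.getLogger(__name__)

BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT", "OT1", "OT2"}

__all__ = [
    "TrajectoryMetadata",
    "NodeSeries",
    "LigandFragmentMap",
    "System",
    "load_system",
    "extract_node_series",
    "parse_frame_selection",
]


@dataclass(frozen=True)
class TrajectoryMetadata:
    n_frames: int
    frame_range_used: tuple[int, int]        # half-open [start, stop)
    system_label: str = ""
    ligand_present: bool = False
    superposed: bool = False

    def __post_init__(self) -> None:
        start, stop = self.frame_range_used
        if not (0 <= start < stop <= self.n_frames):
            raise ValueError(
                f"frame range [{start}, {stop}) not within [0, {self.n_frames})")

    @property
    def n_frames_used(self) -> int:
        start, stop = self.frame_range_used
        return stop - start


@dataclass
class NodeSeries:
    """Per-frame anchors and centered side-chain displacements of one node."""

    node_id: tuple[str, int, str]    # (chain/segid, resid, resname) or fragment
    anchor_xyz: np.ndarray           # (n_frames, 3) CA or fragment COM, A
    sidechain_com_xyz: np.ndarray    # (n_frames, 3), A
    is_ligand_fragment: bool = False

    @property
    def displacement(self) -> np.ndarray:
        """Side-chain COM minus its time mean; zero-mean by construction."""
        return self.sidechain_com_xyz - self.sidechain_com_xyz.mean(axis=0)

    @property
    def label(self) -> str:
        chain, resid, resname = self.node_id
        return f"{chain}:{resname}{resid}"


@dataclass(frozen=True)
class LigandFragmentMap:
    """Partition of the ligand's heavy atoms into named fragments."""

    fragments: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        if not self.fragments:
            raise ValueError("fragment map is empty")
        seen: set[str] = set()
        for frag, atoms in self.fragments.items():
            if not atoms:
                raise ValueError(f"fragment {frag!r} has no atoms")
            overlap = seen & set(atoms)
            if overlap:
                raise ValueError(
                    f"atoms {sorted(overlap)} appear in more than one fragment")
            seen |= set(atoms)

    @classmethod
    def from_dict(cls, mapping: dict[str, Sequence[str]]) -> "LigandFragmentMap":
        return cls({k: tuple(v) for k, v in mapping.items()})

    def validate_against(self, ligand_atoms: Iterable[str]) -> None:
        """Fragments must cover the ligand's heavy atoms exactly."""
        ligand = set(ligand_atoms)
        mapped = {a for atoms in self.fragments.values() for a in atoms}
        missing = ligand - mapped
        unknown = mapped - ligand
        if missing or unknown:
            raise ValueError(
                "fragment map does not partition the ligand heavy atoms: "
                f"uncovered={sorted(missing)}, unknown={sorted(unknown)}")


@dataclass
class System:
    """A frame-sliced trajectory ready for node extraction."""

    universe: mda.Universe
    frames: np.ndarray               # absolute frame indices used
    metadata: TrajectoryMetadata
    ligand_selection: str = "not protein"


def parse_frame_selection(selection, n_frames: int) -> np.ndarray:
    """Resolve a frame selection into absolute frame indices.

    Accepted forms: ``None`` (all frames), ``"last N"``, ``"first N"``,
    an ``(start, stop)`` half-open pair, or an explicit index sequence.
    """
    if selection is None:
        idx = np.arange(n_frames)
    elif isinstance(selection, str):
        parts = selection.split()
        if len(parts) == 2 and parts[0] in {"last", "first"}:
            n = int(parts[1])
            if n <= 0:
                raise ValueError("frame selection is empty")
            n = min(n, n_frames)
            idx = np.arange(n_frames - n, n_frames) if parts[0] == "last" \
                else np.arange(n)
        else:
            raise ValueError(f"unrecognized frame selection {selection!r}")
    elif isinstance(selection, tuple) and len(selection) == 2:
        start, stop = selection
        idx = np.arange(*slice(start, stop).indices(n_frames))
    else:
        idx = np.asarray(list(selection), dtype=int)
    if idx.size == 0:
        raise ValueError("frame selection is empty")
    if idx.min() < 0 or idx.max() >= n_frames:
        raise ValueError(
            f"frame selection outside [0, {n_frames}): "
            f"[{idx.min()}, {idx.max()}]")
    return idx


def load_system(topology, trajectory=None, frame_selection=None,
                system_label: str = "",
                ligand_selection: str = "not protein and not resname HOH WAT SOL",
                universe: mda.Universe | None = None) -> System:
    """Open a topology (+ trajectory) and slice the frames to analyse.

    ``topology`` is typically a PDB file and ``trajectory`` a DCD or XTC
    file; an already-built :class:`MDAnalysis.Universe` may be supplied via
    ``universe`` instead (the in-memory path used by the synthetic module).
    """
    if universe is None:
        try:
            if trajectory is None:
                universe = mda.Universe(str(topology))
            else:
                universe = mda.Universe(str(topology), str(trajectory))
        except (OSError, ValueError) as exc:
            raise IOError(f"could not load system from {topology!r} / "
                          f"{trajectory!r}: {exc}") from exc
    n_frames = universe.trajectory.n_frames
    frames = parse_frame_selection(frame_selection, n_frames)
    ligand = universe.select_atoms(ligand_selection)
    meta = TrajectoryMetadata(
        n_frames=n_frames,
        frame_range_used=(int(frames.min()), int(frames.max()) + 1),
        system_label=system_label,
        ligand_present=ligand.n_atoms > 0,
    )
    logger.info("loaded system %s: %d atoms, %d/%d frames, ligand=%s",
                system_label or "<unnamed>", universe.atoms.n_atoms,
                frames.size, n_frames, meta.ligand_present)
    return System(universe=universe, frames=frames, metadata=meta,
                  ligand_selection=ligand_selection)


def _heavy(group: mda.AtomGroup) -> mda.AtomGroup:
    names = np.asarray(group.names, dtype=str)
    mask = ~np.char.startswith(np.char.upper(names), "H")
    if hasattr(group, "elements"):
        mask &= np.char.upper(np.asarray(group.elements, dtype=str)) != "H"
    return group[mask]


def _residue_nodes(protein: mda.AtomGroup):
    """Per residue: (node_id, CA index, side-chain heavy indices, masses)."""
    nodes = []
    for res in protein.residues:
        ca = res.atoms.select_atoms("name CA")
        if ca.n_atoms != 1:
            raise ValueError(
                f"residue {res.segid}:{res.resname}{res.resid} has "
                f"{ca.n_atoms} CA atoms (expected exactly 1)")
        side = _heavy(res.atoms)
        side = side[~np.isin(side.names, list(BACKBONE_NAMES))]
        if side.n_atoms == 0:          # glycine and friends: fall back to CA
            side = ca
        nodes.append(((str(res.segid), int(res.resid), str(res.resname)),
                      ca.ix[0], side.ix, side.masses))
    return nodes


def extract_node_series(system: System,
                        ligand_map: LigandFragmentMap | dict | None = None,
                        superpose: bool = False,
                        protein_selection: str = "protein or name CA",
                        ) -> list[NodeSeries]:
    """Extract one :class:`NodeSeries` per residue plus one per ligand fragment.

    Node order is residue order in the topology followed by fragment-map
    order, and is stable across calls.  With ``superpose=True`` the
    trajectory is least-squares fitted to its time-mean structure on the
    protein anchors before extraction (in-memory copy; the input files are
    untouched).
    """
    u = system.universe
    protein = u.select_atoms(protein_selection)
    if protein.n_residues == 0:
        raise ValueError("no protein residues selected")
    if isinstance(ligand_map, dict):
        ligand_map = LigandFragmentMap.from_dict(ligand_map)

    if superpose:
        from MDAnalysis.coordinates.memory import MemoryReader

        coords = np.array([system.universe.trajectory[int(f)].positions.copy()
                           for f in system.frames], dtype=float)
        coords = superpose_frames(coords, fit_indices=protein.ix)
        u = mda.Merge(system.universe.atoms)
        u.load_new(coords.astype(np.float32), format=MemoryReader)
        frames = np.arange(coords.shape[0])
        logger.info("applied least-squares superposition to the mean structure")
        protein = u.select_atoms(protein_selection)
    else:
        frames = system.frames

    res_nodes = _residue_nodes(protein)

    frag_defs = []
    if ligand_map is not None:
        ligand = _heavy(u.select_atoms(system.ligand_selection))
        if ligand.n_atoms == 0:
            raise ValueError("ligand_map given but no ligand atoms found")
        ligand_map.validate_against(ligand.names)
        lig_segid = str(ligand.segids[0]) if len(ligand.segids) else "L"
        for frag_name, atom_names in ligand_map.fragments.items():
            sel = ligand[np.isin(ligand.names, list(atom_names))]
            frag_defs.append(((lig_segid, 0, frag_name), sel.ix, sel.masses))

    n_used = len(frames)
    n_res, n_frag = len(res_nodes), len(frag_defs)
    anchors = np.empty((n_res + n_frag, n_used, 3))
    side_com = np.empty((n_res + n_frag, n_used, 3))

    for t, f in enumerate(frames):
        pos = u.trajectory[int(f)].positions
        for i, (_, ca_ix, side_ix, masses) in enumerate(res_nodes):
            anchors[i, t] = pos[ca_ix]
            side_com[i, t] = np.average(pos[side_ix], axis=0, weights=masses)
        for j, (_, atom_ix, masses) in enumerate(frag_defs):
            com = np.average(pos[atom_ix], axis=0, weights=masses)
            anchors[n_res + j, t] = com
            side_com[n_res + j, t] = com

    out: list[NodeSeries] = []
    for i, (node_id, *_rest) in enumerate(res_nodes):
        out.append(NodeSeries(node_id=node_id, anchor_xyz=anchors[i],
                              sidechain_com_xyz=side_com[i]))
    for j, (node_id, *_rest) in enumerate(frag_defs):
        out.append(NodeSeries(node_id=node_id, anchor_xyz=anchors[n_res + j],
                              sidechain_com_xyz=side_com[n_res + j],
                              is_ligand_fragment=True))
    return out
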