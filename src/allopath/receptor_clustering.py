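"""Symmetry-aware k-means clustering of channel conformations.

Receptor conformations for ensemble docking are representative structures of
a trajectory clustered with an RMSD metric (k = 10 in the original
protocol, on the pore-lining S5/S6 residues).  A homotetramer poses an extra
subtlety: its four subunits are chemically equivalent, so a conformation and
its cyclic subunit relabelings describe the same physical state and the four
putative binding sites should be pooled.  That equivalence is handled by
*symmetry expansion*: every frame contributes one copy per cyclic relabeling
of the subunits before clustering, which makes cluster populations invariant
under relabeling of the input.

Clustering itself is k-means on superposed, flattened coordinates
(equivalent to the RMSD metric after alignment), with medoid representatives
and populations P_J over the augmented set.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans

from .geometry import rmsd, superpose_frames

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterSelection",
    "ReceptorClusterSet",
    "symmetry_expand",
    "kmeans_rmsd",
    "extract_selection_coordinates",
]

# pore-lining helices of the hERG homotetramer used in the original protocol
DEFAULT_RESIDUE_RANGES = (("S5", 546, 559), ("S6", 649, 667))


@dataclass(frozen=True)
class ClusterSelection:
    """Residue ranges (inclusive) and atom subset used for clustering."""

    residue_ranges: tuple[tuple[str, int, int], ...] = DEFAULT_RESIDUE_RANGES
    heavy_atoms_only: bool = True

    def __post_init__(self) -> None:
        if not self.residue_ranges:
            raise ValueError("selection has no residue ranges")
        for label, lo, hi in self.residue_ranges:
            if lo > hi:
                raise ValueError(f"range {label}: {lo} > {hi}")

    def mdanalysis_selection(self) -> str:
        parts = [f"resid {lo}:{hi}" for _, lo, hi in self.residue_ranges]
        sel = "(" + " or ".join(parts) + ")"
        if self.heavy_atoms_only:
            sel += " and not name H*"
        return sel


def extract_selection_coordinates(universe, selection: ClusterSelection,
                                  frames=None) -> tuple[np.ndarray, list[np.ndarray]]:
    """Pull (n_frames, n_atoms, 3) coordinates of the selection plus the
    per-subunit atom index groups (one array per segment, congruent order)."""
    group = universe.select_atoms(selection.mdanalysis_selection())
    if group.n_atoms == 0:
        raise ValueError(
            f"selection {selection.mdanalysis_selection()!r} matches no atoms")
    if frames is None:
        frames = range(universe.trajectory.n_frames)
    coords = np.array([universe.trajectory[int(f)].positions[group.ix]
                       for f in frames], dtype=float)
    seg_groups = []
    local_index = {ix: k for k, ix in enumerate(group.ix)}
    for seg in universe.segments:
        seg_atoms = [local_index[ix] for ix in seg.atoms.ix if ix in local_index]
        if seg_atoms:
            seg_groups.append(np.array(seg_atoms))
    return coords, seg_groups


def symmetry_expand(frames: np.ndarray,
                    subunit_indices: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Augment frames with their cyclic subunit relabelings.

    ``frames``: (n_frames, n_atoms, 3); ``subunit_indices``: per subunit, the
    atom indices belonging to it, in congruent within-subunit order.  Each
    frame yields ``n_subunits`` copies: copy ``r`` assigns subunit ``s`` the
    coordinates of subunit ``(s + r) mod n``.  Returns the augmented array
    (n_frames * n_subunits, n_atoms, 3) and a provenance array of
    (original_frame, rotation) pairs.
    """
    frames = np.asarray(frames, dtype=float)
    n_sub = len(subunit_indices)
    if n_sub == 0:
        raise ValueError("no subunits given")
    sizes = {len(ix) for ix in subunit_indices}
    if len(sizes) != 1:
        raise ValueError(
            f"subunits are not congruent (atom counts {sorted(sizes)})")
    if n_sub == 1:
        prov = np.stack([np.arange(len(frames)), np.zeros(len(frames), int)],
                        axis=1)
        return frames.copy(), prov

    n_frames, n_atoms, _ = frames.shape
    out = np.empty((n_frames * n_sub, n_atoms, 3))
    prov = np.empty((n_frames * n_sub, 2), dtype=int)
    item = 0
    for t in range(n_frames):
        for r in range(n_sub):
            frame = frames[t].copy()
            for s in range(n_sub):
                frame[subunit_indices[s]] = frames[t][
                    subunit_indices[(s + r) % n_sub]]
            out[item] = frame
            prov[item] = (t, r)
            item += 1
    return out, prov


@dataclass
class ReceptorClusterSet:
    """k-means clusters of (augmented) channel conformations."""

    k: int
    assignments: np.ndarray          # per augmented item
    populations: np.ndarray          # P_J, sums to 1
    medoid_indices: np.ndarray       # augmented item index per cluster
    provenance: np.ndarray           # (original_frame, rotation) per item
    aligned_coordinates: np.ndarray  # items after superposition
    seed: int

    def population_of(self, cluster: int) -> float:
        return float(self.populations[cluster])

    def populations_as_dict(self) -> dict[str, float]:
        return {str(j + 1): float(p) for j, p in enumerate(self.populations)}

    def representative_coordinates(self, cluster: int) -> np.ndarray:
        return self.aligned_coordinates[self.medoid_indices[cluster]]


def kmeans_rmsd(frames: np.ndarray, k: int = 10, seed: int = 0,
                n_init: int = 10) -> ReceptorClusterSet:
    """k-means with an RMSD-equivalent metric on superposed coordinates.

    Frames are rigid-body fitted to their iteratively refined mean, then
    clustered with seeded k-means++ on the flattened coordinates (Euclidean
    distance there is RMSD times sqrt(n_atoms)).  Representatives are exact
    medoids; populations count augmented items.  Identical input frames
    collapse to fewer than ``k`` effective clusters, reported with a warning.
    """
    frames = np.asarray(frames, dtype=float)
    n_items = frames.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n_items:
        raise ValueError(f"k={k} exceeds the {n_items} items to cluster")

    aligned = superpose_frames(frames)
    X = aligned.reshape(n_items, -1)

    n_unique = np.unique(np.round(X, 6), axis=0).shape[0]
    k_eff = min(k, n_unique)
    if k_eff < k:
        warnings.warn(
            f"only {n_unique} distinct conformations: using {k_eff} clusters "
            f"instead of {k}", stacklevel=2)

    km = KMeans(n_clusters=k_eff, random_state=seed, n_init=n_init)
    labels = km.fit_predict(X)

    populations = np.bincount(labels, minlength=k_eff) / n_items
    medoids = np.empty(k_eff, dtype=int)
    for j in range(k_eff):
        members = np.where(labels == j)[0]
        D = np.linalg.norm(X[members][:, None, :] - X[members][None, :, :],
                           axis=-1)
        medoids[j] = members[np.argmin(D.mean(axis=1))]

    prov = np.stack([np.arange(n_items), np.zeros(n_items, int)], axis=1)
    return ReceptorClusterSet(k=k_eff, assignments=labels,
                              populations=populations,
                              medoid_indices=medoids, provenance=prov,
                              aligned_coordinates=aligned, seed=seed)


def cluster_trajectory(universe, selection: ClusterSelection | None = None,
                       k: int = 10, seed: int = 0,
                       frames=None) -> ReceptorClusterSet:
    """End-to-end: select, symmetry-expand and cluster a trajectory."""
    selection = selection or ClusterSelection()
    coords, seg_groups = extract_selection_coordinates(universe, selection,
                                                       frames)
    augmented, prov = symmetry_expand(coords, seg_groups)
    result = kmeans_rmsd(augmented, k=k, seed=seed)
    result.provenance = prov
    return result
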