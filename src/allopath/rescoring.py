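"""Ensemble-docking post-processing: pose clustering and MaxP/MaxP' rescoring.

In the relaxed complex scheme, docking is repeated against an ensemble of
receptor conformations sampled by MD, for every relevant ligand state.  Raw
docking output ranks poses by the engine's score alone (``E_AD4``); this
module re-ranks them in two stages:

1.  Poses are grouped by an energy-ordered leader clustering at an RMSD
    threshold (default 2 A, no superposition — poses share the receptor
    frame).  Each cluster ``I`` keeps the lowest member energy ``E_I`` and a
    population ``P_I = n_I / N``.
2.  Clusters are scored by the Boltzmann-weighted population
    ``MaxP_I = P_I * exp(-E_I / kT)`` and, when receptor-conformation
    populations ``P_J`` are available (from trajectory clustering),
    ``MaxP'_{I,J} = P_J * P_I * exp(-E_I / kT)``, penalizing binding modes
    found only in rarely visited receptor conformations.

The equivalent additive form ``E_I - kT ln P_I`` yields identical rankings
and is reported alongside.  ``kT`` defaults to 0.593 kcal/mol (298 K).

The ligand considered in the original study (a piperidine-based hERG
activator) has two protonation forms (zwitterionic Z, neutral N), two
pseudorotation states of the ring (positions 3 and 4 swap equatorial/axial)
and two pyramidalization states of the ring nitrogen (position 1 equatorial
or axial) — eight states, of which the four with the position-1 substituent
equatorial are retained for docking.  :func:`enumerate_ligand_states`
reproduces that bookkeeping.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import rmsd

KT_ROOM_TEMPERATURE = 0.593  # kcal/mol at 298 K

__all__ = [
    "LigandState",
    "LigandStateSpace",
    "enumerate_ligand_states",
    "PoseRecord",
    "PoseCluster",
    "PoseClusterSet",
    "cluster_poses",
    "maxp_score",
    "maxp_prime_score",
    "ead4_score",
    "rescore_ensemble",
    "read_pose_table",
    "write_pose_table",
    "poses_from_table",
    "KT_ROOM_TEMPERATURE",
]


# ---------------------------------------------------------------------------
# ligand state enumeration


@dataclass(frozen=True)
class LigandState:
    protonation: str            # 'Z' or 'N'
    position1: str              # 'e'/'a': N-pyramidalization substituent
    position3: str              # 'e'/'a'
    position4: str              # 'e'/'a'

    @property
    def name(self) -> str:
        return f"{self.protonation}({self.position1}{self.position3}{self.position4})"


@dataclass(frozen=True)
class LigandStateSpace:
    """Factorized ligand state space with the syn constraint on ring 3/4.

    The two ring substituents at positions 3 and 4 are syn, so they always
    take opposite equatorial/axial orientations: pseudorotation toggles
    between (e, a) and (a, e).  Position 1 toggles independently with the
    nitrogen pyramidalization.
    """

    protonation_forms: tuple[str, ...] = ("Z", "N")
    position34_states: tuple[tuple[str, str], ...] = (("e", "a"), ("a", "e"))
    position1_states: tuple[str, ...] = ("e", "a")
    retained_position1: str = "e"   # axial R1 is sterically unfavourable

    @property
    def full_size(self) -> int:
        return (len(self.protonation_forms) * len(self.position34_states)
                * len(self.position1_states))


def enumerate_ligand_states(space: LigandStateSpace = LigandStateSpace()
                            ) -> tuple[list[LigandState], list[LigandState]]:
    """Return (full, retained) state lists in a stable order."""
    full = [
        LigandState(p, p1, p3, p4)
        for p in space.protonation_forms
        for p1 in space.position1_states
        for (p3, p4) in space.position34_states
    ]
    retained = [s for s in full if s.position1 == space.retained_position1]
    return full, retained


# ---------------------------------------------------------------------------
# pose records and clustering


@dataclass(frozen=True)
class PoseRecord:
    pose_id: str
    receptor_cluster: str
    ligand_state: str
    energy: float               # kcal/mol (docking score)
    coordinates: np.ndarray     # (n_atoms, 3) heavy atoms, A

    def __post_init__(self) -> None:
        if not np.isfinite(self.energy):
            raise ValueError(f"pose {self.pose_id}: non-finite energy")
        object.__setattr__(self, "coordinates",
                           np.atleast_2d(np.asarray(self.coordinates,
                                                    dtype=float)))


@dataclass
class PoseCluster:
    cluster_id: int
    member_ids: list[str]
    energy: float               # E_I: lowest member energy
    population: float           # P_I
    seed_id: str                # lowest-energy pose, the cluster reference
    receptor_cluster: str = ""
    ligand_state: str = ""


@dataclass
class PoseClusterSet:
    clusters: list[PoseCluster]
    rmsd_threshold: float
    n_poses: int

    def __post_init__(self) -> None:
        total = sum(len(c.member_ids) for c in self.clusters)
        if total != self.n_poses:
            raise ValueError("clusters do not partition the poses")

    @property
    def populations(self) -> np.ndarray:
        return np.array([c.population for c in self.clusters])


def cluster_poses(poses: Sequence[PoseRecord],
                  rmsd_threshold: float = 2.0) -> PoseClusterSet:
    """Energy-ordered leader clustering at an RMSD threshold.

    The best-energy unassigned pose seeds a cluster; every pose joins the
    first existing cluster whose seed is within ``rmsd_threshold`` (plain
    RMSD, no superposition: docked poses share the receptor frame).  The
    cluster energy is the lowest member energy — with energy-ordered seeding
    that is the seed's energy.  Deterministic for a given input.
    """
    if not poses:
        raise ValueError("no poses to cluster")
    shapes = {p.coordinates.shape for p in poses}
    if len(shapes) != 1:
        raise ValueError(f"pose atom sets differ: {sorted(shapes)}")
    order = sorted(range(len(poses)),
                   key=lambda i: (poses[i].energy, poses[i].pose_id))
    seeds: list[int] = []
    members: list[list[int]] = []
    for i in order:
        for k, s in enumerate(seeds):
            if rmsd(poses[i].coordinates, poses[s].coordinates) <= rmsd_threshold:
                members[k].append(i)
                break
        else:
            seeds.append(i)
            members.append([i])
    n = len(poses)
    clusters = [
        PoseCluster(
            cluster_id=k,
            member_ids=[poses[i].pose_id for i in idx],
            energy=min(poses[i].energy for i in idx),
            population=len(idx) / n,
            seed_id=poses[seeds[k]].pose_id,
            receptor_cluster=poses[seeds[k]].receptor_cluster,
            ligand_state=poses[seeds[k]].ligand_state,
        )
        for k, idx in enumerate(members)
    ]
    return PoseClusterSet(clusters=clusters, rmsd_threshold=rmsd_threshold,
                          n_poses=n)


# ---------------------------------------------------------------------------
# scoring


@dataclass
class RescoredRanking:
    """Total order over (receptor cluster, pose cluster) under one score."""

    method: str
    table: pd.DataFrame          # ranked, best first
    kT: float = KT_ROOM_TEMPERATURE

    @property
    def top(self) -> pd.Series:
        return self.table.iloc[0]


def _rank_table(rows: list[dict], method: str, kT: float) -> RescoredRanking:
    df = pd.DataFrame(rows)
    # descending score; ties by lower energy, then cluster identity
    df = df.sort_values(by=["score", "energy", "receptor_cluster",
                            "ligand_state", "cluster_id"],
                        ascending=[False, True, True, True, True],
                        kind="mergesort").reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return RescoredRanking(method=method, table=df, kT=kT)


def _cluster_rows(clusters: Iterable[PoseCluster]) -> list[dict]:
    return [
        {
            "receptor_cluster": c.receptor_cluster,
            "ligand_state": c.ligand_state,
            "cluster_id": c.cluster_id,
            "energy": c.energy,
            "population": c.population,
            "seed_pose": c.seed_id,
            "n_members": len(c.member_ids),
        }
        for c in clusters
    ]


def ead4_score(clusters: PoseClusterSet | Iterable[PoseCluster],
               kT: float = KT_ROOM_TEMPERATURE) -> RescoredRanking:
    """Rank clusters by raw docking energy alone (lower is better)."""
    cl = clusters.clusters if isinstance(clusters, PoseClusterSet) else list(clusters)
    rows = _cluster_rows(cl)
    for r in rows:
        r["score"] = -r["energy"]
    return _rank_table(rows, "E_AD4", kT)


def maxp_score(clusters: PoseClusterSet | Iterable[PoseCluster],
               kT: float = KT_ROOM_TEMPERATURE) -> RescoredRanking:
    """MaxP: score_I = P_I * exp(-E_I / kT), ranked descending.

    The additive equivalent E_I - kT ln P_I is reported as
    ``effective_energy``.
    """
    cl = clusters.clusters if isinstance(clusters, PoseClusterSet) else list(clusters)
    rows = _cluster_rows(cl)
    for r in rows:
        r["score"] = r["population"] * math.exp(-r["energy"] / kT)
        r["effective_energy"] = r["energy"] - kT * math.log(r["population"])
    return _rank_table(rows, "MaxP", kT)


def maxp_prime_score(clusters_by_receptor: Mapping[str, PoseClusterSet],
                     receptor_populations: Mapping[str, float],
                     kT: float = KT_ROOM_TEMPERATURE) -> RescoredRanking:
    """MaxP': score_{I,J} = P_J * P_I * exp(-E_I / kT) over all (I, J).

    ``receptor_populations`` must cover every receptor cluster referenced and
    sum to 1 (within tolerance); P_I is normalized within its own docking run
    (receptor cluster x ligand state), as produced by :func:`cluster_poses`.
    """
    missing = set(clusters_by_receptor) - set(receptor_populations)
    if missing:
        raise KeyError(
            f"no receptor population for cluster(s): {sorted(missing)}")
    total = sum(receptor_populations.values())
    if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-6):
        raise ValueError(f"receptor populations sum to {total}, expected 1")
    rows = []
    for J, cset in clusters_by_receptor.items():
        P_J = receptor_populations[J]
        for r in _cluster_rows(cset.clusters):
            r["receptor_cluster"] = str(J)  # the mapping key is authoritative
            r["receptor_population"] = P_J
            r["score"] = P_J * r["population"] * math.exp(-r["energy"] / kT)
            r["effective_energy"] = (r["energy"]
                                     - kT * math.log(r["population"] * P_J))
            rows.append(r)
    return _rank_table(rows, "MaxP'", kT)


# ---------------------------------------------------------------------------
# pose-table I/O and the aggregated pipeline

POSE_TABLE_FIXED = ["pose_id", "receptor_cluster", "ligand_state", "energy"]


def write_pose_table(table: pd.DataFrame, path: str | Path,
                     sep: str = "\t") -> Path:
    path = Path(path)
    table.to_csv(path, sep=sep, index=False)
    return path


def read_pose_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read the TSV/CSV pose-table dialect (see module docstring of
    :mod:`allopath.synthetic` for the column layout)."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in POSE_TABLE_FIXED if c not in df.columns]
    if missing:
        raise ValueError(f"pose table {path} lacks columns {missing}")
    return df


def poses_from_table(table: pd.DataFrame) -> list[PoseRecord]:
    coord_cols = [c for c in table.columns if c not in POSE_TABLE_FIXED]
    n_atoms, rem = divmod(len(coord_cols), 3)
    if n_atoms == 0 or rem:
        raise ValueError("pose table must carry x/y/z triplets per atom")
    xyz = table[coord_cols].to_numpy(dtype=float).reshape(len(table), n_atoms, 3)
    return [
        PoseRecord(pose_id=str(row.pose_id),
                   receptor_cluster=str(row.receptor_cluster),
                   ligand_state=str(row.ligand_state),
                   energy=float(row.energy),
                   coordinates=xyz[i])
        for i, row in enumerate(table.itertuples(index=False))
    ]


def rescore_ensemble(table: pd.DataFrame,
                     receptor_populations: Mapping[str, float] | None = None,
                     rmsd_threshold: float = 2.0,
                     kT: float = KT_ROOM_TEMPERATURE) -> dict[str, RescoredRanking]:
    """Cluster per (receptor cluster, ligand state) docking run and rank.

    Pose clusters are computed within each run — cross-state RMSD is not
    meaningful because states have different atom identities — and the
    cluster tables are pooled into single rankings under E_AD4 and MaxP
    (and MaxP' when ``receptor_populations`` is given).
    """
    poses = poses_from_table(table)
    runs: dict[tuple[str, str], list[PoseRecord]] = {}
    for p in poses:
        runs.setdefault((p.receptor_cluster, p.ligand_state), []).append(p)

    all_clusters: list[PoseCluster] = []
    by_receptor: dict[str, list[PoseCluster]] = {}
    for (J, state), run_poses in sorted(runs.items()):
        cset = cluster_poses(run_poses, rmsd_threshold)
        all_clusters.extend(cset.clusters)
        by_receptor.setdefault(J, []).extend(cset.clusters)

    out = {
        "E_AD4": ead4_score(all_clusters, kT),
        "MaxP": maxp_score(all_clusters, kT),
    }
    if receptor_populations is not None:
        sets = {
            J: PoseClusterSet(clusters=cl, rmsd_threshold=rmsd_threshold,
                              n_poses=sum(len(c.member_ids) for c in cl))
            for J, cl in by_receptor.items()
        }
        out["MaxP'"] = maxp_prime_score(sets, receptor_populations, kT)
    return out
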