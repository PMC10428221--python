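"""Ligand-state bookkeeping, pose clustering and MaxP/MaxP' ranking."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from allopath.rescoring import (KT_ROOM_TEMPERATURE, LigandStateSpace,
                                PoseClusterSet, PoseRecord, cluster_poses,
                                ead4_score, enumerate_ligand_states,
                                maxp_prime_score, maxp_score,
                                poses_from_table, read_pose_table,
                                rescore_ensemble, write_pose_table)


class TestLigandStates:
    def test_full_enumeration_has_eight_states(self):
        full, retained = enumerate_ligand_states()
        assert len(full) == 8
        assert len({s.name for s in full}) == 8

    def test_retained_states_and_names(self):
        _, retained = enumerate_ligand_states()
        assert [s.name for s in retained] == ["Z(eea)", "Z(eae)",
                                              "N(eea)", "N(eae)"]
        # syn constraint: positions 3 and 4 always opposite
        for s in retained:
            assert {s.position3, s.position4} == {"e", "a"}

    def test_single_protonation_form(self):
        space = LigandStateSpace(protonation_forms=("Z",))
        full, retained = enumerate_ligand_states(space)
        assert len(full) == 4 and len(retained) == 2


def _pose(pid, energy, xyz, receptor="1", state="Z(eea)"):
    return PoseRecord(pose_id=pid, receptor_cluster=receptor,
                      ligand_state=state, energy=energy,
                      coordinates=np.asarray(xyz, dtype=float))


class TestClusterPoses:
    def test_tight_ensemble_single_cluster(self):
        poses = [_pose(f"p{i}", -5.0 + 0.01 * i, np.full((3, 3), 0.1 * i))
                 for i in range(10)]
        cs = cluster_poses(poses, rmsd_threshold=2.0)
        assert len(cs.clusters) == 1
        assert cs.clusters[0].population == 1.0
        assert cs.clusters[0].energy == -5.0

    def test_cluster_energy_is_member_minimum(self):
        poses = ([_pose(f"a{i}", -6.0 + 0.1 * i, np.zeros((2, 3)))
                  for i in range(5)]
                 + [_pose(f"b{i}", -8.0 + 0.1 * i, np.full((2, 3), 10.0))
                    for i in range(3)])
        cs = cluster_poses(poses)
        assert len(cs.clusters) == 2
        for c in cs.clusters:
            for pid in c.member_ids:
                energy = next(p.energy for p in poses if p.pose_id == pid)
                assert c.energy <= energy
        # clusters are seeded best-energy first
        assert cs.clusters[0].energy == -8.0

    def test_atom_mismatch_rejected(self):
        with pytest.raises(ValueError, match="atom sets differ"):
            cluster_poses([_pose("a", -1.0, np.zeros((2, 3))),
                           _pose("b", -1.0, np.zeros((3, 3)))])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000),
           st.integers(min_value=1, max_value=40))
    def test_partition_and_normalization_invariants(self, seed, n):
        rng = np.random.default_rng(seed)
        poses = [_pose(f"p{i}", float(rng.uniform(-10, -2)),
                       rng.uniform(-6, 6, (4, 3))) for i in range(n)]
        cs = cluster_poses(poses)
        ids = [pid for c in cs.clusters for pid in c.member_ids]
        assert sorted(ids) == sorted(p.pose_id for p in poses)
        assert cs.populations.sum() == pytest.approx(1.0)
        assert all(c.population > 0 for c in cs.clusters)


class TestScoring:
    def _two_clusters(self, energies, populations):
        n = 100
        counts = [round(p * n) for p in populations]
        clusters = []
        from allopath.rescoring import PoseCluster

        for k, (e, c) in enumerate(zip(energies, counts)):
            clusters.append(PoseCluster(
                cluster_id=k, member_ids=[f"c{k}_{i}" for i in range(c)],
                energy=e, population=c / n, seed_id=f"c{k}_0",
                receptor_cluster="1", ligand_state="Z(eea)"))
        return PoseClusterSet(clusters=clusters, rmsd_threshold=2.0,
                              n_poses=sum(counts))

    def test_monotone_in_population(self):
        cs = self._two_clusters([-8.0, -8.0], [0.9, 0.1])
        r = maxp_score(cs)
        assert r.top.population == 0.9

    def test_monotone_in_energy(self):
        cs = self._two_clusters([-8.0, -6.0], [0.5, 0.5])
        r = maxp_score(cs)
        assert r.top.energy == -8.0

    def test_hand_evaluated_formula(self):
        """P=(0.2,0.8), E=(-9.0,-8.5), kT=0.593 checked against direct eval."""
        cs = self._two_clusters([-9.0, -8.5], [0.2, 0.8])
        r = maxp_score(cs, kT=0.593)
        s0 = 0.2 * math.exp(9.0 / 0.593)
        s1 = 0.8 * math.exp(8.5 / 0.593)
        assert r.table.score.tolist() == pytest.approx(
            sorted([s0, s1], reverse=True))
        assert r.top.energy == (-9.0 if s0 > s1 else -8.5)

    def test_maxp_prime_receptor_population_weighting(self):
        """Identical pose clusters under P_J = 0.173 vs 0.056: the better
        sampled receptor conformation wins."""
        cs = self._two_clusters([-8.0], [1.0])
        by_receptor = {"3": cs, "7": cs}
        r = maxp_prime_score(by_receptor,
                             {"3": 0.173, "7": 0.056, "rest": 0.771})
        assert r.top.receptor_cluster == "3"
        assert r.table.score.iloc[0] / r.table.score.iloc[1] == pytest.approx(
            0.173 / 0.056)

    def test_maxp_prime_uniform_equals_maxp_order(self):
        cs = self._two_clusters([-9.0, -8.5], [0.2, 0.8])
        order_maxp = maxp_score(cs).table.cluster_id.tolist()
        r = maxp_prime_score({"1": cs, "2": cs}, {"1": 0.5, "2": 0.5})
        per_receptor = r.table[r.table.receptor_cluster == "1"]
        assert per_receptor.cluster_id.tolist() == order_maxp

    def test_maxp_prime_single_receptor_equals_maxp(self):
        cs = self._two_clusters([-9.0, -8.5], [0.2, 0.8])
        a = maxp_score(cs).table
        b = maxp_prime_score({"1": cs}, {"1": 1.0}).table
        assert a.cluster_id.tolist() == b.cluster_id.tolist()
        np.testing.assert_allclose(a.score, b.score)

    def test_missing_receptor_population_rejected(self):
        cs = self._two_clusters([-8.0], [1.0])
        with pytest.raises(KeyError, match="receptor population"):
            maxp_prime_score({"9": cs}, {"1": 1.0})
        with pytest.raises(ValueError, match="sum"):
            maxp_prime_score({"9": cs}, {"9": 0.4})

    def test_ead4_vs_maxp_disagreement(self):
        """A low-energy singleton vs a big slightly-worse cluster: E_AD4 and
        MaxP must disagree on the top rank."""
        cs = self._two_clusters([-9.0, -8.7], [0.01, 0.99])
        top_e = ead4_score(cs).top
        top_p = maxp_score(cs).top
        assert top_e.energy == -9.0
        assert top_p.energy == -8.7
        # sanity on the magnitudes: population factor 99 beats exp(0.3/kT)
        assert 99 > math.exp(0.3 / KT_ROOM_TEMPERATURE)


class TestEnsembleTableRoundtrip:
    def test_tsv_roundtrip_and_aggregated_rescoring(self, tmp_path):
        from allopath.synthetic import (PlantedPoseModel, PoseMode,
                                        generate_pose_ensemble)

        tables = []
        for receptor, state, e in [("3", "Z(eea)", -8.0),
                                   ("7", "Z(eae)", -9.0)]:
            model = PlantedPoseModel(
                modes=(PoseMode(np.zeros((4, 3)), e, 40, 0.3),
                       PoseMode(np.full((4, 3), 6.0), e + 0.5, 60, 0.3)),
                receptor_cluster_id=receptor, ligand_state_id=state)
            tables.append(generate_pose_ensemble(model, seed=int(receptor))[0])
        table = pd.concat(tables, ignore_index=True)
        path = write_pose_table(table, tmp_path / "poses.tsv")
        back = read_pose_table(path)
        assert len(back) == 200

        rankings = rescore_ensemble(back, receptor_populations={"3": 0.7,
                                                                "7": 0.3})
        assert set(rankings) == {"E_AD4", "MaxP", "MaxP'"}
        # every (receptor, state) run contributes two clusters
        assert len(rankings["MaxP"].table) == 4
        assert rankings["E_AD4"].top.energy <= rankings["MaxP"].top.energy

    def test_malformed_table_rejected(self, tmp_path):
        bad = pd.DataFrame({"pose_id": ["a"], "energy": [1.0]})
        bad.to_csv(tmp_path / "bad.csv", index=False)
        with pytest.raises(ValueError, match="lacks columns"):
            read_pose_table(tmp_path / "bad.csv")
        lopsided = pd.DataFrame({"pose_id": ["a"], "receptor_cluster": ["1"],
                                 "ligand_state": ["Z"], "energy": [-1.0],
                                 "x0": [0.0], "y0": [0.0]})
        with pytest.raises(ValueError, match="triplets"):
            poses_from_table(lopsided)
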