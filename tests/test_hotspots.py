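"""Pose competence, pose clustering and SSM-position triage."""

import numpy as np
import pandas as pd
import pytest

from petkinlab import hotspots as hs
from petkinlab import synthetic as syn


def _scenario_with_poses(poses):
    return syn.HotspotScenario(
        residues=(syn.ResidueSpec(87, -1.9, 1.8),),
        poses=tuple(poses))


class TestCompetence:
    def test_all_distances_below_threshold(self):
        pose_set, _, _ = syn.simulate_structures_and_tables(
            _scenario_with_poses([syn.PoseSpec(3.5, 3.0, 3.0)]))
        res = hs.filter_competent_poses(pose_set)
        assert res[0].competent
        d = res[0].distances[0]
        assert d[0] == pytest.approx(3.5, abs=1e-6)

    def test_single_long_distance_disqualifies(self):
        pose_set, _, _ = syn.simulate_structures_and_tables(
            _scenario_with_poses([syn.PoseSpec(4.5, 3.0, 3.0)]))
        assert not hs.filter_competent_poses(pose_set)[0].competent

    def test_threshold_comparison_is_strict(self):
        pose_set, _, _ = syn.simulate_structures_and_tables(
            _scenario_with_poses([syn.PoseSpec(4.0, 3.0, 3.0)]))
        assert not hs.filter_competent_poses(pose_set)[0].competent

    def test_matches_brute_force_distance_oracle(self, rng):
        specs = [syn.PoseSpec(float(rng.uniform(2.5, 5.5)),
                              float(rng.uniform(2.5, 5.5)),
                              float(rng.uniform(2.5, 5.5)))
                 for _ in range(20)]
        pose_set, _, _ = syn.simulate_structures_and_tables(
            _scenario_with_poses(specs))
        results = hs.filter_competent_poses(pose_set)
        og = pose_set.receptor_atom(160, "OG")
        n87 = pose_set.receptor_atom(87, "N")
        n161 = pose_set.receptor_atom(161, "N")
        for p, res in enumerate(results):
            c = pose_set.poses.coord[p][0]
            o = pose_set.poses.coord[p][1]
            expect = (np.linalg.norm(c - og) < 4.0
                      and np.linalg.norm(o - n87) < 4.0
                      and np.linalg.norm(o - n161) < 4.0)
            assert res.competent == expect

    def test_invariant_under_joint_rigid_transform(self):
        pose_set, _, _ = syn.simulate_structures_and_tables(
            _scenario_with_poses([syn.PoseSpec(3.5, 3.0, 3.0),
                                  syn.PoseSpec(4.6, 3.0, 3.0)]))
        before = [r.competent for r in hs.filter_competent_poses(pose_set)]
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0],
                        [0, 0, 1.0]])
        shift = np.array([5.0, -3.0, 11.0])
        pose_set.receptor.coord = pose_set.receptor.coord @ rot.T + shift
        pose_set.poses.coord = pose_set.poses.coord @ rot.T + shift
        after = [r.competent for r in hs.filter_competent_poses(pose_set)]
        assert before == after

    def test_missing_catalytic_atom_named(self):
        pose_set, _, _ = syn.simulate_structures_and_tables(
            _scenario_with_poses([syn.PoseSpec()]))
        site = hs.CatalyticSite(nucleophile_res=999)
        with pytest.raises(ValueError, match="999"):
            hs.filter_competent_poses(pose_set, site=site)


class TestClustering:
    def test_duplicate_poses_collapse_to_one_cluster(self):
        pose_set, _, _ = syn.simulate_structures_and_tables(
            _scenario_with_poses([syn.PoseSpec(), syn.PoseSpec()]))
        clusters = hs.cluster_poses(pose_set)
        assert len(clusters) == 1
        assert set(clusters[0].members) == {0, 1}

    def test_distant_poses_separate(self):
        pose_set, _, _ = syn.simulate_structures_and_tables(
            _scenario_with_poses([syn.PoseSpec(),
                                  syn.PoseSpec(shift=(5.0, 0, 0))]))
        assert len(hs.cluster_poses(pose_set)) == 2

    def test_matches_brute_force_leader_oracle(self, rng):
        specs = [syn.PoseSpec(score=float(rng.normal()),
                              shift=tuple(rng.uniform(-2, 2, 3)))
                 for _ in range(10)]
        pose_set, _, _ = syn.simulate_structures_and_tables(
            _scenario_with_poses(specs))
        clusters = hs.cluster_poses(pose_set, rmsd_threshold=1.0)
        # independent leader clustering over an explicit RMSD matrix
        heavy = pose_set.poses.element != "H"
        coords = pose_set.poses.coord[:, heavy, :]
        n = len(specs)
        rmsd = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                rmsd[i, j] = np.sqrt(np.mean(
                    np.sum((coords[i] - coords[j]) ** 2, axis=1)))
        order = np.argsort([s.score for s in specs], kind="stable")
        expected, assigned = [], set()
        for leader in order:
            if leader in assigned:
                continue
            members = tuple(m for m in range(n)
                            if m not in assigned
                            and rmsd[leader, m] <= 1.0)
            assigned.update(members)
            expected.append((int(leader), members))
        assert [(c.leader, c.members) for c in clusters] == expected

    def test_clusters_partition_the_pose_set(self, rng):
        specs = [syn.PoseSpec(shift=tuple(rng.uniform(-3, 3, 3)))
                 for _ in range(15)]
        pose_set, _, _ = syn.simulate_structures_and_tables(
            _scenario_with_poses(specs))
        clusters = hs.cluster_poses(pose_set)
        members = [m for c in clusters for m in c.members]
        assert sorted(members) == list(range(15))


class TestSelection:
    def test_published_triage_selects_87_238_280(self, hotspot_scenario):
        _, energy, cons = syn.simulate_structures_and_tables(
            hotspot_scenario)
        report = hs.select_ssm_positions(
            energy, cons,
            exclusions={208: "prior substitutions reduced activity"})
        assert report.selected_positions == [87, 238, 280]
        # Trp185 is a strong hotspot but highly conserved (rate ~0.7)
        row = report.table.loc[185]
        assert row["hotspot"] and row["conserved"] and not row["selected"]

    def test_dg_threshold_edge_is_inclusive(self):
        energy = pd.DataFrame({"residue": [10], "mean_dg": [-1.0]})
        cons = pd.DataFrame({"position": [10], "rate": [2.0]})
        report = hs.select_ssm_positions(energy, cons)
        assert bool(report.table.loc[10, "hotspot"])
        assert report.selected_positions == [10]

    def test_row_order_independence(self, hotspot_scenario):
        _, energy, cons = syn.simulate_structures_and_tables(
            hotspot_scenario)
        shuffled_e = energy.sample(frac=1, random_state=1)
        shuffled_c = cons.sample(frac=1, random_state=2)
        a = hs.select_ssm_positions(energy, cons).table
        b = hs.select_ssm_positions(shuffled_e, shuffled_c).table
        pd.testing.assert_frame_equal(a, b)

    def test_stricter_dg_threshold_never_adds_positions(self,
                                                        hotspot_scenario):
        _, energy, cons = syn.simulate_structures_and_tables(
            hotspot_scenario)
        loose = set(hs.select_ssm_positions(
            energy, cons, dg_threshold=-1.0).selected_positions)
        for thr in (-1.2, -1.5, -1.9, -2.5):
            strict = set(hs.select_ssm_positions(
                energy, cons, dg_threshold=thr).selected_positions)
            assert strict <= loose
            loose = strict

    def test_missing_conservation_positions_listed(self):
        energy = pd.DataFrame({"residue": [1, 2, 3],
                               "mean_dg": [-2.0, -2.0, -2.0]})
        cons = pd.DataFrame({"position": [1], "rate": [1.5]})
        with pytest.raises(ValueError, match=r"\[2, 3\]"):
            hs.select_ssm_positions(energy, cons)

    def test_exclusion_requires_reason(self):
        energy = pd.DataFrame({"residue": [5], "mean_dg": [-2.0]})
        cons = pd.DataFrame({"position": [5], "rate": [1.5]})
        with pytest.raises(ValueError, match="reason"):
            hs.select_ssm_positions(energy, cons, exclusions={5: "  "})


class TestFileRoundTrip:
    def test_fixture_round_trips_through_pdb_and_csv(self, tmp_path,
                                                     hotspot_scenario):
        paths = syn.write_hotspot_fixture(hotspot_scenario, tmp_path)
        pose_set = hs.load_pose_set(paths["receptor"], paths["poses"],
                                    paths["esters"], paths["scores"])
        res = hs.filter_competent_poses(pose_set)
        assert res[0].competent
        report = hs.select_ssm_positions(
            hs.read_energy_csv(paths["energy"]),
            hs.read_conservation_csv(paths["conservation"]),
            exclusions={208: "prior substitutions reduced activity"})
        assert report.selected_positions == [87, 238, 280]
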