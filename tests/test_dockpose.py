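"""Pose ingestion, centers of mass, and binding-region clustering."""

import numpy as np
import pandas as pd
import pytest

from bindgap import dockpose, synthgen
from bindgap.dockpose import (
    POSE_COLUMNS,
    PoseFormatError,
    center_of_mass,
    cluster_poses,
    read_pose_table,
    read_vina_poses,
    write_pose_table,
)

VINA_FIXTURE = """\
MODEL 1
REMARK VINA RESULT:      -7.1      0.000      0.000
ATOM      1  C   LIG A   1       1.000   2.000   3.000  0.00  0.00    +0.000 C
ATOM      2  C   LIG A   1       3.000   2.000   3.000  0.00  0.00    +0.000 C
ENDMDL
MODEL 2
REMARK VINA RESULT:      -6.3      1.200      2.100
ATOM      1  N   LIG A   1       1.000   2.000   3.000  0.00  0.00    +0.000 NA
ENDMDL
"""


def pose_frame(rows):
    return pd.DataFrame(rows, columns=POSE_COLUMNS)


class TestPoseTable:
    def test_roundtrip(self, tmp_path):
        df = pose_frame(
            [
                ["c1", 1, 0.0, 0.0, 0.0, -7.0],
                ["c1", 2, 1.0, 0.5, 0.0, -6.5],
                ["c2", 1, 9.9, 0.0, 1.0, -8.1],
            ]
        )
        path = tmp_path / "poses.tsv"
        write_pose_table(df, path)
        back = read_pose_table(path)
        pd.testing.assert_frame_equal(df.astype({"pose_id": back["pose_id"].dtype}), back)

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("compound_id\tpose_id\tx\ty\tz\nc1\t1\t0\t0\t0\n")
        with pytest.raises(PoseFormatError, match="energy_kcal_mol"):
            read_pose_table(path)

    def test_non_numeric_and_duplicates(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "compound_id\tpose_id\tx\ty\tz\tenergy_kcal_mol\nc1\t1\t0\t0\toops\t-7\n"
        )
        with pytest.raises(PoseFormatError, match="non-numeric"):
            read_pose_table(path)
        path.write_text(
            "compound_id\tpose_id\tx\ty\tz\tenergy_kcal_mol\n"
            "c1\t1\t0\t0\t0\t-7\nc1\t1\t1\t1\t1\t-6\n"
        )
        with pytest.raises(PoseFormatError, match="duplicate"):
            read_pose_table(path)


class TestVinaReader:
    def test_two_model_fixture(self, tmp_path):
        path = tmp_path / "lig.pdbqt"
        path.write_text(VINA_FIXTURE)
        poses = read_vina_poses(path)
        assert len(poses) == 2
        assert poses["energy_kcal_mol"].tolist() == [-7.1, -6.3]
        assert poses["compound_id"].unique().tolist() == ["lig"]

    def test_single_atom_com_is_its_coordinates(self, tmp_path):
        path = tmp_path / "lig.pdbqt"
        path.write_text(VINA_FIXTURE)
        poses = read_vina_poses(path)
        assert poses.iloc[1][["x", "y", "z"]].tolist() == [1.0, 2.0, 3.0]

    def test_missing_result_remark(self, tmp_path):
        path = tmp_path / "bad.pdbqt"
        path.write_text(
            "MODEL 1\nATOM      1  C   LIG A   1       1.000   2.000   3.000"
            "  0.00  0.00    +0.000 C\nENDMDL\n"
        )
        with pytest.raises(PoseFormatError, match="VINA RESULT"):
            read_vina_poses(path)

    def test_cross_format_equivalence(self, tmp_path):
        # PDBQT poses re-exported as a pose table cluster identically
        path = tmp_path / "lig.pdbqt"
        path.write_text(VINA_FIXTURE)
        poses = read_vina_poses(path)
        tsv = tmp_path / "poses.tsv"
        write_pose_table(poses, tsv)
        again = read_pose_table(tsv)
        c1 = cluster_poses(poses, cutoff=4.0)
        c2 = cluster_poses(again, cutoff=4.0)
        pd.testing.assert_frame_equal(c1.assignments, c2.assignments)


class TestCenterOfMass:
    def test_symmetric_pair(self):
        assert center_of_mass([("C", 0, 0, 0), ("C", 2, 0, 0)]) == (1.0, 0.0, 0.0)

    def test_single_atom(self):
        assert center_of_mass([("O", 1.5, -2.0, 0.25)]) == (1.5, -2.0, 0.25)

    def test_water_hand_value(self):
        # masses 15.999 / 1.008: x = 1.008*(0.96 - 0.24)/18.015 = 0.0403
        com = center_of_mass([("O", 0, 0, 0), ("H", 0.96, 0, 0), ("H", -0.24, 0.93, 0)])
        assert com[0] == pytest.approx(0.0403, abs=2e-4)

    def test_unknown_element(self):
        with pytest.raises(KeyError, match="unknown element"):
            center_of_mass([("Xx", 0, 0, 0)])

    def test_no_atoms(self):
        with pytest.raises(ValueError, match="zero atoms"):
            center_of_mass([])


def connected_components_clusters(poses, cutoff):
    """Brute-force single-linkage oracle: components of the <=cutoff graph."""
    coords = poses[["x", "y", "z"]].to_numpy(dtype=float)
    n = len(coords)
    adj = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1) <= cutoff
    labels = -np.ones(n, dtype=int)
    comp = 0
    for i in range(n):
        if labels[i] >= 0:
            continue
        stack = [i]
        while stack:
            j = stack.pop()
            if labels[j] >= 0:
                continue
            labels[j] = comp
            stack.extend(np.flatnonzero(adj[j] & (labels < 0)).tolist())
        comp += 1
    return labels


class TestClusterPoses:
    def test_common_com_single_cluster(self):
        df = pose_frame([["c", i, 1.0, 1.0, 1.0, -5.0 - i] for i in range(4)])
        assert cluster_poses(df, cutoff=4.0).n_clusters == 1

    def test_zero_cutoff_one_cluster_per_pose(self):
        df = pose_frame([["c", i, float(i), 0.0, 0.0, -5.0] for i in range(5)])
        assert cluster_poses(df, cutoff=0.0).n_clusters == 5

    def test_partition_property(self, planted_screen):
        _, _, poses = planted_screen
        clusters = cluster_poses(poses[POSE_COLUMNS], cutoff=4.0)
        assert clusters.summary["n_members"].sum() == len(poses)
        assert len(clusters.assignments) == len(poses)
        assert not clusters.assignments.duplicated(["compound_id", "pose_id"]).any()

    def test_cluster_ids_ascend_with_representative_energy(self, planted_screen):
        _, _, poses = planted_screen
        clusters = cluster_poses(poses[POSE_COLUMNS], cutoff=4.0)
        reps = clusters.summary.sort_values("cluster_id")["rep_energy_kcal_mol"]
        assert (np.diff(reps.to_numpy()) >= 0).all()
        assert clusters.summary["cluster_id"].tolist() == list(
            range(1, clusters.n_clusters + 1)
        )

    def test_row_order_invariance(self, planted_screen):
        _, _, poses = planted_screen
        shuffled = poses.sample(frac=1.0, random_state=99).reset_index(drop=True)
        a = cluster_poses(poses[POSE_COLUMNS], cutoff=4.0)
        b = cluster_poses(shuffled[POSE_COLUMNS], cutoff=4.0)
        pd.testing.assert_frame_equal(a.assignments, b.assignments)
        pd.testing.assert_frame_equal(a.summary, b.summary)

    @pytest.mark.parametrize("seed", range(5))
    def test_two_planted_sites_match_connected_components(self, seed):
        cfg = synthgen.DockSimConfig(
            n_sites=2,
            site_centers=np.array([[0.0, 0.0, 0.0], [20.0, 0.0, 0.0]]),
            site_scatter_sd=0.5,
            n_compounds=12,
            poses_per_compound=5,
            specific_fraction=0.0,
            seed=seed,
        )
        _, poses = synthgen.gen_poses(cfg)
        clusters = cluster_poses(poses[POSE_COLUMNS], cutoff=4.0)
        merged = clusters.poses_with_clusters(poses)
        assert clusters.n_clusters == 2
        # identical partition as single-linkage connected components
        cc = connected_components_clusters(merged, 4.0)
        assert (
            pd.crosstab(merged["cluster_id"], cc).to_numpy() > 0
        ).sum() == 2
        # and identical to the generator's truth assignment
        assert (
            pd.crosstab(merged["cluster_id"], merged["true_site"]).to_numpy() > 0
        ).sum() == 2
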