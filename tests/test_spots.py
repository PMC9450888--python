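"""Spot detection, clustering, assembly, encapsulation and classification."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linprog
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist

from exmfoci.image import VoxelGrid
from exmfoci.simulate import generate_structure_scene, match_to_ground_truth, render_volume
from exmfoci.spots import (
    ClassificationError,
    ClassRuleSet,
    EncapsulationParams,
    StructureCluster,
    assemble_structures,
    classify_counts,
    classify_structure,
    class_frequency_table,
    cluster_site_spots,
    continuity_test,
    crop_structure,
    detect_spots,
    encapsulation_test,
    subclassify_by_distance,
    three_channel_rules,
    two_channel_rules,
)
from exmfoci.units import ExmError

from conftest import DETECT_RADIUS_NM, QUALITY_THRESHOLD, detect_and_classify


def _render_points(points_nm, shape=(24, 60, 60), voxel=(250, 100, 100), noise=False, seed=0):
    spots = pd.DataFrame([{"channel": "c", "z": p[0], "y": p[1], "x": p[2]} for p in points_nm])
    return render_volume(
        spots, shape, voxel, ("c",), (300, 100, 100),
        background=20.0 if noise else 0.0, poisson_noise=noise,
        gaussian_noise_sd=2.0 if noise else 0.0,
        rng=np.random.default_rng(seed),
    ).channel("c")


class TestDetectSpots:
    def test_single_spot_recovered_within_half_voxel(self):
        pos = np.array([3050.0, 3020.0, 2980.0])
        grid = _render_points([pos])
        df = detect_spots(grid, DETECT_RADIUS_NM, 0.1)
        assert len(df) == 1
        err = np.abs(df[["z", "y", "x"]].to_numpy()[0] - pos)
        assert np.all(err <= 0.5 * np.array(grid.voxel_size))

    def test_constant_image_no_spots(self):
        grid = VoxelGrid(np.full((10, 20, 20), 5.0), (250, 100, 100))
        assert len(detect_spots(grid, DETECT_RADIUS_NM, 0.1)) == 0

    def test_radius_below_voxel_size_rejected(self):
        grid = VoxelGrid(np.zeros((10, 20, 20)), (250, 100, 100))
        with pytest.raises(ValueError, match="radius"):
            detect_spots(grid, 50.0, 0.1)

    def test_50_spots_all_recovered_no_false_positives(self):
        """Well-separated spots at default SNR: complete recovery, matched
        to ground truth by nearest neighbour."""
        rng = np.random.default_rng(42)
        pitch = 1400.0
        pts = []
        for gy in range(7):
            for gx in range(8):
                if len(pts) == 50:
                    break
                pts.append([
                    2000.0 + rng.uniform(-200, 200),
                    900.0 + gy * pitch + rng.uniform(-150, 150),
                    900.0 + gx * pitch + rng.uniform(-150, 150),
                ])
        pts = np.array(pts)
        grid = _render_points(pts, shape=(16, 100, 112), noise=True, seed=7)
        df = detect_spots(grid, DETECT_RADIUS_NM, QUALITY_THRESHOLD)
        assert len(df) == 50
        m = match_to_ground_truth(df[["z", "y", "x"]].to_numpy(), pts,
                                  2 * max(grid.voxel_size))
        assert (m >= 0).all()
        assert len(set(m)) == 50

    def test_raising_threshold_never_adds_spots(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(1500, 4500, (10, 3))
        grid = _render_points(pts, noise=True, seed=3)
        counts = [len(detect_spots(grid, DETECT_RADIUS_NM, thr))
                  for thr in (0.5, 5.0, 25.0, 80.0)]
        assert counts == sorted(counts, reverse=True)


class TestClusterSiteSpots:
    def test_chain_is_one_cluster(self):
        r = 1000.0
        pts = np.array([[0, 0, 0], [0, 0, 0.9 * r], [0, 0, 1.8 * r]])
        labels, cores = cluster_site_spots(pts, r)
        assert len(cores) == 1
        assert (labels == 0).all()

    def test_two_distant_spots_two_clusters(self):
        pts = np.array([[0, 0, 0], [0, 0, 1100.0]])
        labels, cores = cluster_site_spots(pts, 1000.0)
        assert len(cores) == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_partition(self, seed):
        """Oracle: connected components of the thresholded full distance
        matrix."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(50, 200))
        pts = rng.uniform(0, 20_000, (n, 3))
        r = float(rng.uniform(500, 3000))
        labels, cores = cluster_site_spots(pts, r)
        adj = cdist(pts, pts) <= r
        n_ref, ref = connected_components(adj, directed=False)
        assert len(cores) == n_ref
        # identical partitions up to label permutation
        pairs = {(a, b) for a, b in zip(labels, ref)}
        assert len(pairs) == n_ref

    def test_core_is_unweighted_centre_of_mass(self):
        pts = np.array([[0, 0, 0], [0, 0, 800.0], [0, 800.0, 0]])
        _labels, cores = cluster_site_spots(pts, 1000.0)
        assert np.allclose(cores[0], pts.mean(axis=0))


class TestAssembleStructures:
    def _one_core(self, partner_pts, radius=2000.0):
        site = np.array([[0.0, 0.0, 0.0]])
        labels, cores = cluster_site_spots(site, 500.0)
        return assemble_structures(site, labels, cores,
                                   {"p": np.asarray(partner_pts)}, radius)

    def test_partner_within_radius_attached(self):
        s = self._one_core([[0, 0, 1500.0]])
        assert s[0].partner_count("p") == 1

    def test_partner_beyond_radius_not_attached(self):
        s = self._one_core([[0, 0, 2500.0]])
        assert s[0].partner_count("p") == 0

    def test_matches_brute_force_all_pairs(self):
        rng = np.random.default_rng(1)
        site = rng.uniform(0, 30_000, (40, 3))
        partner = rng.uniform(0, 30_000, (200, 3))
        labels, cores = cluster_site_spots(site, 1200.0)
        structures = assemble_structures(site, labels, cores, {"p": partner}, 2000.0)
        d = cdist(cores, partner)
        for s in structures:
            expected = set(np.nonzero(d[s.structure_id] <= 2000.0)[0])
            assert set(s.member_indices["p"]) == expected

    def test_shared_partner_flagged(self):
        site = np.array([[0.0, 0, 0], [0.0, 0, 3000.0]])
        labels, cores = cluster_site_spots(site, 1000.0)
        structures = assemble_structures(site, labels, cores,
                                         {"p": np.array([[0.0, 0, 1500.0]])}, 2000.0)
        assert all(s.shared_members["p"].all() for s in structures)


class TestEncapsulation:
    def test_octahedral_satellites_encapsulate(self):
        r = 500.0
        sats = np.array([[r, 0, 0], [-r, 0, 0], [0, r, 0], [0, -r, 0], [0, 0, r], [0, 0, -r]])
        assert encapsulation_test(np.zeros(3), sats)

    def test_one_sided_satellites_do_not(self):
        sats = np.array([[0, 100, 500.0], [0, -100, 500.0], [100, 0, 500.0]])
        assert not encapsulation_test(np.zeros(3), sats)

    def test_too_few_satellites_false(self):
        sats = np.array([[0, 0, 500.0], [0, 0, -500.0]])
        assert not encapsulation_test(np.zeros(3), sats)

    def test_coplanar_ring_uses_angular_coverage(self):
        ang = np.linspace(0, 2 * np.pi, 6, endpoint=False)
        sats = np.stack([np.zeros(6), 500 * np.sin(ang), 500 * np.cos(ang)], axis=1)
        assert encapsulation_test(np.zeros(3), sats)
        # shifted far outside the ring: coverage below 180 degrees
        assert not encapsulation_test(np.array([0.0, 0.0, 2000.0]), sats)

    @pytest.mark.parametrize("seed", range(3))
    def test_agrees_with_lp_hull_oracle(self, seed):
        """Non-coplanar configurations against a linear-programming
        point-in-hull feasibility oracle."""
        rng = np.random.default_rng(seed)
        params = EncapsulationParams(coplanar_tol_nm=0.0)
        agree = 0
        n_cfg = 80
        for _ in range(n_cfg):
            sats = rng.uniform(-1000, 1000, (int(rng.integers(4, 9)), 3))
            core = rng.uniform(-800, 800, 3)
            n = len(sats)
            res = linprog(np.zeros(n), A_eq=np.vstack([sats.T, np.ones(n)]),
                          b_eq=np.concatenate([core, [1.0]]), bounds=[(0, None)] * n)
            oracle = res.status == 0
            got = encapsulation_test(core, sats, params)
            agree += got == oracle
        assert agree == n_cfg


class TestClassification:
    @pytest.mark.parametrize(
        "site, partner, enc, expected",
        [
            (1, 0, False, 1),
            (1, 1, False, 2),
            (2, 1, False, 3),
            (3, 4, False, 4),
            (1, 4, False, 4),  # many partners but not encapsulating
            (1, 6, True, 5),
        ],
    )
    def test_two_channel_default_taxonomy(self, site, partner, enc, expected):
        rules = two_channel_rules()
        assert rules.classify(site, {"53bp1": partner}, enc) == expected

    def test_class5_ring_via_geometry(self):
        ang = np.linspace(0, 2 * np.pi, 6, endpoint=False)
        sats = np.stack([np.zeros(6), 650 * np.sin(ang), 650 * np.cos(ang)], axis=1)
        rules = two_channel_rules()
        got = classify_counts(rules, 1, {"53bp1": 6}, core=np.zeros(3), satellites=sats)
        assert got == 5

    @pytest.mark.parametrize(
        "r, p, b, enc, expected",
        [
            (1, 0, 0, False, 1),
            (2, 2, 0, False, 4),   # multiple RAD51 + multiple 53BP1, no BRCA1
            (2, 4, 1, True, 9),    # all three, encapsulated by 53BP1
            (2, 4, 1, False, 8),
            (1, 2, 1, False, 7),
            (2, 0, 1, False, 10),
        ],
    )
    def test_three_channel_default_taxonomy(self, r, p, b, enc, expected):
        rules = three_channel_rules()
        assert rules.classify(r, {"53bp1": p, "brca1": b}, enc) == expected

    def test_rule_sets_validated_exhaustive(self):
        two_channel_rules().validate(max_count=8)
        three_channel_rules().validate(max_count=5)

    def test_gappy_rule_set_rejected(self):
        from exmfoci.spots import ClassRule

        with pytest.raises(ClassificationError, match="site=2"):
            ClassRuleSet(
                name="gappy", site_channel="s", partner_channels=("p",),
                rules=(ClassRule(1, (1, 1), (("p", 0, None),)),),
            )

    def test_classification_invariant_to_rigid_motion(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(0)
        rules = two_channel_rules()
        ang = np.linspace(0, 2 * np.pi, 5, endpoint=False)
        sats = np.stack([np.zeros(5), 700 * np.sin(ang), 700 * np.cos(ang)], axis=1)
        core = np.zeros(3)
        base = classify_counts(rules, 1, {"53bp1": 5}, core=core, satellites=sats)
        for _ in range(5):
            R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
            t = rng.uniform(-5000, 5000, 3)
            got = classify_counts(rules, 1, {"53bp1": 5},
                                  core=core @ R.T + t, satellites=sats @ R.T + t)
            assert got == base

    def test_frequency_table_sums_to_structures(self, structure_scene):
        grid, truth = structure_scene
        _dets, structures = detect_and_classify(grid)
        freq = class_frequency_table(structures)
        assert freq["count"].sum() == len(structures)


class TestDistanceSubclass:
    def _structure_with_sats(self, dist):
        ang = np.linspace(0, 2 * np.pi, 4, endpoint=False)
        sats = np.stack([np.zeros(4), dist * np.sin(ang), dist * np.cos(ang)], axis=1)
        return StructureCluster(
            0, "brca1", np.zeros(3), np.zeros((1, 3)), np.array([0]),
            members={"53bp1": sats}, member_indices={"53bp1": np.arange(4)},
        )

    def test_contracted_bin(self):
        assert subclassify_by_distance(self._structure_with_sats(300.0)) == "contracted"

    def test_control_like_bin(self):
        assert subclassify_by_distance(self._structure_with_sats(1900.0)) == "control_like"

    def test_extended_bin(self):
        assert subclassify_by_distance(self._structure_with_sats(2300.0)) == "extended"

    def test_overflow_bin_warns(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="exmfoci.spots"):
            assert subclassify_by_distance(self._structure_with_sats(4000.0)) == "overflow"
        assert "outside all bins" in caplog.text

    def test_no_satellites_raises(self):
        s = StructureCluster(0, "brca1", np.zeros(3), np.zeros((1, 3)), np.array([0]),
                             members={"53bp1": np.empty((0, 3))})
        with pytest.raises(ExmError):
            subclassify_by_distance(s)


class TestContinuity:
    def _bridged(self, bridge):
        zz, yy, xx = np.mgrid[:16, :16, :48].astype(float)
        vol = np.exp(-((zz - 8) ** 2 + (yy - 8) ** 2 + (xx - 12) ** 2) / 10)
        vol += np.exp(-((zz - 8) ** 2 + (yy - 8) ** 2 + (xx - 36) ** 2) / 10)
        if bridge:
            on_line = (np.abs(zz - 8) < 1.5) & (np.abs(yy - 8) < 1.5) & (xx > 10) & (xx < 38)
            vol = np.maximum(vol, 0.8 * on_line)
        grid = VoxelGrid(vol, (100, 100, 100))
        pts = np.array([[850.0, 850.0, 1250.0], [850.0, 850.0, 3650.0]])
        return grid, pts

    def test_bridged_spots_continuous(self):
        grid, pts = self._bridged(True)
        assert continuity_test(grid, pts) == "continuous"

    def test_isolated_spots_discontinuous(self):
        grid, pts = self._bridged(False)
        assert continuity_test(grid, pts) == "discontinuous"

    def test_single_spot_rejected(self):
        grid, pts = self._bridged(False)
        with pytest.raises(ExmError):
            continuity_test(grid, pts[:1])


class TestCrop:
    def test_5um_box_at_100nm_voxels_is_50_cubed(self):
        grid = VoxelGrid(np.random.default_rng(0).uniform(size=(80, 80, 80)),
                         (100, 100, 100))
        crop = crop_structure(grid, np.array([4000.0, 4000.0, 4000.0]), 5000.0)
        assert crop.data.shape == (50, 50, 50)

    def test_corner_crop_zero_padded_full_size(self):
        grid = VoxelGrid(np.ones((40, 40, 40)), (100, 100, 100))
        crop = crop_structure(grid, np.array([0.0, 0.0, 0.0]), 3000.0)
        assert crop.data.shape == (30, 30, 30)
        assert crop.data[0, 0, 0] == 0.0  # padding
        assert crop.data[-1, -1, -1] == 1.0

    def test_recrop_idempotent(self):
        grid = VoxelGrid(np.random.default_rng(1).uniform(size=(60, 60, 60)),
                         (100, 100, 100))
        core = np.array([3000.0, 3000.0, 3000.0])
        c1 = crop_structure(grid, core, 4000.0)
        c2 = crop_structure(c1, core, 4000.0)
        assert np.array_equal(c1.data, c2.data)

    def test_disjoint_box_raises(self):
        grid = VoxelGrid(np.ones((10, 10, 10)), (100, 100, 100))
        with pytest.raises(ExmError):
            crop_structure(grid, np.array([99_000.0, 0.0, 0.0]), 1000.0)


class TestManualReviewMode:
    def test_export_and_ingest_round_trip(self, tmp_path):
        from exmfoci.spots import export_crops_for_review, ingest_manual_labels

        grid = VoxelGrid(np.random.default_rng(0).uniform(size=(40, 40, 40)),
                         (100.0,) * 3, ("c",))
        structures = [
            StructureCluster(i, "c", np.array([2000.0, 2000.0, 2000.0]),
                             np.zeros((1, 3)), np.array([0]), class_label=1)
            for i in range(3)
        ]
        table = export_crops_for_review(grid, structures, tmp_path, 2000.0)
        assert len(table) == 3
        assert (tmp_path / "structure_0.tif").exists()
        csv = tmp_path / "manual_labels.csv"
        edited = pd.read_csv(csv)
        edited.loc[edited.structure_id == 1, "class"] = 5
        edited.to_csv(csv, index=False)
        n = ingest_manual_labels(structures, csv)
        assert n == 1
        assert structures[1].class_label == 5
        assert structures[0].class_label == 1


class TestEndToEndRecovery:
    def test_planted_classes_recovered_from_images(self, structure_scene):
        grid, truth = structure_scene
        _dets, structures = detect_and_classify(grid)
        tcores = truth.structures[["core_z", "core_y", "core_x"]].to_numpy()
        det_cores = np.array([s.core_position for s in structures])
        m = match_to_ground_truth(det_cores, tcores, 1000.0)
        matched = [(s, int(truth.structures.class_id.iloc[mi]))
                   for s, mi in zip(structures, m) if mi >= 0]
        assert len(matched) >= 0.95 * len(truth.structures)
        correct = sum(s.class_label == c for s, c in matched)
        assert correct / len(matched) >= 0.9
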