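"""Horn similarity fitting, control-point handling and isotropy metrics."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from exmfoci.image import VoxelGrid
from exmfoci.registration import (
    ControlPointSet,
    DegenerateGeometryError,
    SimilarityTransform3D,
    fit_similarity_horn,
    pairwise_distance_table,
    register_control_points,
    registration_mse,
    resample_isotropic,
    split_control_points,
)
from exmfoci.units import ExmError


def _random_similarity(rng):
    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
    s = rng.uniform(0.5, 5.0)
    t = rng.uniform(-1000, 1000, 3)
    return s, R, t


class TestHornFit:
    def test_exact_recovery_scale4_rot90(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 5000, (21, 3))
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        y = 4.0 * x @ R.T + np.array([100.0, 0.0, 0.0])
        T = fit_similarity_horn(x, y)
        assert T.scale == pytest.approx(4.0, rel=1e-9)
        assert np.allclose(T.rotation_matrix, R, atol=1e-9)
        assert np.allclose(T.translation, [100, 0, 0], atol=1e-6)
        mse, _ = registration_mse(T, x, y)
        assert mse < 1e-8

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_recovery_random_similarity(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(-3000, 3000, (21, 3))
        s, R, t = _random_similarity(rng)
        y = s * x @ R.T + t
        T = fit_similarity_horn(x, y)
        assert T.scale == pytest.approx(s, rel=1e-9)
        angle = Rotation.from_matrix(T.rotation_matrix @ R.T).magnitude()
        assert angle < 1e-9

    def test_identity_on_identical_sets(self):
        x = np.random.default_rng(1).uniform(0, 100, (10, 3))
        T = fit_similarity_horn(x, x)
        assert T.scale == pytest.approx(1.0, rel=1e-12)
        assert registration_mse(T, x, x)[0] < 1e-10

    def test_matches_brute_force_optimiser(self):
        """Independent oracle: direct numerical minimisation of the residual
        over (log s, rotation vector, t) from multiple restarts."""
        rng = np.random.default_rng(7)
        x = rng.uniform(-1000, 1000, (12, 3))
        s, R, t = _random_similarity(rng)
        y = s * x @ R.T + t + rng.normal(0, 30.0, x.shape)  # noisy pairs

        def objective(p):
            sc = np.exp(p[0])
            Rm = Rotation.from_rotvec(p[1:4]).as_matrix()
            return np.sum((sc * x @ Rm.T + p[4:7] - y) ** 2)

        best = np.inf
        for k in range(25):
            p0 = np.concatenate(
                [[np.log(rng.uniform(0.3, 4.0))], rng.uniform(-np.pi, np.pi, 3),
                 rng.uniform(-1500, 1500, 3)]
            )
            res = minimize(objective, p0, method="Nelder-Mead",
                           options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10})
            best = min(best, res.fun)

        T = fit_similarity_horn(x, y)
        horn_obj = np.sum((T.apply(x) - y) ** 2)
        assert horn_obj <= best * (1 + 1e-6) + 1e-9

    def test_collinear_points_raise(self):
        x = np.outer(np.arange(5.0), [1.0, 2.0, 3.0])
        with pytest.raises(DegenerateGeometryError):
            fit_similarity_horn(x, x * 2)


class TestTransformGroup:
    def test_inverse_composition_is_identity(self):
        rng = np.random.default_rng(3)
        s, R, t = _random_similarity(rng)
        T = SimilarityTransform3D.from_matrix(s, R, t)
        I = T.compose(T.inverse())
        pts = rng.uniform(-500, 500, (20, 3))
        assert np.allclose(I.apply(pts), pts, atol=1e-8)

    def test_apply_then_invert_recovers_points(self):
        rng = np.random.default_rng(4)
        s, R, t = _random_similarity(rng)
        T = SimilarityTransform3D.from_matrix(s, R, t)
        pts = rng.uniform(-500, 500, (20, 3))
        assert np.allclose(T.inverse().apply(T.apply(pts)), pts, atol=1e-8)

    def test_quaternion_norm_enforced(self):
        with pytest.raises(ValueError):
            SimilarityTransform3D(1.0, (1.0, 1.0, 0.0, 0.0), (0, 0, 0))


class TestSplit:
    @pytest.mark.parametrize("n, frac, n_train, n_val", [(21, 0.8, 17, 4), (10, 0.8, 8, 2)])
    def test_split_counts(self, n, frac, n_train, n_val):
        pts = ControlPointSet(np.zeros((n, 3)), np.ones((n, 3)))
        out = split_control_points(pts, frac, seed=0)
        assert (out.roles == "train").sum() == n_train
        assert (out.roles == "validation").sum() == n_val

    def test_split_deterministic(self):
        pts = ControlPointSet(np.zeros((21, 3)), np.ones((21, 3)))
        a = split_control_points(pts, 0.8, seed=5)
        b = split_control_points(pts, 0.8, seed=5)
        assert (a.roles == b.roles).all()

    def test_too_few_points_raise(self):
        pts = ControlPointSet(np.zeros((4, 3)), np.ones((4, 3)))
        with pytest.raises(ExmError, match="at least"):
            split_control_points(pts, 0.5, seed=0)


class TestMse:
    def test_known_residual_lengths(self):
        T = SimilarityTransform3D.identity()
        pre = np.zeros((3, 3))
        post = np.array([[3.0, 0, 0], [0, 4.0, 0], [0, 0, 5.0]])
        mse, res = registration_mse(T, pre, post)
        assert mse == pytest.approx(4.0)
        assert sorted(res) == [3.0, 4.0, 5.0]

    def test_squared_variant(self):
        T = SimilarityTransform3D.identity()
        post = np.array([[3.0, 0, 0], [0, 4.0, 0]])
        mse, _ = registration_mse(T, np.zeros((2, 3)), post, squared=True)
        assert mse == pytest.approx((9 + 16) / 2)

    def test_noisy_mse_matches_simulated_chi_mean(self):
        """With sigma Gaussian landmark noise the mean 3D residual follows
        the chi-3 mean; the expectation is computed here by brute-force
        Monte-Carlo rather than assumed."""
        sigma = 200.0
        rng = np.random.default_rng(11)
        expected = np.mean(np.linalg.norm(rng.normal(0, sigma, (200_000, 3)), axis=1))
        x = rng.uniform(0, 50_000, (1000, 3))
        y = x + rng.normal(0, sigma, x.shape)
        mse, _ = registration_mse(SimilarityTransform3D.identity(), x, y)
        assert mse == pytest.approx(expected, rel=0.10)


class TestResample:
    def test_constant_preserved(self):
        g = VoxelGrid(np.full((8, 10, 12), 7.5), (200, 100, 100))
        out = resample_isotropic(g, 100.0)
        assert np.allclose(out.data, 7.5, atol=1e-9)
        assert out.voxel_size == (100.0, 100.0, 100.0)

    def test_identity_factor(self):
        rng = np.random.default_rng(0)
        g = VoxelGrid(rng.uniform(size=(6, 6, 6)), (100, 100, 100))
        out = resample_isotropic(g, 100.0)
        assert np.allclose(out.data, g.data, atol=1e-9)

    def test_linear_ramp_preserved(self):
        """Cubic interpolation reproduces polynomials up to degree 3, so a
        linear ramp stays linear away from the borders."""
        z = np.arange(48)[:, None, None] * 1.0
        g = VoxelGrid(np.broadcast_to(z, (48, 12, 12)).copy(), (200, 100, 100))
        out = resample_isotropic(g, 100.0)
        grad = np.diff(out.data[36:60, 6, 6])
        assert np.allclose(grad, 0.5, rtol=1e-6)

    def test_extent_preserved_within_one_voxel(self):
        g = VoxelGrid(np.zeros((7, 11, 13)), (230, 110, 90))
        out = resample_isotropic(g, 100.0)
        for pre_e, post_e in zip(g.physical_extent, out.physical_extent):
            assert abs(pre_e - post_e) <= 100.0

    def test_memory_guard(self):
        g = VoxelGrid(np.zeros((4, 4, 4)), (10_000, 10_000, 10_000))
        with pytest.raises(ExmError, match="upsampling"):
            resample_isotropic(g, 100.0)


class TestPairwiseDistances:
    def test_pair_count_21_points(self):
        rng = np.random.default_rng(2)
        pre = rng.uniform(0, 1000, (21, 3))
        pts = ControlPointSet(pre, pre * 4)
        table = pairwise_distance_table(pts, 4.0)
        assert len(table) == 210

    def test_pure_scaling_zero_deviation(self):
        rng = np.random.default_rng(2)
        pre = rng.uniform(0, 1000, (10, 3))
        table = pairwise_distance_table(ControlPointSet(pre, pre * 4), 4.0)
        assert np.allclose(table["deviation_nm"], 0.0, atol=1e-9)

    def test_deviation_grows_with_distortion(self):
        from exmfoci.simulate import simulate_expansion

        rng = np.random.default_rng(8)
        pre = rng.uniform(0, 20_000, (21, 3))
        maxdev = []
        for amp in (0.0, 100.0, 400.0):
            post, _ = simulate_expansion(pre, 4.0, amp, 3000.0, seed=9)
            table = pairwise_distance_table(ControlPointSet(pre, post), 4.0)
            maxdev.append(table.attrs["summary"]["max_abs_deviation_nm"])
        assert maxdev[0] < maxdev[1] < maxdev[2]


class TestEndToEnd:
    def test_validation_mse_exceeds_train_on_average(self):
        """Overfitting direction: held-out error is on average the larger
        one under landmark noise."""
        rng = np.random.default_rng(21)
        diffs = []
        for rep in range(50):
            x = rng.uniform(0, 30_000, (21, 3))
            s, R, t = _random_similarity(rng)
            y = s * x @ R.T + t + rng.normal(0, 200.0, x.shape)
            rep_report = register_control_points(
                ControlPointSet(x, y), 0.8, seed=rep
            )
            diffs.append(rep_report.mse_validation_nm - rep_report.mse_train_nm)
        assert np.mean(diffs) > 0

    def test_csv_round_trip(self, tmp_path):
        rng = np.random.default_rng(13)
        pts = ControlPointSet(rng.uniform(0, 100, (6, 3)), rng.uniform(0, 100, (6, 3)))
        path = tmp_path / "points.csv"
        pts.to_csv(path)
        back = ControlPointSet.from_csv(path)
        assert np.allclose(back.pre, pts.pre)
        assert np.allclose(back.post, pts.post)
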