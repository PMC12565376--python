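"""Face normalization, parcellation, speeds, signatures, EMD, transfer entropy."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spiba.compare import emd_1d
from spiba.errors import InvalidInputError
from spiba.face import (
    DEFAULT_REGION_MAP,
    FaceGrid,
    RegionMap,
    emd_trajectory,
    landmark_speeds,
    normalize_face,
    parcellate,
    region_signature,
    transfer_entropy,
    transfer_entropy_matrix,
    triangle,
)
from spiba.synthetic import gen_face, gen_region_speeds


def _random_grid(rng, n_frames=10):
    pos = rng.normal(0, 50, (n_frames, 68, 2)) + np.array([300.0, 200.0])
    return FaceGrid(pos, 30.0)


class TestNormalizeFace:
    def test_centroid_at_origin(self, rng):
        out = normalize_face(_random_grid(rng))
        np.testing.assert_allclose(out.positions.mean(axis=1), 0.0, atol=1e-9)

    def test_distance_sd_is_one(self, rng):
        out = normalize_face(_random_grid(rng))
        d = np.linalg.norm(out.positions, axis=2)
        np.testing.assert_allclose(d.std(axis=1), 1.0, atol=1e-9)

    def test_similarity_invariance(self, rng):
        grid = _random_grid(rng)
        moved = FaceGrid(grid.positions * 7.0 + np.array([100.0, -40.0]), 30.0)
        np.testing.assert_allclose(
            normalize_face(grid).positions, normalize_face(moved).positions,
            atol=1e-9,
        )

    def test_idempotent(self, rng):
        once = normalize_face(_random_grid(rng))
        twice = normalize_face(once)
        np.testing.assert_allclose(once.positions, twice.positions, atol=1e-12)

    def test_degenerate_frame_rejected(self):
        pos = np.ones((3, 68, 2))
        with pytest.raises(InvalidInputError):
            normalize_face(FaceGrid(pos, 30.0))


class TestRegionMap:
    def test_default_covers_68_disjointly(self, rng):
        rmap = RegionMap.default()
        counts = {k: len(v) for k, v in rmap.regions.items()}
        assert sum(counts.values()) == 68
        assert all(c > 0 for c in counts.values())
        bundles = parcellate(rmap, _random_grid(rng))
        assert sum(b.shape[1] for b in bundles.values()) == 68

    def test_duplicate_index_rejected(self):
        bad = {k: list(v) for k, v in DEFAULT_REGION_MAP.items()}
        bad["V1"] = list(bad["V1"]) + [5]  # 5 already in V3
        with pytest.raises(InvalidInputError):
            RegionMap(bad)

    def test_missing_index_rejected(self):
        bad = {"V1": tuple(range(0, 30)), "V2": tuple(range(30, 60)),
               "V3": tuple(range(60, 67))}
        with pytest.raises(InvalidInputError):
            RegionMap(bad)

    def test_json_round_trip(self):
        rmap = RegionMap.default()
        again = RegionMap.from_json_dict(rmap.to_json_dict())
        assert again.regions == rmap.regions


class TestLandmarkSpeeds:
    def test_static_landmarks_have_zero_speed(self):
        grid = FaceGrid(np.tile(np.random.default_rng(0).normal(0, 1, (1, 68, 2)),
                                (30, 1, 1)), 30.0)
        speeds = landmark_speeds(grid, smoothing=0.0)
        np.testing.assert_allclose(speeds, 0.0, atol=1e-9)

    def test_linear_motion_speed(self):
        n = 60
        t = np.arange(n)[:, None] / 30.0
        base = np.random.default_rng(1).normal(0, 10, (1, 68, 2))
        pos = base + t[..., None] * np.array([3.0, 4.0])
        speeds = landmark_speeds(FaceGrid(pos, 30.0), smoothing=0.0)
        np.testing.assert_allclose(speeds[5:-5], 5.0, rtol=0.01)

    def test_circular_motion_speed(self):
        n, fps, r, w = 150, 30.0, 2.0, 2.0 * np.pi * 1.0  # 1 Hz circle
        t = np.arange(n) / fps
        pos = np.zeros((n, 68, 2))
        pos[:, :, 0] = r * np.cos(w * t)[:, None]
        pos[:, :, 1] = r * np.sin(w * t)[:, None]
        speeds = landmark_speeds(FaceGrid(pos, fps), smoothing=0.0)
        np.testing.assert_allclose(speeds[10:-10], r * w, rtol=0.02)

    def test_too_few_frames(self):
        with pytest.raises(Exception):
            landmark_speeds(FaceGrid(np.zeros((3, 68, 2)), 30.0))


class TestRegionSignature:
    def test_recovery_within_ci(self):
        speeds, truth = gen_region_speeds(n_landmarks=8, n_spikes=60, seed=0)
        rs = region_signature(speeds, "V1",
                              min_prominence=truth["min_prominence"])
        assert rs.gamma.shape_ci[0] <= truth["shape"] <= rs.gamma.shape_ci[1]
        assert rs.gamma.scale_ci[0] <= truth["scale"] <= rs.gamma.scale_ci[1]

    def test_pooling_is_order_free(self):
        speeds, truth = gen_region_speeds(n_landmarks=5, n_spikes=40, seed=1)
        rs1 = region_signature(speeds, min_prominence=truth["min_prominence"])
        rs2 = region_signature(speeds[:, ::-1],
                               min_prominence=truth["min_prominence"])
        assert rs1.gamma.shape == pytest.approx(rs2.gamma.shape, rel=1e-12)

    def test_distinct_scales_ordered(self):
        est = []
        for i, b0 in enumerate((0.0012, 0.0022)):
            speeds, truth = gen_region_speeds(
                n_landmarks=6, n_spikes=50, shape=0.68 / b0, scale=b0, seed=2 + i)
            rs = region_signature(speeds, min_prominence=truth["min_prominence"])
            est.append(rs.gamma.nsr)
        assert est[0] < est[1]

    def test_frozen_region_flagged(self):
        rs = region_signature(np.zeros((150, 4)), "V2")
        assert rs.insufficient and rs.gamma is None


class _Vertex:
    """Minimal stand-in exposing a moment point, for geometry-only tests."""

    def __init__(self, p):
        self.moment_point = np.asarray(p, dtype=float)


class TestTriangle:
    def test_unit_right_triangle(self):
        tri = triangle(_Vertex([0, 0, 0]), _Vertex([1, 0, 0]), _Vertex([0, 1, 0]))
        assert tri.area == pytest.approx(0.5)

    def test_collinear_zero_area(self):
        tri = triangle(_Vertex([0, 0, 0]), _Vertex([1, 1, 1]), _Vertex([2, 2, 2]))
        assert tri.area == pytest.approx(0.0, abs=1e-12)

    def test_matches_heron_oracle(self, rng):
        for _ in range(20):
            a, b, c = rng.normal(0, 1, (3, 3))
            la, lb, lc = (np.linalg.norm(b - c), np.linalg.norm(a - c),
                          np.linalg.norm(a - b))
            s = 0.5 * (la + lb + lc)
            heron = np.sqrt(max(s * (s - la) * (s - lb) * (s - lc), 0.0))
            tri = triangle(_Vertex(a), _Vertex(b), _Vertex(c))
            assert tri.area == pytest.approx(heron, abs=1e-9)


class TestEMD:
    def test_identical_samples_zero(self, rng):
        x = rng.gamma(4, 0.1, 100)
        assert emd_1d(x, x) == 0.0

    def test_point_masses(self):
        assert emd_1d([0.2], [0.7]) == pytest.approx(0.5)

    def test_matches_quantile_integral_oracle(self):
        rng = np.random.default_rng(42)
        x = rng.gamma(4.0, 0.1, 10_000)
        y = rng.gamma(4.0, 0.2, 10_000)
        p = np.linspace(0, 1, 200_001)[1:-1]
        oracle = np.trapezoid(np.abs(np.quantile(x, p) - np.quantile(y, p)), p)
        assert emd_1d(x, y) == pytest.approx(oracle, rel=0.05)

    def test_metric_axioms_on_random_triples(self, rng):
        for _ in range(10):
            a, b, c = (rng.normal(0, 1, 50) for _ in range(3))
            dab, dba = emd_1d(a, b), emd_1d(b, a)
            assert dab == pytest.approx(dba, rel=1e-12)
            assert emd_1d(a, c) <= dab + emd_1d(b, c) + 1e-12


class TestEMDTrajectory:
    def test_windows_and_self_distance(self):
        grid, _ = gen_face(n_frames=300, seed=5)
        refs = {"rest": np.random.default_rng(0).gamma(400, 0.0017, 500)}
        out = emd_trajectory(grid, refs, window=150, overlap=0.5)
        assert set(out) == {"V1", "V2", "V3"}
        df = out["V1"]
        assert list(df.start_frame) == [0, 75, 150]
        good = df[~df.unreliable]
        assert np.all(good["rest"] >= 0)

    def test_static_grid_flagged_unreliable(self):
        grid, _ = gen_face(n_frames=150, speed_amplitude=0.0, seed=0)
        refs = {"rest": np.linspace(0.5, 0.9, 50)}
        out = emd_trajectory(grid, refs, window=150)
        assert out["V1"].unreliable.all()


class TestTransferEntropy:
    def test_independent_series_near_zero(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(0, 1, 5000), rng.normal(0, 1, 5000)
        assert abs(transfer_entropy(x, y)) < 0.05

    def test_lagged_coupling_is_directional(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 5001)
        y = np.empty(5001)
        y[0] = 0.0
        y[1:] = x[:-1]  # Y(t+1) = X(t)
        fwd = transfer_entropy(x, y)
        rev = transfer_entropy(y, x)
        assert fwd - rev >= 0.2

    def test_constant_series_zero_by_convention(self):
        c = np.ones(1000)
        assert transfer_entropy(c, c) == 0.0

    def test_matrix_shape_and_diagonal(self, rng):
        speeds = {r: rng.normal(0, 1, 600) for r in ("V1", "V2", "V3")}
        mat = transfer_entropy_matrix(speeds)
        assert mat.shape == (3, 3)
        assert np.all(np.isnan(np.diag(mat.to_numpy())))
        assert np.all(mat.to_numpy()[~np.isnan(mat.to_numpy())] >= 0)

    @given(st.integers(0, 1000))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_nonnegative_on_random_series(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(0, 1, 400), rng.normal(0, 1, 400)
        assert transfer_entropy(x, y) >= 0.0
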