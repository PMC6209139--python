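import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import posturegm as pg
from posturegm.errors import DegenerateConfigurationError

from conftest import noisy_ensemble, random_configuration


def brute_force_residual(source, target, step=0.001):
    """Grid-search oracle: minimal SSD over rotation with per-angle
    optimal scale and translation."""
    ac = source - source.mean(axis=0)
    bc = target - target.mean(axis=0)
    na2 = (ac ** 2).sum()
    best = np.inf
    for phi in np.arange(-np.pi, np.pi, step):
        c, s = np.cos(phi), np.sin(phi)
        rot = ac @ np.array([[c, s], [-s, c]])
        beta = max((rot * bc).sum() / na2, 0.0)
        best = min(best, ((beta * rot - bc) ** 2).sum())
    return best


class TestCentroidSize:
    def test_unit_square_example(self):
        square = [[0, 0], [2, 0], [2, 2], [0, 2]]
        assert pg.centroid_size(square) == pytest.approx(2 * np.sqrt(2))

    @given(c=st.floats(0.01, 100))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_homogeneous_in_scale(self, c):
        pts = np.array([[0.0, 1.0], [2.0, -1.0], [-1.5, 0.5], [3.0, 2.0]])
        assert pg.centroid_size(pts * c) == pytest.approx(
            c * pg.centroid_size(pts), rel=1e-12)

    def test_matches_direct_summation(self, rng):
        pts = random_configuration(rng, k=30)
        mu = pts.mean(axis=0)
        direct = np.sqrt(sum((x - mu[0]) ** 2 + (y - mu[1]) ** 2
                             for x, y in pts))
        assert pg.centroid_size(pts) == pytest.approx(direct, rel=1e-12)

    def test_coincident_points_degenerate(self):
        with pytest.raises(DegenerateConfigurationError):
            pg.centroid_size(np.ones((5, 2)))


class TestAlignPair:
    def test_identity_when_target_is_source(self, rng):
        pts = random_configuration(rng)
        fit = pg.align_pair(pts, pts)
        assert fit.rotation == pytest.approx(0.0, abs=1e-12)
        assert fit.scale == pytest.approx(1.0, rel=1e-12)
        assert fit.residual == pytest.approx(0.0, abs=1e-12)

    def test_recovers_pure_rotation(self, rng):
        pts = random_configuration(rng)
        pts -= pts.mean(axis=0)
        rot90 = pts @ np.array([[0.0, 1.0], [-1.0, 0.0]])
        fit = pg.align_pair(pts, rot90)
        assert fit.rotation == pytest.approx(np.pi / 2, abs=1e-12)
        assert fit.residual == pytest.approx(0.0, abs=1e-10)

    def test_residual_matches_grid_search(self, rng):
        for _ in range(3):
            a = random_configuration(rng)
            b = random_configuration(rng)
            fit = pg.align_pair(a, b)
            assert fit.residual == pytest.approx(
                brute_force_residual(a, b), abs=1e-4)

    def test_aligned_equals_transform_of_source(self, rng):
        a, b = random_configuration(rng), random_configuration(rng)
        fit = pg.align_pair(a, b)
        c, s = np.cos(fit.rotation), np.sin(fit.rotation)
        manual = fit.scale * a @ np.array([[c, s], [-s, c]]) \
            + fit.translation
        np.testing.assert_allclose(fit.aligned, manual, atol=1e-10)

    def test_no_reflection_even_for_mirrored_target(self, rng):
        a = random_configuration(rng)
        mirrored = a * np.array([-1.0, 1.0])
        fit = pg.align_pair(a, mirrored)
        # a proper rotation cannot reproduce a reflection: residual > 0
        assert fit.residual > 1e-3

    def test_k_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            pg.align_pair(random_configuration(rng, 5),
                          random_configuration(rng, 6))


class TestGPA:
    def test_identical_configs_have_zero_dispersion(self, rng, template):
        ens = pg.gpa(np.stack([template] * 5))
        assert np.allclose(ens.aligned, ens.aligned[0][None], atol=1e-12)
        np.testing.assert_allclose(ens.consensus, ens.aligned[0],
                                   atol=1e-12)

    def test_similarity_transformed_pair_has_zero_distance(self, template):
        theta = 0.7
        c, s = np.cos(theta), np.sin(theta)
        other = 3.0 * template @ np.array([[c, s], [-s, c]]) + [5.0, -2.0]
        ens = pg.gpa(np.stack([template, other]))
        assert pg.procrustes_distance(
            ens.aligned[0], ens.aligned[1]) < 1e-9

    def test_aligned_shapes_centered_and_unit_size(self, rng, template):
        ens = pg.gpa(noisy_ensemble(rng, template))
        np.testing.assert_allclose(ens.aligned.mean(axis=1), 0, atol=1e-9)
        sizes = np.sqrt((ens.aligned ** 2).sum(axis=(1, 2)))
        np.testing.assert_allclose(sizes, 1.0, atol=1e-9)

    def test_consensus_is_mean_of_aligned(self, rng, template):
        ens = pg.gpa(noisy_ensemble(rng, template))
        np.testing.assert_allclose(ens.consensus,
                                   ens.aligned.mean(axis=0), atol=1e-12)

    def test_invariant_to_similarity_pretransforms(self, rng, template):
        arr = noisy_ensemble(rng, template, n=8)
        ens = pg.gpa(arr)
        thetas = rng.uniform(-np.pi, np.pi, size=8)
        scales = rng.uniform(0.5, 2.0, size=8)
        shifts = rng.normal(size=(8, 2), scale=10)
        moved = np.empty_like(arr)
        for i in range(8):
            c, s = np.cos(thetas[i]), np.sin(thetas[i])
            moved[i] = scales[i] * arr[i] @ np.array([[c, s], [-s, c]]) \
                + shifts[i]
        ens2 = pg.gpa(moved)
        # compare in a common orientation: align run 2 onto run 1
        fit = pg.align_pair(ens2.consensus, ens.consensus)
        c, s = np.cos(fit.rotation), np.sin(fit.rotation)
        R = np.array([[c, s], [-s, c]])
        rms = np.sqrt(((ens2.aligned @ R - ens.aligned) ** 2).mean())
        assert rms < 1e-8

    def test_order_invariant_up_to_rotation(self, rng, template):
        arr = noisy_ensemble(rng, template, n=12)
        perm = rng.permutation(12)
        d = pg.procrustes_distance(
            pg.normalize_shape(pg.gpa(arr).consensus),
            pg.normalize_shape(pg.gpa(arr[perm]).consensus))
        assert d < 1e-8

    def test_final_rotation_target_has_unit_size(self, rng, template):
        # low-dispersion ensemble: consensus stays unit-size to 1e-6
        ens = pg.gpa(noisy_ensemble(rng, template, noise=1e-4))
        assert pg.centroid_size(ens.consensus) == pytest.approx(
            1.0, abs=1e-6)


class TestProcrustesDistance:
    def test_identity_and_symmetry(self, rng):
        a = pg.normalize_shape(random_configuration(rng))
        b = pg.normalize_shape(random_configuration(rng))
        assert pg.procrustes_distance(a, a) == 0.0
        assert pg.procrustes_distance(a, b) == pytest.approx(
            pg.procrustes_distance(b, a), abs=1e-12)

    def test_triangle_inequality_on_random_triples(self, rng):
        for _ in range(100):
            a, b, c = (pg.normalize_shape(random_configuration(rng, 7))
                       for _ in range(3))
            dab = pg.procrustes_distance(a, b)
            dbc = pg.procrustes_distance(b, c)
            dac = pg.procrustes_distance(a, c)
            assert dac <= dab + dbc + 1e-12

    def test_rejects_unnormalized_input(self, rng):
        raw = random_configuration(rng) + 10.0
        with pytest.raises(ValueError, match="center|normalize"):
            pg.procrustes_distance(raw, raw)


class TestDerotation:
    triple = (0, 1, 2)

    def test_moves_ray_b_to_reference_angle(self):
        a80 = np.deg2rad(80)
        pts = np.array([[1.0, 0.0], [0.0, 0.0],
                        [np.cos(a80), np.sin(a80)]])
        # vertex first in outline order: triple uses index order a,v,b
        pts = pts[[0, 1, 2]]
        out = pg.derotate(pts, (0, 1, 2), np.deg2rad(90))
        np.testing.assert_allclose(out[2], [0.0, 1.0], atol=1e-12)
        np.testing.assert_allclose(out[:2], pts[:2])

    def test_noop_when_already_at_reference(self, template):
        angle = pg.measure_angle(template, (0, 14, 29))
        out = pg.derotate(template, (0, 14, 29), angle)
        np.testing.assert_allclose(out, template, atol=1e-12)

    def test_sample_derotation_kills_angle_variance(self, rng, template):
        configs = []
        for _ in range(40):
            pts = template.copy()
            theta = rng.normal(0, np.deg2rad(15))
            v = pts[14]
            c, s = np.cos(theta), np.sin(theta)
            pts[15:] = (pts[15:] - v) @ np.array([[c, s], [-s, c]]).T + v
            configs.append(pts)
        out, ref = pg.derotate_sample(configs, (0, 14, 29))
        angles = np.array([pg.measure_angle(p, (0, 14, 29)) for p in out])
        assert angles.var() < 1e-10
        assert angles.mean() == pytest.approx(ref, abs=1e-9)

    def test_preserves_neck_internal_geometry(self, rng, template):
        out = pg.derotate(template, (0, 14, 29),
                          pg.measure_angle(template, (0, 14, 29)) + 0.5)
        d_before = np.linalg.norm(
            template[15:, None] - template[None, 15:], axis=2)
        d_after = np.linalg.norm(out[15:, None] - out[None, 15:], axis=2)
        np.testing.assert_allclose(d_after, d_before, atol=1e-10)

    def test_ray_on_vertex_is_degenerate(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        with pytest.raises(DegenerateConfigurationError):
            pg.measure_angle(pts, (0, 1, 2))
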