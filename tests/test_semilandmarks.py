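import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize_scalar

import posturegm as pg
from posturegm.errors import DegenerateConfigurationError
from posturegm.io_formats import LANDMARK, SLIDER, PointScheme
from posturegm.superimposition import AlignedEnsemble

from conftest import noisy_ensemble


def curve_scheme(k, slider_idx=None, derotation=None):
    """Open-curve scheme: given indices slide, the rest stay fixed."""
    slider_idx = set(slider_idx or [])
    roles = tuple(SLIDER if i in slider_idx else LANDMARK
                  for i in range(k))
    triples = [(i - 1 if i > 0 else i + 1, i,
                i + 1 if i < k - 1 else i - 1)
               for i in sorted(slider_idx)]
    return PointScheme(n_points=k, roles=roles, slider_triples=triples,
                       derotation_triple=derotation)


def hand_ensemble(shapes):
    """AlignedEnsemble wrapper around explicit pre-aligned shapes;
    consensus = mean."""
    shapes = np.asarray(shapes, float)
    return AlignedEnsemble(aligned=shapes, consensus=shapes.mean(axis=0),
                           centroid_sizes=np.ones(len(shapes)),
                           iterations=0, final_change=0.0)


class TestBendingEnergyMatrix:
    def test_triangle_gives_exact_zero_matrix(self, rng):
        B = pg.bending_energy_matrix(rng.normal(size=(3, 2)))
        assert (B == 0).all()

    def test_psd_with_three_dimensional_affine_null_space(self, rng):
        ref = rng.normal(size=(10, 2))
        B = pg.bending_energy_matrix(ref)
        np.testing.assert_allclose(B, B.T, atol=1e-12)
        w = np.linalg.eigvalsh(B)
        assert w.min() > -1e-9
        assert (np.abs(w) < 1e-9).sum() == 3
        # null space is exactly the affine fields 1, x, y
        for d in (np.ones(10), ref[:, 0], ref[:, 1]):
            assert abs(d @ B @ d) < 1e-9

    @given(st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_annihilates_random_affine_fields(self, seed):
        rng = np.random.default_rng(seed)
        ref = rng.normal(size=(8, 2))
        B = pg.bending_energy_matrix(ref)
        a, bx, by = rng.normal(size=3)
        d = a + bx * ref[:, 0] + by * ref[:, 1]
        assert abs(d @ B @ d) < 1e-9 * max(1.0, (d ** 2).sum())

    def test_coincident_points_error_names_indices(self):
        ref = np.array([[0.0, 0], [1, 0], [1, 0], [0, 1], [2, 2]])
        with pytest.raises(DegenerateConfigurationError, match="1, 2"):
            pg.bending_energy_matrix(ref)

    def test_collinear_reference_needs_regularization(self):
        ref = np.column_stack([np.arange(6.0), np.zeros(6)])
        with pytest.raises(DegenerateConfigurationError):
            pg.bending_energy_matrix(ref)
        B = pg.bending_energy_matrix(ref, regularize=True)
        assert np.isfinite(B).all()


class TestTpsWarp:
    def test_identity_warp(self, rng):
        ref = rng.normal(size=(7, 2))
        warp = pg.tps_warp(ref, ref)
        np.testing.assert_allclose(warp.nonaffine_weights, 0, atol=1e-9)
        np.testing.assert_allclose(
            warp.affine_part, [[0, 1, 0], [0, 0, 1]], atol=1e-9)

    def test_pure_translation(self, rng):
        ref = rng.normal(size=(6, 2))
        warp = pg.tps_warp(ref, ref + [2.0, -3.0])
        np.testing.assert_allclose(warp.nonaffine_weights, 0, atol=1e-9)
        np.testing.assert_allclose(
            warp.affine_part, [[2, 1, 0], [-3, 0, 1]], atol=1e-9)

    def test_interpolates_random_targets(self, rng):
        for _ in range(5):
            ref = rng.normal(size=(9, 2))
            target = ref + rng.normal(scale=0.3, size=ref.shape)
            warp = pg.tps_warp(ref, target)
            np.testing.assert_allclose(warp(ref), target, atol=1e-9)

    def test_side_conditions_hold(self, rng):
        ref = rng.normal(size=(12, 2))
        warp = pg.tps_warp(ref, ref + rng.normal(scale=0.2, size=(12, 2)))
        P = np.column_stack([np.ones(12), ref])
        np.testing.assert_allclose(P.T @ warp.nonaffine_weights, 0,
                                   atol=1e-9)


class TestSlideOnce:
    def test_specimen_equal_to_consensus_does_not_move(self, rng):
        base = np.column_stack([np.linspace(0, 1, 8),
                                np.sin(np.linspace(0, 3, 8))])
        ens = hand_ensemble([base, base])
        out = pg.slide_once(ens, curve_scheme(8, slider_idx=[2, 3, 4, 5]))
        np.testing.assert_allclose(out.displacements, 0, atol=1e-10)

    def test_matches_scalar_minimizer_on_single_slider(self, rng):
        base = np.column_stack([np.linspace(0, 2, 5),
                                [0.0, 0.3, 0.5, 0.3, 0.0]])
        spec = base + rng.normal(scale=0.05, size=base.shape)
        ens = AlignedEnsemble(aligned=spec[None], consensus=base,
                              centroid_sizes=np.ones(1), iterations=0,
                              final_change=0.0)
        scheme = curve_scheme(5, slider_idx=[2])
        out = pg.slide_once(ens, scheme)
        B = pg.bending_energy_matrix(base)
        u = spec[3] - spec[1]
        u = u / np.linalg.norm(u)

        def energy(t):
            moved = spec.copy()
            moved[2] = moved[2] + t * u
            return pg.bending_energy(B, moved - base)

        oracle = minimize_scalar(energy, bounds=(-1, 1), method="bounded",
                                 options={"xatol": 1e-10})
        assert out.displacements[0, 0] == pytest.approx(oracle.x,
                                                        abs=1e-6)

    def test_energy_never_increases_per_specimen(self, rng):
        base = np.column_stack([np.linspace(0, 2, 12),
                                np.sin(np.linspace(0, 4, 12))])
        shapes = base[None] + rng.normal(scale=0.04, size=(9, 12, 2))
        ens = hand_ensemble(shapes)
        scheme = curve_scheme(12, slider_idx=range(1, 11))
        B = pg.bending_energy_matrix(ens.consensus, regularize=True)
        out = pg.slide_once(ens, scheme)
        for i in range(9):
            before = pg.bending_energy(B, shapes[i] - ens.consensus)
            after = pg.bending_energy(
                B, out.ensemble.aligned[i] - ens.consensus)
            assert after <= before + 1e-12

    def test_non_slider_points_untouched(self, rng):
        base = np.column_stack([np.linspace(0, 2, 10),
                                np.cos(np.linspace(0, 3, 10))])
        shapes = base[None] + rng.normal(scale=0.03, size=(4, 10, 2))
        ens = hand_ensemble(shapes)
        out = pg.slide_once(ens, curve_scheme(10, slider_idx=[3, 4, 5]))
        fixed = [i for i in range(10) if i not in (3, 4, 5)]
        np.testing.assert_array_equal(out.ensemble.aligned[:, fixed],
                                      shapes[:, fixed])

    def test_zero_length_chord_reports_specimen_and_slider(self):
        good = np.array([[0.0, 0], [1, 0.1], [2, 0.5], [3, 0.2], [4, 1]])
        bad = good.copy()
        bad[3] = bad[1]  # slider 2's neighbours coincide in this specimen
        ens = hand_ensemble([bad, good])
        scheme = curve_scheme(5, slider_idx=[2])
        with pytest.raises(DegenerateConfigurationError, match="slider 2"):
            pg.slide_once(ens, scheme)


class TestSlideUntilConverged:
    def test_identical_configurations_converge_immediately(self, template,
                                                           ssl_scheme):
        arr = np.stack([template] * 4)
        res = pg.slide_until_converged(arr, ssl_scheme)
        assert res.converged
        assert res.iterations == 1
        np.testing.assert_allclose(res.displacements, 0, atol=1e-8)

    def test_trace_non_increasing(self, rng, template, ssl_scheme):
        arr = noisy_ensemble(rng, template, n=10, noise=0.02)
        res = pg.slide_until_converged(arr, ssl_scheme)
        trace = np.array(res.bending_energy_trace)
        assert (np.diff(trace) <= 1e-12).all()

    def test_no_sliders_reduces_to_plain_gpa(self, rng, template):
        arr = noisy_ensemble(rng, template, n=6)
        scheme = curve_scheme(30)  # all fixed landmarks
        res = pg.slide_until_converged(arr, scheme)
        ens = pg.gpa(arr)
        np.testing.assert_allclose(res.ensemble.aligned, ens.aligned,
                                   atol=1e-12)

    def test_respacing_initial_sliders_changes_little(self, rng):
        """Per-specimen re-spacing of the sliders along the same
        polylines leaves the converged consensus nearly unchanged and
        shrinks the spacing-induced dispersion: sliding removes the
        effect of the arbitrary initial spacing of points along the
        curve.  (A re-spacing component shared by every specimen is
        unidentifiable to tangent sliding, so the jitter here is
        zero-mean across specimens.)"""
        t = np.linspace(0, 1, 400)

        def curve(amp):
            return np.column_stack([2.0 * t,
                                    amp * np.sin(np.pi * t * 1.5)])

        def sample(poly, params):
            idx = params * (len(poly) - 1)
            lo = np.floor(idx).astype(int)
            frac = (idx - lo)[:, None]
            hi = np.minimum(lo + 1, len(poly) - 1)
            return poly[lo] * (1 - frac) + poly[hi] * frac

        k = 12
        uniform = np.linspace(0, 1, k)
        amps = 0.5 + 0.1 * np.arange(8) / 8
        scheme = curve_scheme(k, slider_idx=range(1, k - 1))
        base_arr = np.stack([sample(curve(a), uniform) for a in amps])
        jits = rng.uniform(-0.2, 0.2, size=(8, k)) / (k - 1)
        jits -= jits.mean(axis=0, keepdims=True)
        jits[:, [0, -1]] = 0.0
        pert_arr = np.stack([
            sample(curve(a), np.clip(uniform + j, 0, 1))
            for a, j in zip(amps, jits)])
        res_a = pg.slide_until_converged(base_arr, scheme, max_iter=40)
        res_b = pg.slide_until_converged(pert_arr, scheme, max_iter=40)
        d = pg.procrustes_distance(
            pg.normalize_shape(res_a.ensemble.consensus),
            pg.normalize_shape(res_b.ensemble.consensus))
        assert d < 1e-3
        raw = pg.gpa(pert_arr)
        disp_raw = ((raw.aligned - raw.consensus[None]) ** 2).sum()
        slid = res_b.ensemble
        disp_slid = ((slid.aligned - slid.consensus[None]) ** 2).sum()
        assert disp_slid < 0.5 * disp_raw
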