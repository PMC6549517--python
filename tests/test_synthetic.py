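"""Phantom generators: prescribed fractions, closed-form motion, encoding model."""

import numpy as np
import pytest
from scipy.interpolate import RegularGridInterpolator

import lvflow as lf
from lvflow.components import COMPONENTS, DIRECT_FLOW, RESIDUAL_VOLUME, RETAINED_INFLOW
from lvflow.synthetic import wrap_phase


class TestDuctPhantom:
    def test_ground_truth_fractions_match_prescription(self, duct):
        fr = duct["gt"].fractions()
        for name, want in zip(COMPONENTS, duct["spec"].fractions):
            assert fr[name] == pytest.approx(want, abs=0.02)

    def test_no_flow_prescription_gives_zero_field(self):
        spec = lf.PhantomSpec(shape=(24, 24, 24), fractions=(0, 0, 0, 1))
        field, _, _, gt = lf.make_duct_phantom(spec)
        assert np.all(field.values == 0)
        assert np.all(gt.labels == RESIDUAL_VOLUME)

    def test_all_direct_prescription_enters_and_exits(self):
        spec = lf.PhantomSpec(shape=(24, 24, 24), fractions=(1, 0, 0, 0))
        _, _, _, gt = lf.make_duct_phantom(spec)
        assert np.all(gt.labels == DIRECT_FLOW)
        # every seed entered during diastole: entry time inside the backward window
        t0, t1 = gt.meta["backward_window"]
        assert np.all((gt.entry_times > t0) & (gt.entry_times < t1))
        # and exits by ES: forward transit exceeds remaining chamber length
        x_lo, x_hi = gt.meta["box_bounds_x"]
        end = gt.trajectory(gt.meta["forward_window"][1])
        assert np.all(end[:, 0] > x_hi)

    def test_too_coarse_grid_raises_with_minimum(self):
        with pytest.raises(ValueError, match="need"):
            lf.make_duct_phantom(lf.PhantomSpec(shape=(10, 10, 10)))

    def test_tiny_fraction_unrepresentable_raises(self):
        spec = lf.PhantomSpec(shape=(24, 24, 24),
                              fractions=(0.0005, 0.1995, 0.3, 0.5))
        with pytest.raises(ValueError, match="unachievable"):
            lf.make_duct_phantom(spec)

    def test_volume_conserving_inflow_equals_outflow(self, duct):
        # net flux through the chamber's upstream and downstream faces agrees
        # at every frame: lanes run straight through, so what enters leaves
        field, gt = duct["field"], duct["gt"]
        x_lo, x_hi = gt.meta["box_bounds_x"]
        dx = field.spacing[0]
        i_lo, i_hi = int(round(x_lo / dx)), int(round(x_hi / dx))
        flux_in = field.values[i_lo, :, :, :, 0].sum(axis=(0, 1))
        flux_out = field.values[i_hi - 1, :, :, :, 0].sum(axis=(0, 1))
        np.testing.assert_allclose(flux_in, flux_out, atol=1e-12)

    def test_labels_match_brute_force_time_stepping(self):
        """Oracle equivalence: dense Euler stepping with independent
        interpolation reproduces every ground-truth label."""
        spec = lf.PhantomSpec(shape=(24, 24, 24))
        field, ed, es, gt = lf.make_duct_phantom(spec)
        t0, t_ed = gt.meta["backward_window"]
        t1 = gt.meta["forward_window"][1]
        nx, ny, nz = field.shape
        axes = [(np.arange(n) + 0.5) * field.spacing[i] for i, n in enumerate((nx, ny, nz))]
        interps = [
            RegularGridInterpolator(axes, field.values[..., f, :],
                                    bounds_error=False, fill_value=None)
            for f in range(field.n_frames)
        ]
        ft, cyc = field.frame_times, field.cycle_duration

        def velocity(pos, t):
            tau = (t - ft[0]) % cyc + ft[0]
            j = min(int(np.searchsorted(ft, tau, side="right")) - 1, len(ft) - 1)
            if j == len(ft) - 1:
                ta, tb, fa, fb = ft[-1], ft[0] + cyc, len(ft) - 1, 0
            else:
                ta, tb, fa, fb = ft[j], ft[j + 1], j, j + 1
            w = (tau - ta) / (tb - ta)
            return (1 - w) * interps[fa](pos) + w * interps[fb](pos)

        rng = np.random.default_rng(7)
        pick = rng.choice(len(gt.seed_positions), size=60, replace=False)
        seeds = gt.seed_positions[pick]
        n_steps = 2000
        box_lo, box_hi = gt.meta["box_bounds_x"]
        (y0, y1), (z0, z1) = [
            ((np.argwhere(ed.data)[:, ax].min()) * field.spacing[ax],
             (np.argwhere(ed.data)[:, ax].max() + 1) * field.spacing[ax])
            for ax in (1, 2)
        ]

        def inside(p):
            return (box_lo < p[:, 0]) & (p[:, 0] < box_hi) \
                & (y0 < p[:, 1]) & (p[:, 1] < y1) & (z0 < p[:, 2]) & (p[:, 2] < z1)

        def march(start, ta, tb):
            pos = start.copy()
            h = (tb - ta) / n_steps
            t = ta
            for _ in range(n_steps):
                pos = pos + h * velocity(pos, t)
                t += h
            return pos

        back = march(seeds, t_ed, t0)
        fwd = march(seeds, t_ed, t1)
        labels = np.where(
            inside(back),
            np.where(inside(fwd), "Residual volume", "Delayed ejection flow"),
            np.where(inside(fwd), "Retained inflow", "Direct flow"),
        )
        assert np.all(labels == gt.labels[pick])

    def test_identical_seeds_give_identical_phantoms(self):
        spec = lf.PhantomSpec(shape=(24, 24, 24), seed=5)
        f1, _, _, g1 = lf.make_duct_phantom(spec)
        f2, _, _, g2 = lf.make_duct_phantom(spec)
        assert np.array_equal(f1.values, f2.values)
        assert np.array_equal(g1.entry_times, g2.entry_times, equal_nan=True)


class TestAffinePhantom:
    def test_translation_trajectory_is_linear(self):
        spec = lf.PhantomSpec(phantom_kind="affine", shape=(24, 24, 24),
                              affine_motion="translation",
                              translation_velocity=(0.1, 0, 0))
        field, ed, _, gt = lf.make_affine_phantom(spec)
        t_ed = field.frame_times[spec.ed_frame]
        for dt in (0.1, 0.25):
            got = gt.trajectory(t_ed + dt)
            want = gt.seed_positions + np.array([0.1 * dt, 0, 0])
            np.testing.assert_allclose(got, want, atol=1e-12)
        assert np.allclose(field.values[..., 0], 0.1)

    def test_rotation_preserves_radius(self, affine_rotation):
        gt = affine_rotation["gt"]
        center = gt.meta["center"]
        r0 = np.linalg.norm((gt.seed_positions - center)[:, :2], axis=1)
        for t in (0.2, 0.5, 0.9):
            r = np.linalg.norm((gt.trajectory(t) - center)[:, :2], axis=1)
            np.testing.assert_allclose(r, r0, rtol=1e-12)

    def test_contraction_matches_diagonal_map(self):
        spec = lf.PhantomSpec(phantom_kind="affine", shape=(24, 24, 24),
                              affine_motion="contraction",
                              contraction=(-0.3, -0.3, 0.2), ed_frame=0)
        field, _, _, gt = lf.make_affine_phantom(spec)
        c = gt.meta["center"]
        t = 0.5  # t_hat = 0.5
        scale = np.array([1 - 0.15, 1 - 0.15, 1 + 0.1])
        want = (gt.seed_positions - c) * scale + c
        np.testing.assert_allclose(gt.trajectory(t), want, atol=1e-12)

    def test_singular_map_raises(self):
        spec = lf.PhantomSpec(phantom_kind="affine", shape=(16, 16, 16),
                              affine_motion="contraction",
                              contraction=(-2.0, 0.0, 0.0))
        with pytest.raises(ValueError, match="singular"):
            lf.make_affine_phantom(spec)


class TestEncoding:
    def test_phase_is_pi_v_over_venc(self):
        field = lf.make_aliasing_phantom(shape=(12, 12, 12), peak_over_venc=1.5,
                                         venc=1.2)
        field.values[...] = 0.6  # VENC/2 everywhere
        imgs = lf.encode_phase_contrast(field, lf.EncodingSpec(venc=1.2))
        np.testing.assert_allclose(imgs.phase, np.pi / 2, atol=1e-12)

    def test_constant_polynomial_offset_passes_through(self):
        field = lf.make_aliasing_phantom(shape=(12, 12, 12))
        field.values[...] = 0.0
        coeffs = np.zeros((3, 35))
        coeffs[:, 0] = 0.3  # constant term
        imgs = lf.encode_phase_contrast(field, lf.EncodingSpec(venc=1.2, poly_coeffs=coeffs))
        np.testing.assert_allclose(imgs.phase, 0.3, atol=1e-12)

    def test_wrap_arithmetic_beyond_venc(self):
        venc = 1.2
        field = lf.make_aliasing_phantom(shape=(12, 12, 12), venc=venc)
        field.values[...] = 1.5 * venc
        imgs = lf.encode_phase_contrast(field, lf.EncodingSpec(venc=venc))
        decoded = imgs.decode()
        np.testing.assert_allclose(decoded.values, -0.5 * venc, atol=1e-12)

    def test_round_trip_below_venc_is_exact(self, duct):
        imgs = lf.encode_phase_contrast(duct["field"], lf.EncodingSpec(venc=1.2))
        np.testing.assert_allclose(imgs.decode().values, duct["field"].values,
                                   atol=1e-14)

    def test_noise_reproducible_from_seed(self):
        field = lf.make_aliasing_phantom(shape=(10, 10, 10))
        enc = lf.EncodingSpec(venc=1.2, noise_sd=0.05)
        a = lf.encode_phase_contrast(field, enc, seed=3).phase
        b = lf.encode_phase_contrast(field, enc, seed=3).phase
        c = lf.encode_phase_contrast(field, enc, seed=4).phase
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_moving_static_region_rejected(self, duct):
        with pytest.raises(ValueError, match="static_region"):
            lf.encode_phase_contrast(duct["field"], lf.EncodingSpec(venc=1.2),
                                     static_region=np.ones(duct["field"].shape, bool))

    def test_wrap_phase_range(self):
        phi = np.linspace(-10, 10, 1001)
        w = wrap_phase(phi)
        assert np.all((w > -np.pi - 1e-12) & (w <= np.pi + 1e-12))
        np.testing.assert_allclose(np.exp(1j * w), np.exp(1j * phi), atol=1e-12)


@pytest.mark.parametrize(
    "tr, enc, kseg, want",
    [(5.1, 4, 2, 40.8), (7.0, 1, 1, 7.0), (2.8, 4, 2, 22.4)],
)
def test_temporal_resolution_arithmetic(tr, enc, kseg, want):
    assert lf.acquisition_temporal_resolution(tr, enc, kseg) == pytest.approx(want)


def test_temporal_resolution_rejects_nonpositive():
    with pytest.raises(ValueError):
        lf.acquisition_temporal_resolution(-5.1, 4, 2)
    with pytest.raises(ValueError):
        lf.acquisition_temporal_resolution(5.1, 0, 2)


def test_phantom_spec_validation():
    with pytest.raises(ValueError, match="sum to 1"):
        lf.PhantomSpec(fractions=(0.5, 0.5, 0.5, 0.5))
    with pytest.raises(ValueError, match="spacing"):
        lf.PhantomSpec(spacing=-1.0)
    with pytest.raises(ValueError, match="es_frame"):
        lf.PhantomSpec(es_frame=40)
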