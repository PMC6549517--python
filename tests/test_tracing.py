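"""Seeding, field interpolation and RK4 pathline integration."""

import numpy as np
import pytest

import lvflow as lf
from lvflow.fields import ChamberMask, VelocityField4D
from lvflow.timing import TimingResult
from lvflow.tracing import sample_velocity, seed_grid, trace_pathlines


def uniform_field(v=(0.1, 0.0, 0.0), n=20, nt=8, spacing=2.8e-3, cycle=1.0):
    values = np.zeros((n, n, n, nt, 3))
    values[...] = np.asarray(v)
    return VelocityField4D(values, np.full(3, spacing),
                           np.arange(nt) * cycle / nt, cycle, venc=1.2)


class TestSeedGrid:
    def test_cubic_mask_gives_lattice_count(self):
        # 10 voxels of 2.8 mm per side -> 1000 seeds at voxel spacing
        n = 16
        data = np.zeros((n, n, n), bool)
        data[3:13, 3:13, 3:13] = True
        mask = ChamberMask(data, frame=0, spacing=np.full(3, 2.8e-3))
        grid = seed_grid(mask)
        assert grid.n_seeds == 1000
        assert grid.seed_volume == pytest.approx(2.8e-3 ** 3)
        assert grid.seed_volume * 1e9 == pytest.approx(21.952)

    def test_total_volume_matches_mask_volume(self, duct):
        grid = seed_grid(duct["ed"])
        assert grid.total_volume == pytest.approx(duct["ed"].volume)

    def test_empty_mask_raises(self):
        mask = ChamberMask(np.zeros((8, 8, 8), bool), frame=0,
                           spacing=np.full(3, 2.8e-3))
        with pytest.raises(ValueError, match="empty"):
            seed_grid(mask)

    def test_nonpositive_spacing_raises(self, duct):
        with pytest.raises(ValueError, match="positive"):
            seed_grid(duct["ed"], spacing=-1.0)

    def test_coarser_lattice_represents_same_volume(self, duct):
        fine = seed_grid(duct["ed"])
        coarse = seed_grid(duct["ed"], spacing=2 * 2.8e-3)
        # within one cell per boundary voxel of the fine volume
        assert coarse.total_volume == pytest.approx(fine.total_volume, rel=0.35)


class TestSampleVelocity:
    def test_voxel_centre_at_frame_time_is_exact(self, duct):
        field = duct["field"]
        idx = (10, 12, 14)
        pos = field.voxel_to_world(np.array(idx))
        for f in (0, 5, 20):
            v, ok = sample_velocity(field, pos, field.frame_times[f])
            assert ok.all()
            np.testing.assert_allclose(v[0], field.values[idx][f], atol=1e-14)

    def test_spatial_midpoint_averages_neighbours(self):
        field = uniform_field()
        field.values[3, 5, 5, :, 0] = 0.2
        field.values[4, 5, 5, :, 0] = 0.4
        mid = field.voxel_to_world(np.array([3.5, 5, 5]))
        v, _ = sample_velocity(field, mid, 0.0)
        assert v[0, 0] == pytest.approx(0.3)

    def test_temporal_midpoint_averages_frames(self):
        field = uniform_field(nt=4)
        field.values[..., 0, 0] = 0.1
        field.values[..., 1, 0] = 0.3
        t_mid = 0.5 * (field.frame_times[0] + field.frame_times[1])
        pos = field.voxel_to_world(np.array([10, 10, 10]))
        v, _ = sample_velocity(field, pos, t_mid)
        assert v[0, 0] == pytest.approx(0.2)

    def test_out_of_bounds_flagged_not_raised(self):
        field = uniform_field()
        v, ok = sample_velocity(field, np.array([[-1.0, 0.0, 0.0]]), 0.0)
        assert not ok[0]
        assert np.all(np.isfinite(v))

    def test_cyclic_time_wraps(self):
        field = uniform_field(nt=4)
        pos = field.voxel_to_world(np.array([10, 10, 10]))
        v1, _ = sample_velocity(field, pos, 0.1)
        v2, _ = sample_velocity(field, pos, 0.1 + field.cycle_duration)
        np.testing.assert_allclose(v1, v2, atol=1e-14)


class TestTracePathlines:
    def _trace(self, field, mask, ed, es, **kw):
        return trace_pathlines(field, seed_grid(mask),
                               TimingResult(ed_frame=ed, es_frame=es), **kw)

    def test_uniform_field_displacement(self):
        # 0.1 m/s for the 0.5 s forward half-window -> 50 mm downstream
        field = uniform_field(v=(0.1, 0, 0), n=40, nt=8)
        data = np.zeros((40, 40, 40), bool)
        data[2:5, 18:22, 18:22] = True
        mask = ChamberMask(data, frame=0, spacing=np.full(3, 2.8e-3))
        pl = self._trace(field, mask, ed=0, es=4)
        fwd_disp = pl.positions[:, -1] - pl.positions[:, pl.ed_index]
        np.testing.assert_allclose(fwd_disp[:, 0], 0.05, atol=1e-9)
        np.testing.assert_allclose(fwd_disp[:, 1:], 0.0, atol=1e-9)

    def test_rotation_matches_closed_form(self, affine_rotation):
        spec, gt = affine_rotation["spec"], affine_rotation["gt"]
        pl = self._trace(affine_rotation["field"], affine_rotation["ed"],
                         spec.ed_frame, spec.es_frame)
        dev = max(
            np.max(np.linalg.norm(pl.positions[:, i] - gt.trajectory(t), axis=1))
            for i, t in enumerate(pl.times)
        )
        assert dev < 0.1 * spec.spacing

    def test_backward_forward_time_reversal(self, duct_traced):
        """Re-integrating forward from the backward endpoint returns to the seed."""
        pl, field = duct_traced["pathlines"], duct_traced["field"]
        sel = np.arange(0, pl.n_seeds, 197)
        start = pl.positions[sel, 0]
        grid = lf.SeedGrid(start, spacing=2.8e-3, seed_volume=2.8e-3 ** 3)
        # integrate forward over the backward window by shifting the timing axis
        pos = start.copy()
        n_sub = pl.meta["n_substeps"]
        from lvflow.tracing import _rk4_span
        frozen = np.zeros(len(sel), bool)
        valid = np.ones(len(sel), bool)
        et = np.full(len(sel), np.nan)
        epos = np.full((len(sel), 3), np.nan)
        for i in range(pl.ed_index):
            pos = _rk4_span(field, pos, pl.times[i], pl.times[i + 1], n_sub,
                            frozen, valid, et, epos)
        back_to_seed = np.linalg.norm(pos - pl.positions[sel, pl.ed_index], axis=1)
        assert back_to_seed.max() < 1e-3 * 2.8e-3
        assert grid.n_seeds == len(sel)

    def test_pathline_count_equals_seed_count(self, duct_traced):
        assert duct_traced["pathlines"].n_seeds == duct_traced["seeds"].n_seeds

    def test_position_at_ed_equals_seed(self, duct_traced):
        pl = duct_traced["pathlines"]
        np.testing.assert_array_equal(pl.seed_positions,
                                      duct_traced["seeds"].positions)

    def test_times_strictly_increasing_and_span_cycle(self, duct_traced):
        pl = duct_traced["pathlines"]
        assert np.all(np.diff(pl.times) > 0)
        assert pl.times[-1] - pl.times[0] == pytest.approx(1.0)

    def test_fourth_order_convergence(self, affine_rotation):
        spec = affine_rotation["spec"]
        timing = TimingResult(ed_frame=spec.ed_frame, es_frame=spec.es_frame)
        # subsample seeds for speed
        seeds = seed_grid(affine_rotation["ed"])
        sub = lf.SeedGrid(seeds.positions[::53], seeds.spacing, seeds.seed_volume)
        ends = {}
        for frac in (1.0, 0.5, 0.25):
            pl = trace_pathlines(affine_rotation["field"], sub, timing,
                                 step_fraction=frac)
            ends[frac] = pl.positions[:, -1]
        d1 = np.max(np.linalg.norm(ends[1.0] - ends[0.5], axis=1))
        d2 = np.max(np.linalg.norm(ends[0.5] - ends[0.25], axis=1))
        assert d2 < d1 / 8

    def test_domain_exit_frozen_and_flagged(self):
        field = uniform_field(v=(0.5, 0, 0), n=12, nt=8)  # exits quickly
        data = np.zeros((12, 12, 12), bool)
        data[8:11, 4:8, 4:8] = True
        mask = ChamberMask(data, frame=0, spacing=np.full(3, 2.8e-3))
        pl = trace_pathlines(field, seed_grid(mask),
                             TimingResult(ed_frame=0, es_frame=4))
        assert pl.truncated.all()
        hi = field.bounds[1]
        assert np.all(pl.positions[:, -1, 0] <= hi[0] + 1e-12)
        assert np.all(np.isfinite(pl.exit_time[pl.truncated]))

    def test_bad_step_fraction_rejected(self, duct):
        with pytest.raises(ValueError, match="step_fraction"):
            self._trace(duct["field"], duct["ed"], 0, 15, step_fraction=0.0)
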