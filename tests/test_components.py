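"""Flow-component classification, volumes, kinetic energy, late-diastolic split."""

import numpy as np
import pytest

import lvflow as lf
from lvflow.components import (
    COMPONENTS,
    DELAYED_EJECTION,
    DIRECT_FLOW,
    EXCLUDED,
    RESIDUAL_VOLUME,
    RETAINED_INFLOW,
    KEConfig,
    classify_components,
    component_kinetic_energy,
    component_volumes,
    derived_flow_volumes,
    late_diastolic_split,
)
from lvflow.fields import ChamberMask
from lvflow.tracing import Pathlines


def toy_pathlines(start_xs, end_xs, seed_volume=21.952e-9, ed_speed=1.0):
    """Straight two-sample pathlines along x, ED sample in the middle."""
    n = len(start_xs)
    times = np.array([-0.5, 0.0, 0.5])
    pos = np.zeros((n, 3, 3))
    pos[:, 0, 0] = start_xs
    pos[:, 1, 0] = 0.5 * (np.asarray(start_xs) + np.asarray(end_xs))
    pos[:, 2, 0] = end_xs
    pos[:, :, 1] = pos[:, :, 2] = 0.05
    vel = np.zeros((n, 3, 3))
    vel[:, 1, 0] = ed_speed
    return Pathlines(
        times=times, positions=pos, velocities=vel, ed_index=1,
        seed_volume=seed_volume,
        valid=np.ones(n, bool), truncated=np.zeros(n, bool),
        exit_time=np.full(n, np.nan), exit_position=np.full((n, 3), np.nan),
    )


@pytest.fixture()
def box_mask():
    """LV spanning x in [0.028, 0.084) m on a 40-voxel 2.8 mm grid."""
    data = np.zeros((40, 40, 40), bool)
    data[10:30, 10:30, 10:30] = True
    return ChamberMask(data, frame=15, spacing=np.full(3, 2.8e-3))


class TestClassification:
    def test_origin_fate_truth_table(self, box_mask):
        # (origin x, fate x): outside the box is < 0.028 or >= 0.084
        pl = toy_pathlines(
            start_xs=[0.010, 0.010, 0.050, 0.050],
            end_xs=[0.100, 0.050, 0.100, 0.050],
        )
        labels = classify_components(pl, box_mask)
        assert list(labels) == [DIRECT_FLOW, RETAINED_INFLOW,
                                DELAYED_EJECTION, RESIDUAL_VOLUME]

    def test_invalid_and_truncated_excluded(self, box_mask):
        pl = toy_pathlines([0.010, 0.010, 0.050], [0.100, 0.050, 0.100])
        pl.valid[0] = False
        pl.truncated[1] = True
        labels = classify_components(pl, box_mask)
        assert list(labels) == [EXCLUDED, EXCLUDED, DELAYED_EJECTION]

    def test_duct_phantom_matches_ground_truth(self, duct_traced):
        labels = duct_traced["result"].labels.astype(str)
        agreement = np.mean(labels == duct_traced["gt"].labels)
        assert agreement >= 0.98

    def test_nearest_inside_test_agrees_on_interior(self, duct_traced):
        pl, es = duct_traced["pathlines"], duct_traced["es"]
        a = classify_components(pl, es, inside_test="interpolated")
        b = classify_components(pl, es, inside_test="nearest")
        assert np.mean(a == b) > 0.97


class TestVolumes:
    def test_count_times_seed_volume(self):
        labels = np.array([DIRECT_FLOW] * 100 + [RESIDUAL_VOLUME] * 50, dtype=object)
        vols, ratios = component_volumes(labels, 21.952e-9)
        assert vols[DIRECT_FLOW] * 1e6 == pytest.approx(2.1952)
        assert ratios[DIRECT_FLOW] == pytest.approx(100 * 100 / 150)

    def test_single_label_takes_all(self):
        labels = np.array([RETAINED_INFLOW] * 7, dtype=object)
        _, ratios = component_volumes(labels, 1e-9)
        assert ratios[RETAINED_INFLOW] == 100.0
        assert all(ratios[c] == 0.0 for c in COMPONENTS if c != RETAINED_INFLOW)

    def test_duct_ratios_within_two_points_of_prescription(self, duct_traced):
        ratios = duct_traced["result"].volume_ratios
        for name, want in zip(COMPONENTS, duct_traced["spec"].fractions):
            assert ratios[name] == pytest.approx(100 * want, abs=2.0)

    def test_ratios_sum_to_100(self, duct_traced):
        assert sum(duct_traced["result"].volume_ratios.values()) == pytest.approx(
            100.0, abs=1e-6)


class TestKineticEnergy:
    def test_single_pathline_reference_value(self):
        # ½ · 1060 kg/m³ · 21.952 mm³ · (1 m/s)² = 0.011635 mJ
        pl = toy_pathlines([0.010], [0.100], ed_speed=1.0)
        labels = np.array([DIRECT_FLOW], dtype=object)
        ke, ratios, _ = component_kinetic_energy(pl, labels, KEConfig(rho=1060.0))
        assert ke[DIRECT_FLOW] * 1e3 == pytest.approx(0.0116346, rel=1e-4)
        assert ratios[DIRECT_FLOW] == pytest.approx(100.0)

    def test_zero_velocities_zero_ke(self):
        pl = toy_pathlines([0.010], [0.100], ed_speed=0.0)
        ke, ratios, _ = component_kinetic_energy(
            pl, np.array([DIRECT_FLOW], dtype=object))
        assert ke[DIRECT_FLOW] == 0.0
        assert np.isnan(ratios[DIRECT_FLOW])

    def test_doubling_speed_quadruples_ke_ratios_invariant(self, duct_traced):
        pl, res = duct_traced["pathlines"], duct_traced["result"]
        ke1, r1, _ = component_kinetic_energy(pl, res.labels)
        fast = Pathlines(
            times=pl.times, positions=pl.positions, velocities=2 * pl.velocities,
            ed_index=pl.ed_index, seed_volume=pl.seed_volume, valid=pl.valid,
            truncated=pl.truncated, exit_time=pl.exit_time,
            exit_position=pl.exit_position)
        ke2, r2, _ = component_kinetic_energy(fast, res.labels)
        for c in COMPONENTS:
            assert ke2[c] == pytest.approx(4 * ke1[c], rel=1e-12)
            if not np.isnan(r1[c]):
                assert r2[c] == pytest.approx(r1[c], rel=1e-12)

    def test_ke_ratios_sum_to_100(self, duct_traced):
        assert sum(duct_traced["result"].ke_ratios.values()) == pytest.approx(
            100.0, abs=1e-6)


class TestDerivedVolumes:
    def test_stated_sums(self):
        vols = dict(zip(COMPONENTS, (30.0, 20.0, 18.0, 32.0)))
        d = derived_flow_volumes(vols)
        assert d == {"inflow": 50.0, "stroke": 48.0, "non_ejected": 52.0}

    def test_zero_components_zero_derived(self):
        d = derived_flow_volumes(dict.fromkeys(COMPONENTS, 0.0))
        assert all(v == 0.0 for v in d.values())

    def test_partition_identity(self, duct_traced):
        res = duct_traced["result"]
        d = res.derived_volumes
        # inflow + DEF + RV = traced LVEDV, exactly
        assert d["inflow"] + res.volumes[DELAYED_EJECTION] + \
            res.volumes[RESIDUAL_VOLUME] == res.lvedv_traced
        assert d["inflow"] == res.volumes[DIRECT_FLOW] + res.volumes[RETAINED_INFLOW]
        assert d["stroke"] == res.volumes[DIRECT_FLOW] + res.volumes[DELAYED_EJECTION]
        assert d["non_ejected"] == res.volumes[RETAINED_INFLOW] + res.volumes[RESIDUAL_VOLUME]


class TestLateDiastolicSplit:
    def test_half_late_gives_fifty_percent(self):
        labels = np.array([DIRECT_FLOW] * 4, dtype=object)
        entry = np.array([-0.5, -0.4, -0.2, -0.1])
        ke = np.ones(4)
        vol_pct, ke_pct = late_diastolic_split(labels, entry, ke, -0.3)
        assert vol_pct == 50.0
        assert ke_pct == 50.0

    def test_onset_at_window_start_means_all_late(self, duct_traced):
        res = duct_traced["result"]
        pl = duct_traced["pathlines"]
        _, ke_per = None, None
        from lvflow.components import component_kinetic_energy
        _, _, ke_per = component_kinetic_energy(pl, res.labels)
        vol_pct, ke_pct = late_diastolic_split(res.labels, res.entry_times,
                                               ke_per, pl.times[0])
        assert vol_pct == 100.0
        assert ke_pct == 100.0

    def test_onset_at_ed_means_none_late(self, duct_traced):
        res = duct_traced["result"]
        pl = duct_traced["pathlines"]
        from lvflow.components import component_kinetic_energy
        _, _, ke_per = component_kinetic_energy(pl, res.labels)
        vol_pct, ke_pct = late_diastolic_split(res.labels, res.entry_times,
                                               ke_per, pl.times[pl.ed_index] + 1e-12)
        assert vol_pct == 0.0
        assert ke_pct == 0.0

    def test_zero_inflow_raises(self):
        labels = np.array([RESIDUAL_VOLUME] * 3, dtype=object)
        with pytest.raises(ValueError, match="inflow"):
            late_diastolic_split(labels, np.full(3, np.nan), np.ones(3), 0.0)

    def test_pipeline_matches_analytic_entry_schedule(self, duct_traced):
        gt = duct_traced["gt"]
        res = duct_traced["result"]
        onset = gt.meta["late_onset_time"]
        inflow = np.isin(gt.labels, [DIRECT_FLOW, RETAINED_INFLOW])
        want = 100.0 * np.mean(gt.entry_times[inflow] >= onset)
        assert res.late_volume_pct == pytest.approx(want, abs=1.0)

    def test_entry_times_match_closed_form(self, duct_traced):
        got = duct_traced["result"].entry_times
        want = duct_traced["gt"].entry_times
        mask = ~np.isnan(want)
        assert np.nanmax(np.abs(got[mask] - want[mask])) < 1e-3
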