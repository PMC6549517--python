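#!/usr/bin/env python
"""Paired two-timepoint comparison on a synthetic 10-subject cohort.

Emulates the study design: each subject is examined right after restoration
of sinus rhythm, while the atrium is mechanically stunned (Time-1), and
again four weeks later when atrial contraction has recovered (Time-2).
Per subject, flow-component fractions, ejection fraction, heart rate and LA
areas are drawn from the two conditions' published distributions (depressed
Direct flow / inflated Residual volume and low LA FAC at Time-1, recovery
at Time-2); the full pipeline then runs on a duct phantom per exam and the
paired t / Wilcoxon / KS workflow compares every metric.

Writes results/cohort_time1.csv, cohort_time2.csv and cohort_comparison.csv.
"""

from pathlib import Path

import numpy as np

import lvflow as lf
import lvflow.io as lio
from lvflow.fields import ChamberMask
from lvflow.metrics import la_fractional_area_change, lv_global_metrics
from lvflow.qc import inflow_outflow_discrepancy
from lvflow.stats import compare_metrics_tables
from lvflow.timing import TimingResult

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 1
N_SUBJECTS = 10
GRID = (40, 40, 40)

# Time-1 (atrial stunning) component means/SDs in % of LVEDV, and the mean
# per-subject change to Time-2 (recovered atrial contraction)
T1_MEAN = np.array([29.0, 20.0, 18.0, 32.0])
T1_SD = np.array([8.0, 3.0, 3.0, 7.0])
T2_SHIFT = np.array([8.0, 0.0, 1.0, -7.0])


def volume_mask(volume_ml: float, frame: int, n: int = 24,
                spacing: float = 2.8e-3) -> ChamberMask:
    nvox = int(round(volume_ml / (spacing**3 * 1e6)))
    data = np.zeros(n**3, bool)
    data[:nvox] = True
    return ChamberMask(data.reshape(n, n, n), frame=frame,
                       spacing=np.full(3, spacing))


def draw_fractions(rng, mean, sd):
    f = np.clip(rng.normal(mean, sd), 2.0, None)
    return tuple(f / f.sum())


def run_exam(fractions, ef_pct, hr_bpm, la_max, la_fac, height, weight,
             subject, rng):
    spec = lf.PhantomSpec(shape=GRID, fractions=fractions)
    field, ed, es, gt = lf.make_duct_phantom(spec)
    timing = TimingResult(ed_frame=spec.ed_frame, es_frame=spec.es_frame)
    pl = lf.trace_pathlines(field, lf.seed_grid(ed), timing)
    comp = lf.analyze_lv_flow(pl, es, ed, gt.meta["late_onset_time"])
    qc = inflow_outflow_discrepancy(comp)

    edv = 85.0 * np.sqrt(height * weight / 3600.0)  # EDVI 85 ml/m² of BSA
    case = lv_global_metrics(
        volume_mask(edv, 0), volume_mask(edv * (1 - ef_pct / 100), 15),
        heart_rate_bpm=hr_bpm, height_cm=height, weight_kg=weight)
    jitter = rng.normal(0, 0.3, 4)
    fac, big, small = la_fractional_area_change(
        (la_max + jitter[0], la_max + jitter[1]),
        (la_max * (1 - la_fac / 100) + jitter[2],
         la_max * (1 - la_fac / 100) + jitter[3]))
    case.la_max_area_cm2, case.la_min_area_cm2, case.la_fac_pct = big, small, fac
    return lio.results_row(case, comp, qc, subject=subject)


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)
    rows1, rows2 = [], []
    for i in range(N_SUBJECTS):
        subject = f"subj{i:02d}"
        height = rng.normal(182, 10)
        weight = rng.normal(92, 13)
        fr1 = draw_fractions(rng, T1_MEAN, T1_SD)
        fr2 = draw_fractions(rng, 100 * np.array(fr1) + T2_SHIFT,
                             np.full(4, 2.0))
        ef1 = float(np.clip(rng.normal(53, 8), 40, 70))
        ef2 = float(np.clip(ef1 + rng.normal(8, 2), 40, 78))
        hr1, hr2 = rng.normal(61, 5), rng.normal(56, 6)
        la_max1 = rng.normal(36, 6)
        fac1 = float(np.clip(rng.normal(20, 5), 5, 40))
        fac2 = float(np.clip(fac1 + rng.normal(10, 3), 5, 50))
        print(f"{subject}: DF {100*fr1[0]:.0f}->{100*fr2[0]:.0f}% of LVEDV, "
              f"EF {ef1:.0f}->{ef2:.0f}%, FAC {fac1:.0f}->{fac2:.0f}%")
        rows1.append(run_exam(fr1, ef1, hr1, la_max1, fac1, height, weight,
                              subject, rng))
        rows2.append(run_exam(fr2, ef2, hr2, la_max1 - rng.normal(3, 1), fac2,
                              height, weight, subject, rng))

    t1 = lio.write_results(rows1, RESULTS / "cohort_time1.csv")
    t2 = lio.write_results(rows2, RESULTS / "cohort_time2.csv")

    # the duct phantom fixes the entry schedule and gives non-moving lanes
    # zero KE at ED, so late-diastolic share, EDVI and residual-volume KE are
    # structurally constant here and left out of the comparison
    metrics = [
        "ef_pct", "la_fac_pct",
        "direct_flow_volume_pct", "retained_inflow_volume_pct",
        "delayed_ejection_volume_pct", "residual_volume_volume_pct",
        "direct_flow_ke_pct", "retained_inflow_ke_pct",
        "inflow_volume_ml", "stroke_volume_ml", "non_ejected_volume_ml",
    ]
    cmp = compare_metrics_tables(t1, t2, metrics=metrics)
    cmp.to_csv(RESULTS / "cohort_comparison.csv", index=False)
    print("\npaired Time-1 vs Time-2 comparison (n = %d):" % N_SUBJECTS)
    for _, r in cmp.iterrows():
        star = " *" if r["significant"] else ""
        print(f"  {r['metric']:<30} {r['mean_t1']:7.1f} ± {r['sd_t1']:4.1f}  ->  "
              f"{r['mean_t2']:7.1f} ± {r['sd_t2']:4.1f}   p_t={r['p_paired_t']:.4f} "
              f"p_w={r['p_wilcoxon']:.4f}{star}")
    print(
        "\nthe recovery condition shows the expected pattern: Direct flow and "
        "LA FAC rise, Residual volume falls, Retained inflow and Delayed "
        "ejection stay put."
    )


if __name__ == "__main__":
    main()
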