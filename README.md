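# lvflow — left-ventricular flow-component analysis for 4D flow CMR

`lvflow` analyses time-resolved, three-directional phase-contrast MRI
(4D flow CMR) of the left ventricle. Given the velocity field over one
cardiac cycle plus binary LV segmentations at end-diastole (ED) and
end-systole (ES), it separates the end-diastolic blood volume into the four
functional flow components used to characterise LV function and
atrio-ventricular coupling, and quantifies their volumes and kinetic
energies. It is aimed at researchers in cardiovascular imaging who want a
tested, scriptable version of this analysis with synthetic ground-truth
phantoms for validation.

## The method

Pathlines — trajectories of virtual blood particles — are emitted at ED
from an isotropic grid filling the LV segmentation, one seed per grid cell,
each representing a blood volume equal to the cell (21.952 mm³ at the
standard 2.8 mm grid). Each seed is integrated **backward** through
diastole to the preceding end-systole (*where did this blood come from?*)
and **forward** through systole to end-systole (*where is it going?*) with
fixed-step RK4 on the trilinearly/linearly interpolated field. The ES
segmentation classifies each trajectory's origin and fate:

| component | at previous ES | at end-systole |
|---|---|---|
| Direct flow (DF) | outside LV | outside LV (ejected) |
| Retained inflow (RI) | outside LV | inside LV |
| Delayed ejection flow (DEF) | inside LV | outside LV (ejected) |
| Residual volume (RV) | inside LV | inside LV |

Per component the pipeline reports volume V(c) = N(c)·Δx³ and kinetic
energy at ED, KE(c) = Σ ½ ρ V_p |v_p(t_ED)|² (ρ = 1060 kg/m³), both
absolute and as % of LVEDV / total KE, plus the derived volumes

    LV inflow   = DF + RI        stroke volume = DF + DEF
    non-ejected = RI + RV

the late-diastolic share of the inflow (entries after the diastasis onset,
detected from the LV volume curve), conventional chamber metrics (LVEF,
BSA-indexed volumes, cardiac output, LA fractional area change), and the
standard quality gates (inflow-vs-outflow discrepancy with a 15% exclusion
threshold; aberrant-pathline fraction).

Upstream, the package inverts the two phase-contrast acquisition
artifacts: eddy-current background offsets (degree-4 trivariate polynomial
fitted to static tissue and subtracted) and velocity aliasing beyond ±VENC
(per-voxel temporal unwrap by exact minimisation of the cyclic
frame-to-frame jump). Downstream, a paired t / Wilcoxon / Kolmogorov–
Smirnov workflow compares any metric across two timepoints of a cohort.

Because clinical 4D flow exams are rarely shareable, the package ships
synthetic phantoms with *closed-form* trajectories: a duct phantom whose
flow lanes realise any prescribed component fractions with analytic entry
times, an affine-motion phantom for integrator accuracy, and a
phase-contrast encoder that injects the background polynomial, wraps and
noise that preprocessing must remove.

## Worked example

```python
import lvflow as lf
from lvflow.timing import TimingResult

spec = lf.PhantomSpec(shape=(64, 64, 64), fractions=(0.30, 0.20, 0.18, 0.32))
field, ed_mask, es_mask, truth = lf.make_duct_phantom(spec)

pathlines = lf.trace_pathlines(field, lf.seed_grid(ed_mask),
                               TimingResult(ed_frame=0, es_frame=15))
result = lf.analyze_lv_flow(pathlines, es_mask, ed_mask,
                            late_onset_time=truth.meta["late_onset_time"])
for c in lf.COMPONENTS:
    print(f"{c:<22} {result.volumes[c]*1e6:6.2f} ml ({result.volume_ratios[c]:5.2f}%)")
```

prints

```
Direct flow            114.57 ml (29.98%)
Retained inflow         76.50 ml (20.02%)
Delayed ejection flow   68.67 ml (17.97%)
Residual volume        122.40 ml (32.03%)
```

i.e. the pipeline recovers the prescribed fractions (30/20/18/32% of a
382 ml chamber) to within the seed-grid quantisation; the inflow/outflow
discrepancy of this exam is 4.1% (pass at the 15% gate) and classification
agrees with the analytic ground truth for 100% of the 17 408 pathlines.

The numbered drivers under `analysis/` run the full study: `01` builds the
phantoms, `02` demonstrates the artifact corrections, `03` runs the
component separation above, and `04` simulates a 10-subject two-timepoint
cohort (depressed vs recovered atrial function) and applies the paired
statistics; tables land in `results/`.

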