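# Methods

This note documents the models, conventions and design choices behind
`lvflow`, and what the synthetic validation does and does not establish
about real data.

## Coordinates, units, timing

All in-memory quantities are SI (m, s, m/s, J); clinical units (mm, cm/s,
ml, mJ) exist only at the I/O boundary and in printed tables. Voxel
indices are 0-based and the centre of voxel *i* lies at
`origin + (i + 0.5)·spacing` — seeds, interpolation and mask tests all use
this convention, so a seed "at a voxel centre" is exact.

The cardiac cycle is cyclic: frame times live in `[0, RR)` and all temporal
interpolation wraps. Pathlines are analysed on an unwrapped axis spanning
one cycle from the *previous* end-systole (negative times) through ED
(t = 0 when ED is frame 0) to end-systole. ED is defined as one timeframe
after mitral-valve closure and ES as one timeframe before mitral-valve
opening (cyclic arithmetic); valve events are manual inputs. The onset of
late diastole is the end of early filling: after the E-wave peak of dV/dt
(central differences on the cyclic LV volume curve), the first diastolic
frame where dV/dt drops below a configurable fraction (default 10%) of
that peak. The threshold is a package choice — diastasis flow is
near-zero, so any small fraction marks the same shoulder; degenerate
(monotone/flat) curves fall back to the diastolic midpoint with a warning.
The ED frame itself is excluded as a candidate onset since filling has
ended there by definition.

## Preprocessing

*Background phase.* Eddy-current offsets are modelled as a full trivariate
polynomial of total degree 4 (35 monomials) per velocity direction, on grid
coordinates normalised to [-1, 1]³ for conditioning. The fit target is the
*temporal-mean* velocity of static-tissue voxels (temporal velocity SD
below 0.03 m/s by default, optionally gated by an image-magnitude floor):
the offset is static in time, and averaging suppresses noise; per-frame
fits would add variance without bias benefit. The fitted surface is
subtracted from every frame. The fit refuses rank-deficient static sets
(e.g. coplanar voxels) rather than extrapolating.

*Velocity aliasing.* Within one voxel's cyclic time series, wraps add
integer multiples of 2·VENC. The unwrapper minimises the total absolute
frame-to-frame jump over offsets in ±2 wraps (±2 wraps on a 1.2 m/s VENC
already admits 6 m/s, far beyond intracardiac speeds) by exact dynamic
programming with cyclic closure; ties break towards the smallest total
|offset|, so wrap-free series are provably returned unchanged. Voxels
whose largest cyclic jump is below VENC are skipped (zero offsets are
optimal there). One honest limitation of *any* temporal-jump criterion: a
plateau that aliases to a small value with single-frame transitions
produces only small apparent jumps and is left alone; recovery requires
the ramps to be temporally resolved, which the aliasing test phantom
therefore provides.

## Pathline engine

Seeds sit on an isotropic lattice clipped to the ED mask (default spacing =
voxel size, which aligns the lattice to voxel centres so the represented
volume equals the segmented volume exactly; each seed carries spacing³ of
blood). Integration is classical fixed-step RK4, five steps per frame
interval by default (`step_fraction = 0.2`), on a field that is trilinear
in space and linear in time. RK4 was chosen because its 4th-order
convergence is itself a testable property (halving the step shrinks the
endpoint error ≈16×), substituting for bit-compatibility with any
particular clinical implementation, which is unspecified. Trajectories
that leave the grid are frozen at the exit point and flagged rather than
extrapolated; flagged pathlines are excluded from the component analysis
and counted by QC, mirroring the visual rejection of aberrant traces in
clinical workflows.

## Component separation

Origin (backward endpoint at the previous ES) and fate (forward endpoint at
ES) are tested against the ES segmentation with trilinear mask
interpolation ≥ 0.5 (sub-voxel-consistent with the velocity interpolation;
a nearest-voxel test is available). Entry times of inflow pathlines are
the last outside→inside crossing of the *ED* mask along the backward
branch, linearly interpolated between recorded samples; the ED mask proxies
the diastolic chamber because the pipeline carries no time-resolved
segmentation — a recorded limitation. KE is evaluated at the ED sample
with ρ = 1060 kg/m³ (configurable; conventions differ between groups).
Volume ratios and KE ratios each sum to 100% by construction, and
inflow = DF + RI, stroke = DF + DEF, non-ejected = RI + RV hold exactly
because the label partition is exhaustive and exclusive.

QC operationalises "outflow" as the flow-component stroke volume
(DF + DEF), keeping the inflow/outflow discrepancy internal to the
pathline analysis (no outflow-plane flux is measured); the exclusion
threshold defaults to 15%.

## Statistics

Two-sided paired t-tests with a Wilcoxon signed-rank companion (zero
differences dropped; exact null up to n = 25) and a plain KS normality
check of the differences against a normal with the sample's own moments
(no Lilliefors correction — the flag is advisory, not a gate). No
multiple-testing correction is applied. α = 0.05.

## Synthetic phantoms: what they emulate, and what they do not

*Duct phantom.* A fixed box "chamber" fed by straight lanes along x; each
lane's axial speed switches between a diastolic and a systolic plateau
(linear one-frame ramps on the frame grid), sized so that a moving lane's
transit over its phase is 1.15× the chamber length. Lane groups therefore
realise the four components exactly, at any prescribed fractions
(largest-remainder apportionment of the lane cross-section; default
fractions 0.30/0.20/0.18/0.32, the split typical of depressed atrial
function). The diastolic plateau stays on through the ED frame so inflow
carries nonzero KE at ED (the ~0.7 mm of spill-over into early systole is
below half a voxel and flips no labels); the systolic plateau is zeroed at
the ES frame so no systolic motion leaks across the cyclic boundary into
the backward-trace window. Transit distances, trajectories and entry times
come from exact quadrature of the linearly-interpolated lane-speed series,
so the ground truth equals what a perfect integrator of the gridded field
would produce. Because lanes run straight through, instantaneous lane
inflow equals outflow and volume is conserved; the residual inflow/outflow
discrepancy of the *analysis* is then analytic, |RI − DEF| / (DF + RI)
(4% at the default fractions, 0 for balanced ones).

What the duct does **not** emulate: chamber-wall motion (ED and ES masks
coincide, so mask-derived EF is 0 and EDV stays constant), vortical flow,
a valve plane, spatial velocity gradients within lanes, and any
physiological entry schedule (the late-diastolic share is fixed by lane
geometry, not atrial function). Passing its tests shows the *machinery* —
tracing, classification, bookkeeping, QC — is correct, not that the
pipeline is robust to segmentation error or in-vivo flow complexity.

*Affine phantom.* x(t) = A(t)x₀ + b(t) with
v(x,t) = A′A⁻¹(x − b) + b′ — exactly affine in space, hence trilinear
interpolation is exact and the only numerical errors are temporal. The
rotation motion (ω about z) has a time-independent field and closed-form
circular trajectories: the integrator-accuracy oracle. Translation and
diagonal contraction cover the trivial and volume-changing cases.

*Encoder.* φ = π·v/VENC + P₄(x, y, z) + ε, wrapped into (−π, π]; noise is
Gaussian *in phase* (the physical encoding model), reproducible from a
seed; the background polynomial is constant over the cycle. The injected
and fitted polynomial share one basis, so recovery is testable at the
coefficient level. Acquired temporal resolution follows
TR × (encodings per sample) × (k-space segmentation factor), e.g.
5.1 ms × 4 × 2 = 40.8 ms; the factor 4 (reference + three flow encodes)
is a parameter, since referenced 4-point encoding is an assumption.

## Problem sizes and numerical tolerances

The validation phantoms use the clinical acquisition geometry — 2.8 mm
isotropic voxels, 40 frames, VENC 1.2 m/s — at 64³ voxels (≈17 000
pathlines) for the headline run and 24–32³ for unit tests; these sizes
make every check exhaustive rather than sampled while keeping a full run
in seconds. Key tolerances: component-ratio recovery within 2 points of
prescription (seed-grid quantisation dominates; observed ≤ 0.04),
integrator deviation < 0.1 voxel versus closed form (observed ~10⁻⁸),
artifact inversion < 10⁻⁶ m/s for |v| < 2·VENC (observed ~10⁻¹⁵),
conservation sums to 10⁻⁶%, and statistical oracles to 10⁻¹⁰.

## Known limitations

Beyond the phantom caveats above: no Maxwell (concomitant-gradient)
correction — assumed done at reconstruction; no spatial phase unwrapping;
no time-resolved segmentation (single ED/ES masks); no vortex
quantification or turbulence/energy-loss metrics; LA analysis is limited to
planimetric areas supplied per exam; the HDF5 exam layout is this
package's own and claims no compatibility with clinical tools' internal
formats.
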