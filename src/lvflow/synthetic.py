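"""Synthetic velocity-field phantoms with analytically known pathlines.

Two phantom families provide ground truth for every downstream stage:

* **Duct phantom** — a box-shaped "LV" fed by straight flow lanes.  Each
  lane carries a constant axial speed that switches between a diastolic and
  a systolic regime, chosen so that all blood in a lane realises exactly one
  of the four flow components (Direct flow, Retained inflow, Delayed
  ejection flow, Residual volume) with a prescribed volume fraction.  Entry
  times and trajectories are available in closed form (exact quadrature of
  the linearly-interpolated lane-speed series), so component labels, entry
  schedules and transit distances can be checked without a numerical
  integrator.
* **Affine phantom** — a time-varying affine motion x(t) = A(t)x0 + b(t)
  whose velocity field v(x,t) = A'(t)A(t)^-1 (x - b(t)) + b'(t) is affine in
  space.  Trajectories are known in closed form, which makes it the
  accuracy/convergence oracle for the pathline integrator.

A phase-contrast encoder turns any velocity field into wrapped phase
images with a degree-4 background polynomial and Gaussian phase noise — the
forward model of the two artifacts the preprocessing stage inverts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as _field
from typing import Callable

import numpy as np
from scipy.optimize import brentq

from . import polynomial
from .components import (
    COMPONENTS,
    DELAYED_EJECTION,
    DIRECT_FLOW,
    RESIDUAL_VOLUME,
    RETAINED_INFLOW,
)
from .fields import ChamberMask, VelocityField4D
from .timing import frame_time_in_window as _frame_time_in_window

__all__ = [
    "PhantomSpec",
    "EncodingSpec",
    "GroundTruth",
    "PhaseImages",
    "make_duct_phantom",
    "make_affine_phantom",
    "encode_phase_contrast",
    "acquisition_temporal_resolution",
    "wrap_phase",
]

# geometry constants of the duct phantom
SHELL = 2            # zero-velocity "tissue" shell, voxels per side
TRANSIT_MARGIN = 1.15  # transit distance of moving lanes, in units of box length


@dataclass
class PhantomSpec:
    """Parameters of a synthetic phantom.

    The defaults describe a 64³ grid at 2.8 mm isotropic voxels and 40
    reconstructed frames over a 1 s cycle — the acquisition geometry of a
    typical clinical 4D flow exam — with component fractions
    (0.30, 0.20, 0.18, 0.32), i.e. the Direct flow / Retained inflow /
    Delayed ejection flow / Residual volume split observed in patients with
    depressed atrial function.
    """

    phantom_kind: str = "duct"
    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: float = 2.8e-3        # isotropic voxel size, m
    n_frames: int = 40
    cycle_duration: float = 1.0    # s
    ed_frame: int = 0
    es_frame: int = 15
    late_onset_frame: int = 28     # first frame of late diastole
    fractions: tuple[float, float, float, float] = (0.30, 0.20, 0.18, 0.32)
    peak_speed: float = 1.0        # upper bound on lane speeds, m/s
    venc: float = 1.2              # m/s (120 cm/s)
    seed: int = 0
    # affine-motion parameters (used when phantom_kind == "affine")
    affine_motion: str = "rotation"          # translation | rotation | contraction
    translation_velocity: tuple[float, float, float] = (0.1, 0.0, 0.0)  # m/s
    omega: float = math.pi                   # rotation rate about z, rad/s
    contraction: tuple[float, float, float] = (-0.3, -0.3, 0.2)  # axis scale rates per cycle

    def __post_init__(self) -> None:
        if self.phantom_kind not in ("duct", "affine"):
            raise ValueError(f"unknown phantom_kind {self.phantom_kind!r}")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"component fractions must sum to 1, got {sum(self.fractions)}")
        if min(self.fractions) < 0:
            raise ValueError("component fractions must be non-negative")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        for name, f in (("ed_frame", self.ed_frame), ("es_frame", self.es_frame),
                        ("late_onset_frame", self.late_onset_frame)):
            if not 0 <= f < self.n_frames:
                raise ValueError(f"{name}={f} outside [0, {self.n_frames})")
        if self.ed_frame == self.es_frame:
            raise ValueError("ED and ES frames must differ")

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.cycle_duration / self.n_frames


@dataclass
class GroundTruth:
    """Analytic truth for a phantom's seeds.

    ``labels`` holds one component name per seed; ``entry_times`` the LV
    entry time in seconds for inflow seeds (NaN elsewhere); ``trajectory``
    maps a time to the closed-form positions ``(n_seeds, 3)`` of all seeds.
    """

    labels: np.ndarray
    entry_times: np.ndarray
    seed_positions: np.ndarray
    trajectory: Callable[[float], np.ndarray]
    meta: dict = _field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(np.unique(self.labels)) - set(COMPONENTS)
        if bad:
            raise ValueError(f"unknown component labels: {bad}")
        inflow = np.isin(self.labels, [DIRECT_FLOW, RETAINED_INFLOW])
        if np.any(np.isnan(self.entry_times[inflow])) or np.any(
            ~np.isnan(self.entry_times[~inflow])
        ):
            raise ValueError("entry time must be present exactly for inflow seeds")

    def fractions(self) -> dict[str, float]:
        n = len(self.labels)
        return {c: float(np.sum(self.labels == c)) / n for c in COMPONENTS}


class CyclicPL:
    """Cyclic piecewise-linear scalar function of time with exact quadrature."""

    def __init__(self, times: np.ndarray, values: np.ndarray, cycle: float):
        self.t = np.append(times, times[0] + cycle)
        self.y = np.append(values, values[0])
        self.cycle = float(cycle)
        self.t0 = float(times[0])
        seg = 0.5 * (self.y[1:] + self.y[:-1]) * np.diff(self.t)
        self.cum = np.concatenate([[0.0], np.cumsum(seg)])
        self.total = float(self.cum[-1])

    def __call__(self, t):
        tau = (np.asarray(t, dtype=float) - self.t0) % self.cycle + self.t0
        return np.interp(tau, self.t, self.y)

    def antiderivative(self, t):
        t = np.asarray(t, dtype=float)
        nper = np.floor((t - self.t0) / self.cycle)
        tau = t - nper * self.cycle
        idx = np.clip(np.searchsorted(self.t, tau, side="right") - 1, 0, len(self.t) - 2)
        dt = tau - self.t[idx]
        slope = (self.y[idx + 1] - self.y[idx]) / (self.t[idx + 1] - self.t[idx])
        part = self.cum[idx] + self.y[idx] * dt + 0.5 * slope * dt * dt
        return nper * self.total + part

    def integral(self, a: float, b: float) -> float:
        return float(self.antiderivative(b) - self.antiderivative(a))


def _cyclic_membership(start: int, stop: int, n: int) -> np.ndarray:
    """Boolean frame membership of the cyclic half-open-from-left range (start, stop]."""
    member = np.zeros(n, dtype=bool)
    f = (start + 1) % n
    while True:
        member[f] = True
        if f == stop:
            break
        f = (f + 1) % n
    return member


def phase_profiles(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame diastolic and systolic lane-speed envelopes (0..1).

    The diastolic plateau spans frames after ES up to and including ED (so
    inflow is still moving at the end-diastolic frame, giving a nonzero KE
    at ED); the systolic plateau spans frames after ED up to one frame
    before ES, so that systolic motion never leaks across the cyclic
    boundary into the backward-trace window.
    """
    n = spec.n_frames
    dia = _cyclic_membership(spec.es_frame, spec.ed_frame, n).astype(float)
    sys_stop = (spec.es_frame - 1) % n
    if sys_stop == spec.ed_frame:  # single-frame systole: no plateau
        sys_ = np.zeros(n)
    else:
        sys_ = _cyclic_membership(spec.ed_frame, sys_stop, n).astype(float)
    sys_[spec.es_frame] = 0.0
    sys_[spec.ed_frame] = 0.0
    return dia, sys_


def _apportion(fractions: np.ndarray, n_cells: int) -> np.ndarray:
    """Largest-remainder apportionment of ``n_cells`` among fractions."""
    quota = np.asarray(fractions) * n_cells
    counts = np.floor(quota).astype(int)
    rem = quota - counts
    for i in np.argsort(-rem)[: n_cells - counts.sum()]:
        counts[i] += 1
    return counts


def duct_layout(spec: PhantomSpec) -> dict:
    """Voxel-index layout of the duct phantom (box extents, lane block)."""
    nx, ny, nz = spec.shape
    l_vox = int((nx - 2 * SHELL - 2) / (1 + 2 * TRANSIT_MARGIN))
    if l_vox < 3:
        raise ValueError(
            "grid too coarse for the duct phantom along the flow axis: "
            f"nx={nx} gives a {l_vox}-voxel chamber; need nx >= "
            f"{math.ceil(3 * (1 + 2 * TRANSIT_MARGIN)) + 2 * SHELL + 2}"
        )
    run = math.ceil(TRANSIT_MARGIN * l_vox)
    x0 = SHELL + 1 + run
    if x0 + l_vox + run + 1 > nx - SHELL:
        l_vox -= 1  # conservative fallback for rounding edge cases
        run = math.ceil(TRANSIT_MARGIN * l_vox)
        x0 = SHELL + 1 + run
    cs_y, cs_z = ny // 2, nz // 2
    if min(cs_y, cs_z) < 2 or ny - 2 * SHELL < cs_y or nz - 2 * SHELL < cs_z:
        raise ValueError("grid too coarse for the duct phantom cross-section")
    y0, z0 = (ny - cs_y) // 2, (nz - cs_z) // 2
    return {
        "box_x": (x0, x0 + l_vox),
        "lane_y": (y0, y0 + cs_y),
        "lane_z": (z0, z0 + cs_z),
        "flow_x": (SHELL, nx - SHELL),
        "n_cells": cs_y * cs_z,
    }


def make_duct_phantom(
    spec: PhantomSpec,
) -> tuple[VelocityField4D, ChamberMask, ChamberMask, GroundTruth]:
    """Build the duct phantom: field, ED mask, ES mask and ground truth.

    The chamber is a fixed box; four groups of lanes (contiguous blocks of
    the cross-section) carry axial flow whose diastolic/systolic transit
    distance is ``TRANSIT_MARGIN`` times the box length, so every particle
    of a moving lane completes its prescribed entry and/or exit with margin.
    Instantaneous lane inflow equals lane outflow, so the field conserves
    volume across the chamber boundary at all times.
    """
    if spec.phantom_kind != "duct":
        raise ValueError("spec.phantom_kind must be 'duct'")
    lay = duct_layout(spec)
    nx, ny, nz = spec.shape
    nt, dx = spec.n_frames, spec.spacing
    times = spec.frame_times
    fr = np.asarray(spec.fractions, dtype=float)

    counts = _apportion(fr, lay["n_cells"])
    starved = (fr > 0) & (counts == 0)
    if np.any(starved):
        need = math.ceil(1.0 / fr[fr > 0].min())
        side = 2 * (math.ceil(math.sqrt(need)) + 2 * SHELL)
        raise ValueError(
            "component fractions unachievable on this grid: "
            f"{lay['n_cells']} lane cells cannot represent a fraction of "
            f"{fr[starved].min():g}; need a grid of at least {side}³ voxels"
        )

    # lane label per cross-section cell, contiguous blocks in raster order
    (y0, y1), (z0, z1) = lay["lane_y"], lay["lane_z"]
    cell_labels = np.repeat(np.arange(4), counts)
    lane_grid = np.full((ny, nz), -1, dtype=int)
    block = cell_labels.reshape(y1 - y0, z1 - z0)
    lane_grid[y0:y1, z0:z1] = block

    # lane speeds from exact transit over each phase window
    dia_prof, sys_prof = phase_profiles(spec)
    dia_pl = CyclicPL(times, dia_prof, spec.cycle_duration)
    sys_pl = CyclicPL(times, sys_prof, spec.cycle_duration)
    t_ed = float(times[spec.ed_frame])
    t_es = float(times[spec.es_frame])
    t_es_fwd = t_es if t_es > t_ed else t_es + spec.cycle_duration
    t_es_prev = t_es_fwd - spec.cycle_duration
    box_len = (lay["box_x"][1] - lay["box_x"][0]) * dx
    transit = TRANSIT_MARGIN * box_len
    i_dia = dia_pl.integral(t_es_prev, t_ed)
    i_sys = sys_pl.integral(t_ed, t_es_fwd)
    flowing = np.any(fr[:3] > 0)
    v_dia = transit / i_dia if flowing else 0.0
    v_sys = transit / i_sys if flowing else 0.0
    if max(v_dia, v_sys) > spec.peak_speed:
        raise ValueError(
            f"required lane speed {max(v_dia, v_sys):.3f} m/s exceeds peak_speed="
            f"{spec.peak_speed}; use a finer grid, longer cycle or higher peak_speed"
        )
    # (diastolic, systolic) plateau speed per component
    lane_speeds = {
        DIRECT_FLOW: (v_dia, v_sys),
        RETAINED_INFLOW: (v_dia, 0.0),
        DELAYED_EJECTION: (0.0, v_sys),
        RESIDUAL_VOLUME: (0.0, 0.0),
    }

    values = np.zeros((nx, ny, nz, nt, 3))
    xs = slice(*lay["flow_x"])
    for code, comp in enumerate(COMPONENTS):
        vd, vs = lane_speeds[comp]
        if vd == 0.0 and vs == 0.0:
            continue
        iy, iz = np.where(lane_grid == code)
        values[xs, iy, iz, :, 0] = vd * dia_prof + vs * sys_prof

    field = VelocityField4D(
        values=values,
        spacing=np.full(3, dx),
        frame_times=times,
        cycle_duration=spec.cycle_duration,
        venc=spec.venc,
    )

    mask_data = np.zeros((nx, ny, nz), dtype=bool)
    bx0, bx1 = lay["box_x"]
    mask_data[bx0:bx1, y0:y1, z0:z1] = lane_grid[y0:y1, z0:z1] >= 0
    ed_mask = ChamberMask(mask_data, frame=spec.ed_frame, spacing=field.spacing,
                          origin=field.origin)
    es_mask = ChamberMask(mask_data.copy(), frame=spec.es_frame, spacing=field.spacing,
                          origin=field.origin)

    gt = _duct_ground_truth(spec, lay, lane_grid, lane_speeds, dia_pl, sys_pl,
                            t_ed, t_es_prev, ed_mask)
    gt.meta.update(
        box_bounds_x=(bx0 * dx, bx1 * dx),
        lane_speeds=lane_speeds,
        transit_distance=transit,
        backward_window=(t_es_prev, t_ed),
        forward_window=(t_ed, t_es_fwd),
        late_onset_time=_frame_time_in_window(
            spec.late_onset_frame, spec.es_frame, times, spec.cycle_duration
        ),
    )
    return field, ed_mask, es_mask, gt


def _duct_ground_truth(spec, lay, lane_grid, lane_speeds, dia_pl, sys_pl,
                       t_ed, t_es_prev, ed_mask) -> GroundTruth:
    dx = spec.spacing
    idx = np.argwhere(ed_mask.data)            # raster order: matches seed_grid
    seeds = (idx + 0.5) * dx
    labels = np.array([COMPONENTS[lane_grid[iy, iz]] for _, iy, iz in idx])

    # per-component cyclic speed profile along x
    speed_pl = {
        comp: CyclicPL(spec.frame_times,
                       vd * dia_pl.y[:-1] + vs * sys_pl.y[:-1],
                       spec.cycle_duration)
        for comp, (vd, vs) in lane_speeds.items()
    }

    # entry times: solve  ∫_t^{t_ED} s(τ) dτ = depth  for inflow seeds
    box_lo = lay["box_x"][0] * dx
    entry = np.full(len(seeds), np.nan)
    for comp in (DIRECT_FLOW, RETAINED_INFLOW):
        sel = labels == comp
        if not sel.any():
            continue
        pl = speed_pl[comp]
        depths = seeds[sel, 0] - box_lo
        cache: dict[float, float] = {}
        t_entry = np.empty(depths.shape)
        for i, d in enumerate(depths):
            key = round(d, 12)
            if key not in cache:
                cache[key] = brentq(
                    lambda t, d=d: pl.integral(t, t_ed) - d, t_es_prev, t_ed,
                    xtol=1e-12,
                )
            t_entry[i] = cache[key]
        entry[sel] = t_entry

    comp_of_seed = labels.copy()

    def trajectory(t: float) -> np.ndarray:
        pos = seeds.copy()
        for comp in COMPONENTS:
            sel = comp_of_seed == comp
            if sel.any():
                pos[sel, 0] += speed_pl[comp].integral(t_ed, float(t))
        return pos

    return GroundTruth(labels=labels, entry_times=entry, seed_positions=seeds,
                       trajectory=trajectory)


# ---------------------------------------------------------------------------
# affine phantom
# ---------------------------------------------------------------------------

def _affine_maps(spec: PhantomSpec, center: np.ndarray):
    """Return callables A(t), A'(t), b(t), b'(t) for the requested motion."""
    if spec.affine_motion == "translation":
        u = np.asarray(spec.translation_velocity, dtype=float)

        return (lambda t: np.eye(3), lambda t: np.zeros((3, 3)),
                lambda t: center + u * t, lambda t: u)
    if spec.affine_motion == "rotation":
        w = spec.omega

        def a(t):
            c, s = math.cos(w * t), math.sin(w * t)
            return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])

        def adot(t):
            c, s = math.cos(w * t), math.sin(w * t)
            return w * np.array([[-s, -c, 0.0], [c, -s, 0.0], [0.0, 0.0, 0.0]])

        return a, adot, lambda t: center, lambda t: np.zeros(3)
    if spec.affine_motion == "contraction":
        rates = np.asarray(spec.contraction, dtype=float) / spec.cycle_duration

        return (lambda t: np.diag(1.0 + rates * t),
                lambda t: np.diag(rates),
                lambda t: center, lambda t: np.zeros(3))
    raise ValueError(f"unknown affine_motion {spec.affine_motion!r}")


def make_affine_phantom(
    spec: PhantomSpec,
) -> tuple[VelocityField4D, ChamberMask, ChamberMask, GroundTruth]:
    """Build an affine-motion phantom with closed-form trajectories.

    The material domain is a sphere centred on the grid at ED, advected by
    the affine map; the ES mask is the advected image of that sphere.
    """
    if spec.phantom_kind != "affine":
        raise ValueError("spec.phantom_kind must be 'affine'")
    nx, ny, nz = spec.shape
    dx = spec.spacing
    times = spec.frame_times
    center = 0.5 * np.array([nx, ny, nz]) * dx
    a_of, adot_of, b_of, bdot_of = _affine_maps(spec, center)

    for t in times:
        if abs(np.linalg.det(a_of(t))) < 1e-12:
            raise ValueError(f"affine map singular at t={t:.4f}s")

    ii, jj, kk = np.meshgrid(*(np.arange(n) for n in (nx, ny, nz)), indexing="ij")
    pts = (np.stack([ii, jj, kk], axis=-1) + 0.5) * dx        # (nx,ny,nz,3)
    flat = pts.reshape(-1, 3)
    values = np.empty((nx, ny, nz, spec.n_frames, 3))
    for f, t in enumerate(times):
        m = adot_of(t) @ np.linalg.inv(a_of(t))
        v = flat @ m.T + (bdot_of(t) - m @ b_of(t))
        values[..., f, :] = v.reshape(nx, ny, nz, 3)

    field = VelocityField4D(values, np.full(3, dx), times, spec.cycle_duration,
                            spec.venc)

    radius = 0.22 * min(nx, ny, nz) * dx
    t_ed, t_es = float(times[spec.ed_frame]), float(times[spec.es_frame])

    def region_at(t: float) -> np.ndarray:
        """Boolean voxel mask of the advected material sphere at time t."""
        ainv = np.linalg.inv(a_of(t))
        ref = (flat - b_of(t)) @ ainv.T
        return (np.linalg.norm(ref, axis=1) <= radius).reshape(nx, ny, nz)

    ed_mask = ChamberMask(region_at(t_ed), frame=spec.ed_frame,
                          spacing=field.spacing, origin=field.origin)
    es_mask = ChamberMask(region_at(t_es), frame=spec.es_frame,
                          spacing=field.spacing, origin=field.origin)

    idx = np.argwhere(ed_mask.data)
    seeds = (idx + 0.5) * dx
    a_ed_inv = np.linalg.inv(a_of(t_ed))
    ref_seeds = (seeds - b_of(t_ed)) @ a_ed_inv.T

    def trajectory(t: float) -> np.ndarray:
        return ref_seeds @ np.asarray(a_of(t)).T + b_of(t)

    t_es_fwd = t_es if t_es > t_ed else t_es + spec.cycle_duration
    t_es_prev = t_es_fwd - spec.cycle_duration

    def inside_es_region(pos: np.ndarray) -> np.ndarray:
        ainv = np.linalg.inv(a_of(t_es))
        return np.linalg.norm((pos - b_of(t_es)) @ ainv.T, axis=1) <= radius

    origin_inside = inside_es_region(trajectory(t_es_prev))
    fate_inside = inside_es_region(trajectory(t_es_fwd))
    labels = np.where(
        origin_inside,
        np.where(fate_inside, RESIDUAL_VOLUME, DELAYED_EJECTION),
        np.where(fate_inside, RETAINED_INFLOW, DIRECT_FLOW),
    )

    entry = np.full(len(seeds), np.nan)
    inflow = ~origin_inside
    if inflow.any():
        # last outside->inside crossing of the ED region along the closed form
        tgrid = np.linspace(t_es_prev, t_ed, 512)
        inside_ed = np.empty((len(tgrid), len(seeds)), dtype=bool)
        for i, t in enumerate(tgrid):
            inside_ed[i] = np.linalg.norm(trajectory(t) - center, axis=1) <= radius
        for s in np.where(inflow)[0]:
            cross = np.where(~inside_ed[:-1, s] & inside_ed[1:, s])[0]
            if cross.size:
                lo, hi = tgrid[cross[-1]], tgrid[cross[-1] + 1]
                entry[s] = brentq(
                    lambda t, s=s: np.linalg.norm(trajectory(t)[s] - center) - radius,
                    lo, hi,
                )
            else:
                entry[s] = t_es_prev  # started outside, first seen inside
    entry[~inflow] = np.nan

    gt = GroundTruth(labels=labels, entry_times=entry, seed_positions=seeds,
                     trajectory=trajectory,
                     meta={"radius": radius, "center": center,
                           "backward_window": (t_es_prev, t_ed),
                           "forward_window": (t_ed, t_es_fwd)})
    return field, ed_mask, es_mask, gt


def make_aliasing_phantom(
    shape: tuple[int, int, int] = (24, 24, 24),
    spacing: float = 2.8e-3,
    n_frames: int = 40,
    cycle_duration: float = 1.0,
    venc: float = 1.2,
    peak_over_venc: float = 1.5,
    plateau_frames: tuple[int, int] | None = None,
    ramp_frames: int | None = None,
) -> VelocityField4D:
    """Field with a velocity plateau beyond VENC, for unwrap testing.

    A central block moves along x with a trapezoidal temporal profile that
    peaks at ``peak_over_venc × VENC`` and ramps over several frames, so the
    aliased series shows the large apparent jumps that temporal unwrapping
    relies on.  A zero-velocity shell surrounds the block (static tissue).
    """
    nx, ny, nz = shape
    if peak_over_venc <= 1.0:
        raise ValueError("peak_over_venc must exceed 1 to produce a wrap")
    if plateau_frames is None:
        plateau_frames = (round(0.3 * n_frames), round(0.55 * n_frames))
    if ramp_frames is None:
        ramp_frames = max(1, n_frames // 13)
    prof = np.zeros(n_frames)
    f0, f1 = plateau_frames
    if not 0 < f0 < f1 <= n_frames:
        raise ValueError(f"plateau frames {plateau_frames} outside (0, {n_frames}]")
    prof[f0:f1] = 1.0
    for r in range(1, ramp_frames + 1):
        w = 1.0 - r / (ramp_frames + 1)
        if f0 - r >= 0:
            prof[f0 - r] = w
        if f1 - 1 + r < n_frames:
            prof[f1 - 1 + r] = w
    values = np.zeros((nx, ny, nz, n_frames, 3))
    b = max(2, nx // 4)
    values[b:nx - b, b:ny - b, b:nz - b, :, 0] = peak_over_venc * venc * prof
    return VelocityField4D(values, np.full(3, spacing),
                           np.arange(n_frames) * cycle_duration / n_frames,
                           cycle_duration, venc)


# ---------------------------------------------------------------------------
# phase-contrast encoding
# ---------------------------------------------------------------------------

@dataclass
class EncodingSpec:
    """Phase-contrast encoding parameters (SI units).

    ``poly_coeffs`` are per-direction coefficients ``(3, 35)`` of the
    degree-4 background polynomial on normalised grid coordinates, in
    radians of phase.
    """

    venc: float = 1.2                   # m/s
    poly_coeffs: np.ndarray = None      # (3, 35) radians; zeros if None
    noise_sd: float = 0.0               # phase noise SD, radians
    tr: float = 5.1e-3                  # repetition time, s
    encodings_per_sample: int = 4       # velocity encodings per sample
    k_segmentation: int = 2             # k-space segmentation factor

    def __post_init__(self) -> None:
        if self.venc <= 0:
            raise ValueError("VENC must be positive")
        if self.poly_coeffs is None:
            self.poly_coeffs = np.zeros((3, polynomial.N_TERMS))
        self.poly_coeffs = np.asarray(self.poly_coeffs, dtype=float)
        if self.poly_coeffs.shape != (3, polynomial.N_TERMS):
            raise ValueError(
                f"poly_coeffs must have shape (3, {polynomial.N_TERMS}) — a full "
                f"degree-4 trivariate polynomial per direction; got {self.poly_coeffs.shape}"
            )
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")


@dataclass
class PhaseImages:
    """Wrapped phase volumes, one per velocity-encoding direction."""

    phase: np.ndarray          # (nx, ny, nz, n_frames, 3), radians in (-pi, pi]
    venc: float                # m/s
    spacing: np.ndarray
    frame_times: np.ndarray
    cycle_duration: float
    origin: np.ndarray

    def decode(self) -> VelocityField4D:
        """Naive decode: v = phase * VENC / pi (aliased where wrapped)."""
        return VelocityField4D(
            values=self.phase * self.venc / np.pi,
            spacing=self.spacing,
            frame_times=self.frame_times,
            cycle_duration=self.cycle_duration,
            venc=self.venc,
        )


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap phase into (-pi, pi]."""
    return np.pi - (np.pi - phi) % (2 * np.pi)


def encode_phase_contrast(
    field: VelocityField4D,
    enc: EncodingSpec,
    static_region: np.ndarray | None = None,
    seed: int = 0,
) -> PhaseImages:
    """Forward phase-contrast model: phase = pi*v/VENC + P4(x,y,z) + noise, wrapped.

    The background polynomial is constant over the cycle (eddy-current
    offsets are static); noise is Gaussian in phase.  If ``static_region``
    is given it must contain only zero-velocity voxels (it is the region a
    background fit will later rely on).
    """
    if static_region is not None:
        vmax = np.abs(field.values[np.asarray(static_region, bool)]).max()
        if vmax > 1e-9:
            raise ValueError(
                f"static_region contains moving voxels (max |v| = {vmax:.2e} m/s)"
            )
    coords = polynomial.normalized_coords(field.shape)
    bg = np.stack(
        [polynomial.evaluate(enc.poly_coeffs[d], coords).reshape(field.shape)
         for d in range(3)],
        axis=-1,
    )  # (nx, ny, nz, 3)
    phi = np.pi * field.values / enc.venc + bg[:, :, :, None, :]
    if enc.noise_sd > 0:
        rng = np.random.default_rng(seed)
        phi = phi + rng.normal(0.0, enc.noise_sd, size=phi.shape)
    return PhaseImages(
        phase=wrap_phase(phi),
        venc=enc.venc,
        spacing=field.spacing.copy(),
        frame_times=field.frame_times.copy(),
        cycle_duration=field.cycle_duration,
        origin=field.origin.copy(),
    )


def acquisition_temporal_resolution(
    tr_ms: float, encodings_per_sample: int, k_segmentation_factor: int
) -> float:
    """Acquired temporal resolution (ms) of a segmented phase-contrast scan.

    One velocity sample needs ``encodings_per_sample`` TRs (reference plus
    three flow encodes for interleaved three-directional encoding), and
    ``k_segmentation_factor`` k-space lines are collected per segment, so
    the acquired temporal footprint is their product with TR.
    """
    if tr_ms <= 0 or encodings_per_sample <= 0 or k_segmentation_factor <= 0:
        raise ValueError("all acquisition parameters must be positive")
    return tr_ms * encodings_per_sample * k_segmentation_factor
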