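"""Pathline seeding and integration through the time-resolved velocity field.

Seeds are placed on an isotropic lattice filling the end-diastolic LV
segmentation, each representing a blood volume equal to the lattice cell.
From the ED timeframe every seed is traced *backward* through diastole to
the preceding end-systole (where did this blood come from?) and *forward*
through systole to end-systole (where is it going?).  The merged trajectory
spans one full cardiac cycle from ES to ES and is the basis of the
flow-component separation.

Integration is classical fixed-step RK4 on the trilinearly (space) and
linearly (time) interpolated field, cyclic in time.  Trajectories that
leave the grid are frozen at the exit point and flagged; they are excluded
from component analysis and counted by QC.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _field

import numpy as np

from .fields import ChamberMask, VelocityField4D, check_same_geometry
from .timing import TimingResult

__all__ = ["SeedGrid", "Pathlines", "seed_grid", "sample_velocity", "trace_pathlines",
           "interpolate_mask"]


@dataclass
class SeedGrid:
    """Pathline emission sites inside the ED segmentation.

    ``positions`` are world coordinates (m); every seed represents
    ``seed_volume = spacing³`` of blood.
    """

    positions: np.ndarray     # (n, 3) m
    spacing: float            # m, isotropic
    seed_volume: float        # m³

    @property
    def n_seeds(self) -> int:
        return len(self.positions)

    @property
    def total_volume(self) -> float:
        return self.n_seeds * self.seed_volume


def seed_grid(ed_mask: ChamberMask, spacing: float | None = None) -> SeedGrid:
    """Emit seeds on an isotropic lattice clipped to the ED mask.

    With ``spacing`` equal to the (isotropic) voxel size — the default —
    the lattice is aligned to the voxel lattice, i.e. one seed per masked
    voxel centre, so the represented volume equals the segmented volume
    exactly.
    """
    if ed_mask.n_voxels == 0:
        raise ValueError("ED mask is empty; cannot emit seeds")
    vox = ed_mask.spacing
    if spacing is None:
        if not np.allclose(vox, vox[0]):
            raise ValueError(
                f"voxel spacing {vox} is anisotropic; pass an explicit seed spacing"
            )
        spacing = float(vox[0])
    if spacing <= 0:
        raise ValueError("seed spacing must be positive")

    if np.allclose(vox, spacing):
        idx = np.argwhere(ed_mask.data)
        pos = ed_mask.origin + (idx + 0.5) * vox
    else:
        lo = ed_mask.origin
        hi = ed_mask.origin + np.array(ed_mask.shape) * vox
        axes = [np.arange(lo[d] + spacing / 2, hi[d], spacing) for d in range(3)]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        lattice = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=-1)
        inside = interpolate_mask(ed_mask, lattice) >= 0.5
        pos = lattice[inside]
    if len(pos) == 0:
        raise ValueError("no lattice point falls inside the ED mask")
    return SeedGrid(positions=pos, spacing=float(spacing),
                    seed_volume=float(spacing) ** 3)


# ---------------------------------------------------------------------------
# interpolation
# ---------------------------------------------------------------------------

def _trilinear(vol: np.ndarray, cidx: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of ``vol`` (nx, ny, nz[, c]) at fractional
    voxel indices ``cidx`` (n, 3), with clamped edges."""
    scalar = vol.ndim == 3
    if scalar:
        vol = vol[..., None]
    n = np.array(vol.shape[:3])
    c = np.clip(cidx, 0.0, n - 1.0)
    i0 = np.minimum(np.floor(c).astype(int), np.maximum(n - 2, 0))
    f = c - i0
    i1 = np.minimum(i0 + 1, n - 1)
    out = np.zeros((len(c), vol.shape[-1]))
    for bx in (0, 1):
        wx = f[:, 0] if bx else 1.0 - f[:, 0]
        ix = i1[:, 0] if bx else i0[:, 0]
        for by in (0, 1):
            wy = f[:, 1] if by else 1.0 - f[:, 1]
            iy = i1[:, 1] if by else i0[:, 1]
            for bz in (0, 1):
                wz = f[:, 2] if bz else 1.0 - f[:, 2]
                iz = i1[:, 2] if bz else i0[:, 2]
                out += (wx * wy * wz)[:, None] * vol[ix, iy, iz]
    return out[:, 0] if scalar else out


def interpolate_mask(mask: ChamberMask, positions: np.ndarray) -> np.ndarray:
    """Trilinearly interpolated mask value (0..1) at world positions (m)."""
    cidx = mask.world_to_voxel(np.atleast_2d(positions))
    return _trilinear(mask.data.astype(float), cidx)


def _time_weights(field: VelocityField4D, t: float) -> tuple[int, int, float]:
    ft = field.frame_times
    cyc = field.cycle_duration
    tau = (t - ft[0]) % cyc + ft[0]
    j = int(np.searchsorted(ft, tau, side="right")) - 1
    if j >= len(ft) - 1:
        t0, t1 = ft[-1], ft[0] + cyc
        f0, f1 = len(ft) - 1, 0
    else:
        t0, t1 = ft[j], ft[j + 1]
        f0, f1 = j, j + 1
    return f0, f1, float((tau - t0) / (t1 - t0))


def sample_velocity(
    field: VelocityField4D, positions: np.ndarray, t: float
) -> tuple[np.ndarray, np.ndarray]:
    """Velocity (m/s) at world positions and time, with in-domain flags.

    Trilinear in space, linear in time between the bracketing frames,
    cyclic in time.  Out-of-bounds positions are *flagged*, not raised; the
    interpolant there uses edge-clamped values.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    lo, hi = field.bounds
    in_domain = np.all((positions >= lo) & (positions <= hi), axis=1)
    f0, f1, w = _time_weights(field, t)
    cidx = field.world_to_voxel(positions)
    v0 = _trilinear(field.values[:, :, :, f0, :], cidx)
    if w == 0.0:
        return v0, in_domain
    v1 = _trilinear(field.values[:, :, :, f1, :], cidx)
    return (1.0 - w) * v0 + w * v1, in_domain


# ---------------------------------------------------------------------------
# tracing
# ---------------------------------------------------------------------------

@dataclass
class Pathlines:
    """Merged backward+forward trajectories of all seeds.

    ``times`` runs from the preceding end-systole to end-systole and
    contains every acquisition frame time; ``ed_index`` locates the
    end-diastolic sample (where positions equal the seeds exactly).
    """

    times: np.ndarray          # (n_samples,) s, strictly increasing
    positions: np.ndarray      # (n_seeds, n_samples, 3) m
    velocities: np.ndarray     # (n_seeds, n_samples, 3) m/s
    ed_index: int
    seed_volume: float         # m³ represented per pathline
    valid: np.ndarray          # (n_seeds,) False if non-finite velocity occurred
    truncated: np.ndarray      # (n_seeds,) True if the trajectory left the grid
    exit_time: np.ndarray      # (n_seeds,) s, NaN if never exited
    exit_position: np.ndarray  # (n_seeds, 3) m, NaN if never exited
    meta: dict = _field(default_factory=dict)

    @property
    def n_seeds(self) -> int:
        return self.positions.shape[0]

    @property
    def seed_positions(self) -> np.ndarray:
        return self.positions[:, self.ed_index, :]

    @property
    def usable(self) -> np.ndarray:
        """Pathlines that enter the component analysis."""
        return self.valid & ~self.truncated

    def ed_speed(self) -> np.ndarray:
        return np.linalg.norm(self.velocities[:, self.ed_index, :], axis=1)


def _rk4_span(field, pos, t0, t1, n_sub, frozen, valid, exit_time, exit_pos):
    """Advance all particles from t0 to t1 (either direction) with RK4."""
    h = (t1 - t0) / n_sub
    lo, hi = field.bounds
    t = t0
    for _ in range(n_sub):
        k1, _in = sample_velocity(field, pos, t)
        k2, _ = sample_velocity(field, pos + 0.5 * h * k1, t + 0.5 * h)
        k3, _ = sample_velocity(field, pos + 0.5 * h * k2, t + 0.5 * h)
        k4, _ = sample_velocity(field, pos + h * k3, t + h)
        step = (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        bad = ~np.all(np.isfinite(step), axis=1)
        if bad.any():
            valid[bad & ~frozen] = False
            frozen |= bad
            step[bad] = 0.0
        new = np.where(frozen[:, None], pos, pos + step)
        t = t + h
        exited = ~np.all((new >= lo) & (new <= hi), axis=1) & ~frozen
        if exited.any():
            new[exited] = np.clip(new[exited], lo, hi)  # freeze at the exit point
            exit_time[exited] = t
            exit_pos[exited] = new[exited]
            frozen |= exited
        pos = new
    return pos


def trace_pathlines(
    field: VelocityField4D,
    seeds: SeedGrid,
    timing: TimingResult,
    step_fraction: float = 0.2,
    es_mask: ChamberMask | None = None,
) -> Pathlines:
    """Trace every seed backward to the previous ES and forward to ES.

    The integration step is ``step_fraction`` of the local inter-frame
    interval (default 0.2, i.e. five RK4 steps per frame); samples are
    recorded at every acquisition frame time.
    """
    if step_fraction <= 0 or step_fraction > 1:
        raise ValueError("step_fraction must lie in (0, 1]")
    if es_mask is not None:
        check_same_geometry(field, es_mask, "ES mask")
    ft = field.frame_times
    nt = field.n_frames
    cyc = field.cycle_duration
    ed, es = timing.ed_frame, timing.es_frame
    for name, f in (("ED", ed), ("ES", es)):
        if not 0 <= f < nt:
            raise ValueError(f"{name} frame {f} outside [0, {nt})")

    # record times: one full cycle of frame times from previous ES to ES,
    # unwrapped to a strictly increasing axis containing t_ED
    k = np.arange(nt + 1)
    rec_times = ft[(es + k) % nt] + cyc * ((es + k) // nt) - cyc
    ed_index = int((ed - es) % nt)
    n_sub = max(1, round(1.0 / step_fraction))

    n = seeds.n_seeds
    positions = np.empty((n, nt + 1, 3))
    frozen = np.zeros(n, dtype=bool)
    valid = np.ones(n, dtype=bool)
    exit_time = np.full(n, np.nan)
    exit_pos = np.full((n, 3), np.nan)

    # backward branch: ED down to previous ES (equivalent to integrating the
    # reversed field forward)
    pos = seeds.positions.copy()
    positions[:, ed_index] = pos
    for i in range(ed_index, 0, -1):
        pos = _rk4_span(field, pos, rec_times[i], rec_times[i - 1], n_sub,
                        frozen, valid, exit_time, exit_pos)
        positions[:, i - 1] = pos

    # forward branch: ED up to ES, integrated independently of any backward
    # domain exit (the truncation flag still marks the pathline for QC)
    bwd_frozen = frozen
    frozen = np.zeros(n, dtype=bool)
    exit_time_f = np.full(n, np.nan)
    exit_pos_f = np.full((n, 3), np.nan)
    pos = seeds.positions.copy()
    for i in range(ed_index, nt):
        pos = _rk4_span(field, pos, rec_times[i], rec_times[i + 1], n_sub,
                        frozen, valid, exit_time_f, exit_pos_f)
        positions[:, i + 1] = pos
    first_exit = np.isnan(exit_time) & ~np.isnan(exit_time_f)
    exit_time[first_exit] = exit_time_f[first_exit]
    exit_pos[first_exit] = exit_pos_f[first_exit]

    velocities = np.empty_like(positions)
    for i, t in enumerate(rec_times):
        velocities[:, i], _ = sample_velocity(field, positions[:, i], t)

    truncated = frozen | bwd_frozen
    return Pathlines(
        times=rec_times,
        positions=positions,
        velocities=velocities,
        ed_index=ed_index,
        seed_volume=seeds.seed_volume,
        valid=valid,
        truncated=truncated,
        exit_time=exit_time,
        exit_position=exit_pos,
        meta={"step_fraction": step_fraction, "n_substeps": n_sub,
              "ed_frame": ed, "es_frame": es},
    )
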