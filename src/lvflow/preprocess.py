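"""Inversion of the two phase-contrast acquisition artifacts.

Eddy currents leave a smooth, temporally static background phase offset in
the velocity images; it is estimated by fitting a full degree-4 trivariate
polynomial to the temporal-mean velocity of static tissue and subtracted
from every timeframe.  Velocities beyond ±VENC alias by multiples of
2·VENC; they are restored per voxel by choosing the integer wrap offsets
that minimise the total absolute frame-to-frame velocity jump over the
cyclic time series (exact dynamic programming over a bounded offset range).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import polynomial
from .fields import VelocityField4D
from .synthetic import PhaseImages

__all__ = [
    "StaticTissueMask", "BackgroundModel", "detect_static_tissue",
    "correct_background_phase", "unwrap_temporal", "decode_and_correct",
]

DEFAULT_SD_THRESHOLD = 0.03   # m/s; typical noise floor at VENC 1.2 m/s
DEFAULT_MAX_WRAPS = 2         # ±2 wraps ≈ ±3.6 m/s beyond VENC 1.2: ample for the LV


@dataclass
class StaticTissueMask:
    """Voxels whose velocity is temporally quiet enough to be tissue."""

    data: np.ndarray
    sd_threshold: float
    magnitude_floor: float | None = None

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class BackgroundModel:
    """Fitted degree-4 background polynomial, one coefficient set per direction.

    Coefficients live on grid coordinates normalised to [-1, 1] per axis.
    """

    coeffs: np.ndarray            # (3, 35)
    residual_rms: np.ndarray      # (3,) m/s over the static voxels
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.coeffs.shape != (3, polynomial.N_TERMS):
            raise ValueError("background model must be a full degree-4 polynomial")

    def evaluate(self) -> np.ndarray:
        """Background velocity offset (nx, ny, nz, 3) on the model's grid."""
        coords = polynomial.normalized_coords(self.shape)
        return np.stack(
            [polynomial.evaluate(self.coeffs[d], coords).reshape(self.shape)
             for d in range(3)],
            axis=-1,
        )


def detect_static_tissue(
    field: VelocityField4D,
    magnitude: np.ndarray | None = None,
    sd_threshold: float = DEFAULT_SD_THRESHOLD,
    magnitude_floor: float = 0.0,
) -> StaticTissueMask:
    """Flag voxels whose temporal velocity SD stays below threshold.

    If a magnitude image is given, voxels at or below ``magnitude_floor``
    (air, lung) are excluded as well.
    """
    sd = field.values.std(axis=3)          # (nx, ny, nz, 3)
    quiet = np.all(sd < sd_threshold, axis=-1)
    if magnitude is not None:
        quiet &= np.asarray(magnitude) > magnitude_floor
    if not quiet.any():
        raise ValueError(
            "no static tissue found; raise sd_threshold (currently "
            f"{sd_threshold} m/s) or lower magnitude_floor"
        )
    return StaticTissueMask(quiet, sd_threshold,
                            magnitude_floor if magnitude is not None else None)


def correct_background_phase(
    field: VelocityField4D, static_mask: StaticTissueMask
) -> tuple[VelocityField4D, BackgroundModel]:
    """Fit and subtract the eddy-current background offset.

    The degree-4 polynomial is fitted per velocity direction to the
    *temporal-mean* velocity over static voxels (the offset is static in
    time, and averaging suppresses noise) and subtracted from every frame.
    """
    static = np.asarray(static_mask.data, dtype=bool)
    if static.sum() == 0:
        raise ValueError("static-tissue mask is empty")
    coords = polynomial.normalized_coords(field.shape)
    flat_static = static.ravel()
    design = polynomial.design_matrix(coords[flat_static])
    rank = np.linalg.matrix_rank(design)
    if rank < polynomial.N_TERMS:
        raise ValueError(
            f"static voxels span a rank-{rank} design; a degree-4 fit needs rank "
            f"{polynomial.N_TERMS} (≥ {polynomial.N_TERMS} voxels with full 3-D spread)"
        )
    mean_v = field.values.mean(axis=3)          # (nx, ny, nz, 3)
    target = mean_v.reshape(-1, 3)[flat_static]
    coeffs, _, _, _ = np.linalg.lstsq(design, target, rcond=None)
    residual = target - design @ coeffs
    model = BackgroundModel(
        coeffs=coeffs.T.copy(),
        residual_rms=np.sqrt(np.mean(residual**2, axis=0)),
        shape=field.shape,
    )
    background = model.evaluate()               # (nx, ny, nz, 3)
    corrected = field.values - background[:, :, :, None, :]
    return replace(field, values=corrected), model


def unwrap_temporal(
    field: VelocityField4D, max_wraps: int = DEFAULT_MAX_WRAPS
) -> VelocityField4D:
    """Restore velocities aliased beyond ±VENC using the full time series.

    Per voxel and direction, integer multiples of 2·VENC in
    ``[-max_wraps, max_wraps]`` are added per frame so that the total
    absolute frame-to-frame jump around the cyclic series is minimal
    (exact dynamic programming; ties broken towards the smallest total
    offset magnitude).  Series whose largest cyclic jump is already below
    VENC are provably optimal unchanged and skipped.
    """
    v = field.values
    nt = field.n_frames
    venc2 = 2.0 * field.venc
    # one series per (voxel, direction): time must be the trailing axis
    stacked = np.moveaxis(v, 3, 4).copy()           # (nx, ny, nz, 3, nt)
    series = stacked.reshape(-1, nt)
    jumps = np.abs(np.diff(series, axis=1, append=series[:, :1]))
    suspect = np.where(jumps.max(axis=1) > field.venc)[0]
    if suspect.size:
        offsets = _optimal_wrap_offsets(series[suspect], venc2, max_wraps)
        series[suspect] += offsets * venc2
    return replace(field, values=np.moveaxis(stacked, 4, 3))


def _optimal_wrap_offsets(series: np.ndarray, venc2: float, max_wraps: int) -> np.ndarray:
    """Exact minimiser of the cyclic total-variation objective per series.

    Returns integer offsets (n_series, nt).  A secondary penalty of
    ``1e-9 · venc2`` per unit |offset| makes the minimiser unique and
    biased towards leaving samples unchanged.
    """
    n, nt = series.shape
    ks = np.arange(-max_wraps, max_wraps + 1)
    m = len(ks)
    tie = 1e-9 * venc2
    best_cost = np.full(n, np.inf)
    best_k = np.zeros((n, nt), dtype=int)

    for s0 in range(m):
        # dp over frames with k[0] fixed to ks[s0]
        cost = np.full((n, m), np.inf)
        cost[:, s0] = tie * abs(ks[s0])
        back = np.zeros((n, nt, m), dtype=np.int8)
        for f in range(1, nt):
            # transition: |v[f] + k*venc2 - v[f-1] - k'*venc2|
            step = np.abs(
                series[:, f, None, None] + ks[None, None, :] * venc2
                - series[:, f - 1, None, None] - ks[None, :, None] * venc2
            )  # (n, m_prev, m_new)
            total = cost[:, :, None] + step + tie * np.abs(ks)[None, None, :]
            back[:, f] = np.argmin(total, axis=1)
            cost = np.min(total, axis=1)
        # cyclic closure back to frame 0
        close = np.abs(
            series[:, 0] [:, None] + ks[s0] * venc2
            - series[:, -1][:, None] - ks[None, :] * venc2
        )
        total = cost + close
        last = np.argmin(total, axis=1)
        final = total[np.arange(n), last]
        improve = final < best_cost - 1e-15
        if improve.any():
            idx = np.where(improve)[0]
            best_cost[idx] = final[idx]
            # backtrack
            kk = last[idx]
            path = np.empty((len(idx), nt), dtype=int)
            path[:, -1] = kk
            for f in range(nt - 1, 0, -1):
                kk = back[idx, f, kk]
                path[:, f - 1] = kk
            best_k[idx] = ks[path]
    return best_k


def decode_and_correct(
    phase_images: PhaseImages,
    magnitude: np.ndarray | None = None,
    sd_threshold: float = DEFAULT_SD_THRESHOLD,
    max_wraps: int = DEFAULT_MAX_WRAPS,
) -> tuple[VelocityField4D, BackgroundModel, StaticTissueMask]:
    """Full inversion chain: decode → static tissue → background fit → unwrap."""
    decoded = phase_images.decode()
    static = detect_static_tissue(decoded, magnitude, sd_threshold)
    corrected, model = correct_background_phase(decoded, static)
    return unwrap_temporal(corrected, max_wraps), model, static
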