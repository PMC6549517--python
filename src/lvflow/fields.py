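"""Core in-memory containers for time-resolved velocity data and chamber masks.

Conventions
-----------
* All in-memory quantities are SI: metres, seconds, m/s, joules.  File
  readers/writers convert from/to the clinical units (mm, cm/s, ml, mJ) at
  the I/O boundary only.
* Voxel indices are 0-based.  The world position of the centre of voxel
  ``i`` along an axis is ``origin + (i + 0.5) * spacing``.
* Frame times live inside one cardiac cycle ``[0, cycle_duration)`` and the
  field is treated as cyclic in time.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _field

import numpy as np

__all__ = ["VelocityField4D", "ChamberMask"]


@dataclass
class VelocityField4D:
    """Gridded three-directional velocity data over one cardiac cycle.

    Parameters
    ----------
    values
        Array of shape ``(nx, ny, nz, n_frames, 3)`` in m/s.
    spacing
        Voxel spacing ``(dx, dy, dz)`` in metres.
    frame_times
        Strictly increasing frame times in seconds, all within one cycle.
    cycle_duration
        Length of the cardiac cycle in seconds (RR interval).
    venc
        Velocity-encoding limit in m/s; velocities beyond ``±venc`` alias.
    origin
        World coordinate (m) of the grid corner; voxel centre ``i`` sits at
        ``origin + (i + 0.5) * spacing``.
    """

    values: np.ndarray
    spacing: np.ndarray
    frame_times: np.ndarray
    cycle_duration: float
    venc: float
    origin: np.ndarray = _field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.values.ndim != 5 or self.values.shape[-1] != 3:
            raise ValueError(
                f"values must have shape (nx, ny, nz, n_frames, 3), got {self.values.shape}"
            )
        if self.n_frames < 2:
            raise ValueError("a velocity field needs at least two frames")
        if np.any(self.spacing <= 0):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("velocity values must be finite")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if self.frame_times.shape != (self.n_frames,):
            raise ValueError("one frame time per frame is required")
        if self.frame_times[-1] - self.frame_times[0] >= self.cycle_duration:
            raise ValueError("frame times must span less than one cycle")
        if self.venc <= 0:
            raise ValueError("VENC must be positive")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape[:3]

    @property
    def n_frames(self) -> int:
        return self.values.shape[3]

    @property
    def extent(self) -> np.ndarray:
        """Physical size of the grid (m) along each axis."""
        return np.array(self.shape) * self.spacing

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Lower and upper world-coordinate corners of the grid (m)."""
        return self.origin.copy(), self.origin + self.extent

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        """World position (m) of voxel centres given (possibly fractional) indices."""
        return self.origin + (np.asarray(idx, dtype=float) + 0.5) * self.spacing

    def world_to_voxel(self, pos: np.ndarray) -> np.ndarray:
        """Fractional voxel index of world positions (m)."""
        return (np.asarray(pos, dtype=float) - self.origin) / self.spacing - 0.5

    def same_geometry(self, other: "VelocityField4D | ChamberMask", atol: float = 1e-9) -> bool:
        return (
            self.shape == tuple(np.asarray(other_shape(other)))
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )


@dataclass
class ChamberMask:
    """Binary chamber segmentation bound to one cardiac frame.

    ``data`` is a boolean grid on the same geometry as the velocity field it
    accompanies; ``frame`` is the cardiac frame index the segmentation was
    drawn on (typically ED or ES); ``label`` is the chamber ("LV" or "LA").
    """

    data: np.ndarray
    frame: int
    label: str = "LV"
    spacing: np.ndarray = _field(default_factory=lambda: np.full(3, np.nan))
    origin: np.ndarray = _field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.data.ndim != 3:
            raise ValueError("mask must be a 3-D binary grid")
        if self.label not in ("LV", "LA"):
            raise ValueError(f"chamber label must be 'LV' or 'LA', got {self.label!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in m³."""
        return float(np.prod(self.spacing))

    @property
    def volume(self) -> float:
        """Chamber volume in m³ (voxel count × voxel volume)."""
        return self.n_voxels * self.voxel_volume

    @property
    def volume_ml(self) -> float:
        return self.volume * 1e6

    def world_to_voxel(self, pos: np.ndarray) -> np.ndarray:
        return (np.asarray(pos, dtype=float) - self.origin) / self.spacing - 0.5


def other_shape(obj) -> tuple[int, ...]:
    if isinstance(obj, ChamberMask):
        return obj.data.shape
    return obj.values.shape[:3]


def check_same_geometry(field: VelocityField4D, mask: ChamberMask, what: str = "mask") -> None:
    """Raise if a mask does not share the velocity grid's geometry."""
    if mask.shape != field.shape:
        raise ValueError(
            f"{what} grid {mask.shape} does not match velocity grid {field.shape}"
        )
    if not np.allclose(mask.spacing, field.spacing):
        raise ValueError(f"{what} spacing {mask.spacing} != field spacing {field.spacing}")
    if not np.allclose(mask.origin, field.origin):
        raise ValueError(f"{what} origin {mask.origin} != field origin {field.origin}")
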