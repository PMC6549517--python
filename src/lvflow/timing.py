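"""Cardiac-frame landmarks: ED, ES and the onset of late diastole.

ED and ES are tied to mitral-valve events (one frame after closure, one
frame before opening); the onset of late diastole — the start of diastasis,
ending the early filling phase — is read off the LV volume curve as the
point where the filling rate dV/dt collapses after the E-wave peak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .fields import ChamberMask

__all__ = ["TimingResult", "compute_volume_curve", "frames_from_valve_events",
           "detect_late_diastole_onset", "frame_time_in_window"]


def frame_time_in_window(
    frame: int, es_frame: int, frame_times: np.ndarray, cycle_duration: float
) -> float:
    """Time of a cardiac frame on the traced-cycle axis.

    Pathlines span one cycle from the *previous* end-systole to end-systole;
    on that axis diastolic frames that precede ED across the cyclic boundary
    carry negative times.  This maps a frame index into that window.
    """
    n = len(frame_times)
    k = (frame - es_frame) % n
    return float(frame_times[frame] + cycle_duration * ((es_frame + k) // n) - cycle_duration)


@dataclass
class TimingResult:
    """Cardiac landmarks for one exam."""

    ed_frame: int
    es_frame: int
    late_onset_frame: int | None = None
    volume_curve_ml: np.ndarray | None = None
    heart_rate_bpm: float | None = None

    def __post_init__(self) -> None:
        if self.ed_frame == self.es_frame:
            raise ValueError("ED and ES frames must be distinct")
        if self.volume_curve_ml is not None:
            self.volume_curve_ml = np.asarray(self.volume_curve_ml, dtype=float)
            if np.any(self.volume_curve_ml < 0):
                raise ValueError("volume curve must be non-negative")


def compute_volume_curve(masks: list[ChamberMask]) -> np.ndarray:
    """LV volume per frame in ml (voxel count × voxel volume)."""
    if any(m is None for m in masks):
        missing = [i for i, m in enumerate(masks) if m is None]
        raise ValueError(f"missing segmentation for frames {missing}")
    vols = np.array([m.volume_ml for m in masks])
    if np.any(vols == 0):
        warnings.warn("empty LV segmentation in volume curve", stacklevel=2)
    return vols


def frames_from_valve_events(
    mv_closure_frame: int, mv_opening_frame: int, n_frames: int
) -> tuple[int, int]:
    """ED/ES frames from mitral-valve events (cyclic arithmetic).

    ED is one timeframe after mitral-valve closure; ES one timeframe before
    mitral-valve opening.
    """
    ed = (mv_closure_frame + 1) % n_frames
    es = (mv_opening_frame - 1) % n_frames
    if ed == es:
        raise ValueError(
            f"valve events give coincident ED and ES (frame {ed}); check annotations"
        )
    return ed, es


def detect_late_diastole_onset(
    volume_curve_ml: np.ndarray,
    es_frame: int,
    ed_frame: int,
    diastasis_fraction: float = 0.1,
) -> int:
    """First diastasis frame: the end of the early (E-wave) filling phase.

    dV/dt is computed by central differences on the cyclic volume curve.
    After the early-filling peak of dV/dt, the onset of late diastole is the
    first diastolic frame where dV/dt falls below ``diastasis_fraction`` of
    that peak.  A monotone or flat diastolic curve has no such structure; a
    warning is issued and the midpoint of diastole returned.
    """
    v = np.asarray(volume_curve_ml, dtype=float)
    n = len(v)
    t = np.arange(n)
    dvdt = (np.roll(v, -1) - np.roll(v, 1)) / 2.0  # per frame

    # diastolic frames from ES up to (not including) ED, cyclic: filling has
    # ended at ED by definition, so ED cannot be a diastasis onset
    dia = [(es_frame + k) % n for k in range(1, (ed_frame - es_frame) % n)]
    dia_rates = dvdt[dia]
    midpoint = dia[len(dia) // 2]
    peak_pos = int(np.argmax(dia_rates))
    peak = dia_rates[peak_pos]
    if peak <= 0 or np.ptp(v[dia]) < 1e-12:
        warnings.warn(
            "monotone or flat diastolic volume curve; returning midpoint of diastole",
            stacklevel=2,
        )
        return midpoint
    below = np.where(dia_rates[peak_pos:] < diastasis_fraction * peak)[0]
    if below.size == 0:
        warnings.warn(
            "filling rate never collapses after the E peak; returning midpoint of diastole",
            stacklevel=2,
        )
        return midpoint
    _ = t  # frame axis retained for clarity
    return dia[peak_pos + int(below[0])]
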