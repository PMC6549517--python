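"""Conventional chamber metrics: LV volumes, EF, indexed volumes, LA FAC.

These are the standard clinical measures computed alongside the flow
components: end-diastolic/end-systolic volumes from the segmentations,
ejection fraction, body-surface-area-indexed volumes, cardiac output, and
the left atrial fractional area change (a planimetric surrogate for atrial
mechanical function).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .fields import ChamberMask

__all__ = ["CaseMetrics", "lv_global_metrics", "body_surface_area",
           "la_fractional_area_change"]


@dataclass
class CaseMetrics:
    """Conventional metrics for one exam (clinical units)."""

    lvedv_ml: float | None = None
    lvesv_ml: float | None = None
    lvef_pct: float | None = None
    stroke_volume_ml: float | None = None
    cardiac_output_lpm: float | None = None
    lvedvi_ml_m2: float | None = None
    lvesvi_ml_m2: float | None = None
    bsa_m2: float | None = None
    heart_rate_bpm: float | None = None
    la_max_area_cm2: float | None = None
    la_min_area_cm2: float | None = None
    la_fac_pct: float | None = None

    def __post_init__(self) -> None:
        if self.lvef_pct is not None and not 0 <= self.lvef_pct <= 100:
            raise ValueError(f"LVEF {self.lvef_pct}% outside [0, 100]")
        if (
            self.lvedv_ml is not None
            and self.lvesv_ml is not None
            and self.lvesv_ml > self.lvedv_ml + 1e-9
        ):
            raise ValueError("LVESV exceeds LVEDV")
        if self.la_fac_pct is not None and not 0 <= self.la_fac_pct <= 100:
            raise ValueError(f"LA FAC {self.la_fac_pct}% outside [0, 100]")


def body_surface_area(height_cm: float, weight_kg: float,
                      formula: str = "mosteller") -> float:
    """Body surface area in m².

    Mosteller: sqrt(height × weight / 3600); Du Bois available as an
    alternative convention.
    """
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be positive")
    if formula == "mosteller":
        return math.sqrt(height_cm * weight_kg / 3600.0)
    if formula == "dubois":
        return 0.007184 * height_cm**0.725 * weight_kg**0.425
    raise ValueError(f"unknown BSA formula {formula!r}")


def lv_global_metrics(
    ed_mask: ChamberMask,
    es_mask: ChamberMask,
    heart_rate_bpm: float | None = None,
    height_cm: float | None = None,
    weight_kg: float | None = None,
    bsa_formula: str = "mosteller",
) -> CaseMetrics:
    """EDV, ESV, EF, SV, cardiac output and BSA-indexed volumes from masks."""
    if ed_mask.shape != es_mask.shape:
        raise ValueError(
            f"ED mask grid {ed_mask.shape} does not match ES mask grid {es_mask.shape}"
        )
    edv = ed_mask.volume_ml
    esv = es_mask.volume_ml
    if edv == 0:
        raise ValueError("empty ED segmentation: LVEDV = 0")
    sv = edv - esv
    ef = 100.0 * sv / edv
    co = sv * heart_rate_bpm / 1000.0 if heart_rate_bpm is not None else None
    bsa = edvi = esvi = None
    if height_cm is not None and weight_kg is not None:
        bsa = body_surface_area(height_cm, weight_kg, bsa_formula)
        edvi, esvi = edv / bsa, esv / bsa
    return CaseMetrics(
        lvedv_ml=edv,
        lvesv_ml=esv,
        lvef_pct=ef,
        stroke_volume_ml=sv,
        cardiac_output_lpm=co,
        lvedvi_ml_m2=edvi,
        lvesvi_ml_m2=esvi,
        bsa_m2=bsa,
        heart_rate_bpm=heart_rate_bpm,
    )


def la_fractional_area_change(
    largest_areas_cm2: tuple[float, float],
    smallest_areas_cm2: tuple[float, float],
) -> tuple[float, float, float]:
    """LA fractional area change from duplicate planimetric measurements.

    Each extreme area is measured twice and averaged; then
    FAC = (largest − smallest) × 100 / largest.
    Returns (FAC %, mean largest area, mean smallest area).
    """
    big = sum(largest_areas_cm2) / len(largest_areas_cm2)
    small = sum(smallest_areas_cm2) / len(smallest_areas_cm2)
    if big <= 0:
        raise ValueError("largest LA area must be positive")
    if small > big:
        raise ValueError(
            f"smallest LA area ({small} cm²) exceeds largest ({big} cm²)"
        )
    return 100.0 * (big - small) / big, big, small
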