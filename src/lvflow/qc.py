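"""Data-quality gates for the pathline analysis.

Two checks guard against impaired velocity data: the consistency of the
pathline-derived LV inflow and outflow volumes (exams exceeding a 15%
discrepancy are excluded), and the fraction of aberrant pathlines that
leave the cardiac confines or fail to integrate.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _field

import numpy as np

from .components import ComponentResult, derived_flow_volumes
from .tracing import Pathlines

__all__ = ["QCReport", "inflow_outflow_discrepancy", "aberrant_fraction"]

DEFAULT_DISCREPANCY_THRESHOLD = 15.0  # % of inflow volume


@dataclass
class QCReport:
    """Quality-control summary for one exam."""

    inflow_ml: float
    outflow_ml: float
    discrepancy_pct: float
    threshold_pct: float
    passed: bool
    invalid_count: int | None = None
    invalid_fraction_pct: float | None = None
    exit_summary: dict = _field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.discrepancy_pct < 0:
            raise ValueError("discrepancy must be non-negative")
        if self.passed != (self.discrepancy_pct <= self.threshold_pct):
            raise ValueError("pass flag inconsistent with threshold")


def inflow_outflow_discrepancy(
    result: ComponentResult | dict,
    threshold_pct: float = DEFAULT_DISCREPANCY_THRESHOLD,
) -> QCReport:
    """Inflow-vs-outflow consistency of the traced volumes.

    Outflow is the flow-component stroke volume (Direct flow + Delayed
    ejection flow), which keeps the check internal to the pathline
    analysis; discrepancy = |inflow − outflow| / inflow × 100.
    """
    if isinstance(result, ComponentResult):
        derived = result.derived_volumes
    else:
        derived = derived_flow_volumes(result)
    inflow, outflow = derived["inflow"], derived["stroke"]
    if inflow <= 0:
        raise ValueError("zero LV inflow; discrepancy undefined")
    disc = 100.0 * abs(inflow - outflow) / inflow
    return QCReport(
        inflow_ml=inflow * 1e6 if isinstance(result, ComponentResult) else inflow,
        outflow_ml=outflow * 1e6 if isinstance(result, ComponentResult) else outflow,
        discrepancy_pct=disc,
        threshold_pct=threshold_pct,
        passed=disc <= threshold_pct,
    )


def aberrant_fraction(
    pathlines: Pathlines,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[float, dict]:
    """Percentage of pathlines leaving the given bounds or failing to integrate.

    ``bounds`` defaults to the velocity-grid bounding box the tracer used
    (a truncated trajectory is exactly one that left it); a tighter
    "cardiac confines" box may be supplied.  Returns the percentage and a
    summary of exit locations by face.
    """
    n = pathlines.n_seeds
    if bounds is None:
        aberrant = pathlines.truncated | ~pathlines.valid
    else:
        lo, hi = (np.asarray(b, dtype=float) for b in bounds)
        pos = pathlines.positions  # (n, nt, 3)
        outside = np.any((pos < lo) | (pos > hi), axis=(1, 2))
        aberrant = outside | ~pathlines.valid
    summary: dict = {"n_aberrant": int(aberrant.sum())}
    exited = np.isfinite(pathlines.exit_time)
    if exited.any():
        ep = pathlines.exit_position[exited]
        for ax, name in enumerate("xyz"):
            summary[f"exit_min_{name}"] = float(np.nanmin(ep[:, ax]))
            summary[f"exit_max_{name}"] = float(np.nanmax(ep[:, ax]))
    return 100.0 * aberrant.sum() / n, summary
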