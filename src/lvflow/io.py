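"""On-disk formats: velocity datasets, masks, pathlines, configs, result tables.

Velocity data travel either as three 4-D NIfTI volumes (one per encoding
direction) with a YAML sidecar, or as a single HDF5 exam container.  All
stored clinical units (mm, cm/s) are converted to the package's internal SI
units on load.  Pathlines are exported as VTK legacy ASCII polydata, one
polyline per seed with per-point time and speed and a per-line component
label.
"""

from __future__ import annotations

import copy
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .components import COMPONENTS, ComponentResult
from .fields import ChamberMask, VelocityField4D, check_same_geometry
from .metrics import CaseMetrics
from .qc import QCReport
from .tracing import Pathlines

__all__ = [
    "read_velocity_dataset", "write_velocity_dataset",
    "read_mask", "write_mask", "write_exam_hdf5", "read_exam_hdf5",
    "write_results", "read_results", "write_pathlines_vtk", "read_pathlines_vtk",
    "load_config", "DEFAULT_CONFIG",
]

_SPEED_UNITS = {"m/s": 1.0, "cm/s": 1e-2, "mm/s": 1e-3}

DEFAULT_CONFIG: dict = {
    "preprocess": {"polynomial_order": 4, "sd_threshold": 0.03, "max_wraps": 2},
    "timing": {"diastasis_fraction": 0.1},
    "trace": {"step_fraction": 0.2, "record_every_frame": True},
    "components": {"inside_test": "interpolated", "rho": 1060.0},
    "qc": {"discrepancy_threshold": 15.0},
}


def load_config(path: str | Path | None = None) -> dict:
    """Pipeline configuration: package defaults overlaid with a YAML file."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for section, entries in user.items():
            cfg.setdefault(section, {}).update(entries or {})
    if cfg["preprocess"]["polynomial_order"] != 4:
        raise ValueError("the background-phase model is a degree-4 polynomial; "
                         "preprocess.polynomial_order must be 4")
    return cfg


# ---------------------------------------------------------------------------
# NIfTI triplet + sidecar
# ---------------------------------------------------------------------------

_DIRS = ("x", "y", "z")


def write_velocity_dataset(
    field: VelocityField4D, stem: str | Path, dialect: str = "nifti",
    units: str = "m/s",
) -> list[Path]:
    """Write a velocity field; ``dialect`` is ``"nifti"`` or ``"hdf5"``.

    The NIfTI dialect produces ``{stem}_v{x,y,z}.nii.gz`` plus a
    ``{stem}.yaml`` sidecar carrying spacing, frame times, VENC and the
    stored speed units.
    """
    stem = Path(stem)
    if dialect == "hdf5":
        path = stem.with_suffix(".h5")
        write_exam_hdf5(path, field)
        return [path]
    if dialect != "nifti":
        raise ValueError(f"unknown dialect {dialect!r}")
    scale = 1.0 / _SPEED_UNITS[units]
    affine = np.diag([*(field.spacing * 1e3), 1.0])
    affine[:3, 3] = field.origin * 1e3
    out = []
    for d, name in enumerate(_DIRS):
        img = nib.Nifti1Image(field.values[..., d] * scale, affine)
        p = stem.parent / f"{stem.name}_v{name}.nii.gz"
        nib.save(img, p)
        out.append(p)
    sidecar = {
        "units": units,
        "venc_cms": field.venc * 100.0,
        "spacing_mm": (field.spacing * 1e3).tolist(),
        "origin_mm": (field.origin * 1e3).tolist(),
        "frame_times_s": field.frame_times.tolist(),
        "cycle_duration_s": field.cycle_duration,
    }
    meta = stem.with_suffix(".yaml")
    with open(meta, "w") as fh:
        yaml.safe_dump(sidecar, fh)
    return out + [meta]


def read_velocity_dataset(stem: str | Path, dialect: str = "nifti") -> VelocityField4D:
    """Read a velocity dataset, converting stored units to m/s."""
    stem = Path(stem)
    if dialect == "hdf5":
        field, _, _ = read_exam_hdf5(stem if stem.suffix else stem.with_suffix(".h5"))
        return field
    if dialect != "nifti":
        raise ValueError(f"unknown dialect {dialect!r}")
    meta_path = stem.with_suffix(".yaml")
    if not meta_path.exists():
        raise FileNotFoundError(f"sidecar metadata {meta_path} not found")
    with open(meta_path) as fh:
        meta = yaml.safe_load(fh)
    for key in ("units", "venc_cms", "spacing_mm", "frame_times_s", "cycle_duration_s"):
        if key not in meta:
            raise ValueError(f"sidecar metadata is missing required field {key!r}")
    if meta["units"] not in _SPEED_UNITS:
        raise ValueError(f"unknown speed units {meta['units']!r} in sidecar")
    vols = []
    for name in _DIRS:
        p = stem.parent / f"{stem.name}_v{name}.nii.gz"
        vols.append(np.asarray(nib.load(p).dataobj, dtype=float))
    shapes = {v.shape for v in vols}
    if len(shapes) != 1:
        raise ValueError(f"velocity component volumes disagree in shape: {shapes}")
    values = np.stack(vols, axis=-1) * _SPEED_UNITS[meta["units"]]
    if values.ndim != 5:
        raise ValueError(f"expected 4-D volumes per direction, got shape {values.shape}")
    return VelocityField4D(
        values=values,
        spacing=np.asarray(meta["spacing_mm"]) * 1e-3,
        frame_times=np.asarray(meta["frame_times_s"]),
        cycle_duration=float(meta["cycle_duration_s"]),
        venc=float(meta["venc_cms"]) * 1e-2,
        origin=np.asarray(meta.get("origin_mm", [0, 0, 0])) * 1e-3,
    )


def write_mask(mask: ChamberMask, path: str | Path) -> Path:
    path = Path(path)
    affine = np.diag([*(mask.spacing * 1e3), 1.0])
    affine[:3, 3] = mask.origin * 1e3
    img = nib.Nifti1Image(mask.data.astype(np.uint8), affine)
    img.header["descrip"] = f"{mask.label} frame={mask.frame}".encode()
    nib.save(img, path)
    return path


def read_mask(path: str | Path, frame: int | None = None,
              label: str | None = None) -> ChamberMask:
    img = nib.load(path)
    desc = bytes(img.header["descrip"]).decode(errors="ignore").rstrip("\x00")
    parts = dict(
        p.split("=") for p in desc.split() if "=" in p
    )
    lab = label or (desc.split()[0] if desc else "LV")
    frm = frame if frame is not None else int(parts.get("frame", 0))
    spacing = np.asarray(img.header.get_zooms()[:3]) * 1e-3
    origin = np.asarray(img.affine[:3, 3]) * 1e-3
    return ChamberMask(np.asarray(img.dataobj) > 0, frame=frm, label=lab,
                       spacing=spacing, origin=origin)


# ---------------------------------------------------------------------------
# HDF5 exam container
# ---------------------------------------------------------------------------

def write_exam_hdf5(
    path: str | Path,
    field: VelocityField4D,
    ed_mask: ChamberMask | None = None,
    es_mask: ChamberMask | None = None,
    group: str = "exam",
) -> Path:
    """One exam per group: /velocity, /masks/{ed,es}, /meta (lossless, SI)."""
    path = Path(path)
    with h5py.File(path, "w") as fh:
        g = fh.create_group(group)
        dv = g.create_dataset("velocity", data=field.values)
        dv.attrs["units"] = "m/s"
        meta = g.create_group("meta")
        meta.attrs["spacing_m"] = field.spacing
        meta.attrs["origin_m"] = field.origin
        meta.attrs["frame_times_s"] = field.frame_times
        meta.attrs["cycle_duration_s"] = field.cycle_duration
        meta.attrs["venc_ms"] = field.venc
        masks = g.create_group("masks")
        for name, m in (("ed", ed_mask), ("es", es_mask)):
            if m is None:
                continue
            dm = masks.create_dataset(name, data=m.data.astype(np.uint8))
            dm.attrs["frame"] = m.frame
            dm.attrs["label"] = m.label
    return path


def read_exam_hdf5(
    path: str | Path, group: str = "exam"
) -> tuple[VelocityField4D, ChamberMask | None, ChamberMask | None]:
    with h5py.File(path, "r") as fh:
        g = fh[group]
        meta = g["meta"].attrs
        field = VelocityField4D(
            values=g["velocity"][()],
            spacing=np.asarray(meta["spacing_m"]),
            frame_times=np.asarray(meta["frame_times_s"]),
            cycle_duration=float(meta["cycle_duration_s"]),
            venc=float(meta["venc_ms"]),
            origin=np.asarray(meta["origin_m"]),
        )
        masks = {}
        for name in ("ed", "es"):
            if "masks" in g and name in g["masks"]:
                dm = g["masks"][name]
                masks[name] = ChamberMask(
                    dm[()] > 0, frame=int(dm.attrs["frame"]),
                    label=str(dm.attrs["label"]),
                    spacing=field.spacing, origin=field.origin,
                )
                check_same_geometry(field, masks[name], f"{name} mask")
    return field, masks.get("ed"), masks.get("es")


# ---------------------------------------------------------------------------
# results tables
# ---------------------------------------------------------------------------

_COMP_KEYS = {
    "Direct flow": "direct_flow",
    "Retained inflow": "retained_inflow",
    "Delayed ejection flow": "delayed_ejection",
    "Residual volume": "residual_volume",
}


def results_row(
    case: CaseMetrics | None = None,
    comp: ComponentResult | None = None,
    qc: QCReport | None = None,
    subject: str = "case",
) -> dict:
    """Flatten one exam's metrics into a CSV-ready row (clinical units)."""
    row: dict = {"subject": subject}
    if case is not None:
        row.update(
            edv_ml=case.lvedv_ml, esv_ml=case.lvesv_ml, ef_pct=case.lvef_pct,
            edvi_ml_m2=case.lvedvi_ml_m2, esvi_ml_m2=case.lvesvi_ml_m2,
            sv_ml=case.stroke_volume_ml, co_lpm=case.cardiac_output_lpm,
            la_fac_pct=case.la_fac_pct, heart_rate_bpm=case.heart_rate_bpm,
            bsa_m2=case.bsa_m2,
        )
    if comp is not None:
        for name in COMPONENTS:
            key = _COMP_KEYS[name]
            row[f"{key}_volume_ml"] = comp.volumes[name] * 1e6
            row[f"{key}_volume_pct"] = comp.volume_ratios[name]
            row[f"{key}_ke_mj"] = comp.ke[name] * 1e3
            row[f"{key}_ke_pct"] = comp.ke_ratios[name]
        for agg in ("inflow", "stroke", "non_ejected"):
            row[f"{agg}_volume_ml"] = comp.derived_volumes[agg] * 1e6
            row[f"{agg}_ke_mj"] = comp.derived_ke[agg] * 1e3
        row["late_inflow_volume_pct"] = comp.late_volume_pct
        row["late_inflow_ke_pct"] = comp.late_ke_pct
        row["n_excluded_pathlines"] = comp.n_excluded
    if qc is not None:
        row["qc_discrepancy_pct"] = qc.discrepancy_pct
        row["qc_pass"] = qc.passed
    return row


def write_results(rows: dict | list[dict], path: str | Path) -> pd.DataFrame:
    """Write exam rows (see :func:`results_row`) to CSV with full precision."""
    if isinstance(rows, dict):
        rows = [rows]
    df = pd.DataFrame(rows)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g")
    return df


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# VTK legacy ASCII polydata (pathlines)
# ---------------------------------------------------------------------------

def write_pathlines_vtk(
    pathlines: Pathlines,
    path: str | Path,
    labels: np.ndarray | None = None,
) -> Path:
    """Export pathlines as VTK legacy ASCII polydata.

    One polyline per seed; per-point ``time`` (s) and ``speed`` (m/s), and a
    per-line integer ``component`` label (index into the component list, -1
    for excluded pathlines).  Positions are written in millimetres, the
    visualisation convention.
    """
    path = Path(path)
    n, nt = pathlines.n_seeds, len(pathlines.times)
    pts_mm = pathlines.positions.reshape(-1, 3) * 1e3
    speed = np.linalg.norm(pathlines.velocities, axis=2).ravel()
    times = np.tile(pathlines.times, n)
    if labels is None:
        codes = np.full(n, -1, dtype=int)
    else:
        name_to_code = {c: i for i, c in enumerate(COMPONENTS)}
        codes = np.array([name_to_code.get(str(l), -1) for l in labels])

    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("LV pathlines (one polyline per seed)\n")
        fh.write("ASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {n * nt} float\n")
        np.savetxt(fh, pts_mm, fmt="%.6g")
        fh.write(f"LINES {n} {n * (nt + 1)}\n")
        conn = np.column_stack(
            [np.full(n, nt), np.arange(n * nt).reshape(n, nt)]
        )
        np.savetxt(fh, conn, fmt="%d")
        fh.write(f"POINT_DATA {n * nt}\n")
        fh.write("SCALARS time float 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, times, fmt="%.6g")
        fh.write("SCALARS speed float 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, speed, fmt="%.6g")
        fh.write(f"CELL_DATA {n}\n")
        fh.write("SCALARS component int 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, codes, fmt="%d")
    return path


def read_pathlines_vtk(path: str | Path) -> dict:
    """Minimal VTK legacy ASCII polydata reader (round-trip checks).

    Returns points (mm), per-line point-index lists, and the point/cell
    scalar arrays found in the file.
    """
    tokens: list[str] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines[0].startswith("# vtk DataFile"):
        raise ValueError(f"{path} is not a VTK legacy file")
    if lines[2].strip().upper() != "ASCII":
        raise ValueError("only ASCII VTK files are supported")
    for ln in lines[3:]:
        tokens.extend(ln.split())
    out: dict = {"points": None, "lines": [], "point_data": {}, "cell_data": {}}
    i = 0
    scal_target = None
    while i < len(tokens):
        tok = tokens[i].upper()
        if tok == "POINTS":
            npts = int(tokens[i + 1])
            vals = np.array(tokens[i + 3: i + 3 + 3 * npts], dtype=float)
            out["points"] = vals.reshape(npts, 3)
            i += 3 + 3 * npts
        elif tok == "LINES":
            nlines, total = int(tokens[i + 1]), int(tokens[i + 2])
            vals = np.array(tokens[i + 3: i + 3 + total], dtype=int)
            j = 0
            for _ in range(nlines):
                cnt = vals[j]
                out["lines"].append(vals[j + 1: j + 1 + cnt])
                j += 1 + cnt
            i += 3 + total
        elif tok == "POINT_DATA":
            scal_target = ("point_data", int(tokens[i + 1]))
            i += 2
        elif tok == "CELL_DATA":
            scal_target = ("cell_data", int(tokens[i + 1]))
            i += 2
        elif tok == "SCALARS":
            name = tokens[i + 1]
            where, count = scal_target
            # skip 'SCALARS name type [ncomp]' + 'LOOKUP_TABLE default'
            j = i + 3
            if tokens[j].isdigit():
                j += 1
            j += 2
            out[where][name] = np.array(tokens[j: j + count], dtype=float)
            i = j + count
        else:
            i += 1
    return out
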