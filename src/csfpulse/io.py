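"""NIfTI + sidecar-JSON I/O, phase<->velocity conversion, metric tables.

A series is stored as a 4D NIfTI-1 image ``(x, y, 1, t)`` together with a
JSON sidecar (same stem, ``.json``) holding ``{kind, dt, venc, duration,
resp_period, subject_id}``.  Velocity (cm/s, positive = cranial) is the
canonical internal unit; phase is only an encoding.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import AcquisitionMeta, PhaseSeries, ROIMask, VelocitySeries, wrap_phase

__all__ = [
    "phase_to_velocity",
    "velocity_to_phase",
    "save_series",
    "load_series",
    "save_masks",
    "load_masks",
    "export_metrics_table",
]

#: |v|/venc above which a decoded value is flagged as a possible alias.
ALIAS_FRACTION = 0.98


def velocity_to_phase(vel: VelocitySeries) -> PhaseSeries:
    """Encode velocity to phase: ``phi = pi * v / venc``, wrapped to (-pi, pi].

    Velocities beyond VENC wrap (alias) exactly as in the scanner encoding;
    no error is raised.
    """
    phi = wrap_phase(np.pi * vel.data / vel.meta.venc)
    return PhaseSeries(data=phi, meta=vel.meta)


def phase_to_velocity(phase: PhaseSeries) -> VelocitySeries:
    """Decode phase to velocity: ``v = venc * phi / pi`` (cm/s).

    Values with ``|v|`` within 2% of VENC are counted as possible aliasing
    and reported via a warning and the ``n_alias`` field; nothing is
    "corrected" — at the study's velocities (~1 cm/s vs VENC 10 cm/s)
    aliasing indicates a configuration problem, not a fixable wrap.
    """
    venc = phase.meta.venc
    v = venc * phase.data / np.pi
    n_alias = int(np.count_nonzero(np.abs(v) >= ALIAS_FRACTION * venc))
    if n_alias:
        warnings.warn(
            f"{n_alias} voxel-frames decode within 2% of VENC={venc} cm/s; "
            "possible velocity aliasing",
            stacklevel=2,
        )
    return VelocitySeries(data=v, meta=phase.meta, n_alias=n_alias)


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)] + ".json")
    return path.with_suffix(".json")


def save_series(series: PhaseSeries | VelocitySeries, path: str | Path) -> Path:
    """Write a series as 4D NIfTI plus JSON sidecar; returns the image path."""
    path = Path(path)
    kind = "phase" if isinstance(series, PhaseSeries) else "velocity"
    affine = np.eye(4)
    img = nib.Nifti1Image(np.asarray(series.data, dtype=np.float64), affine)
    img.header["pixdim"][4] = series.meta.dt
    img.header["descrip"] = (
        f"csfpulse {kind}; dt={series.meta.dt}s venc={series.meta.venc}cm/s".encode()
    )
    nib.save(img, str(path))
    sidecar = {"kind": kind, **series.meta.to_dict()}
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def load_series(path: str | Path) -> PhaseSeries | VelocitySeries:
    """Load a 4D NIfTI series and its sidecar metadata.

    Raises
    ------
    FileNotFoundError
        If the image or its sidecar is missing.
    ValueError
        If the image is not 4D, or the sidecar lacks ``dt`` or ``venc``
        (the error names the missing field).
    """
    path = Path(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise ValueError(f"expected a 4D series, got {data.ndim}D in {path}")
    sc_path = _sidecar_path(path)
    if not sc_path.exists():
        raise FileNotFoundError(f"sidecar metadata {sc_path} not found")
    sidecar = json.loads(sc_path.read_text())
    for required in ("dt", "venc"):
        if sidecar.get(required) is None:
            raise ValueError(f"sidecar {sc_path} is missing required field {required!r}")
    meta = AcquisitionMeta(
        dt=float(sidecar["dt"]),
        venc=float(sidecar["venc"]),
        duration=sidecar.get("duration"),
        resp_period=sidecar.get("resp_period"),
        subject_id=sidecar.get("subject_id", ""),
    )
    kind = sidecar.get("kind", "velocity")
    cls = PhaseSeries if kind == "phase" else VelocitySeries
    return cls(data=data, meta=meta)


def save_masks(masks: dict[str, ROIMask], path: str | Path) -> Path:
    """Write ROI masks as one integer label NIfTI + JSON label table."""
    path = Path(path)
    shapes = {m.mask.shape for m in masks.values()}
    if len(shapes) != 1:
        raise ValueError("all masks must share one image shape")
    shape = shapes.pop()
    labels = np.zeros(shape + (1,), dtype=np.int16)
    table = {}
    for i, (name, roi) in enumerate(sorted(masks.items()), start=1):
        if np.any(labels[roi.mask, 0] != 0):
            raise ValueError(f"mask {name!r} overlaps a previously written mask")
        labels[roi.mask, 0] = i
        table[str(i)] = name
    nib.save(nib.Nifti1Image(labels, np.eye(4)), str(path))
    _sidecar_path(path).write_text(json.dumps({"labels": table}, indent=1))
    return path


def load_masks(path: str | Path) -> dict[str, ROIMask]:
    path = Path(path)
    labels = np.asanyarray(nib.load(str(path)).dataobj)
    if labels.ndim == 3 and labels.shape[2] == 1:
        labels = labels[:, :, 0]
    table = json.loads(_sidecar_path(path).read_text())["labels"]
    return {
        name: ROIMask(mask=labels == int(val), label=name)
        for val, name in table.items()
    }


def export_metrics_table(metrics: list, path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Write per-subject component metrics and a mean +/- SD summary.

    ``metrics`` is a list of :class:`~csfpulse.quantify.ComponentMetrics`.
    The long table has one row per subject x region x direction x component
    with peak velocity, displacement and the two fractions; the summary
    aggregates mean and SD by (region, resp_period, direction, component)
    and is written next to ``path`` with a ``_summary`` suffix.
    """
    if not metrics:
        raise ValueError("no metrics to export")
    rows = []
    for m in metrics:
        for component in ("cardiac", "respiratory"):
            rows.append(
                {
                    "subject": m.subject_id,
                    "region": m.region,
                    "resp_period": m.resp_period,
                    "direction": m.direction,
                    "component": component,
                    "peak_velocity": m.v_c if component == "cardiac" else m.v_r,
                    "displacement": m.d_c if component == "cardiac" else m.d_r,
                    "velocity_fraction": m.f_c if component == "cardiac" else m.f_r,
                    "displacement_fraction": (
                        m.f_c_disp if component == "cardiac" else m.f_r_disp
                    ),
                }
            )
    df = pd.DataFrame(rows)
    summary = (
        df.groupby(["region", "resp_period", "direction", "component"])[
            ["peak_velocity", "displacement", "velocity_fraction", "displacement_fraction"]
        ]
        .agg(["mean", "std"])
        .reset_index()
    )
    summary.columns = [
        "_".join(c for c in col if c) if isinstance(col, tuple) else col
        for col in summary.columns
    ]
    path = Path(path)
    df.to_csv(path, index=False)
    summary_path = path.with_name(path.stem + "_summary" + path.suffix)
    summary.to_csv(summary_path, index=False)
    return df, summary
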