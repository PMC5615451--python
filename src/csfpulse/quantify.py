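"""Component fractions and direction-gated displacements per ROI.

Two summary quantities per region, direction and component:

* **peak velocity** — each voxel's directional extreme of the component
  waveform (largest positive sample for cranial, most negative for caudal),
  averaged over the ROI; caudal peaks keep their negative sign.
* **displacement** ``D = (1/N) * sum_n [ dt * sum_m v(m dt) ]`` — per voxel,
  velocity summed over the M time points of a directional excursion (a
  maximal run of consecutive same-sign samples), times the frame interval,
  averaged over the excursions in the record and then over the N ROI
  voxels.  Cranial displacement is >= 0, caudal <= 0 by construction.

The per-excursion definition is what makes the displacement a *distance
travelled before flow reversal*: a slow oscillation integrates for half its
(long) period before reversing and so covers more ground per excursion than
a fast one of larger velocity — for a sinusoid of peak V and period T each
directional excursion displaces V*T/pi.  Summing over the whole record
instead would scale both components by the record duration and erase the
period dependence; that variant is available as ``mode="total"``.

Fractions follow ``F_r = v_r / (v_r + v_c)`` on magnitudes (``F_c = 1 -
F_r``), applied to peak velocities, and in the same form to displacements
separately for each direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ROIMask
from .separation import ComponentSet, peak_velocity

__all__ = [
    "ComponentMetrics",
    "velocity_fraction",
    "directional_displacement",
    "roi_waveforms",
    "quantify_subject",
]

DIRECTIONS = ("cranial", "caudal")


@dataclass
class ComponentMetrics:
    """Per region x direction summary of one subject run.

    Velocities in cm/s (caudal negative), displacements in cm (caudal
    negative), fractions unitless in [0, 1] with ``f_r + f_c = 1``.
    """

    subject_id: str
    region: str
    resp_period: float | None
    direction: str
    v_c: float
    v_r: float
    f_c: float
    f_r: float
    d_c: float
    d_r: float
    f_c_disp: float
    f_r_disp: float
    n_voxels: int


def velocity_fraction(v_r: float, v_c: float) -> tuple[float, float]:
    """Respiratory and cardiac share of the summed component magnitudes.

    Inputs are magnitudes (caudal peaks must be negated before entry).
    Returns ``(F_r, F_c)`` with ``F_r = v_r / (v_r + v_c)``.
    """
    if v_r < 0 or v_c < 0:
        raise ValueError("fraction inputs are magnitudes and must be >= 0")
    total = v_r + v_c
    if total == 0:
        raise ValueError("undefined fraction: v_r + v_c = 0")
    f_r = v_r / total
    return f_r, 1.0 - f_r


def directional_displacement(
    waveforms: np.ndarray, dt: float, direction: str, mode: str = "per_excursion"
) -> float:
    """ROI-mean direction-gated displacement of component waveforms, cm.

    ``waveforms`` is (n_voxels, n_frames) in cm/s.  For each voxel the
    samples whose sign matches the direction (positive = cranial, negative
    = caudal; exact zeros belong to neither — a measure-zero event for
    continuous velocities) are summed over the M time points of each
    directional excursion and multiplied by ``dt``; the per-voxel value is
    the mean over that voxel's excursions (``mode="per_excursion"``,
    default: the typical distance travelled before flow reversal) or the
    sum over all of them (``mode="total"``: net directional transport over
    the record).  The result is averaged across voxels.  A voxel with no
    excursion in the requested direction contributes 0.
    """
    w = np.atleast_2d(np.asarray(waveforms, dtype=float))
    if w.shape[0] < 1 or w.shape[1] < 2:
        raise ValueError("need at least 1 voxel and 2 time points")
    if direction == "cranial":
        match = w > 0
    elif direction == "caudal":
        match = w < 0
    else:
        raise ValueError(f"direction must be 'cranial' or 'caudal', got {direction!r}")
    if mode not in ("per_excursion", "total"):
        raise ValueError(f"unknown displacement mode {mode!r}")
    gated = np.where(match, w, 0.0)
    totals = gated.sum(axis=1)  # per-voxel whole-record directional sum
    if mode == "total":
        return float(dt * totals.mean())
    # number of maximal same-sign runs per voxel: count run starts
    starts = np.empty_like(match)
    starts[:, 0] = match[:, 0]
    starts[:, 1:] = match[:, 1:] & ~match[:, :-1]
    n_runs = starts.sum(axis=1)
    per_vox = np.divide(totals, n_runs, out=np.zeros_like(totals), where=n_runs > 0)
    return float(dt * per_vox.mean())


def roi_waveforms(cs: ComponentSet, mask: ROIMask) -> dict[str, np.ndarray]:
    """Extract (n_voxels, n_frames) component waveforms under a mask."""
    m = mask.mask
    out = {}
    for name in ("cardiac", "respiratory", "residual"):
        comp = getattr(cs, name)
        if comp.ndim == 4:
            comp = comp[:, :, 0, :]
        out[name] = comp[m]
    return out


def quantify_subject(
    components: ComponentSet,
    masks: dict[str, ROIMask] | list[ROIMask],
    meta=None,
    aggregation: str = "voxel_peak_mean",
    displacement_mode: str = "per_excursion",
) -> list[ComponentMetrics]:
    """Compute all component metrics for one subject: region x direction.

    ``aggregation`` selects the ROI reduction for peak velocity:
    ``"voxel_peak_mean"`` (default) takes each voxel's directional peak and
    averages over the ROI — consistent with the voxel-mean structure of the
    displacement measure — while ``"roi_mean_waveform"`` takes the
    directional peak of the ROI-averaged waveform.
    """
    if components is None:
        raise ValueError("missing component set")
    if aggregation not in ("voxel_peak_mean", "roi_mean_waveform"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    if isinstance(masks, dict):
        mask_items = list(masks.items())
    else:
        mask_items = [(m.label, m) for m in masks]
    if not mask_items:
        raise ValueError("missing ROI masks")
    meta = meta if meta is not None else components.meta
    dt = meta.dt
    subject_id = getattr(meta, "subject_id", "")
    resp_period = getattr(meta, "resp_period", None)

    out: list[ComponentMetrics] = []
    for region, mask in mask_items:
        waves = roi_waveforms(components, mask)
        for direction in DIRECTIONS:
            peaks = {}
            for comp in ("cardiac", "respiratory"):
                if aggregation == "voxel_peak_mean":
                    per_vox = [peak_velocity(w, direction) for w in waves[comp]]
                    peaks[comp] = float(np.mean(per_vox))
                else:
                    peaks[comp] = peak_velocity(waves[comp].mean(axis=0), direction)
            f_r, f_c = velocity_fraction(abs(peaks["respiratory"]), abs(peaks["cardiac"]))
            d_c = directional_displacement(
                waves["cardiac"], dt, direction, mode=displacement_mode
            )
            d_r = directional_displacement(
                waves["respiratory"], dt, direction, mode=displacement_mode
            )
            f_r_disp, f_c_disp = velocity_fraction(abs(d_r), abs(d_c))
            out.append(
                ComponentMetrics(
                    subject_id=subject_id,
                    region=region,
                    resp_period=resp_period,
                    direction=direction,
                    v_c=peaks["cardiac"],
                    v_r=peaks["respiratory"],
                    f_c=f_c,
                    f_r=f_r,
                    d_c=d_c,
                    d_r=d_r,
                    f_c_disp=f_c_disp,
                    f_r_disp=f_r_disp,
                    n_voxels=mask.n,
                )
            )
    return out
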