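"""Core containers for phase-contrast velocimetry time series.

Conventions fixed across the package:

* images are single-slice 4D arrays shaped ``(x, y, 1, t)``;
* velocity is in cm/s with **positive = cranial** (foot-head flow encode);
* phase is in radians, wrapped to the half-open interval ``(-pi, pi]``,
  reaching +/-pi exactly at the velocity-encoding limit (VENC).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AcquisitionMeta",
    "PhaseSeries",
    "VelocitySeries",
    "ROIMask",
    "wrap_phase",
]


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap angles into ``(-pi, pi]``.

    The upper edge is closed so that a velocity exactly at +VENC encodes to
    +pi rather than -pi; -pi itself maps to +pi (the two are the same
    physical phase).
    """
    phi = np.asarray(phi, dtype=float)
    return -(np.mod(-phi + np.pi, 2.0 * np.pi) - np.pi)


@dataclass
class AcquisitionMeta:
    """Scan metadata needed to interpret a velocity/phase series.

    Parameters
    ----------
    dt
        Frame interval in seconds (temporal resolution).
    venc
        Velocity encoding in cm/s: the velocity mapped to a phase of pi.
    duration
        Total acquisition time in seconds (``~ dt * n_frames``).
    resp_period
        Guided-respiration period in seconds, if any.
    subject_id
        Free-text subject / run identifier.
    """

    dt: float
    venc: float
    duration: float | None = None
    resp_period: float | None = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if not self.venc > 0:
            raise ValueError(f"venc must be positive, got {self.venc}")

    @property
    def nyquist(self) -> float:
        """Nyquist frequency of the frame sampling, Hz."""
        return 0.5 / self.dt

    def to_dict(self) -> dict:
        return {
            "dt": self.dt,
            "venc": self.venc,
            "duration": self.duration,
            "resp_period": self.resp_period,
            "subject_id": self.subject_id,
        }


def _check_4d(data: np.ndarray, what: str) -> np.ndarray:
    data = np.asarray(data)
    if data.ndim != 4:
        raise ValueError(
            f"{what} must be 4D (x, y, z, t); got {data.ndim}D shape {data.shape}"
        )
    if data.shape[-1] < 2:
        raise ValueError(f"{what} needs at least 2 time frames, got {data.shape[-1]}")
    return data


@dataclass
class PhaseSeries:
    """4D phase image series in radians, values in ``(-pi, pi]``."""

    data: np.ndarray
    meta: AcquisitionMeta

    def __post_init__(self) -> None:
        self.data = _check_4d(self.data, "phase series")
        lo, hi = float(self.data.min()), float(self.data.max())
        if lo <= -np.pi - 1e-12 or hi > np.pi + 1e-12:
            raise ValueError(
                f"phase values must lie in (-pi, pi]; found range [{lo}, {hi}]"
            )

    @property
    def n_frames(self) -> int:
        return self.data.shape[-1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.meta.dt


@dataclass
class VelocitySeries:
    """4D velocity series, cm/s, positive = cranial.

    ``n_alias`` counts voxel-frames whose decoded speed fell within 2% of
    VENC, flagging possible phase aliasing; it is informational only.
    """

    data: np.ndarray
    meta: AcquisitionMeta
    n_alias: int = 0

    def __post_init__(self) -> None:
        self.data = _check_4d(self.data, "velocity series")

    @property
    def n_frames(self) -> int:
        return self.data.shape[-1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.meta.dt


@dataclass
class ROIMask:
    """Boolean single-slice region mask with a region label.

    ``n`` (the ROI voxel count) is the averaging denominator used by the
    displacement measure.
    """

    mask: np.ndarray
    label: str
    # "foramen of Monro" appears in some descriptions of this protocol as a
    # likely erratum for the foramen magnum; both labels are accepted.
    KNOWN_LABELS = ("aqueduct", "foramen_magnum", "foramen_monro")

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim == 3 and self.mask.shape[2] == 1:
            self.mask = self.mask[:, :, 0]
        if self.mask.ndim != 2:
            raise ValueError(f"mask must be 2D, got shape {self.mask.shape}")
        if self.n < 1:
            raise ValueError(f"mask for region {self.label!r} is empty")

    @property
    def n(self) -> int:
        return int(self.mask.sum())
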