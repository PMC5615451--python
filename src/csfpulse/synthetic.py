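"""Synthetic phase-contrast MRI generator with known cardiac/respiratory content.

Emulates a single-slice asynchronous 2D-PC acquisition of the kind used for
CSF motion studies: a 256x256 matrix sampled at ~4.6 frames/s for 55 s with
VENC 10 cm/s, containing two CSF regions — a small "aqueduct" disc (2-3
voxels across, i.e. deep in the partial-volume regime at ~2 mm voxels) and a
larger "foramen magnum" region.  Each CSF voxel carries the sum of

* a quasi-pulsatile cardiac waveform (harmonic series on a fundamental in
  the 1.0-1.6 Hz heart-rate band),
* a guided-respiration sinusoid (period 6, 10 or 16 s),
* an optional sub-respiratory drift,

which is spatially blurred (partial volume), perturbed by Gaussian phase
noise, and encoded to wrapped phase via ``phi = pi * v / VENC``.  The ground
truth (pre-blur, pre-noise region waveforms, amplitudes and masks) is
returned alongside for recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import AcquisitionMeta, PhaseSeries, ROIMask, VelocitySeries
from .io import velocity_to_phase

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "SubjectRun",
    "make_phantom",
    "cardiac_waveform",
    "respiratory_waveform",
    "generate_subject",
    "generate_cohort",
]

REGIONS = ("aqueduct", "foramen_magnum")


@dataclass
class SyntheticConfig:
    """Generation parameters for one synthetic subject run.

    Amplitude defaults describe the aqueduct; the foramen magnum uses the
    same waveforms scaled by ``fm_cardiac_scale`` / ``fm_resp_scale``,
    reflecting the several-fold larger velocities seen at the skull base.

    Parameters
    ----------
    grid_size
        Image matrix side (voxels).
    n_frames
        Frames in the record; 253 = floor(55 s / 0.217 s).
    dt
        Frame interval, s.
    venc
        Velocity encoding, cm/s.
    resp_period
        Guided-respiration period, s (study values: 6, 10, 16).
    resp_amp
        Respiratory velocity peak in the aqueduct, cm/s.
    cardiac_freq
        Cardiac fundamental, Hz (normal resting heart rate band 1.0-1.6).
    cardiac_amp
        Cardiac velocity peak in the aqueduct, cm/s.
    cardiac_harmonics
        Relative harmonic amplitudes of the cardiac pulse; harmonics whose
        frequency exceeds the sampling Nyquist are dropped at generation.
    noise_sd
        Gaussian velocity-noise SD per voxel-frame, cm/s.
    drift_amp
        Amplitude of a slow (sub-respiratory-band) drift, cm/s; 0 disables.
    blur_sigma
        Gaussian spatial blur SD in voxels, emulating partial volume.
    fm_cardiac_scale, fm_resp_scale
        Foramen-magnum amplitudes relative to the aqueduct.
    seed
        RNG seed; identical (config, seed) gives bit-identical output.
    """

    grid_size: int = 256
    n_frames: int = 253
    dt: float = 0.217
    venc: float = 10.0
    resp_period: float = 6.0
    resp_amp: float = 0.12
    cardiac_freq: float = 1.2
    cardiac_amp: float = 0.2
    cardiac_harmonics: tuple[float, ...] = (1.0, 0.5, 0.25)
    noise_sd: float = 0.02
    drift_amp: float = 0.0
    blur_sigma: float = 1.0
    fm_cardiac_scale: float = 4.75
    fm_resp_scale: float = 3.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.venc <= 0:
            raise ValueError("venc must be positive")
        if self.resp_period <= 0:
            raise ValueError("resp_period must be positive")
        if self.cardiac_freq >= 0.5 / self.dt:
            raise ValueError(
                f"cardiac_freq {self.cardiac_freq} Hz is at/above the sampling "
                f"Nyquist {0.5 / self.dt:.3f} Hz"
            )
        for name in ("resp_amp", "cardiac_amp", "noise_sd", "drift_amp", "blur_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def duration(self) -> float:
        return self.n_frames * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt

    def meta(self, subject_id: str = "synthetic") -> AcquisitionMeta:
        return AcquisitionMeta(
            dt=self.dt,
            venc=self.venc,
            duration=self.duration,
            resp_period=self.resp_period,
            subject_id=subject_id,
        )

    def region_amps(self, region: str) -> tuple[float, float]:
        """(cardiac, respiratory) peak amplitude for a region, cm/s."""
        if region == "aqueduct":
            return self.cardiac_amp, self.resp_amp
        if region == "foramen_magnum":
            return (
                self.cardiac_amp * self.fm_cardiac_scale,
                self.resp_amp * self.fm_resp_scale,
            )
        raise KeyError(f"unknown region {region!r}")


@dataclass
class GroundTruth:
    """Generator-side truth for recovery tests.

    ``component_waveforms[region][component]`` are the injected pre-blur,
    pre-noise time series (length ``n_frames``); amplitudes are the true
    waveform peaks in cm/s.  ``n_wrapped`` counts voxel-frames whose true
    velocity exceeded VENC and therefore aliased during phase encoding.
    """

    masks: dict[str, ROIMask]
    labels: np.ndarray
    true_cardiac_amp: dict[str, float]
    true_resp_amp: dict[str, float]
    cardiac_freq: float
    resp_period: float
    component_waveforms: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    n_wrapped: int = 0


@dataclass
class SubjectRun:
    """One generated acquisition: a subject at one respiratory period."""

    subject_id: str
    config: SyntheticConfig
    phase: PhaseSeries
    truth: GroundTruth


def make_phantom(config: SyntheticConfig) -> tuple[np.ndarray, GroundTruth]:
    """Lay out the two CSF regions on the image grid.

    Returns a 2D integer label image (0 = background, 1 = aqueduct,
    2 = foramen magnum) and a :class:`GroundTruth` carrying the crisp masks
    (recorded before any blurring).  The aqueduct is a disc ~2-3 voxels
    across; the foramen magnum a disc of ~12-voxel diameter.  Positions are
    fixed fractions of the grid, so the same config always yields the same
    phantom.
    """
    g = config.grid_size
    if g < 32:
        raise ValueError(f"grid_size {g} too small to place both regions (need >= 32)")
    yy, xx = np.mgrid[0:g, 0:g]
    labels = np.zeros((g, g), dtype=np.int16)

    aq_c = (0.30 * g, 0.50 * g)
    aq_r = 1.4  # voxels: 2-3 voxel diameter, partial-volume regime
    fm_c = (0.70 * g, 0.50 * g)
    fm_r = max(3.0, 0.09 * min(g, 64))

    aq = (yy - aq_c[0]) ** 2 + (xx - aq_c[1]) ** 2 <= aq_r**2
    fm = (yy - fm_c[0]) ** 2 + (xx - fm_c[1]) ** 2 <= fm_r**2
    labels[aq] = 1
    labels[fm] = 2
    masks = {
        "aqueduct": ROIMask(mask=aq, label="aqueduct"),
        "foramen_magnum": ROIMask(mask=fm, label="foramen_magnum"),
    }
    truth = GroundTruth(
        masks=masks,
        labels=labels,
        true_cardiac_amp={r: config.region_amps(r)[0] for r in REGIONS},
        true_resp_amp={r: config.region_amps(r)[1] for r in REGIONS},
        cardiac_freq=config.cardiac_freq,
        resp_period=config.resp_period,
    )
    return labels, truth


def cardiac_waveform(
    t: np.ndarray,
    freq: float,
    amp: float,
    harmonics: tuple[float, ...] = (1.0, 0.5, 0.25),
    phases: tuple[float, ...] | None = None,
    nyquist: float | None = None,
) -> np.ndarray:
    """Quasi-pulsatile cardiac velocity waveform, cm/s.

    A harmonic series ``sum_k h_k sin(2 pi k f t + phi_k)`` normalized so
    its peak absolute value over a dense cycle equals ``amp`` — the peak is
    the quantity the downstream analysis reports, so the stated amplitude is
    defined as the waveform peak, not an RMS.  Harmonics at or above
    ``nyquist`` (when given) are dropped; if none survive, an error is
    raised rather than silently returning an aliased shape.
    """
    if freq <= 0:
        raise ValueError("cardiac frequency must be positive")
    t = np.asarray(t, dtype=float)
    harmonics = tuple(harmonics)
    if phases is None:
        phases = (0.0,) * len(harmonics)
    if len(phases) != len(harmonics):
        raise ValueError("phases and harmonics must have equal length")
    kept = [
        (k, h, p)
        for k, (h, p) in enumerate(zip(harmonics, phases), start=1)
        if h != 0 and (nyquist is None or k * freq < nyquist)
    ]
    if amp == 0:
        return np.zeros_like(t)
    if not kept:
        raise ValueError(
            f"all cardiac harmonics lie at/above the Nyquist frequency {nyquist} Hz"
        )

    def synth(tt: np.ndarray) -> np.ndarray:
        w = np.zeros_like(tt)
        for k, h, p in kept:
            w += h * np.sin(2.0 * np.pi * k * freq * tt + p)
        return w

    # peak over one fundamental period on a dense grid (the waveform is
    # periodic, so one cycle suffices); 2^17 points keeps the peak-location
    # error below 1e-9 relative
    t_dense = np.linspace(0.0, 1.0 / freq, 1 << 17, endpoint=False)
    peak = np.max(np.abs(synth(t_dense)))
    return amp / peak * synth(t)


def respiratory_waveform(t: np.ndarray, period: float, amp: float) -> np.ndarray:
    """Guided-respiration velocity waveform: ``amp * sin(2 pi t / period)``."""
    if period <= 0:
        raise ValueError("respiratory period must be positive")
    t = np.asarray(t, dtype=float)
    return amp * np.sin(2.0 * np.pi * t / period)


def _drift_waveform(t: np.ndarray, duration: float, amp: float) -> np.ndarray:
    # quarter-cycle of a sinusoid over the record: monotonic slow drift whose
    # frequency 1/(4*duration) sits well below the respiratory band floor
    return amp * np.sin(2.0 * np.pi * t / (4.0 * duration))


def generate_subject(
    config: SyntheticConfig, subject_id: str = "synthetic"
) -> tuple[PhaseSeries, GroundTruth]:
    """Generate one phase-encoded acquisition plus its ground truth.

    Per-voxel velocity = region cardiac + respiratory + drift waveform,
    spatially blurred by ``blur_sigma`` (partial-volume emulation), plus
    i.i.d. Gaussian noise of SD ``noise_sd``; then encoded to wrapped phase.
    Harmonic phase offsets (beyond the fundamental) are drawn from the
    seeded RNG so repeated calls are bit-identical.
    """
    labels, truth = make_phantom(config)
    rng = np.random.default_rng(config.seed)
    t = config.times
    nyq = 0.5 / config.dt

    n_harm = len(config.cardiac_harmonics)
    harm_phases = (0.0,) + tuple(rng.uniform(0, 2 * np.pi, size=max(0, n_harm - 1)))

    vel = np.zeros((config.grid_size, config.grid_size, config.n_frames))
    for region_idx, region in enumerate(REGIONS, start=1):
        c_amp, r_amp = config.region_amps(region)
        cw = cardiac_waveform(
            t, config.cardiac_freq, c_amp, config.cardiac_harmonics,
            phases=harm_phases, nyquist=nyq,
        )
        rw = respiratory_waveform(t, config.resp_period, r_amp)
        dw = _drift_waveform(t, config.duration, config.drift_amp)
        vel[labels == region_idx] = cw + rw + dw
        truth.component_waveforms[region] = {
            "cardiac": cw,
            "respiratory": rw,
            "drift": dw,
        }

    if config.blur_sigma > 0:
        vel = gaussian_filter(vel, sigma=(config.blur_sigma, config.blur_sigma, 0))
    if config.noise_sd > 0:
        vel = vel + rng.normal(0.0, config.noise_sd, size=vel.shape)

    truth.n_wrapped = int(np.count_nonzero(np.abs(vel) > config.venc))
    vel4d = vel[:, :, np.newaxis, :]
    series = VelocitySeries(data=vel4d, meta=config.meta(subject_id))
    return velocity_to_phase(series), truth


def generate_cohort(
    n_subjects: int = 7,
    base_config: SyntheticConfig | None = None,
    inter_subject_sd: float = 0.15,
    freq_sd: float = 0.1,
    periods: tuple[float, ...] = (6.0, 10.0, 16.0),
    seed: int | None = None,
) -> list[SubjectRun]:
    """Generate a guided-respiration cohort: one run per subject per period.

    Subject-level amplitudes are jittered log-normally (multiplicative
    ``exp(N(0, inter_subject_sd))`` — amplitudes stay positive) and the
    cardiac fundamental normally with SD ``freq_sd`` Hz, clipped to the
    1.0-1.6 Hz heart-rate band; each subject keeps its own amplitudes and
    heart rate across its three respiratory-period runs, mirroring a
    repeated-measures design.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    base = base_config if base_config is not None else SyntheticConfig()
    root = np.random.default_rng(base.seed if seed is None else seed)
    runs: list[SubjectRun] = []
    for s in range(n_subjects):
        jitter = root.normal(0.0, 1.0, size=3)
        c_amp = base.cardiac_amp * float(np.exp(inter_subject_sd * jitter[0]))
        r_amp = base.resp_amp * float(np.exp(inter_subject_sd * jitter[1]))
        c_freq = float(np.clip(base.cardiac_freq + freq_sd * jitter[2], 1.0, 1.6))
        for period in periods:
            cfg = replace(
                base,
                cardiac_amp=c_amp,
                resp_amp=r_amp,
                cardiac_freq=c_freq,
                resp_period=period,
                seed=int(root.integers(0, 2**31 - 1)),
            )
            sid = f"S{s + 1:02d}"
            phase, truth = generate_subject(cfg, subject_id=f"{sid}_T{period:g}s")
            runs.append(SubjectRun(subject_id=sid, config=cfg, phase=phase, truth=truth))
    return runs
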