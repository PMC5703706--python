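"""Synthetic BOLD phantoms with known hemodynamic delay structure.

The generator emulates resting-state acquisitions in which a systemic
low-frequency oscillation (sLFO) travels through the vasculature: every
voxel carries the same band-limited waveform, time-shifted by that voxel's
position in the vascular tree.  Positive delay means the voxel *leads* the
global mean signal (upstream / arterial side); negative delay marks the
venous, downstream side.  Because propagation is modelled as a pure time
shift, the delay field is exact ground truth for the lag-mapping pipeline.

The default phantom mirrors a patient acquisition at desk scale: a
16x16x8 grid of 3 mm voxels, TR 2.0 s, 180 volumes (6 min), sLFO band
0.008-0.07 Hz.  Ground-truth fields encode the phenomena the group
statistics must detect: a central "periventricular" region whose lag is
shifted downstream between sessions (tap-test analogue) and deep /
superficial regions whose lag varies linearly with age in opposite
directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .containers import BoldSeries, MotionTrace
from .errors import GenerationError, ParameterError

__all__ = [
    "SLFO",
    "generate_slfo",
    "PhantomSpec",
    "GroundTruth",
    "default_phantom_spec",
    "default_ground_truth",
    "synthesize_subject",
    "synthesize_cohort",
    "Cohort",
]

MAX_TRACKABLE_LAG = 7.0  # seconds; the lag grid spans +/- this value


# ---------------------------------------------------------------------------
# sLFO waveform
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class SLFO:
    """A band-limited oscillation as a closed-form harmonic sum.

    The waveform is a sum of sinusoids at Fourier frequencies of the
    requested duration, so it can be evaluated *exactly* at arbitrary
    times — voxel time series at off-grid delays carry no interpolation
    error and ground truth stays exact.  The stored affine rescaling makes
    the samples on the nominal grid zero-mean and unit-variance.
    """

    frequencies: np.ndarray  # Hz
    cos_amp: np.ndarray
    sin_amp: np.ndarray
    offset: float
    scale: float
    duration: float
    dt: float
    band: tuple[float, float]

    def __call__(self, t: np.ndarray | float) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros(t.shape, dtype=float)
        for f, a, b in zip(self.frequencies, self.cos_amp, self.sin_amp):
            w = 2.0 * np.pi * f
            out += a * np.cos(w * t) + b * np.sin(w * t)
        return (out - self.offset) / self.scale

    @property
    def times(self) -> np.ndarray:
        return np.arange(round(self.duration / self.dt)) * self.dt

    @property
    def values(self) -> np.ndarray:
        """Samples on the nominal grid (zero mean, unit variance)."""
        return self(self.times)


def generate_slfo(
    duration: float, dt: float, band: tuple[float, float] = (0.008, 0.07), seed: int = 0
) -> SLFO:
    """Generate a unit-variance band-limited sLFO reference waveform.

    The spectrum is flat across the band: cosine/sine amplitudes at every
    Fourier frequency ``k/duration`` inside ``band`` are drawn i.i.d.
    standard normal.  Sampled on the nominal ``dt`` grid, all periodogram
    power falls inside the band (the harmonics sit exactly on the DFT
    grid, so there is no spectral leakage).

    Raises
    ------
    ParameterError
        If the band lies outside ``(0, 1/(2 dt))`` or the grid has fewer
        than 64 samples.
    """
    low, high = band
    nyquist = 1.0 / (2.0 * dt)
    if not (0.0 < low < high):
        raise ParameterError(f"band must satisfy 0 < low < high, got {band}")
    if high >= nyquist:
        raise ParameterError(
            f"band upper edge {high} Hz is at or beyond the Nyquist frequency "
            f"{nyquist} Hz for dt={dt} s"
        )
    n = int(round(duration / dt))
    if n < 64:
        raise ParameterError(f"duration/dt = {n} samples; need at least 64")

    k = np.arange(1, n // 2 + 1)
    freqs = k / duration
    in_band = (freqs >= low) & (freqs <= high)
    if not np.any(in_band):
        raise ParameterError(
            f"no Fourier frequency of a {duration} s record falls inside {band}"
        )
    freqs = freqs[in_band]
    rng = np.random.default_rng(seed)
    cos_amp = rng.standard_normal(freqs.size)
    sin_amp = rng.standard_normal(freqs.size)

    raw = SLFO(freqs, cos_amp, sin_amp, 0.0, 1.0, duration, dt, (low, high))
    samples = raw(raw.times)
    offset = float(samples.mean())
    scale = float(samples.std())
    if scale == 0.0:
        raise GenerationError("degenerate sLFO draw with zero variance")
    return SLFO(freqs, cos_amp, sin_amp, offset, scale, duration, dt, (low, high))


# ---------------------------------------------------------------------------
# Phantom specification and ground truth
# ---------------------------------------------------------------------------
@dataclass
class PhantomSpec:
    """Full parameterization of one synthetic subject acquisition."""

    grid_shape: tuple[int, int, int] = (16, 16, 8)
    tr: float = 2.0
    n_volumes: int = 180
    slfo_band: tuple[float, float] = (0.008, 0.07)
    delay_field: np.ndarray | None = None  # seconds per voxel; None -> use GroundTruth
    noise_sd: float = 1.0  # relative to unit sLFO amplitude
    spike_times: tuple[int, ...] = ()
    spike_magnitude_mm: float = 13.0
    spike_magnitude_deg: float = 0.0
    seed: int = 0
    voxel_size_mm: float = 3.0
    signal_amplitude: float = 1.0
    slice_times: np.ndarray | None = None  # default: ascending order over [0, tr)

    def __post_init__(self) -> None:
        low, high = self.slfo_band
        nyq = 1.0 / (2.0 * self.tr)
        if not (0.0 < low < high < nyq):
            raise ParameterError(
                f"slfo_band {self.slfo_band} must lie within (0, Nyquist={nyq}) for tr={self.tr}"
            )
        if self.n_volumes * self.tr < 180.0:
            raise ParameterError(
                "scan too short for lag extraction: need n_volumes*tr >= 180 s, got "
                f"{self.n_volumes * self.tr} s"
            )
        if self.delay_field is not None:
            self.delay_field = np.asarray(self.delay_field, dtype=float)
            if self.delay_field.shape != tuple(self.grid_shape):
                raise ParameterError("delay_field shape must equal grid_shape")
            if np.any(np.abs(self.delay_field) > MAX_TRACKABLE_LAG):
                raise ParameterError(
                    f"delay_field exceeds the max trackable lag of {MAX_TRACKABLE_LAG} s"
                )
        if self.slice_times is None:
            nz = self.grid_shape[2]
            self.slice_times = np.arange(nz) * (self.tr / nz)

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        return aff

    @property
    def duration(self) -> float:
        return self.n_volumes * self.tr


@dataclass
class GroundTruth:
    """Ground-truth fields driving subject synthesis and verification.

    ``delay_field`` is the base per-voxel lag (s); ``shift_field`` the
    pre→post session difference (zero outside the target region);
    ``age_slope_field`` the per-voxel lag change per year of age.
    """

    delay_field: np.ndarray
    shift_field: np.ndarray
    age_slope_field: np.ndarray
    mask: np.ndarray
    regions: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.delay_field = np.asarray(self.delay_field, dtype=float)
        self.shift_field = np.asarray(self.shift_field, dtype=float)
        self.age_slope_field = np.asarray(self.age_slope_field, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        for name in ("shift_field", "age_slope_field"):
            if getattr(self, name).shape != self.delay_field.shape:
                raise ParameterError(f"{name} shape must match delay_field")
        if self.mask.shape != self.delay_field.shape:
            raise ParameterError("mask shape must match delay_field")
        target = self.regions.get("target")
        if target is not None and np.any(self.shift_field[~np.asarray(target, bool)] != 0):
            raise ParameterError("shift_field must be zero outside the target region")
        total = self.delay_field + self.shift_field
        if np.any(np.abs(total[self.mask]) > MAX_TRACKABLE_LAG):
            raise ParameterError(
                "delay_field + shift_field leaves the trackable range "
                f"+/-{MAX_TRACKABLE_LAG} s inside the mask"
            )

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.delay_field.shape


def _ellipsoid(shape: tuple[int, int, int], center: np.ndarray, radii: np.ndarray) -> np.ndarray:
    idx = np.indices(shape, dtype=float)
    d2 = sum(((idx[i] - center[i]) / radii[i]) ** 2 for i in range(3))
    return d2 <= 1.0


def default_phantom_spec(**overrides) -> PhantomSpec:
    """The desk-scale standard acquisition (16x16x8 grid, TR 2 s, 180 vols)."""
    return PhantomSpec(**overrides)


def default_ground_truth(
    grid_shape: tuple[int, int, int] = (16, 16, 8),
    delay_span: float = 4.0,
    tap_shift: float = -2.5,
    age_slope: float = 0.05,
    on_grid: bool = False,
) -> GroundTruth:
    """Build the default ground truth on an ellipsoidal brain mask.

    The base delay field is an antisymmetric left-right gradient spanning
    roughly ``+/-delay_span`` seconds (its in-mask distribution is exactly
    symmetric about zero, so the global mean signal has zero net phase).
    Three regions are defined:

    - ``target`` (central, "periventricular"): receives ``tap_shift``
      seconds in the post session (negative = downstream, i.e. shortened
      drainage time after the tap test);
    - ``deep`` (same central region): age slope ``+age_slope`` s/year
      (drainage time extends with age);
    - ``superficial`` (two para-midline blobs): age slope ``-age_slope``
      s/year (drainage shortens with age).

    ``on_grid=True`` snaps base delays to the 0.5 s lag grid so that exact
    recovery through the full pipeline is well-defined.
    """
    shape = tuple(grid_shape)
    center = (np.array(shape) - 1) / 2.0
    radii = np.array(shape) / 2.0 - 0.4
    mask = _ellipsoid(shape, center, radii)

    x = np.indices(shape, dtype=float)[0]
    xn = (x - center[0]) / max(center[0], 1.0)  # in [-1, 1]
    delay = delay_span * xn
    if on_grid:
        delay = np.round(delay / 0.5) * 0.5
    delay[~mask] = 0.0

    scale = np.array(shape) / np.array([16.0, 16.0, 8.0])
    deep = _ellipsoid(shape, center, np.array([3.5, 3.5, 2.2]) * scale)
    deep &= mask
    # tap target: the core of the deep region, kept to a small fraction of
    # the mask so the session shift barely moves the global reference
    target = _ellipsoid(shape, center, np.array([2.5, 2.5, 1.5]) * scale)
    target &= mask
    off = np.array([0.0, shape[1] * 0.28, 0.0])
    sup_r = np.array([3.0, 3.0, 2.0]) * scale
    sup = _ellipsoid(shape, center + off, sup_r) | _ellipsoid(shape, center - off, sup_r)
    sup &= mask & ~deep

    shift = np.zeros(shape)
    shift[target] = tap_shift

    slope = np.zeros(shape)
    slope[deep] = age_slope
    slope[sup] = -age_slope

    return GroundTruth(
        delay_field=delay,
        shift_field=shift,
        age_slope_field=slope,
        mask=mask,
        regions={"target": target, "deep": deep, "superficial": sup},
    )


# ---------------------------------------------------------------------------
# Subject synthesis
# ---------------------------------------------------------------------------
def synthesize_subject(
    spec: PhantomSpec,
    truth: GroundTruth,
    session: str = "single",
) -> tuple[BoldSeries, MotionTrace]:
    """Synthesize one subject's BOLD series and motion trace.

    Voxel ``v`` is sampled as ``amplitude * slfo(t_acq + delay_v) + noise``
    where ``t_acq`` includes the slice acquisition offset, and
    ``delay_v = base (+ shift_v if session == "post")``.  Positive delay
    makes the voxel lead the global signal (upstream / arterial).  Motion
    is near zero except for translation/rotation spikes at
    ``spec.spike_times``, which perturb only the motion trace.
    """
    if session not in ("pre", "post", "single"):
        raise ParameterError(f"session must be pre|post|single, got {session!r}")
    if tuple(spec.grid_shape) != tuple(truth.grid_shape):
        raise ParameterError(
            f"spec grid {spec.grid_shape} and truth grid {truth.grid_shape} differ"
        )
    base = spec.delay_field if spec.delay_field is not None else truth.delay_field
    delay = base + (truth.shift_field if session == "post" else 0.0)
    if np.any(np.abs(delay[truth.mask]) > MAX_TRACKABLE_LAG):
        raise GenerationError(
            f"requested delays exceed the trackable +/-{MAX_TRACKABLE_LAG} s support"
        )

    rng = np.random.default_rng(spec.seed)
    # pad the waveform support so t + delay never leaves it
    slfo = generate_slfo(
        spec.duration + 2 * MAX_TRACKABLE_LAG + 2 * spec.tr,
        dt=min(0.1, spec.tr / 4),
        band=spec.slfo_band,
        seed=int(rng.integers(2**31 - 1)),
    )

    shape = tuple(spec.grid_shape)
    nz, nt = shape[2], spec.n_volumes
    data = np.zeros((*shape, nt))
    vol_times = np.arange(nt) * spec.tr + MAX_TRACKABLE_LAG + spec.tr  # padded origin
    for z in range(nz):
        t_acq = vol_times + spec.slice_times[z]  # (nt,)
        d = delay[:, :, z][..., None]  # (nx, ny, 1)
        data[:, :, z, :] = spec.signal_amplitude * slfo(t_acq[None, None, :] + d)
    if spec.noise_sd > 0:
        data += rng.normal(0.0, spec.noise_sd, size=data.shape)
    data[~truth.mask, :] = rng.normal(0.0, max(spec.noise_sd, 1e-3), size=((~truth.mask).sum(), nt))

    series = BoldSeries(
        data=data,
        sampling_interval=spec.tr,
        affine=spec.affine,
        mask=truth.mask,
        slice_times=spec.slice_times,
    )

    trans = rng.normal(0.0, 0.02, size=(nt, 3))
    rot = rng.normal(0.0, 0.02, size=(nt, 3))
    for t_idx in spec.spike_times:
        if not (0 <= t_idx < nt):
            raise ParameterError(f"spike time {t_idx} outside [0, {nt})")
        trans[t_idx, 0] += spec.spike_magnitude_mm
        rot[t_idx, 0] += spec.spike_magnitude_deg
    motion = MotionTrace(trans, rot)
    return series, motion


# ---------------------------------------------------------------------------
# Cohort synthesis
# ---------------------------------------------------------------------------
@dataclass
class Cohort:
    """A synthetic cohort: per-subject acquisitions plus the design table."""

    subjects: list[dict]  # keys: subject_id, session -> (BoldSeries, MotionTrace)
    design: pd.DataFrame  # subject_id, group, session, age, sex
    truth: GroundTruth
    true_delay_fields: dict[str, np.ndarray]  # subject_id -> realized base field


def _smooth_jitter(shape, sd, rng) -> np.ndarray:
    """Spatially smooth zero-mean jitter field with pointwise SD ``sd``."""
    if sd == 0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    sm = ndimage.gaussian_filter(white, sigma=1.5)
    sm /= sm.std()
    return sd * sm


def synthesize_cohort(
    n_subjects: int = 40,
    age_range: tuple[float, float] = (20.0, 80.0),
    truth: GroundTruth | None = None,
    spec: PhantomSpec | None = None,
    jitter_sd: float = 0.5,
    session_jitter_sd: float = 0.4,
    paired: bool = False,
    group: str | None = None,
    seed: int = 0,
) -> Cohort:
    """Synthesize a cohort of subjects with known delay structure.

    Subject ``i`` receives delay field ``base + (age_i - mid_age) *
    age_slope_field + jitter_i`` (age is centred at the range midpoint so
    the slope does not push delays out of the trackable range), a random
    sex label, and — when ``paired`` — both a pre and a post session, the
    post session with ``truth.shift_field`` added.  ``jitter_sd`` is the
    between-subject variability of the delay field; ``session_jitter_sd``
    is an independent per-session (scan-rescan) variability, emulating the
    test-retest noise of lag estimates.  Deterministic under ``seed``.
    """
    if n_subjects < 1:
        raise ParameterError("n_subjects must be >= 1")
    truth = truth if truth is not None else default_ground_truth()
    spec = spec if spec is not None else default_phantom_spec(grid_shape=truth.grid_shape)
    rng = np.random.default_rng(seed)
    mid_age = 0.5 * (age_range[0] + age_range[1])

    sessions = ("pre", "post") if paired else ("single",)
    subjects: list[dict] = []
    rows = []
    fields: dict[str, np.ndarray] = {}
    for i in range(n_subjects):
        sid = f"sub{i:03d}"
        age = float(rng.uniform(*age_range))
        sex = "F" if rng.random() < 0.5 else "M"
        base = (
            truth.delay_field
            + (age - mid_age) * truth.age_slope_field
            + _smooth_jitter(truth.grid_shape, jitter_sd, rng)
        )
        base = np.clip(base, -MAX_TRACKABLE_LAG + 0.5, MAX_TRACKABLE_LAG - 0.5)
        base[~truth.mask] = 0.0
        fields[sid] = base
        entry: dict = {"subject_id": sid}
        for sess in sessions:
            sess_field = base + _smooth_jitter(truth.grid_shape, session_jitter_sd, rng)
            sess_field = np.clip(
                sess_field, -MAX_TRACKABLE_LAG + 0.5, MAX_TRACKABLE_LAG - 0.5
            )
            sess_field[~truth.mask] = 0.0
            sub_spec = PhantomSpec(
                grid_shape=spec.grid_shape,
                tr=spec.tr,
                n_volumes=spec.n_volumes,
                slfo_band=spec.slfo_band,
                delay_field=sess_field,
                noise_sd=spec.noise_sd,
                spike_times=spec.spike_times,
                spike_magnitude_mm=spec.spike_magnitude_mm,
                spike_magnitude_deg=spec.spike_magnitude_deg,
                seed=int(rng.integers(2**31 - 1)),
                voxel_size_mm=spec.voxel_size_mm,
                signal_amplitude=spec.signal_amplitude,
            )
            entry[sess] = synthesize_subject(sub_spec, truth, session=sess)
            rows.append(
                {
                    "subject_id": sid,
                    "group": group or ("patient" if paired else "control"),
                    "session": sess,
                    "age": age,
                    "sex": sex,
                }
            )
        subjects.append(entry)
    design = pd.DataFrame(rows)
    return Cohort(subjects=subjects, design=design, truth=truth, true_delay_fields=fields)
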