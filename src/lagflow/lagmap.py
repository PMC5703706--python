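"""BOLD lag mapping against the global mean signal.

For every in-mask voxel the lag is the discrete time shift τ ∈
{−7, −6.5, …, +7} s maximizing the Pearson correlation between the voxel
time course and the reference shifted by τ, computed over the overlapping
samples only (no zero padding).  Positive τ means the voxel *leads* the
reference — the upstream, arterial side of the circulation; negative τ
marks downstream, venous territory ("relative drainage time").

Failure rule: voxels whose correlogram peaks at the ±7 s boundary, or
whose peak correlation is negative, are ambiguous; they are uniformly
assigned the sentinel lag −7 and marked invalid so that group statistics
can exclude them.

Quality control mirrors the exclusion rule used on patients: a lag
histogram collapsing into a very narrow peak at zero (here: more than a
configurable fraction of voxels within ±0.5 s) indicates that tracking
failed, typically from excessive motion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .containers import BoldSeries
from .errors import LagflowError, ParameterError

__all__ = [
    "LagMap",
    "LagQC",
    "global_reference",
    "lag_correlate",
    "compute_lagmap",
    "lag_histogram_qc",
    "relative_phase",
]


@dataclass
class LagMap:
    """Per-voxel lag (s), peak correlation, and validity on a brain mask."""

    lag: np.ndarray  # 3D, seconds, multiples of `step` in [-max_lag, max_lag]
    peak_r: np.ndarray  # 3D, Pearson r at the selected shift
    valid: np.ndarray  # 3D bool; False where the failure rule fired
    mask: np.ndarray  # 3D bool
    affine: np.ndarray
    max_lag: float = 7.0
    step: float = 0.5

    @property
    def lag_grid(self) -> np.ndarray:
        k = int(round(self.max_lag / self.step))
        return np.arange(-k, k + 1) * self.step

    def to_nifti(self, prefix: str | Path) -> dict[str, Path]:
        """Write lag / peak_r / valid volumes as ``<prefix>_{lag,peakr,valid}.nii``."""
        prefix = Path(prefix)
        paths = {}
        for name, arr, dtype in (
            ("lag", self.lag, np.float32),
            ("peakr", self.peak_r, np.float32),
            ("valid", self.valid.astype(np.uint8), np.uint8),
        ):
            p = prefix.parent / f"{prefix.name}_{name}.nii"
            nib.Nifti1Image(np.asarray(arr, dtype=dtype), self.affine).to_filename(str(p))
            paths[name] = p
        return paths


@dataclass
class LagQC:
    """Lag-histogram quality control result."""

    histogram: np.ndarray  # counts per lag bin
    bin_centers: np.ndarray  # seconds
    zero_peak_fraction: float
    threshold: float
    failed: bool

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "histogram": [int(c) for c in self.histogram],
                    "bin_centers": [float(b) for b in self.bin_centers],
                    "zero_peak_fraction": self.zero_peak_fraction,
                    "threshold": self.threshold,
                    "failed": self.failed,
                },
                indent=2,
            )
        )


# ---------------------------------------------------------------------------
def global_reference(series: BoldSeries) -> np.ndarray:
    """Global mean signal: unweighted mean over in-mask voxels, demeaned."""
    if not series.mask.any():
        raise ParameterError("mask is empty; cannot form a global reference")
    ref = series.data[series.mask].mean(axis=0)
    return ref - ref.mean()


def _pearson_overlap(data: np.ndarray, ref: np.ndarray, k: int) -> np.ndarray:
    """Pearson r between each row of ``data`` and ``ref`` shifted by ``k`` samples.

    Positive ``k`` pairs ``data[:, i]`` with ``ref[i + k]`` (voxel leads by
    ``k`` samples); only the overlapping samples enter the correlation.
    """
    n = data.shape[1]
    if k >= 0:
        x = data[:, : n - k] if k else data
        y = ref[k:]
    else:
        x = data[:, -k:]
        y = ref[: n + k]
    xm = x - x.mean(axis=1, keepdims=True)
    ym = y - y.mean()
    denom = np.sqrt((xm**2).sum(axis=1) * (ym**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xm @ ym) / denom
    return np.where(denom > 0, r, 0.0)


def _select_peak(corr: np.ndarray, taus: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Argmax over shifts with the documented tie rule.

    Ties at equal correlation resolve to the shift smallest in absolute
    value; a residual ±τ tie resolves toward the negative (venous) side.
    Returns (selected tau per voxel, peak r per voxel).
    """
    order = sorted(range(len(taus)), key=lambda i: (abs(taus[i]), taus[i]))
    order = np.asarray(order)
    corr_ord = corr[order]  # (n_shift, n_vox)
    best = np.argmax(corr_ord, axis=0)  # first occurrence = preferred tie winner
    tau_sel = taus[order][best]
    r_sel = corr_ord[best, np.arange(corr.shape[1])]
    return tau_sel, r_sel


def lag_correlate(
    data: np.ndarray,
    reference: np.ndarray,
    dt: float,
    max_lag: float = 7.0,
    step: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cross-correlation lag estimation on a (n_voxels, n_times) array.

    Builds the voxel × shift correlation matrix (the time × voxel × shift
    construction collapsed over time) and picks the per-voxel maximum.
    Returns ``(lag, peak_r, valid)`` per voxel; failed voxels (boundary
    peak or negative peak correlation) carry ``lag = -max_lag``.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    reference = np.asarray(reference, dtype=float)
    if data.shape[1] != reference.shape[0]:
        raise ParameterError("data and reference must share the time grid")
    if np.ptp(reference) == 0:
        raise ParameterError("reference signal is constant; lags are undefined")
    if step <= 0 or max_lag <= 0:
        raise ParameterError("max_lag and step must be positive")
    ratio = step / dt
    if abs(ratio - round(ratio)) > 1e-9:
        raise ParameterError(
            f"lag step {step} s must be an integer multiple of the sampling "
            f"interval {dt} s (resample the series first)"
        )
    spr = int(round(ratio))
    k_max = int(round(max_lag / step))
    n = data.shape[1]
    if n - 2 * k_max * spr < 8:
        raise LagflowError(
            "series too short: fewer than 8 overlapping samples remain at the "
            f"extreme ±{max_lag} s shifts"
        )
    taus = np.arange(-k_max, k_max + 1) * step
    corr = np.empty((taus.size, data.shape[0]))
    for i, m in enumerate(range(-k_max, k_max + 1)):
        corr[i] = _pearson_overlap(data, reference, m * spr)

    tau_sel, r_sel = _select_peak(corr, taus)
    invalid = (np.abs(tau_sel) >= max_lag - 1e-12) | (r_sel < 0)
    lag = np.where(invalid, -max_lag, tau_sel)
    return lag, r_sel, ~invalid


def compute_lagmap(
    series: BoldSeries,
    reference: np.ndarray | None = None,
    max_lag: float = 7.0,
    step: float = 0.5,
) -> LagMap:
    """Compute the 3D lag map of a preprocessed series vs. a reference.

    ``reference`` defaults to the global mean signal of the series itself.
    The series must be on a grid compatible with ``step`` (i.e. after the
    0.5 s lag-tracking resample).
    """
    if reference is None:
        reference = global_reference(series)
    data = series.data[series.mask]
    lag_v, r_v, valid_v = lag_correlate(
        data, reference, dt=series.sampling_interval, max_lag=max_lag, step=step
    )
    shape = series.mask.shape
    lag = np.zeros(shape)
    peak_r = np.zeros(shape)
    valid = np.zeros(shape, dtype=bool)
    lag[series.mask] = lag_v
    peak_r[series.mask] = r_v
    valid[series.mask] = valid_v
    return LagMap(
        lag=lag,
        peak_r=peak_r,
        valid=valid,
        mask=series.mask.copy(),
        affine=series.affine.copy(),
        max_lag=max_lag,
        step=step,
    )


# ---------------------------------------------------------------------------
def lag_histogram_qc(lagmap: LagMap, zero_frac_threshold: float = 0.6) -> LagQC:
    """Flag maps whose lag histogram collapses into a narrow peak at zero.

    ``zero_peak_fraction`` is the fraction of in-mask voxels with
    |lag| ≤ 0.5 s (the central three bins of the 29-bin histogram); the
    map fails QC when it exceeds the threshold.
    """
    grid = lagmap.lag_grid
    lags = lagmap.lag[lagmap.mask]
    idx = np.searchsorted(grid - lagmap.step / 2, lags, side="right") - 1
    idx = np.clip(idx, 0, grid.size - 1)
    counts = np.bincount(idx, minlength=grid.size)
    zero_frac = float(np.mean(np.abs(lags) <= lagmap.step + 1e-9))
    return LagQC(
        histogram=counts,
        bin_centers=grid,
        zero_peak_fraction=zero_frac,
        threshold=zero_frac_threshold,
        failed=zero_frac > zero_frac_threshold,
    )


def relative_phase(lagmap: LagMap, roi: np.ndarray) -> float:
    """Mean lag over valid ROI voxels (the region's phase advance, s).

    Negative values place the region on the venous / downstream side of
    the vascular tree relative to the global signal phase.
    """
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != lagmap.mask.shape:
        raise ParameterError("roi shape must match the lag map")
    if np.any(roi & ~lagmap.mask):
        raise ParameterError("roi extends outside the brain mask")
    sel = roi & lagmap.valid
    if not sel.any():
        raise LagflowError("no valid voxels in the ROI; phase is undefined")
    return float(lagmap.lag[sel].mean())
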