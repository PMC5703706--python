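"""Core data containers: 4D BOLD series and rigid-body motion traces.

A :class:`BoldSeries` couples the voxel data with the sampling metadata the
temporal pipeline needs (sampling interval, per-slice acquisition offsets,
voxel-to-world affine, brain mask) plus a record of which preprocessing
stages have been applied.  A :class:`MotionTrace` carries the six
rigid-body realignment parameters per volume (3 translations in mm,
3 rotations in degrees) consumed by scrubbing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import ParameterError

__all__ = ["BoldSeries", "MotionTrace"]


@dataclass
class BoldSeries:
    """A 4D BOLD time series with sampling metadata.

    Parameters
    ----------
    data:
        Array of shape ``(x, y, z, t)``.
    sampling_interval:
        Seconds between successive volumes on the *current* grid (equals
        the acquisition TR until temporal resampling).
    affine:
        4x4 voxel-to-world transform.
    mask:
        Boolean brain mask with the spatial shape of ``data``.
    slice_times:
        Per-slice acquisition offsets in seconds, each in ``[0, TR)``;
        ``None`` once slice-timing correction has been applied (or when
        the slice order is unknown).
    history:
        Names of the preprocessing stages applied so far, in order.
    """

    data: np.ndarray
    sampling_interval: float
    affine: np.ndarray
    mask: np.ndarray
    slice_times: np.ndarray | None = None
    history: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ParameterError(f"data must be 4D (x,y,z,t), got shape {self.data.shape}")
        if self.data.shape[3] < 2:
            raise ParameterError("a BOLD series needs at least 2 volumes")
        if self.sampling_interval <= 0:
            raise ParameterError("sampling_interval must be positive")
        self.affine = np.asarray(self.affine, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.data.shape[:3]:
            raise ParameterError(
                f"mask shape {self.mask.shape} does not match spatial shape {self.data.shape[:3]}"
            )
        if self.slice_times is not None:
            self.slice_times = np.asarray(self.slice_times, dtype=float)
            if self.slice_times.shape != (self.data.shape[2],):
                raise ParameterError(
                    "slice_times must have one entry per z-slice "
                    f"({self.data.shape[2]}), got {self.slice_times.shape}"
                )
            if np.any(self.slice_times < 0) or np.any(self.slice_times >= self.sampling_interval):
                raise ParameterError("slice_times must lie in [0, TR)")

    # -- convenience -------------------------------------------------------
    @property
    def tr(self) -> float:
        return self.sampling_interval

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def duration(self) -> float:
        """Time spanned by the series (first to last volume), seconds."""
        return (self.n_volumes - 1) * self.sampling_interval

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_volumes) * self.sampling_interval

    @property
    def voxel_sizes(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def in_mask(self) -> np.ndarray:
        """Return the masked voxel time courses as a (n_voxels, t) view-copy."""
        return self.data[self.mask]

    def with_data(self, data: np.ndarray, *, stage: str | None = None, **changes) -> "BoldSeries":
        """Copy, replacing the data and optionally appending a history stage."""
        if stage is not None:
            changes["history"] = self.history + (stage,)
        return replace(self, data=data, **changes)

    # -- I/O ---------------------------------------------------------------
    def to_nifti(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        img.header.set_zooms((*self.voxel_sizes, self.sampling_interval))
        img.to_filename(str(path))

    @classmethod
    def from_nifti(
        cls,
        path: str | Path,
        mask: np.ndarray | str | Path | None = None,
        slice_times: np.ndarray | None = None,
        sampling_interval: float | None = None,
    ) -> "BoldSeries":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj, dtype=float)
        if sampling_interval is None:
            zooms = img.header.get_zooms()
            if len(zooms) < 4 or zooms[3] <= 0:
                raise ParameterError(
                    f"{path}: TR not present in NIfTI header; pass sampling_interval"
                )
            sampling_interval = float(zooms[3])
        if mask is None:
            mask_arr = np.ones(data.shape[:3], dtype=bool)
        elif isinstance(mask, (str, Path)):
            mask_arr = np.asanyarray(nib.load(str(mask)).dataobj) > 0
        else:
            mask_arr = np.asarray(mask, dtype=bool)
        return cls(
            data=data,
            sampling_interval=sampling_interval,
            affine=img.affine,
            mask=mask_arr,
            slice_times=slice_times,
        )


@dataclass
class MotionTrace:
    """Per-volume rigid-body motion parameters.

    ``translations`` are in mm, ``rotations`` in degrees, one row per
    volume.  Files are whitespace-delimited with six columns
    (tx ty tz rx ry rz); a radians dialect is converted on read.
    """

    translations: np.ndarray
    rotations: np.ndarray

    def __post_init__(self) -> None:
        self.translations = np.atleast_2d(np.asarray(self.translations, dtype=float))
        self.rotations = np.atleast_2d(np.asarray(self.rotations, dtype=float))
        if self.translations.shape[1] != 3 or self.rotations.shape[1] != 3:
            raise ParameterError("translations and rotations must each have 3 columns")
        if self.translations.shape[0] != self.rotations.shape[0]:
            raise ParameterError("translations and rotations must have equal row counts")

    @property
    def n_volumes(self) -> int:
        return self.translations.shape[0]

    @property
    def params(self) -> np.ndarray:
        """(n, 6) array: translations then rotations."""
        return np.hstack([self.translations, self.rotations])

    def drop_first(self, n: int) -> "MotionTrace":
        """Trim the leading ``n`` rows (pair with an initial-volume discard)."""
        if n >= self.n_volumes:
            raise ParameterError(f"cannot drop {n} of {self.n_volumes} motion rows")
        return MotionTrace(self.translations[n:], self.rotations[n:])

    def to_file(self, path: str | Path) -> None:
        np.savetxt(str(path), self.params, fmt="%.6f")

    @classmethod
    def from_file(cls, path: str | Path, rotations_in_radians: bool = False) -> "MotionTrace":
        arr = np.loadtxt(str(path), ndmin=2)
        if arr.shape[1] != 6:
            raise ParameterError(f"{path}: expected 6 columns, found {arr.shape[1]}")
        rot = arr[:, 3:]
        if rotations_in_radians:
            rot = np.degrees(rot)
        return cls(arr[:, :3], rot)

    @classmethod
    def zeros(cls, n_volumes: int) -> "MotionTrace":
        return cls(np.zeros((n_volumes, 3)), np.zeros((n_volumes, 3)))
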