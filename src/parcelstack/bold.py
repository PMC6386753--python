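"""BOLD time-series container and temporal preprocessing.

The container holds one subject's preprocessed, spatially normalized 4D
volume together with its repetition time (TR), an in-brain mask and the
voxel-to-world affine. All temporal operations are pure: they return a new
:class:`BoldSeries` and never mutate their input.

The band-pass filter is an ideal (boxcar) frequency-domain filter: a DFT
frequency bin k sits at k / (n * TR) Hz and is kept iff
``low <= f <= high`` (inclusive). This gives an exact pass-band contract
at the cost of the usual ringing, which is irrelevant for the band-power
summaries computed downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage, signal

from .exceptions import MotionFormatError

#: FWHM of a Gaussian = sigma * 2*sqrt(2*ln 2)
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class BandSpec:
    """Frequency band of interest, in Hz. Defaults to the 0.01-0.08 Hz
    low-frequency fluctuation band conventional for resting-state BOLD."""

    low_hz: float = 0.01
    high_hz: float = 0.08

    def validate(self, tr_seconds: float) -> None:
        nyquist = 1.0 / (2.0 * tr_seconds)
        if not (0.0 <= self.low_hz < self.high_hz):
            raise ValueError(f"invalid band [{self.low_hz}, {self.high_hz}]")
        if self.high_hz > nyquist:
            raise ValueError(
                f"band upper edge {self.high_hz} Hz exceeds Nyquist {nyquist} Hz"
            )


@dataclass
class BoldSeries:
    """One subject's 4D BOLD volume (x, y, z, t) with acquisition geometry.

    Parameters
    ----------
    data : (X, Y, Z, T) float array
    tr_seconds : repetition time in seconds, > 0
    mask : (X, Y, Z) boolean in-brain mask, non-empty
    affine : (4, 4) voxel-to-world (mm) affine
    n_discard : leading volumes already removed (bookkeeping only)
    """

    data: np.ndarray
    tr_seconds: float
    mask: np.ndarray
    affine: np.ndarray
    n_discard: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("BOLD data must be 4D (x, y, z, t)")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape must match spatial dimensions")
        if not self.mask.any():
            raise ValueError("mask is empty")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def voxel_sizes_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def frequencies_hz(self) -> np.ndarray:
        """Single-sided DFT bin frequencies k/(n*TR) for k = 0..n//2."""
        return np.fft.rfftfreq(self.n_timepoints, d=self.tr_seconds)


def discard_initial_volumes(series: BoldSeries, n: int) -> BoldSeries:
    """Drop the first `n` volumes (dummy scans before steady magnetization)."""
    if n < 0:
        raise ValueError("n must be nonnegative")
    if n >= series.n_timepoints:
        raise ValueError(
            f"cannot discard {n} of {series.n_timepoints} volumes"
        )
    return replace(
        series,
        data=series.data[..., n:].copy(),
        n_discard=series.n_discard + n,
    )


def detrend(series: BoldSeries) -> BoldSeries:
    """Remove, per voxel, the least-squares linear trend (and mean)."""
    if series.n_timepoints < 3:
        raise ValueError("need at least 3 timepoints to detrend")
    out = signal.detrend(series.data, axis=-1, type="linear")
    return replace(series, data=out)


def bandpass(series: BoldSeries, band: BandSpec | None = None) -> BoldSeries:
    """Ideal frequency-domain band-pass filter (see module docstring)."""
    band = band or BandSpec()
    band.validate(series.tr_seconds)
    n = series.n_timepoints
    freqs = np.fft.rfftfreq(n, d=series.tr_seconds)
    keep = (freqs >= band.low_hz) & (freqs <= band.high_hz)
    spectrum = np.fft.rfft(series.data, axis=-1)
    spectrum[..., ~keep] = 0.0
    out = np.fft.irfft(spectrum, n=n, axis=-1)
    return replace(series, data=out)


def smooth_gaussian(series: BoldSeries, fwhm_mm: float = 4.0) -> BoldSeries:
    """Spatially smooth each volume with a Gaussian kernel of the given FWHM.

    The kernel width is expressed in mm and converted per axis using the
    voxel sizes from the affine; the time axis is untouched. ``fwhm_mm=0``
    is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be nonnegative")
    if fwhm_mm == 0:
        return replace(series, data=series.data.copy())
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / series.voxel_sizes_mm
    out = ndimage.gaussian_filter(series.data, sigma=(*sigma_vox, 0.0))
    return replace(series, data=out)


def smooth_map_gaussian(
    values: np.ndarray, affine: np.ndarray, fwhm_mm: float = 4.0
) -> np.ndarray:
    """Gaussian-smooth a single 3D map with a kernel given in mm."""
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be nonnegative")
    if fwhm_mm == 0:
        return np.array(values, dtype=float)
    voxel_sizes = np.sqrt((np.asarray(affine)[:3, :3] ** 2).sum(axis=0))
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / voxel_sizes
    return ndimage.gaussian_filter(np.asarray(values, dtype=float), sigma_vox)


def check_motion_exclusion(
    motion_params: np.ndarray,
    rotation_unit: str = "degrees",
    max_translation_mm: float = 2.0,
    max_rotation_deg: float = 2.0,
) -> tuple[bool, str]:
    """Apply the head-motion exclusion rule to a t x 6 realignment table.

    Columns are 3 translations (mm) then 3 rotations (in `rotation_unit`,
    ``"degrees"`` or ``"radians"``). A subject fails if any translation
    magnitude exceeds ``max_translation_mm`` or any rotation magnitude
    exceeds ``max_rotation_deg``, relative to the reference volume.

    Returns ``(passed, reason)`` where `reason` is "" on a pass.
    """
    params = np.atleast_2d(np.asarray(motion_params, dtype=float))
    if params.ndim != 2 or params.shape[1] != 6:
        raise MotionFormatError(
            f"expected a t x 6 motion table, got shape {params.shape}"
        )
    if rotation_unit not in ("degrees", "radians"):
        raise ValueError(f"unknown rotation unit {rotation_unit!r}")
    trans = np.abs(params[:, :3])
    rot = np.abs(params[:, 3:])
    if rotation_unit == "radians":
        rot = np.degrees(rot)
    reasons = []
    if trans.max() > max_translation_mm:
        reasons.append(
            f"translation {trans.max():.2f} mm > {max_translation_mm} mm"
        )
    if rot.max() > max_rotation_deg:
        reasons.append(f"rotation {rot.max():.2f} deg > {max_rotation_deg} deg")
    return (not reasons, "; ".join(reasons))
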