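"""Voxelwise regional resting-state features and ROI aggregation.

Three regional features are computed per voxel:

ALFF
    amplitude of low-frequency fluctuations: the sum of the single-sided
    amplitude spectrum over the DFT bins inside the band of interest
    (default 0.01-0.08 Hz). Computed on detrended, *unfiltered* series —
    filtering to the band and then measuring in-band power would be
    circular.
fALFF
    fractional ALFF: the in-band amplitude sum divided by the amplitude
    sum over the entire detectable range (0, Nyquist]; lies in [0, 1],
    with 0/0 defined as 0.
ReHo
    regional homogeneity: Kendall's coefficient of concordance W among a
    voxel's own and its neighbours' time series (default 27-voxel
    neighbourhood, clipped at the mask edge), computed on detrended,
    band-passed, *unsmoothed* series to avoid overestimating spatial
    homogeneity.

A config switch ``power_mode`` selects between summing the amplitude
spectrum (default, the common toolbox convention) or the periodogram
power for ALFF/fALFF.

Voxel maps are z-scored across the in-brain mask (population standard
deviation) before ROI averaging so regional features are comparable
across subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .atlas import RoiDesign
from .bold import BandSpec, BoldSeries

REHO_NEIGHBORHOODS = (7, 19, 27)


@dataclass
class VoxelMap:
    """A 3D feature map defined over an in-brain mask."""

    values: np.ndarray
    mask: np.ndarray
    feature: str
    standardized: bool = False


def _amplitude_spectrum(data: np.ndarray, power_mode: str) -> np.ndarray:
    """Single-sided amplitude (or power) spectrum along the last axis.

    Bin k (0 < k < n/2) amplitude is 2|X_k|/n; the DC and (even-n)
    Nyquist bins are |X_k|/n.
    """
    n = data.shape[-1]
    spec = np.abs(np.fft.rfft(data, axis=-1)) / n
    spec[..., 1:] *= 2.0
    if n % 2 == 0:
        spec[..., -1] /= 2.0
    if power_mode == "power":
        spec = spec**2
    elif power_mode != "amplitude":
        raise ValueError(f"unknown power_mode {power_mode!r}")
    return spec


def _band_bins(series: BoldSeries, band: BandSpec) -> np.ndarray:
    band.validate(series.tr_seconds)
    freqs = series.frequencies_hz()
    in_band = (freqs >= band.low_hz) & (freqs <= band.high_hz)
    if not in_band.any():
        raise ValueError(
            f"no frequency bin falls inside [{band.low_hz}, {band.high_hz}] Hz "
            f"for n={series.n_timepoints}, TR={series.tr_seconds}s"
        )
    return in_band


def compute_alff(
    series: BoldSeries,
    band: BandSpec | None = None,
    power_mode: str = "amplitude",
) -> VoxelMap:
    """ALFF: total in-band amplitude of the voxel spectrum (see module doc)."""
    band = band or BandSpec()
    in_band = _band_bins(series, band)
    spec = _amplitude_spectrum(series.data, power_mode)
    values = spec[..., in_band].sum(axis=-1)
    values[~series.mask] = 0.0
    return VoxelMap(values, series.mask, "ALFF")


def compute_falff(
    series: BoldSeries,
    band: BandSpec | None = None,
    power_mode: str = "amplitude",
) -> VoxelMap:
    """fALFF: in-band amplitude over total amplitude in (0, Nyquist]."""
    band = band or BandSpec()
    in_band = _band_bins(series, band)
    spec = _amplitude_spectrum(series.data, power_mode)
    numer = spec[..., in_band].sum(axis=-1)
    denom = spec[..., 1:].sum(axis=-1)  # exclude DC: detectable range (0, Nyq]
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(denom > 0, numer / np.maximum(denom, 1e-300), 0.0)
    values[~series.mask] = 0.0
    return VoxelMap(values, series.mask, "fALFF")


_OFFSETS = {
    7: [
        (0, 0, 0), (1, 0, 0), (-1, 0, 0),
        (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1),
    ],
    19: [
        (dx, dy, dz)
        for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
        if abs(dx) + abs(dy) + abs(dz) <= 2
    ],
    27: [
        (dx, dy, dz)
        for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
    ],
}


def _shift3d(volume: np.ndarray, offset: tuple[int, int, int]) -> np.ndarray:
    """Shift a (possibly 4D) volume spatially, zero-filling the border."""
    out = np.zeros_like(volume)
    src = [slice(None)] * volume.ndim
    dst = [slice(None)] * volume.ndim
    for axis, d in enumerate(offset):
        n = volume.shape[axis]
        if d >= 0:
            dst[axis] = slice(d, n)
            src[axis] = slice(0, n - d)
        else:
            dst[axis] = slice(0, n + d)
            src[axis] = slice(-d, n)
    out[tuple(dst)] = volume[tuple(src)]
    return out


def kendalls_w(series_matrix: np.ndarray) -> float:
    """Kendall's coefficient of concordance over K time series.

    `series_matrix` has shape (K, n). Ranks are taken within each series
    (average ranks on ties, with the standard tie correction):

        W = 12 * sum_i (R_i - Rbar)^2 / (K^2 (n^3 - n) - K * sum T_j)

    where R_i is the sum over the K series of the rank of timepoint i
    and T_j = sum over tie groups g of (t_g^3 - t_g) in series j.
    Reference implementation used by the vectorized voxel map below.
    """
    mat = np.asarray(series_matrix, dtype=float)
    k, n = mat.shape
    if k < 2:
        raise ValueError("need at least 2 series")
    if n < 3:
        raise ValueError("need at least 3 timepoints")
    ranks = np.apply_along_axis(rankdata, 1, mat)
    r_i = ranks.sum(axis=0)
    s = ((r_i - r_i.mean()) ** 2).sum()
    tie = 0.0
    for j in range(k):
        _, counts = np.unique(mat[j], return_counts=True)
        tie += float((counts**3 - counts).sum())
    denom = k**2 * (n**3 - n) - k * tie
    if denom <= 0:
        return 0.0
    return float(12.0 * s / denom)


def compute_reho(
    series: BoldSeries, neighborhood: int = 27
) -> VoxelMap:
    """ReHo: Kendall's W over each voxel's K-neighbourhood time series.

    The neighbourhood (7, 19 or 27 voxels including the centre) is
    clipped at the mask boundary; voxels left with K < 2 neighbours get
    W = 0. Input must be detrended and band-passed but NOT smoothed.
    """
    if neighborhood not in _OFFSETS:
        raise ValueError(f"neighborhood must be one of {REHO_NEIGHBORHOODS}")
    n = series.n_timepoints
    if n < 3:
        raise ValueError("need at least 3 timepoints for ReHo")

    mask = series.mask
    data = np.where(mask[..., None], series.data, 0.0)
    # within-series ranks over time (average ranks on ties)
    ranks = rankdata(data, axis=-1).astype(float)
    ranks[~mask] = 0.0
    # per-voxel tie correction term T_j = sum over tie groups (t^3 - t)
    sorted_t = np.sort(data, axis=-1)
    same = np.concatenate(
        [
            np.ones(mask.shape + (1,), dtype=bool),
            sorted_t[..., 1:] == sorted_t[..., :-1],
        ],
        axis=-1,
    )
    # run-length encode ties: for each run of length t, (t^3 - t) equals
    # sum over positions p=2..t of (3p^2 - 3p); accumulate incrementally
    run_len = np.zeros(mask.shape)
    tie_term = np.zeros(mask.shape)
    for i in range(n):
        run_len = np.where(same[..., i], run_len + 1, 1.0)
        inc = 3.0 * run_len * (run_len - 1.0)
        tie_term += np.where(same[..., i], inc, 0.0)
    tie_term[~mask] = 0.0

    rank_sum = np.zeros_like(ranks)
    k_count = np.zeros(mask.shape)
    tie_sum = np.zeros(mask.shape)
    maskf = mask.astype(float)
    for off in _OFFSETS[neighborhood]:
        rank_sum += _shift3d(ranks, off)
        k_count += _shift3d(maskf, off)
        tie_sum += _shift3d(tie_term, off)

    mean_rank = k_count[..., None] * (n + 1) / 2.0
    s = ((rank_sum - mean_rank) ** 2).sum(axis=-1)
    denom = k_count**2 * (n**3 - n) - k_count * tie_sum
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(denom > 0, 12.0 * s / np.maximum(denom, 1e-300), 0.0)
    w = np.clip(w, 0.0, 1.0)
    w[~mask] = 0.0
    w[k_count < 2] = 0.0
    return VoxelMap(w, mask, "ReHo")


def standardize_map(vmap: VoxelMap) -> VoxelMap:
    """Z-score a voxel map across the in-mask voxels (population SD)."""
    in_mask = vmap.values[vmap.mask]
    if in_mask.size < 2:
        raise ValueError("need at least 2 in-mask voxels to standardize")
    mu = in_mask.mean()
    sd = in_mask.std()  # population (divide-by-N)
    out = np.zeros_like(vmap.values, dtype=float)
    if sd == 0:
        warnings.warn(
            f"constant {vmap.feature} map: standardized to all zeros",
            stacklevel=2,
        )
    else:
        out[vmap.mask] = (in_mask - mu) / sd
    return VoxelMap(out, vmap.mask, vmap.feature, standardized=True)


def aggregate_regional(vmap: VoxelMap, design: RoiDesign) -> np.ndarray:
    """Average a (standardized) voxel map over an atlas's ROIs.

    labels/spheres: unweighted mean over member voxels; maps:
    weight-normalized mean sum(w*v)/sum(w). Output order follows the
    atlas ROI order.
    """
    flat = vmap.values.ravel()
    if design.dialect in ("labels", "spheres"):
        return np.array([flat[idx].mean() for idx in design.members])
    vals = flat[design.mask_indices]
    num = design.weights @ vals
    den = design.weights.sum(axis=1)
    return num / den
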