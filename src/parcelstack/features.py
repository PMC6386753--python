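"""Per-subject feature extraction across parcellations and feature types.

Each (feature type, parcellation) pair is one *source*. The temporal
preprocessing applied before each feature type differs, and the routing
is fixed by construction here:

=============  =========  ============  ==========
feature type   smoothing  band-pass     input
=============  =========  ============  ==========
ALFF, fALFF    4 mm       no (spectral  detrended
                          measure is
                          taken in-band)
ReHo           none       yes           detrended
connectivity   4 mm       yes           detrended
=============  =========  ============  ==========

ALFF/fALFF are computed on *unfiltered* series because band-pass
filtering first and then measuring in-band power would be circular;
ReHo skips smoothing to avoid overestimating spatial homogeneity.

Regional voxel maps are standardized over the mask and averaged per
ROI; connectivity features are the strictly-lower-triangular entries of
the ROI-pair matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .atlas import Atlas, RoiDesign, resolve_design
from .bold import BandSpec, BoldSeries, bandpass, detrend, smooth_gaussian
from .connectivity import (
    connectivity_correlation,
    connectivity_partial,
    connectivity_precision,
    extract_roi_timeseries,
    lower_triangular_names,
    vectorize_lower_triangular,
)
from .regional import (
    aggregate_regional,
    compute_alff,
    compute_falff,
    compute_reho,
    standardize_map,
)
from .sourcedefs import (
    CONNECTIVITY_FEATURE_TYPES,
    FEATURE_TYPES,
    REGIONAL_FEATURE_TYPES,
)

#: preprocessing routing per feature type (asserted by the routing test)
ROUTING = {
    "alff": ("detrend", "smooth"),
    "falff": ("detrend", "smooth"),
    "reho": ("detrend", "bandpass"),
    "corr": ("detrend", "smooth", "bandpass"),
    "pcorr": ("detrend", "smooth", "bandpass"),
    "prec": ("detrend", "smooth", "bandpass"),
}


@dataclass
class ExtractionConfig:
    """Knobs of the extraction stage (defaults are the package's
    standard analysis conditions)."""

    band: BandSpec = field(default_factory=BandSpec)
    smoothing_fwhm_mm: float = 4.0
    reho_neighborhood: int = 27
    power_mode: str = "amplitude"
    precision_regularization: float | str = "cv"


@dataclass
class FeatureSet:
    """Subjects x features matrix for one (feature type, parcellation)
    source; ``source_id = (feature_type, atlas_name)``."""

    source_id: tuple[str, str]
    matrix: np.ndarray
    feature_names: list[str]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]


def feature_vector_lengths(n_rois: int) -> dict[str, int]:
    """Feature counts per source for an atlas of ``n_rois`` regions:
    n for regional sources, n(n-1)/2 for connectivity sources."""
    conn = n_rois * (n_rois - 1) // 2
    out = {ft: n_rois for ft in REGIONAL_FEATURE_TYPES}
    out.update({ft: conn for ft in CONNECTIVITY_FEATURE_TYPES})
    return out


def _preprocessed_variants(
    series: BoldSeries, config: ExtractionConfig
) -> dict[str, BoldSeries]:
    """The three shared preprocessing products, computed once."""
    base = detrend(series)
    smoothed = smooth_gaussian(base, config.smoothing_fwhm_mm)
    return {
        "regional_amplitude": smoothed,                 # ALFF / fALFF
        "reho": bandpass(base, config.band),            # no smoothing
        "connectivity": bandpass(smoothed, config.band),
    }


def extract_subject_features(
    series: BoldSeries,
    designs: dict[str, RoiDesign],
    config: ExtractionConfig | None = None,
) -> dict[tuple[str, str], np.ndarray]:
    """All 6 x n_atlases feature vectors for one subject.

    ``designs`` maps atlas name to a design resolved on the subject's
    grid/mask. Returns ``{(feature_type, atlas_name): vector}``.
    """
    config = config or ExtractionConfig()
    variants = _preprocessed_variants(series, config)

    vmaps = {
        "alff": standardize_map(
            compute_alff(variants["regional_amplitude"], config.band,
                         config.power_mode)
        ),
        "falff": standardize_map(
            compute_falff(variants["regional_amplitude"], config.band,
                          config.power_mode)
        ),
        "reho": standardize_map(
            compute_reho(variants["reho"], config.reho_neighborhood)
        ),
    }

    out: dict[tuple[str, str], np.ndarray] = {}
    for atlas_name, design in designs.items():
        for ftype, vmap in vmaps.items():
            out[(ftype, atlas_name)] = aggregate_regional(vmap, design)
        ts = extract_roi_timeseries(variants["connectivity"], design)
        conn = {
            "corr": connectivity_correlation(ts),
            "pcorr": connectivity_partial(ts),
            "prec": connectivity_precision(
                ts, config.precision_regularization
            ),
        }
        for ftype, cmat in conn.items():
            out[(ftype, atlas_name)] = vectorize_lower_triangular(cmat)
    return out


def extract_feature_sets(
    series_iter,
    atlases: list[Atlas],
    config: ExtractionConfig | None = None,
) -> dict[tuple[str, str], FeatureSet]:
    """Feature matrices over a cohort.

    ``series_iter`` yields :class:`BoldSeries` in subject order (a list
    or a lazy generator — volumes are released after extraction). The
    result maps every source id to a :class:`FeatureSet` whose rows
    follow the iteration order.
    """
    config = config or ExtractionConfig()
    designs: dict[str, RoiDesign] | None = None
    rows: dict[tuple[str, str], list[np.ndarray]] = {}
    names: dict[tuple[str, str], list[str]] = {}

    for series in series_iter:
        if designs is None:
            designs = {
                a.name: resolve_design(a, series.mask, series.affine)
                for a in atlases
            }
            for atlas in atlases:
                design = designs[atlas.name]
                for ft in REGIONAL_FEATURE_TYPES:
                    names[(ft, atlas.name)] = list(design.roi_names)
                edge_names = lower_triangular_names(design.roi_names)
                for ft in CONNECTIVITY_FEATURE_TYPES:
                    names[(ft, atlas.name)] = edge_names
        feats = extract_subject_features(series, designs, config)
        for sid, vec in feats.items():
            rows.setdefault(sid, []).append(vec)

    if designs is None:
        raise ValueError("no subjects given")
    out = {}
    for atlas in atlases:
        for ft in FEATURE_TYPES:
            sid = (ft, atlas.name)
            out[sid] = FeatureSet(sid, np.vstack(rows[sid]), names[sid])
    return out
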