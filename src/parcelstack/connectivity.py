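"""ROI time-series extraction and functional-connectivity estimators.

Connectivity between ROI-average BOLD time series is summarized three
ways: full Pearson correlation, partial correlation derived from a
shrinkage (Ledoit-Wolf) precision matrix, and a sparse precision matrix
estimated by the graphical lasso (l1-penalized inverse covariance),
whose zeros indicate conditional independence given all other regions.

ROI rows are z-scored over time before estimation, so covariance and
correlation coincide. Feature vectors are the strictly-lower-triangular
entries of the symmetric matrix in row-major order — this ordering is
part of the on-disk contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.covariance import (
    GraphicalLassoCV,
    LedoitWolf,
    graphical_lasso,
)

from .atlas import RoiDesign
from .bold import BoldSeries

CONNECTIVITY_KINDS = ("correlation", "partial_correlation", "precision")

#: alpha grid used when the graphical-lasso penalty is chosen by
#: internal cross-validation over timepoint splits
GLASSO_ALPHA_GRID = tuple(np.logspace(-3, 0, 10))
GLASSO_CV_FOLDS = 3


@dataclass
class RoiTimeseries:
    """n_rois x t matrix of ROI-average time series (rows z-scored)."""

    values: np.ndarray
    atlas_name: str
    tr_seconds: float
    roi_names: list[str]
    constant_rows: np.ndarray | None = None

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


@dataclass
class ConnectivityMatrix:
    """Symmetric n_rois x n_rois connectivity estimate."""

    values: np.ndarray
    kind: str
    roi_names: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("connectivity matrix is not symmetric")
        if self.kind not in CONNECTIVITY_KINDS:
            raise ValueError(f"unknown kind {self.kind!r}")
        self.values = v


def _zscore_rows(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, keepdims=True)
    constant = sd[:, 0] == 0
    out = np.where(constant[:, None], 0.0, (mat - mu) / np.where(sd == 0, 1, sd))
    return out, constant


def extract_roi_timeseries(
    series: BoldSeries, design: RoiDesign
) -> RoiTimeseries:
    """Per-ROI average time series (labels/spheres) or least-squares
    projection of the voxel data onto the map stack (maps dialect, the
    established convention for possibly-overlapping continuous maps).
    Each row is then z-scored over time; constant rows are zeroed and
    flagged with a warning.
    """
    t = series.n_timepoints
    flat = series.data.reshape(-1, t)
    if design.dialect in ("labels", "spheres"):
        values = np.stack([flat[idx].mean(axis=0) for idx in design.members])
    else:
        x = flat[design.mask_indices]  # (n_vox, t)
        coefs, *_ = np.linalg.lstsq(design.weights.T, x, rcond=None)
        values = coefs
    values, constant = _zscore_rows(values)
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant ROI time series zeroed",
            stacklevel=2,
        )
    return RoiTimeseries(
        values, design.atlas.name, series.tr_seconds,
        list(design.roi_names), constant_rows=constant,
    )


def connectivity_correlation(ts: RoiTimeseries) -> ConnectivityMatrix:
    """Pairwise Pearson correlation; diagonal exactly 1; correlations of
    constant (zeroed) rows are set to 0."""
    if ts.values.shape[1] < 3:
        raise ValueError("need at least 3 timepoints")
    z, constant = _zscore_rows(ts.values)
    corr = (z @ z.T) / z.shape[1]
    corr = np.clip(corr, -1.0, 1.0)
    if constant.any():
        warnings.warn("constant rows: correlations set to 0", stacklevel=2)
        corr[constant, :] = 0.0
        corr[:, constant] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr = (corr + corr.T) / 2.0
    return ConnectivityMatrix(corr, "correlation", ts.roi_names)


def _samples(ts: RoiTimeseries) -> np.ndarray:
    """Row-standardized data as (t, n_rois) samples for covariance fits."""
    z, _ = _zscore_rows(ts.values)
    return z.T


def connectivity_precision(
    ts: RoiTimeseries, regularization: float | str = "cv"
) -> ConnectivityMatrix:
    """Sparse precision via the graphical lasso.

    ``regularization`` is the l1 penalty alpha, ``"cv"`` to select it by
    internal 3-fold cross-validation on timepoint splits over a 10-point
    log grid in [1e-3, 1], or 0 for the plain inverse of the sample
    covariance (which must be well conditioned). At a fixed alpha the
    lasso runs on the Ledoit-Wolf shrunk covariance, which keeps the
    solver stable when ROI series are nearly collinear.
    """
    x = _samples(ts)
    n_rois = ts.n_rois
    if x.shape[0] <= 3:
        raise ValueError("need more than 3 timepoints")
    if regularization == 0:
        cov = (x.T @ x) / x.shape[0]
        if np.linalg.cond(cov) > 1e10:
            raise np.linalg.LinAlgError(
                "sample covariance is singular at alpha=0; use alpha > 0"
            )
        theta = np.linalg.inv(cov)
    elif regularization == "cv":
        est = GraphicalLassoCV(
            alphas=list(GLASSO_ALPHA_GRID),
            cv=GLASSO_CV_FOLDS,
            assume_centered=True,
        )
        try:
            est.fit(x)
        except FloatingPointError as exc:  # pragma: no cover
            raise RuntimeError(
                f"graphical lasso did not converge: {exc}"
            ) from exc
        theta = est.precision_
    else:
        cov = LedoitWolf(assume_centered=True).fit(x).covariance_
        try:
            _, theta = graphical_lasso(cov, alpha=float(regularization))
        except FloatingPointError as exc:
            raise RuntimeError(
                f"graphical lasso did not converge: {exc}"
            ) from exc
    theta = (theta + theta.T) / 2.0
    assert theta.shape == (n_rois, n_rois)
    return ConnectivityMatrix(theta, "precision", ts.roi_names)


def connectivity_partial(ts: RoiTimeseries) -> ConnectivityMatrix:
    """Partial correlation from a Ledoit-Wolf shrinkage precision:
    rho_ij = -Theta_ij / sqrt(Theta_ii * Theta_jj), diagonal set to 1."""
    x = _samples(ts)
    if x.shape[0] <= 3:
        raise ValueError("need more than 3 timepoints")
    if ts.n_rois == 1:
        return ConnectivityMatrix(np.ones((1, 1)), "partial_correlation",
                                  ts.roi_names)
    theta = np.linalg.pinv(LedoitWolf(assume_centered=True).fit(x).covariance_)
    d = np.sqrt(np.diag(theta))
    rho = -theta / np.outer(d, d)
    np.fill_diagonal(rho, 1.0)
    rho = (rho + rho.T) / 2.0
    return ConnectivityMatrix(rho, "partial_correlation", ts.roi_names)


def vectorize_lower_triangular(matrix) -> np.ndarray:
    """Strictly-lower-triangular entries in row-major order.

    For an n x n symmetric matrix the result has length n(n-1)/2:
    (1,0), (2,0), (2,1), (3,0), ...
    """
    values = matrix.values if isinstance(matrix, ConnectivityMatrix) else (
        np.asarray(matrix, dtype=float)
    )
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("need a square matrix")
    if not np.allclose(values, values.T, atol=1e-8):
        raise ValueError("matrix is not symmetric")
    rows, cols = np.tril_indices(values.shape[0], k=-1)
    return values[rows, cols]


def lower_triangular_names(roi_names: list[str]) -> list[str]:
    """Edge labels 'roiA|roiB' matching the vectorization order."""
    rows, cols = np.tril_indices(len(roi_names), k=-1)
    return [f"{roi_names[r]}|{roi_names[c]}" for r, c in zip(rows, cols)]
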