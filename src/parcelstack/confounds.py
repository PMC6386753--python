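"""Nuisance-variable handling: framewise displacement and confound
regression of ROI-level features.

The confounds regressed from every feature column are the ones routinely
reported in neuroimaging group studies — age, sex, total intracranial
volume (TIV) and mean framewise displacement (FD) — via ordinary least
squares with an intercept. Fitting is done on a designated subject set
(normally the training fold, to keep the held-out subjects untouched by
the fit) and the fitted coefficients are applied to everyone.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import MotionFormatError

CONFOUND_COLUMNS = ("age", "sex", "tiv", "mean_fd")
METADATA_COLUMNS = ("subject_id", "label") + CONFOUND_COLUMNS


def compute_mean_fd(
    motion_params: np.ndarray,
    rotation_unit: str = "radians",
    sphere_radius_mm: float = 50.0,
) -> float:
    """Mean framewise displacement from a t x 6 realignment table.

    FD at frame t is the sum over the six parameters of the absolute
    backward difference, with rotations converted to arc length on a
    sphere of ``sphere_radius_mm`` (50 mm approximates the head).
    The mean is over frames 2..t.
    """
    params = np.asarray(motion_params, dtype=float)
    if params.ndim != 2 or params.shape[1] != 6:
        raise MotionFormatError(
            f"expected a t x 6 motion table, got shape {params.shape}"
        )
    if params.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    if rotation_unit == "degrees":
        params = params.copy()
        params[:, 3:] = np.radians(params[:, 3:])
    elif rotation_unit != "radians":
        raise ValueError(f"unknown rotation unit {rotation_unit!r}")
    diffs = np.abs(np.diff(params, axis=0))
    diffs[:, 3:] *= sphere_radius_mm
    return float(diffs.sum(axis=1).mean())


def _design_matrix(records: pd.DataFrame) -> np.ndarray:
    missing = [c for c in CONFOUND_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"metadata lacks confound columns {missing}")
    x = records.loc[:, list(CONFOUND_COLUMNS)].to_numpy(dtype=float)
    return np.column_stack([np.ones(len(x)), x])


def _check_full_rank(design: np.ndarray) -> None:
    cols = ("intercept",) + CONFOUND_COLUMNS
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # name the columns involved in the deficiency via QR pivoting
        _, r = np.linalg.qr(design)
        diag = np.abs(np.diag(r))  # length min(n_rows, n_cols)
        bad = [cols[i] for i in range(design.shape[1])
               if i >= len(diag) or diag[i] < 1e-10 * max(1.0, diag[0])]
        raise np.linalg.LinAlgError(
            f"confound design is rank deficient (rank {rank} < "
            f"{design.shape[1]}); collinear columns: {bad or 'unknown'}"
        )


def residualize_features(
    features: np.ndarray,
    records: pd.DataFrame,
    fit_subjects: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """OLS-residualize each feature column on (1, age, sex, tiv, mean_fd).

    Coefficients are fitted on ``fit_subjects`` (row indices; all rows
    when None) and applied to every row. Returns ``(residuals, coef)``
    with ``coef`` of shape (5, n_features).
    """
    x = np.asarray(features, dtype=float)
    design = _design_matrix(records)
    if len(design) != len(x):
        raise ValueError("features and records row counts differ")
    fit_idx = (
        np.arange(len(x)) if fit_subjects is None
        else np.asarray(fit_subjects, dtype=int)
    )
    _check_full_rank(design[fit_idx])
    coef, *_ = np.linalg.lstsq(design[fit_idx], x[fit_idx], rcond=None)
    return x - design @ coef, coef


class ConfoundRegressor(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer removing confound effects from features.

    ``fit(X, y=None, confounds=records)`` fits per-column OLS on the
    rows it is given; ``transform(X, confounds=records)`` subtracts the
    fitted confound contribution. Passing the training fold to ``fit``
    and the full sample to ``transform`` reproduces train-only fitting.
    """

    def fit(self, X, y=None, *, confounds: pd.DataFrame):
        X = np.asarray(X, dtype=float)
        design = _design_matrix(confounds)
        if len(design) != len(X):
            raise ValueError("X and confounds row counts differ")
        _check_full_rank(design)
        self.coef_, *_ = np.linalg.lstsq(design, X, rcond=None)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X, *, confounds: pd.DataFrame):
        X = np.asarray(X, dtype=float)
        design = _design_matrix(confounds)
        return X - design @ self.coef_
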