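"""Single-source classifiers and the stacked multi-source ensemble.

The model has two levels. Level one fits, per (feature type,
parcellation) source, a pipeline of dimensionality handling followed by
an L2-regularized logistic regression; the regularization strength C is
chosen by internal repeated stratified cross-validation on the training
split (default 10-fold, 5 shuffled iterations), maximizing mean
accuracy with ties broken toward the smallest (most regularized) C.
Dimensionality handling is, by default, a full-rank PCA keeping
min(n_features, n_train) components — a pure change of basis that
uniformizes the pipeline across sources whose widths span orders of
magnitude, and under which the L2 penalty is invariant. Alternatives
are univariate top-r% selection by ANOVA F score, a mixed mode (all
regional features, top 30% of connectivity features), or no reduction.

Level two ("stacking") collects each base model's predicted probability
of the positive class on the *same* training instances it was fitted on
and fits one more L2 logistic regression over those probability
columns, with C chosen by the same internal-CV rule. A cross-fitted
variant (``stack_cv=True``) is available as a clearly-labelled
extension. Estimators follow scikit-learn conventions (``fit`` /
``predict`` / ``predict_proba``, ``get_params``, fitted attributes with
a trailing underscore).
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin, clone
from sklearn.decomposition import PCA
from sklearn.feature_selection import f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted, check_X_y

from .sourcedefs import REGIONAL_FEATURE_TYPES

#: default grid for the inverse regularization strength C
C_GRID = (0.001, 0.01, 0.1, 1.0, 10.0, 100.0, 1000.0)

SELECTION_MODES = ("pca", "top_r_percent", "regional_all_plus_30pct_conn",
                   "standardize", "none")
TOP_R_GRID = (0.5, 1, 2, 5, 10, 20, 30)

# L2 penalty (sklearn's default); tight tolerance so that the PCA
# rotation-invariance contract holds to 1e-6 in probability
_LR_KWARGS = dict(solver="lbfgs", tol=1e-10, max_iter=20000)


def fit_pca_basis(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-mean center and full-rank principal axes of a training
    matrix: returns ``(center, rotation)`` with rotation of shape
    (p, min(p, n)) and orthonormal columns. No whitening."""
    x = np.asarray(matrix, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    pca = PCA(n_components=None, svd_solver="full").fit(x)
    return pca.mean_, pca.components_.T


def select_top_r(
    matrix: np.ndarray, labels: np.ndarray, r_percent: float
) -> np.ndarray:
    """Indices of the ceil(p*r/100) columns with the highest one-way
    ANOVA F statistic between classes; ties (and degenerate columns)
    break deterministically toward the lower column index."""
    if r_percent <= 0:
        raise ValueError("r_percent must be positive")
    x = np.asarray(matrix, dtype=float)
    p = x.shape[1]
    k = min(p, math.ceil(p * r_percent / 100.0))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scores, _ = f_classif(x, labels)
    scores = np.where(np.isfinite(scores), scores, -np.inf)
    order = np.argsort(-scores, kind="stable")
    return np.sort(order[:k])


class TopRSelector(BaseEstimator, TransformerMixin):
    """In-fold univariate top-r% column selector (ANOVA F score)."""

    def __init__(self, r_percent: float = 10.0):
        self.r_percent = r_percent

    def fit(self, X, y):
        self.selected_ = select_top_r(X, y, self.r_percent)
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "selected_")
        return np.asarray(X)[:, self.selected_]


def _resolve_selection(selection: str, r: float | None,
                       source_id=None) -> tuple[str, float | None]:
    """Map a selection spec to the concrete (mode, r) for one source."""
    if selection == "regional_all_plus_30pct_conn":
        ftype = source_id[0] if isinstance(source_id, tuple) else source_id
        if ftype in REGIONAL_FEATURE_TYPES:
            return "none", None
        return "top_r_percent", 30.0
    return selection, r


class SingleSourceClassifier(BaseEstimator, ClassifierMixin):
    """PCA (or top-r) + L2 logistic regression with internal-CV choice
    of C — the base learner fitted once per feature source.

    Parameters
    ----------
    selection : one of "pca", "top_r_percent", "none"
        ("regional_all_plus_30pct_conn" is resolved per source by the
        ensemble before construction).
    r : top-r percentage when selection="top_r_percent".
    C_grid : candidate inverse regularization strengths, ascending.
    inner_folds, inner_repeats : internal CV scheme for choosing C.
    random_state : seed for the internal CV shuffles.
    positive_label : class treated as "patient" for probabilities;
        defaults to the lexicographically larger of the two classes.

    Attributes
    ----------
    classes_, chosen_C_, inner_scores_, pipeline_ ; with
    selection="pca" additionally center_ and rotation_ (orthonormal
    columns), plus lr_weights_ / lr_intercept_ in the reduced basis.
    """

    def __init__(
        self,
        selection: str = "pca",
        r: float | None = None,
        C_grid=C_GRID,
        inner_folds: int = 10,
        inner_repeats: int = 5,
        random_state: int | None = None,
        positive_label=None,
    ):
        self.selection = selection
        self.r = r
        self.C_grid = C_grid
        self.inner_folds = inner_folds
        self.inner_repeats = inner_repeats
        self.random_state = random_state
        self.positive_label = positive_label

    # -- internals ---------------------------------------------------
    def _make_pipeline(self, C: float) -> Pipeline:
        if self.selection == "pca":
            step = PCA(n_components=None, svd_solver="full")
        elif self.selection == "top_r_percent":
            if self.r is None:
                raise ValueError("selection='top_r_percent' requires r")
            step = TopRSelector(self.r)
        elif self.selection == "standardize":
            step = StandardScaler()
        elif self.selection == "none":
            step = "passthrough"
        else:
            raise ValueError(f"unknown selection mode {self.selection!r}")
        lr = LogisticRegression(C=C, **_LR_KWARGS)
        return Pipeline([("reduce", step), ("lr", lr)])

    def _inner_cv_scores(self, X, y) -> dict[float, float]:
        counts = np.bincount(np.searchsorted(self.classes_, y))
        folds = int(min(self.inner_folds, counts.min()))
        grid = sorted(float(c) for c in self.C_grid)
        if folds < 2:
            warnings.warn(
                "too few samples per class for internal CV; "
                "defaulting to the smallest C", stacklevel=2,
            )
            return {c: np.nan for c in grid}
        cv = RepeatedStratifiedKFold(
            n_splits=folds,
            n_repeats=self.inner_repeats,
            random_state=self.random_state,
        )
        splits = list(cv.split(X, y))
        scores = {}
        for c in grid:
            accs = []
            for train_idx, test_idx in splits:
                pipe = self._make_pipeline(c)
                pipe.fit(X[train_idx], y[train_idx])
                accs.append(
                    float(np.mean(pipe.predict(X[test_idx]) == y[test_idx]))
                )
            scores[c] = float(np.mean(accs))
        return scores

    # -- sklearn API -------------------------------------------------
    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(
                f"need exactly 2 classes, got {len(self.classes_)}"
            )
        self.n_features_in_ = X.shape[1]
        pos = self.positive_label
        self.positive_label_ = self.classes_[-1] if pos is None else pos
        if self.positive_label_ not in self.classes_:
            raise ValueError(
                f"positive_label {self.positive_label_!r} not among classes"
            )

        grid = sorted(float(c) for c in self.C_grid)
        if len(grid) == 1:
            self.inner_scores_ = {grid[0]: np.nan}
            self.chosen_C_ = grid[0]
        else:
            self.inner_scores_ = self._inner_cv_scores(X, y)
            vals = np.array([self.inner_scores_[c] for c in grid])
            if np.all(np.isnan(vals)):
                self.chosen_C_ = grid[0]
            else:
                best = np.nanmax(vals)
                # smallest C within numerical tie of the best mean accuracy
                self.chosen_C_ = grid[
                    int(np.flatnonzero(vals >= best - 1e-12)[0])
                ]

        self.pipeline_ = self._make_pipeline(self.chosen_C_).fit(X, y)
        if self.selection == "pca":
            pca = self.pipeline_.named_steps["reduce"]
            self.center_ = pca.mean_
            self.rotation_ = pca.components_.T
        lr = self.pipeline_.named_steps["lr"]
        self.lr_weights_ = lr.coef_.ravel()
        self.lr_intercept_ = float(lr.intercept_[0])
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "pipeline_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        return self.pipeline_.predict_proba(X)

    def predict_proba_positive(self, X) -> np.ndarray:
        """Probability of the positive ("patient") class."""
        proba = self.predict_proba(X)
        idx = int(np.flatnonzero(self.classes_ == self.positive_label_)[0])
        return proba[:, idx]

    def predict(self, X):
        """Positive class iff its probability >= 0.5 (binary)."""
        p = self.predict_proba_positive(X)
        neg = self.classes_[self.classes_ != self.positive_label_][0]
        return np.where(p >= 0.5, self.positive_label_, neg)


class StackedEnsembleClassifier(BaseEstimator, ClassifierMixin):
    """Two-level stacked ensemble over multiple feature sources.

    ``fit`` takes a mapping ``{source_id: (n, p_source) array}`` sharing
    row order with ``y``; one :class:`SingleSourceClassifier` is fitted
    per source, their positive-class probabilities on the training
    instances form the level-two design, and a final L2 logistic
    regression (same internal-CV rule for C) is fitted on it.

    Attributes: ``source_ids_``, ``base_models_`` (dict),
    ``stack_model_`` plus ``substacks_`` created by
    :meth:`fit_substack`.
    """

    def __init__(
        self,
        selection: str = "pca",
        r: float | None = None,
        C_grid=C_GRID,
        inner_folds: int = 10,
        inner_repeats: int = 5,
        random_state: int | None = None,
        positive_label=None,
        stack_cv: bool = False,
        stack_cv_folds: int = 5,
    ):
        self.selection = selection
        self.r = r
        self.C_grid = C_grid
        self.inner_folds = inner_folds
        self.inner_repeats = inner_repeats
        self.random_state = random_state
        self.positive_label = positive_label
        self.stack_cv = stack_cv
        self.stack_cv_folds = stack_cv_folds

    def _base_template(self, source_id) -> SingleSourceClassifier:
        mode, r = _resolve_selection(self.selection, self.r, source_id)
        return SingleSourceClassifier(
            selection=mode,
            r=r,
            C_grid=self.C_grid,
            inner_folds=self.inner_folds,
            inner_repeats=self.inner_repeats,
            random_state=self.random_state,
            positive_label=self.positive_label,
        )

    def _stack_template(self) -> SingleSourceClassifier:
        # level-1 probability columns are z-scored before the stacking
        # LR: the internal accuracy-scored choice of C is indifferent to
        # base-probability scale, so informative but strongly-shrunk
        # base models would otherwise be invisible to an L2 stacker
        return SingleSourceClassifier(
            selection="standardize",
            C_grid=self.C_grid,
            inner_folds=self.inner_folds,
            inner_repeats=self.inner_repeats,
            random_state=self.random_state,
            positive_label=self.positive_label,
        )

    def fit(self, X: dict, y):
        y = np.asarray(y)
        self.source_ids_ = list(X.keys())
        if not self.source_ids_:
            raise ValueError("no feature sources given")
        self.base_models_ = {}
        level1 = np.empty((len(y), len(self.source_ids_)))
        for j, sid in enumerate(self.source_ids_):
            model = self._base_template(sid).fit(np.asarray(X[sid]), y)
            self.base_models_[sid] = model
            if self.stack_cv:
                level1[:, j] = self._cross_fitted_probs(
                    model, np.asarray(X[sid]), y
                )
            else:
                level1[:, j] = model.predict_proba_positive(X[sid])
        self.level1_train_ = level1
        self.stack_model_ = self._stack_template().fit(level1, y)
        self.classes_ = self.stack_model_.classes_
        self.positive_label_ = self.stack_model_.positive_label_
        self.substacks_ = {}
        return self

    def _cross_fitted_probs(self, fitted_model, x, y) -> np.ndarray:
        """Out-of-fold level-1 probabilities (extension mode)."""
        out = np.empty(len(y))
        cv = StratifiedKFold(
            n_splits=self.stack_cv_folds, shuffle=True,
            random_state=self.random_state,
        )
        for tr, te in cv.split(x, y):
            m = clone(fitted_model).fit(x[tr], y[tr])
            out[te] = m.predict_proba_positive(x[te])
        return out

    def fit_substack(self, name: str, source_ids, y) -> SingleSourceClassifier:
        """Fit a second-level model over a subset of already-fitted
        sources (e.g. the 14 sources of one feature type)."""
        check_is_fitted(self, "stack_model_")
        cols = [self.source_ids_.index(s) for s in source_ids]
        sub = self._stack_template().fit(
            self.level1_train_[:, cols], np.asarray(y)
        )
        self.substacks_[name] = (list(source_ids), sub)
        return sub

    def base_probabilities(self, X: dict) -> np.ndarray:
        check_is_fitted(self, "stack_model_")
        missing = [s for s in self.source_ids_ if s not in X]
        if missing:
            raise ValueError(f"missing sources {missing}")
        cols = [
            self.base_models_[sid].predict_proba_positive(np.asarray(X[sid]))
            for sid in self.source_ids_
        ]
        return np.column_stack(cols)

    def predict_proba_positive(self, X: dict, substack: str | None = None):
        probs = self.base_probabilities(X)
        if substack is None:
            return self.stack_model_.predict_proba_positive(probs)
        source_ids, model = self.substacks_[substack]
        cols = [self.source_ids_.index(s) for s in source_ids]
        return model.predict_proba_positive(probs[:, cols])

    def predict_proba(self, X: dict):
        return self.stack_model_.predict_proba(self.base_probabilities(X))

    def predict(self, X: dict):
        p = self.predict_proba_positive(X)
        neg = self.classes_[self.classes_ != self.positive_label_][0]
        return np.where(p >= 0.5, self.positive_label_, neg)


def reliability_scores(
    fold_weights: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature reliability of logistic-regression weights over CV
    folds: mean weight divided by its standard error across folds, with
    SE = SD(ddof=1)/sqrt(n_folds).

    Returns ``(scores, flagged)``; a feature whose weight has zero
    variance across folds gets a signed-infinity sentinel (NaN if its
    mean is also 0) and is flagged.
    """
    w = np.asarray(fold_weights, dtype=float)
    if w.ndim != 2 or w.shape[0] < 2:
        raise ValueError("need a (n_folds >= 2, n_features) weight matrix")
    mean = w.mean(axis=0)
    se = w.std(axis=0, ddof=1) / np.sqrt(w.shape[0])
    flagged = se == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = mean / se
    scores[flagged & (mean != 0)] = np.copysign(np.inf, mean[flagged & (mean != 0)])
    scores[flagged & (mean == 0)] = np.nan
    return scores, flagged


def top_percentile_features(
    scores: np.ndarray, percentile: float = 98.0
) -> np.ndarray:
    """Indices of features whose |score| exceeds the given percentile of
    the finite |score| distribution."""
    a = np.abs(np.asarray(scores, dtype=float))
    finite = a[np.isfinite(a)]
    if finite.size == 0:
        return np.array([], dtype=int)
    thresh = np.percentile(finite, percentile)
    return np.flatnonzero((a > thresh) | ~np.isfinite(a))
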