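"""Outer cross-validation, metrics, permutation baseline and the
symptom-severity sub-analysis.

The evaluation scheme is repeated stratified ("balanced") k-fold CV —
by default 5 shuffled iterations of 10-fold, i.e. 50 train-test splits.
Within each training split the entire learning procedure is repeated
from scratch: confound residualization (fitted on the training subjects
only, by default), all base single-source models, and the stacking
models. Per-fold confusion counts (patient = positive class) yield
accuracy, precision, sensitivity and specificity; means and standard
errors (SD over folds / sqrt(n_folds), SD with ddof=1) are reported
over the folds. Undefined ratios (zero denominator) are reported as
absent (NaN), never as 0.

The permutation baseline repeats the *entire* learning-plus-CV
procedure on label-shuffled copies of the data, giving the empirical
chance distribution of each metric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .confounds import residualize_features
from .ensemble import C_GRID, StackedEnsembleClassifier
from .sourcedefs import FEATURE_TYPE_LABELS

logger = logging.getLogger(__name__)

METRICS = ("accuracy", "precision", "sensitivity", "specificity")


def make_folds(
    labels: np.ndarray, k: int = 10, repeats: int = 5, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified repeated k-fold train/test splits (k*repeats of them).

    Every subject appears in exactly one test fold per repeat. With
    ``k == n`` (and repeats=1) this degenerates to leave-one-out.
    Deterministic given ``seed``.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if k == n:
        idx = np.arange(n)
        return [(np.delete(idx, i), np.array([i])) for i in range(n)]
    counts = pd.Series(labels).value_counts()
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} subjects < k={k}"
        )
    splits = []
    for rep in range(repeats):
        cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + rep)
        splits.extend(
            (np.asarray(tr), np.asarray(te)) for tr, te in cv.split(
                np.zeros(n), labels
            )
        )
    return splits


def compute_metrics(tp: int, tn: int, fp: int, fn: int) -> dict[str, float]:
    """Accuracy, precision, sensitivity, specificity from confusion
    counts (patient = positive). Ratios with zero denominator are NaN."""
    for v in (tp, tn, fp, fn):
        if v < 0:
            raise ValueError("confusion counts must be nonnegative")
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("empty confusion matrix")

    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    return {
        "accuracy": (tp + tn) / total,
        "precision": ratio(tp, tp + fp),
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
    }


@dataclass
class CvReport:
    """Per-fold confusion counts and metrics for one model."""

    model: str
    rows: pd.DataFrame
    fold_tests: list[np.ndarray]
    seed: int
    positive_label: object = "patient"
    summary_: dict = field(default=None, repr=False)

    @property
    def n_folds(self) -> int:
        return len(self.rows)

    @property
    def fold_accuracies(self) -> np.ndarray:
        return self.rows["accuracy"].to_numpy()

    def summary(self) -> pd.DataFrame:
        """Mean and standard error (SD/sqrt(n_folds)) per metric."""
        recs = {}
        for m in METRICS + ("tp", "tn", "fp", "fn"):
            vals = self.rows[m].to_numpy(dtype=float)
            ok = np.isfinite(vals)
            mean = vals[ok].mean() if ok.any() else float("nan")
            se = (
                vals[ok].std(ddof=1) / np.sqrt(self.n_folds)
                if ok.sum() > 1 else float("nan")
            )
            recs[m] = {"mean": mean, "se": se}
        return pd.DataFrame(recs).T

    def to_tidy(self) -> pd.DataFrame:
        """One row per fold per metric (long format for serialization)."""
        long = self.rows.melt(
            id_vars=["repeat", "fold"], value_vars=list(METRICS),
            var_name="metric", value_name="value",
        )
        long.insert(0, "model", self.model)
        return long


def _confusion(y_true, y_pred, positive) -> tuple[int, int, int, int]:
    t = np.asarray(y_true) == positive
    p = np.asarray(y_pred) == positive
    tp = int(np.sum(t & p))
    tn = int(np.sum(~t & ~p))
    fp = int(np.sum(~t & p))
    fn = int(np.sum(t & ~p))
    return tp, tn, fp, fn


def _positive_label(labels: np.ndarray):
    uniq = np.unique(labels)
    for name in ("patient", "high"):
        if name in uniq.astype(str):
            return uniq[uniq.astype(str) == name][0]
    return uniq[-1]


def _report_from_folds(model, fold_rows, fold_tests, seed, positive):
    rows = pd.DataFrame(fold_rows)
    return CvReport(model, rows, fold_tests, seed, positive)


def run_cv_evaluation(
    feature_sets: dict,
    labels: np.ndarray,
    records: pd.DataFrame | None = None,
    k: int = 10,
    repeats: int = 5,
    seed: int = 0,
    confound_scope: str = "train",
    selection: str = "pca",
    r: float | None = None,
    C_grid=C_GRID,
    inner_folds: int = 10,
    inner_repeats: int = 5,
    stack_cv: bool = False,
    include_per_type: bool = True,
    include_ssm: bool = True,
    fold_splits: list | None = None,
) -> dict[str, CvReport]:
    """Evaluate the stacked ensemble (and its members) under repeated
    stratified CV; returns reports keyed ``"stacked-multi"``,
    ``"stacked-<feature type>"`` and, optionally, ``"ssm:<type>:<atlas>"``.

    ``confound_scope`` is ``"train"`` (residualization fitted inside
    each training fold — the leakage-safe default), ``"all"``
    (whole-sample fit) or ``"none"``.
    """
    labels = np.asarray(labels)
    source_ids = list(feature_sets.keys())
    ftypes = sorted({sid[0] for sid in source_ids})
    atlases = sorted({sid[1] for sid in source_ids})
    # the source grid must be the full crossing (84 for the canonical
    # 6-type x 14-parcellation registry), checked at run time
    assert len(source_ids) == len(ftypes) * len(atlases), (
        f"expected {len(ftypes)}x{len(atlases)} sources, got "
        f"{len(source_ids)}"
    )
    if confound_scope not in ("train", "all", "none"):
        raise ValueError(f"unknown confound_scope {confound_scope!r}")
    if confound_scope != "none" and records is None:
        raise ValueError("confound_scope requires a records table")

    positive = _positive_label(labels)
    splits = fold_splits if fold_splits is not None else make_folds(
        labels, k=k, repeats=repeats, seed=seed
    )
    k_eff = k if fold_splits is None else len(splits)

    mats = {sid: np.asarray(m, dtype=float) for sid, m in feature_sets.items()}
    if confound_scope == "all":
        mats = {
            sid: residualize_features(m, records)[0]
            for sid, m in mats.items()
        }

    model_rows: dict[str, list] = {}
    fold_tests = [te for _, te in splits]

    for fold_no, (tr, te) in enumerate(splits):
        if confound_scope == "train":
            fold_mats = {
                sid: residualize_features(m, records, fit_subjects=tr)[0]
                for sid, m in mats.items()
            }
        else:
            fold_mats = mats
        xs_train = {sid: m[tr] for sid, m in fold_mats.items()}
        xs_test = {sid: m[te] for sid, m in fold_mats.items()}
        y_train, y_test = labels[tr], labels[te]
        if len(np.unique(y_train)) < 2:
            raise ValueError(f"training fold {fold_no} has a single class")

        ens = StackedEnsembleClassifier(
            selection=selection, r=r, C_grid=C_GRID if C_grid is None else C_grid,
            inner_folds=inner_folds, inner_repeats=inner_repeats,
            random_state=seed, positive_label=positive, stack_cv=stack_cv,
        ).fit(xs_train, y_train)

        preds = {"stacked-multi": ens.predict(xs_test)}
        if include_per_type:
            for ftype in ftypes:
                members = [sid for sid in source_ids if sid[0] == ftype]
                name = f"stacked-{FEATURE_TYPE_LABELS.get(ftype, ftype)}"
                ens.fit_substack(name, members, y_train)
                p = ens.predict_proba_positive(xs_test, substack=name)
                neg = ens.classes_[ens.classes_ != positive][0]
                preds[name] = np.where(p >= 0.5, positive, neg)
        if include_ssm:
            base = ens.base_probabilities(xs_test)
            neg = ens.classes_[ens.classes_ != positive][0]
            for j, sid in enumerate(ens.source_ids_):
                preds[f"ssm:{sid[0]}:{sid[1]}"] = np.where(
                    base[:, j] >= 0.5, positive, neg
                )

        for name, y_pred in preds.items():
            tp, tn, fp, fn = _confusion(y_test, y_pred, positive)
            row = {
                "repeat": fold_no // k_eff if fold_splits is None else 0,
                "fold": fold_no % k_eff if fold_splits is None else fold_no,
                "tp": tp, "tn": tn, "fp": fp, "fn": fn,
                **compute_metrics(tp, tn, fp, fn),
            }
            model_rows.setdefault(name, []).append(row)

    return {
        name: _report_from_folds(name, rows, fold_tests, seed, positive)
        for name, rows in model_rows.items()
    }


def permutation_baseline(
    feature_sets: dict,
    labels: np.ndarray,
    records: pd.DataFrame | None = None,
    n_perm: int = 100,
    seed: int = 0,
    **cv_kwargs,
) -> pd.DataFrame:
    """Chance distribution of the stacked-multi metrics: the entire
    learning + CV evaluation repeated on ``n_perm`` label shufflings.

    Returns one row per permutation with the mean of each metric over
    folds.
    """
    if n_perm < 2:
        raise ValueError("need at least 2 permutations")
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    out = []
    cv_kwargs = {
        **cv_kwargs, "include_per_type": False, "include_ssm": False,
    }
    for p in range(n_perm):
        perm = rng.permutation(labels)
        reports = run_cv_evaluation(
            feature_sets, perm, records,
            seed=int(rng.integers(2**31 - 1)), **cv_kwargs,
        )
        summary = reports["stacked-multi"].summary()
        out.append(
            {"perm": p, **{m: summary.loc[m, "mean"] for m in METRICS}}
        )
        logger.info("permutation %d/%d done", p + 1, n_perm)
    return pd.DataFrame(out)


def compare_models(report_a: CvReport, report_b: CvReport):
    """Paired two-sided t-test over per-fold accuracies of two reports
    sharing fold assignments. Returns (t, p); identical reports give
    (0, 1); a constant nonzero difference gives (inf-sentinel, 0)."""
    if len(report_a.fold_tests) != len(report_b.fold_tests) or any(
        not np.array_equal(a, b)
        for a, b in zip(report_a.fold_tests, report_b.fold_tests)
    ):
        raise ValueError("reports do not share fold assignments")
    a = report_a.fold_accuracies
    b = report_b.fold_accuracies
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return 0.0, 1.0
        return float(np.copysign(np.inf, d.mean())), 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def severity_groups(
    scores: np.ndarray, q_low: float = 0.25, q_high: float = 0.75
) -> tuple[np.ndarray, np.ndarray]:
    """First/last-quartile split of symptom-severity scores.

    Inclusive empirical-quantile rule: low group = scores <= Q1, high
    group = scores >= Q3 (linear interpolation quantiles). Returns
    (low_idx, high_idx) over the finite scores' positions.
    """
    s = np.asarray(scores, dtype=float)
    finite = np.isfinite(s)
    q1, q3 = np.quantile(s[finite], [q_low, q_high])
    low = np.flatnonzero(finite & (s <= q1))
    high = np.flatnonzero(finite & (s >= q3))
    return low, high


def severity_subanalysis(
    feature_sets: dict,
    severity: np.ndarray,
    records: pd.DataFrame | None = None,
    min_group: int = 8,
    **cv_kwargs,
) -> dict[str, CvReport]:
    """Classify most- vs least-symptomatic patients (quartile extremes
    of a clinical scale) with the same ensemble machinery, evaluated by
    leave-one-out CV (appropriate for the small extreme-group sample).

    ``feature_sets`` and ``severity`` cover the patient subsample;
    patients with a missing score are dropped with a log entry.
    """
    severity = np.asarray(severity, dtype=float)
    missing = ~np.isfinite(severity)
    if missing.any():
        logger.info("dropping %d patients with missing severity scores",
                    int(missing.sum()))
    low, high = severity_groups(severity)
    if len(low) < min_group or len(high) < min_group:
        raise ValueError(
            f"extreme groups too small ({len(low)}/{len(high)} < {min_group})"
        )
    keep = np.concatenate([low, high])
    y = np.array(["low"] * len(low) + ["high"] * len(high))
    subsets = {
        sid: np.asarray(m, dtype=float)[keep]
        for sid, m in feature_sets.items()
    }
    sub_records = records.iloc[keep].reset_index(drop=True) if (
        records is not None
    ) else None
    loo = make_folds(y, k=len(y), repeats=1, seed=0)
    return run_cv_evaluation(
        subsets, y, sub_records, fold_splits=loo, **cv_kwargs
    )
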