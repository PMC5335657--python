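"""Feature selection, SVR prediction and nested cross-validated evaluation.

Fitted row norms of the unfolded weight stack rank features; the selected
subset (common to every time point and score type within one training
fold) feeds one linear epsilon-SVR per (time, score) cell.  Evaluation uses
subject-level 10-fold cross-validation with an inner 5-fold loop choosing
the regularization weights, and reports Pearson correlation and RMSE per
cell together with per-fold selections for stability analysis.  A per-task
l1 (lasso) selector with the identical protocol serves as the sanity
baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso
from sklearn.model_selection import KFold
from sklearn.svm import SVR

from .datatypes import FeatureMatrix, Normalization, ScoreTensor
from .optimizer import FitConfig, FitResult, fit

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionResult",
    "FoldRecord",
    "PredictionReport",
    "EmptySelectionError",
    "rank_features",
    "unit_norm_rows",
    "train_predictors",
    "evaluate",
    "lambda_grid",
    "cross_validate",
    "lasso_select",
    "lasso_baseline",
    "region_frequency_report",
]

REPORT_SCHEMA_VERSION = 1


class EmptySelectionError(ValueError):
    """Raised when a selection rule keeps no features at all."""


@dataclass
class SelectionResult:
    """Ranking of features by unfolded row norm plus the selected subset.

    ``ranked`` is a permutation of 0..F-1 in descending row-norm order with
    ties broken by ascending original index; ``selected`` is a prefix of the
    ranking under the top_k rule, or the above-threshold head under the
    relative-threshold rule (kept in ranking order).
    """

    ranked: np.ndarray
    selected: np.ndarray
    row_norms: np.ndarray
    selection_rule: str


@dataclass
class FoldRecord:
    """Everything computed from one outer training fold."""

    fold: int
    test_subjects: list[int]
    hyperparameters: dict
    selected_indices: list[int]
    norm_mean: list[float]
    norm_sd: list[float]
    corr: list[list[float | None]]  # T x C, None when undefined
    rmse: list[list[float]]  # T x C
    n_test: int
    row_norms: list[float] | None = None
    selected_per_cell: dict[str, list[int]] | None = None


@dataclass
class PredictionReport:
    """Cross-validated per-cell metrics plus per-fold selection details."""

    method: str
    time_labels: list[str]
    score_names: list[str]
    feature_names: list[str]
    fold_assignments: list[int]
    per_fold: list[FoldRecord]
    corr_mean: list[list[float | None]] = field(default_factory=list)
    corr_sd: list[list[float | None]] = field(default_factory=list)
    rmse_mean: list[list[float]] = field(default_factory=list)
    rmse_sd: list[list[float]] = field(default_factory=list)
    schema_version: int = REPORT_SCHEMA_VERSION

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "method": self.method,
            "time_labels": self.time_labels,
            "score_names": self.score_names,
            "feature_names": self.feature_names,
            "fold_assignments": self.fold_assignments,
            "corr_mean": self.corr_mean,
            "corr_sd": self.corr_sd,
            "rmse_mean": self.rmse_mean,
            "rmse_sd": self.rmse_sd,
            "per_fold": [
                {
                    "fold": r.fold,
                    "test_subjects": r.test_subjects,
                    "hyperparameters": r.hyperparameters,
                    "selected_indices": r.selected_indices,
                    "norm_mean": r.norm_mean,
                    "norm_sd": r.norm_sd,
                    "corr": r.corr,
                    "rmse": r.rmse,
                    "n_test": r.n_test,
                    "row_norms": r.row_norms,
                    "selected_per_cell": r.selected_per_cell,
                }
                for r in self.per_fold
            ],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "PredictionReport":
        folds = [
            FoldRecord(
                fold=r["fold"],
                test_subjects=r["test_subjects"],
                hyperparameters=r["hyperparameters"],
                selected_indices=r["selected_indices"],
                norm_mean=r["norm_mean"],
                norm_sd=r["norm_sd"],
                corr=r["corr"],
                rmse=r["rmse"],
                n_test=r["n_test"],
                row_norms=r.get("row_norms"),
                selected_per_cell=r.get("selected_per_cell"),
            )
            for r in payload["per_fold"]
        ]
        return cls(
            method=payload["method"],
            time_labels=payload["time_labels"],
            score_names=payload["score_names"],
            feature_names=payload["feature_names"],
            fold_assignments=payload["fold_assignments"],
            per_fold=folds,
            corr_mean=payload["corr_mean"],
            corr_sd=payload["corr_sd"],
            rmse_mean=payload["rmse_mean"],
            rmse_sd=payload["rmse_sd"],
            schema_version=payload["schema_version"],
        )


# ---------------------------------------------------------------------------
# feature ranking and selection
# ---------------------------------------------------------------------------


def rank_features(
    fit_result: FitResult | np.ndarray,
    rule: str = "relative_threshold",
    rel_threshold: float = 1e-3,
    top_k: int | None = None,
) -> SelectionResult:
    """Rank features by descending unfolded row norm and select a subset.

    The iterative solver never produces exact zeros, so "non-zero rows" are
    identified numerically: the default rule keeps rows whose norm exceeds
    ``rel_threshold`` times the maximum row norm; ``rule="top_k"`` keeps the
    first ``top_k`` ranked features instead.  Ties are broken by ascending
    original feature index, making the ranking deterministic.
    """
    norms = (
        fit_result.row_norms
        if isinstance(fit_result, FitResult)
        else np.asarray(fit_result, dtype=float)
    )
    if not np.all(np.isfinite(norms)):
        raise ValueError("row norms must be finite")
    if np.all(norms == 0):
        raise EmptySelectionError("empty model: every weight row is zero")
    order = np.lexsort((np.arange(norms.size), -norms))
    if rule == "top_k":
        if top_k is None or top_k < 1:
            raise ValueError("top_k rule requires a positive top_k")
        selected = order[: min(top_k, norms.size)]
        descriptor = f"top_k({top_k})"
    elif rule == "relative_threshold":
        keep = norms > rel_threshold * norms.max()
        selected = np.array([i for i in order if keep[i]], dtype=int)
        descriptor = f"relative_threshold({rel_threshold})"
    else:
        raise ValueError(f"unknown selection rule {rule!r}")
    if selected.size == 0:
        raise EmptySelectionError("selection rule kept no features")
    return SelectionResult(
        ranked=order, selected=selected, row_norms=norms, selection_rule=descriptor
    )


# ---------------------------------------------------------------------------
# SVR prediction
# ---------------------------------------------------------------------------


def unit_norm_rows(values: np.ndarray) -> np.ndarray:
    """Scale each row to unit Euclidean norm (zero rows left unchanged)."""
    values = np.asarray(values, dtype=float)
    norms = np.linalg.norm(values, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return values / norms


class _ConstantPredictor:
    """Fallback when a training target is constant; flagged as degenerate."""

    degenerate = True

    def __init__(self, value: float):
        self.value = float(value)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.full(np.asarray(x).shape[0], self.value)


class _SvrCell:
    """Linear epsilon-SVR on unit-normalized rows of the selected features."""

    degenerate = False

    def __init__(self, c: float, epsilon: float):
        self._svr = SVR(kernel="linear", C=c, epsilon=epsilon)

    def fit(self, x: np.ndarray, y: np.ndarray) -> "_SvrCell":
        self._svr.fit(unit_norm_rows(x), y)
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self._svr.predict(unit_norm_rows(np.asarray(x, dtype=float)))


def train_predictors(
    x_selected: np.ndarray,
    y: ScoreTensor | np.ndarray,
    c: float = 1.0,
    epsilon: float = 0.1,
) -> list[list[object]]:
    """Train one independent predictor per (time, score) cell.

    Each cell gets a linear epsilon-SVR with toolbox-default parameters
    (cost 1, epsilon 0.1) on the selected feature columns after scaling
    every subject row to unit norm.  A constant training target yields a
    flagged constant predictor instead.
    """
    x_selected = np.asarray(x_selected, dtype=float)
    yv = y.values if isinstance(y, ScoreTensor) else np.asarray(y, dtype=float)
    if x_selected.shape[0] < 2:
        raise ValueError("need at least 2 training subjects")
    if x_selected.shape[1] < 1:
        raise ValueError("need at least 1 selected feature")
    if yv.shape[1] != x_selected.shape[0]:
        raise ValueError("subject counts of X and Y disagree")
    grid: list[list[object]] = []
    for t in range(yv.shape[0]):
        row: list[object] = []
        for j in range(yv.shape[2]):
            target = yv[t, :, j]
            if np.ptp(target) == 0:
                logger.warning("constant training target at cell (%d, %d)", t, j)
                row.append(_ConstantPredictor(target[0]))
            else:
                row.append(_SvrCell(c, epsilon).fit(x_selected, target))
        grid.append(row)
    return grid


def evaluate(predictions: np.ndarray, actual: np.ndarray) -> dict:
    """Pearson correlation and RMSE of predictions against observed values.

    When either vector is constant the correlation is undefined and
    reported as None (never silently imputed as 0); a warning is logged.
    """
    predictions = np.asarray(predictions, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if predictions.shape != actual.shape:
        raise ValueError("prediction and actual lengths differ")
    if predictions.size < 2:
        raise ValueError("need at least 2 values to evaluate")
    rmse = float(np.sqrt(np.mean((predictions - actual) ** 2)))
    if np.ptp(predictions) == 0 or np.ptp(actual) == 0:
        logger.warning("constant vector: Pearson correlation undefined")
        return {"corr": None, "corr_defined": False, "rmse": rmse}
    corr = float(stats.pearsonr(predictions, actual).statistic)
    return {"corr": corr, "corr_defined": True, "rmse": rmse}


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


def lambda_grid(
    lambda1_values: Sequence[float], lambda2_values: Sequence[float]
) -> list[tuple[float, float]]:
    """Cartesian grid of (lambda1, lambda2) pairs in deterministic order."""
    return [(float(a), float(b)) for a, b in product(lambda1_values, lambda2_values)]


DEFAULT_GRID = lambda_grid(
    [1e-3, 1e-2, 1e-1, 1.0, 10.0, 1e2, 1e3], [1e-3, 1e-2, 1e-1, 1.0, 10.0, 1e2, 1e3]
)


def _normalize_fold(x: FeatureMatrix, train_idx: np.ndarray):
    """Training-rows-only z-scoring applied to all rows; returns (X_norm, stats)."""
    ref = x.values[train_idx]
    mean = ref.mean(axis=0)
    sd = ref.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = x.feature_names[int(np.flatnonzero(sd == 0)[0])]
        raise ValueError(f"zero-variance column {bad!r} in training fold")
    norm = Normalization(mean=mean, sd=sd)
    return norm.apply(x.values), norm


def _predict_cells(
    predictors: list[list[object]], x_eval: np.ndarray
) -> np.ndarray:
    t_pts = len(predictors)
    c = len(predictors[0])
    out = np.empty((t_pts, x_eval.shape[0], c))
    for t in range(t_pts):
        for j in range(c):
            out[t, :, j] = predictors[t][j].predict(x_eval)
    return out


def _cell_metrics(pred: np.ndarray, actual: np.ndarray):
    """Per-cell corr/rmse over a (T, n, C) prediction block."""
    t_pts, _, c = pred.shape
    corr = [[None] * c for _ in range(t_pts)]
    rmse = [[0.0] * c for _ in range(t_pts)]
    for t in range(t_pts):
        for j in range(c):
            m = evaluate(pred[t, :, j], actual[t, :, j])
            corr[t][j] = m["corr"]
            rmse[t][j] = m["rmse"]
    return corr, rmse


def _summed_rmse(pred: np.ndarray, actual: np.ndarray) -> float:
    total = 0.0
    for t in range(pred.shape[0]):
        for j in range(pred.shape[2]):
            total += float(np.sqrt(np.mean((pred[t, :, j] - actual[t, :, j]) ** 2)))
    return total


def _aggregate(report: PredictionReport) -> None:
    t_pts = len(report.time_labels)
    c = len(report.score_names)
    corr_mean = [[None] * c for _ in range(t_pts)]
    corr_sd = [[None] * c for _ in range(t_pts)]
    rmse_mean = [[0.0] * c for _ in range(t_pts)]
    rmse_sd = [[0.0] * c for _ in range(t_pts)]
    for t in range(t_pts):
        for j in range(c):
            corrs = [
                r.corr[t][j] for r in report.per_fold if r.corr[t][j] is not None
            ]
            rmses = [r.rmse[t][j] for r in report.per_fold]
            if corrs:
                corr_mean[t][j] = float(np.mean(corrs))
                corr_sd[t][j] = float(np.std(corrs))
            rmse_mean[t][j] = float(np.mean(rmses))
            rmse_sd[t][j] = float(np.std(rmses))
    report.corr_mean = corr_mean
    report.corr_sd = corr_sd
    report.rmse_mean = rmse_mean
    report.rmse_sd = rmse_sd


def _outer_splits(n_subjects: int, outer_folds: int, seed: int):
    if n_subjects < 2 * outer_folds:
        raise ValueError(
            f"S={n_subjects} too small for {outer_folds}-fold cross-validation"
        )
    splitter = KFold(n_splits=outer_folds, shuffle=True, random_state=seed)
    return list(splitter.split(np.arange(n_subjects)))


def cross_validate(
    x: FeatureMatrix,
    y: ScoreTensor,
    grid: Sequence[tuple[float, float]] | None = None,
    seed: int = 0,
    *,
    outer_folds: int = 10,
    inner_folds: int = 5,
    base_config: FitConfig | None = None,
    selection_rule: str = "relative_threshold",
    rel_threshold: float = 1e-3,
    top_k: int | None = None,
    svr_c: float = 1.0,
    svr_epsilon: float = 0.1,
) -> PredictionReport:
    """Nested cross-validated evaluation of the joint selection model.

    Outer loop: seeded subject-level K-fold.  Per outer fold the features
    are z-scored with training statistics, an inner K-fold over ``grid``
    picks (lambda1, lambda2) by the validation RMSE summed over all
    (time, score) cells, the model is refit on the whole training fold, a
    single common feature subset is selected, and one SVR per cell predicts
    the held-out subjects.  Nothing derived from test rows enters training.
    """
    if grid is None:
        grid = DEFAULT_GRID
    grid = list(grid)
    if not grid:
        raise ValueError("hyperparameter grid is empty")
    base = base_config or FitConfig()
    splits = _outer_splits(x.n_subjects, outer_folds, seed)

    fold_assignments = np.empty(x.n_subjects, dtype=int)
    per_fold: list[FoldRecord] = []
    for fold_id, (train_idx, test_idx) in enumerate(splits):
        fold_assignments[test_idx] = fold_id
        x_norm, norm = _normalize_fold(x, train_idx)
        y_all = y.values

        if len(grid) > 1:
            chosen = _inner_select(
                x_norm, y_all, train_idx, grid, inner_folds, seed, base,
                selection_rule, rel_threshold, top_k, svr_c, svr_epsilon,
            )
        else:
            chosen = grid[0]
        lam1, lam2 = chosen

        cfg = FitConfig(
            lambda1=lam1,
            lambda2=lam2,
            max_iter=base.max_iter,
            tol=base.tol,
            epsilon_l21=base.epsilon_l21,
            sigma=base.sigma,
            ridge=base.ridge,
        )
        result = fit(x_norm[train_idx], y_all[:, train_idx, :], cfg)
        selection = rank_features(
            result, rule=selection_rule, rel_threshold=rel_threshold, top_k=top_k
        )
        cols = selection.selected
        predictors = train_predictors(
            x_norm[train_idx][:, cols], y_all[:, train_idx, :], svr_c, svr_epsilon
        )
        preds = _predict_cells(predictors, x_norm[test_idx][:, cols])
        corr, rmse = _cell_metrics(preds, y_all[:, test_idx, :])
        logger.info(
            "fold %d: lambda1=%g lambda2=%g selected %d/%d features, "
            "n_iter=%d converged=%s",
            fold_id, lam1, lam2, cols.size, x.n_features, result.n_iter,
            result.converged,
        )
        per_fold.append(
            FoldRecord(
                fold=fold_id,
                test_subjects=[int(i) for i in test_idx],
                hyperparameters={"lambda1": lam1, "lambda2": lam2},
                selected_indices=[int(i) for i in cols],
                norm_mean=[float(v) for v in norm.mean],
                norm_sd=[float(v) for v in norm.sd],
                corr=corr,
                rmse=rmse,
                n_test=int(test_idx.size),
                row_norms=[float(v) for v in selection.row_norms],
            )
        )

    report = PredictionReport(
        method="joint_graph_l21",
        time_labels=list(y.time_labels),
        score_names=list(y.score_names),
        feature_names=list(x.feature_names),
        fold_assignments=[int(v) for v in fold_assignments],
        per_fold=per_fold,
    )
    _aggregate(report)
    return report


def _inner_select(
    x_norm, y_all, train_idx, grid, inner_folds, seed, base,
    selection_rule, rel_threshold, top_k, svr_c, svr_epsilon,
) -> tuple[float, float]:
    """Inner K-fold over the lambda grid; returns the pair with the lowest
    mean validation RMSE summed over cells (ties resolved by grid order)."""
    inner = KFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    scores = np.full(len(grid), np.inf)
    inner_splits = list(inner.split(train_idx))
    for g, (lam1, lam2) in enumerate(grid):
        cfg = FitConfig(
            lambda1=lam1,
            lambda2=lam2,
            max_iter=base.max_iter,
            tol=base.tol,
            epsilon_l21=base.epsilon_l21,
            sigma=base.sigma,
            ridge=base.ridge,
        )
        fold_scores = []
        for tr, va in inner_splits:
            tr_rows = train_idx[tr]
            va_rows = train_idx[va]
            try:
                result = fit(x_norm[tr_rows], y_all[:, tr_rows, :], cfg)
                selection = rank_features(
                    result, rule=selection_rule,
                    rel_threshold=rel_threshold, top_k=top_k,
                )
                cols = selection.selected
                predictors = train_predictors(
                    x_norm[tr_rows][:, cols], y_all[:, tr_rows, :],
                    svr_c, svr_epsilon,
                )
                preds = _predict_cells(predictors, x_norm[va_rows][:, cols])
                fold_scores.append(_summed_rmse(preds, y_all[:, va_rows, :]))
            except (EmptySelectionError, ValueError) as exc:
                logger.debug("inner fold failed for grid point %d: %s", g, exc)
                fold_scores.append(np.inf)
        scores[g] = float(np.mean(fold_scores))
    best = int(np.argmin(scores))
    if not np.isfinite(scores[best]):
        raise ValueError("every grid point failed in the inner loop")
    return grid[best]


# ---------------------------------------------------------------------------
# lasso baseline
# ---------------------------------------------------------------------------


def lasso_select(
    x: np.ndarray, target: np.ndarray, alpha: float
) -> tuple[np.ndarray, np.ndarray]:
    """l1-penalized linear selection for a single task.

    Returns (coefficients, indices of nonzero coefficients).  ``alpha=0``
    falls back to ordinary least squares (every feature kept on full-rank
    input).
    """
    x = np.asarray(x, dtype=float)
    target = np.asarray(target, dtype=float)
    if alpha == 0:
        coef, *_ = np.linalg.lstsq(x, target, rcond=None)
        selected = np.flatnonzero(np.abs(coef) > 1e-10)
    else:
        model = Lasso(alpha=alpha, max_iter=50_000)
        model.fit(x, target)
        coef = model.coef_
        selected = np.flatnonzero(coef != 0)
    return coef, selected


def lasso_baseline(
    x: FeatureMatrix,
    y: ScoreTensor,
    grid: Sequence[float],
    seed: int = 0,
    *,
    outer_folds: int = 10,
    inner_folds: int = 5,
    svr_c: float = 1.0,
    svr_epsilon: float = 0.1,
) -> PredictionReport:
    """Per-task l1 selection + SVR under the identical CV protocol.

    Each (time, score) cell independently picks its own l1 penalty by inner
    cross-validation and its own feature subset, in contrast to the joint
    model's single shared subset.
    """
    grid = [float(a) for a in grid]
    if not grid:
        raise ValueError("alpha grid is empty")
    splits = _outer_splits(x.n_subjects, outer_folds, seed)
    t_pts, _, c = y.values.shape

    fold_assignments = np.empty(x.n_subjects, dtype=int)
    per_fold: list[FoldRecord] = []
    for fold_id, (train_idx, test_idx) in enumerate(splits):
        fold_assignments[test_idx] = fold_id
        x_norm, norm = _normalize_fold(x, train_idx)
        y_all = y.values
        inner = KFold(n_splits=inner_folds, shuffle=True, random_state=seed)
        inner_splits = list(inner.split(train_idx))

        chosen_alpha: dict[str, float] = {}
        selected_per_cell: dict[str, list[int]] = {}
        corr = [[None] * c for _ in range(t_pts)]
        rmse = [[0.0] * c for _ in range(t_pts)]
        union: set[int] = set()
        for t in range(t_pts):
            for j in range(c):
                target_all = y_all[t, :, j]
                if len(grid) > 1:
                    alpha = _inner_select_lasso(
                        x_norm, target_all, train_idx, grid, inner_splits,
                        svr_c, svr_epsilon,
                    )
                else:
                    alpha = grid[0]
                _, cols = lasso_select(
                    x_norm[train_idx], target_all[train_idx], alpha
                )
                if cols.size == 0:
                    raise EmptySelectionError(
                        f"lasso kept no features at alpha={alpha} "
                        f"for cell ({t}, {j})"
                    )
                cell = _fit_svr_cell(
                    x_norm[train_idx][:, cols], target_all[train_idx],
                    svr_c, svr_epsilon,
                )
                pred = cell.predict(x_norm[test_idx][:, cols])
                m = evaluate(pred, target_all[test_idx])
                corr[t][j] = m["corr"]
                rmse[t][j] = m["rmse"]
                key = f"{t},{j}"
                chosen_alpha[key] = alpha
                selected_per_cell[key] = [int(i) for i in cols]
                union.update(int(i) for i in cols)

        per_fold.append(
            FoldRecord(
                fold=fold_id,
                test_subjects=[int(i) for i in test_idx],
                hyperparameters={"alpha": chosen_alpha},
                selected_indices=sorted(union),
                norm_mean=[float(v) for v in norm.mean],
                norm_sd=[float(v) for v in norm.sd],
                corr=corr,
                rmse=rmse,
                n_test=int(test_idx.size),
                selected_per_cell=selected_per_cell,
            )
        )

    report = PredictionReport(
        method="lasso_per_task",
        time_labels=list(y.time_labels),
        score_names=list(y.score_names),
        feature_names=list(x.feature_names),
        fold_assignments=[int(v) for v in fold_assignments],
        per_fold=per_fold,
    )
    _aggregate(report)
    return report


def _fit_svr_cell(x_cols, target, svr_c, svr_epsilon):
    if np.ptp(target) == 0:
        return _ConstantPredictor(target[0])
    return _SvrCell(svr_c, svr_epsilon).fit(x_cols, target)


def _inner_select_lasso(
    x_norm, target_all, train_idx, grid, inner_splits, svr_c, svr_epsilon
) -> float:
    scores = np.full(len(grid), np.inf)
    for g, alpha in enumerate(grid):
        fold_scores = []
        for tr, va in inner_splits:
            tr_rows = train_idx[tr]
            va_rows = train_idx[va]
            _, cols = lasso_select(x_norm[tr_rows], target_all[tr_rows], alpha)
            if cols.size == 0:
                fold_scores.append(np.inf)
                continue
            cell = _fit_svr_cell(
                x_norm[tr_rows][:, cols], target_all[tr_rows], svr_c, svr_epsilon
            )
            pred = cell.predict(x_norm[va_rows][:, cols])
            fold_scores.append(float(np.sqrt(np.mean((pred - target_all[va_rows]) ** 2))))
        scores[g] = float(np.mean(fold_scores))
    best = int(np.argmin(scores))
    if not np.isfinite(scores[best]):
        raise EmptySelectionError("every alpha produced an empty selection")
    return grid[best]


# ---------------------------------------------------------------------------
# region stability report
# ---------------------------------------------------------------------------


def region_frequency_report(
    report: PredictionReport,
    feature_names: Sequence[str] | None = None,
    k: int = 30,
) -> pd.DataFrame:
    """Top-k features by selection frequency across cross-validation folds.

    Frequency is the fraction of folds in which the feature was selected;
    mean_weight is the mean (over folds) of its unfolded row norm when
    available.  Sorted by frequency desc, mean weight desc, index asc.
    Features never selected in any fold are excluded.
    """
    if feature_names is None:
        feature_names = report.feature_names
    n_features = len(feature_names)
    if k > n_features:
        raise ValueError(f"k={k} exceeds the number of features {n_features}")
    n_folds = len(report.per_fold)
    counts = np.zeros(n_features)
    weight_sums = np.zeros(n_features)
    have_weights = all(r.row_norms is not None for r in report.per_fold)
    for rec in report.per_fold:
        for i in rec.selected_indices:
            counts[i] += 1
        if have_weights:
            weight_sums += np.asarray(rec.row_norms)
    freq = counts / n_folds
    mean_weight = weight_sums / n_folds if have_weights else np.zeros(n_features)
    ever = np.flatnonzero(counts > 0)
    order = sorted(ever, key=lambda i: (-freq[i], -mean_weight[i], i))
    top = order[:k]
    return pd.DataFrame(
        {
            "feature_name": [feature_names[i] for i in top],
            "feature_index": top,
            "frequency": [freq[i] for i in top],
            "mean_weight": [mean_weight[i] for i in top],
            "rank": np.arange(1, len(top) + 1),
        }
    )
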