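"""Per-species random-forest distribution models.

Presence-absence of each species is modelled from the environmental
predictors with both flavours of random forest: a regression forest on
the 0/1 response, whose prediction is read as an occurrence probability,
and a classification forest predicting the class directly.  Model skill
is estimated by stratified tenfold cross-validation (AUC and Cohen's
kappa); regression probabilities are converted to presence/absence with
the sensitivity-specificity difference minimizer threshold.

Defaults follow common SDM practice for this model family: 1000 trees,
mtry of p/3 (regression) or sqrt(p) (classification), permutation
importance over 10 shuffles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .rasters import EnvStack, GridSpec

Kind = Literal["regression", "classification"]


@dataclass
class RFConfig:
    n_trees: int = 1000
    importance_permutations: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")

    def mtry(self, p: int, kind: Kind) -> int:
        """Number of candidate predictors per split: p/3 for regression
        forests, sqrt(p) for classification forests (floored, >= 1)."""
        m = p // 3 if kind == "regression" else int(math.isqrt(p))
        return min(max(1, m), p)


@dataclass
class CVMetrics:
    """Per-fold and mean cross-validation scores for one species."""

    auc_folds: list[float] = field(default_factory=list)
    kappa_regression_folds: list[float] = field(default_factory=list)
    kappa_classification_folds: list[float] = field(default_factory=list)

    @property
    def auc(self) -> float:
        return float(np.mean(self.auc_folds)) if self.auc_folds else float("nan")

    @property
    def kappa_regression(self) -> float:
        return float(np.mean(self.kappa_regression_folds)) if self.kappa_regression_folds else float("nan")

    @property
    def kappa_classification(self) -> float:
        return float(np.mean(self.kappa_classification_folds)) if self.kappa_classification_folds else float("nan")

    def as_dict(self) -> dict[str, float]:
        return {
            "auc": self.auc,
            "kappa_regression": self.kappa_regression,
            "kappa_classification": self.kappa_classification,
        }


@dataclass
class SpeciesSDM:
    """One species' fitted forest plus evaluation artifacts."""

    species: str
    kind: Kind
    model: object
    predictors: list[str]
    importance: pd.Series  # permutation importance, descending
    threshold: float | None = None  # regression kind only
    cv: CVMetrics | None = None


@dataclass
class PredictionGrid:
    """Equispaced prediction points with probability and binary layers.

    ``valid`` marks points with complete predictors; invalid points are
    no-prediction, distinct from predicted absence.
    """

    grid: GridSpec
    x: np.ndarray
    y: np.ndarray
    probability: np.ndarray
    present: np.ndarray
    valid: np.ndarray

    def binary_map(self) -> np.ndarray:
        """Presence as a (n_rows, n_cols) float array, NaN where invalid."""
        out = np.where(self.valid, self.present.astype(float), np.nan)
        return out.reshape(self.grid.n_rows, self.grid.n_cols)

    def probability_map(self) -> np.ndarray:
        out = np.where(self.valid, self.probability, np.nan)
        return out.reshape(self.grid.n_rows, self.grid.n_cols)


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve, tie-aware: the probability that a
    random presence outscores a random absence, ties counted half."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC needs both presences and absences")
    return float(roc_auc_score(labels, scores))


def cohens_kappa(predicted: Sequence[int], observed: Sequence[int]) -> float:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e).

    When both vectors are degenerate (chance agreement p_e = 1) the
    statistic is undefined; 0 is returned with a warning, reading "no
    better than chance" for constant predictions.
    """
    pred = np.asarray(predicted).astype(int)
    obs = np.asarray(observed).astype(int)
    if pred.shape != obs.shape:
        raise ValueError("predicted and observed must have equal length")
    n = pred.size
    p_o = float(np.mean(pred == obs))
    p_e = 0.0
    for c in (0, 1):
        p_e += float(np.mean(pred == c)) * float(np.mean(obs == c))
    if np.isclose(p_e, 1.0):
        warnings.warn("kappa undefined (chance agreement = 1); returning 0", stacklevel=2)
        return 0.0
    return (p_o - p_e) / (1.0 - p_e)


def select_threshold(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Probability cutoff by the sensitivity-specificity difference
    minimizer: over candidate thresholds (the unique score values, with
    presence predicted when score >= t) return the t minimizing
    |sensitivity - specificity|, ties resolved toward the smallest t."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("threshold selection needs both classes")
    candidates = np.unique(scores)  # ascending
    # at threshold t: sens = P(score >= t | pos), spec = P(score < t | neg);
    # compare |sens - spec| in integer arithmetic (x n_pos n_neg) so exact
    # ties resolve to the smallest candidate instead of float noise
    pos_below = np.searchsorted(np.sort(scores[labels == 1]), candidates, side="left")
    neg_below = np.searchsorted(np.sort(scores[labels == 0]), candidates, side="left")
    gap = np.abs((n_pos - pos_below) * n_neg - neg_below * n_pos)
    return float(candidates[int(np.argmin(gap))])  # argmin takes first = smallest t


def stratified_folds(
    labels: Sequence[int], k: int = 10, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified fold assignment (sampling without replacement):
    (train_idx, test_idx) pairs preserving the class ratio per fold."""
    y = np.asarray(labels).astype(int)
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in splitter.split(np.zeros((y.size, 1)), y)]


def _make_forest(kind: Kind, p: int, config: RFConfig, seed: int):
    mtry = config.mtry(p, kind)
    if kind == "regression":
        return RandomForestRegressor(
            n_estimators=config.n_trees, max_features=mtry,
            oob_score=True, random_state=seed, n_jobs=1,
        )
    return RandomForestClassifier(
        n_estimators=config.n_trees, max_features=mtry,
        oob_score=True, random_state=seed, n_jobs=1,
    )


def _scores(model, kind: Kind, X: np.ndarray) -> np.ndarray:
    if kind == "regression":
        return np.clip(model.predict(X), 0.0, 1.0)
    return model.predict_proba(X)[:, list(model.classes_).index(1)]


def fit_rf(
    features: pd.DataFrame,
    response: Sequence[int],
    kind: Kind = "regression",
    config: RFConfig | None = None,
    compute_importance: bool = True,
) -> SpeciesSDM:
    """Fit one species' forest on the full feature table.

    The regression kind also learns its presence threshold from the
    out-of-bag score distribution, so downstream maps never threshold
    on resubstitution scores.
    """
    config = config or RFConfig()
    y = np.asarray(response).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("response has a single class; a distribution model needs both")
    X = features.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("features contain missing values")
    model = _make_forest(kind, X.shape[1], config, config.seed)
    model.fit(X, y)

    if compute_importance:
        imp = permutation_importance(
            model, X, y, n_repeats=config.importance_permutations,
            random_state=config.seed, n_jobs=1,
        )
        importance = pd.Series(imp.importances_mean, index=features.columns).sort_values(ascending=False)
    else:
        importance = pd.Series(dtype=float)

    threshold = None
    if kind == "regression":
        oob = np.clip(model.oob_prediction_, 0.0, 1.0)
        ok = ~np.isnan(oob)  # samples never out-of-bag (tiny forests) carry no OOB score
        threshold = select_threshold(oob[ok], y[ok])
    name = getattr(response, "name", None) or "species"
    return SpeciesSDM(
        species=str(name), kind=kind, model=model,
        predictors=list(features.columns), importance=importance, threshold=threshold,
    )


def cross_validate(
    features: pd.DataFrame,
    response: Sequence[int],
    k: int = 10,
    kinds: Sequence[Kind] = ("regression", "classification"),
    config: RFConfig | None = None,
) -> CVMetrics:
    """Stratified k-fold cross-validation of both forest kinds.

    Folds preserve the presence/absence ratio; each iteration trains on
    k-1 folds (90% of records at k=10) and scores the held-out fold.
    The regression kind reports AUC and kappa, the latter after the
    sensitivity-specificity threshold learned on the held-out fold's own
    score distribution; the classification kind reports kappa only.
    """
    config = config or RFConfig()
    y = np.asarray(response).astype(int)
    n_pos, n_neg = int(y.sum()), int((y == 0).sum())
    if min(n_pos, n_neg) < k:
        raise ValueError(
            f"need at least {k} records of each class for stratified {k}-fold CV "
            f"(have {n_pos} presences, {n_neg} absences)"
        )
    X = features.to_numpy(dtype=float)
    metrics = CVMetrics()
    for fold_i, (tr, te) in enumerate(stratified_folds(y, k, config.seed)):
        for kind in kinds:
            model = _make_forest(kind, X.shape[1], config, config.seed + fold_i)
            model.fit(X[tr], y[tr])
            s = _scores(model, kind, X[te])
            if kind == "regression":
                metrics.auc_folds.append(auc(s, y[te]))
                t = select_threshold(s, y[te])
                metrics.kappa_regression_folds.append(cohens_kappa((s >= t).astype(int), y[te]))
            else:
                metrics.kappa_classification_folds.append(cohens_kappa(model.predict(X[te]), y[te]))
    return metrics


def prediction_points(env: EnvStack, grid_step: float = 100.0) -> GridSpec:
    """Equispaced prediction grid covering the stack extent."""
    g = env.grid
    n_cols = max(1, int(g.width // grid_step))
    n_rows = max(1, int(g.height // grid_step))
    return GridSpec(n_rows=n_rows, n_cols=n_cols, cell_size=grid_step, x0=g.x0, y0=g.y0)


def predict_grid(model: SpeciesSDM, env: EnvStack, grid_step: float = 100.0) -> PredictionGrid:
    """Predict probability and thresholded presence on an equispaced
    grid of points; presence is probability >= threshold (inclusive)."""
    missing = [p for p in model.predictors if p not in env.layers]
    if missing:
        raise ValueError(f"environment stack lacks predictors {missing}")
    pgrid = prediction_points(env, grid_step)
    gx, gy = pgrid.cell_centers()
    x, y = gx.ravel(), gy.ravel()
    sampled = env.sample(x, y)
    X = np.column_stack([sampled[p] for p in model.predictors])
    valid = ~np.isnan(X).any(axis=1)
    if not valid.any():
        raise ValueError("prediction grid does not overlap valid environment data")
    prob = np.full(x.size, np.nan)
    prob[valid] = _scores(model.model, model.kind, X[valid])
    if model.kind == "regression":
        if model.threshold is None:
            raise ValueError("regression model has no threshold")
        present = (prob >= model.threshold) & valid
    else:
        present = (prob >= 0.5) & valid
    return PredictionGrid(
        grid=pgrid, x=x, y=y, probability=prob,
        present=present.astype(np.int8), valid=valid,
    )


def cv_table(results: dict[str, CVMetrics]) -> pd.DataFrame:
    """Per-species CV summary plus an 'average' row, mirroring the usual
    reporting layout (species, AUC, kappa by model kind)."""
    rows = {sp: m.as_dict() for sp, m in results.items()}
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.loc["average"] = table.mean()
    table.index.name = "species"
    return table
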