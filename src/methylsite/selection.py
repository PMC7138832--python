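"""PCC-ranked stepwise feature selection and RBF-SVM model fitting.

Per feature subtype, features are ranked by the absolute Pearson correlation
between the feature column and the binary label vector, then added greedily
down the ranked list: a candidate is kept only when the stratified
cross-validated SVM accuracy *strictly* increases.  The surviving columns of
all subtypes are concatenated, standardised, and an RBF SVM is fitted with
(C, gamma) chosen from the classic log2 grid (C = 2^-5..2^15, gamma =
2^-15..2^3, step 2^2), ties broken toward the simpler model (smaller C,
then smaller gamma).

Both stages are exposed as sklearn estimators (:class:`StepwiseSubtypeSelector`,
:class:`SubtypeSvmClassifier`) so they compose with pipelines and model
selection; everything is deterministic under ``random_state``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

DEFAULT_C_GRID = tuple(2.0 ** e for e in range(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(2.0 ** e for e in range(-15, 4, 2))


def pearson_cc(x, y) -> float:
    """Pearson correlation between a feature vector and a 0/1 label vector.

    Defined as 0 when either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 2:
        raise ValueError("need at least two observations")
    if np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def rank_by_pcc(X: np.ndarray, y) -> np.ndarray:
    """Column indices ordered by |PCC| descending (ties: lower index first)."""
    X = np.asarray(X, dtype=float)
    scores = np.array([abs(pearson_cc(X[:, j], y)) for j in range(X.shape[1])])
    return np.argsort(-scores, kind="stable")


@dataclass(frozen=True)
class SVMParams:
    """RBF-kernel SVM hyper-parameters."""

    C: float
    gamma: float
    cv_accuracy: float = float("nan")
    class_weight: str | None = None

    def __post_init__(self):
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")


def _cv(cv_folds, y, random_state):
    counts = np.bincount(np.asarray(y, dtype=int))
    n_splits = min(cv_folds, int(counts[counts > 0].min()))
    if n_splits < 2:
        raise ValueError("need at least two instances per class for CV")
    return StratifiedKFold(n_splits=n_splits, shuffle=True,
                           random_state=random_state)


class StepwiseSubtypeSelector(BaseEstimator, TransformerMixin):
    """Greedy forward selection over a PCC-ranked feature list.

    The first-ranked feature is always kept; each further candidate (in rank
    order, optionally capped at ``max_candidates``) is accepted iff the
    stratified ``cv``-fold CV accuracy of a standardised RBF SVM on the
    current set plus the candidate strictly increases.  Accepted step
    accuracies are strictly increasing by construction.

    Attributes
    ----------
    ranked_ : feature indices by |PCC| descending
    selected_ : accepted indices, in rank order
    trace_ : list of (feature index, cv accuracy, accepted flag)
    """

    def __init__(self, cv=5, random_state=0, C=1.0, gamma="scale",
                 max_candidates=None):
        self.cv = cv
        self.random_state = random_state
        self.C = C
        self.gamma = gamma
        self.max_candidates = max_candidates

    def _cv_accuracy(self, X, y, cols, splitter):
        model = make_pipeline(
            StandardScaler(), SVC(kernel="rbf", C=self.C, gamma=self.gamma)
        )
        return float(
            cross_val_score(model, X[:, cols], y, cv=splitter,
                            scoring="accuracy").mean()
        )

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("labels contain a single class")
        splitter = _cv(self.cv, y, self.random_state)
        self.ranked_ = rank_by_pcc(X, y)
        candidates = self.ranked_
        if self.max_candidates is not None:
            candidates = candidates[: self.max_candidates]
        selected = [int(candidates[0])]
        best = self._cv_accuracy(X, y, selected, splitter)
        trace = [(selected[0], best, True)]
        for j in candidates[1:]:
            acc = self._cv_accuracy(X, y, selected + [int(j)], splitter)
            accept = acc > best
            trace.append((int(j), acc, accept))
            if accept:
                selected.append(int(j))
                best = acc
        self.selected_ = np.array(selected, dtype=int)
        self.trace_ = trace
        self.best_accuracy_ = best
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        return np.asarray(X, dtype=float)[:, self.selected_]

    def get_support(self, indices: bool = False):
        if indices:
            return self.selected_.copy()
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.selected_] = True
        return mask


def grid_search_svm(X, y, C_grid=None, gamma_grid=None, cv_folds=5,
                    seed=0, class_weight=None) -> SVMParams:
    """Pick (C, gamma) maximising stratified CV accuracy on the log2 grid.

    Ties break toward smaller C, then smaller gamma.  ``X`` is standardised
    internally fold-by-fold.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if np.all(X == X[0]):
        raise ValueError("degenerate X: all rows identical")
    C_grid = DEFAULT_C_GRID if C_grid is None else tuple(C_grid)
    gamma_grid = DEFAULT_GAMMA_GRID if gamma_grid is None else tuple(gamma_grid)
    splitter = _cv(cv_folds, y, seed)
    best = None
    for C in sorted(C_grid):
        for gamma in sorted(gamma_grid):
            model = make_pipeline(
                StandardScaler(),
                SVC(kernel="rbf", C=C, gamma=gamma, class_weight=class_weight),
            )
            acc = float(
                cross_val_score(model, X, y, cv=splitter, scoring="accuracy").mean()
            )
            if best is None or acc > best.cv_accuracy:
                best = SVMParams(C=C, gamma=gamma, cv_accuracy=acc,
                                 class_weight=class_weight)
    return best


class SubtypeSvmClassifier(BaseEstimator, ClassifierMixin):
    """Per-subtype stepwise selection + grid-searched RBF SVM.

    ``feature_groups`` maps subtype name -> column indices of ``X``.  Each
    subtype is reduced independently; the union of selected columns feeds a
    standardised SVM whose (C, gamma) come from :func:`grid_search_svm`.
    Probability outputs use Platt scaling fitted inside cross-validation.
    """

    def __init__(self, feature_groups=None, do_selection=True, cv=5,
                 random_state=0, max_candidates=None, C_grid=None,
                 gamma_grid=None, class_weight=None):
        self.feature_groups = feature_groups
        self.do_selection = do_selection
        self.cv = cv
        self.random_state = random_state
        self.max_candidates = max_candidates
        self.C_grid = C_grid
        self.gamma_grid = gamma_grid
        self.class_weight = class_weight

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        groups = self.feature_groups or {"all": np.arange(X.shape[1])}
        self.selectors_ = {}
        support: list[int] = []
        if self.do_selection:
            for name, cols in groups.items():
                cols = np.asarray(cols, dtype=int)
                if cols.size == 0:
                    continue
                sel = StepwiseSubtypeSelector(
                    cv=self.cv, random_state=self.random_state,
                    max_candidates=self.max_candidates,
                )
                sel.fit(X[:, cols], y)
                self.selectors_[name] = sel
                support.extend(cols[sel.selected_].tolist())
        else:
            for cols in groups.values():
                support.extend(np.asarray(cols, dtype=int).tolist())
        self.support_ = np.array(sorted(support), dtype=int)
        Xs = X[:, self.support_]
        # guard: constant columns across the board
        if np.all(Xs == Xs[0]):
            raise ValueError("selected feature matrix is degenerate")
        self.svm_params_ = grid_search_svm(
            Xs, y, C_grid=self.C_grid, gamma_grid=self.gamma_grid,
            cv_folds=self.cv, seed=self.random_state,
            class_weight=self.class_weight,
        )
        self.scaler_ = StandardScaler().fit(Xs)
        # probability outputs: Platt scaling fitted inside cross-validation
        base = SVC(
            kernel="rbf", C=self.svm_params_.C, gamma=self.svm_params_.gamma,
            class_weight=self.class_weight,
        )
        calib_cv = _cv(self.cv, y, self.random_state)
        self.estimator_ = CalibratedClassifierCV(
            base, method="sigmoid", cv=calib_cv, ensemble=False
        ).fit(self.scaler_.transform(Xs), y)
        self.classes_ = self.estimator_.classes_
        self.cv_accuracy_ = self.svm_params_.cv_accuracy
        return self

    def _reduce(self, X):
        return self.scaler_.transform(np.asarray(X, dtype=float)[:, self.support_])

    def predict(self, X):
        return self.estimator_.predict(self._reduce(X))

    def predict_proba(self, X):
        return self.estimator_.predict_proba(self._reduce(X))

    def positive_proba(self, X) -> np.ndarray:
        """P(methylated) for each row."""
        proba = self.predict_proba(X)
        pos_col = int(np.where(self.classes_ == 1)[0][0])
        return proba[:, pos_col]
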