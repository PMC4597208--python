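"""Correlation-shrinkage protein selection and double (nested) cross-validation.

The prediction model follows the shrunken-centroid (PAM) recipe transplanted
onto a soft-margin Gaussian-kernel SVM:

1. screen: Pearson correlation r_p of every protein's abundance ratio with
   the observed CRP change (a continuous score, not the binary flag);
2. shrink: zero out proteins with |r_p| below a threshold, keep the rest;
3. tune: pick the threshold with the lowest inner-cross-validation
   misclassification error on the training fold (ties go to the larger
   threshold, i.e. the smaller protein set);
4. classify: RBF-kernel SVM with the package-default hyperparameters
   (cost 1, kernel width 1/p on standardized features) and Platt-sigmoid
   class probabilities.

``double_cv`` wraps steps 1-4 in an outer leave-one-out loop. In
``mode="nested"`` the screening correlations are recomputed inside every
outer training fold, so the held-out patient never influences feature
selection. ``mode="paper"`` screens once on the full cohort -- the variant
that computes correlations "in all patients" before cross-validating, which
leaks outcome information into selection and is kept only to demonstrate
and quantify that optimism.

Patients are processed in canonical (sorted-identifier) order internally,
so results are invariant to the row order of the input tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.svm import SVC

try:  # low-level libsvm binding: same solver as SVC without per-call overhead
    from sklearn.svm import _libsvm

    _libsvm.set_verbosity_wrap(0)
    _HAVE_LIBSVM = True
except Exception:  # pragma: no cover - fallback to the public estimator
    _HAVE_LIBSVM = False

from .cohortio import OutcomeVector, ProteinMatrix
from .evaluation import ConfusionCounts, confusion_metrics

__all__ = [
    "FeatureScreen",
    "SvmClassifier",
    "SignatureModel",
    "CVResult",
    "EmptySelectionError",
    "pearson_screen",
    "default_grid",
    "shrink_select",
    "fit_classifier",
    "choose_threshold",
    "double_cv",
    "final_signature",
]

DEFAULT_COST = 1.0
DEFAULT_GRID_SIZE = 40
#: Quantile of |r| capping the default threshold grid; guarantees a
#: non-empty selection at every grid point.
GRID_UPPER_QUANTILE = 0.95


class EmptySelectionError(ValueError):
    """Every protein was shrunk to zero at the requested threshold."""


@dataclass(frozen=True)
class FeatureScreen:
    """Per-protein Pearson correlations with the CRP change."""

    protein_ids: tuple[str, ...]
    r: np.ndarray

    def __post_init__(self) -> None:
        if len(self.protein_ids) != len(self.r):
            raise ValueError("one correlation per protein required")

    def as_series(self) -> pd.Series:
        return pd.Series(self.r, index=list(self.protein_ids), name="pearson_r")


def pearson_screen(matrix: ProteinMatrix, delta_crp: Sequence[float]) -> FeatureScreen:
    """Product-moment correlation of each protein with the CRP change.

    Constant proteins (zero variance) get r = 0 with a warning rather than
    NaN, so they are simply never selected.
    """
    X = matrix.values.to_numpy(dtype=float)
    y = np.asarray(delta_crp, dtype=float)
    if y.shape[0] != X.shape[0]:
        raise ValueError(
            f"outcome length {y.shape[0]} does not match patient count {X.shape[0]}"
        )
    if X.shape[0] < 3:
        raise ValueError("screening needs at least 3 patients")
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    degenerate = (sx == 0) | (sy == 0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} constant protein(s) (or constant outcome); "
            "their correlation is defined as 0",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc * yc[:, None]).sum(axis=0) / (sx * sy)
    r[~np.isfinite(r)] = 0.0
    r = np.clip(r, -1.0, 1.0)
    return FeatureScreen(protein_ids=tuple(matrix.protein_ids), r=r)


def default_grid(screen: FeatureScreen, n_points: int = DEFAULT_GRID_SIZE) -> np.ndarray:
    """Evenly spaced thresholds from 0 to the 95th percentile of |r|."""
    upper = float(np.quantile(np.abs(screen.r), GRID_UPPER_QUANTILE))
    return np.linspace(0.0, upper, n_points)


def shrink_select(screen: FeatureScreen, threshold: float) -> list[str]:
    """Proteins surviving the shrinkage: those with |r| >= threshold."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    keep = np.abs(screen.r) >= threshold
    if not keep.any():
        raise EmptySelectionError(f"no protein has |r| >= {threshold}")
    return [pid for pid, k in zip(screen.protein_ids, keep) if k]


class SvmClassifier:
    """RBF-kernel SVM with training-fold standardization and Platt probabilities.

    Mirrors the defaults of the classical e1071 SVM: cost 1, kernel width
    gamma = 1/p after standardizing each feature to zero mean and unit
    variance with training statistics only, and a sigmoid fit on decision
    values via internal 3-fold cross-validation for class probabilities.
    Deterministic: internal folds are stratified without shuffling, and
    callers present training rows in canonical patient order.
    """

    def __init__(self, cost: float = DEFAULT_COST, seed: int = 0, probability: bool = True):
        self.cost = cost
        self.seed = seed
        self.probability = probability
        self._svc: SVC | None = None
        self._cal = None

    def fit(self, X: np.ndarray, events: np.ndarray) -> "SvmClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(events, dtype=bool)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("need at least 2 training patients")
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        self._mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        self._sd = np.where(sd == 0, 1.0, sd)
        Z = (X - self._mean) / self._sd
        gamma = 1.0 / X.shape[1]
        self._svc = SVC(C=self.cost, kernel="rbf", gamma=gamma)
        self._svc.fit(Z, y)
        self._cal = None
        if self.probability:
            # Platt sigmoid on decision values, fitted by internal
            # stratified 3-fold CV (fewer folds if a class is tiny).
            folds = min(3, int(y.sum()), int((~y).sum()))
            if folds >= 2:
                cal = CalibratedClassifierCV(
                    SVC(C=self.cost, kernel="rbf", gamma=gamma),
                    method="sigmoid",
                    cv=folds,
                    ensemble=False,
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    self._cal = cal.fit(Z, y)
        return self

    def _transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self._mean) / self._sd

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """P(event) per row (calibrated; falls back to a logistic map of the
        decision values when a class was too small for internal CV)."""
        if self._svc is None:
            raise RuntimeError("classifier not fitted")
        if self._cal is not None:
            col = int(np.flatnonzero(self._cal.classes_ == True)[0])  # noqa: E712
            return self._cal.predict_proba(self._transform(X))[:, col]
        return 1.0 / (1.0 + np.exp(-self.decision_function(X)))

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self._svc is None:
            raise RuntimeError("classifier not fitted")
        return self._svc.predict(self._transform(X)).astype(bool)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        if self._svc is None:
            raise RuntimeError("classifier not fitted")
        d = self._svc.decision_function(self._transform(X))
        # orient so larger = more event-like
        return d if bool(self._svc.classes_[1]) else -d


def fit_classifier(
    X: np.ndarray | pd.DataFrame,
    events: Sequence[bool],
    cost: float = DEFAULT_COST,
    seed: int = 0,
    probability: bool = True,
) -> SvmClassifier:
    """Fit the RBF-SVM on a (patients x selected proteins) block."""
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    return SvmClassifier(cost=cost, seed=seed, probability=probability).fit(
        X, np.asarray(events, dtype=bool)
    )


# ---------------------------------------------------------------------------
# threshold tuning (inner loop)
# ---------------------------------------------------------------------------


def _inner_fold_labels(y: np.ndarray, k: int) -> np.ndarray:
    """Deterministic stratified fold assignment (cyclic within class)."""
    folds = np.empty(len(y), dtype=int)
    for cls in (False, True):
        idx = np.flatnonzero(y == cls)
        folds[idx] = np.arange(len(idx)) % k
    return folds


def _misclassification(X: np.ndarray, y: np.ndarray, inner: str | int, cost: float) -> int:
    """Inner-CV misclassification count for one candidate protein set.

    ``inner="loo"`` is exact leave-one-out; an integer requests
    deterministic stratified k-fold. Plain (uncalibrated) SVM class labels
    are used -- probability calibration plays no role in the error estimate.
    Single-class inner training folds fall back to majority vote.
    """
    n = len(y)
    if inner == "loo":
        folds = np.arange(n)
        k = n
    else:
        k = int(inner)
        folds = _inner_fold_labels(y, k)
    gamma = 1.0 / X.shape[1]
    errors = 0
    for f in range(k):
        test = folds == f
        train = ~test
        ytr = y[train]
        if ytr.all() or not ytr.any():
            pred = np.full(int(test.sum()), ytr[0] if len(ytr) else True)
        else:
            Xtr = X[train]
            mean = Xtr.mean(axis=0)
            sd = Xtr.std(axis=0, ddof=0)
            sd[sd == 0] = 1.0
            Ztr = np.ascontiguousarray((Xtr - mean) / sd)
            Zte = np.ascontiguousarray((X[test] - mean) / sd)
            if _HAVE_LIBSVM:
                model = _libsvm.fit(
                    Ztr, ytr.astype(np.float64), svm_type=0, kernel="rbf",
                    C=cost, gamma=gamma, tol=1e-3,
                )
                pred = _libsvm.predict(
                    Zte, *model[:7], svm_type=0, kernel="rbf", gamma=gamma
                ) > 0.5
            else:
                svc = SVC(C=cost, kernel="rbf", gamma=gamma).fit(Ztr, ytr)
                pred = svc.predict(Zte).astype(bool)
        errors += int((pred != y[test]).sum())
    return errors


@dataclass(frozen=True)
class ThresholdChoice:
    threshold: float
    errors: dict[float, float]       # grid value -> inner misclassification count
    set_sizes: dict[float, int]      # grid value -> surviving protein count


def choose_threshold(
    X: pd.DataFrame,
    events: Sequence[bool],
    screen: FeatureScreen,
    grid: Sequence[float],
    inner: str | int = "loo",
    cost: float = DEFAULT_COST,
) -> ThresholdChoice:
    """Pick the shrinkage threshold with minimal inner-CV prediction error.

    Grid values whose selection is empty are skipped; if every value is
    empty an :class:`EmptySelectionError` is raised. Identical protein sets
    arising at different thresholds are evaluated once. Ties are broken
    toward the larger threshold (fewer proteins).
    """
    grid = list(grid)
    if not grid:
        raise ValueError("threshold grid is empty")
    y = np.asarray(events, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("training cohort must contain both classes")
    Xall = X.to_numpy(dtype=float)
    col_of = {pid: j for j, pid in enumerate(X.columns)}

    errors: dict[float, float] = {}
    sizes: dict[float, int] = {}
    cache: dict[frozenset, int] = {}
    for t in grid:
        try:
            sel = shrink_select(screen, t)
        except EmptySelectionError:
            continue
        key = frozenset(sel)
        if key not in cache:
            cols = [col_of[pid] for pid in sel]
            cache[key] = _misclassification(Xall[:, cols], y, inner, cost)
        errors[t] = cache[key]
        sizes[t] = len(sel)
    if not errors:
        raise EmptySelectionError("all grid values yield empty protein selections")
    best_err = min(errors.values())
    best = max(t for t, e in errors.items() if e == best_err)
    return ThresholdChoice(threshold=float(best), errors=errors, set_sizes=sizes)


# ---------------------------------------------------------------------------
# outer loop
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SignatureModel:
    """A fitted signature: selected proteins, threshold, classifier, cutoff."""

    selected_proteins: tuple[str, ...]
    threshold: float
    classifier: SvmClassifier
    probability_cutoff: float
    screen: FeatureScreen

    def predict_proba(self, matrix: ProteinMatrix) -> pd.Series:
        X = matrix.values[list(self.selected_proteins)].to_numpy(dtype=float)
        return pd.Series(self.classifier.predict_proba(X), index=matrix.patient_ids)

    def predict(self, matrix: ProteinMatrix) -> pd.Series:
        # probability exactly at the cutoff classifies as event (>= rule)
        return self.predict_proba(matrix) >= self.probability_cutoff


@dataclass(frozen=True)
class CVResult:
    """Per-patient out-of-fold predictions from the outer leave-one-out loop."""

    predictions: pd.DataFrame  # prob, predicted, observed, fold
    fold_thresholds: np.ndarray
    fold_set_sizes: np.ndarray
    confusion: ConfusionCounts
    mode: str

    @property
    def prob(self) -> pd.Series:
        return self.predictions["prob"]

    @property
    def predicted(self) -> pd.Series:
        return self.predictions["predicted"]

    @property
    def observed(self) -> pd.Series:
        return self.predictions["observed"]


def _aligned_arrays(matrix: ProteinMatrix, outcome: OutcomeVector):
    ids = matrix.patient_ids
    if set(ids) != set(outcome.patient_ids):
        raise ValueError("matrix and outcome cover different patients")
    order = sorted(ids)  # canonical order: row-permutation invariance
    values = matrix.values.loc[order]
    delta = outcome.delta_crp.loc[order].to_numpy(dtype=float)
    events = outcome.event.loc[order].to_numpy(dtype=bool)
    return order, values, delta, events


def double_cv(
    matrix: ProteinMatrix,
    outcome: OutcomeVector,
    grid: Sequence[float] | None = None,
    mode: str = "nested",
    inner: str | int = "loo",
    n_grid: int = DEFAULT_GRID_SIZE,
    cost: float = DEFAULT_COST,
    seed: int = 0,
    calibrate: bool = True,
) -> CVResult:
    """Outer leave-one-out loop around screening, tuning and classification.

    Each patient is predicted exactly once by a model that never saw them:
    screening correlations (mode="nested") and the tuned threshold are
    recomputed on the remaining patients, the SVM is refit, and the held-out
    probability is thresholded at the training fold's event prevalence.
    mode="paper" screens once on all patients before the loop.

    ``calibrate=False`` replaces the cross-validated Platt sigmoid with a
    plain logistic map of the SVM decision value -- a monotone transform
    that leaves rank statistics (AUC) and the LOOCV structure unchanged but
    runs considerably faster.
    """
    if mode not in ("nested", "paper"):
        raise ValueError(f"mode must be 'nested' or 'paper', got {mode!r}")
    order, values, delta, events = _aligned_arrays(matrix, outcome)
    n = len(order)
    if n < 4:
        raise ValueError("outer cross-validation needs at least 4 patients")
    if events.all() or not events.any():
        raise ValueError("cohort must contain both classes")

    full_screen = pearson_screen(ProteinMatrix(values), delta) if mode == "paper" else None
    fixed_grid = None if grid is None else np.asarray(list(grid), dtype=float)
    if fixed_grid is None and mode == "paper":
        fixed_grid = default_grid(full_screen, n_grid)

    prob = np.empty(n)
    pred = np.empty(n, dtype=bool)
    thresholds = np.empty(n)
    sizes = np.empty(n, dtype=int)
    for i in range(n):
        train = np.ones(n, dtype=bool)
        train[i] = False
        ytr = events[train]
        if ytr.all() or not ytr.any():
            raise ValueError(f"training data single-class in fold holding out {order[i]!r}")
        Xtr = values.iloc[train]
        if mode == "nested":
            screen = pearson_screen(ProteinMatrix(Xtr), delta[train])
        else:
            screen = full_screen
        g = default_grid(screen, n_grid) if fixed_grid is None else fixed_grid
        choice = choose_threshold(Xtr, ytr, screen, g, inner=inner, cost=cost)
        sel = shrink_select(screen, choice.threshold)
        clf = fit_classifier(Xtr[sel], ytr, cost=cost, seed=seed, probability=calibrate)
        p = float(clf.predict_proba(values.iloc[[i]][sel].to_numpy(dtype=float))[0])
        cutoff = float(ytr.mean())
        prob[i] = p
        pred[i] = p >= cutoff
        thresholds[i] = choice.threshold
        sizes[i] = len(sel)

    predictions = pd.DataFrame(
        {"prob": prob, "predicted": pred, "observed": events, "fold": np.arange(n)},
        index=pd.Index(order, name="patient_id"),
    ).loc[matrix.patient_ids]
    confusion = confusion_metrics(predictions["predicted"], predictions["observed"])
    return CVResult(
        predictions=predictions,
        fold_thresholds=thresholds,
        fold_set_sizes=sizes,
        confusion=confusion,
        mode=mode,
    )


def final_signature(
    matrix: ProteinMatrix,
    outcome: OutcomeVector,
    grid: Sequence[float] | None = None,
    inner: str | int = "loo",
    n_grid: int = DEFAULT_GRID_SIZE,
    cost: float = DEFAULT_COST,
    seed: int = 0,
) -> SignatureModel:
    """Screen, tune and fit on the full cohort; cutoff = event prevalence."""
    order, values, delta, events = _aligned_arrays(matrix, outcome)
    if events.all() or not events.any():
        raise ValueError("cohort must contain both classes")
    screen = pearson_screen(ProteinMatrix(values), delta)
    g = default_grid(screen, n_grid) if grid is None else np.asarray(list(grid), dtype=float)
    choice = choose_threshold(values, events, screen, g, inner=inner, cost=cost)
    sel = shrink_select(screen, choice.threshold)
    clf = fit_classifier(values[sel], events, cost=cost, seed=seed)
    return SignatureModel(
        selected_proteins=tuple(sel),
        threshold=choice.threshold,
        classifier=clf,
        probability_cutoff=float(events.mean()),
        screen=screen,
    )
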