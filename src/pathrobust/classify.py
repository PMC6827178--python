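"""Classifiers, cross-validation schemes and complexity selection.

Three classifier families are supported, each with a single complexity
knob: PLS-DA (number of latent components), kNN (number of neighbours)
and a linear SVM (soft-margin cost). PLS-DA regresses a dummy-coded
class indicator matrix on mean-centered predictors via standard PLS2
and decodes predictions by argmax over the class responses; its
coefficient matrix ``B`` (predictors × classes) is the raw material for
the coefficient signatures elsewhere in the package.

Cross-validation is either leave-one-group-out (every sample of one
group — e.g. one compound treatment — held out per fold) or class-
stratified k-fold (default 2 folds). Accuracy is pooled: correctly
classified samples over all samples, each predicted exactly once.

``select_complexity`` implements the sum-of-median-accuracies rule: for
each candidate complexity, the median cross-validated accuracy is taken
over repeats at every degradation level, summed over levels, and the
candidate maximizing the sum wins (ties go to the smallest complexity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

from .data import LabelledExpression, PathwayCollection
from .degradation import DegradationConfig, degrade
from .scoring import score_matrix

__all__ = ["FittedClassifier", "CVScheme", "fit_plsda", "fit_knn", "fit_svm",
           "fit_classifier", "predict_class", "cross_validate",
           "select_complexity"]

DEFAULT_CANDIDATES = {
    "plsda": (1, 2, 3, 4, 5, 6, 7, 8, 9, 10),
    "knn": (1, 3, 5, 7, 9, 11, 15),
    "svm": (0.01, 0.1, 1.0, 10.0, 100.0),
}


@dataclass
class FittedClassifier:
    """A trained classifier plus the metadata needed for prediction.

    For ``kind == "plsda"`` the fields ``B`` (p × C coefficient matrix),
    ``x_mean``/``y_mean`` (centering constants), ``x_rotations`` and
    ``y_loadings`` are populated; predictions at a truncated number of
    components k ≤ fitted components are available via ``n_comp=``.
    """

    kind: str
    complexity: float
    classes: np.ndarray
    n_features: int
    B: np.ndarray | None = None
    x_mean: np.ndarray | None = None
    y_mean: np.ndarray | None = None
    x_rotations: np.ndarray | None = None
    y_loadings: np.ndarray | None = None
    _train_X: np.ndarray | None = field(default=None, repr=False)
    _train_y: np.ndarray | None = field(default=None, repr=False)
    _nn: object = field(default=None, repr=False)
    _svm: object = field(default=None, repr=False)


@dataclass
class CVScheme:
    """Cross-validation layout: ``leave_one_group_out`` or ``stratified_kfold``."""

    kind: str = "stratified_kfold"
    n_folds: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("leave_one_group_out", "stratified_kfold"):
            raise ValueError(f"unknown CV scheme {self.kind!r}")
        if self.kind == "stratified_kfold" and self.n_folds < 2:
            raise ValueError("stratified k-fold needs n_folds >= 2")

    def folds(self, y: np.ndarray, groups: np.ndarray | None):
        """Yield (train_idx, test_idx) pairs; every sample is tested once."""
        n = len(y)
        if self.kind == "leave_one_group_out":
            if groups is None:
                raise ValueError("leave_one_group_out requires group labels")
            idx = np.arange(n)
            for g in np.unique(groups):
                test = idx[groups == g]
                train = idx[groups != g]
                yield train, test
        else:
            skf = StratifiedKFold(n_splits=self.n_folds, shuffle=True,
                                  random_state=int(self.seed) % (2**32))
            yield from skf.split(np.zeros((n, 1)), y)


def _dummy_code(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least two classes to fit a classifier")
    Y = (np.asarray(y)[:, None] == classes[None, :]).astype(float)
    return classes, Y


def fit_plsda(X: np.ndarray, y: np.ndarray, n_comp: int) -> FittedClassifier:
    """Fit PLS-DA: PLS2 regression of the class indicator matrix on X.

    X and the dummy-coded Y are mean-centered only (no autoscaling). The
    coefficient matrix B maps centered predictors to centered dummy
    responses. ``n_comp`` must not exceed min(n−1, p) nor the rank of the
    centered predictor matrix.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    classes, Y = _dummy_code(y)
    if n_comp < 1:
        raise ValueError("n_comp must be >= 1")
    if n_comp > min(n - 1, p):
        raise ValueError(f"n_comp={n_comp} exceeds min(n-1, p) = {min(n - 1, p)}")
    with warnings.catch_warnings():
        # sklearn warns when residual variance is exhausted early
        warnings.simplefilter("ignore")
        pls = PLSRegression(n_components=n_comp, scale=False).fit(X, Y)
    rot, load = pls.x_rotations_, pls.y_loadings_
    if not (np.all(np.isfinite(rot)) and np.all(np.isfinite(load))):
        raise ValueError(f"n_comp={n_comp} exceeds the rank of the predictor matrix")
    B = rot @ load.T
    return FittedClassifier(
        kind="plsda", complexity=n_comp, classes=classes, n_features=p,
        B=B, x_mean=X.mean(axis=0), y_mean=Y.mean(axis=0),
        x_rotations=rot, y_loadings=load,
    )


def plsda_response(model: FittedClassifier, X: np.ndarray,
                   n_comp: int | None = None) -> np.ndarray:
    """Predicted dummy responses; ``n_comp`` truncates the fitted model.

    Because PLS components are nested, the coefficient matrix of a
    k-component model equals the first k rotation/loading columns of a
    larger fit — truncation reproduces a fresh k-component fit exactly.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.n_features:
        raise ValueError(f"expected {model.n_features} predictor columns, "
                         f"got {X.shape[1]}")
    if n_comp is None:
        B = model.B
    else:
        if not 1 <= n_comp <= model.x_rotations.shape[1]:
            raise ValueError("truncation n_comp out of range")
        B = model.x_rotations[:, :n_comp] @ model.y_loadings[:, :n_comp].T
    return (X - model.x_mean) @ B + model.y_mean


def fit_knn(X: np.ndarray, y: np.ndarray, k: int) -> FittedClassifier:
    X = np.asarray(X, dtype=float)
    classes, _ = _dummy_code(y)
    if not 1 <= k <= len(y):
        raise ValueError(f"k={k} out of range for {len(y)} training samples")
    nn = NearestNeighbors(n_neighbors=k).fit(X)
    return FittedClassifier(kind="knn", complexity=k, classes=classes,
                            n_features=X.shape[1], _train_X=X,
                            _train_y=np.asarray(y), _nn=nn)


def fit_svm(X: np.ndarray, y: np.ndarray, cost: float) -> FittedClassifier:
    X = np.asarray(X, dtype=float)
    classes, _ = _dummy_code(y)
    if cost <= 0:
        raise ValueError("SVM cost must be positive")
    svm = SVC(kernel="linear", C=cost).fit(X, y)
    return FittedClassifier(kind="svm", complexity=cost, classes=classes,
                            n_features=X.shape[1], _svm=svm)


_FITTERS = {"plsda": fit_plsda, "knn": fit_knn, "svm": fit_svm}


def fit_classifier(kind: str, X: np.ndarray, y: np.ndarray,
                   complexity: float) -> FittedClassifier:
    try:
        fitter = _FITTERS[kind]
    except KeyError:
        raise ValueError(f"unknown classifier {kind!r}") from None
    if kind in ("plsda", "knn"):
        complexity = int(complexity)
    return fitter(X, y, complexity)


def predict_class(model: FittedClassifier, X: np.ndarray) -> np.ndarray:
    """Predict class labels.

    PLS-DA: argmax over predicted dummy responses (ties: first class in
    sorted label order). kNN: majority vote among the k nearest training
    points; vote ties are broken by the smaller mean neighbour distance,
    then by label order. SVM: one-vs-one voting.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(f"expected {model.n_features} predictor columns")
    if model.kind == "plsda":
        resp = plsda_response(model, X)
        return model.classes[np.argmax(resp, axis=1)]
    if model.kind == "svm":
        return model._svm.predict(X)
    # kNN with explicit tie handling
    dist, nbr = model._nn.kneighbors(X)
    ty = model._train_y
    out = np.empty(X.shape[0], dtype=model.classes.dtype)
    for i in range(X.shape[0]):
        labels = ty[nbr[i]]
        votes = np.array([np.sum(labels == c) for c in model.classes])
        top = votes.max()
        tied = np.flatnonzero(votes == top)
        if len(tied) == 1:
            out[i] = model.classes[tied[0]]
        else:
            mean_d = [dist[i][labels == model.classes[t]].mean() for t in tied]
            out[i] = model.classes[tied[int(np.argmin(mean_d))]]
    return out


def _check_folds_cover_classes(y: np.ndarray, folds) -> list:
    classes = np.unique(y)
    realized = []
    for train, test in folds:
        missing = set(classes) - set(y[train])
        if missing:
            raise ValueError(f"a training fold lacks class(es) {sorted(missing)}")
        realized.append((train, test))
    return realized


def cv_predictions(X: np.ndarray, y: np.ndarray, groups: np.ndarray | None,
                   kind: str, complexity: float, scheme: CVScheme) -> np.ndarray:
    """Out-of-fold predicted labels, aligned with the input samples."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    folds = _check_folds_cover_classes(y, scheme.folds(y, groups))
    pred = np.empty(len(y), dtype=y.dtype)
    for train, test in folds:
        model = fit_classifier(kind, X[train], y[train], complexity)
        pred[test] = predict_class(model, X[test])
    return pred


def cross_validate(X: np.ndarray, y: np.ndarray, groups: np.ndarray | None,
                   kind: str, complexity: float, scheme: CVScheme) -> float:
    """Pooled cross-validated accuracy: correct predictions / n."""
    pred = cv_predictions(X, y, groups, kind, complexity, scheme)
    return float(np.mean(pred == np.asarray(y)))


def cross_validate_multi(X: np.ndarray, y: np.ndarray, groups: np.ndarray | None,
                         kind: str, candidates: Sequence[float],
                         scheme: CVScheme) -> dict[float, float]:
    """Cross-validated accuracy for every candidate complexity at once.

    For PLS-DA one maximal-component model is fitted per fold and every
    candidate read off by truncation (identical to refitting); kNN and
    SVM refit per candidate.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    candidates = list(candidates)
    if not candidates:
        raise ValueError("empty candidate list")
    folds = _check_folds_cover_classes(y, scheme.folds(y, groups))
    if kind != "plsda":
        acc = {}
        for c in candidates:
            pred = np.empty(len(y), dtype=y.dtype)
            for train, test in folds:
                model = fit_classifier(kind, X[train], y[train], c)
                pred[test] = predict_class(model, X[test])
            acc[c] = float(np.mean(pred == y))
        return acc
    cand = sorted(int(c) for c in candidates)
    preds = {c: np.empty(len(y), dtype=y.dtype) for c in cand}
    for train, test in folds:
        kmax_fold = min(cand[-1], len(train) - 1, X.shape[1])
        model = fit_plsda(X[train], y[train], kmax_fold)
        for c in cand:
            resp = plsda_response(model, X[test], n_comp=min(c, kmax_fold))
            preds[c][test] = model.classes[np.argmax(resp, axis=1)]
    return {c: float(np.mean(preds[c] == y)) for c in cand}


def _scheme_for_repeat(scheme: CVScheme, repeat: int) -> CVScheme:
    if scheme.kind == "stratified_kfold":
        return CVScheme(kind=scheme.kind, n_folds=scheme.n_folds,
                        seed=scheme.seed + repeat)
    return scheme


def complexity_sweep(expr: LabelledExpression, coll: PathwayCollection | None,
                     candidates: Sequence[float], deg_config: DegradationConfig,
                     scheme: CVScheme, kind: str = "plsda",
                     scoring_method: str = "pca",
                     scoring_kwargs: dict | None = None) -> dict:
    """Accuracy table over (candidate × level × repeat) for one space.

    Degrades the gene matrix per (level, repeat) cell with seeds derived
    from ``deg_config.seed``, re-scores pathways when a collection is
    given, and evaluates every candidate complexity on the same
    realisation. Returns ``{"accuracies": {cand: levels × repeats array},
    "best": winning candidate, "sums": {cand: sum of medians}}``.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("empty candidate list")
    scoring_kwargs = scoring_kwargs or {}
    y, groups = expr.class_labels, expr.group_labels
    L, R = len(deg_config.levels), deg_config.n_repeats
    acc = {c: np.zeros((L, R)) for c in candidates}
    for li, level in enumerate(deg_config.levels):
        for rep in range(R):
            rng = np.random.default_rng(
                np.random.SeedSequence([deg_config.seed, li, rep]))
            degraded = degrade(expr, level, deg_config.method, rng)
            if coll is not None:
                Xcell = score_matrix(degraded, coll, scoring_method,
                                     **scoring_kwargs).scores
            else:
                Xcell = degraded.values
            cell = cross_validate_multi(Xcell, y, groups, kind, candidates,
                                        _scheme_for_repeat(scheme, rep))
            for c in candidates:
                acc[c][li, rep] = cell[int(c) if kind in ("plsda", "knn") else c]
    sums = {c: float(np.median(acc[c], axis=1).sum()) for c in candidates}
    best = min((c for c in candidates), key=lambda c: (-sums[c], c))
    return {"accuracies": acc, "sums": sums, "best": best}


def select_complexity(expr: LabelledExpression, coll: PathwayCollection | None,
                      candidates: Sequence[float], deg_config: DegradationConfig,
                      scheme: CVScheme, kind: str = "plsda",
                      scoring_method: str = "pca",
                      scoring_kwargs: dict | None = None) -> float:
    """Sum-of-median-accuracies complexity selection (ties: smallest)."""
    return complexity_sweep(expr, coll, candidates, deg_config, scheme, kind,
                            scoring_method, scoring_kwargs)["best"]
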