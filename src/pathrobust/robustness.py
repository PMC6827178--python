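"""Degradation experiments, profiles, and the predictive-robustness statistic.

A *degradation profile* is the curve of cross-validated accuracy versus
degradation level, with ``n_repeats`` independent noise realisations per
level. From it:

* local robustness at level u:  r_u = (median accuracy at u) / a_0,
  where a_0 is the median accuracy on undegraded data (r_0 ≡ 1);
* predictive robustness:  R = ∫₀¹ r_u du, evaluated on the discrete level
  grid by the trapezium rule. An approximate 90% confidence interval comes
  from recomputing R per repeat (each repeat's own accuracies divided by
  a_0) and taking the 5th/95th percentiles of that sample.

R is not clipped: degradation that happens to help can push r_u, and
hence R, above 1.

``degradation_sweep`` is the engine: for each (level, repeat) cell it
degrades the gene matrix once (seed derived deterministically from the
config seed and the cell coordinates) and evaluates one or more "spaces"
— gene space and/or pathway space under some scoring method — on that
shared realisation, so paired comparisons see identical noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from joblib import Parallel, delayed

from .classify import (CVScheme, DEFAULT_CANDIDATES, _scheme_for_repeat,
                       cross_validate_multi)
from .data import LabelledExpression, PathwayCollection
from .degradation import DegradationConfig, degrade
from .scoring import score_matrix

__all__ = ["DegradationProfile", "RobustnessResult", "SpaceSpec",
           "degradation_sweep", "run_degradation_experiment",
           "local_robustness", "predictive_robustness"]


@dataclass
class DegradationProfile:
    """Accuracy at each degradation level × repeat, plus metadata."""

    levels: tuple[float, ...]
    accuracies: np.ndarray          # shape (n_levels, n_repeats)
    space: str                      # "gene" or "pathway"
    classifier: str = "plsda"
    complexity: float = 1
    scoring_method: str | None = None
    degradation_method: str = "gaussian"

    def __post_init__(self) -> None:
        self.levels = tuple(float(v) for v in self.levels)
        self.accuracies = np.atleast_2d(np.asarray(self.accuracies, dtype=float))
        if self.accuracies.shape[0] != len(self.levels):
            raise ValueError("accuracy rows must match the number of levels")
        if self.levels[0] != 0.0:
            raise ValueError("profile must include level 0")
        if np.any(self.accuracies < 0) or np.any(self.accuracies > 1):
            raise ValueError("accuracies must lie in [0, 1]")

    @property
    def a0(self) -> float:
        """Baseline accuracy: median over repeats at level 0."""
        return float(np.median(self.accuracies[0]))

    @property
    def n_repeats(self) -> int:
        return self.accuracies.shape[1]

    def to_frame(self):
        import pandas as pd

        rows = [
            {"space": self.space, "level": lv, "repeat": r,
             "accuracy": self.accuracies[i, r]}
            for i, lv in enumerate(self.levels)
            for r in range(self.n_repeats)
        ]
        return pd.DataFrame(rows)


@dataclass
class RobustnessResult:
    """Local robustness curve, R, and its percentile confidence interval."""

    levels: tuple[float, ...]
    local_r: np.ndarray
    R: float
    ci_90: tuple[float, float]
    per_repeat_R: np.ndarray

    def __post_init__(self) -> None:
        if self.ci_90[0] > self.ci_90[1]:
            raise ValueError("confidence interval bounds out of order")


def local_robustness(profile: DegradationProfile) -> np.ndarray:
    """r_u = median accuracy at level u over the baseline a_0; r_0 = 1 exactly."""
    a0 = profile.a0
    if a0 == 0.0:
        raise ValueError("undegraded model has zero accuracy")
    r = np.median(profile.accuracies, axis=1) / a0
    r[0] = 1.0
    return r


def predictive_robustness(profile: DegradationProfile,
                          repeat_level0_own_ratio: bool = True) -> RobustnessResult:
    """Trapezium-rule area under the local-robustness curve, with 90% CI.

    ``repeat_level0_own_ratio`` controls the per-repeat curves used for the
    confidence interval: each repeat's r at level 0 is its own accuracy
    divided by a_0 (default), or exactly 1 when False.
    """
    levels = np.asarray(profile.levels)
    if len(levels) < 2 or levels[0] != 0.0 or levels[-1] != 1.0:
        raise ValueError("profile levels must span [0, 1] with at least 2 points")
    r = local_robustness(profile)
    R = float(np.trapezoid(r, levels))
    a0 = profile.a0
    per_repeat = profile.accuracies / a0
    if not repeat_level0_own_ratio:
        per_repeat = per_repeat.copy()
        per_repeat[0] = 1.0
    per_repeat_R = np.trapezoid(per_repeat, levels, axis=0)
    lo, hi = np.percentile(per_repeat_R, [5.0, 95.0])
    return RobustnessResult(levels=tuple(levels), local_r=r, R=R,
                            ci_90=(float(lo), float(hi)),
                            per_repeat_R=per_repeat_R)


@dataclass
class SpaceSpec:
    """One representation to evaluate inside a degradation sweep.

    ``collection=None`` means gene space (the degraded matrix is used
    directly); otherwise pathway scores are recomputed from each degraded
    matrix with ``scoring_method``. ``complexity`` is a number or
    ``"auto"``, in which case ``candidates`` (default grid per classifier)
    are all evaluated and the sum-of-median-accuracies rule picks one.
    """

    name: str
    collection: PathwayCollection | None = None
    scoring_method: str = "pca"
    scoring_kwargs: dict = field(default_factory=dict)
    classifier: str = "plsda"
    complexity: float | str = "auto"
    candidates: tuple | None = None

    def resolved_candidates(self) -> list:
        if self.complexity != "auto":
            return [self.complexity]
        cands = self.candidates or DEFAULT_CANDIDATES[self.classifier]
        return list(cands)


def _sweep_cell(expr: LabelledExpression, spaces: list[SpaceSpec],
                deg_config: DegradationConfig, scheme: CVScheme,
                li: int, level: float, rep: int) -> dict:
    rng = np.random.default_rng(np.random.SeedSequence([deg_config.seed, li, rep]))
    degraded = degrade(expr, level, deg_config.method, rng)
    rep_scheme = _scheme_for_repeat(scheme, rep)
    out = {}
    for sp in spaces:
        if sp.collection is None:
            X = degraded.values
        else:
            X = score_matrix(degraded, sp.collection, sp.scoring_method,
                             **sp.scoring_kwargs).scores
        out[sp.name] = cross_validate_multi(
            X, expr.class_labels, expr.group_labels, sp.classifier,
            sp.resolved_candidates(), rep_scheme)
    return out


def degradation_sweep(expr: LabelledExpression, spaces: list[SpaceSpec],
                      deg_config: DegradationConfig, scheme: CVScheme,
                      n_jobs: int = 1) -> dict[str, dict]:
    """Run the full (level × repeat) grid for one or more spaces.

    Every space sees the identical degraded matrix in each cell (paired
    design). Cell seeds derive from ``deg_config.seed`` and the cell
    coordinates, so results are independent of execution order and of
    ``n_jobs``. Returns, per space name: the accuracy array of the chosen
    complexity as a ``DegradationProfile``, the chosen complexity, and the
    full candidate accuracy table.
    """
    L, Rr = len(deg_config.levels), deg_config.n_repeats
    cells = [(li, lv, rep) for li, lv in enumerate(deg_config.levels)
             for rep in range(Rr)]
    if n_jobs == 1:
        results = [_sweep_cell(expr, spaces, deg_config, scheme, li, lv, rep)
                   for li, lv, rep in cells]
    else:
        results = Parallel(n_jobs=n_jobs)(
            delayed(_sweep_cell)(expr, spaces, deg_config, scheme, li, lv, rep)
            for li, lv, rep in cells)
    out = {}
    for sp in spaces:
        cands = sp.resolved_candidates()
        key_cands = [int(c) if sp.classifier in ("plsda", "knn") else c
                     for c in cands]
        acc = {c: np.zeros((L, Rr)) for c in key_cands}
        for (li, _, rep), cell in zip(cells, results):
            for c in key_cands:
                acc[c][li, rep] = cell[sp.name][c]
        sums = {c: float(np.median(acc[c], axis=1).sum()) for c in key_cands}
        best = min(key_cands, key=lambda c: (-sums[c], c))
        profile = DegradationProfile(
            levels=deg_config.levels, accuracies=acc[best], space=sp.name,
            classifier=sp.classifier, complexity=best,
            scoring_method=None if sp.collection is None else sp.scoring_method,
            degradation_method=deg_config.method)
        out[sp.name] = {"profile": profile, "complexity": best,
                        "accuracies": acc, "sums": sums}
    return out


def run_degradation_experiment(expr: LabelledExpression,
                               coll: PathwayCollection | None,
                               deg_config: DegradationConfig,
                               scheme: CVScheme,
                               scoring_method: str = "pca",
                               scoring_kwargs: dict | None = None,
                               classifier: str = "plsda",
                               complexity: float | str = "auto",
                               candidates: tuple | None = None,
                               n_jobs: int = 1) -> DegradationProfile:
    """Degrade → (re-score) → cross-validate over the full level × repeat grid.

    With ``coll`` given the experiment runs in pathway space, recomputing
    pathway scores from every degraded matrix; with ``coll=None`` it runs
    in gene space. ``complexity="auto"`` applies the sum-of-median-
    accuracies selection over the candidate grid inside the same sweep.
    """
    space = SpaceSpec(name="pathway" if coll is not None else "gene",
                      collection=coll, scoring_method=scoring_method,
                      scoring_kwargs=scoring_kwargs or {},
                      classifier=classifier, complexity=complexity,
                      candidates=candidates)
    return degradation_sweep(expr, [space], deg_config, scheme,
                             n_jobs=n_jobs)[space.name]["profile"]
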