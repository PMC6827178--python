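"""Model/results interface for the package's two main analyses.

The entry points follow the model → ``fit()`` → results pattern:

``RobustnessAnalysis``
    Degradation robustness of one representation (gene space, or pathway
    space under a chosen scoring method). ``fit(seed)`` runs the full
    (level × repeat) degradation sweep and returns a ``RobustnessFit``
    carrying the degradation profile, the local-robustness curve, the
    predictive robustness R with its 90% percentile interval, and the
    selected model complexity.

``PairedRobustnessAnalysis``
    Gene space and pathway space evaluated on *identical* degraded
    matrices per cell, so the difference in R is not inflated by
    independent Monte-Carlo noise.

``SignatureAnalysis``
    PLS-DA coefficient signature (entropy, ABC) of a collection against
    gene-label-permutation fakes, on undegraded data.

All randomness derives from the single seed passed to ``fit``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import CVScheme
from .data import LabelledExpression, PathwayCollection
from .degradation import DEFAULT_LEVELS, DegradationConfig
from .robustness import (DegradationProfile, RobustnessResult, SpaceSpec,
                         degradation_sweep, local_robustness,
                         predictive_robustness)
from .signatures import SignatureComparison, database_signature

__all__ = ["RobustnessAnalysis", "RobustnessFit", "PairedRobustnessAnalysis",
           "PairedRobustnessFit", "SignatureAnalysis", "SignatureFit"]


def _resolve_scheme(expr: LabelledExpression, cv: str, n_folds: int,
                    seed: int) -> CVScheme:
    if cv == "auto":
        cv = ("leave_one_group_out" if expr.group_labels is not None
              else "stratified_kfold")
    return CVScheme(kind=cv, n_folds=n_folds, seed=seed)


@dataclass
class RobustnessFit:
    """Results of one degradation-robustness experiment."""

    profile: DegradationProfile
    result: RobustnessResult
    complexity: float
    space: str

    @property
    def R(self) -> float:
        return self.result.R

    @property
    def ci_90(self) -> tuple[float, float]:
        return self.result.ci_90

    @property
    def local_r(self) -> np.ndarray:
        return self.result.local_r

    @property
    def per_repeat_R(self) -> np.ndarray:
        return self.result.per_repeat_R

    def summary_row(self) -> dict:
        return {"space": self.space, "classifier": self.profile.classifier,
                "complexity": self.complexity,
                "a0": self.profile.a0, "R": self.R,
                "ci_lo": self.ci_90[0], "ci_hi": self.ci_90[1]}

    def summary(self) -> str:
        rows = [f"Predictive robustness — {self.space} space",
                "=" * 46,
                f"classifier      {self.profile.classifier}",
                f"complexity      {self.complexity}",
                f"degradation     {self.profile.degradation_method}",
                f"levels          {len(self.profile.levels)}",
                f"repeats/level   {self.profile.n_repeats}",
                f"baseline a0     {self.profile.a0:.4f}",
                f"R               {self.R:.4f}",
                f"90% CI          [{self.ci_90[0]:.4f}, {self.ci_90[1]:.4f}]"]
        return "\n".join(rows)

    def plot_profile(self, ax=None):
        """Boxplots of accuracy per degradation level."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.boxplot([self.profile.accuracies[i]
                    for i in range(len(self.profile.levels))],
                   positions=list(self.profile.levels), widths=0.05,
                   manage_ticks=False)
        ax.set_xlabel("degradation level")
        ax.set_ylabel("CV accuracy")
        ax.set_title(f"{self.space} space (R = {self.R:.3f})")
        return ax


class RobustnessAnalysis:
    """Degradation-robustness experiment for one representation.

    Parameters
    ----------
    expr : LabelledExpression
        Expression data; already restricted to the pathway universe when a
        collection is supplied.
    collection : PathwayCollection or None
        None → gene space; otherwise pathway space with ``scoring``.
    scoring : {"pca", "mean", "ssgsea"}
    classifier : {"plsda", "knn", "svm"}
    complexity : number or "auto"
        "auto" applies the sum-of-median-accuracies selection over
        ``candidates`` (default grid per classifier) inside the sweep.
    levels, n_repeats, degradation : the degradation design.
    cv : {"auto", "leave_one_group_out", "stratified_kfold"}
    """

    def __init__(self, expr: LabelledExpression,
                 collection: PathwayCollection | None = None,
                 scoring: str = "pca", scoring_kwargs: dict | None = None,
                 classifier: str = "plsda", complexity: float | str = "auto",
                 candidates: tuple | None = None,
                 levels: tuple = DEFAULT_LEVELS, n_repeats: int = 20,
                 degradation: str = "gaussian",
                 cv: str = "auto", n_folds: int = 2):
        self.expr = expr
        self.collection = collection
        self.scoring = scoring
        self.scoring_kwargs = scoring_kwargs or {}
        self.classifier = classifier
        self.complexity = complexity
        self.candidates = candidates
        self.levels = tuple(levels)
        self.n_repeats = n_repeats
        self.degradation = degradation
        self.cv = cv
        self.n_folds = n_folds

    def _space(self, name: str | None = None) -> SpaceSpec:
        return SpaceSpec(
            name=name or ("pathway" if self.collection is not None else "gene"),
            collection=self.collection, scoring_method=self.scoring,
            scoring_kwargs=self.scoring_kwargs, classifier=self.classifier,
            complexity=self.complexity, candidates=self.candidates)

    def fit(self, seed: int = 0, n_jobs: int = 1) -> RobustnessFit:
        config = DegradationConfig(levels=self.levels, n_repeats=self.n_repeats,
                                   method=self.degradation, seed=seed)
        scheme = _resolve_scheme(self.expr, self.cv, self.n_folds, seed)
        space = self._space()
        res = degradation_sweep(self.expr, [space], config, scheme,
                                n_jobs=n_jobs)[space.name]
        profile = res["profile"]
        return RobustnessFit(profile=profile,
                             result=predictive_robustness(profile),
                             complexity=res["complexity"], space=space.name)


@dataclass
class PairedRobustnessFit:
    """Gene- and pathway-space robustness on shared degraded realisations."""

    gene: RobustnessFit
    pathway: RobustnessFit

    @property
    def delta_R(self) -> float:
        """Pathway-space R minus gene-space R."""
        return self.pathway.R - self.gene.R

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.gene.summary_row(),
                             self.pathway.summary_row()])

    def summary(self) -> str:
        lines = [self.pathway.summary(), "", self.gene.summary(), "",
                 f"delta R (pathway - gene)  {self.delta_R:+.4f}"]
        return "\n".join(lines)

    def plot_profiles(self):
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
        self.gene.plot_profile(axes[0])
        self.pathway.plot_profile(axes[1])
        fig.tight_layout()
        return fig


class PairedRobustnessAnalysis(RobustnessAnalysis):
    """Gene vs pathway space under identical noise realisations.

    Accepts the same arguments as ``RobustnessAnalysis`` but requires a
    collection; ``fit`` evaluates both spaces inside every degradation
    cell and selects complexity independently per space.
    """

    def __init__(self, expr: LabelledExpression, collection: PathwayCollection,
                 **kwargs):
        if collection is None:
            raise ValueError("paired analysis requires a pathway collection")
        super().__init__(expr, collection, **kwargs)

    def fit(self, seed: int = 0, n_jobs: int = 1) -> PairedRobustnessFit:
        config = DegradationConfig(levels=self.levels, n_repeats=self.n_repeats,
                                   method=self.degradation, seed=seed)
        scheme = _resolve_scheme(self.expr, self.cv, self.n_folds, seed)
        gene_space = SpaceSpec(name="gene", collection=None,
                               classifier=self.classifier,
                               complexity=self.complexity,
                               candidates=self.candidates)
        path_space = self._space("pathway")
        res = degradation_sweep(self.expr, [gene_space, path_space], config,
                                scheme, n_jobs=n_jobs)
        fits = {}
        for name in ("gene", "pathway"):
            profile = res[name]["profile"]
            fits[name] = RobustnessFit(profile=profile,
                                       result=predictive_robustness(profile),
                                       complexity=res[name]["complexity"],
                                       space=name)
        return PairedRobustnessFit(gene=fits["gene"], pathway=fits["pathway"])


@dataclass
class SignatureFit:
    """Coefficient-signature comparison of one collection vs permutation fakes."""

    comparison: SignatureComparison
    name: str = "collection"

    @property
    def entropy(self) -> float:
        return self.comparison.real_signature.entropy

    @property
    def abc(self) -> float:
        return self.comparison.abc_real

    def summary_row(self) -> dict:
        return {"database": self.name, **self.comparison.summary_row()}

    def summary(self) -> str:
        row = self.comparison.summary_row()
        lines = [f"Coefficient signature — {self.name}",
                 "=" * 46,
                 f"fakes                 {row['n_fakes']}",
                 f"entropy (real)        {row['H_real']:.4f}",
                 f"entropy (fake median) {row['H_fake_median']:.4f}",
                 f"entropy percentile    {row['H_percentile']:.1f}",
                 f"ABC (real)            {row['ABC_real']:.4f}",
                 f"ABC (fake median)     {row['ABC_fake_median']:.4f}",
                 f"ABC percentile        {row['ABC_percentile']:.1f}"]
        return "\n".join(lines)

    def plot_histograms(self, ax=None):
        """Real coefficient histogram over the median fake histogram."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sig = self.comparison.real_signature
        centers = 0.5 * (sig.bin_edges[:-1] + sig.bin_edges[1:])
        fake_med = np.median([s.hist for s in self.comparison.fake_signatures],
                             axis=0)
        width = sig.bin_edges[1] - sig.bin_edges[0]
        ax.bar(centers, fake_med, width=width, alpha=0.5, label="fake (median)")
        ax.step(centers, sig.hist, where="mid", label="real")
        ax.set_xlabel("|coefficient|")
        ax.set_ylabel("probability")
        ax.legend()
        return ax


class SignatureAnalysis:
    """Entropy/ABC signature of a pathway collection vs permutation nulls.

    ``fit`` trains PLS-DA (``n_comp`` components) in pathway space on the
    undegraded data for the real collection and ``n_fakes`` label-permuted
    copies. ``fit_by_source`` repeats the comparison per source-database
    tag of the collection.
    """

    def __init__(self, expr: LabelledExpression, collection: PathwayCollection,
                 scoring: str = "pca", scoring_kwargs: dict | None = None,
                 n_comp: int = 3, n_fakes: int = 100):
        self.expr = expr
        self.collection = collection
        self.scoring = scoring
        self.scoring_kwargs = scoring_kwargs or {}
        self.n_comp = n_comp
        self.n_fakes = n_fakes

    def _one(self, coll: PathwayCollection, rng, name: str) -> SignatureFit:
        comp = database_signature(self.expr, coll, rng, n_fakes=self.n_fakes,
                                  scoring_method=self.scoring,
                                  scoring_kwargs=self.scoring_kwargs,
                                  n_comp=self.n_comp)
        return SignatureFit(comparison=comp, name=name)

    def fit(self, seed: int = 0, name: str = "collection") -> SignatureFit:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
        return self._one(self.collection, rng, name)

    def fit_by_source(self, seed: int = 0) -> dict[str, SignatureFit]:
        out = {}
        for i, (tag, sub) in enumerate(self.collection.by_source().items()):
            rng = np.random.default_rng(np.random.SeedSequence([seed, 17, i]))
            out[tag] = self._one(sub, rng, tag)
        return out
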