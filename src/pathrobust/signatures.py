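"""Coefficient-distribution signatures of pathway collections.

When a PLS-DA model is trained in pathway space, the magnitude of each
pathway's regression coefficient measures its contribution to the
prediction rule. Collections of genuinely informative pathways tend to
produce *sparser* models — an excess of near-zero coefficients and a
deficit of mid/high ones — than size- and overlap-matched fake
collections. Two summaries capture this:

* Shannon entropy of the 50-bin histogram of absolute coefficients,
  H = −Σ p_i ln p_i (nats; 0·ln 0 ≡ 0). Lower entropy = more mass
  concentrated in few bins = a simpler model.
* The area-between-curves (ABC) statistic: Σ over bins of
  |p_real − median fake p|, the summed absolute difference between a
  collection's histogram and the per-bin median histogram of the fakes
  (probability-mass units, bounded by 2).

``database_signature`` runs the whole comparison: fit PLS-DA in pathway
space on undegraded data for the real collection and for n label-permuted
fakes, histogram the coefficients on shared bin edges, and report where
the real collection falls within the fake distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import CVScheme, fit_plsda, FittedClassifier
from .data import LabelledExpression, PathwayCollection
from .randomization import permute_gene_labels
from .scoring import score_matrix

__all__ = ["CoefficientSignature", "SignatureComparison",
           "coefficient_signature", "abc_statistic", "database_signature"]

N_BINS = 50


@dataclass
class CoefficientSignature:
    """Histogram + entropy of pooled absolute PLS-DA coefficients."""

    abs_coeffs: np.ndarray
    hist: np.ndarray          # 50 probabilities summing to 1
    bin_edges: np.ndarray     # 51 edges
    entropy: float

    def __post_init__(self) -> None:
        if abs(self.hist.sum() - 1.0) > 1e-12:
            raise ValueError("histogram probabilities must sum to 1")
        if not 0.0 <= self.entropy <= np.log(len(self.hist)) + 1e-12:
            raise ValueError("entropy outside [0, ln(n_bins)]")


@dataclass
class SignatureComparison:
    """Real-vs-fake signature comparison for one pathway collection."""

    real_signature: CoefficientSignature
    fake_signatures: list
    abc_real: float
    abc_fakes: np.ndarray
    entropy_percentile: float   # of the real H within the fake H distribution
    abc_percentile: float       # of the real ABC within the fake ABC distribution

    @property
    def fake_entropies(self) -> np.ndarray:
        return np.array([s.entropy for s in self.fake_signatures])

    def summary_row(self) -> dict:
        fh = self.fake_entropies
        return {
            "n_fakes": len(self.fake_signatures),
            "H_real": self.real_signature.entropy,
            "H_fake_median": float(np.median(fh)),
            "H_fake_q05": float(np.percentile(fh, 5)),
            "H_fake_q95": float(np.percentile(fh, 95)),
            "ABC_real": self.abc_real,
            "ABC_fake_median": float(np.median(self.abc_fakes)),
            "ABC_fake_q05": float(np.percentile(self.abc_fakes, 5)),
            "ABC_fake_q95": float(np.percentile(self.abc_fakes, 95)),
            "H_percentile": self.entropy_percentile,
            "ABC_percentile": self.abc_percentile,
        }


def _entropy(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def _histogram(abs_b: np.ndarray, bin_edges: np.ndarray) -> np.ndarray:
    counts, _ = np.histogram(abs_b, bins=bin_edges)
    return counts / counts.sum()


def coefficient_signature(model: FittedClassifier,
                          bin_edges: np.ndarray | None = None) -> CoefficientSignature:
    """Signature of one fitted PLS-DA model.

    All entries of B are pooled as absolute values across predictors and
    response columns, histogrammed on 50 equal-width bins (edges supplied,
    or [0, max|b|] when None) and summarized by Shannon entropy.
    """
    if model.kind != "plsda":
        raise ValueError("coefficient signatures are defined for PLS-DA models")
    abs_b = np.abs(model.B).ravel()
    if np.all(abs_b == 0):
        raise ValueError("degenerate model: all coefficients are zero")
    if bin_edges is None:
        bin_edges = np.linspace(0.0, abs_b.max(), N_BINS + 1)
    else:
        bin_edges = np.asarray(bin_edges, dtype=float)
        if len(bin_edges) != N_BINS + 1:
            raise ValueError(f"expected {N_BINS + 1} bin edges")
    # values exactly at the upper edge land in the last bin (np.histogram)
    hist = _histogram(np.clip(abs_b, bin_edges[0], bin_edges[-1]), bin_edges)
    return CoefficientSignature(abs_coeffs=abs_b, hist=hist,
                                bin_edges=bin_edges, entropy=_entropy(hist))


def abc_statistic(real_hist: np.ndarray, fake_hists: list) -> float:
    """Σ over bins of |p_real − per-bin median fake probability|."""
    real_hist = np.asarray(real_hist, dtype=float)
    fakes = np.atleast_2d(np.asarray(fake_hists, dtype=float))
    if fakes.shape[0] < 1:
        raise ValueError("need at least one fake histogram")
    if fakes.shape[1] != real_hist.shape[0]:
        raise ValueError("histograms must share the same bins")
    med = np.median(fakes, axis=0)
    return float(np.abs(real_hist - med).sum())


def _fit_space_plsda(expr: LabelledExpression, coll: PathwayCollection,
                     scoring_method: str, scoring_kwargs: dict,
                     n_comp: int) -> FittedClassifier:
    scores = score_matrix(expr, coll, scoring_method, **scoring_kwargs)
    return fit_plsda(scores.scores, expr.class_labels, n_comp)


def database_signature(expr: LabelledExpression, coll: PathwayCollection,
                       rng: np.random.Generator, n_fakes: int = 100,
                       scoring_method: str = "pca",
                       scoring_kwargs: dict | None = None,
                       n_comp: int = 3,
                       scheme: CVScheme | None = None) -> SignatureComparison:
    """Compare a collection's coefficient signature against permutation fakes.

    PLS-DA is fitted in pathway space on the *undegraded* data for the
    real collection and for ``n_fakes`` gene-label-permuted copies. All
    histograms share bin edges [0, max |b| over real and fakes]. Each
    fake's own ABC is measured against the leave-one-out median of the
    other fakes' histograms (the real ABC uses all fakes). Percentiles
    locate the real collection's entropy and ABC within the fake
    distributions. ``scheme`` is accepted for interface symmetry with the
    degradation experiments and unused: no cross-validation is involved.
    """
    if n_fakes < 2:
        raise ValueError("n_fakes must be >= 2 (a single fake has no "
                         "reference median for its own ABC)")
    scoring_kwargs = scoring_kwargs or {}
    real_model = _fit_space_plsda(expr, coll, scoring_method, scoring_kwargs, n_comp)
    fake_models = []
    for _ in range(n_fakes):
        fake_coll = permute_gene_labels(coll, rng)
        fake_models.append(_fit_space_plsda(expr, fake_coll, scoring_method,
                                            scoring_kwargs, n_comp))
    bmax = max(np.abs(real_model.B).max(),
               *(np.abs(m.B).max() for m in fake_models))
    edges = np.linspace(0.0, bmax, N_BINS + 1)
    real_sig = coefficient_signature(real_model, edges)
    fake_sigs = [coefficient_signature(m, edges) for m in fake_models]
    fake_hists = np.array([s.hist for s in fake_sigs])
    abc_real = abc_statistic(real_sig.hist, fake_hists)
    abc_fakes = np.array([
        abc_statistic(fake_hists[i], np.delete(fake_hists, i, axis=0))
        for i in range(n_fakes)
    ])
    fake_H = np.array([s.entropy for s in fake_sigs])
    h_pct = 100.0 * (np.sum(fake_H < real_sig.entropy)
                     + 0.5 * np.sum(fake_H == real_sig.entropy)) / n_fakes
    a_pct = 100.0 * (np.sum(abc_fakes < abc_real)
                     + 0.5 * np.sum(abc_fakes == abc_real)) / n_fakes
    return SignatureComparison(real_signature=real_sig, fake_signatures=fake_sigs,
                               abc_real=abc_real, abc_fakes=abc_fakes,
                               entropy_percentile=float(h_pct),
                               abc_percentile=float(a_pct))
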