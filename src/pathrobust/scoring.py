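"""Pathway scoring: transform a gene-space matrix into pathway space.

A pathway score is a per-sample summary of the expression of one pathway's
member genes. Three families are provided:

* ``score_pca`` — projection on the leading principal component(s) of the
  mean-centered member-gene submatrix (the default throughout the toolkit).
* ``score_mean`` — arithmetic mean of member-gene expression.
* ``score_ssgsea`` — single-sample gene-set enrichment: a weighted
  Kolmogorov–Smirnov-like running sum over each sample's gene ranking.

All scorers are permutation-equivariant in samples and deterministic:
the PCA loading sign is fixed so its largest-magnitude element is positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .data import LabelledExpression, PathwayCollection

__all__ = ["PathwayScoreMatrix", "score_pca", "score_mean", "score_ssgsea",
           "score_matrix"]


@dataclass
class PathwayScoreMatrix:
    """Samples × pathway-score matrix (the "pathway space").

    ``scores`` has one column per pathway (``score_pca`` with several
    components contributes adjacent columns per pathway, labelled
    ``name|pc2`` etc.). Row order is identical to the source expression.
    """

    scores: np.ndarray
    column_pathway_ids: list[str]
    sample_ids: list[str]
    method: str
    ssgsea_alpha: float | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.sample_ids), len(self.column_pathway_ids)):
            raise ValueError("score matrix shape does not match ids")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("pathway scores contain non-finite values")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.scores, index=self.sample_ids,
                            columns=self.column_pathway_ids)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="sample_id",
                               float_format="%.10g")


def _member_columns(expr: LabelledExpression, coll: PathwayCollection) -> dict[str, np.ndarray]:
    idx = expr.gene_index()
    cols = {}
    for name, genes in coll.pathways.items():
        try:
            cols[name] = np.array(sorted(idx[g] for g in genes), dtype=int)
        except KeyError as e:
            raise ValueError(
                f"pathway {name!r} contains unmeasured gene {e.args[0]!r}; "
                "restrict the collection to the expression universe first"
            ) from None
    return cols


def score_pca(expr: LabelledExpression, coll: PathwayCollection,
              n_components: int = 1, scale: bool = False) -> PathwayScoreMatrix:
    """Score each pathway by projection on its leading principal component(s).

    Per pathway the n × q member submatrix is column mean-centered (and,
    if ``scale``, divided by the column standard deviation) and decomposed
    by SVD; scores are the projections on the first ``n_components`` right
    singular vectors. The sign of each loading is fixed so its element of
    largest absolute value is positive (ties: first index). A pathway whose
    centered submatrix is identically zero scores 0 with a warning;
    ``n_components`` exceeding the submatrix rank is an error.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    n = expr.n_samples
    cols = _member_columns(expr, coll)
    out = np.empty((n, coll.n_pathways * n_components))
    names: list[str] = []
    for j, (name, cidx) in enumerate(cols.items()):
        if n_components > min(n, len(cidx)):
            raise ValueError(
                f"n_components={n_components} exceeds pathway {name!r} "
                f"dimensions ({n}×{len(cidx)})"
            )
        sub = expr.values[:, cidx]
        centered = sub - sub.mean(axis=0)
        if scale:
            sd = centered.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            centered = centered / sd
        block = np.zeros((n, n_components))
        norm = np.linalg.norm(centered)
        if norm == 0.0:
            warnings.warn(f"pathway {name!r} has zero variance; scores set to 0")
        else:
            U, s, Vt = np.linalg.svd(centered, full_matrices=False)
            rank = int(np.sum(s > s[0] * max(n, len(cidx)) * np.finfo(float).eps))
            if n_components > rank:
                raise ValueError(
                    f"n_components={n_components} exceeds rank {rank} of "
                    f"pathway {name!r} submatrix"
                )
            for c in range(n_components):
                loading = Vt[c]
                pivot = int(np.argmax(np.abs(loading)))
                sign = 1.0 if loading[pivot] >= 0 else -1.0
                block[:, c] = centered @ (sign * loading)
        out[:, j * n_components:(j + 1) * n_components] = block
        if n_components == 1:
            names.append(name)
        else:
            names.extend([name] + [f"{name}|pc{c + 1}" for c in range(1, n_components)])
    return PathwayScoreMatrix(scores=out, column_pathway_ids=names,
                              sample_ids=list(expr.sample_ids), method="pca")


def score_mean(expr: LabelledExpression, coll: PathwayCollection) -> PathwayScoreMatrix:
    """Score(sample, pathway) = mean expression of the pathway's member genes."""
    cols = _member_columns(expr, coll)
    out = np.column_stack([expr.values[:, cidx].mean(axis=1) for cidx in cols.values()])
    return PathwayScoreMatrix(scores=out, column_pathway_ids=list(cols),
                              sample_ids=list(expr.sample_ids), method="mean")


def score_ssgsea(expr: LabelledExpression, coll: PathwayCollection,
                 alpha: float = 0.25, rescale: bool = False) -> PathwayScoreMatrix:
    """Single-sample gene-set enrichment scores.

    Per sample, genes are ranked by expression (descending; ties receive
    average ranks). Walking down the ranked list, the enrichment score is
    the summed difference between the weighted empirical CDF of in-set
    genes (weights rank^alpha, normalized within the set) and the
    unweighted empirical CDF of out-of-set genes. A pathway covering every
    measured gene has no out-of-set CDF and scores 0 with a warning.

    ``rescale`` divides all scores by the overall score range (an optional
    normalization of the original method; off by default, scores are raw).
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    cols = _member_columns(expr, coll)
    n, m = expr.values.shape
    out = np.empty((n, len(cols)))
    masks = {}
    for name, cidx in cols.items():
        mask = np.zeros(m, dtype=bool)
        mask[cidx] = True
        masks[name] = mask
        if mask.all():
            warnings.warn(f"pathway {name!r} covers all genes; ssGSEA score is 0")
    for i in range(n):
        x = expr.values[i]
        ranks = rankdata(x)          # ascending, ties -> average rank
        order = np.argsort(-x, kind="stable")
        w = ranks ** alpha
        w_ord = w[order]
        for j, (name, mask) in enumerate(masks.items()):
            in_ord = mask[order]
            q = int(mask.sum())
            if q == m:
                out[i, j] = 0.0
                continue
            w_in = np.where(in_ord, w_ord, 0.0)
            p_in = np.cumsum(w_in) / w_in.sum()
            p_out = np.cumsum(~in_ord) / (m - q)
            out[i, j] = float(np.sum(p_in - p_out))
    if rescale:
        rng_ = out.max() - out.min()
        if rng_ > 0:
            out = out / rng_
    return PathwayScoreMatrix(scores=out, column_pathway_ids=list(cols),
                              sample_ids=list(expr.sample_ids), method="ssgsea",
                              ssgsea_alpha=alpha)


_SCORERS = {
    "pca": score_pca,
    "mean": score_mean,
    "ssgsea": score_ssgsea,
}


def score_matrix(expr: LabelledExpression, coll: PathwayCollection,
                 method: str = "pca", **kwargs) -> PathwayScoreMatrix:
    """Dispatch to a scorer by name (``pca``, ``mean``, ``ssgsea``)."""
    try:
        scorer = _SCORERS[method]
    except KeyError:
        raise ValueError(f"unknown scoring method {method!r}; "
                         f"choose from {sorted(_SCORERS)}") from None
    return scorer(expr, coll, **kwargs)
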