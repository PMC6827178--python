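"""Synthetic expression data with pathway-structured class signal.

The generator emulates the structure of a multi-class, compound-treated
toxicogenomics design: ``n_classes`` outcome classes, each treated with
``groups_per_class`` compounds (groups), with expression driven by a
one-latent-factor-per-pathway linear model:

* the first ``n_informative`` pathways each carry a latent activity
  z = (δ·offset_class + e) / √(1+δ²), e ~ N(0,1) — class offsets are
  drawn per pathway (centered, unit population SD across samples), so
  δ is the class shift in latent SD units and different pathways separate
  different class contrasts; the latent is standardized so ρ below is
  exactly the gene–latent correlation;
* each member gene of an informative pathway is ρ·z + √(1−ρ²)·noise_sd·ε;
* a small per-compound random intercept (SD 0.3 on the latent scale) is
  shared by all samples of a group, making leave-one-group-out
  cross-validation genuinely harder than random splits;
* non-informative pathway genes and leftover background genes are
  independent N(0, noise_sd²).

Pathways occupy the first gene slots as consecutive blocks; a binomial
number of genes (probability ``overlap_fraction``) is shared between each
pair of consecutive pathways, keeping overlap accounting exactly
checkable. The returned collection carries the true definitions with
source tag ``"truth"``. Output is bit-identical for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import LabelledExpression, PathwayCollection

__all__ = ["SyntheticParams", "generate_synthetic"]

GROUP_INTERCEPT_SD = 0.3


@dataclass
class SyntheticParams:
    """Design of the synthetic dataset (defaults: the study conditions
    used throughout the package's own experiments)."""

    n_samples: int = 120
    n_classes: int = 3
    groups_per_class: int = 4
    n_genes: int = 2000
    n_pathways: int = 100
    q_min: int = 10
    q_max: int = 30
    overlap_fraction: float = 0.1
    n_informative: int = 20
    effect_size: float = 1.5     # δ, class shift of latent activity (latent SD units)
    loading: float = 0.6         # ρ, gene-on-latent correlation
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if self.n_informative > self.n_pathways:
            raise ValueError("n_informative cannot exceed n_pathways")
        if self.q_min < 2 or self.q_max < self.q_min:
            raise ValueError("pathway size range must satisfy 2 <= q_min <= q_max")
        if not 0.0 < self.loading < 1.0:
            raise ValueError("loading must be in (0, 1)")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must be in [0, 1]")
        denom = self.n_classes * self.groups_per_class
        if self.n_samples % denom != 0:
            raise ValueError(
                f"n_samples={self.n_samples} must be divisible by "
                f"n_classes*groups_per_class={denom}")


def generate_synthetic(params: SyntheticParams,
                       rng: np.random.Generator | None = None
                       ) -> tuple[LabelledExpression, PathwayCollection]:
    """Draw one synthetic (expression, collection) pair.

    If ``rng`` is omitted one is created from ``params.seed``.
    """
    p = params
    if rng is None:
        rng = np.random.default_rng(p.seed)

    # --- design: samples, classes, compounds ---
    per_group = p.n_samples // (p.n_classes * p.groups_per_class)
    class_labels, group_labels = [], []
    for c in range(p.n_classes):
        for g in range(p.groups_per_class):
            class_labels += [f"class_{c}"] * per_group
            group_labels += [f"cmpd_{c}_{g}"] * per_group
    class_idx = np.repeat(np.arange(p.n_classes),
                          p.groups_per_class * per_group)
    groups = np.asarray(group_labels)
    uniq_groups, group_idx = np.unique(groups, return_inverse=True)

    # --- pathway layout: consecutive blocks with binomial overlap ---
    sizes = rng.integers(p.q_min, p.q_max + 1, size=p.n_pathways)
    starts = np.zeros(p.n_pathways, dtype=int)
    pos = 0
    for i in range(p.n_pathways):
        starts[i] = pos
        if i + 1 < p.n_pathways:
            max_ov = min(sizes[i], sizes[i + 1]) - 1  # keep blocks distinct
            ov = min(int(rng.binomial(min(sizes[i], sizes[i + 1]),
                                      p.overlap_fraction)), max_ov)
            pos += sizes[i] - ov
        else:
            pos += sizes[i]
    total_pathway_genes = int(starts[-1] + sizes[-1])
    if total_pathway_genes > p.n_genes:
        raise ValueError(
            f"pathway layout needs {total_pathway_genes} genes but "
            f"n_genes={p.n_genes}")

    gene_ids = [f"g{j:05d}" for j in range(p.n_genes)]
    pathways = {
        f"PW{i:04d}": frozenset(gene_ids[starts[i]:starts[i] + sizes[i]])
        for i in range(p.n_pathways)
    }
    coll = PathwayCollection(pathways=pathways,
                             source_db={name: "truth" for name in pathways})

    # --- expression: background everywhere, then overwrite informative genes ---
    values = rng.standard_normal((p.n_samples, p.n_genes)) * p.noise_sd
    delta, rho = p.effect_size, p.loading
    assigned = np.zeros(p.n_genes, dtype=bool)  # overlap genes: first owner wins
    for i in range(p.n_informative):
        offsets = rng.standard_normal(p.n_classes)
        offsets -= offsets.mean()
        sd = offsets.std()
        if sd > 0:
            offsets /= sd
        latent_noise = rng.standard_normal(p.n_samples)
        z = (delta * offsets[class_idx] + latent_noise) / np.sqrt(1.0 + delta**2)
        z = z + rng.normal(0.0, GROUP_INTERCEPT_SD, size=len(uniq_groups))[group_idx]
        cols = np.arange(starts[i], starts[i] + sizes[i])
        cols = cols[~assigned[cols]]
        eps = rng.standard_normal((p.n_samples, len(cols)))
        values[:, cols] = (rho * z[:, None]
                           + np.sqrt(1.0 - rho**2) * p.noise_sd * eps)
        assigned[cols] = True

    expr = LabelledExpression(
        values=values,
        sample_ids=[f"s{j:04d}" for j in range(p.n_samples)],
        gene_ids=gene_ids,
        class_labels=np.asarray(class_labels, dtype=object),
        group_labels=np.asarray(group_labels, dtype=object),
    )
    return expr, coll
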