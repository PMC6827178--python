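"""Null models for pathway collections.

``permute_gene_labels`` draws one uniform permutation of the gene
universe and relabels every pathway through it — sizes and all pairwise
membership overlaps are preserved exactly (the gene–pathway incidence
structure is isomorphic to the original). ``random_gene_sets`` instead
draws each fake pathway as an independent uniform sample of the original
size from the universe, preserving sizes but not overlaps.
``subsample_database`` keeps a uniform subset of pathways, emulating
smaller databases. All three are pure functions of (collection, rng).
"""

from __future__ import annotations

import numpy as np

from .data import PathwayCollection

__all__ = ["permute_gene_labels", "random_gene_sets", "subsample_database"]


def permute_gene_labels(coll: PathwayCollection,
                        rng: np.random.Generator) -> PathwayCollection:
    """Relabel genes through a single uniform permutation of the universe."""
    universe = sorted(coll.universe)
    if not universe:
        raise ValueError("empty gene universe")
    perm = rng.permutation(len(universe))
    mapping = {universe[i]: universe[perm[i]] for i in range(len(universe))}
    fake = {name: frozenset(mapping[g] for g in genes)
            for name, genes in coll.pathways.items()}
    return PathwayCollection(pathways=fake, source_db=dict(coll.source_db),
                             universe=coll.universe)


def random_gene_sets(coll: PathwayCollection,
                     rng: np.random.Generator) -> PathwayCollection:
    """Independent size-matched uniform gene sets from the universe."""
    universe = np.array(sorted(coll.universe))
    fake = {}
    for name, genes in coll.pathways.items():
        q = len(genes)
        if q > len(universe):
            raise ValueError(f"pathway {name!r} larger than the universe")
        fake[name] = frozenset(rng.choice(universe, size=q, replace=False))
    return PathwayCollection(pathways=fake, source_db=dict(coll.source_db),
                             universe=coll.universe)


def subsample_database(coll: PathwayCollection, n_pathways: int,
                       rng: np.random.Generator) -> PathwayCollection:
    """Uniformly retain ``n_pathways`` pathways; the universe is recomputed
    as the union of the retained members."""
    if not 1 <= n_pathways <= coll.n_pathways:
        raise ValueError(f"n_pathways must be in [1, {coll.n_pathways}]")
    names = coll.names
    keep_idx = np.sort(rng.choice(len(names), size=n_pathways, replace=False))
    keep = [names[i] for i in keep_idx]
    sub = {n: coll.pathways[n] for n in keep}
    return PathwayCollection(
        pathways=sub,
        source_db={n: coll.source_db[n] for n in keep if n in coll.source_db})
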