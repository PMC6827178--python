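"""Controlled degradation of expression matrices.

Three strategies destroy gene-level signal at a chosen intensity:

* ``gaussian`` (default) — a random subset of genes is replaced by draws
  from a Normal with each gene's own sample mean and variance.
* ``permute`` — the selected genes' values are independently permuted
  across samples, preserving each gene's marginal distribution exactly.
* ``global`` — every gene is moved toward pure noise simultaneously:
  x' = μ + √(1−level)·(x−μ) + √level·ε with ε ~ N(0, s²), a
  variance-preserving interpolation whose level-1 limit is full Gaussian
  replacement and whose expected squared original–degraded correlation
  is (1−level).

For ``gaussian``/``permute`` the level is the *fraction of genes* touched;
⌊fraction·m⌉ genes (round half up, so fraction 1 always hits all genes)
are drawn uniformly without replacement. Labels are never modified; with a
fixed random generator all strategies are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import LabelledExpression

__all__ = ["DegradationConfig", "degrade_gaussian", "degrade_permute",
           "degrade_global", "degrade"]

DEFAULT_LEVELS = tuple(np.round(np.linspace(0.0, 1.0, 11), 10))


@dataclass
class DegradationConfig:
    """Level grid, repeat count, strategy and seed for a degradation sweep.

    ``levels`` must be strictly increasing, start at 0 and end at 1; at
    each level ``n_repeats`` independent degraded matrices are generated
    (each repeat draws its own gene subset).
    """

    levels: tuple[float, ...] = DEFAULT_LEVELS
    n_repeats: int = 20
    method: str = "gaussian"
    seed: int = 0

    def __post_init__(self) -> None:
        self.levels = tuple(float(v) for v in self.levels)
        if len(self.levels) < 1:
            raise ValueError("need at least one degradation level")
        if any(b <= a for a, b in zip(self.levels, self.levels[1:])):
            raise ValueError("levels must be strictly increasing")
        if self.levels[0] != 0.0:
            raise ValueError("first level must be 0")
        if self.levels[-1] > 1.0:
            raise ValueError("levels must lie in [0, 1]")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be positive")
        if self.method not in ("gaussian", "permute", "global"):
            raise ValueError(f"unknown degradation method {self.method!r}")


def _n_degraded(fraction: float, m: int) -> int:
    # round half up: fraction 0.5 of 10 genes -> 5, fraction 1 -> all
    return int(np.floor(fraction * m + 0.5))


def _check_fraction(fraction: float) -> None:
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"degradation level must be in [0, 1], got {fraction}")


def degrade_gaussian(expr: LabelledExpression, fraction: float,
                     rng: np.random.Generator) -> LabelledExpression:
    """Replace a random ⌊fraction·m⌉-gene subset by moment-matched noise.

    Each selected gene's column is replaced by i.i.d. Normal draws with
    that gene's sample mean and unbiased sample variance; unselected
    columns are bit-identical to the input.
    """
    _check_fraction(fraction)
    n, m = expr.values.shape
    c = _n_degraded(fraction, m)
    values = expr.values.copy()
    if c > 0:
        chosen = rng.choice(m, size=c, replace=False)
        sub = values[:, chosen]
        mu = sub.mean(axis=0)
        sd = sub.std(axis=0, ddof=1) if n > 1 else np.zeros(c)
        values[:, chosen] = mu + sd * rng.standard_normal((n, c))
    return expr.with_values(values)


def degrade_permute(expr: LabelledExpression, fraction: float,
                    rng: np.random.Generator) -> LabelledExpression:
    """Independently permute the sample order of a random gene subset."""
    _check_fraction(fraction)
    n, m = expr.values.shape
    c = _n_degraded(fraction, m)
    values = expr.values.copy()
    if c > 0:
        chosen = rng.choice(m, size=c, replace=False)
        for j in chosen:
            values[:, j] = values[rng.permutation(n), j]
    return expr.with_values(values)


def degrade_global(expr: LabelledExpression, level: float,
                   rng: np.random.Generator) -> LabelledExpression:
    """Interpolate every gene toward moment-matched noise in parallel.

    x' = μ_g + √(1−level)·(x−μ_g) + √level·ε, ε ~ N(0, s_g²) per cell.
    Level 0 is the identity; level 1 coincides in distribution with
    ``degrade_gaussian`` at fraction 1. A constant column stays constant.
    """
    _check_fraction(level)
    if level == 0.0:
        return expr.with_values(expr.values.copy())
    n, m = expr.values.shape
    mu = expr.values.mean(axis=0)
    sd = expr.values.std(axis=0, ddof=1) if n > 1 else np.zeros(m)
    eps = rng.standard_normal((n, m)) * sd
    values = mu + np.sqrt(1.0 - level) * (expr.values - mu) + np.sqrt(level) * eps
    return expr.with_values(values)


_METHODS = {
    "gaussian": degrade_gaussian,
    "permute": degrade_permute,
    "global": degrade_global,
}


def degrade(expr: LabelledExpression, level: float, method: str,
            rng: np.random.Generator) -> LabelledExpression:
    """Apply one degradation strategy by name at the given level."""
    try:
        fn = _METHODS[method]
    except KeyError:
        raise ValueError(f"unknown degradation method {method!r}") from None
    return fn(expr, level, rng)
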