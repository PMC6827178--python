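"""End-to-end experiment orchestration driven by a config mapping.

A config is a plain (YAML-loadable) nested dict. Recognised sections:

``seed``          master seed; every stage derives its own stream from it.
``data``          either ``{"simulate": {<SyntheticParams fields>}}`` or
                  ``{"matrix": path, "labels": path, "gmt": path}``.
``restrict``      ``{"min_size": int}`` for universe restriction (default 2).
``scoring``       ``{"method": "pca"|"mean"|"ssgsea", "kwargs": {...}}``.
``degradation``   ``{"method", "levels", "n_repeats"}``.
``model``         ``{"classifier", "complexity" ("auto" or number),
                  "candidates"}``.
``cv``            ``{"kind": "auto"|..., "folds": int}``.
``fake_compare``  ``{"n_fakes": int}``.
``signature``     ``{"n_fakes": int, "n_comp": int}``.

All outputs are TSV files with fixed float formatting, so a rerun with
the same config and seed reproduces them byte-for-byte; results are also
independent of the thread count (cell seeds are derived from coordinates,
not execution order).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .analysis import (PairedRobustnessAnalysis, RobustnessFit,
                       SignatureAnalysis)
from .classify import CVScheme
from .data import (DataError, LabelledExpression, PathwayCollection, read_gmt,
                   read_expression, restrict_to_universe, write_expression,
                   write_gmt)
from .degradation import DEFAULT_LEVELS, DegradationConfig
from .randomization import permute_gene_labels, subsample_database
from .robustness import SpaceSpec, degradation_sweep, predictive_robustness
from .synthetic import SyntheticParams, generate_synthetic

__all__ = ["load_config", "load_inputs", "run_robustness_comparison",
           "run_fake_comparison", "run_database_analysis"]

FLOAT_FMT = "%.10g"

_KNOWN_SECTIONS = {"seed", "out_dir", "threads", "data", "restrict", "scoring",
                   "degradation", "model", "cv", "fake_compare", "signature",
                   "plot"}


class ConfigError(ValueError):
    pass


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh) or {}
    validate_config(config)
    return config


def validate_config(config: dict) -> None:
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    unknown = sorted(set(config) - _KNOWN_SECTIONS)
    if unknown:
        raise ConfigError(f"unknown config keys: {unknown}")
    data = config.get("data")
    if data is not None:
        if "simulate" not in data and not {"matrix", "labels"} <= set(data):
            raise ConfigError(
                "config section 'data' needs either 'simulate' or "
                "'matrix'+'labels' (+'gmt'); offending keys: "
                f"{sorted(data)}")


def load_inputs(config: dict) -> tuple[LabelledExpression, PathwayCollection | None]:
    """Materialize (expression, collection) from the config, restricted."""
    data = config.get("data") or {"simulate": {}}
    if "simulate" in data:
        params = SyntheticParams(**{**(data["simulate"] or {}),
                                    "seed": int(config.get("seed", 0))})
        expr, coll = generate_synthetic(params)
    else:
        expr = read_expression(data["matrix"], data["labels"])
        coll = read_gmt(data["gmt"]) if "gmt" in data else None
    if coll is not None:
        min_size = (config.get("restrict") or {}).get("min_size", 2)
        expr, coll = restrict_to_universe(expr, coll, min_size=min_size)
    return expr, coll


def _analysis_kwargs(config: dict) -> dict:
    scoring = config.get("scoring") or {}
    deg = config.get("degradation") or {}
    model = config.get("model") or {}
    cv = config.get("cv") or {}
    cands = model.get("candidates")
    return dict(
        scoring=scoring.get("method", "pca"),
        scoring_kwargs=scoring.get("kwargs") or {},
        classifier=model.get("classifier", "plsda"),
        complexity=model.get("complexity", "auto"),
        candidates=tuple(cands) if cands else None,
        levels=tuple(deg.get("levels", DEFAULT_LEVELS)),
        n_repeats=int(deg.get("n_repeats", 20)),
        degradation=deg.get("method", "gaussian"),
        cv=cv.get("kind", "auto"),
        n_folds=int(cv.get("folds", 2)),
    )


def _write(df: pd.DataFrame, out_dir: Path, name: str) -> Path:
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / name
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    return path


def run_robustness_comparison(config: dict, out_dir: str | Path):
    """Paired gene-space vs pathway-space robustness; writes
    ``profiles.tsv`` and ``robustness_summary.tsv``."""
    out_dir = Path(out_dir)
    seed = int(config.get("seed", 0))
    n_jobs = int(config.get("threads", 1))
    expr, coll = load_inputs(config)
    if coll is None:
        raise ConfigError("robustness comparison requires a pathway collection")
    fit = PairedRobustnessAnalysis(expr, coll, **_analysis_kwargs(config)).fit(
        seed=seed, n_jobs=n_jobs)
    profiles = pd.concat([fit.gene.profile.to_frame(),
                          fit.pathway.profile.to_frame()], ignore_index=True)
    _write(profiles, out_dir, "profiles.tsv")
    _write(fit.to_frame(), out_dir, "robustness_summary.tsv")
    if config.get("plot"):
        fig = fit.plot_profiles()
        fig.savefig(out_dir / "profiles.png", dpi=150)
    return fit


def run_fake_comparison(config: dict, out_dir: str | Path) -> pd.DataFrame:
    """Pathway-space robustness of the real collection and of n label-
    permuted fake collections, all on shared degraded realisations;
    writes ``fake_comparison.tsv``."""
    out_dir = Path(out_dir)
    seed = int(config.get("seed", 0))
    n_jobs = int(config.get("threads", 1))
    n_fakes = int((config.get("fake_compare") or {}).get("n_fakes", 10))
    expr, coll = load_inputs(config)
    if coll is None:
        raise ConfigError("fake comparison requires a pathway collection")
    kw = _analysis_kwargs(config)
    deg_config = DegradationConfig(levels=kw["levels"],
                                   n_repeats=kw["n_repeats"],
                                   method=kw["degradation"], seed=seed)
    scheme = CVScheme(
        kind=("leave_one_group_out" if kw["cv"] == "auto"
              and expr.group_labels is not None else
              "stratified_kfold" if kw["cv"] == "auto" else kw["cv"]),
        n_folds=kw["n_folds"], seed=seed)

    def space(name, collection, complexity):
        return SpaceSpec(name=name, collection=collection,
                         scoring_method=kw["scoring"],
                         scoring_kwargs=kw["scoring_kwargs"],
                         classifier=kw["classifier"], complexity=complexity,
                         candidates=kw["candidates"])

    # complexity is resolved once, on the real collection, then reused
    real = degradation_sweep(expr, [space("real", coll, kw["complexity"])],
                             deg_config, scheme, n_jobs=n_jobs)["real"]
    complexity = real["complexity"]
    spaces = []
    for i in range(n_fakes):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 23, i]))
        spaces.append(space(f"fake_{i}", permute_gene_labels(coll, rng),
                            complexity))
    fakes = (degradation_sweep(expr, spaces, deg_config, scheme, n_jobs=n_jobs)
             if spaces else {})
    rows = []
    for name, res in [("real", real)] + [(s.name, fakes[s.name]) for s in spaces]:
        rob = predictive_robustness(res["profile"])
        rows.append({"collection": name, "classifier": kw["classifier"],
                     "complexity": complexity, "a0": res["profile"].a0,
                     "R": rob.R, "ci_lo": rob.ci_90[0], "ci_hi": rob.ci_90[1]})
    table = pd.DataFrame(rows)
    _write(table, out_dir, "fake_comparison.tsv")
    return table


def run_database_analysis(config: dict, out_dir: str | Path) -> pd.DataFrame:
    """Entropy/ABC signature comparison per source database; writes
    ``database_signatures.tsv`` (plus ``subsample_control.tsv`` when a
    subsampling control is configured)."""
    out_dir = Path(out_dir)
    seed = int(config.get("seed", 0))
    sig_cfg = config.get("signature") or {}
    expr, coll = load_inputs(config)
    if coll is None:
        raise ConfigError("database analysis requires a pathway collection")
    if not coll.source_db:
        raise ConfigError(
            "collection has no source-database tags; re-read the GMT with a "
            "source override (CLI: --source-tag) or supply tagged pathways")
    analysis = SignatureAnalysis(
        expr, coll, scoring=(config.get("scoring") or {}).get("method", "pca"),
        scoring_kwargs=(config.get("scoring") or {}).get("kwargs") or {},
        n_comp=int(sig_cfg.get("n_comp", 3)),
        n_fakes=int(sig_cfg.get("n_fakes", 100)))
    fits = analysis.fit_by_source(seed=seed)
    rows = [fit.summary_row() for fit in fits.values()]
    for row, (tag, _) in zip(rows, fits.items()):
        row["k"] = coll.by_source()[tag].n_pathways
    table = pd.DataFrame(rows)
    _write(table, out_dir, "database_signatures.tsv")

    sub_cfg = sig_cfg.get("subsample")
    if sub_cfg:
        db = sub_cfg["database"]
        sizes = sub_cfg["sizes"]
        base = coll.by_source()[db]
        sub_rows = []
        for j, size in enumerate(sizes):
            rng = np.random.default_rng(np.random.SeedSequence([seed, 31, j]))
            sub_coll = subsample_database(base, int(size), rng)
            sub_fit = SignatureAnalysis(
                expr, sub_coll, scoring=analysis.scoring,
                scoring_kwargs=analysis.scoring_kwargs, n_comp=analysis.n_comp,
                n_fakes=analysis.n_fakes)._one(
                    sub_coll,
                    np.random.default_rng(np.random.SeedSequence([seed, 37, j])),
                    f"{db}[{size}]")
            sub_rows.append({**sub_fit.summary_row(), "k": size})
        _write(pd.DataFrame(sub_rows), out_dir, "subsample_control.tsv")
    return table
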