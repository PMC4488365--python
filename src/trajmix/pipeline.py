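"""End-to-end orchestration: config, validation, pipeline stages, reports.

``run_pipeline`` sequences read -> filter -> stratify -> center -> select
-> classify -> refit with covariates -> RRR tables -> sensitivity refits,
writing plain-CSV outputs plus a JSON manifest (config hash, seed, library
versions) sufficient to reproduce every output.  Validation happens before
any file is written.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import adjusted_and_unadjusted
from .mixture import classify, fit_em, select_model
from .panel import (
    BaselineTable,
    ConfigError,
    ExposureSpec,
    SUBSET_RULES,
    TrajectoryPanel,
    filter_min_visits,
    preprocess_exposure_series,
    read_baseline_table,
    read_long_panel,
    stratify,
)
from .transform import center_trajectories

log = logging.getLogger("trajmix")

__all__ = ["PipelineConfig", "run_pipeline", "render_report", "load_config"]


@dataclass
class PipelineConfig:
    panel_path: str
    baseline_path: str
    seed: int
    exposures: list = field(default_factory=list)  # dicts: name, lod?, log10_applied?
    confounders: list = field(default_factory=list)
    column_map: dict = field(default_factory=dict)
    K_range: tuple = (2, 3, 4, 5)
    cov_kinds: tuple = ("independence", "exponential")
    min_visits: int = 4
    stratify_by: str | None = "sex"
    sensitivity: list = field(default_factory=list)
    em: dict = field(default_factory=dict)  # tol, max_iter, n_starts
    ci_method: str = "full"

    @classmethod
    def from_mapping(cls, raw: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in raw:
            raise ConfigError("config must set a seed (stochastic fitting steps)")
        cfg = cls(**raw)
        cfg.K_range = tuple(cfg.K_range)
        cfg.cov_kinds = tuple(cfg.cov_kinds)
        return cfg


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} is not a mapping")
    return PipelineConfig.from_mapping(raw)


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(cfg.__dict__, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _validate(cfg: PipelineConfig) -> tuple[TrajectoryPanel, BaselineTable]:
    """Fail fast: read inputs and resolve every referenced name before
    anything is written."""
    panel = read_long_panel(cfg.panel_path, cfg.column_map or None)
    baseline = read_baseline_table(cfg.baseline_path)
    cols = set(baseline.table.columns)
    for spec in cfg.exposures:
        if spec["name"] not in cols:
            raise ConfigError(f"exposure column {spec['name']!r} not in baseline table")
    for c in cfg.confounders:
        if c not in cols:
            raise ConfigError(f"confounder column {c!r} not in baseline table")
    if cfg.stratify_by and cfg.stratify_by != "sex":
        raise ConfigError(f"unsupported stratify_by {cfg.stratify_by!r}")
    for rule in cfg.sensitivity:
        if rule not in SUBSET_RULES:
            raise ConfigError(f"unknown sensitivity rule {rule!r}")
    missing = [s for s in panel.subjects if s not in set(baseline.subjects)]
    if missing:
        raise ConfigError(f"panel subjects missing from baseline: {missing[:5]}")
    return panel, baseline


def _prepare_exposures(cfg: PipelineConfig, baseline: BaselineTable) -> tuple[BaselineTable, list]:
    """log10-transform raw concentration columns (below-LOD -> LOD/2)."""
    tab = baseline.table
    names = []
    for spec in cfg.exposures:
        name = spec["name"]
        if spec.get("log10_applied", False):
            names.append(name)
            continue
        es = ExposureSpec(name=name, lod=spec.get("lod"))
        out = f"log10_{name}"
        tab[out] = preprocess_exposure_series(tab[name], es)
        names.append(out)
    return BaselineTable(tab.reset_index()), names


def _analyse_stratum(label, panel, baseline, cfg, exposure_names, seed):
    em = dict(cfg.em)
    centered = center_trajectories(panel)
    best, table = select_model(
        centered, K_range=cfg.K_range, cov_kinds=cfg.cov_kinds, seed=seed, **em
    )
    labels, uncertainty = classify(best)
    rrr_table = (
        adjusted_and_unadjusted(
            centered,
            baseline,
            exposure_names,
            cfg.confounders,
            K=best.model.K,
            cov_kind=best.model.cov[0].kind,
            seed=seed,
            base_fit=best,
            stratum=label,
            ci_method=cfg.ci_method,
            **em,
        )
        if exposure_names
        else pd.DataFrame()
    )
    return dict(
        label=label,
        panel=panel,
        fit=best,
        selection=table.assign(stratum=label),
        labels=labels,
        uncertainty=uncertainty.assign(stratum=label),
        rrr=rrr_table,
    )


def run_pipeline(cfg: PipelineConfig, out_dir) -> dict:
    """Execute the full analysis; returns the report bundle (also written
    under ``out_dir``).  Identical config + inputs give identical outputs."""
    panel, baseline = _validate(cfg)
    out = Path(out_dir)

    baseline, exposure_names = _prepare_exposures(cfg, baseline)
    panel = filter_min_visits(panel, cfg.min_visits)
    log.info("retained %d subjects with >= %d visits", panel.n_subjects, cfg.min_visits)

    if cfg.stratify_by:
        strata = stratify(panel, baseline, by=cfg.stratify_by)
    else:
        strata = [("all", panel, baseline.restrict(panel.subjects))]

    seeds = np.random.SeedSequence(cfg.seed).generate_state(
        len(strata) * (1 + len(cfg.sensitivity))
    ) & 0x7FFFFFFF
    si = 0
    results = []
    for label, p_s, b_s in strata:
        log.info("stratum %s: n=%d", label, p_s.n_subjects)
        results.append(_analyse_stratum(label, p_s, b_s, cfg, exposure_names, int(seeds[si])))
        si += 1
        for rule in cfg.sensitivity:
            (r_label, p_r, b_r), = stratify(p_s, b_s, by=rule)
            results.append(
                _analyse_stratum(
                    f"{label}:{rule}", p_r, b_r, cfg, exposure_names, int(seeds[si])
                )
            )
            si += 1

    bundle = render_report(results, out)
    manifest = dict(
        config_hash=_config_hash(cfg),
        seed=cfg.seed,
        trajmix_version=__version__,
        numpy_version=np.__version__,
        pandas_version=pd.__version__,
        python_version=sys.version.split()[0],
        strata=[r["label"] for r in results],
    )
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    bundle["manifest"] = manifest
    return bundle


def render_report(results: list, out_dir) -> dict:
    """Write CSV summaries: selection table, group sizes, per-visit raw-BMI
    summaries by assigned group, posterior tables, uncertainty fractions,
    RRR tables, and dense-grid mean curves for plotting."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    selection = pd.concat([r["selection"] for r in results], ignore_index=True)
    uncertainty = pd.concat([r["uncertainty"] for r in results], ignore_index=True)
    rrr_tables = [r["rrr"] for r in results if len(r["rrr"])]
    rrr = pd.concat(rrr_tables, ignore_index=True) if rrr_tables else pd.DataFrame()

    sizes = []
    visit_summaries = []
    curves = []
    posteriors = []
    for r in results:
        fit = r["fit"]
        lab = r["labels"]
        counts = lab.value_counts().sort_index()
        for g, c in counts.items():
            sizes.append(dict(stratum=r["label"], group=int(g), n=int(c)))
        raw = r["panel"].records
        raw = raw.assign(group=lab.reindex(raw["subject_id"]).to_numpy())
        summ = (
            raw.groupby(["group", "age"])["value"]
            .agg(["mean", "std", "count"])
            .reset_index()
            .assign(stratum=r["label"])
        )
        visit_summaries.append(summ)
        lo, hi = fit.model.basis.boundary
        grid = np.linspace(lo, hi, 81)
        M = fit.model.mean_curves(grid)  # (len(grid), K)
        cdf = pd.DataFrame(M, columns=[f"group_{k + 1}" for k in range(fit.model.K)])
        cdf.insert(0, "age", grid)
        cdf["stratum"] = r["label"]
        curves.append(cdf)
        pt = fit.posterior_table.reset_index()
        pt["stratum"] = r["label"]
        posteriors.append(pt)

    tables = {
        "selection": selection,
        "group_sizes": pd.DataFrame(sizes),
        "group_visit_summary": pd.concat(visit_summaries, ignore_index=True),
        "uncertainty": uncertainty,
        "rrr": rrr,
        "mean_curves": pd.concat(curves, ignore_index=True),
        "posteriors": pd.concat(posteriors, ignore_index=True),
    }
    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False)
    return dict(results=results, **tables)
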