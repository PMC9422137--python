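"""Orchestration: crossing-effect and proximity-effect analyses per tactic.

Each tactic (migrant / resident) is analyzed in a fully independent run:
its own empirical kernels, crossing caps, collinearity screen, 32-model AIC
comparison, standardized refit of the top model, and RSS contrasts. Every
filtering stage logs counts in/out so sample-size attrition is auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import Polygon, box

from . import choiceset, covariates, model, tracks
from .covariates import StackedLayerIndex
from .features import ConfigClass, FeatureLayer
from .geoio import CategoricalRaster
from .tracks import Tactic, TrackPoint

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Analysis constants; defaults are the study design's stated values."""

    fix_interval_h: float = 4.0
    fix_tolerance_min: float = 15.0
    k_available: int = 5
    buffer_radius_m: float = 6746.0
    distance_cap_m: float = 1000.0
    crossing_cap_percentile: float = 98.0
    min_relocations: int = 500
    road_buffer_paved_m: float = 40.0
    road_buffer_unpaved_m: float = 20.0
    correlation_threshold: float = 0.7
    delta_aic_cutoff: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "fix_interval_h", "fix_tolerance_min", "k_available", "buffer_radius_m",
            "distance_cap_m", "crossing_cap_percentile", "min_relocations",
            "road_buffer_paved_m", "road_buffer_unpaved_m", "correlation_threshold",
            "delta_aic_cutoff",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


@dataclass
class ScaleResult:
    """One tactic x scale analysis: data summary through RSS contrasts."""

    tactic: Tactic
    scale: str
    n_animals: int
    n_strata: int
    relocation_summary: dict[str, float]
    strata: pd.DataFrame  # capped covariate table (one row per candidate)
    caps: dict[ConfigClass, covariates.CapRule] | None
    screen: covariates.ScreenReport
    comparison: model.ModelComparison
    recipe: model.StandardizationRecipe
    fit_std: model.FitResult
    fit_raw: model.FitResult
    contrasts: pd.DataFrame | None  # crossing scale: 1-vs-0 crossing RSS
    rss_curves: pd.DataFrame  # range-vs-mean curves per feature covariate


def _reloc_summary(groups: dict[str, list[TrackPoint]]) -> dict[str, float]:
    counts = np.array([len(v) for v in groups.values()], dtype=float)
    if len(counts) == 0:
        return {"n_animals": 0, "mean": np.nan, "se": np.nan, "min": np.nan, "max": np.nan}
    return {
        "n_animals": len(counts),
        "mean": float(counts.mean()),
        "se": float(counts.std(ddof=1) / np.sqrt(len(counts))) if len(counts) > 1 else 0.0,
        "min": float(counts.min()),
        "max": float(counts.max()),
    }


def _retained_groups(
    points: list[TrackPoint],
    tactic: Tactic,
    study_area: tuple[float, float, float, float],
    config: RunConfig,
) -> dict[str, list[TrackPoint]]:
    tactic_pts = [p for p in points if p.tactic is tactic]
    in_area = tracks.points_in_area(tactic_pts, study_area)
    groups = tracks.group_by_animal(in_area)
    retained = tracks.filter_min_relocations(groups, config.min_relocations)
    logger.info(
        "%s: %d relocations in area, %d/%d animals retained (>=%d relocations)",
        tactic.value, len(in_area), len(retained), len(groups), config.min_relocations,
    )
    return dict(sorted(retained.items()))


def _screen_columns(table: pd.DataFrame, feature_cols: list[str]) -> covariates.ScreenReport:
    design = model.expand_landcover(table)[
        feature_cols + [f"lc_{lvl}" for lvl in model.LANDCOVER_LEVELS]
    ]
    return covariates.screen_collinearity(design)


def run_crossing_analysis(
    points: list[TrackPoint],
    layers: dict[ConfigClass, FeatureLayer] | StackedLayerIndex,
    raster: CategoricalRaster,
    config: RunConfig,
    tactic: Tactic,
    study_area: tuple[float, float, float, float],
    availability_kernel: choiceset.ParametricKernel | None = None,
) -> ScaleResult:
    """Step-scale analysis: do animals select against steps that cross features?

    ``availability_kernel`` overrides the per-animal empirical kernels with a
    known proposal kernel (e.g., the generating kernel of a simulation);
    the default is empirical resampling of each animal's own steps.
    """
    stacked = covariates._as_stacked(layers)
    retained = _retained_groups(points, tactic, study_area, config)
    summary = _reloc_summary(retained)

    ss = np.random.SeedSequence([config.seed, 0, 0 if tactic is Tactic.migrant else 1])
    seeds = ss.spawn(len(retained))
    strata_parts = []
    for (aid, pts), child in zip(retained.items(), seeds):
        reg = tracks.regularize(pts, config.fix_interval_h, config.fix_tolerance_min)
        steps = tracks.build_steps(reg, config.fix_interval_h, config.fix_tolerance_min)
        kernel = choiceset.build_kernel(steps)
        if kernel is None:
            continue
        if availability_kernel is not None:
            kernel = availability_kernel
        df = choiceset.build_crossing_strata(
            steps, kernel, np.random.default_rng(child), k=config.k_available
        )
        if len(df):
            strata_parts.append(df)
    if not strata_parts:
        raise ValueError(f"no crossing-scale strata for tactic {tactic.value}")
    strata = pd.concat(strata_parts, ignore_index=True)

    table = covariates.compute_crossing_covariates(strata, stacked, raster)
    counts_by_class = {
        cc: table[f"n_cross_{cc.value}"].to_numpy() for cc in ConfigClass
    }
    caps = covariates.fit_caps(counts_by_class, config.crossing_cap_percentile)
    table = covariates.apply_crossing_caps(table, caps)
    feature_cols = covariates.crossing_covariate_columns()
    screen = _screen_columns(table, feature_cols)
    table = model.expand_landcover(table)

    comparison = model.compare_models(table, "crossing", config.delta_aic_cutoff)
    top_spec = comparison.top.spec
    recipe, fit_std = model.standardize_and_refit(top_spec, table)
    fit_raw = comparison.top

    rows = []
    for cc in ConfigClass:
        col = f"n_cross_{cc.value}"
        if col in fit_raw.covariates:
            c = model.crossing_contrast(fit_raw, cc)
            rows.append(
                (cc.value, fit_raw.beta[col], c.log_rss, c.rss, 100.0 * (1.0 - c.rss))
            )
    contrasts = pd.DataFrame(
        rows, columns=["feature", "beta_raw", "log_rss", "rss", "pct_decrease"]
    )

    means = {c: float(table[c].mean()) for c in fit_raw.covariates if not c.startswith("lc_")}
    curves = []
    for cc in ConfigClass:
        col = f"n_cross_{cc.value}"
        if col in fit_raw.covariates and caps is not None:
            grid = np.arange(0, caps[cc].cap_value + 1, dtype=float)
            curves.append(model.range_vs_mean_curve(fit_raw, col, grid, means))
    rss_curves = pd.concat(curves, ignore_index=True) if curves else pd.DataFrame()

    return ScaleResult(
        tactic=tactic,
        scale="crossing",
        n_animals=int(summary["n_animals"]),
        n_strata=int(table["stratum_id"].nunique()),
        relocation_summary=summary,
        strata=table,
        caps=caps,
        screen=screen,
        comparison=comparison,
        recipe=recipe,
        fit_std=fit_std,
        fit_raw=fit_raw,
        contrasts=contrasts,
        rss_curves=rss_curves,
    )


def run_proximity_analysis(
    points: list[TrackPoint],
    layers: dict[ConfigClass, FeatureLayer] | StackedLayerIndex,
    raster: CategoricalRaster,
    config: RunConfig,
    tactic: Tactic,
    study_area: tuple[float, float, float, float],
) -> ScaleResult:
    """Broad-scale analysis: do animals position themselves away from features?"""
    stacked = covariates._as_stacked(layers)
    retained = _retained_groups(points, tactic, study_area, config)
    summary = _reloc_summary(retained)

    ss = np.random.SeedSequence([config.seed, 1, 0 if tactic is Tactic.migrant else 1])
    seeds = ss.spawn(len(retained))
    strata_parts = []
    for (aid, pts), child in zip(retained.items(), seeds):
        df = choiceset.build_proximity_strata(
            pts,
            np.random.default_rng(child),
            radius=config.buffer_radius_m,
            k=config.k_available,
        )
        strata_parts.append(df)
    if not strata_parts:
        raise ValueError(f"no proximity-scale strata for tactic {tactic.value}")
    strata = pd.concat(strata_parts, ignore_index=True)

    table = covariates.compute_proximity_covariates(
        strata, stacked, raster, cap=config.distance_cap_m
    )
    feature_cols = covariates.distance_covariate_columns()
    screen = _screen_columns(table, feature_cols)
    table = model.expand_landcover(table)

    comparison = model.compare_models(table, "proximity", config.delta_aic_cutoff)
    top_spec = comparison.top.spec
    recipe, fit_std = model.standardize_and_refit(top_spec, table)
    fit_raw = comparison.top

    means = {c: float(table[c].mean()) for c in fit_raw.covariates if not c.startswith("lc_")}
    curves = []
    for cc in ConfigClass:
        col = f"dist_{cc.value}"
        if col in fit_raw.covariates:
            grid = np.linspace(0.0, config.distance_cap_m, 21)
            curves.append(model.range_vs_mean_curve(fit_raw, col, grid, means))
    rss_curves = pd.concat(curves, ignore_index=True) if curves else pd.DataFrame()

    rows = []
    for cc in ConfigClass:
        col = f"dist_{cc.value}"
        if col in fit_raw.covariates:
            c = model.log_rss(
                fit_raw,
                {**{k: means.get(k, 0.0) for k in fit_raw.covariates}, col: 0.0,
                 **{f"lc_{lvl}": (1.0 if lvl == "NATIVE" else 0.0) for lvl in model.LANDCOVER_LEVELS if f"lc_{lvl}" in fit_raw.covariates}},
                {**{k: means.get(k, 0.0) for k in fit_raw.covariates}, col: config.distance_cap_m,
                 **{f"lc_{lvl}": (1.0 if lvl == "NATIVE" else 0.0) for lvl in model.LANDCOVER_LEVELS if f"lc_{lvl}" in fit_raw.covariates}},
            )
            rows.append((cc.value, fit_raw.beta[col], c.log_rss, c.rss, 100.0 * (c.rss - 1.0)))
    contrasts = pd.DataFrame(
        rows, columns=["feature", "beta_raw", "log_rss", "rss_near_vs_far", "pct_change_near_vs_far"]
    )

    return ScaleResult(
        tactic=tactic,
        scale="proximity",
        n_animals=int(summary["n_animals"]),
        n_strata=int(table["stratum_id"].nunique()),
        relocation_summary=summary,
        strata=table,
        caps=None,
        screen=screen,
        comparison=comparison,
        recipe=recipe,
        fit_std=fit_std,
        fit_raw=fit_raw,
        contrasts=contrasts,
        rss_curves=rss_curves,
    )


def summarize_features(
    layers: dict[ConfigClass, FeatureLayer], study_area: Polygon | tuple
) -> pd.DataFrame:
    """Per-class total length (km) and density (km/km^2) over a study area."""
    poly = study_area if isinstance(study_area, Polygon) else box(*study_area)
    area_km2 = poly.area / 1e6
    if area_km2 <= 0:
        raise ValueError("study area must have positive area")
    rows = []
    for cc in ConfigClass:
        km = layers[cc].total_length_km if cc in layers else 0.0
        rows.append((cc.value, km, km / area_km2))
    return pd.DataFrame(rows, columns=["config_class", "length_km", "density_km_per_km2"])


def write_scale_result(
    result: ScaleResult, outdir: str | Path, include_strata: bool = False
) -> None:
    """Serialize one tactic x scale analysis to CSVs (AIC table, coefficients,
    contrasts, RSS curves; optionally the flat strata+covariate table)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag = f"{result.tactic.value}_{result.scale}"
    if include_strata:
        result.strata.to_csv(outdir / f"strata_{tag}.csv", index=False)
    result.comparison.table.to_csv(outdir / f"aic_{tag}.csv", index=False)
    coef = pd.DataFrame(
        {
            "covariate": result.fit_std.covariates,
            "beta_std": result.fit_std.beta.to_numpy(),
            "se_std": result.fit_std.se.to_numpy(),
            "beta_raw": [result.fit_raw.beta.get(c, np.nan) for c in result.fit_std.covariates],
            "se_raw": [result.fit_raw.se.get(c, np.nan) for c in result.fit_std.covariates],
        }
    )
    coef.to_csv(outdir / f"coefficients_{tag}.csv", index=False)
    if result.contrasts is not None:
        result.contrasts.to_csv(outdir / f"contrasts_{tag}.csv", index=False)
    result.rss_curves.to_csv(outdir / f"rss_curves_{tag}.csv", index=False)


def write_markdown_report(results: list[ScaleResult], path: str | Path) -> None:
    """Assemble a human-readable Markdown summary of one or more analyses."""
    lines = ["# Selection analysis report", ""]
    for r in results:
        s = r.relocation_summary
        lines += [
            f"## {r.tactic.value} — {r.scale} effect",
            "",
            f"- animals: {r.n_animals}; strata: {r.n_strata}",
            f"- relocations/animal: mean {s['mean']:.1f} (SE {s['se']:.2f}, "
            f"range {s['min']:.0f}-{s['max']:.0f})",
        ]
        if r.caps is not None:
            caps = ", ".join(f"{cc.value}={rule.cap_value}" for cc, rule in r.caps.items())
            lines.append(f"- crossing caps (98th pct): {caps}")
        if r.screen.flagged:
            pairs = "; ".join(f"{a}~{b} (r={v:.2f})" for a, b, v in r.screen.flagged)
            lines.append(f"- collinearity flags: {pairs}")
        top = r.comparison.table.iloc[0]
        lines += [
            f"- top model: **{top['model']}** (AIC {top['aic']:.1f}, "
            f"weight {top['weight']:.2f}); {len(r.comparison.competing)} "
            "model(s) at dAIC < 2",
            "",
            "| covariate | beta (std) | SE (std) |",
            "|---|---|---|",
        ]
        for c in r.fit_std.covariates:
            lines.append(f"| {c} | {r.fit_std.beta[c]:.3f} | {r.fit_std.se[c]:.3f} |")
        if r.contrasts is not None and len(r.contrasts):
            cols = list(r.contrasts.columns)
            lines += ["", "| " + " | ".join(cols) + " |",
                      "|" + "---|" * len(cols)]
            for _, row in r.contrasts.iterrows():
                cells = [
                    f"{v:.4g}" if isinstance(v, float) else str(v) for v in row
                ]
                lines.append("| " + " | ".join(cells) + " |")
        lines.append("")
    Path(path).write_text("\n".join(lines))
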