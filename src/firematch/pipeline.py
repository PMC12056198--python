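"""End-to-end orchestration: simulate → filter → sample → match → fit → counterfactual.

Stage order follows the analysis design: classification-confidence filter,
per-one-degree-cell capped sampling, tree-cover filter, per-country matching
with method selection, the covariate-balance gate (<0.25 after-match SMD for
every covariate), the burn-fraction gate (>0.1% of matched points burned),
one pooled penalized-spline GAM over the retained countries, per-country
Monte-Carlo counterfactuals, and the pooled group effect.

The master seed spawns independent named sub-seeds per stage so any stage
can be rerun in isolation without perturbing the others.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import accounting, matching
from .counterfactual import (
    CounterfactualResult,
    GroupEffect,
    counterfactual_country,
    expected_difference,
    pooled_effect,
)
from .gam import GamFit, GamSpec, fit_gam
from .scenarios import temperate1_config  # noqa: F401  (re-exported for drivers)
from .synthetic import COVARIATES, ScenarioConfig, SyntheticTruth, generate_scenario

__all__ = [
    "PipelineConfig",
    "RunReport",
    "run_pipeline",
    "read_points",
    "write_points",
    "make_report",
    "stage_seed",
]

#: ForestPoint CSV schema (order preserved on write).
POINT_COLUMNS = (
    ["id", "lon", "lat", "country", "biome", "mgmt_class", "confidence"]
    + COVARIATES
    + ["burned"]
)

_STAGES = ("simulate", "sample", "match", "fit", "counterfactual")


def stage_seed(master_seed: int, stage: str) -> int:
    """Independent per-stage sub-seed derived from the master seed."""
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(_STAGES.index(stage),))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """All thresholds, sizes and seeds of one reproducible run."""

    scenario: ScenarioConfig
    confidence_min: float = 0.70
    treecover_min: float = 0.30
    balance_threshold: float = 0.25
    burn_frac_min: float = 0.001
    cell_deg: float = 1.0
    max_per_cell: int = 5000
    methods: tuple[str, ...] = ("propensity", "mahalanobis")
    calipers: tuple[float, ...] = (0.2, 0.5)
    exact_vars: tuple[str, ...] = ("biome",)
    gam_k: int = 10
    tie_lambdas: bool = False  # one λ for all smooths + one per penalized factor class
    cf_n_points: int = 1000
    cf_n_reps: int = 10_000
    cf_mode: str = "bernoulli"
    seed: int = 0

    def __post_init__(self) -> None:
        for name, lo, hi in (
            ("confidence_min", 0, 1),
            ("treecover_min", 0, 1),
            ("burn_frac_min", 0, 1),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name} must be in [{lo},{hi}], got {v}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scenario"] = self.scenario.to_dict()
        for k in ("methods", "calipers", "exact_vars"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d["scenario"] = ScenarioConfig.from_dict(d["scenario"])
        for k in ("methods", "calipers", "exact_vars"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class RunReport:
    """Everything a run computed, plus its audit trail."""

    config: PipelineConfig
    truth: SyntheticTruth
    stage_counts: dict[str, int]
    matching_summary: dict[str, dict]
    balance_tables: dict[str, pd.DataFrame] = field(repr=False, default_factory=dict)
    dropped_countries: dict[str, str] = field(default_factory=dict)
    country_results: list[CounterfactualResult] = field(default_factory=list)
    group_effect: GroupEffect | None = None
    naive_relative_pct: float | None = None
    expected_relative_pct: float | None = None
    fit: GamFit | None = field(repr=False, default=None)
    matched_points: pd.DataFrame | None = field(repr=False, default=None)
    wall_times: dict[str, float] = field(default_factory=dict)

    @property
    def retained_countries(self) -> list[str]:
        return [r.country for r in self.country_results]

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "config_hash": self.config.config_hash(),
            "truth": self.truth.to_dict() if self.truth else None,
            "stage_counts": self.stage_counts,
            "matching_summary": self.matching_summary,
            "dropped_countries": self.dropped_countries,
            "country_results": [r.to_dict() for r in self.country_results],
            "group_effect": self.group_effect.to_dict() if self.group_effect else None,
            "naive_relative_pct": self.naive_relative_pct,
            "expected_relative_pct": self.expected_relative_pct,
            "wall_times": self.wall_times,
        }


def naive_relative_pct(points: pd.DataFrame) -> float:
    """Unmatched, unadjusted burn-rate contrast (the confounded estimate)."""
    plant = points["mgmt_class"].str.startswith("plantation")
    rate_pl = points.loc[plant, "burned"].mean()
    rate_nat = points.loc[~plant, "burned"].mean()
    if not rate_nat > 0:
        return float("nan")
    return float(100.0 * (rate_pl - rate_nat) / rate_nat)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages on the configured synthetic scenario."""
    times: dict[str, float] = {}
    counts: dict[str, int] = {}

    t0 = time.perf_counter()
    points, _rasters, truth = generate_scenario(config.scenario)
    counts["generated"] = len(points)
    times["simulate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    points = accounting.filter_confidence(points, config.confidence_min)
    counts["after_confidence_filter"] = len(points)
    points = accounting.stratified_sample(
        points,
        cell_deg=config.cell_deg,
        max_per_class=config.max_per_cell,
        seed=stage_seed(config.seed, "sample"),
    )
    counts["after_cell_sampling"] = len(points)
    points = accounting.filter_tree_cover(points, config.treecover_min)
    counts["after_treecover_filter"] = len(points)
    times["filter_sample"] = time.perf_counter() - t0

    naive_pct = naive_relative_pct(points)

    t0 = time.perf_counter()
    match_seed = stage_seed(config.seed, "match")
    matched_parts: list[pd.DataFrame] = []
    matching_summary: dict[str, dict] = {}
    balance_tables: dict[str, pd.DataFrame] = {}
    dropped: dict[str, str] = {}
    for country, grp in points.groupby("country", sort=True):
        grp = grp.reset_index(drop=True)
        treated = grp["mgmt_class"].str.startswith("plantation").to_numpy()
        if treated.sum() < 2 or (~treated).sum() < 2:
            dropped[country] = "too few treated or control points"
            continue
        try:
            scores, _model = matching.propensity_logit(grp, treated)
            ms, bt = matching.select_matching_method(
                grp,
                scores,
                methods=config.methods,
                calipers=config.calipers,
                exact_vars=config.exact_vars,
                seed=match_seed,
            )
        except ValueError as exc:
            dropped[country] = f"matching failed: {exc}"
            continue
        balance_tables[country] = bt
        matching_summary[country] = {
            "method": ms.method,
            "caliper": ms.caliper,
            "n_pairs": ms.n_pairs,
            "n_treated_dropped": ms.n_treated_dropped,
            "max_smd_after": float(bt["smd_after"].max()),
            "max_smd_before": float(bt["smd_before"].max()),
        }
        if not bool(bt["acceptable"].all()):
            dropped[country] = "covariate balance not achieved"
            continue
        matched_parts.append(grp[grp["id"].isin(ms.matched_ids())])
    times["match"] = time.perf_counter() - t0

    report = RunReport(
        config=config,
        truth=truth,
        stage_counts=counts,
        matching_summary=matching_summary,
        balance_tables=balance_tables,
        dropped_countries=dropped,
        naive_relative_pct=naive_pct,
    )
    if not matched_parts:
        counts["matched_points"] = 0
        counts["retained_countries"] = 0
        return report

    matched = pd.concat(matched_parts, ignore_index=True)
    counts["matched_points"] = len(matched)

    keep = accounting.country_inclusion(matched, config.burn_frac_min)
    for country, ok in keep.items():
        if not ok:
            dropped[country] = "burned fraction below inclusion threshold"
    matched = matched[matched["country"].map(keep)]
    counts["retained_countries"] = int(matched["country"].nunique())
    report.matched_points = matched
    if len(matched) == 0:
        return report

    t0 = time.perf_counter()
    spec = GamSpec(k=config.gam_k)
    tie = None
    if config.tie_lambdas:
        # pool λ selection into three classes to keep large runs tractable
        tie = {"smooths": [], "random": [], "interactions": []}
        for g in (
            [f"s({c})" for c in spec.covariates] + ["s(lon)", "s(lat)"]
        ):
            tie["smooths"].append(g)
        for v in spec.random_intercepts:
            tie["random"].append(f"ri({v})")
        tie["interactions"] += ["biome:country", "biome:management", "biome:s(tree_cover)"]
        if matched["biome"].nunique() < 2 or matched["country"].nunique() < 2:
            tie = None  # degenerate factor structure; fall back to per-term λ
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_gam(matched, spec, tie_groups=tie)
    report.fit = fit
    times["fit"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    cf_seed = stage_seed(config.seed, "counterfactual")
    results = []
    exp_diffs, exp_base = [], []
    for i, (country, grp) in enumerate(matched.groupby("country", sort=True)):
        res = counterfactual_country(
            fit,
            grp.reset_index(drop=True),
            n_points=config.cf_n_points,
            n_reps=config.cf_n_reps,
            seed=cf_seed + i,
            mode=config.cf_mode,
        )
        results.append(res)
        exp_diffs.append(expected_difference(fit, grp))
        exp_base.append(res.mean_prob_natural)
    report.country_results = results
    group = config.scenario.plantation_kind
    report.group_effect = pooled_effect(
        results, group=group, seed=stage_seed(config.seed, "counterfactual")
    )
    # analytic (noise-free) twin of the pooled Monte-Carlo estimate
    report.expected_relative_pct = float(
        100.0 * np.mean(exp_diffs) / np.mean(exp_base)
    )
    times["counterfactual"] = time.perf_counter() - t0
    report.wall_times = times
    return report


def write_points(points: pd.DataFrame, path) -> None:
    """Write a point table as CSV in the documented column order."""
    missing = [c for c in POINT_COLUMNS if c not in points.columns]
    if missing:
        raise ValueError(f"point table missing mandatory column(s): {missing}")
    extra = [c for c in points.columns if c not in POINT_COLUMNS]
    points[POINT_COLUMNS + extra].to_csv(path, index=False)


def read_points(path) -> pd.DataFrame:
    """Read a point-table CSV, validating the mandatory schema."""
    df = pd.read_csv(path)
    missing = [c for c in POINT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"point table missing mandatory column(s): {missing}")
    bad = df.index[~df["burned"].isin((0, 1))].tolist()
    if bad:
        raise ValueError(f"burned must be 0/1; bad rows: {bad[:10]}")
    return df


def make_report(report: RunReport) -> tuple[dict, str]:
    """JSON-ready dict plus a Markdown summary table of country effects."""
    d = report.to_dict()
    lines = [
        "| country | prob natural | prob plantation | % difference | significant |",
        "|---|---|---|---|---|",
    ]
    for r in report.country_results:
        lines.append(
            f"| {r.country} | {r.mean_prob_natural:.4f} | {r.mean_prob_plantation:.4f} "
            f"| {r.relative_pct:+.1f}% | {'yes' if r.significant else 'no'} |"
        )
    if report.group_effect is not None:
        g = report.group_effect
        lines.append(
            f"\nPooled {g.group} effect: {g.mean_relative_pct:+.1f}% "
            f"(p = {g.p_value:.4g})"
        )
    return d, "\n".join(lines)
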