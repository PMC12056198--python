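"""Reference synthetic scenarios used by the test-bench analyses.

``TEMPERATE-1`` is the parameter-recovery surface: a confounded landscape
(plantations preferentially assigned to hot, high-fire-weather, road-near
terrain, the same covariates that raise burn probability) whose treatment
log-odds shift is calibrated per seed so the true population relative
effect is exactly +100% — the doubling of burn probability the pipeline
must recover.  ``NULL-1`` keeps the confounding but sets the treatment
effect to zero, for type-I-error calibration: any "effect" it finds is a
false positive.
"""

from __future__ import annotations

from .synthetic import (
    ScenarioConfig,
    calibrate_treatment_log_or,
    generate_covariate_fields,
    assign_management,
    _block_labels,
)

__all__ = ["temperate1_config", "null1_config", "PROPENSITY_COEFFS", "OUTCOME_COEFFS"]

# Plantations sit on more fire-prone ground: hotter, higher extreme fire
# weather, closer to roads, gentler and lower terrain.  Per-SD logit scale.
PROPENSITY_COEFFS = {
    "intercept": -0.6,
    "temp_hot_q": 0.7,
    "fwi95": 0.7,
    "precip_wet_q": -0.3,
    "elevation": -0.3,
    "slope": -0.3,
    "dist_road": -0.4,
    "tree_cover": 0.3,
}

# Burn process: fire weather and heat dominate, wet climates suppress,
# recent fire history begets fire.  Intercept gives a ~6-8% base burn rate.
OUTCOME_COEFFS = {
    "intercept": -2.8,
    "temp_hot_q": 0.5,
    "precip_wet_q": -0.4,
    "precip_dry_q": -0.2,
    "slope": 0.2,
    "burn_hist_15y": 0.5,
    "pop_density": -0.2,
}

OUTCOME_SMOOTH_FNS = {"fwi95": "saturating", "elevation": "quadratic"}


def _base_config(n_points: int, n_countries: int, seed: int) -> ScenarioConfig:
    return ScenarioConfig(
        n_points=n_points,
        n_countries=n_countries,
        extent=(0.0, 4.0 * n_countries, 35.0, 55.0),
        biome_labels=("mediterranean", "temperate_broadleaf", "boreal"),
        propensity_coeffs=dict(PROPENSITY_COEFFS),
        outcome_coeffs=dict(OUTCOME_COEFFS),
        outcome_smooth_fns=dict(OUTCOME_SMOOTH_FNS),
        treatment_log_or=0.0,
        plantation_kind="temperate",
        seed=seed,
    )


def temperate1_config(seed: int, n_points: int = 40_000, n_countries: int = 10,
                      target_relative_pct: float = 100.0) -> ScenarioConfig:
    """Confounded scenario with true pooled relative effect +100%.

    Calibrated per seed: covariate fields and management assignment do not
    depend on the treatment effect (independent RNG streams), so the
    log-odds shift can be solved on the realized population before burns
    are drawn.  The calibration target is the country-pooled estimand — the
    unweighted mean of within-country relative effects — because that is
    the quantity the pipeline's pooled group effect estimates.
    """
    cfg = _base_config(n_points, n_countries, seed)
    points = generate_covariate_fields(cfg)
    lon0, lon1 = cfg.extent[0], cfg.extent[1]
    points["country"] = _block_labels(
        points["lon"].to_numpy(), lon0, lon1,
        [f"C{i + 1:02d}" for i in range(cfg.n_countries)],
    )
    points = assign_management(points, cfg.propensity_coeffs, cfg.seed, cfg.plantation_kind)
    cfg.treatment_log_or = calibrate_treatment_log_or(
        points, cfg.outcome_coeffs, cfg.outcome_smooth_fns, target_relative_pct,
        estimand="country_pooled",
    )
    return cfg


def null1_config(seed: int, n_points: int = 8_000, n_countries: int = 5) -> ScenarioConfig:
    """Same confounding structure, zero treatment effect."""
    return _base_config(n_points, n_countries, seed)
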