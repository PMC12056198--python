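"""Synthetic timber-production landscapes with known ground truth.

The generator emulates the statistical structure the matching/modelling
pipeline assumes rather than any real geography: ten environmental and
anthropogenic covariates vary as smooth spatial fields, management class
(timber plantation vs natural production forest) is assigned by a logistic
propensity model on those covariates (so assignment is confounded), and
stand-replacing burns follow a logistic model with linear and smooth
covariate effects plus a management log-odds shift.  Because the generating
model is known, the population-average burn-probability difference between
the two management regimes — the quantity the counterfactual stage
estimates — can be computed exactly and used as ground truth in
parameter-recovery tests.

Countries are longitudinal blocks and biomes latitudinal bands, so exact
matching on biome and per-country analyses get non-trivial structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .grids import Raster

__all__ = [
    "COVARIATES",
    "MGMT_CODES",
    "SMOOTH_FN_REGISTRY",
    "ScenarioConfig",
    "SyntheticTruth",
    "generate_covariate_fields",
    "assign_management",
    "simulate_burns",
    "true_marginal_difference",
    "true_country_effects",
    "generate_scenario",
    "calibrate_treatment_log_or",
]

#: The ten matching covariates, in canonical order.
COVARIATES = [
    "elevation",
    "slope",
    "temp_hot_q",
    "precip_dry_q",
    "precip_wet_q",
    "fwi95",
    "burn_hist_15y",
    "tree_cover",
    "dist_road",
    "pop_density",
]

#: Raster class codes (0 = not timber-producing / nodata handled separately).
MGMT_CODES = {"natural_production": 1, "plantation_temperate": 2, "plantation_tropical": 3}

# Named nonlinear effects applied to standardized covariates on the logit
# scale.  Registered by name so scenario configs stay JSON-serializable.
SMOOTH_FN_REGISTRY: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "none": lambda z: np.zeros_like(z),
    "sin": lambda z: 0.8 * np.sin(1.5 * z),
    "quadratic": lambda z: 0.5 * (z**2 - 1.0),
    "saturating": lambda z: 1.2 * np.tanh(z),
    "bump": lambda z: 1.0 * np.exp(-0.5 * (z - 0.5) ** 2) - 0.626,
}

# Natural location/scale for each covariate; statistically irrelevant (models
# standardize internally) but keeps tables physically plausible.
_NATURAL_SCALE = {
    "elevation": ("affine", 600.0, 350.0),
    "slope": ("affine_pos", 8.0, 5.0),
    "temp_hot_q": ("affine", 22.0, 6.0),
    "precip_dry_q": ("affine_pos", 120.0, 80.0),
    "precip_wet_q": ("affine_pos", 500.0, 200.0),
    "fwi95": ("affine_pos", 30.0, 12.0),
    "burn_hist_15y": ("expit", -2.2, 0.9),
    "tree_cover": ("expit", 1.0, 0.9),
    "dist_road": ("logn", 1.0, 0.8),
    "pop_density": ("logn", 2.5, 1.2),
}

# Named RNG sub-streams derived from the master seed, so e.g. changing the
# outcome model never perturbs the assignment draws.
_STREAMS = {"fields": 0, "assign": 1, "outcome": 2, "confidence": 3, "fire_year": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


@dataclass
class ScenarioConfig:
    """Full description of one synthetic landscape.

    ``propensity_coeffs`` and ``outcome_coeffs`` are logit-scale coefficients
    keyed by covariate name (plus ``"intercept"``); covariates are
    standardized internally before the coefficients apply.
    ``outcome_smooth_fns`` maps covariate names to entries of
    :data:`SMOOTH_FN_REGISTRY`.  ``treatment_log_or`` is the plantation vs
    natural-production log-odds shift — the causal effect the pipeline must
    recover.  ``covariate_correlation`` mixes a shared latent field into every
    covariate (the data sources give no cross-covariate covariance, so it is
    a knob rather than an assumption).
    """

    n_points: int = 10_000
    n_countries: int = 5
    extent: tuple[float, float, float, float] = (0.0, 20.0, 35.0, 55.0)  # lon0, lon1, lat0, lat1
    biome_labels: tuple[str, ...] = ("mediterranean", "temperate_broadleaf", "boreal")
    propensity_coeffs: dict[str, float] = field(default_factory=lambda: {"intercept": -0.5})
    outcome_coeffs: dict[str, float] = field(default_factory=lambda: {"intercept": -2.5})
    outcome_smooth_fns: dict[str, str] = field(default_factory=dict)
    treatment_log_or: float = 0.0
    plantation_kind: str = "temperate"
    confidence_model: dict[str, float] = field(
        default_factory=lambda: {
            "mean_natural": 0.80,
            "mean_plantation": 0.78,
            "concentration": 12.0,
        }
    )
    field_amplitude: float = 1.0
    noise_sd: float = 0.35
    covariate_correlation: float = 0.3
    cellsize: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 1:
            raise ValueError(f"n_points must be >= 1, got {self.n_points}")
        lon0, lon1, lat0, lat1 = self.extent
        if not (lon1 > lon0 and lat1 > lat0):
            raise ValueError(f"degenerate extent {self.extent}")
        if not np.isfinite(self.treatment_log_or):
            raise ValueError("treatment_log_or must be finite")
        if self.plantation_kind not in ("temperate", "tropical"):
            raise ValueError(f"unknown plantation_kind {self.plantation_kind!r}")

    @property
    def plantation_class(self) -> str:
        return f"plantation_{self.plantation_kind}"

    def resolved_cellsize(self) -> float:
        """Lattice cell size: auto-chosen so cells outnumber points ~4:1."""
        if self.cellsize is not None:
            return float(self.cellsize)
        lon0, lon1, lat0, lat1 = self.extent
        area = (lon1 - lon0) * (lat1 - lat0)
        return float(np.sqrt(area / (4.0 * self.n_points)))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        d["extent"] = tuple(d["extent"])
        d["biome_labels"] = tuple(d["biome_labels"])
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Ground truth for a scenario.

    ``true_marginal_diff`` is the exact population-average difference in burn
    probability (plantation − natural production) over the generated points;
    ``true_relative_pct`` expresses it relative to the natural-production
    average, matching the percentage scale the pipeline reports.
    """

    true_marginal_diff: float
    true_relative_pct: float
    mean_prob_natural: float
    mean_prob_plantation: float
    scenario: ScenarioConfig | None = None
    #: within-country relative effects (same oracle, restricted per country)
    country_relative_pct: dict[str, float] | None = None
    #: unweighted mean of country_relative_pct — the estimand the pipeline's
    #: pooled group effect reports (mean of ratios ≥ ratio of means when
    #: baseline burn rates differ across countries)
    true_pooled_relative_pct: float | None = None

    def to_dict(self) -> dict:
        d = {
            "true_marginal_diff": self.true_marginal_diff,
            "true_relative_pct": self.true_relative_pct,
            "mean_prob_natural": self.mean_prob_natural,
            "mean_prob_plantation": self.mean_prob_plantation,
            "country_relative_pct": self.country_relative_pct,
            "true_pooled_relative_pct": self.true_pooled_relative_pct,
        }
        if self.scenario is not None:
            d["scenario"] = self.scenario.to_dict()
        return d


def _smooth_field(u: np.ndarray, v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sum of 3–6 low-frequency sinusoids and Gaussian bumps on [0,1]²."""
    out = np.zeros_like(u)
    for _ in range(rng.integers(3, 7)):
        amp = rng.uniform(0.5, 1.0)
        if rng.random() < 0.5:
            fx, fy = rng.uniform(0.5, 2.5, size=2)
            phase = rng.uniform(0, 2 * np.pi)
            out += amp * np.sin(2 * np.pi * (fx * u + fy * v) + phase)
        else:
            u0, v0 = rng.uniform(0, 1, size=2)
            s = rng.uniform(0.12, 0.3)
            out += amp * np.exp(-((u - u0) ** 2 + (v - v0) ** 2) / (2 * s**2))
    return out


def _to_natural(name: str, z: np.ndarray) -> np.ndarray:
    kind, a, b = _NATURAL_SCALE[name]
    if kind == "affine":
        return a + b * z
    if kind == "affine_pos":
        return np.maximum(a + b * z, 0.0)
    if kind == "expit":
        return expit(a + b * z)
    if kind == "logn":
        return np.exp(a + b * z)
    raise AssertionError(kind)


def generate_covariate_fields(config: ScenarioConfig) -> pd.DataFrame:
    """Sample ``n_points`` lattice cells and evaluate the ten covariate fields.

    Points sit at cell centres of a regular lon/lat lattice (one point per
    cell), so later rasterization is exact.  Each covariate is a seeded
    smooth field plus white noise, optionally correlated with the others
    through a shared latent field, then mapped to a plausible natural scale.
    """
    rng = _rng(config.seed, "fields")
    lon0, lon1, lat0, lat1 = config.extent
    cs = config.resolved_cellsize()
    ncol = max(int(np.ceil((lon1 - lon0) / cs)), 1)
    nrow = max(int(np.ceil((lat1 - lat0) / cs)), 1)
    n_cells = nrow * ncol
    if n_cells < config.n_points:
        raise ValueError(
            f"lattice of {n_cells} cells cannot host {config.n_points} distinct points; "
            "decrease cellsize"
        )
    flat = rng.choice(n_cells, size=config.n_points, replace=False)
    row, col = np.divmod(flat, ncol)
    lon = lon0 + (col + 0.5) * cs
    lat = lat0 + (nrow - row - 0.5) * cs

    u = (lon - lon0) / (lon1 - lon0)
    v = (lat - lat0) / (lat1 - lat0)
    rho = float(config.covariate_correlation)
    shared = _smooth_field(u, v, rng)
    out = {"id": np.arange(config.n_points), "lon": lon, "lat": lat}
    for name in COVARIATES:
        own = _smooth_field(u, v, rng)
        smooth = np.sqrt(max(1 - rho, 0.0)) * own + np.sqrt(max(rho, 0.0)) * shared
        raw = config.field_amplitude * smooth + config.noise_sd * rng.standard_normal(len(u))
        sd = raw.std()
        z = (raw - raw.mean()) / sd if sd > 0 else raw - raw.mean()
        out[name] = _to_natural(name, z)
    return pd.DataFrame(out)


def _standardized(points: pd.DataFrame) -> pd.DataFrame:
    """Z-score the ten covariates (population SD; internal use only)."""
    z = {}
    for name in COVARIATES:
        x = points[name].to_numpy(float)
        sd = x.std()
        z[name] = (x - x.mean()) / sd if sd > 0 else x - x.mean()
    return pd.DataFrame(z, index=points.index)


def _check_coeffs(coeffs: dict[str, float], what: str) -> None:
    unknown = set(coeffs) - set(COVARIATES) - {"intercept"}
    if unknown:
        raise ValueError(f"{what} refer to unknown covariates: {sorted(unknown)}")


def assign_management(
    points: pd.DataFrame,
    propensity_coeffs: dict[str, float],
    seed: int,
    plantation_kind: str = "temperate",
) -> pd.DataFrame:
    """Label each point plantation or natural production by a logistic draw.

    The linear predictor applies ``propensity_coeffs`` to internally
    standardized covariates, so coefficients are on a per-SD logit scale and
    nonzero coefficients make assignment confounded with the burn process.
    """
    _check_coeffs(propensity_coeffs, "propensity_coeffs")
    z = _standardized(points)
    eta = np.full(len(points), float(propensity_coeffs.get("intercept", 0.0)))
    for name, coef in propensity_coeffs.items():
        if name != "intercept":
            eta += coef * z[name].to_numpy()
    rng = _rng(seed, "assign")
    plantation = rng.random(len(points)) < expit(eta)
    out = points.copy()
    out["mgmt_class"] = np.where(
        plantation, f"plantation_{plantation_kind}", "natural_production"
    )
    return out


def _outcome_linear_predictor(
    points: pd.DataFrame,
    outcome_coeffs: dict[str, float],
    outcome_smooth_fns: dict[str, str],
    treatment_log_or: float,
    plantation: np.ndarray,
) -> np.ndarray:
    _check_coeffs(outcome_coeffs, "outcome_coeffs")
    _check_coeffs({k: 0.0 for k in outcome_smooth_fns}, "outcome_smooth_fns")
    z = _standardized(points)
    eta = np.full(len(points), float(outcome_coeffs.get("intercept", 0.0)))
    for name, coef in outcome_coeffs.items():
        if name == "intercept":
            continue
        term = coef * z[name].to_numpy()
        if not np.all(np.isfinite(term)):
            raise ValueError(f"non-finite linear term for covariate {name!r}")
        eta += term
    for name, fn_name in outcome_smooth_fns.items():
        term = SMOOTH_FN_REGISTRY[fn_name](z[name].to_numpy())
        if not np.all(np.isfinite(term)):
            raise ValueError(f"non-finite smooth term {fn_name!r} for covariate {name!r}")
        eta += term
    return eta + treatment_log_or * plantation.astype(float)


def simulate_burns(
    points: pd.DataFrame,
    outcome_coeffs: dict[str, float],
    outcome_smooth_fns: dict[str, str],
    treatment_log_or: float,
    seed: int,
) -> pd.DataFrame:
    """Draw burned ∈ {0,1} from the logistic outcome model.

    Uses an RNG stream independent of the assignment stream: rerunning with a
    different outcome model leaves management labels untouched.
    """
    if "mgmt_class" not in points:
        raise ValueError("management labels must be assigned before simulating burns")
    plantation = points["mgmt_class"].str.startswith("plantation").to_numpy()
    eta = _outcome_linear_predictor(
        points, outcome_coeffs, outcome_smooth_fns, treatment_log_or, plantation
    )
    rng = _rng(seed, "outcome")
    out = points.copy()
    out["burned"] = (rng.random(len(points)) < expit(eta)).astype(int)
    return out


def true_marginal_difference(
    points: pd.DataFrame,
    outcome_coeffs: dict[str, float],
    outcome_smooth_fns: dict[str, str],
    treatment_log_or: float,
    scenario: ScenarioConfig | None = None,
) -> SyntheticTruth:
    """Exact population-average burn-probability contrast (no sampling).

    Forces every point to plantation and to natural production in turn,
    averages the two probability vectors, and differences them — the
    noise-free analogue of the pipeline's Monte-Carlo counterfactual.
    """
    n = len(points)
    eta1 = _outcome_linear_predictor(
        points, outcome_coeffs, outcome_smooth_fns, treatment_log_or, np.ones(n, bool)
    )
    eta0 = _outcome_linear_predictor(
        points, outcome_coeffs, outcome_smooth_fns, treatment_log_or, np.zeros(n, bool)
    )
    p1 = float(np.mean(expit(eta1)))
    p0 = float(np.mean(expit(eta0)))
    diff = p1 - p0
    return SyntheticTruth(
        true_marginal_diff=diff,
        true_relative_pct=100.0 * diff / p0,
        mean_prob_natural=p0,
        mean_prob_plantation=p1,
        scenario=scenario,
    )


def true_country_effects(
    points: pd.DataFrame,
    outcome_coeffs: dict[str, float],
    outcome_smooth_fns: dict[str, str],
    treatment_log_or: float,
) -> tuple[dict[str, float], float]:
    """Within-country relative effects and their unweighted mean.

    Probabilities are computed on the full population (covariate
    standardization is population-wide), then averaged per country; the
    pooled value is the estimand of the pipeline's group effect, which
    averages per-country ratios rather than taking a ratio of averages.
    """
    if "country" not in points:
        raise ValueError("points need a 'country' column")
    n = len(points)
    eta1 = _outcome_linear_predictor(
        points, outcome_coeffs, outcome_smooth_fns, treatment_log_or, np.ones(n, bool)
    )
    eta0 = _outcome_linear_predictor(
        points, outcome_coeffs, outcome_smooth_fns, treatment_log_or, np.zeros(n, bool)
    )
    df = pd.DataFrame(
        {"country": points["country"].to_numpy(), "p1": expit(eta1), "p0": expit(eta0)}
    )
    per = {}
    for country, grp in df.groupby("country", sort=True):
        per[str(country)] = float(100.0 * (grp["p1"].mean() - grp["p0"].mean()) / grp["p0"].mean())
    return per, float(np.mean(list(per.values())))


def calibrate_treatment_log_or(
    points: pd.DataFrame,
    outcome_coeffs: dict[str, float],
    outcome_smooth_fns: dict[str, str],
    target_relative_pct: float,
    estimand: str = "population",
) -> float:
    """Solve for the treatment log-odds giving a target relative effect.

    The relative effect is strictly increasing in the log-odds shift, so a
    bracketing root-finder pins it down exactly; used to build scenarios
    whose ground-truth relative effect is a round number.  ``estimand``
    selects which truth is targeted: the population-wide ratio of mean
    probabilities (``"population"``) or the unweighted mean of
    within-country ratios (``"country_pooled"``, the pipeline's pooled
    group-effect estimand).
    """
    if estimand not in ("population", "country_pooled"):
        raise ValueError(f"unknown estimand {estimand!r}")

    def gap(b: float) -> float:
        if estimand == "population":
            t = true_marginal_difference(points, outcome_coeffs, outcome_smooth_fns, b)
            value = t.true_relative_pct
        else:
            _, value = true_country_effects(points, outcome_coeffs, outcome_smooth_fns, b)
        return value - target_relative_pct

    return float(brentq(gap, -10.0, 10.0, xtol=1e-10))


def _block_labels(values: np.ndarray, lo: float, hi: float, labels: list[str]) -> np.ndarray:
    """Assign labels by equal-width blocks of ``values`` over [lo, hi]."""
    idx = np.floor((values - lo) / (hi - lo) * len(labels)).astype(int)
    idx = np.clip(idx, 0, len(labels) - 1)
    return np.asarray(labels, dtype=object)[idx]


def generate_scenario(
    config: ScenarioConfig,
) -> tuple[pd.DataFrame, dict[str, Raster], SyntheticTruth]:
    """End-to-end scenario: point table, toy rasters, and ground truth.

    Countries are equal-width longitudinal blocks (``C01`` …), biomes
    latitudinal bands from ``biome_labels``; per-pixel classification
    confidence is Beta-distributed with class-specific means; burned points
    get a fire-loss year uniform on 2016–2022 for the raster overlay stage.
    """
    lon0, lon1, lat0, lat1 = config.extent
    points = generate_covariate_fields(config)
    points["country"] = _block_labels(
        points["lon"].to_numpy(), lon0, lon1,
        [f"C{i + 1:02d}" for i in range(config.n_countries)],
    )
    points["biome"] = _block_labels(
        points["lat"].to_numpy(), lat0, lat1, list(config.biome_labels)
    )
    points = assign_management(
        points, config.propensity_coeffs, config.seed, config.plantation_kind
    )
    points = simulate_burns(
        points,
        config.outcome_coeffs,
        config.outcome_smooth_fns,
        config.treatment_log_or,
        config.seed,
    )
    truth = true_marginal_difference(
        points,
        config.outcome_coeffs,
        config.outcome_smooth_fns,
        config.treatment_log_or,
        scenario=config,
    )
    truth.country_relative_pct, truth.true_pooled_relative_pct = true_country_effects(
        points, config.outcome_coeffs, config.outcome_smooth_fns, config.treatment_log_or
    )

    cm = config.confidence_model
    conc = float(cm.get("concentration", 12.0))
    mean = np.where(
        points["mgmt_class"] == "natural_production",
        float(cm.get("mean_natural", 0.8)),
        float(cm.get("mean_plantation", 0.78)),
    )
    rng_conf = _rng(config.seed, "confidence")
    points["confidence"] = rng_conf.beta(mean * conc, (1 - mean) * conc)

    rng_fy = _rng(config.seed, "fire_year")
    burned = points["burned"].to_numpy() == 1
    fire_year = np.where(burned, rng_fy.integers(2016, 2023, size=len(points)), 0)

    cs = config.resolved_cellsize()
    ncol = max(int(np.ceil((lon1 - lon0) / cs)), 1)
    nrow = max(int(np.ceil((lat1 - lat0) / cs)), 1)

    def _rasterize(values: np.ndarray, fill: float, nodata: float) -> Raster:
        grid = np.full((nrow, ncol), fill)
        r = Raster(grid, xll=lon0, yll=lat0, cellsize=cs, nodata=nodata)
        row, col = r.index_of(points["lon"].to_numpy(), points["lat"].to_numpy())
        grid[row, col] = values
        return r

    rasters = {
        "management": _rasterize(
            points["mgmt_class"].map(MGMT_CODES).to_numpy(float), 0.0, 0.0
        ),
        "fire_year": _rasterize(fire_year.astype(float), 0.0, -9999.0),
        "confidence": _rasterize(
            np.round(points["confidence"].to_numpy() * 100), -9999.0, -9999.0
        ),
    }

    cols = (
        ["id", "lon", "lat", "country", "biome", "mgmt_class", "confidence"]
        + COVARIATES
        + ["burned"]
    )
    return points[cols].reset_index(drop=True), rasters, truth
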