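"""Penalized-spline binomial GAM with logit link, fitted by penalized IRLS.

The burn-probability model: a parametric management-class term (plantation
vs natural production), cubic-regression-spline smooths of the ten matching
covariates plus longitude and latitude (to soak up residual spatial
autocorrelation), random intercepts for country and biome, and
biome×country, biome×management and per-biome tree-cover interaction terms.
Random intercepts and interaction indicator blocks are implemented as
ridge-penalized dummy blocks — the standard identity between a Gaussian
random intercept and a quadratic penalty — so a single machinery
(penalized IRLS + smoothing-parameter selection) fits everything.

Smoothing parameters are chosen by GCV over a log-spaced grid with
coordinate-wise refinement: deterministic given the data, and accurate
enough at this scale that exact REML machinery would buy little.

Degrees of freedom per term are effective degrees of freedom (EDF): the
trace of the influence matrix restricted to the term's columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial import cKDTree
from scipy.special import expit

from .splines import SplineBasisSpec, cr_basis, cr_knots, sum_to_zero
from .synthetic import COVARIATES

__all__ = [
    "GamSpec",
    "GamDesign",
    "GamFit",
    "build_design",
    "fit_pirls",
    "select_smoothing",
    "fit_gam",
    "predict_burn_prob",
    "morans_i",
    "residual_morans_i",
    "save_diagnostics",
]


@dataclass
class GamSpec:
    """Model structure: which terms enter and at what basis dimension."""

    covariates: tuple[str, ...] = tuple(COVARIATES)
    coord_smooths: bool = True
    k: int = 10
    management_term: bool = True
    random_intercepts: tuple[str, ...] = ("country", "biome")
    interactions: tuple[str, ...] = (
        "biome_country",
        "biome_management",
        "biome_tree_cover",
    )


@dataclass
class TermBlock:
    """One column block of the design with its (optional) quadratic penalty."""

    name: str
    kind: str  # parametric | smooth | random | interaction
    sl: slice
    S: np.ndarray | None  # penalty in block coordinates; None = unpenalized
    group: str | None  # smoothing-parameter group; None = unpenalized

    @property
    def n_cols(self) -> int:
        return self.sl.stop - self.sl.start

    def null_dim(self) -> int:
        if self.S is None:
            return self.n_cols
        eig = np.linalg.eigvalsh(self.S)
        return int((eig < 1e-8 * max(eig.max(), 1.0)).sum())


@dataclass
class GamDesign:
    """Design matrix plus everything needed to rebuild rows at predict time."""

    X: np.ndarray
    blocks: list[TermBlock]
    spec: GamSpec
    standardization: dict[str, tuple[float, float]]
    smooth_specs: dict[str, SplineBasisSpec]
    levels: dict[str, list]
    biome_country_pairs: list[tuple]

    @property
    def n_params(self) -> int:
        return self.X.shape[1]

    def penalized_groups(self) -> list[str]:
        seen: list[str] = []
        for b in self.blocks:
            if b.group is not None and b.group not in seen:
                seen.append(b.group)
        return seen

    def total_penalty(self, lambdas: dict[str, float]) -> np.ndarray:
        S = np.zeros((self.n_params, self.n_params))
        for b in self.blocks:
            if b.S is not None:
                S[b.sl, b.sl] += lambdas[b.group] * b.S
        return S


def _standardize_with(
    points: pd.DataFrame, name: str, record: dict[str, tuple[float, float]]
) -> np.ndarray:
    c, s = record[name]
    return (points[name].to_numpy(dtype=float) - c) / s


def _dummies(values: np.ndarray, levels: list, what: str) -> np.ndarray:
    unseen = set(values) - set(levels)
    if unseen:
        raise ValueError(f"unseen {what} level(s): {sorted(map(str, unseen))}")
    out = np.zeros((len(values), len(levels)))
    for j, lev in enumerate(levels):
        out[:, j] = values == lev
    return out


def _plantation_indicator(points: pd.DataFrame, management_override: str | None) -> np.ndarray:
    if management_override is None:
        return points["mgmt_class"].str.startswith("plantation").to_numpy(float)
    if management_override == "natural_production":
        return np.zeros(len(points))
    if management_override in ("plantation", "plantation_temperate", "plantation_tropical"):
        return np.ones(len(points))
    raise ValueError(f"unknown management override {management_override!r}")


def _assemble(
    points: pd.DataFrame,
    spec: GamSpec,
    standardization: dict[str, tuple[float, float]],
    smooth_specs: dict[str, SplineBasisSpec],
    levels: dict[str, list],
    biome_country_pairs: list[tuple],
    management_override: str | None = None,
) -> tuple[np.ndarray, list[TermBlock]]:
    """Build (or rebuild) the design matrix from stored metadata."""
    n = len(points)
    cols: list[np.ndarray] = []
    blocks: list[TermBlock] = []
    pos = 0

    def add(name: str, kind: str, M: np.ndarray, S: np.ndarray | None, group: str | None):
        nonlocal pos
        M = np.atleast_2d(M.T).T if M.ndim == 1 else M
        if S is not None:
            # normalize each penalty to unit largest entry so smoothing
            # parameters are comparable across terms and H stays well-scaled
            scale = np.max(np.abs(S))
            if scale > 0:
                S = S / scale
        cols.append(M)
        blocks.append(TermBlock(name, kind, slice(pos, pos + M.shape[1]), S, group))
        pos += M.shape[1]

    add("intercept", "parametric", np.ones((n, 1)), None, None)
    plant = _plantation_indicator(points, management_override) if (
        spec.management_term or "biome_management" in spec.interactions
    ) else np.zeros(n)
    if spec.management_term:
        add("management", "parametric", plant[:, None], None, None)

    smooth_vars = list(spec.covariates) + (["lon", "lat"] if spec.coord_smooths else [])
    centered_tc: np.ndarray | None = None
    for name in smooth_vars:
        z = _standardize_with(points, name, standardization)
        bspec = smooth_specs[name]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # extrapolation expected at predict time
            B, S = cr_basis(z, bspec)
        Bc, Sc, _ = sum_to_zero(B, S, Z=bspec.Z)
        add(f"s({name})", "smooth", Bc, Sc, f"s({name})")
        if name == "tree_cover":
            centered_tc = Bc

    for var in spec.random_intercepts:
        D = _dummies(points[var].to_numpy(), levels[var], var)
        add(f"ri({var})", "random", D, np.eye(D.shape[1]), f"ri({var})")

    if "biome_country" in spec.interactions:
        pairs = list(zip(points["biome"].to_numpy(), points["country"].to_numpy()))
        _dummies(points["biome"].to_numpy(), levels["biome"], "biome")
        _dummies(points["country"].to_numpy(), levels["country"], "country")
        M = np.zeros((n, len(biome_country_pairs)))
        index = {p: j for j, p in enumerate(biome_country_pairs)}
        for i, p in enumerate(pairs):
            j = index.get(p)
            if j is not None:  # unseen pair of seen levels contributes zero
                M[i, j] = 1.0
        add("biome:country", "interaction", M, np.eye(M.shape[1]), "biome:country")

    if "biome_management" in spec.interactions:
        D = _dummies(points["biome"].to_numpy(), levels["biome"], "biome")
        M = D * plant[:, None]
        add("biome:management", "interaction", M, np.eye(M.shape[1]), "biome:management")

    if "biome_tree_cover" in spec.interactions:
        assert centered_tc is not None
        D = _dummies(points["biome"].to_numpy(), levels["biome"], "biome")
        per_biome = [centered_tc * D[:, [j]] for j in range(D.shape[1])]
        M = np.hstack(per_biome)
        Sc = blocks[[b.name for b in blocks].index("s(tree_cover)")].S
        S = np.kron(np.eye(D.shape[1]), Sc)
        # all per-biome smooths share one smoothing parameter
        add("biome:s(tree_cover)", "interaction", M, S, "biome:s(tree_cover)")

    return np.hstack(cols), blocks


def build_design(points: pd.DataFrame, spec: GamSpec | None = None) -> GamDesign:
    """Assemble the full design from a matched point table.

    Covariates are centred and standardized (records kept for prediction);
    smooth-term knots sit at quantiles of the standardized values, with the
    sum-to-zero constraint absorbed so each k-dimensional smooth contributes
    k−1 columns.  Factor-interaction blocks keep all observed level
    combinations — their identity (ridge) penalties make them identifiable
    without reference-level drops.
    """
    spec = spec or GamSpec()
    standardization: dict[str, tuple[float, float]] = {}
    smooth_vars = list(spec.covariates) + (["lon", "lat"] if spec.coord_smooths else [])
    for name in smooth_vars:
        x = points[name].to_numpy(dtype=float)
        sd = float(x.std(ddof=1))
        if sd == 0:
            raise ValueError(f"covariate {name!r} has zero variance")
        standardization[name] = (float(x.mean()), sd)

    smooth_specs: dict[str, SplineBasisSpec] = {}
    for name in smooth_vars:
        z = _standardize_with(points, name, standardization)
        knots = cr_knots(z, spec.k)
        bspec = SplineBasisSpec(covariate=name, knots=knots, k=spec.k)
        B, S = cr_basis(z, bspec)
        _, _, Z = sum_to_zero(B, S)
        bspec.Z = Z
        smooth_specs[name] = bspec

    needs = set(spec.random_intercepts)
    if "biome_country" in spec.interactions:
        needs |= {"biome", "country"}
    if {"biome_management", "biome_tree_cover"} & set(spec.interactions):
        needs.add("biome")
    levels = {v: sorted(points[v].unique().tolist()) for v in needs}
    biome_country_pairs = (
        sorted(set(zip(points["biome"].to_numpy(), points["country"].to_numpy())))
        if "biome_country" in spec.interactions
        else []
    )
    X, blocks = _assemble(
        points, spec, standardization, smooth_specs, levels, biome_country_pairs
    )
    return GamDesign(
        X=X,
        blocks=blocks,
        spec=spec,
        standardization=standardization,
        smooth_specs=smooth_specs,
        levels=levels,
        biome_country_pairs=biome_country_pairs,
    )


@dataclass
class GamFit:
    """A converged (or flagged) penalized fit."""

    design: GamDesign
    coefficients: np.ndarray
    lambdas: dict[str, float]
    deviance: float
    penalized_deviance: float
    edf: dict[str, float]
    converged: bool
    n_iterations: int
    fitted: np.ndarray = field(repr=False, default=None)

    @property
    def edf_total(self) -> float:
        return float(sum(self.edf.values()))

    def coefficient(self, term: str) -> np.ndarray:
        for b in self.design.blocks:
            if b.name == term:
                return self.coefficients[b.sl]
        raise KeyError(term)

    def summary_dict(self) -> dict:
        return {
            "coefficients": self.coefficients.tolist(),
            "lambdas": self.lambdas,
            "deviance": self.deviance,
            "edf": self.edf,
            "edf_total": self.edf_total,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "standardization": {k: list(v) for k, v in self.design.standardization.items()},
            "terms": [b.name for b in self.design.blocks],
        }


def _edf_diagonal(XtWX: np.ndarray, S: np.ndarray) -> np.ndarray:
    """diag((XᵀWX + S)⁻ XᵀWX): per-coefficient effective degrees of freedom.

    Cholesky in the regular case; under exact collinearity (e.g. intercept
    plus full dummy blocks at λ → 0) the penalized Hessian is singular, and
    the pseudo-inverse form keeps the trace well-defined on the identifiable
    subspace — null directions contribute zero EDF.
    """
    H = XtWX + S
    ev, U = np.linalg.eigh(H)
    # cutoff just above eigh's backward-error floor: keeps a smooth's linear
    # null-space direction alive under λ ~ 1e12 while zeroing directions that
    # are non-identifiable (collinear and unpenalized)
    keep = ev > 1e-12 * max(ev[-1], 1.0)
    inv = np.where(keep, 1.0 / np.where(keep, ev, 1.0), 0.0)
    # diag(U inv Uᵀ XtWX) without forming the full product
    M = U.T @ XtWX
    return np.einsum("jk,kj->j", U * inv, M)


def _deviance(y: np.ndarray, eta: np.ndarray) -> float:
    # saturated log-likelihood is 0 for binary outcomes
    return float(2.0 * np.sum(np.logaddexp(0.0, eta) - y * eta))


def fit_pirls(
    design: GamDesign,
    y: np.ndarray,
    lambdas: dict[str, float] | float = 1.0,
    beta0: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> GamFit:
    """Penalized IRLS for the binomial/logit likelihood.

    Minimizes deviance + Σ_t λ_t βᵀS_tβ.  Steps that increase the penalized
    deviance are halved (up to 30 times); convergence is a relative
    penalized-deviance change below ``tol``.  Per-term EDFs are traces of
    (XᵀWX + S_λ)⁻¹XᵀWX over the term's columns.
    """
    X = design.X
    y = np.asarray(y, dtype=float)
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("y must be binary")
    if np.isscalar(lambdas):
        lambdas = {g: float(lambdas) for g in design.penalized_groups()}
    for g in design.penalized_groups():
        if lambdas.get(g, 0.0) < 0:
            raise ValueError(f"negative smoothing parameter for {g!r}")
    S = design.total_penalty(lambdas)
    beta = np.zeros(X.shape[1]) if beta0 is None else beta0.copy()
    eta = X @ beta
    pdev = _deviance(y, eta) + float(beta @ S @ beta)
    converged = False
    it = 0
    H = None
    for it in range(1, max_iter + 1):
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        if not np.all(np.isfinite(w)):
            raise FloatingPointError("non-finite working weights")
        z = eta + (y - mu) / w
        Xw = X * w[:, None]
        H = X.T @ Xw + S
        rhs = Xw.T @ z
        try:
            c, low = cho_factor(H, check_finite=False)
            beta_prop = cho_solve((c, low), rhs, check_finite=False)
        except np.linalg.LinAlgError:
            ridge = 1e-8 * max(float(np.max(np.diag(H))), 1.0)
            beta_prop = np.linalg.lstsq(
                H + ridge * np.eye(H.shape[0]), rhs, rcond=None
            )[0]
        # step halving on the penalized deviance
        step = beta_prop - beta
        pdev_new = np.inf
        tol_accept = 1e-9 * (abs(pdev) + 1.0)
        for _ in range(30):
            cand = beta + step
            eta_c = X @ cand
            pdev_new = _deviance(y, eta_c) + float(cand @ S @ cand)
            if np.isfinite(pdev_new) and pdev_new <= pdev + tol_accept:
                break
            step *= 0.5
        else:
            # with extreme λ the penalty term carries O(cond·eps) noise; a
            # step unable to improve beyond that noise means convergence
            if np.isfinite(pdev_new) and pdev_new <= pdev + 1e-4 * (abs(pdev) + 1.0):
                converged = True
                break
            raise FloatingPointError("step halving failed to reduce penalized deviance")
        beta = beta + step
        eta = X @ beta
        if abs(pdev - pdev_new) < tol * (abs(pdev_new) + 1e-3):
            pdev = pdev_new
            converged = True
            break
        pdev = pdev_new

    mu = expit(eta)
    w = np.clip(mu * (1 - mu), 1e-10, None)
    XtWX = X.T @ (X * w[:, None])
    diag = _edf_diagonal(XtWX, S)
    edf = {b.name: float(diag[b.sl].sum()) for b in design.blocks}
    dev = _deviance(y, eta)
    return GamFit(
        design=design,
        coefficients=beta,
        lambdas=dict(lambdas),
        deviance=dev,
        penalized_deviance=float(dev + beta @ S @ beta),
        edf=edf,
        converged=converged,
        n_iterations=it,
        fitted=mu,
    )


def _gcv(fit: GamFit, n: int, gamma: float = 1.4) -> float:
    # gamma > 1 inflates the EDF cost, the standard guard against GCV's
    # tendency to undersmooth
    denom = max(n - gamma * fit.edf_total, 1e-8)
    return n * fit.deviance / denom**2


def select_smoothing(
    design: GamDesign,
    y: np.ndarray,
    tie_groups: dict[str, list[str]] | None = None,
    grid_factors: np.ndarray | None = None,
    sweeps: int = 2,
    lambda_init: float = 1.0,
    gamma: float = 1.4,
) -> tuple[dict[str, float], GamFit]:
    """Choose smoothing parameters by GCV with coordinate-wise refinement.

    Starts every penalized group at ``lambda_init`` and cycles through the
    groups, trying multiplicative grid moves (wide on the first sweep,
    narrower on later sweeps) and keeping any move that lowers
    GCV = n·deviance / (n − γ·EDF)² (γ = 1.4 counters the criterion's
    undersmoothing bias).  Fits are warm-started from the current
    coefficients, and non-converged grid points are skipped with a warning.
    ``tie_groups`` maps a super-group name to penalized group names forced
    to share one λ (used to keep large pipeline runs cheap).
    """
    base_groups = design.penalized_groups()
    if tie_groups is None:
        tied = {g: [g] for g in base_groups}
    else:
        tied = {k: list(v) for k, v in tie_groups.items()}
        covered = [g for gs in tied.values() for g in gs]
        missing = set(base_groups) - set(covered)
        if missing:
            raise ValueError(f"tie_groups misses penalized groups: {sorted(missing)}")

    n = len(y)
    current = {name: float(lambda_init) for name in tied}

    def expand(cur: dict[str, float]) -> dict[str, float]:
        return {g: cur[name] for name, gs in tied.items() for g in gs}

    best_fit = fit_pirls(design, y, expand(current))
    best_score = _gcv(best_fit, n, gamma)
    for sweep in range(sweeps):
        factors = (
            grid_factors
            if grid_factors is not None
            else np.logspace(-3, 3, 7) if sweep == 0 else np.logspace(-1, 1, 5)
        )
        for name in tied:
            for f in factors:
                if f == 1.0:
                    continue
                trial = dict(current)
                trial[name] = current[name] * f
                try:
                    fit = fit_pirls(
                        design, y, expand(trial), beta0=best_fit.coefficients
                    )
                except FloatingPointError as exc:
                    warnings.warn(f"skipping λ grid point for {name}: {exc}")
                    continue
                if not fit.converged:
                    warnings.warn(f"non-converged λ grid point for {name}; skipped")
                    continue
                score = _gcv(fit, n, gamma)
                if score < best_score - 1e-12:
                    best_score, best_fit, current = score, fit, trial
    return expand(current), best_fit


def fit_gam(
    points: pd.DataFrame,
    spec: GamSpec | None = None,
    tie_groups: dict[str, list[str]] | None = None,
    **select_kwargs,
) -> GamFit:
    """Build the design, select smoothing parameters, return the final fit."""
    design = build_design(points, spec)
    _, fit = select_smoothing(
        design, points["burned"].to_numpy(float), tie_groups=tie_groups, **select_kwargs
    )
    return fit


def predict_burn_prob(
    fit: GamFit,
    points: pd.DataFrame,
    management_override: str | None = None,
) -> np.ndarray:
    """Predicted burn probabilities, optionally forcing the management class.

    All other fields stay at the points' observed values — the
    counterfactual contrast holds each point's environment fixed and flips
    only the treatment.  Unseen country/biome levels raise.
    """
    d = fit.design
    X, _ = _assemble(
        points,
        d.spec,
        d.standardization,
        d.smooth_specs,
        d.levels,
        d.biome_country_pairs,
        management_override=management_override,
    )
    p = expit(X @ fit.coefficients)
    return np.clip(p, 1e-12, 1 - 1e-12)


def morans_i(
    values: np.ndarray,
    lon: np.ndarray,
    lat: np.ndarray,
    k_neighbors: int = 8,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Moran's I with row-standardized k-nearest-neighbour weights.

    Returns (I, expected I under the null = −1/(n−1), two-sided permutation
    p-value from ``n_perm`` seeded shuffles with add-one correction).
    """
    r = np.asarray(values, dtype=float)
    n = len(r)
    if n < 30:
        raise ValueError("need at least 30 points for a stable Moran's I")
    if r.std() == 0:
        raise ValueError("constant values: Moran's I undefined")
    tree = cKDTree(np.column_stack([lon, lat]))
    _, idx = tree.query(np.column_stack([lon, lat]), k=k_neighbors + 1)
    neighbors = idx[:, 1:]  # drop self

    def stat(v: np.ndarray) -> float:
        vc = v - v.mean()
        lagged = vc[neighbors].mean(axis=1)
        # with row-standardized weights the weight total is n, so the n/ΣW
        # prefactor cancels
        return float((vc @ lagged) / (vc @ vc))

    I = stat(r)
    expected = -1.0 / (n - 1)
    rng = np.random.default_rng(seed)
    perm = np.empty(n_perm)
    for b in range(n_perm):
        perm[b] = stat(rng.permutation(r))
    lo = (1 + np.sum(perm <= I)) / (n_perm + 1)
    hi = (1 + np.sum(perm >= I)) / (n_perm + 1)
    p = min(1.0, 2.0 * min(lo, hi))
    return I, expected, p


def save_diagnostics(
    fit: GamFit,
    points: pd.DataFrame,
    out_prefix: str,
    n_bins: int = 20,
    max_points: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Residual spatial-structure diagnostics: empirical variogram + CSV/PNG.

    Bins half squared residual differences by pairwise distance on a
    subsample; a flat variogram indicates no residual spatial
    autocorrelation.  Writes ``<prefix>_variogram.csv`` and
    ``<prefix>_diagnostics.png`` and returns the binned table.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    resid = points["burned"].to_numpy(float) - predict_burn_prob(fit, points)
    rng = np.random.default_rng(seed)
    if len(points) > max_points:
        idx = rng.choice(len(points), size=max_points, replace=False)
    else:
        idx = np.arange(len(points))
    lon = points["lon"].to_numpy(float)[idx]
    lat = points["lat"].to_numpy(float)[idx]
    r = resid[idx]
    dx = lon[:, None] - lon[None, :]
    dy = lat[:, None] - lat[None, :]
    iu = np.triu_indices(len(r), k=1)
    dist = np.hypot(dx, dy)[iu]
    gamma = 0.5 * (r[:, None] - r[None, :])[iu] ** 2
    edges = np.linspace(0, np.quantile(dist, 0.5), n_bins + 1)
    which = np.digitize(dist, edges) - 1
    rows = []
    for b in range(n_bins):
        m = which == b
        if m.sum() > 0:
            rows.append({"distance": 0.5 * (edges[b] + edges[b + 1]),
                         "semivariance": float(gamma[m].mean()),
                         "n_pairs": int(m.sum())})
    table = pd.DataFrame(rows)
    table.to_csv(f"{out_prefix}_variogram.csv", index=False)

    figure, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    axes[0].plot(table["distance"], table["semivariance"], "o-")
    axes[0].set_xlabel("distance (degrees)")
    axes[0].set_ylabel("semivariance")
    axes[0].set_title("residual variogram")
    axes[1].hist(resid, bins=40)
    axes[1].set_xlabel("response residual")
    axes[1].set_title("residual distribution")
    figure.tight_layout()
    figure.savefig(f"{out_prefix}_diagnostics.png", dpi=100)
    plt.close(figure)
    return table


def residual_morans_i(
    fit: GamFit,
    points: pd.DataFrame,
    k_neighbors: int = 8,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Moran's I of response residuals (burned − fitted probability)."""
    resid = points["burned"].to_numpy(float) - predict_burn_prob(fit, points)
    return morans_i(
        resid,
        points["lon"].to_numpy(float),
        points["lat"].to_numpy(float),
        k_neighbors=k_neighbors,
        n_perm=n_perm,
        seed=seed,
    )
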