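"""Observational matching of plantation points to natural-production controls.

Pre-processing stage that removes covariate imbalance between management
classes before any outcome model is fitted.  Treated units (plantation
points) are matched 1:1 without replacement to natural-production controls
by greedy nearest-neighbour search under a caliper, with exact matching on
biome.  Two distance metrics are supported — the logit propensity score
(logistic regression of treatment on the ten covariates) and Mahalanobis
distance on the standardized covariates — and two calipers (0.2 and 0.5 SD
of the logit propensity score); :func:`select_matching_method` runs all four
candidates and keeps the one with the best worst-covariate balance.

Balance is measured by the absolute standardized mean difference (SMD):
|mean_treated − mean_control| divided by the treated-group SD *before*
matching, so before/after values share a denominator.  A covariate is in
acceptable balance when its after-matching SMD is below 0.25.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .synthetic import COVARIATES

__all__ = [
    "BALANCE_THRESHOLD",
    "PropensityModel",
    "MatchedSet",
    "standardize_covariates",
    "fit_propensity",
    "propensity_logit",
    "nn_match",
    "smd",
    "balance_table",
    "select_matching_method",
]

#: After-matching SMD below this is acceptable covariate balance.
BALANCE_THRESHOLD = 0.25


def standardize_covariates(
    points: pd.DataFrame, covariate_names: list[str] | None = None
) -> tuple[np.ndarray, dict[str, tuple[float, float]]]:
    """Centre/scale covariates to mean 0, sample SD 1 (n−1 denominator).

    Returns the standardized matrix (columns in ``covariate_names`` order)
    and a per-covariate (centre, scale) record allowing exact back-transform.
    """
    names = list(covariate_names) if covariate_names is not None else list(COVARIATES)
    cols, record = [], {}
    for name in names:
        x = points[name].to_numpy(dtype=float)
        if len(np.unique(x)) < 2:
            raise ValueError(f"covariate {name!r} has zero variance")
        c, s = float(x.mean()), float(x.std(ddof=1))
        record[name] = (c, s)
        cols.append((x - c) / s)
    return np.column_stack(cols), record


@dataclass
class PropensityModel:
    """Logistic regression of treatment on standardized covariates."""

    coefficients: np.ndarray  # intercept first
    standardization: dict[str, tuple[float, float]] | None
    converged: bool
    n_iterations: int

    def logit_scores(self, X: np.ndarray) -> np.ndarray:
        return self.coefficients[0] + X @ self.coefficients[1:]

    def scores(self, X: np.ndarray) -> np.ndarray:
        return expit(self.logit_scores(X))


def fit_propensity(
    X: np.ndarray,
    treated: np.ndarray,
    standardization: dict[str, tuple[float, float]] | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> PropensityModel:
    """Maximum-likelihood logistic regression by IRLS.

    Converges when the largest coefficient update falls below ``tol``.
    Diverging coefficients (perfect separation) are flagged as
    non-converged with a warning; scores are still usable for matching.
    """
    y = np.asarray(treated, dtype=float)
    if y.sum() < 1 or (1 - y).sum() < 1:
        raise ValueError("need at least one treated and one control unit")
    Xd = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(Xd.shape[1])
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = Xd @ beta
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        Xw = Xd * w[:, None]
        beta_new = np.linalg.solve(Xd.T @ Xw, Xw.T @ z)
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        # |coef| ≈ 15 on standardized covariates is far beyond any plausible
        # propensity model and keeps growing under separation
        if np.max(np.abs(beta)) > 15.0:
            warnings.warn("propensity coefficients diverging (possible separation)")
            break
        if step < tol:
            converged = True
            break
    return PropensityModel(
        coefficients=beta,
        standardization=standardization,
        converged=converged,
        n_iterations=it,
    )


def propensity_logit(points: pd.DataFrame, treated: np.ndarray) -> tuple[np.ndarray, PropensityModel]:
    """Convenience: standardize the ten covariates, fit, return logit scores."""
    X, record = standardize_covariates(points)
    model = fit_propensity(X, treated, standardization=record)
    return model.logit_scores(X), model


@dataclass
class MatchedSet:
    """1:1 matched treated/control pairs with method metadata."""

    pairs: list[tuple[int, int]]  # (treated row id, control row id)
    distances: list[float]
    method: str  # "propensity" | "mahalanobis"
    caliper: float  # in SDs of the logit propensity score
    caliper_scale: float  # the SD itself; threshold = caliper * caliper_scale
    exact_vars: tuple[str, ...]
    n_treated_dropped: int
    n_control_unused: int
    seed: int
    strata: list = field(default_factory=list)  # exact-var values per pair

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def matched_ids(self) -> np.ndarray:
        if not self.pairs:
            return np.array([], dtype=int)
        return np.unique(np.asarray(self.pairs).ravel())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "treated_id": [t for t, _ in self.pairs],
                "control_id": [c for _, c in self.pairs],
                "distance": self.distances,
                "stratum": [str(s) for s in self.strata],
            }
        )


def _greedy_stratum(
    t_ids: np.ndarray,
    c_ids: np.ndarray,
    dist_fn,
    threshold: float,
    order: np.ndarray,
) -> tuple[list[tuple[int, int]], list[float]]:
    """Greedy 1:1 matching inside one exact stratum.

    ``dist_fn(i)`` returns distances from treated position ``i`` to all
    controls; ties at the minimum go to the lowest control id.
    """
    alive = np.ones(len(c_ids), dtype=bool)
    pairs, dists = [], []
    for i in order:
        if not alive.any():
            break
        d = dist_fn(i).copy()
        d[~alive] = np.inf
        dmin = d.min()
        if not np.isfinite(dmin) or dmin > threshold:
            continue
        candidates = np.flatnonzero(d == dmin)
        j = candidates[np.argmin(c_ids[candidates])]
        alive[j] = False
        pairs.append((int(t_ids[i]), int(c_ids[j])))
        dists.append(float(dmin))
    return pairs, dists


def nn_match(
    points: pd.DataFrame,
    logit_scores: np.ndarray,
    method: str = "propensity",
    caliper: float = 0.2,
    exact_vars: tuple[str, ...] = ("biome",),
    seed: int = 0,
    covariate_names: list[str] | None = None,
    mahalanobis_propensity_caliper: bool = True,
    ridge: float = 1e-8,
) -> MatchedSet:
    """Greedy 1:1 nearest-neighbour matching without replacement.

    Treated units (``mgmt_class`` starting with ``plantation``) are visited
    in a seeded random order; each is paired to its nearest eligible control
    sharing all ``exact_vars`` values.  Eligibility requires the absolute
    logit-propensity difference ≤ ``caliper`` × SD(logit score over all
    points); for ``method="mahalanobis"`` the nearest neighbour is chosen by
    Mahalanobis distance on the standardized covariates while the propensity
    caliper still gates eligibility (the common MatchIt convention; disable
    via ``mahalanobis_propensity_caliper``).  Unmatched treated units are
    counted, and ids are the DataFrame's ``id`` column.
    """
    if method not in ("propensity", "mahalanobis"):
        raise ValueError(f"unknown matching method {method!r}")
    if caliper <= 0:
        raise ValueError("caliper must be > 0")
    logit_scores = np.asarray(logit_scores, dtype=float)
    treated_mask = points["mgmt_class"].str.startswith("plantation").to_numpy()
    ids = points["id"].to_numpy()
    scale = float(logit_scores.std(ddof=1))
    threshold = caliper * scale

    if method == "mahalanobis":
        Z, _ = standardize_covariates(points, covariate_names)
        V = np.cov(Z, rowvar=False) + ridge * np.eye(Z.shape[1])
        Vinv = np.linalg.inv(V)

    rng = np.random.default_rng(seed)
    pairs: list[tuple[int, int]] = []
    dists: list[float] = []
    strata: list = []
    n_dropped = 0
    key = [points[v] for v in exact_vars]
    groups = points.groupby(key, sort=True).indices if exact_vars else {"": np.arange(len(points))}
    for stratum, idx in sorted(groups.items(), key=lambda kv: str(kv[0])):
        t_pos = idx[treated_mask[idx]]
        c_pos = idx[~treated_mask[idx]]
        if len(t_pos) == 0:
            continue
        if len(c_pos) == 0:
            warnings.warn(f"no controls in exact stratum {stratum!r}; dropping treated units")
            n_dropped += len(t_pos)
            continue
        order = rng.permutation(len(t_pos))
        ls_t, ls_c = logit_scores[t_pos], logit_scores[c_pos]
        if method == "propensity":
            def dist_fn(i, ls_t=ls_t, ls_c=ls_c):
                return np.abs(ls_c - ls_t[i])
            new_pairs, new_d = _greedy_stratum(ids[t_pos], ids[c_pos], dist_fn, threshold, order)
        else:
            Zt, Zc = Z[t_pos], Z[c_pos]
            def dist_fn(i, Zt=Zt, Zc=Zc, ls_t=ls_t, ls_c=ls_c):
                diff = Zc - Zt[i]
                d = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", diff, Vinv, diff), 0.0))
                if mahalanobis_propensity_caliper:
                    d = np.where(np.abs(ls_c - ls_t[i]) <= threshold, d, np.inf)
                return d
            thr = threshold if not mahalanobis_propensity_caliper else np.inf
            new_pairs, new_d = _greedy_stratum(ids[t_pos], ids[c_pos], dist_fn, thr, order)
        n_dropped += len(t_pos) - len(new_pairs)
        pairs.extend(new_pairs)
        dists.extend(new_d)
        strata.extend([stratum] * len(new_pairs))

    n_controls = int((~treated_mask).sum())
    return MatchedSet(
        pairs=pairs,
        distances=dists,
        method=method,
        caliper=caliper,
        caliper_scale=scale,
        exact_vars=tuple(exact_vars),
        n_treated_dropped=n_dropped,
        n_control_unused=n_controls - len(pairs),
        seed=seed,
        strata=strata,
    )


def smd(
    values: np.ndarray,
    treated: np.ndarray,
    subset: np.ndarray | None = None,
) -> float:
    """Absolute standardized mean difference.

    Denominator is the treated-group sample SD over *all* units (before any
    matching), so before/after SMDs are on a common scale; ``subset`` is a
    boolean or index mask selecting the matched units for the after value.
    """
    values = np.asarray(values, dtype=float)
    treated = np.asarray(treated, dtype=bool)
    sd = values[treated].std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("treated group has zero variance")
    v = values if subset is None else values[subset]
    t = treated if subset is None else treated[subset]
    if t.sum() < 2 or (~t).sum() < 2:
        raise ValueError("need >=2 treated and >=2 control values")
    return float(abs(v[t].mean() - v[~t].mean()) / sd)


def balance_table(
    points: pd.DataFrame,
    matched: MatchedSet,
    covariate_names: list[str] | None = None,
) -> pd.DataFrame:
    """Before/after SMD for every covariate, with acceptability flags.

    Exact-matched variables are balanced by construction and not listed.
    """
    if matched.n_pairs == 0:
        raise ValueError("matched set is empty")
    names = list(covariate_names) if covariate_names is not None else list(COVARIATES)
    treated = points["mgmt_class"].str.startswith("plantation").to_numpy()
    matched_mask = points["id"].isin(matched.matched_ids()).to_numpy()
    rows = []
    for name in names:
        x = points[name].to_numpy(dtype=float)
        before = smd(x, treated)
        after = smd(x, treated, subset=matched_mask)
        rows.append(
            {
                "covariate": name,
                "smd_before": before,
                "smd_after": after,
                "acceptable": after < BALANCE_THRESHOLD,
            }
        )
    return pd.DataFrame(rows)


def select_matching_method(
    points: pd.DataFrame,
    logit_scores: np.ndarray,
    methods: tuple[str, ...] = ("propensity", "mahalanobis"),
    calipers: tuple[float, ...] = (0.2, 0.5),
    exact_vars: tuple[str, ...] = ("biome",),
    seed: int = 0,
    covariate_names: list[str] | None = None,
    return_candidates: bool = False,
):
    """Run every method × caliper candidate and keep the best-balanced one.

    Ranking: smallest maximum after-match SMD, then larger matched sample,
    then propensity before Mahalanobis, then smaller caliper.  The returned
    balance table's ``acceptable`` column tells the caller whether the
    winner clears the 0.25 rule for every covariate (if not, the country is
    dropped downstream).
    """
    candidates = []
    for method in methods:
        for caliper in calipers:
            ms = nn_match(
                points, logit_scores, method=method, caliper=caliper,
                exact_vars=exact_vars, seed=seed, covariate_names=covariate_names,
            )
            if ms.n_pairs < 2:
                continue
            bt = balance_table(points, ms, covariate_names)
            candidates.append((ms, bt))
    if not candidates:
        raise ValueError("no matching candidate produced at least 2 pairs")

    def rank(cand):
        ms, bt = cand
        return (
            bt["smd_after"].max(),
            -ms.n_pairs,
            0 if ms.method == "propensity" else 1,
            ms.caliper,
        )

    best = min(candidates, key=rank)
    if return_candidates:
        return best[0], best[1], candidates
    return best
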