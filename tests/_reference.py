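"""Independent brute-force oracles used by the test suite.

Deliberately naive re-implementations (double loops, per-point arithmetic)
kept free of any code path they are checking.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from firematch.gam import GamDesign, GamFit, GamSpec, build_design


def smd_brute(values, treated) -> float:
    """Two-line SMD oracle: |mean_t − mean_c| / sd_t (sample SD)."""
    v = np.asarray(values, float)
    t = np.asarray(treated, bool)
    return abs(v[t].mean() - v[~t].mean()) / v[t].std(ddof=1)


def morans_i_brute(values, lon, lat, k_neighbors=8) -> float:
    """Moran's I by explicit double loop over row-standardized kNN weights."""
    v = np.asarray(values, float)
    n = len(v)
    vc = v - v.mean()
    num = 0.0
    wsum = 0.0
    for i in range(n):
        d2 = (lon - lon[i]) ** 2 + (lat - lat[i]) ** 2
        order = np.argsort(d2, kind="stable")
        nn = [j for j in order if j != i][:k_neighbors]
        w = 1.0 / len(nn)
        for j in nn:
            num += w * vc[i] * vc[j]
            wsum += w
    return (n / wsum) * num / np.sum(vc**2)


def greedy_match_reference(points: pd.DataFrame, logit_scores, caliper, seed):
    """Plain-Python greedy propensity matcher (same order and tie rules).

    Treated units visited in the seeded random order within each sorted
    exact-biome stratum; nearest eligible control by |Δ logit score|,
    ties to the lowest control id, no replacement.
    """
    scores = np.asarray(logit_scores, float)
    treated = points["mgmt_class"].str.startswith("plantation").to_numpy()
    ids = points["id"].to_numpy()
    threshold = caliper * scores.std(ddof=1)
    rng = np.random.default_rng(seed)
    pairs = []
    for stratum in sorted(points["biome"].unique(), key=str):
        in_s = (points["biome"] == stratum).to_numpy()
        t_pos = np.flatnonzero(in_s & treated)
        c_pos = np.flatnonzero(in_s & ~treated)
        if len(t_pos) == 0 or len(c_pos) == 0:
            continue  # no permutation drawn in these cases
        order = rng.permutation(len(t_pos))
        used = set()
        for oi in order:
            ti = t_pos[oi]
            best, best_d = None, np.inf
            for cj in c_pos:
                if cj in used:
                    continue
                d = abs(scores[cj] - scores[ti])
                if d < best_d or (d == best_d and best is not None and ids[cj] < ids[best]):
                    best, best_d = cj, d
            if best is not None and best_d <= threshold:
                used.add(best)
                pairs.append((int(ids[ti]), int(ids[best])))
    return pairs


def intercept_management_fit(intercept: float, management: float) -> GamFit:
    """Hand-built fit with only an intercept and a management coefficient."""
    spec = GamSpec(covariates=(), coord_smooths=False,
                   random_intercepts=(), interactions=())
    toy = pd.DataFrame(
        {"mgmt_class": ["natural_production", "plantation_temperate"],
         "country": ["A", "A"], "biome": ["b", "b"]}
    )
    design = build_design(toy, spec)
    return GamFit(
        design=design,
        coefficients=np.array([intercept, management]),
        lambdas={},
        deviance=np.nan,
        penalized_deviance=np.nan,
        edf={"intercept": 1.0, "management": 1.0},
        converged=True,
        n_iterations=0,
        fitted=None,
    )
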