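"""Matching stage: propensity IRLS, greedy caliper matching, balance."""

import numpy as np
import pandas as pd
import pytest

from _reference import greedy_match_reference, smd_brute
from firematch import matching
from firematch.scenarios import null1_config
from firematch.synthetic import COVARIATES, generate_scenario


def _make_points(n, scores_to_logit=None, biomes=None, mgmt=None, seed=0):
    """Minimal point table for matcher-level tests."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({"id": np.arange(n)})
    df["biome"] = biomes if biomes is not None else ["a"] * n
    df["mgmt_class"] = mgmt
    for name in COVARIATES:
        df[name] = rng.normal(size=n)
    return df


class TestStandardize:
    def test_simple_column(self):
        df = pd.DataFrame({"elevation": [1.0, 2.0, 3.0]})
        X, rec = matching.standardize_covariates(df, ["elevation"])
        np.testing.assert_allclose(X[:, 0], [-1.0, 0.0, 1.0])
        assert rec["elevation"] == (2.0, 1.0)

    def test_idempotent_and_roundtrip(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"slope": rng.normal(2, 5, 100)})
        X, rec = matching.standardize_covariates(df, ["slope"])
        X2, _ = matching.standardize_covariates(pd.DataFrame({"slope": X[:, 0]}), ["slope"])
        np.testing.assert_allclose(X2[:, 0], X[:, 0], atol=1e-12)
        c, s = rec["slope"]
        np.testing.assert_allclose(X[:, 0] * s + c, df["slope"], atol=1e-12)

    def test_zero_variance_named(self):
        df = pd.DataFrame({"fwi95": np.ones(10)})
        with pytest.raises(ValueError, match="fwi95"):
            matching.standardize_covariates(df, ["fwi95"])


class TestPropensity:
    def test_null_model_symmetry(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(5000, 3))
        y = np.repeat([1, 0], 2500)
        m = matching.fit_propensity(X, y)
        assert m.converged
        scores = m.scores(X)
        assert np.all(np.abs(scores - 0.5) < 0.05)
        se = 2.0 / np.sqrt(5000)  # logistic slope SE ≈ 2/sqrt(n) at p = 0.5
        assert np.all(np.abs(m.coefficients[1:]) < 3 * se)

    def test_matches_statsmodels_mle(self):
        import statsmodels.api as sm

        x = np.array([-1.5, -1.0, -0.5, -0.2, 0.2, 0.5, 1.0, 1.5])
        y = np.array([0, 0, 1, 0, 1, 0, 1, 1])
        m = matching.fit_propensity(x[:, None], y)
        ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0, method="newton", tol=1e-12)
        np.testing.assert_allclose(m.coefficients, ref.params, atol=1e-6)

    def test_intercept_only_quarter(self):
        X = np.zeros((4, 0))
        y = np.array([1, 0, 0, 0])
        m = matching.fit_propensity(X, y)
        scores = m.scores(X)
        np.testing.assert_allclose(scores, 0.25, atol=1e-8)
        assert m.coefficients[0] == pytest.approx(np.log(0.25 / 0.75), abs=1e-8)

    def test_separation_flagged_not_fatal(self):
        x = np.array([-2.0, -1.0, 1.0, 2.0])
        y = np.array([0, 0, 1, 1])
        with pytest.warns(UserWarning, match="diverging"):
            m = matching.fit_propensity(x[:, None], y)
        assert not m.converged
        assert np.all(np.isfinite(m.scores(x[:, None])))


class TestNNMatch:
    def _scores_setup(self, scores, mgmt, biomes=None):
        n = len(scores)
        pts = _make_points(n, biomes=biomes, mgmt=mgmt)
        from scipy.special import logit

        return pts, logit(np.asarray(scores))

    def test_matches_nearest(self):
        pts, ls = self._scores_setup(
            [0.30, 0.25, 0.50],
            ["plantation_temperate", "natural_production", "natural_production"],
        )
        ms = matching.nn_match(pts, ls, caliper=50.0, seed=1)
        assert ms.pairs == [(0, 1)]

    def test_caliper_excludes(self):
        pts, ls = self._scores_setup(
            [0.9, 0.1], ["plantation_temperate", "natural_production"]
        )
        ms = matching.nn_match(pts, ls, caliper=0.2, seed=1)
        assert ms.pairs == [] and ms.n_treated_dropped == 1

    def test_exact_biome_constraint(self):
        pts, ls = self._scores_setup(
            [0.30, 0.31, 0.45],
            ["plantation_temperate", "natural_production", "natural_production"],
            biomes=["A", "B", "A"],
        )
        ms = matching.nn_match(pts, ls, caliper=50.0, seed=1)
        # nearest control (id 1) is in the wrong biome; must take id 2
        assert ms.pairs == [(0, 2)]

    def test_no_control_reuse_and_caliper_respected(self, null_scenario):
        _, points, _, _ = null_scenario
        grp = points[points["country"] == "C01"].reset_index(drop=True)
        treated = grp["mgmt_class"].str.startswith("plantation").to_numpy()
        ls, _ = matching.propensity_logit(grp, treated)
        ms = matching.nn_match(grp, ls, caliper=0.2, seed=3)
        controls = [c for _, c in ms.pairs]
        assert len(controls) == len(set(controls))
        score_of = dict(zip(grp["id"], ls))
        biome_of = dict(zip(grp["id"], grp["biome"]))
        thr = 0.2 * ls.std(ddof=1)
        for t, c in ms.pairs:
            assert abs(score_of[t] - score_of[c]) <= thr + 1e-12
            assert biome_of[t] == biome_of[c]

    def test_agrees_with_reference_on_random_instances(self):
        rng = np.random.default_rng(10)
        for trial in range(100):
            n = int(rng.integers(6, 51))
            mgmt = rng.choice(["plantation_temperate", "natural_production"], n)
            if (mgmt == "natural_production").all() or (mgmt != "natural_production").all():
                mgmt[0] = "plantation_temperate"
                mgmt[1] = "natural_production"
            biomes = rng.choice(["A", "B"], n)
            pts = _make_points(n, biomes=biomes, mgmt=mgmt, seed=trial)
            ls = rng.normal(size=n)
            caliper = float(rng.choice([0.2, 0.5, 2.0]))
            seed = int(rng.integers(0, 1000))
            ms = matching.nn_match(pts, ls, caliper=caliper, seed=seed)
            ref = greedy_match_reference(pts, ls, caliper, seed)
            assert ms.pairs == ref, f"trial {trial}"


class TestSMD:
    def test_identical_distributions_zero(self):
        v = np.concatenate([np.arange(10.0), np.arange(10.0)])
        t = np.repeat([True, False], 10)
        assert matching.smd(v, t) == 0.0

    def test_hand_value(self):
        v = np.array([2.0, 4.0, 1.0, 3.0])
        t = np.array([True, True, False, False])
        assert matching.smd(v, t) == pytest.approx(1.0 / np.sqrt(2.0), abs=1e-12)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            v = rng.normal(size=60)
            t = rng.random(60) < 0.4
            if t.sum() < 2 or (~t).sum() < 2:
                continue
            assert matching.smd(v, t) == pytest.approx(smd_brute(v, t), abs=1e-12)

    def test_zero_treated_sd_rejected(self):
        v = np.array([1.0, 1.0, 0.0, 2.0])
        t = np.array([True, True, False, False])
        with pytest.raises(ValueError):
            matching.smd(v, t)


class TestBalanceTable:
    def test_copied_controls_balance_perfectly(self):
        rng = np.random.default_rng(4)
        n = 40
        base = _make_points(n, mgmt=["plantation_temperate"] * n, seed=4)
        copy = base.copy()
        copy["id"] += n
        copy["mgmt_class"] = "natural_production"
        pts = pd.concat([base, copy], ignore_index=True)
        ms = matching.MatchedSet(
            pairs=[(i, i + n) for i in range(n)], distances=[0.0] * n,
            method="propensity", caliper=0.2, caliper_scale=1.0,
            exact_vars=("biome",), n_treated_dropped=0, n_control_unused=0, seed=0,
        )
        bt = matching.balance_table(pts, ms)
        assert np.allclose(bt["smd_after"], 0.0, atol=1e-12)
        assert bt["acceptable"].all()

    def test_acceptability_threshold(self):
        bt = pd.DataFrame({"smd_after": [0.24, 0.26]})
        assert (bt["smd_after"] < matching.BALANCE_THRESHOLD).tolist() == [True, False]


class TestSelection:
    def test_argmin_and_tiebreaks(self, monkeypatch):
        calls = {}

        def fake_nn_match(points, scores, method, caliper, **kw):
            n_pairs = {("propensity", 0.2): 5, ("propensity", 0.5): 9,
                       ("mahalanobis", 0.2): 9, ("mahalanobis", 0.5): 9}[(method, caliper)]
            return matching.MatchedSet(
                pairs=[(i, 100 + i) for i in range(n_pairs)],
                distances=[0.0] * n_pairs, method=method, caliper=caliper,
                caliper_scale=1.0, exact_vars=("biome",),
                n_treated_dropped=0, n_control_unused=0, seed=0,
            )

        def fake_balance(points, ms, names=None):
            max_smd = {("propensity", 0.2): 0.20, ("propensity", 0.5): 0.10,
                       ("mahalanobis", 0.2): 0.10, ("mahalanobis", 0.5): 0.10}[
                           (ms.method, ms.caliper)]
            return pd.DataFrame({"covariate": ["x"], "smd_before": [0.5],
                                 "smd_after": [max_smd], "acceptable": [max_smd < 0.25]})

        monkeypatch.setattr(matching, "nn_match", fake_nn_match)
        monkeypatch.setattr(matching, "balance_table", fake_balance)
        ms, bt = matching.select_matching_method(pd.DataFrame({"id": []}), np.array([]))
        # 0.20 candidates lose to the 0.10 ones; among those, propensity@0.5,
        # mahalanobis@0.2 and mahalanobis@0.5 tie on SMD and n_pairs →
        # propensity wins, then the smaller caliper would break further ties
        assert (ms.method, ms.caliper) == ("propensity", 0.5)

    def test_confounded_scenario_end_to_end_balances(self):
        cfg = null1_config(seed=11, n_points=4000, n_countries=1)
        points, _, _ = generate_scenario(cfg)
        treated = points["mgmt_class"].str.startswith("plantation").to_numpy()
        ls, _ = matching.propensity_logit(points, treated)
        ms, bt = matching.select_matching_method(points, ls, seed=11)
        assert (bt["smd_after"] < 0.25).all()
        assert bt["smd_after"].max() < bt["smd_before"].max()

    def test_balance_improves_over_seeds(self):
        """Matching should reduce the worst-covariate imbalance on average."""
        before, after = [], []
        for seed in range(20):
            cfg = null1_config(seed=100 + seed, n_points=1500, n_countries=1)
            points, _, _ = generate_scenario(cfg)
            treated = points["mgmt_class"].str.startswith("plantation").to_numpy()
            ls, _ = matching.propensity_logit(points, treated)
            ms, bt = matching.select_matching_method(points, ls, seed=seed)
            before.append(bt["smd_before"].max())
            after.append(bt["smd_after"].max())
        assert np.mean(after) < np.mean(before)
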