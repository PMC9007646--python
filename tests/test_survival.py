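import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from spongecerna.config import RunConfig
from spongecerna.survival import (
    cox_fit,
    hub_mrna_correlation,
    km_estimate,
    logrank_test,
    screen_hubs,
)
from spongecerna.synthetic import simulate_survival


def _rec(times, events):
    return pd.DataFrame({"time": times, "event": events})


class TestKm:
    def test_closed_form_small_sample(self):
        # censored at 1, events at 2 and 3: S(2)=1/2 (risk set 2), S(3)=0
        km = km_estimate(_rec([1, 2, 3], [0, 1, 1]))
        s = dict(zip(km["time"], km["survival"]))
        assert s[2.0] == pytest.approx(0.5) and s[3.0] == pytest.approx(0.0)

    def test_all_censored_flat_at_one(self):
        km = km_estimate(_rec([1, 2, 3], [0, 0, 0]))
        assert (km["survival"] == 1.0).all()
        assert km.attrs["all_censored"]

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(2.0, 30)
        km = km_estimate(_rec(t, np.ones(30, dtype=int)))
        for _, row in km.iloc[1:].iterrows():
            emp = (t > row["time"]).mean()
            assert row["survival"] == pytest.approx(emp, abs=1e-12)

    def test_matches_lifelines_reference(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(1)
        t = rng.exponential(3.0, 50)
        e = rng.integers(0, 2, 50)
        e[0] = 1
        km = km_estimate(_rec(t, e))
        kmf = KaplanMeierFitter().fit(t, e)
        for _, row in km.iterrows():
            ref = float(kmf.predict(row["time"]))
            assert row["survival"] == pytest.approx(ref, abs=1e-10)

    def test_nonincreasing(self):
        rng = np.random.default_rng(2)
        km = km_estimate(_rec(rng.exponential(1, 40), rng.integers(0, 2, 40)))
        assert (np.diff(km["survival"]) <= 1e-12).all()


class TestLogrank:
    def test_identical_groups(self):
        rec = _rec([1, 2, 3, 4], [1, 1, 0, 1])
        res = logrank_test(rec, rec)
        assert res["chi2"] == pytest.approx(0.0, abs=1e-12) and res["p"] == pytest.approx(1.0)

    def test_no_events_convention(self):
        res = logrank_test(_rec([1, 2], [0, 0]), _rec([3], [0]))
        assert res["p"] == 1.0

    def test_matches_lifelines_reference(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(3)
        a = _rec(rng.exponential(1.0, 25), rng.integers(0, 2, 25))
        b = _rec(rng.exponential(2.0, 25), rng.integers(0, 2, 25))
        mine = logrank_test(a, b)
        ref = ll_logrank(a["time"], b["time"], a["event"], b["event"])
        assert mine["chi2"] == pytest.approx(ref.test_statistic, rel=1e-8)
        assert mine["p"] == pytest.approx(ref.p_value, rel=1e-8)

    def test_extreme_separation_detected(self):
        a = _rec(np.full(20, 1.0), np.ones(20, dtype=int))
        b = _rec(np.full(20, 2.0), np.zeros(20, dtype=int))
        assert logrank_test(a, b)["p"] < 1e-6

    def test_time_unit_invariance(self):
        rng = np.random.default_rng(4)
        a = _rec(rng.exponential(1.0, 30), rng.integers(0, 2, 30))
        b = _rec(rng.exponential(1.5, 30), rng.integers(0, 2, 30))
        res_years = logrank_test(a, b)
        res_days = logrank_test(a.assign(time=a["time"] * 365.25),
                                b.assign(time=b["time"] * 365.25))
        assert res_years["chi2"] == pytest.approx(res_days["chi2"], rel=1e-12)


class TestCox:
    def test_toy_matches_grid_search_oracle(self):
        # events at t=1 (x=0), t=2 (x=1), t=3 (x=0): finite interior MLE
        rec = _rec([2.0, 1.0, 3.0], [1, 1, 1]).assign(x=[1.0, 0.0, 0.0])
        fit = cox_fit(rec, ["x"])

        def neg_partial_loglik(b):
            # t=1: risk {all}, event x=0; t=2: risk {x=1, x=0}, event x=1
            return -(-np.log(2.0 + np.exp(b)) + b - np.log(1.0 + np.exp(b)))

        grid = np.linspace(-5, 5, 2000001)
        best = grid[np.argmin(neg_partial_loglik(grid))]
        assert not fit["diverged"]
        assert fit["beta"]["x"] == pytest.approx(best, abs=1e-4)

    def test_matches_lifelines_reference(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(5)
        x = rng.standard_normal(50)
        tab = simulate_survival(x, 0.8, rng, censor_frac=0.2).assign(x=x)
        fit = cox_fit(tab, ["x"])
        cph = CoxPHFitter().fit(tab, duration_col="time", event_col="event")
        assert fit["beta"]["x"] == pytest.approx(cph.params_["x"], abs=1e-5)
        assert fit["se"]["x"] == pytest.approx(cph.standard_errors_["x"], abs=1e-4)

    def test_breslow_ties_match_naive_likelihood_maximizer(self):
        # heavy ties: compare Newton-Raphson against a brute-force maximizer
        # of an independently coded Breslow partial likelihood
        rng = np.random.default_rng(6)
        x = rng.standard_normal(40)
        t = rng.integers(1, 6, 40).astype(float)
        e = rng.integers(0, 2, 40)
        e[:5] = 1
        tab = pd.DataFrame({"time": t, "event": e, "x": x})
        fit = cox_fit(tab, ["x"])

        def breslow_loglik(beta):
            ll = 0.0
            for tt in np.unique(t[e == 1]):
                d_mask = (t == tt) & (e == 1)
                risk = t >= tt
                ll += beta * x[d_mask].sum()
                ll -= d_mask.sum() * np.log(np.exp(beta * x[risk]).sum())
            return ll

        best = optimize.minimize_scalar(lambda b: -breslow_loglik(b),
                                        bounds=(-10, 10), method="bounded",
                                        options={"xatol": 1e-10})
        assert fit["beta"]["x"] == pytest.approx(best.x, abs=1e-5)

    def test_null_coverage(self):
        rng = np.random.default_rng(7)
        covered = 0
        for _ in range(500):
            x = rng.standard_normal(60)
            tab = simulate_survival(x, 0.0, rng, censor_frac=0.2).assign(x=x)
            fit = cox_fit(tab, ["x"])
            b, se = fit["beta"]["x"], fit["se"]["x"]
            covered += (b - 1.96 * se) <= 0.0 <= (b + 1.96 * se)
        assert 0.93 <= covered / 500 <= 0.97

    def test_constant_covariate_rejected(self):
        rec = _rec([1, 2, 3], [1, 1, 0]).assign(x=1.0)
        with pytest.raises(ValueError, match="constant"):
            cox_fit(rec, ["x"])

    def test_perfect_separation_flagged(self):
        rec = _rec([1, 2, 3, 4], [1, 1, 1, 1]).assign(x=[3.0, 2.0, 1.0, 0.0])
        fit = cox_fit(rec, ["x"])
        assert fit["diverged"]

    def test_risk_scores_are_exp_linear_predictor(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(30)
        tab = simulate_survival(x, 0.5, rng).assign(x=x)
        fit = cox_fit(tab, ["x"])
        xc = x - x.mean()
        expected = np.exp(xc * fit["beta"]["x"])
        assert np.allclose(fit["risk_scores"].to_numpy(), expected)


class TestScreenHubs:
    def _screen_input(self, n=120, prognostic=True, seed=0):
        rng = np.random.default_rng(seed)
        expr = pd.DataFrame(rng.normal(8, 1, size=(3, n)),
                            index=["h1", "h2", "h3"],
                            columns=[f"s{i}" for i in range(n)])
        x = expr.loc["h1"].to_numpy() - 8.0 if prognostic else np.zeros(n)
        tab = simulate_survival(x, 1.0 if prognostic else 0.0, rng, censor_frac=0.2)
        records = pd.DataFrame({"time": tab["time"].to_numpy(),
                                "event": tab["event"].to_numpy()},
                               index=expr.columns)
        return expr, records

    def test_prognostic_gene_flagged(self):
        expr, records = self._screen_input(prognostic=True)
        res = screen_hubs(expr, ["h1"], records, RunConfig())
        assert res["logrank_p"].iloc[0] < 0.01

    def test_null_gene_rarely_flagged(self):
        hits = 0
        for seed in range(100):
            expr, records = self._screen_input(n=60, prognostic=False, seed=seed)
            res = screen_hubs(expr, ["h2"], records, RunConfig())
            hits += res["logrank_p"].iloc[0] < 0.01
        assert hits <= 5

    def test_constant_gene_skipped(self):
        expr, records = self._screen_input()
        expr.loc["h3"] = 5.0
        res = screen_hubs(expr, ["h3"], records)
        assert bool(res["skipped"].iloc[0])

    def test_empty_hub_list(self):
        expr, records = self._screen_input()
        assert screen_hubs(expr, [], records).empty

    def test_significant_requires_both_gates(self):
        expr, records = self._screen_input(prognostic=True)
        strict = screen_hubs(expr, ["h1"], records, RunConfig(survival_hr=1e6))
        assert not strict["significant"].iloc[0]


class TestHubMrnaCorrelation:
    def test_identical_vectors_flagged(self):
        samples = [f"s{i}" for i in range(30)]
        v = np.linspace(0, 1, 30)
        lnc = pd.DataFrame([v], index=["L1"], columns=samples)
        mrna = pd.DataFrame([v], index=["G1"], columns=samples)
        edges = pd.DataFrame({"lncrna": ["L1"], "mrna": ["G1"]})
        res = hub_mrna_correlation(lnc, mrna, edges, samples)
        assert bool(res["flagged"].iloc[0]) and res["pearson_r"].iloc[0] == 1.0

    def test_boundary_r_is_strict(self):
        # r exactly at the threshold must not be flagged
        samples = [f"s{i}" for i in range(10)]
        rng = np.random.default_rng(9)
        x = rng.standard_normal(10)
        lnc = pd.DataFrame([x], index=["L1"], columns=samples)
        mrna = pd.DataFrame([x], index=["G1"], columns=samples)
        edges = pd.DataFrame({"lncrna": ["L1"], "mrna": ["G1"]})
        res = hub_mrna_correlation(lnc, mrna, edges, samples, r_threshold=1.0)
        assert not bool(res["flagged"].iloc[0])

    def test_independent_vectors_rarely_flagged(self):
        rng = np.random.default_rng(10)
        samples = [f"s{i}" for i in range(261)]
        lnc = pd.DataFrame(rng.standard_normal((50, 261)),
                           index=[f"L{i}" for i in range(50)], columns=samples)
        mrna = pd.DataFrame(rng.standard_normal((50, 261)),
                            index=[f"G{i}" for i in range(50)], columns=samples)
        edges = pd.DataFrame({"lncrna": [f"L{i}" for i in range(50)],
                              "mrna": [f"G{i}" for i in range(50)]})
        res = hub_mrna_correlation(lnc, mrna, edges, samples)
        assert int(res["flagged"].sum()) == 0

    def test_zero_variance_gives_na_row(self):
        samples = [f"s{i}" for i in range(10)]
        lnc = pd.DataFrame([np.ones(10)], index=["L1"], columns=samples)
        mrna = pd.DataFrame([np.arange(10.0)], index=["G1"], columns=samples)
        edges = pd.DataFrame({"lncrna": ["L1"], "mrna": ["G1"]})
        res = hub_mrna_correlation(lnc, mrna, edges, samples)
        assert np.isnan(res["pearson_r"].iloc[0])
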