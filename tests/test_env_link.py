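import numpy as np
import pandas as pd
import pytest

from latidyn.env_link import (
    climate_summaries,
    dereplicate_predictors,
    fit_ols_aic,
    forward_select,
    niche_breadth,
    pcnm,
    pearson_screen,
    plant_summaries,
    relative_importance_lmg,
    variation_partition,
)


def daily_series(tmax, tmin, precip=None, start="2013-01-01", site="S"):
    n = len(tmax)
    return pd.DataFrame(
        {
            "site": site,
            "date": pd.date_range(start, periods=n, freq="D"),
            "tmax": tmax,
            "tmin": tmin,
            "precip": precip if precip is not None else np.zeros(n),
        }
    )


def campaign(date, season="Sp", year=2013, site="S"):
    return pd.DataFrame(
        [{"site": site, "season": season, "year": year, "date": date}]
    )


class TestClimateSummaries:
    def test_constant_temperature(self):
        daily = daily_series([10.0] * 400, [10.0] * 400)
        out = climate_summaries(daily, campaign("2013-05-10"), scale="week")
        row = out.iloc[0]
        assert row["DTR"] == 0.0 and row["TR"] == 0.0 and row["AT"] == 10.0

    def test_week_window_with_constant_range(self):
        daily = daily_series([20.0] * 400, [10.0] * 400)
        out = climate_summaries(daily, campaign("2013-05-10"), scale="week").iloc[0]
        assert out["DTR"] == pytest.approx(10.0)
        assert out["TR"] == pytest.approx(10.0)
        assert out["AT"] == pytest.approx(15.0)  # Tmean defaults to midpoint

    def test_single_hot_day_separates_tr_from_dtr(self):
        tmax = np.full(400, 20.0)
        tmin = np.full(400, 10.0)
        idx = 128  # 2013-05-09, inside the week before the campaign
        tmax[idx] = 25.0
        daily = daily_series(tmax, tmin)
        out = climate_summaries(daily, campaign("2013-05-10"), scale="week").iloc[0]
        assert out["TR"] == pytest.approx(15.0)
        assert out["DTR"] == pytest.approx((6 * 10 + 15) / 7)

    def test_season_window_is_calendar_based(self):
        rng = np.random.default_rng(0)
        n = 400
        daily = daily_series(
            rng.uniform(15, 25, n), rng.uniform(5, 14, n),
            precip=rng.uniform(0, 5, n),
        )
        out = climate_summaries(daily, campaign("2013-05-10"), scale="season").iloc[0]
        window = daily.set_index("date").loc["2013-03-01":"2013-05-31"]
        assert out["Precip"] == pytest.approx(window["precip"].sum())
        assert out["TR"] == pytest.approx(window["tmax"].max() - window["tmin"].min())

    def test_shifting_all_dates_shifts_windows_identically(self):
        rng = np.random.default_rng(1)
        n = 500
        tmax, tmin = rng.uniform(15, 25, n), rng.uniform(5, 14, n)
        precip = rng.uniform(0, 8, n)
        a = climate_summaries(
            daily_series(tmax, tmin, precip),
            campaign("2013-05-10"), scale="month",
        )
        b = climate_summaries(
            daily_series(tmax, tmin, precip, start="2013-01-31"),
            campaign("2013-06-09"), scale="month",
        )
        for col in ("DTR", "TR", "AT", "Precip", "Precip_SD"):
            assert a.iloc[0][col] == pytest.approx(b.iloc[0][col])

    def test_missing_days_listed(self):
        daily = daily_series([20.0] * 10, [10.0] * 10)
        with pytest.raises(ValueError, match="missing"):
            climate_summaries(daily, campaign("2013-05-10"), scale="week")


class TestNicheBreadth:
    def test_definition_against_manual_computation(self):
        df = pd.DataFrame(
            {
                "site": ["a", "a", "a", "b", "b", "b"],
                "value": [10.0, 20.0, 30.0, 19.0, 20.0, 21.0],
            }
        )
        out = niche_breadth(df)
        z = (df["value"] - df["value"].mean()) / df["value"].std(ddof=1)
        assert out["a"] == pytest.approx(z[:3].var(ddof=1))
        assert out["b"] == pytest.approx(z[3:].var(ddof=1))
        assert out["a"] > out["b"]  # wider seasonal spread = broader niche

    def test_constant_site_has_zero_breadth(self):
        df = pd.DataFrame(
            {"site": ["a", "a", "b", "b"], "value": [5.0, 5.0, 1.0, 9.0]}
        )
        assert niche_breadth(df)["a"] == pytest.approx(0.0)

    def test_globally_constant_variable_rejected(self):
        df = pd.DataFrame({"site": ["a", "a", "b"], "value": [2.0, 2.0, 2.0]})
        with pytest.raises(ValueError):
            niche_breadth(df)


class TestPcnm:
    def test_line_transect_first_eigenvector_is_smooth_gradient(self):
        coords = np.column_stack([np.arange(10.0), np.zeros(10)])
        out = pcnm(coords)
        assert out.attrs["morans_i"][0] > 0
        v1 = out["PCNM1"].to_numpy()
        # a single-period smooth gradient changes sign once
        assert int((np.sign(v1[:-1]) != np.sign(v1[1:])).sum()) == 1
        # eigenvectors from the truncated matrix are orthogonal
        gram = out.to_numpy().T @ out.to_numpy()
        assert np.allclose(gram, np.diag(np.diag(gram)), atol=1e-8)

    def test_equilateral_triangle_symmetry(self):
        coords = np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2]])
        out = pcnm(coords)
        vals = out.attrs["eigenvalues"]
        assert len(vals) == 2
        assert vals[0] == pytest.approx(vals[1], abs=1e-10)

    def test_two_points_rejected(self):
        with pytest.raises(ValueError):
            pcnm(np.array([[0.0, 0.0], [1.0, 1.0]]))

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError):
            pcnm(np.zeros((4, 2)))


class TestDereplicate:
    def test_duplicated_column_dropped(self):
        rng = np.random.default_rng(0)
        x = pd.DataFrame({"a": rng.normal(size=20)})
        x["b"] = x["a"]
        x["c"] = rng.normal(size=20)
        reduced, report = dereplicate_predictors(x, 0.8)
        assert list(reduced.columns) == ["a", "c"]
        assert report == {"b": "a"}

    def test_exact_boundary_kept(self):
        n = 40
        rng = np.random.default_rng(1)
        a = rng.normal(size=n)
        a = (a - a.mean()) / a.std(ddof=1)
        e = rng.normal(size=n)
        e -= e @ a / (a @ a) * a  # orthogonalize
        e = (e - e.mean()) / e.std(ddof=1)
        b = 0.8 * a + np.sqrt(1 - 0.64) * e  # sample correlation exactly 0.8
        x = pd.DataFrame({"a": a, "b": b})
        reduced, report = dereplicate_predictors(x, 0.8)
        assert list(reduced.columns) == ["a", "b"]  # strictly greater required

    def test_greedy_chain_keeps_ends(self):
        rng = np.random.default_rng(2)
        n = 300
        z = rng.normal(size=n)
        x1 = z + rng.normal(0, 0.6, n)
        x2 = z
        x3 = z + rng.normal(0, 0.6, n)
        x = pd.DataFrame({"x1": x1, "x2": x2, "x3": x3})
        r12 = abs(x["x1"].corr(x["x2"]))
        r13 = abs(x["x1"].corr(x["x3"]))
        assert r12 > 0.8 and r13 < 0.8  # construction sanity
        reduced, report = dereplicate_predictors(x, 0.8)
        assert list(reduced.columns) == ["x1", "x3"]
        assert report == {"x2": "x1"}


class TestFitOlsAic:
    def test_noise_predictor_pruned(self):
        rng = np.random.default_rng(0)
        x1 = rng.normal(size=50)
        x2 = rng.normal(size=50)
        y = pd.Series(x1)
        fit = fit_ols_aic(y, pd.DataFrame({"x1": x1, "x2": x2}))
        assert fit.selected == ["x1"]
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_response_rejected(self):
        x = pd.DataFrame({"x1": np.arange(10.0)})
        with pytest.raises(ValueError, match="zero variance"):
            fit_ols_aic(pd.Series(np.ones(10)), x)

    def test_too_few_observations_rejected(self):
        rng = np.random.default_rng(1)
        x = pd.DataFrame(rng.normal(size=(5, 4)), columns=list("abcd"))
        with pytest.raises(ValueError, match="too few"):
            fit_ols_aic(pd.Series(rng.normal(size=5)), x)

    def test_rank_deficiency_rejected(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=30)
        x = pd.DataFrame({"a": a, "b": 2 * a})
        with pytest.raises(ValueError, match="rank"):
            fit_ols_aic(pd.Series(rng.normal(size=30)), x)


def orthogonal_predictors(n, r2_shares, seed=0):
    """Response built from exactly orthogonal standardized predictors with
    prescribed marginal R^2 shares."""
    rng = np.random.default_rng(seed)
    raw = rng.normal(size=(n, len(r2_shares) + 1))
    q, _ = np.linalg.qr(raw - raw.mean(axis=0))
    cols = q[:, : len(r2_shares)]
    noise = q[:, len(r2_shares)]
    y = sum(
        np.sqrt(s) * cols[:, k] for k, s in enumerate(r2_shares)
    ) + np.sqrt(max(1 - sum(r2_shares), 0)) * noise
    x = pd.DataFrame(cols, columns=[f"x{k}" for k in range(len(r2_shares))])
    return pd.Series(y), x


class TestLmg:
    def test_single_predictor_share_equals_r2(self):
        rng = np.random.default_rng(0)
        x = pd.DataFrame({"a": rng.normal(size=40)})
        y = pd.Series(0.5 * x["a"] + rng.normal(0, 1, 40))
        shares = relative_importance_lmg(y, x)
        rss = np.polyfit(x["a"], y, 1)
        resid = y - np.polyval(rss, x["a"])
        r2 = 1 - (resid @ resid) / ((y - y.mean()) @ (y - y.mean()))
        assert shares["a"] == pytest.approx(r2, abs=1e-10)

    def test_orthogonal_predictors_get_marginal_r2(self):
        y, x = orthogonal_predictors(100, [0.3, 0.2])
        shares = relative_importance_lmg(y, x)
        assert shares["x0"] == pytest.approx(0.3, abs=1e-10)
        assert shares["x1"] == pytest.approx(0.2, abs=1e-10)

    def test_duplicated_predictor_splits_shares(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=60)
        y = pd.Series(a + rng.normal(0, 1.0, 60))
        x = pd.DataFrame({"a": a, "b": a.copy()})
        shares = relative_importance_lmg(y, x)
        assert shares["a"] == pytest.approx(shares["b"], abs=1e-10)

    def test_shares_sum_to_full_model_r2(self):
        rng = np.random.default_rng(4)
        x = pd.DataFrame(rng.normal(size=(50, 5)), columns=list("abcde"))
        y = pd.Series(x @ rng.normal(size=5) + rng.normal(0, 2, 50))
        shares = relative_importance_lmg(y, x)
        xs = np.column_stack([np.ones(50), x])
        beta, *_ = np.linalg.lstsq(xs, y, rcond=None)
        resid = y - xs @ beta
        r2 = 1 - (resid @ resid) / (((y - y.mean()) ** 2).sum())
        assert shares.sum() == pytest.approx(r2, abs=1e-8)
        assert (shares >= -1e-12).all()

    def test_guard_on_large_p(self):
        rng = np.random.default_rng(5)
        x = pd.DataFrame(rng.normal(size=(40, 13)))
        with pytest.raises(ValueError, match="p <= 12"):
            relative_importance_lmg(pd.Series(rng.normal(size=40)), x)


class TestVariationPartition:
    def test_fractions_sum_to_total_adjusted_r2(self):
        rng = np.random.default_rng(0)
        n = 100
        groups = {
            "climate": pd.DataFrame(rng.normal(size=(n, 2)), columns=["c1", "c2"]),
            "plant": pd.DataFrame(rng.normal(size=(n, 2)), columns=["p1", "p2"]),
            "soil": pd.DataFrame(rng.normal(size=(n, 1)), columns=["s1"]),
        }
        y = pd.Series(
            groups["climate"]["c1"] + 0.5 * groups["plant"]["p1"]
            + rng.normal(0, 1, n)
        )
        vpa = variation_partition(y, groups, forward=False)
        parts = vpa.drop(["total", "residual"])
        assert parts.sum() == pytest.approx(vpa["total"], abs=1e-8)

    def test_single_group_construction_concentrates_unique_fraction(self):
        rng = np.random.default_rng(1)
        n = 100
        a = pd.DataFrame(rng.normal(size=(n, 2)), columns=["a1", "a2"])
        b = pd.DataFrame(rng.normal(size=(n, 2)), columns=["b1", "b2"])
        y = pd.Series(a["a1"] - 0.8 * a["a2"] + 0.1 * rng.normal(size=n))
        vpa = variation_partition(y, {"A": a, "B": b}, forward=False)
        assert vpa["A"] == pytest.approx(vpa["total"], abs=0.02)
        assert abs(vpa["B"]) < 0.02

    def test_shared_latent_driver_gives_positive_shared_fraction(self):
        rng = np.random.default_rng(2)
        n = 150
        latent = rng.normal(size=n)
        a = pd.DataFrame({"a1": latent + rng.normal(0, 0.4, n)})
        b = pd.DataFrame({"b1": latent + rng.normal(0, 0.4, n)})
        y = pd.Series(latent + rng.normal(0, 0.5, n))
        vpa = variation_partition(y, {"A": a, "B": b}, forward=False)
        assert vpa["A&B"] > 0.2

    def test_forward_selection_drops_pure_noise(self):
        rng = np.random.default_rng(3)
        n = 80
        a = pd.DataFrame(
            {"signal": rng.normal(size=n), "junk": rng.normal(size=n)}
        )
        y = pd.Series(2 * a["signal"] + rng.normal(0, 0.5, n))
        selected = forward_select(y.to_numpy(), a, seed=1)
        assert selected == ["signal"]


class TestPearsonScreen:
    def test_perfect_correlation(self):
        x = pd.DataFrame({"x": np.arange(10.0)})
        r, p = pearson_screen(x.rename(columns={"x": "f"}), x)
        assert r.loc["f", "x"] == pytest.approx(1.0)
        assert p.loc["f", "x"] < 1e-10

    def test_orthogonal_pair_p_near_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = x - x.mean()
        z = np.array([1.0, -1.0, 0.5, 0.5, -1.0])
        z -= z @ y / (y @ y) * y  # exactly uncorrelated with x
        r, p = pearson_screen(pd.DataFrame({"f": x}), pd.DataFrame({"z": z}))
        assert r.loc["f", "z"] == pytest.approx(0.0, abs=1e-12)
        assert p.loc["f", "z"] == pytest.approx(1.0, abs=1e-9)

    def test_zero_variance_flagged_nan(self):
        with pytest.warns(UserWarning):
            r, p = pearson_screen(
                pd.DataFrame({"f": [1.0, 2, 3, 4]}),
                pd.DataFrame({"z": [5.0, 5, 5, 5]}),
            )
        assert np.isnan(r.loc["f", "z"])


class TestPlantSummaries:
    def test_intra_seasonal_mean_and_sd(self):
        monthly = pd.DataFrame(
            {
                "site": "S", "year": 2013, "month": range(1, 13),
                "GPP": np.arange(12, dtype=float),
            }
        )
        out = plant_summaries(monthly).set_index("season")
        assert out.loc["Sp", "GPP_avg"] == pytest.approx(np.mean([2, 3, 4]))
        assert out.loc["Su", "GPP_SD"] == pytest.approx(np.std([5, 6, 7], ddof=1))
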