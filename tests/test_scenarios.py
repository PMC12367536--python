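"""Scenario projection: named scenarios, BAU trend, grid surfaces, ensembles."""

import numpy as np
import pandas as pd
import pytest

from nsurplus import budget, response, scenarios, synth, typology


def make_baseline(in_fert=45.0, in_man=35.0, in_dep=10.0, in_bnf=10.0,
                  total_out=80.0, scope="FERT"):
    return scenarios.Baseline(
        scope=scope, window=(2015, 2019),
        in_fert=in_fert, in_man=in_man, in_dep=in_dep, in_bnf=in_bnf,
        total_out=total_out,
    )


def make_fit(c, scope="FERT"):
    return response.ResponseFit(scope=scope, window=(2015, 2019),
                                mean_in=100.0, mean_out=80.0, c=c)


def make_trend(c_2030, lo=None, hi=None):
    return response.TrendFit(
        scope="FERT", midpoints=(0.0,) * 8, c_values=(1.0,) * 8,
        slope=0.0, intercept=0.0, c_2030=c_2030,
        c_low=lo if lo is not None else c_2030,
        c_high=hi if hi is not None else c_2030,
    )


class TestRunScenario:
    def test_no_reduction_is_identity(self):
        base = make_baseline()
        cfg = scenarios.ScenarioConfig("noop", 0.0, 0.0, "same")
        res = scenarios.run_scenario(cfg, base, make_fit(400.0))
        assert res.surplus_reduction_pct == pytest.approx(0.0)
        assert res.surplus_2030 == pytest.approx(base.surplus)

    def test_green_deal_worked_example_same_tmp(self):
        # baseline In=100 (fert share 45%), c=400 -> Out=80, Surp=20
        base = make_baseline()
        cfg = scenarios.ScenarioConfig("GD-F", 0.20, 0.0, "same")
        res = scenarios.run_scenario(cfg, base, make_fit(400.0))
        assert res.in_2030 == pytest.approx(91.0)
        assert res.out_2030 == pytest.approx(74.134, abs=1e-3)
        assert res.surplus_2030 == pytest.approx(16.866, abs=1e-3)
        assert res.surplus_reduction_pct == pytest.approx(15.67, abs=0.01)
        assert not res.target_met

    def test_green_deal_worked_example_improved_tmp(self):
        base = make_baseline()
        cfg = scenarios.ScenarioConfig("GD-F", 0.20, 0.0, "improved")
        res = scenarios.run_scenario(cfg, base, make_fit(400.0), make_trend(500.0))
        assert res.out_2030 == pytest.approx(76.99, abs=0.01)
        assert res.surplus_2030 == pytest.approx(14.01, abs=0.01)
        assert res.surplus_reduction_pct == pytest.approx(29.95, abs=0.05)
        # technology improvement dominates the frozen-technology outcome
        same = scenarios.run_scenario(
            scenarios.ScenarioConfig("GD-F", 0.20, 0.0, "same"), base, make_fit(400.0)
        )
        assert res.surplus_reduction_pct > same.surplus_reduction_pct

    def test_nat_scope_refused(self):
        base = make_baseline(scope="NAT")
        cfg = scenarios.ScenarioConfig("GD-F", 0.20, 0.0)
        with pytest.raises(ValueError, match="NAT"):
            scenarios.run_scenario(cfg, base, make_fit(400.0))

    def test_reduction_fraction_validated(self):
        with pytest.raises(ValueError, match="r_fert"):
            scenarios.ScenarioConfig("bad", 1.2, 0.0)


class TestRunGrid:
    def test_origin_cell_zero(self):
        surf = scenarios.run_grid(make_baseline(), make_fit(400.0))
        assert surf.surplus_reduction_pct[0, 0] == pytest.approx(0.0)

    def test_full_cut_below_100pct(self):
        # dep+bnf remain, so even 100% fertilizer+manure cuts keep surplus > 0
        surf = scenarios.run_grid(make_baseline(), make_fit(400.0))
        assert surf.surplus_reduction_pct[-1, -1] < 100.0

    def test_monotone_in_both_axes(self):
        surf = scenarios.run_grid(make_baseline(), make_fit(400.0))
        assert (np.diff(surf.surplus_reduction_pct, axis=0) >= 0).all()
        assert (np.diff(surf.surplus_reduction_pct, axis=1) >= 0).all()
        assert (np.diff(surf.output_reduction_pct, axis=0) >= 0).all()
        assert (np.diff(surf.output_reduction_pct, axis=1) >= 0).all()

    def test_contour_matches_analytic_inversion(self):
        base = make_baseline(in_fert=60.0, in_man=20.0, total_out=70.0)
        fit = make_fit(250.0)
        surf = scenarios.run_grid(base, fit)
        analytic = scenarios.analytic_contour_r_fert(base, fit.c, r_man=0.0)
        assert surf.contour_r_fert[0] == pytest.approx(analytic, abs=0.01)

    def test_damping_output_change_below_input_change(self):
        base = make_baseline()
        surf = scenarios.run_grid(base, make_fit(400.0))
        RF, RM = np.meshgrid(surf.r_fert, surf.r_man, indexing="ij")
        d_in = RF * base.in_fert + RM * base.in_man
        d_out = base.total_out * surf.output_reduction_pct / 100.0
        assert (d_out <= d_in + 1e-9).all()

    def test_bad_step_rejected(self):
        with pytest.raises(ValueError, match="grid step"):
            scenarios.run_grid(make_baseline(), make_fit(400.0), step=0.7)

    def test_named_scenarios_are_grid_cells(self):
        base = make_baseline()
        fit = make_fit(400.0)
        trend = make_trend(460.0)
        for mode in ("same", "improved"):
            surf = scenarios.run_grid(base, fit, trend, tmp_mode=mode)
            for cfg in scenarios.named_scenarios(mode):
                res = scenarios.run_scenario(cfg, base, fit, trend)
                i = int(round(cfg.r_fert * 100))
                j = int(round(cfg.r_man * 100))
                assert surf.surplus_reduction_pct[i, j] == res.surplus_reduction_pct

    def test_improved_dominates_cellwise(self):
        base = make_baseline()
        fit = make_fit(400.0)
        trend = make_trend(460.0)  # c_2030 > c_baseline
        same = scenarios.run_grid(base, fit, None, tmp_mode="same")
        improved = scenarios.run_grid(base, fit, trend, tmp_mode="improved")
        assert (
            improved.surplus_reduction_pct >= same.surplus_reduction_pct - 1e-12
        ).all()


class TestBAU:
    @staticmethod
    def series(values, years=None):
        years = years if years is not None else range(1961, 1961 + len(values))
        return pd.DataFrame({"year": list(years), "surplus": list(values)})

    def test_constant_series_projects_constant(self):
        ser = self.series([40.0] * 59)
        model = scenarios.fit_bau(ser)
        assert model.projection_2030 == pytest.approx(40.0, rel=0.01)

    def test_increasing_series_keeps_increasing(self):
        ser = self.series([30.0 + 0.5 * k for k in range(59)])
        model = scenarios.fit_bau(ser)
        assert model.projection_2030 >= ser["surplus"].iloc[-1]

    def test_smooth_curve_recovered_within_5pct(self):
        # exponential decline is exactly log-linear, the link-scale of the fit
        rng = np.random.default_rng(3)
        years = np.arange(1961, 2020)
        curve = 60.0 * np.exp(-0.01 * (years - 1961))
        ser = self.series(curve * np.exp(rng.normal(0, 0.02, size=len(years))), years)
        model = scenarios.fit_bau(ser)
        truth_2030 = 60.0 * np.exp(-0.01 * (2030 - 1961))
        assert model.projection_2030 == pytest.approx(truth_2030, rel=0.05)

    def test_non_positive_surplus_advises_fallback(self):
        ser = self.series([5.0] * 30 + [-1.0] + [5.0] * 28)
        with pytest.raises(ValueError, match="gaussian"):
            scenarios.fit_bau(ser)

    def test_gaussian_fallback(self):
        ser = self.series([5.0] * 30 + [-1.0] + [5.0] * 28)
        model = scenarios.fit_bau(ser, family="gaussian")
        assert np.isfinite(model.projection_2030)

    def test_run_bau_reports_negative_reduction_for_growth(self):
        ser = self.series([30.0 + 0.5 * k for k in range(59)])
        base = make_baseline(total_out=42.0)  # surplus 58 ~ recent level
        res = scenarios.run_bau(ser, base, scope="EU27")
        assert res.name == "BAU"
        assert res.surplus_reduction_pct < 0


class TestPipelines:
    def test_single_region_country_matches_region(self, mini_records):
        # a country containing one region aggregates to itself
        one = mini_records[mini_records["region_id"] == "R0000"].copy()
        as_region = scenarios.run_all_scenarios(one, scope="EU27", include_bau=False)
        as_country = scenarios.run_all_scenarios(one, scope="country", include_bau=False)
        merged = as_region.merge(as_country, on=["name", "tmp_mode", "bound"])
        assert np.allclose(
            merged["surplus_reduction_pct_x"], merged["surplus_reduction_pct_y"],
            rtol=1e-10,
        )

    def test_country_breakdown_flags_match_recount(self, mini_records):
        table = scenarios.country_breakdown(mini_records)
        recount = (table["surplus_reduction_pct"] >= 50.0).sum()
        assert table["target_met"].sum() == recount

    def test_ensemble_identical_members_zero_band(self, mini_records):
        # replicate member 1 across all member ids: zero-width band
        m1 = mini_records[mini_records["member_id"] == 1]
        clones = []
        for m in range(1, 17):
            c = m1.copy()
            c["member_id"] = m
            clones.append(c)
        rec = pd.concat(clones, ignore_index=True)
        cfg = scenarios.ScenarioConfig("GD-F", 0.20, 0.0, "same")
        band = scenarios.ensemble_propagate(rec, cfg, scope="EU27")
        row = band.iloc[0]
        assert row["min_reduction_pct"] == pytest.approx(row["max_reduction_pct"])
        assert row["headline_reduction_pct"] == pytest.approx(row["mean_reduction_pct"])

    def test_ensemble_scale_invariance(self, mini_records):
        # scaling every component of a member leaves its reduction % unchanged
        scales = np.linspace(0.9, 1.1, 16)
        m1 = mini_records[mini_records["member_id"] == 1]
        clones = []
        for m, s in zip(range(1, 17), scales):
            c = m1.copy()
            c["member_id"] = m
            for col in budget.COMPONENTS:
                c[col] = c[col] * s
            clones.append(c)
        rec = pd.concat(clones, ignore_index=True)
        cfg = scenarios.ScenarioConfig("LAP", 0.20, 0.20, "same")
        band = scenarios.ensemble_propagate(rec, cfg, scope="EU27")
        row = band.iloc[0]
        assert row["max_reduction_pct"] - row["min_reduction_pct"] < 1e-9

    def test_ensemble_band_contains_headline(self, mini_records):
        cfg = scenarios.ScenarioConfig("GD-F", 0.20, 0.0, "same")
        band = scenarios.ensemble_propagate(mini_records, cfg, scope="EU27")
        row = band.iloc[0]
        assert row["min_reduction_pct"] <= row["headline_reduction_pct"] <= row["max_reduction_pct"]
        assert row["n_members"] == 16

    def test_typology_pipeline_improved_dominates(self, recovery):
        records, truth = recovery
        table = scenarios.run_all_scenarios(
            records, scope="typology", groups=truth, include_bau=False,
            bounds=("point",),
        )
        merged = table[table["tmp_mode"] == "same"].merge(
            table[table["tmp_mode"] == "improved"], on=["scope", "name"]
        )
        assert (
            merged["surplus_reduction_pct_y"] >= merged["surplus_reduction_pct_x"]
        ).all()
        assert set(table["scope"]) == {"MAN", "FERT", "MOD"}
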