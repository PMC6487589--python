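"""Revised-Monteith terms: RIE_plant, CP, CI, R_leaf, RUE dissection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import canopydissect as cd
from canopydissect.dissection import (
    CanopyDissection,
    WindowSummary,
    dissect_day,
    neighbourhood,
)


def grid_layout(n=6, spacing=0.5, la=0.3, rie=0.6):
    rows = []
    for i in range(n):
        for j in range(n):
            rows.append(
                {
                    "plant_id": f"p{i}{j}",
                    "x": (i + 0.5) * spacing,
                    "y": (j + 0.5) * spacing,
                    "leaf_area": la,
                    "rie_plant": rie,
                }
            )
    return pd.DataFrame(rows)


class TestRiePlant:
    def test_formula(self):
        assert cd.rie_plant(0.5, 10, 10) == pytest.approx(0.5)

    def test_values_above_one_allowed(self):
        assert cd.rie_plant(1.2, 10, 10) == pytest.approx(1.2)

    def test_zero_incident_rejected(self):
        with pytest.raises(ValueError):
            cd.rie_plant(1.0, 10, 0.0)


class TestNeighbourhood:
    def test_window_contains_focal_and_nearest(self):
        lay = grid_layout(6)
        w = neighbourhood(lay, "p33", k=15)
        assert "p33" in w.member_ids
        assert len(w.member_ids) == 15
        # all members within 2 grid steps of the focal plant
        focal = lay.set_index("plant_id").loc["p33"]
        m = lay.set_index("plant_id").loc[list(w.member_ids)]
        d = np.hypot(m["x"] - focal["x"], m["y"] - focal["y"])
        assert d.max() <= 0.5 * 2 * np.sqrt(2) + 1e-9

    def test_identical_plants_mean_equals_any(self):
        lay = grid_layout(5, la=0.42)
        w = neighbourhood(lay, "p22", k=15)
        assert w.la_c == pytest.approx(0.42)

    def test_border_window_reaches_further(self):
        lay = grid_layout(6)
        xy = lay.set_index("plant_id")

        def mean_dist(focal):
            w = neighbourhood(lay, focal, k=15)
            f = xy.loc[focal]
            m = xy.loc[list(w.member_ids)]
            return float(np.hypot(m["x"] - f["x"], m["y"] - f["y"]).mean())

        assert mean_dist("p00") > mean_dist("p33")

    def test_too_few_plants_rejected(self):
        with pytest.raises(ValueError):
            neighbourhood(grid_layout(3), "p00", k=15)


class TestCompetitionTerms:
    def test_cp_ratio(self):
        w = WindowSummary("f", ("f",), la_c=0.30, rie_c=0.60)
        assert cd.competition_pressure(w) == pytest.approx(0.50)

    def test_cp_constant_when_rie_proportional_to_la(self):
        # isolated small plants: RIE = c * LA in every window -> CP = 1/c
        cps = []
        for la, rie in [(0.1, 0.05), (0.3, 0.15), (0.5, 0.25)]:
            w = WindowSummary("f", ("f",), la_c=la, rie_c=rie)
            cps.append(cd.competition_pressure(w))
        assert np.ptp(cps) < 1e-12

    def test_ci_homogeneous_is_one(self):
        w = WindowSummary("f", ("f",), la_c=0.3, rie_c=0.6)
        assert cd.competitiveness_index(0.6, 0.3, w) == pytest.approx(1.0)

    def test_ci_double_interceptor(self):
        w = WindowSummary("f", ("f",), la_c=0.3, rie_c=0.6)
        assert cd.competitiveness_index(1.2, 0.3, w) == pytest.approx(2.0)

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(0.1, 10.0))
    def test_ci_scale_invariance(self, factor):
        w1 = WindowSummary("f", ("f",), la_c=0.3, rie_c=0.6)
        w2 = WindowSummary("f", ("f",), la_c=0.3 * factor, rie_c=0.6 * factor)
        ci1 = cd.competitiveness_index(0.9, 0.25, w1)
        ci2 = cd.competitiveness_index(0.9 * factor, 0.25 * factor, w2)
        assert ci2 == pytest.approx(ci1, rel=1e-9)

    def test_zero_leaf_area_rejected(self):
        w = WindowSummary("f", ("f",), la_c=0.3, rie_c=0.6)
        with pytest.raises(ValueError):
            cd.competitiveness_index(0.5, 0.0, w)


class TestRLeaf:
    def test_unit_conversion(self):
        # 0.864 mol d-1 over 2 m2 at 12 h -> 10 umol m-2 s-1
        assert cd.r_leaf(0.864, 2.0, 12.0) == pytest.approx(10.0)

    def test_inverse_in_leaf_area(self):
        assert cd.r_leaf(1.0, 2.0) == pytest.approx(cd.r_leaf(1.0, 1.0) / 2)

    def test_zero_interception(self):
        assert cd.r_leaf(0.0, 1.5) == 0.0


class TestEstimateRue:
    def test_exact_line_recovers_slope(self):
        t = np.arange(28, 55, 2.0)
        cum = np.linspace(0, 30, len(t))
        bm = 15.0 * cum + 7.0
        assert cd.estimate_rue(t, bm, cum) == pytest.approx(15.0)

    def test_offset_invariance(self):
        t = np.arange(30, 51, 2.0)
        cum = np.linspace(5, 25, len(t))
        bm = 12.0 * cum
        s1 = cd.estimate_rue(t, bm, cum)
        s2 = cd.estimate_rue(t, bm + 100.0, cum)
        assert s1 == pytest.approx(s2)

    def test_interval_filter_and_minimum_points(self):
        t = np.array([10.0, 20.0, 60.0])
        with pytest.raises(ValueError):
            cd.estimate_rue(t, t, t)


class TestRueResponseFit:
    def test_noiseless_recovery_is_exact(self):
        rng = np.random.default_rng(0)
        rl = rng.uniform(50, 400, 60)
        a, b = -0.003, 3.4
        df = pd.DataFrame(
            {
                "plant_id": [f"p{i}" for i in range(60)],
                "genotype_id": [f"g{i % 20}" for i in range(60)],
                "r_leaf": rl,
                "rue": np.exp(a * rl + b),
            }
        )
        fit = cd.fit_rue_response(df)
        assert fit.a == pytest.approx(a, abs=1e-12)
        assert fit.b == pytest.approx(b, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0)
        assert np.abs(fit.eps_rue).max() < 1e-10

    def test_residuals_mean_zero_and_genotype_aggregation(self):
        rng = np.random.default_rng(1)
        n = 90
        df = pd.DataFrame(
            {
                "plant_id": [f"p{i}" for i in range(n)],
                "genotype_id": [f"g{i % 30}" for i in range(n)],
                "r_leaf": rng.uniform(50, 400, n),
                "rue": rng.uniform(10, 25, n),
            }
        )
        fit = cd.fit_rue_response(df)
        assert fit.residuals.mean() == pytest.approx(0.0, abs=1e-10)
        g0 = fit.residuals[df["genotype_id"].to_numpy() == "g0"]
        assert fit.eps_rue["g0"] == pytest.approx(g0.mean())

    def test_non_positive_rue_rejected(self):
        df = pd.DataFrame(
            {
                "plant_id": ["a", "b", "c"],
                "genotype_id": ["g", "g", "g"],
                "r_leaf": [100.0, 200.0, 300.0],
                "rue": [15.0, -1.0, 12.0],
            }
        )
        with pytest.raises(ValueError, match="RUE must be > 0"):
            cd.fit_rue_response(df)


class TestRuePredictAndIncrement:
    def test_eps_zero_identity(self):
        base = cd.rue_predict(-0.002, 3.2, 150.0)
        assert cd.rue_predict(-0.002, 3.2, 150.0, 0.0) == pytest.approx(base)

    def test_eps_extremes_factors(self):
        base = cd.rue_predict(-0.002, 3.2, 150.0)
        assert cd.rue_predict(-0.002, 3.2, 150.0, 0.109) == pytest.approx(
            base * np.exp(0.109)
        )
        assert cd.rue_predict(-0.002, 3.2, 150.0, -0.126) == pytest.approx(
            base * np.exp(-0.126)
        )
        assert np.exp(0.109) == pytest.approx(1.1152, abs=1e-4)
        assert np.exp(-0.126) == pytest.approx(0.8816, abs=1e-4)

    def test_increment_formula_arithmetic(self):
        # RIE_plant = LA*CI/CP = 0.5, R_i = 40, D = 10, RUE = 15 -> 30 g d-1
        la, ci, cp = 0.5, 1.0, 1.0
        b = np.log(15.0)
        out = cd.biomass_increment(40.0, la, ci, cp, a=0.0, b=b, eps=0.0, density=10.0)
        assert out == pytest.approx(40.0 * 0.5 * 15.0 / 10.0)

    def test_linear_in_incident(self):
        kw = dict(leaf_area=0.4, ci=1.1, cp=0.5, a=0.0, b=3.0, eps=0.02, density=8.0)
        assert cd.biomass_increment(80.0, **kw) == pytest.approx(
            2 * cd.biomass_increment(40.0, **kw)
        )

    @settings(max_examples=200, derandomize=True)
    @given(
        st.floats(1.0, 80.0),
        st.floats(0.01, 1.5),
        st.floats(0.2, 3.0),
        st.floats(0.05, 1.0),
        st.floats(-0.01, -1e-5),
        st.floats(1.0, 4.0),
        st.floats(-0.2, 0.2),
        st.floats(1.0, 30.0),
    )
    def test_identity_with_product_form(self, ri, la, ci, cp, a, b, eps, d):
        rie = la * ci / cp
        r_plant = rie * ri / d
        rl = cd.r_leaf(r_plant, la)
        direct = r_plant * cd.rue_predict(a, b, rl, eps)
        via_eq = cd.biomass_increment(ri, la, ci, cp, a, b, eps, d)
        assert via_eq == pytest.approx(direct, rel=1e-9)


@pytest.fixture(scope="module")
def fitted():
    """Dissection of data generated exactly from the log-linear RUE model."""
    rng = np.random.default_rng(7)
    n_g, reps, days = 12, 3, np.arange(28.0, 52.0, 2.0)
    a, b = -0.0025, 3.2
    rows = []
    for gi in range(n_g):
        eps = rng.normal(0, 0.04)
        for r in range(reps):
            pid = f"g{gi:02d}_r{r}"
            x, y = rng.uniform(0, 2, 2)
            la_final = 0.5 * rng.lognormal(0, 0.1)
            shade = rng.uniform(0.3, 0.9)  # per-plant light environment
            bm = 5.0
            for day in days:
                la = la_final / (1 + np.exp(-0.25 * (day - 30)))
                rp = shade * 40.0 * la
                rl = cd.r_leaf(rp, la)
                rue = cd.rue_predict(a, b, rl, eps)
                bm += rp * rue * 2.0
                rows.append(
                    {
                        "plant_id": pid, "genotype_id": f"g{gi:02d}",
                        "day": day, "x": x, "y": y, "leaf_area": la,
                        "r_i": 40.0, "r_plant": rp, "biomass": bm,
                    }
                )
    model = CanopyDissection(pd.DataFrame(rows), density=9.0)
    return model.fit()


class TestCanopyDissectionModel:

    def test_records_carry_all_indices(self, fitted):
        for col in ["rie_plant", "cp", "ci", "r_leaf", "la_c", "rie_c"]:
            assert col in fitted.records.columns
        assert (fitted.records[["rie_plant", "cp", "ci"]] >= 0).all().all()

    def test_rue_fit_recovers_generating_coefficients(self, fitted):
        assert fitted.rue_fit is not None
        assert fitted.rue_fit.a == pytest.approx(-0.0025, rel=0.15)
        assert fitted.rue_fit.a < 0

    def test_genotype_means_and_summary(self, fitted):
        gm = fitted.genotype_means()
        assert "eps_rue" in gm.columns
        assert len(gm) == 12
        s = fitted.summary()
        assert "RUE response" in s and "CI" in s

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            CanopyDissection(pd.DataFrame({"plant_id": []}), density=1.0)


def test_dissect_day_uniform_canopy_gives_unit_ci():
    lay = grid_layout(6, la=0.3, rie=0.6)
    lay["r_i"] = 40.0
    lay["r_plant"] = 0.6 * 40.0 / 4.0  # D = 4 plants m-2
    out = dissect_day(lay.drop(columns="rie_plant"), density=4.0)
    np.testing.assert_allclose(out["ci"], 1.0)
    np.testing.assert_allclose(out["cp"], 0.3 / 0.6)
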