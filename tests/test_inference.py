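import numpy as np
import pandas as pd
import pytest

from mrpop.core_data import Component, ComponentTable, DimensionRegistry, cell_grid
from mrpop.dynamics import KappaSpec
from mrpop.inference import (
    MCMCConfig,
    PosteriorDraws,
    RateForecast,
    candidate_ladder,
    fit_component,
    forecast_component,
    select_model,
    simplify_spec,
)
from mrpop.loglin import ModelSpec, PriorSpec, TermSpec, default_model_specs


def _fertility_table(registry, counts):
    grid = cell_grid(Component.FERTILITY, registry)
    grid["count"] = counts
    grid["exposure"] = 1e4
    return ComponentTable(Component.FERTILITY, grid, registry)


@pytest.fixture
def fert_registry():
    return DimensionRegistry(
        ("A", "B"),
        (0, 5, 10, 15, 20, 25),
        tuple(range(2004, 2012)),
        (3, 5),
    )


class TestFitBookkeeping:
    def test_draw_count_is_chains_times_samples(self, fert_registry):
        rng = np.random.default_rng(0)
        table = _fertility_table(fert_registry, rng.poisson(300, 2 * 3 * 8))
        spec = default_model_specs(Component.FERTILITY)
        draws = fit_component(spec, table, MCMCConfig(chains=2, warmup=20, samples=50, seed=1))
        assert draws.n_draws == 100
        assert draws.sigma.shape == (100,)
        assert draws.kappa["kappa_age"].shape == (100, 1, 8)

    def test_identical_seed_gives_identical_draws(self, fert_registry):
        rng = np.random.default_rng(1)
        table = _fertility_table(fert_registry, rng.poisson(300, 2 * 3 * 8))
        spec = default_model_specs(Component.FERTILITY)
        cfg = MCMCConfig(chains=2, warmup=15, samples=25, seed=7)
        a = fit_component(spec, table, cfg)
        b = fit_component(spec, table, cfg)
        np.testing.assert_array_equal(a.sigma, b.sigma)
        np.testing.assert_array_equal(a.kappa["kappa_age"], b.kappa["kappa_age"])
        for name in a.terms:
            np.testing.assert_array_equal(a.terms[name], b.terms[name])

    def test_no_signal_table_keeps_kappa_near_zero(self, fert_registry):
        # identical counts at huge exposure: no time signal, kappa ~ 0
        table = _fertility_table(fert_registry, np.full(2 * 3 * 8, 5000))
        spec = default_model_specs(Component.FERTILITY)
        draws = fit_component(spec, table, MCMCConfig(chains=2, warmup=150, samples=150, seed=2))
        kap = draws.kappa["kappa_age"][:, 0, 1:]
        assert np.abs(np.median(kap, axis=0)).max() < 0.05

    def test_constraints_hold_in_every_draw(self, fert_registry):
        rng = np.random.default_rng(3)
        table = _fertility_table(fert_registry, rng.poisson(300, 2 * 3 * 8))
        spec = default_model_specs(Component.FERTILITY)
        draws = fit_component(spec, table, MCMCConfig(chains=2, warmup=20, samples=30, seed=3))
        np.testing.assert_allclose(draws.terms["A2"].sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(draws.terms["R2"].sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_array_equal(draws.kappa["kappa_age"][:, :, 0], 0.0)

    def test_save_load_roundtrip(self, fert_registry, tmp_path):
        rng = np.random.default_rng(4)
        table = _fertility_table(fert_registry, rng.poisson(300, 2 * 3 * 8))
        spec = default_model_specs(Component.FERTILITY)
        draws = fit_component(spec, table, MCMCConfig(chains=1, warmup=10, samples=10, seed=4))
        path = draws.save(tmp_path)
        back = PosteriorDraws.load(path)
        np.testing.assert_allclose(back.sigma, draws.sigma)
        np.testing.assert_allclose(back.kappa["kappa_region"], draws.kappa["kappa_region"])
        assert back.level_keys["R1"] == draws.level_keys["R1"]


def _handmade_draws(registry, nd=50, sigma=0.0, kappa_frozen=True):
    """A PosteriorDraws with all effects zero for forecasting tests."""
    spec = default_model_specs(Component.FERTILITY)
    years = list(registry.years)
    T = len(years)
    a0, b0 = registry.reproductive_window
    n_ages = b0 - a0 + 1
    ages = list(registry.reproductive_ages)
    terms = {
        "c": np.zeros((nd, 1)),
        "RA": np.zeros((nd, registry.n_regions * n_ages)),
        "A1": np.zeros((nd, n_ages)),
        "A2": np.tile(np.full(n_ages, 1.0 / n_ages), (nd, 1)),
        "R1": np.zeros((nd, registry.n_regions)),
        "R2": np.tile(np.full(registry.n_regions, 1.0 / registry.n_regions), (nd, 1)),
    }
    level_keys = {
        "c": [()],
        "RA": [(r, a) for r in registry.regions for a in ages],
        "A1": [(a,) for a in ages],
        "A2": [(a,) for a in ages],
        "R1": [(r,) for r in registry.regions],
        "R2": [(r,) for r in registry.regions],
    }
    dyn = {
        name: {"phi1": np.zeros((nd,)), "phi2": np.full((nd,), 0.5), "sigma": np.zeros(nd)}
        for name in ("kappa_age", "kappa_region")
    }
    return PosteriorDraws(
        component=Component.FERTILITY,
        spec=spec,
        registry=registry,
        years=years,
        n_chains=1,
        terms=terms,
        hier_sd={},
        od={},
        kappa={k: np.zeros((nd, 1, T)) for k in ("kappa_age", "kappa_region")},
        dyn=dyn,
        sigma=np.full(nd, sigma),
        level_keys=level_keys,
    )


class TestForecast:
    def test_all_zero_effects_give_unit_rates(self, fert_registry):
        draws = _handmade_draws(fert_registry, sigma=0.0)
        rng = np.random.default_rng(0)
        rf = forecast_component(draws, draws.spec, [2012, 2013], rng)
        np.testing.assert_allclose(rf.values, 1.0)

    def test_noise_free_kappa_follows_point_recursion(self, fert_registry):
        draws = _handmade_draws(fert_registry, sigma=0.0)
        # driftless AR(1) from kappa_T = 0 stays at 0; shift last kappa to 1
        draws.kappa["kappa_age"][:, 0, -1] = 1.0
        rng = np.random.default_rng(0)
        rf = forecast_component(draws, draws.spec, [2012, 2013], rng)
        ages = len(fert_registry.reproductive_ages)
        cells_2012 = rf.cells["year"] == 2012
        # predictor = A2 * kappa = (1/ages) * 0.5 after one step
        expected = np.exp(0.5 / ages)
        np.testing.assert_allclose(rf.values[:, cells_2012.to_numpy()], expected)

    def test_lognormal_median_property(self, fert_registry):
        draws = _handmade_draws(fert_registry, nd=4000, sigma=0.4)
        rng = np.random.default_rng(1)
        rf = forecast_component(draws, draws.spec, [2012], rng)
        # median over draws of exp(N(0, sigma^2)) ~ 1
        med = np.median(rf.values, axis=0)
        np.testing.assert_allclose(med, 1.0, atol=0.05)

    def test_horizon_must_extend_grid(self, fert_registry):
        draws = _handmade_draws(fert_registry)
        with pytest.raises(ValueError, match="extend the observed grid"):
            forecast_component(draws, draws.spec, [2015], np.random.default_rng(0))

    def test_forecast_roundtrip_csv(self, fert_registry, tmp_path):
        draws = _handmade_draws(fert_registry, nd=5, sigma=0.1)
        rf = forecast_component(draws, draws.spec, [2012], np.random.default_rng(2))
        path = rf.save(tmp_path)
        back = RateForecast.load(path, fert_registry, Component.FERTILITY)
        np.testing.assert_allclose(back.values, rf.values)


class TestSelectModel:
    def _mortality_table_one_year(self):
        reg = DimensionRegistry(("A", "B"), (0, 5), (2011,), (0, 1))
        grid = cell_grid(Component.MORTALITY, reg)
        rng = np.random.default_rng(5)
        grid["exposure"] = 1e4
        rates = rng.uniform(0.002, 0.05, len(grid))
        grid["count"] = rng.poisson(rates * 1e4)
        if (grid["count"] == 0).any():
            grid.loc[grid["count"] == 0, "count"] = 1
        return ComponentTable(Component.MORTALITY, grid, reg)

    def test_saturated_candidate_has_zero_rmse(self):
        table = self._mortality_table_one_year()
        saturated = ModelSpec(
            Component.MORTALITY,
            [
                TermSpec("c", (), "intercept", PriorSpec("normal_fixed_sd", sd=1)),
                TermSpec(
                    "RAS", ("region", "age", "sex"), "interaction",
                    PriorSpec("normal_fixed_sd", sd=1),
                ),
            ],
            [],
        )
        out = select_model([saturated], table)
        assert out["rmse"].iloc[0] == pytest.approx(0.0, abs=1e-6)

    def test_nested_rmse_monotonicity(self):
        table = self._mortality_table_one_year()
        ladder = candidate_ladder(Component.MORTALITY)
        out = select_model(ladder, table)
        rmse = out["rmse"].to_numpy()
        assert rmse[-1] <= rmse[0] + 1e-12

    def test_bic_matches_glm_oracle(self):
        import statsmodels.api as sm

        table = self._mortality_table_one_year()
        intercept_only = ModelSpec(
            Component.MORTALITY,
            [TermSpec("c", (), "intercept", PriorSpec("normal_fixed_sd", sd=1))],
            [],
        )
        out = select_model([intercept_only], table)
        Y = table.data["count"].to_numpy(dtype=float)
        K = table.data["exposure"].to_numpy(dtype=float)
        res = sm.GLM(
            Y, np.ones((len(Y), 1)), family=sm.families.Poisson(), offset=np.log(K)
        ).fit()
        expected_bic = -2 * res.llf + 1 * np.log(len(Y))
        assert out["bic"].iloc[0] == pytest.approx(expected_bic, rel=1e-8)

    def test_rejects_bilinear_candidates(self):
        table = self._mortality_table_one_year()
        with pytest.raises(ValueError, match="simplified"):
            select_model([default_model_specs(Component.MORTALITY)], table)

    def test_simplify_strips_bilinear(self):
        spec = default_model_specs(Component.IMMIGRATION)
        simple = simplify_spec(spec)
        assert all(t.kind != "bilinear_loading" for t in simple.terms)
        assert simple.kappas == []
        # the break indicator survives simplification
        assert any(t.kind == "break_indicator" for t in simple.terms)


def test_draws_flat_table_export(fert_registry):
    rng = np.random.default_rng(6)
    table = _fertility_table(fert_registry, rng.poisson(300, 2 * 3 * 8))
    spec = default_model_specs(Component.FERTILITY)
    draws = fit_component(spec, table, MCMCConfig(chains=2, warmup=10, samples=15, seed=5))
    frame = draws.to_frame()
    assert len(frame) == 30
    assert "sigma" in frame.columns and "c" in frame.columns
    assert "kappa_age[2004]" in frame.columns
    np.testing.assert_allclose(frame["kappa_age[2004]"], 0.0)  # anchored
    # every stored scalar appears exactly once
    n_scalar = (
        sum(np.prod(v.shape[1:], dtype=int) for v in draws.terms.values())
        + len(draws.hier_sd)
        + sum(np.prod(v.shape[1:], dtype=int) for v in draws.kappa.values())
        + sum(np.prod(v.shape[1:], dtype=int) for d in draws.dyn.values() for v in d.values())
        + 1
    )
    assert len(frame.columns) == n_scalar + 2  # + chain, draw
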