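import numpy as np
import pytest
from scipy import stats

from mrpop.core_data import Component
from mrpop.loglin import (
    ModelSpec,
    PriorSpec,
    TermSpec,
    bilinear_prior_logdensity,
    bilinear_psi,
    constrain_bilinear_loadings,
    default_model_specs,
    expand_symmetric,
    linear_predictor,
    poisson_lognormal_loglik,
    symmetric_od_prior,
)


def _toy_spec():
    from mrpop.dynamics import KappaSpec

    return ModelSpec(
        Component.FERTILITY,
        terms=[
            TermSpec("c", (), "intercept", PriorSpec("normal_fixed_sd", sd=np.sqrt(5))),
            TermSpec("A1", ("age",), "main", PriorSpec("normal_hier_sd_half_t")),
            TermSpec(
                "A2", ("age",), "bilinear_loading", PriorSpec("constrained_bilinear"),
                kappa="k2",
            ),
        ],
        kappas=[KappaSpec("k2", "scalar", "ar1_nodrift")],
    )


class TestLinearPredictor:
    def test_zero_parameters_give_zero(self):
        spec = _toy_spec()
        params = {"c": {(): 0.0}, "A1": {(20,): 0.0}, "A2": {(20,): 0.0}}
        kappas = {"k2": {2011: 2.0}}
        cell = {"age": 20, "year": 2011}
        assert linear_predictor(spec, params, kappas, cell) == 0.0

    def test_additive_arithmetic(self):
        spec = _toy_spec()
        params = {"c": {(): -3.0}, "A1": {(20,): 0.5}, "A2": {(20,): 0.1}}
        kappas = {"k2": {2011: 2.0}}
        cell = {"age": 20, "year": 2011}
        assert linear_predictor(spec, params, kappas, cell) == pytest.approx(-2.3)

    def test_break_indicator_only_after_threshold(self):
        from mrpop.dynamics import KappaSpec

        spec = ModelSpec(
            Component.IMMIGRATION,
            terms=[
                TermSpec("c", (), "intercept", PriorSpec("normal_fixed_sd", sd=1.0)),
                TermSpec(
                    "Rbrk", ("region",), "break_indicator",
                    PriorSpec("normal_hier_sd_half_t"), break_year=2004,
                ),
            ],
            kappas=[],
        )
        params = {"c": {(): 0.0}, "Rbrk": {("A",): 0.3}}
        before = linear_predictor(spec, params, {}, {"region": "A", "year": 2003})
        after = linear_predictor(spec, params, {}, {"region": "A", "year": 2005})
        assert after - before == pytest.approx(0.3)
        at = linear_predictor(spec, params, {}, {"region": "A", "year": 2004})
        assert at == after

    def test_unknown_level_raises(self):
        spec = _toy_spec()
        params = {"c": {(): 0.0}, "A1": {(20,): 0.0}, "A2": {(20,): 0.0}}
        with pytest.raises(KeyError, match="unknown cell level"):
            linear_predictor(spec, params, {"k2": {2011: 0.0}}, {"age": 85, "year": 2011})


class TestConstrainedLoadings:
    def test_uniform_prior_mean_case(self):
        z = 5
        out = constrain_bilinear_loadings(np.full(z - 1, 1 / z))
        np.testing.assert_allclose(out, np.full(z, 1 / z))

    def test_degenerate_corner(self):
        np.testing.assert_allclose(
            constrain_bilinear_loadings(np.array([1.0, 0.0])), [1.0, 0.0, 0.0]
        )

    @pytest.mark.parametrize("z", [2, 3, 7, 18])
    def test_sum_is_exactly_one(self, z):
        rng = np.random.default_rng(z)
        u = rng.normal(0, 1, z - 1)
        assert constrain_bilinear_loadings(u).sum() == pytest.approx(1.0, abs=1e-12)


class TestBilinearPrior:
    def test_z2_closed_form(self):
        # one free element: Normal(1/2, 1/8)
        for u in (0.1, 0.5, 0.9):
            expected = stats.norm.logpdf(u, loc=0.5, scale=np.sqrt(1 / 8))
            assert bilinear_prior_logdensity(np.array([u])) == pytest.approx(expected)

    def test_z3_matrix_inverse_oracle(self):
        z = 3
        psi = np.array([[2.0, 1.0], [1.0, 2.0]])
        cov = np.linalg.inv(psi) / z**2
        rng = np.random.default_rng(1)
        u = rng.normal(1 / 3, 0.1, 2)
        diff = u - 1 / 3
        expected = (
            -np.log(2 * np.pi)
            - 0.5 * np.log(np.linalg.det(cov))
            - 0.5 * diff @ np.linalg.solve(cov, diff)
        )
        assert bilinear_prior_logdensity(u) == pytest.approx(expected)

    def test_density_maximal_at_uniform(self):
        z = 6
        at_mean = bilinear_prior_logdensity(np.full(z - 1, 1 / z))
        rng = np.random.default_rng(2)
        for _ in range(10):
            u = 1 / z + rng.normal(0, 0.05, z - 1)
            assert bilinear_prior_logdensity(u) <= at_mean

    def test_psi_pattern(self):
        psi = bilinear_psi(4)
        assert psi.shape == (3, 3)
        assert (np.diag(psi) == 2).all()
        assert psi[0, 1] == psi[2, 0] == 1


class TestSymmetricODPrior:
    def test_n2_single_free_alpha(self):
        od1 = np.array([[0.0, 0.4], [0.6, 0.0]])
        alpha = np.array([0.5])
        got = symmetric_od_prior(alpha, od1, 0.2, 2)
        expected = stats.norm.logpdf(0.4, 0.5, 0.2) + stats.norm.logpdf(0.6, 0.5, 0.2)
        assert got == pytest.approx(expected)

    def test_n3_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        alpha_free = rng.normal(0, 1, 3)  # pairs (0,1), (0,2), (1,2)
        od1 = rng.normal(0, 1, (3, 3))
        np.fill_diagonal(od1, 0.0)
        alpha = expand_symmetric(alpha_free, 3)
        expected = sum(
            stats.norm.logpdf(od1[i, j], alpha[i, j], 0.3)
            for i in range(3)
            for j in range(3)
            if i != j
        )
        assert symmetric_od_prior(alpha_free, od1, 0.3, 3) == pytest.approx(expected)

    def test_density_maximal_at_alpha(self):
        alpha_free = np.array([0.2, -0.1, 0.3])
        alpha = expand_symmetric(alpha_free, 3)
        at_mode = symmetric_od_prior(alpha_free, alpha, 0.5, 3)
        perturbed = alpha + 0.1
        np.fill_diagonal(perturbed, 0.0)
        assert symmetric_od_prior(alpha_free, perturbed, 0.5, 3) < at_mode

    def test_expand_symmetric(self):
        out = expand_symmetric(np.array([1.0, 2.0, 3.0]), 3)
        assert out[0, 1] == out[1, 0] == 1.0
        assert out[0, 2] == out[2, 0] == 2.0
        assert out[1, 2] == out[2, 1] == 3.0
        assert (np.diag(out) == 0).all()


class TestPoissonLognormal:
    def test_poisson_part_oracle(self):
        # Y=5, K=100, mu=0.05 -> lambda=5
        got = poisson_lognormal_loglik(5, 100.0, np.log(0.05), np.log(0.05), 1.0)
        # Poisson part by hand: 5 log 5 - 5 - log 5!
        by_hand = 5 * np.log(5.0) - 5.0 - np.log(120.0)
        expected = by_hand + stats.norm.logpdf(0.0, 0.0, 1.0)
        assert got == pytest.approx(expected)

    def test_normal_part_at_mode(self):
        sigma = 1e-3
        got = poisson_lognormal_loglik(0, 1.0, 0.0, 0.0, sigma)
        # normal part collapses to -log(sigma sqrt(2 pi)); poisson part is -lambda
        assert got == pytest.approx(-1.0 - np.log(sigma * np.sqrt(2 * np.pi)))

    def test_zero_count(self):
        lam = 3.0
        got = poisson_lognormal_loglik(0, 1.0, np.log(lam), np.log(lam), 1.0)
        assert got == pytest.approx(-lam + stats.norm.logpdf(0.0, 0.0, 1.0))

    @pytest.mark.parametrize("Y,K,sigma", [(-1, 1.0, 1.0), (2.5, 1.0, 1.0), (1, 0.0, 1.0), (1, 1.0, 0.0)])
    def test_input_errors(self, Y, K, sigma):
        with pytest.raises(ValueError):
            poisson_lognormal_loglik(Y, K, 0.0, 0.0, sigma)


class TestDefaultSpecs:
    def test_internal_migration_terms(self):
        spec = default_model_specs(Component.INTERNAL_MIGRATION)
        assert [t.name for t in spec.terms] == ["c", "AS", "OA", "DA", "OD1", "OD2", "A1", "A2"]
        assert {k.dynamics for k in spec.kappas} == {"ar1_drift"}

    def test_mortality_has_no_region_time_bilinear(self):
        spec = default_model_specs(Component.MORTALITY)
        bilinear_dims = [t.dims for t in spec.terms if t.kind == "bilinear_loading"]
        assert bilinear_dims == [("age", "sex")]
        assert spec.kappas[0].dynamics == "mrw_drift"

    def test_fertility_is_driftless(self):
        spec = default_model_specs(Component.FERTILITY)
        assert all(k.dynamics == "ar1_nodrift" for k in spec.kappas)

    def test_immigration_break_and_var1(self):
        spec = default_model_specs(Component.IMMIGRATION, break_year=2004)
        brk = [t for t in spec.terms if t.kind == "break_indicator"]
        assert len(brk) == 1 and brk[0].break_year == 2004
        assert spec.kappa("kappa_as").dynamics == "var1_drift"
        assert spec.kappa("kappa_region").dynamics == "ar1_drift"

    def test_yaml_roundtrip(self):
        spec = default_model_specs(Component.EMIGRATION)
        back = ModelSpec.from_dict(spec.to_dict())
        assert [t.name for t in back.terms] == [t.name for t in spec.terms]
        assert back.kappa("kappa_as").dimension == "sex_paired"
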