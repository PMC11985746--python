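import numpy as np
import pytest

from mrpop.core_data import DimensionRegistry
from mrpop.projection import (
    MatrixSet,
    build_matrix_set,
    conditional_transitions,
    infant_survivorship,
    project_step,
    survivorship,
    uncondition,
)


def _stochastic(rng, n):
    m = rng.uniform(0.01, 1.0, (n, n))
    return m / m.sum(axis=1, keepdims=True)


class TestConditionalTransitions:
    def test_identity_fixed_point(self):
        sbar = np.stack([np.eye(3)] * 5)
        pbar = conditional_transitions(sbar)
        np.testing.assert_allclose(pbar, sbar)

    def test_elementwise_average(self):
        s_x = np.array([[0.9, 0.1], [0.2, 0.8]])
        s_xm5 = np.array([[0.8, 0.2], [0.4, 0.6]])
        sbar = np.stack([s_xm5, s_x, s_x])
        pbar = conditional_transitions(sbar)
        np.testing.assert_allclose(pbar[1], 0.5 * (s_x + s_xm5))

    def test_youngest_uses_squared_form(self):
        rng = np.random.default_rng(0)
        s0 = _stochastic(rng, 3)
        sbar = np.stack([s0, _stochastic(rng, 3), _stochastic(rng, 3)])
        pbar = conditional_transitions(sbar)
        np.testing.assert_allclose(pbar[0], 0.5 * (s0 @ s0 + s0))

    def test_oldest_equals_sbar(self):
        rng = np.random.default_rng(1)
        sbar = np.stack([_stochastic(rng, 4) for _ in range(6)])
        pbar = conditional_transitions(sbar)
        np.testing.assert_allclose(pbar[-1], sbar[-1])

    def test_rows_stay_stochastic(self):
        rng = np.random.default_rng(2)
        sbar = np.stack([_stochastic(rng, 5) for _ in range(8)])
        pbar = conditional_transitions(sbar)
        np.testing.assert_allclose(pbar.sum(axis=2), 1.0, atol=1e-12)

    def test_rejects_non_stochastic(self):
        with pytest.raises(ValueError):
            conditional_transitions(np.stack([np.full((2, 2), 0.6)] * 3))


class TestUncondition:
    def test_zero_rates_identity_adjustment(self):
        rng = np.random.default_rng(3)
        pbar = _stochastic(rng, 4)
        out = uncondition(pbar, np.zeros(4), np.zeros(4))
        np.testing.assert_allclose(out, pbar)

    def test_single_region_scalar(self):
        out = uncondition(np.array([[1.0]]), np.array([0.02]), np.array([0.01]))
        assert out[0, 0] == pytest.approx((1 - 0.075) / (1 + 0.075))

    def test_monotone_in_mortality(self):
        rng = np.random.default_rng(4)
        pbar = _stochastic(rng, 3)
        d = np.array([0.01, 0.02, 0.015])
        e = np.full(3, 0.005)
        base = uncondition(pbar, d, e)
        bumped = uncondition(pbar, d + np.array([0.0, 0.01, 0.0]), e)
        # raising region k's mortality cannot raise any transition probability
        assert np.all(bumped <= base + 1e-15)
        de = d + e
        num = 1 - 2.5 * de
        den = 1 + 2.5 * pbar @ de
        np.testing.assert_allclose(base, pbar * (num / den)[None, :])

    def test_precondition_enforced(self):
        with pytest.raises(ValueError, match="5/2"):
            uncondition(np.array([[1.0]]), np.array([0.3]), np.array([0.2]))


class TestSurvivorship:
    def test_identity(self):
        I = np.eye(3)
        np.testing.assert_allclose(survivorship(I, I), I)

    def test_scalar_oracle(self):
        out = survivorship(np.array([[0.9]]), np.array([[0.8]]))
        assert out[0, 0] == pytest.approx(1.8 * 0.9 / 1.9)

    def test_equal_matrices_scalar_identity(self):
        out = survivorship(np.array([[0.7]]), np.array([[0.7]]))
        assert out[0, 0] == pytest.approx(0.7)

    def test_infant_identity_at_zero_mortality(self):
        np.testing.assert_allclose(infant_survivorship(np.eye(3)), np.eye(3))

    def test_infant_scalar_first_form(self):
        out = infant_survivorship(None or np.array([[0.9]]), M_0=np.array([[0.01]]))
        assert out[0, 0] == pytest.approx(1 / 1.025)

    def test_infant_forms_agree_one_region(self):
        # a single-region P0 encoding mortality m has both printed forms equal
        m = 0.013
        P0 = np.array([[(1 - 2.5 * m) / (1 + 2.5 * m)]])
        from_p = infant_survivorship(P0)
        from_m = infant_survivorship(P0, M_0=np.array([[m]]))
        np.testing.assert_allclose(from_p, from_m, atol=1e-14)


def _registry(n_regions=2, n_ages=4):
    return DimensionRegistry(
        tuple(f"R{i}" for i in range(n_regions)),
        tuple(5 * i for i in range(n_ages)),
        (2011,),
        (1, 2),
    )


def _identity_mats(n, z):
    I3 = np.stack([np.eye(n)] * z)
    return MatrixSet(I3, I3, I3.copy(), np.eye(n))


class TestProjectStep:
    def test_closed_population_pure_shift(self):
        reg = _registry(2, 4)
        K = np.arange(2 * 4 * 2, dtype=float).reshape(2, 4, 2) + 1
        mats = {s: _identity_mats(2, 4) for s in ("M", "F")}
        # survivors of the terminal group also remain (S_z = I), so the last
        # group accumulates; with fertility zero the first group empties
        out = project_step(K, mats, np.zeros((2, 4)), np.zeros((2, 4, 2)), reg)
        np.testing.assert_allclose(out[:, 1, :], K[:, 0, :])
        np.testing.assert_allclose(out[:, 2, :], K[:, 1, :])
        np.testing.assert_allclose(out[:, 3, :], K[:, 2, :] + K[:, 3, :])
        np.testing.assert_allclose(out[:, 0, :], 0.0)

    def test_sex_ratio_at_birth_split_exact(self):
        reg = _registry(2, 4)
        K = np.full((2, 4, 2), 100.0)
        mats = {s: _identity_mats(2, 4) for s in ("M", "F")}
        f = np.zeros((2, 4))
        f[:, 1:3] = 0.04
        out = project_step(K, mats, f, np.zeros((2, 4, 2)), reg, srb=105.0)
        male, female = out[:, 0, 0], out[:, 0, 1]
        np.testing.assert_allclose(male / female, 105.0 / 100.0)
        # with identity survivorship, births = 5/2 * sum over ages of (f_x + f_{x+5}) * K
        expected_total = 2.5 * ((0.04 + 0.04) + (0.04 + 0.0)) * 100.0
        np.testing.assert_allclose(male + female, expected_total)

    def test_immigrants_half_period_accounting(self):
        reg = _registry(2, 4)
        K = np.zeros((2, 4, 2))
        G = np.zeros((2, 4, 2))
        G[:, 2, :] = 10.0
        mats = {s: _identity_mats(2, 4) for s in ("M", "F")}
        out = project_step(K, mats, np.zeros((2, 4)), G, reg)
        # half of G_x survives into x+5, half of G_{x+5} arrives directly
        np.testing.assert_allclose(out[:, 3, :], 5.0)
        np.testing.assert_allclose(out[:, 2, :], 5.0)

    def test_mortality_monotonicity(self):
        reg = _registry(2, 4)
        rng = np.random.default_rng(8)
        sbar = np.stack([_stochastic(rng, 2) for _ in range(4)])
        K = np.full((2, 4, 2), 1000.0)
        d_lo = {s: np.full((2, 4), 0.01) for s in ("M", "F")}
        d_hi = {s: v.copy() for s, v in d_lo.items()}
        d_hi["M"][0, :] = 0.05  # raise region 0 male mortality
        e = {s: np.full((2, 4), 0.002) for s in ("M", "F")}
        out = {}
        for tag, d in (("lo", d_lo), ("hi", d_hi)):
            mats = {s: build_matrix_set(sbar, d[s], e[s]) for s in ("M", "F")}
            out[tag] = project_step(K, mats, np.zeros((2, 4)), np.zeros((2, 4, 2)), reg)
        assert out["hi"][0, 1:, 0].sum() < out["lo"][0, 1:, 0].sum()

    def test_negative_output_raises(self):
        reg = _registry(2, 4)
        mats = {s: _identity_mats(2, 4) for s in ("M", "F")}
        bad = _identity_mats(2, 4)
        bad.S[0] = np.array([[-0.5, 0.0], [0.0, 1.0]])
        mats["M"] = bad
        K = np.full((2, 4, 2), 10.0)
        with pytest.raises(ValueError, match="negative"):
            project_step(K, mats, np.zeros((2, 4)), np.zeros((2, 4, 2)), reg)


def _uniregional_step(K, d, e, f, G, srb, repro, sbar_scalar=1.0):
    """Independent scalar cohort-component step for one region and sex pair.

    K, G: (z, 2); d, e: (z, 2); f: (z,).  Plain-loop re-implementation used
    as an oracle; shares no code with the engine.
    """
    z = K.shape[0]
    P = np.zeros((z, 2))
    for s in range(2):
        for a in range(z):
            de = d[a, s] + e[a, s]
            P[a, s] = sbar_scalar * (1 - 2.5 * de) / (1 + 2.5 * sbar_scalar * de)
    S = np.zeros((z, 2))
    Sm5 = np.zeros(2)
    for s in range(2):
        for a in range(z - 1):
            S[a, s] = (1 + P[a + 1, s]) * P[a, s] / (1 + P[a, s])
        S[z - 1, s] = P[z - 1, s]
        Sm5[s] = 1.0 / (1.0 + (1 - P[0, s]) / (1 + P[0, s]))
    out = np.zeros((z, 2))
    for s in range(2):
        for a in range(z - 1):
            out[a + 1, s] += S[a, s] * (K[a, s] + 0.5 * G[a, s])
        out[z - 1, s] += S[z - 1, s] * (K[z - 1, s] + 0.5 * G[z - 1, s])
        for a in range(1, z):
            out[a, s] += 0.5 * G[a, s]
    births = 0.0
    a0, b0 = repro
    for a in range(a0, b0 + 1):
        fa5 = f[a + 1] if a + 1 < z else 0.0
        births += (f[a] + S[a, 1] * fa5) * (K[a, 1] + 0.5 * G[a, 1])
    births *= 2.5
    out[0, 0] = Sm5[0] * births * srb / (srb + 100.0) + 0.5 * G[0, 0]
    out[0, 1] = Sm5[1] * births * 100.0 / (srb + 100.0) + 0.5 * G[0, 1]
    return out


class TestZeroMigrationEquivalence:
    def test_matches_independent_uniregional_projection(self):
        n, z = 3, 6
        reg = DimensionRegistry(
            ("R0", "R1", "R2"), tuple(5 * i for i in range(z)), (2011,), (1, 3)
        )
        rng = np.random.default_rng(77)
        K = rng.uniform(500, 5000, (n, z, 2))
        G = rng.uniform(0, 50, (n, z, 2))
        f = np.zeros((n, z))
        f[:, 1:4] = rng.uniform(0.01, 0.08, (n, 3))
        d = {s: rng.uniform(0.001, 0.05, (n, z)) for s in ("M", "F")}
        e = {s: rng.uniform(0.0005, 0.01, (n, z)) for s in ("M", "F")}
        sbar = np.stack([np.eye(n)] * z)
        mats = {s: build_matrix_set(sbar, d[s], e[s]) for s in ("M", "F")}
        multi = project_step(K, mats, f, G, reg, srb=105.0)
        for r in range(n):
            d_r = np.stack([d["M"][r], d["F"][r]], axis=1)
            e_r = np.stack([e["M"][r], e["F"][r]], axis=1)
            uni = _uniregional_step(K[r], d_r, e_r, f[r], G[r], 105.0, (1, 3))
            np.testing.assert_allclose(multi[r], uni, rtol=1e-12, atol=1e-9)


class TestOrientation:
    def test_asymmetric_two_region_flow_direction(self):
        # all of region 0 moves to region 1; nobody moves the other way
        n, z = 2, 3
        reg = DimensionRegistry(("R0", "R1"), (0, 5, 10), (2011,), (1, 1))
        move = np.array([[0.0, 1.0], [0.0, 1.0]])  # rows = origins
        sbar = np.stack([move] * z)
        zero = np.zeros((n, z))
        mats = {s: build_matrix_set(sbar, zero, zero) for s in ("M", "F")}
        K = np.zeros((n, z, 2))
        K[0, 0, :] = 100.0
        out = project_step(K, mats, np.zeros((n, z)), np.zeros((n, z, 2)), reg)
        assert out[1, 1, 0] == pytest.approx(100.0)
        assert out[0, 1, 0] == pytest.approx(0.0)
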