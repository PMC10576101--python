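"""Opinion-field game: payoffs, replicator dynamics, equilibria, stability."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import optimize

import panicseir as ps
from conftest import draw_payoffs, draw_rates


class TestPayoffs:
    @pytest.mark.parametrize("y1", [0.0, 0.5, 1.0])
    def test_official_payoffs_baseline_values(self, pm, y1):
        # b1 - c11 = b2 makes positive guidance's payoff independent of y1.
        u1, u2, _ = ps.official_payoffs(pm, ps.GameState(0.3, y1))
        assert u1 == pytest.approx(9.0)
        assert u2 == pytest.approx(5.0)

    def test_official_average_at_vertex_is_pure_payoff(self, pm):
        state = ps.GameState(1.0, 0.37)
        u1, _, ubar = ps.official_payoffs(pm, state)
        assert ubar == pytest.approx(u1)

    @pytest.mark.parametrize(
        "x1, expected", [(1.0, (3.0, 1.0)), (0.0, (3.0, 1.0))]
    )
    def test_public_payoffs_baseline_values(self, pm, x1, expected):
        u1, u2, _ = ps.public_payoffs(pm, ps.GameState(x1, 0.4))
        assert (u1, u2) == pytest.approx(expected)

    def test_public_average_at_vertex_is_pure_payoff(self, pm):
        state = ps.GameState(0.2, 0.0)
        _, u2, ubar = ps.public_payoffs(pm, state)
        assert ubar == pytest.approx(u2)


class TestReplicator:
    @pytest.mark.parametrize(
        "p21, q21, expected",
        [(1.0, 1.0, (0.96, 0.5)), (0.5, 0.5, (1.56, 0.625))],
    )
    def test_two_field_rhs_values(self, pm, p21, q21, expected):
        rates = ps.GameRates(p21=p21, q21=q21)
        rhs = ps.replicator_rhs(ps.GameState(0.6, 0.5), pm, rates)
        assert rhs == pytest.approx(expected, abs=1e-12)

    @given(
        x1=st.floats(0, 1), y1=st.floats(0, 1),
        seed=st.integers(0, 100),
    )
    def test_vertex_components_vanish(self, x1, y1, seed):
        """The x1(1-x1) / y1(1-y1) factors absorb every boundary."""
        rng = np.random.default_rng(seed)
        pm, rates = draw_payoffs(rng), draw_rates(rng)
        dx, dy = ps.replicator_rhs(ps.GameState(float(x1), float(y1)), pm, rates)
        if x1 in (0.0, 1.0):
            assert dx == 0.0
        if y1 in (0.0, 1.0):
            assert dy == 0.0


class TestGeneralReplicator:
    def test_equal_influence_reduces_to_classical(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = rng.integers(2, 6)
            pop = ps.StrategyPopulation(
                counts=rng.uniform(0.1, 5.0, n),
                payoffs=rng.uniform(-2.0, 2.0, n),
                kappa=np.full(n, 1.3),
            )
            z, u = pop.shares, pop.payoffs
            classical = z * 1.3 * (u - z @ u)
            np.testing.assert_allclose(
                ps.general_replicator_rhs(pop), classical, atol=1e-12
            )

    def test_share_derivatives_sum_to_zero(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = rng.integers(2, 8)
            pop = ps.StrategyPopulation(
                counts=rng.uniform(0.0, 5.0, n) + 1e-3,
                payoffs=rng.uniform(-3.0, 3.0, n),
                kappa=rng.uniform(0.1, 3.0, n),
            )
            assert abs(ps.general_replicator_rhs(pop).sum()) < 1e-12

    def test_matches_exponential_growth_oracle(self):
        """With constant payoffs the counts grow exponentially at rates
        kappa_i*u_i, so the share derivative has an independent closed form
        checkable by central finite differences."""
        rng = np.random.default_rng(3)
        for _ in range(25):
            n = int(rng.integers(2, 6))
            n0 = rng.uniform(0.5, 4.0, n)
            u = rng.uniform(-2.0, 2.0, n)
            k = rng.uniform(0.2, 3.0, n)
            pop = ps.StrategyPopulation(counts=n0, payoffs=u, kappa=k)

            def shares(t):
                nt = n0 * np.exp(k * u * t)
                return nt / nt.sum()

            h = 1e-6
            fd = (shares(h) - shares(-h)) / (2 * h)
            np.testing.assert_allclose(
                ps.general_replicator_rhs(pop), fd, atol=1e-7
            )

    def test_two_strategy_case_matches_two_field_rhs(self, pm):
        """An official field modelled as a 2-strategy population with
        kappa = (lambda1, lambda2) reproduces the dedicated x1 equation."""
        rates = ps.GameRates(lambda1=1.4, p21=0.7)
        state = ps.GameState(0.35, 0.8)
        u1, u2, _ = ps.official_payoffs(pm, state)
        pop = ps.StrategyPopulation(
            counts=np.array([state.x1, state.x2]) * 100.0,
            payoffs=np.array([u1, u2]),
            kappa=np.array([rates.lambda1, rates.lambda2]),
        )
        dx1_expected, _ = ps.replicator_rhs(state, pm, rates)
        assert ps.general_replicator_rhs(pop)[0] == pytest.approx(
            dx1_expected, abs=1e-10
        )

    def test_rejects_empty_and_zero_populations(self):
        with pytest.raises(ValueError):
            ps.StrategyPopulation(np.array([]), np.array([]), np.array([]))
        with pytest.raises(ValueError):
            ps.StrategyPopulation(
                np.zeros(3), np.ones(3), np.ones(3)
            )


class TestEquilibria:
    def test_corners_always_present(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            pts = {
                (e.x1, e.y1)
                for e in ps.find_equilibria(draw_payoffs(rng), draw_rates(rng))
            }
            assert {(0, 0), (0, 1), (1, 0), (1, 1)} <= pts

    def test_interior_absent_for_baseline_payoffs(self, pm):
        # Both closed-form denominators vanish for these payoffs.
        eqs = ps.find_equilibria(pm, ps.GameRates(p21=0.5, q21=0.5))
        assert len(eqs) == 4

    def test_every_equilibrium_is_a_fixed_point(self):
        rng = np.random.default_rng(29)
        for _ in range(50):
            pm, rates = draw_payoffs(rng), draw_rates(rng)
            for eq in ps.find_equilibria(pm, rates):
                dx, dy = ps.replicator_rhs(eq, pm, rates)
                assert np.hypot(dx, dy) < 1e-12

    def test_interior_point_matches_numeric_root_finder(self):
        from panicseir.model import _bracket_x, _bracket_y

        rng = np.random.default_rng(31)
        found = 0
        for _ in range(4000):
            pm, rates = draw_payoffs(rng), draw_rates(rng)
            interior = [e for e in ps.find_equilibria(pm, rates)
                        if 0.05 < e.x1 < 0.95 and 0.05 < e.y1 < 0.95]
            if not interior:
                continue
            found += 1
            eq = interior[0]

            def rhs(v):  # polynomial RHS, smooth beyond the unit square
                x, y = v
                return [
                    rates.lambda1 * x * (1 - x) * _bracket_x(pm, rates, y),
                    rates.rho1 * y * (1 - y) * _bracket_y(pm, rates, x),
                ]

            sol = optimize.root(
                rhs,
                x0=np.array([eq.x1, eq.y1]) + rng.uniform(-0.01, 0.01, 2),
            )
            assert np.max(np.abs(rhs(sol.x))) < 1e-12
            np.testing.assert_allclose(sol.x, [eq.x1, eq.y1], atol=1e-9)
            if found >= 10:
                break
        assert found >= 10


class TestJacobian:
    def test_origin_with_unit_dependence(self, pm):
        jac = ps.game_jacobian(ps.GameState(0, 0), pm, ps.GameRates())
        np.testing.assert_allclose(jac, np.diag([4.0, 2.0]))
        assert np.linalg.det(jac) == pytest.approx(8.0)
        assert np.trace(jac) == pytest.approx(6.0)

    def test_corner_off_diagonals_vanish(self):
        rng = np.random.default_rng(37)
        for _ in range(20):
            pm, rates = draw_payoffs(rng), draw_rates(rng)
            for x, y in [(0, 0), (0, 1), (1, 0), (1, 1)]:
                jac = ps.game_jacobian(ps.GameState(x, y), pm, rates)
                assert jac[0, 1] == 0.0 and jac[1, 0] == 0.0

    def test_matches_central_finite_differences(self):
        rng = np.random.default_rng(41)
        h = 1e-6
        for _ in range(30):
            pm, rates = draw_payoffs(rng), draw_rates(rng)
            x1, y1 = rng.uniform(0.05, 0.95, 2)
            jac = ps.game_jacobian(ps.GameState(x1, y1), pm, rates)
            fd = np.empty((2, 2))
            for j, (dx, dy) in enumerate([(h, 0.0), (0.0, h)]):
                hi = ps.replicator_rhs(ps.GameState(x1 + dx, y1 + dy), pm, rates)
                lo = ps.replicator_rhs(ps.GameState(x1 - dx, y1 - dy), pm, rates)
                fd[:, j] = (np.array(hi) - np.array(lo)) / (2 * h)
            np.testing.assert_allclose(jac, fd, atol=1e-6)


class TestClassification:
    def test_baseline_corner_labels(self, pm):
        rates = ps.GameRates()
        labels = {
            (e.x1, e.y1): ps.classify_equilibrium(e, pm, rates).label
            for e in ps.find_equilibria(pm, rates)
        }
        assert labels == {
            (0.0, 0.0): "unstable",
            (0.0, 1.0): "saddle",
            (1.0, 0.0): "saddle",
            (1.0, 1.0): "ESS",
        }

    def test_rejects_non_fixed_point(self, pm):
        with pytest.raises(ValueError, match="not a replicator fixed point"):
            ps.classify_equilibrium(ps.GameState(0.6, 0.5), pm, ps.GameRates())

    @pytest.mark.parametrize("p21", [0.5, 1.0, 1.5])
    @pytest.mark.parametrize("q21", [0.5, 1.0, 1.5])
    def test_scenario_cooperation_case(self, pm, p21, q21):
        """Both degeneracy conditions vanish for the baseline payoffs, and
        the positive-strategy advantages stay positive, so (1,1) is the
        predicted evolutionarily stable outcome for every tested ratio."""
        result = ps.classify_scenario(pm, ps.GameRates(p21=p21, q21=q21))
        assert result.case == "I.4"
        assert result.ess == ((1.0, 1.0),)

    def test_scenario_defection_case(self, pm):
        # 9 - 5*p21 < 0 and 3 - q21 < 0 flip both advantages negative.
        result = ps.classify_scenario(pm, ps.GameRates(p21=2.5, q21=4.0))
        assert result.case == "I.1"
        assert result.ess == ((0.0, 0.0),)
        numeric_ess = [r.point for r in result.reports if r.label == "ESS"]
        assert numeric_ess == [(0.0, 0.0)]

    def test_scenario_boundary_is_degenerate(self, pm):
        # p21 = 1.8 puts the official-field advantage exactly at zero.
        result = ps.classify_scenario(pm, ps.GameRates(p21=1.8, q21=1.0))
        assert result.degenerate
        assert result.case == "numeric"

    def test_scenario_single_degeneracy_case(self):
        """With b2 + c11 > b1 the second degeneracy condition is nonzero and
        the eight-case table applies; the chosen signs select (1,0)."""
        pm = ps.PayoffMatrix(b1=14, b2=10, b3=7, b4=5, b5=3, b6=1,
                             c1=5, c11=5, c21=4)
        result = ps.classify_scenario(pm, ps.GameRates(p21=0.5, q21=4.0))
        assert result.case == "II.7"
        assert result.ess == ((1.0, 0.0),)
        numeric_ess = [r.point for r in result.reports if r.label == "ESS"]
        assert numeric_ess == [(1.0, 0.0)]
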