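"""Kinetic model: rate laws, stoichiometry, simulation, Jacobian."""

import math

import numpy as np
import pytest

from fermstate.kinetics import (
    IDX,
    NO_INHIBITION,
    KineticParameters,
    StateVector,
    competitive_inhibition_factor,
    inhibition_factor,
    inhibitor_uptake_rate,
    jacobian,
    product_inhibition_factor,
    reaction_rhs,
    simulate,
    specific_rates,
    stoichiometric_matrix,
    substrate_uptake_rate,
)


def random_feasible_states(n, seed=0):
    rng = np.random.default_rng(seed)
    hi = np.array([40.0, 25.0, 1.0, 1.0, 0.5, 4.0, 30.0, 8.0])
    return rng.uniform(0.0, 1.0, size=(n, 8)) * hi


class TestRateLaws:
    @pytest.mark.parametrize(
        "s, vmax, ks, ki, expected",
        [
            (0.0, 1.7, 0.5, 10.0, 0.0),
            (0.5, 1.7, 0.5, NO_INHIBITION, 1.7 / 2),  # half-saturation, no Si
            (1.0, 2.0, 1.0, 1.0, 2.0 / 3.0),
        ],
    )
    def test_substrate_uptake(self, s, vmax, ks, ki, expected):
        assert substrate_uptake_rate(s, vmax, ks, ki) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "i, vmax, ksp, expected",
        [(0.0, 1.0, 0.3, 0.0), (0.3, 1.0, 0.3, 0.5), (3.0, 1.0, 1.0, 0.75)],
    )
    def test_inhibitor_uptake(self, i, vmax, ksp, expected):
        assert inhibitor_uptake_rate(i, vmax, ksp) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "i, ki, expected",
        [(0.0, 2.0, 1.0), (2.0, 2.0, 0.5), (6.0, 2.0, 0.25)],
    )
    def test_inhibition_factor(self, i, ki, expected):
        assert inhibition_factor(i, ki) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "p, pmax, gamma, expected",
        [(0.0, 90.0, 1.3, 1.0), (90.0, 90.0, 1.3, 0.0), (45.0, 90.0, 1.0, 0.5),
         (100.0, 90.0, 0.7, 0.0)],  # clamped above Pmax
    )
    def test_product_inhibition(self, p, pmax, gamma, expected):
        assert product_inhibition_factor(p, pmax, gamma) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "glu, ki, expected", [(0.0, 3.0, 1.0), (3.0, 3.0, 0.5), (12.0, 3.0, 0.2)]
    )
    def test_competitive_inhibition(self, glu, ki, expected):
        assert competitive_inhibition_factor(glu, ki) == pytest.approx(expected)

    def test_substrate_rate_bounded_by_vmax(self):
        s = np.linspace(0, 200, 400)
        rates = [substrate_uptake_rate(x, 2.0, 0.5, 50.0) for x in s]
        assert 0 <= min(rates) and max(rates) <= 2.0

    def test_factors_monotone_decreasing(self):
        grid = np.linspace(0, 50, 200)
        inh = [inhibition_factor(x, 4.0) for x in grid]
        prod = [product_inhibition_factor(x, 40.0, 1.3) for x in grid]
        assert all(np.diff(inh) < 0)
        assert all(np.diff(prod) <= 0)
        assert all(0 < v <= 1 for v in inh)
        assert all(0 <= v <= 1 for v in prod)

    @pytest.mark.parametrize(
        "func, args",
        [
            (substrate_uptake_rate, (-1.0, 1.0, 1.0, 1.0)),
            (substrate_uptake_rate, (1.0, -2.0, 1.0, 1.0)),
            (inhibitor_uptake_rate, (-0.1, 1.0, 1.0)),
            (inhibition_factor, (-0.5, 2.0)),
            (inhibition_factor, (0.5, 0.0)),
            (product_inhibition_factor, (-1.0, 40.0, 1.0)),
        ],
    )
    def test_domain_errors(self, func, args):
        with pytest.raises(ValueError):
            func(*args)


class TestStoichiometry:
    def test_each_process_consumes_one_compound(self, params):
        s = stoichiometric_matrix(params)
        assert s.shape == (5, 8)
        assert np.all(np.sum(s == -1.0, axis=1) == 1)

    def test_non_yield_entries_zero_or_minus_one(self, params):
        s = stoichiometric_matrix(params)
        yields = {(0, IDX["etoh"]), (0, IDX["x"]), (1, IDX["etoh"]), (1, IDX["x"]),
                  (2, IDX["fa"]), (3, IDX["hac"])}
        for i in range(5):
            for j in range(8):
                if (i, j) not in yields:
                    assert s[i, j] in (0.0, -1.0)


class TestReactionRhs:
    def test_zero_biomass_freezes_system(self, params):
        x = np.array([30.0, 20.0, 0.5, 0.1, 0.2, 2.0, 5.0, 0.0])
        assert np.all(reaction_rhs(x, params) == 0.0)

    def test_pure_glucose_state_matches_monod(self, params):
        glu, biomass = 20.0, 2.0
        x = np.array([glu, 0, 0, 0, 0, 0, 0, biomass])
        expected = substrate_uptake_rate(glu, params.vmax_glu, params.k_glu,
                                         params.ki_glu) * biomass
        dx = reaction_rhs(x, params)
        assert dx[IDX["glu"]] == pytest.approx(-expected, rel=1e-12)

    def test_ethanol_rate_is_yield_combination(self, params):
        for x in random_feasible_states(20, seed=3):
            q = specific_rates(x, params)
            dx = reaction_rhs(x, params)
            d_glu_uptake = -q[0] * x[IDX["x"]]
            d_xyl_uptake = -q[1] * x[IDX["x"]]
            expected = -params.y_etoh_glu * d_glu_uptake - params.y_etoh_xyl * d_xyl_uptake
            assert dx[IDX["etoh"]] == pytest.approx(expected, rel=1e-10, abs=1e-12)

    def test_mass_coupling_identities(self, params):
        for x in random_feasible_states(20, seed=4):
            q = specific_rates(x, params)
            dx = reaction_rhs(x, params)
            biomass = x[IDX["x"]]
            assert dx[IDX["fa"]] == pytest.approx(
                params.y_fa_fur * q[2] * biomass, rel=1e-10, abs=1e-12)
            assert dx[IDX["x"]] == pytest.approx(
                (params.y_x_glu * q[0] + params.y_x_xyl * q[1]) * biomass,
                rel=1e-10, abs=1e-12)


class TestSimulate:
    def test_zero_inoculum_constant_trajectory(self, params):
        x0 = StateVector(glu=37, xyl=22, fur=0.5, fa=0, hmf=0.15, hac=2.5, etoh=0, x=0.0)
        traj = simulate(x0, params, np.linspace(0, 10, 11))
        assert np.allclose(traj.y, x0.to_array(), atol=1e-12)

    def test_first_row_is_initial_condition(self, params, ferm1_x0):
        traj = simulate(ferm1_x0, params, np.linspace(0, 30, 61))
        assert np.array_equal(traj.y[0], ferm1_x0.to_array())

    def test_non_negative_states(self, params, ferm1_x0):
        traj = simulate(ferm1_x0, params, np.linspace(0, 40, 241))
        assert traj.y.min() >= -1e-9

    def test_batch_finishes_sugars_in_window(self, params):
        """Glucose exhausted around 10 h and xylose by 30 h under the
        reference batch conditions."""
        x0 = StateVector(glu=37, xyl=22, fur=0.5, fa=0, hmf=0.15, hac=2.5, etoh=0, x=1.0)
        traj = simulate(x0, params, np.linspace(0, 35, 211))
        t = traj.t
        glu_done = t[np.argmax(traj.state("glu") < 0.5)]
        xyl_done = t[np.argmax(traj.state("xyl") < 0.5)]
        assert 7.0 < glu_done < 13.0
        assert 20.0 < xyl_done < 33.0

    def test_ethanol_conservation(self, params, ferm1_x0):
        """Cumulative EtOH equals the yield-weighted sugar consumption at
        every time point (linear combination fixed by the stoichiometry)."""
        traj = simulate(ferm1_x0, params, np.linspace(0, 30, 121))
        glu0, xyl0 = ferm1_x0.glu, ferm1_x0.xyl
        expected = (params.y_etoh_glu * (glu0 - traj.state("glu"))
                    + params.y_etoh_xyl * (xyl0 - traj.state("xyl")))
        assert np.allclose(traj.state("etoh"), expected, atol=1e-5)

    def test_bad_grid_rejected(self, params, ferm1_x0):
        with pytest.raises(ValueError):
            simulate(ferm1_x0, params, np.array([0.0, 1.0, 1.0]))


class TestJacobian:
    def test_matches_finite_differences_on_random_states(self, params):
        worst = 0.0
        for x in random_feasible_states(100, seed=0):
            jac = jacobian(x, params)
            fd = np.zeros((8, 8))
            for j in range(8):
                h = 1e-6 * (1.0 + abs(x[j]))
                xp, xm = x.copy(), x.copy()
                xp[j] += h
                xm[j] -= h
                fd[:, j] = (reaction_rhs(xp, params) - reaction_rhs(xm, params)) / (2 * h)
            worst = max(worst, np.max(np.abs(jac - fd) / (1.0 + np.abs(fd))))
        assert worst < 1e-6

    def test_zero_state_gives_zero_matrix(self, params):
        assert np.all(jacobian(np.zeros(8), params) == 0.0)

    def test_zero_biomass_structure(self, params):
        """With X = 0 the only nonzero column is d f / d X, which equals the
        specific-rate vector mapped through the stoichiometry."""
        x = np.array([30.0, 20.0, 0.5, 0.1, 0.2, 2.0, 5.0, 0.0])
        jac = jacobian(x, params)
        q = specific_rates(x, params)
        expected_col = stoichiometric_matrix(params).T @ q
        np.testing.assert_allclose(jac[:, IDX["x"]], expected_col, rtol=1e-12)
        others = np.delete(jac, IDX["x"], axis=1)
        assert np.all(others == 0.0)


class TestParameters:
    def test_round_trip_dict(self, params):
        assert KineticParameters.from_dict(params.to_dict()) == params

    def test_validation(self):
        with pytest.raises(ValueError):
            KineticParameters(vmax_glu=-1.0)
        with pytest.raises(ValueError):
            KineticParameters(y_etoh_glu=1.5)

    def test_no_inhibition_sentinel_is_usable(self, params):
        p = params.replace(ki_glu=math.inf)
        x = np.array([10.0, 0, 0, 0, 0, 0, 0, 1.0])
        expected = params.vmax_glu * 10.0 / (params.k_glu + 10.0)
        assert reaction_rhs(x, p)[IDX["glu"]] == pytest.approx(-expected)
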