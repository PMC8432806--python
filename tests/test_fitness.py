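"""Malthusian parameter, R0, stable composition and Floquet dose analysis."""

import numpy as np
import pytest

from phenoswitch.model import GrowthLaw, SwitchingStrategy
from phenoswitch.fitness import (
    basic_reproduction_number, dose_scale_reference, linear_generator,
    malthusian_parameter, malthusian_parameter_allee, min_effective_dose,
    sensitive_fraction_limited, sensitive_fraction_stable,
    treated_period_multiplier,
)
from phenoswitch.ode import simulate
from phenoswitch.pkpd import PKParams
from conftest import make_params, random_params

NO_SWITCH = (1.0, 1.0, 0.01)


class TestMalthusianParameter:
    def test_no_switching_max_rule(self):
        p = make_params(strat_A=NO_SWITCH, strat_B=NO_SWITCH,
                        r_A=0.04, d_A=0.01, r_B=0.03, d_B=0.035)
        assert malthusian_parameter(p) == pytest.approx(max(0.03, -0.005))

    def test_identical_phenotypes(self):
        p = make_params(r_A=0.04, r_B=0.04, d_A=0.02, d_B=0.02,
                        strat_A=(0.9, 0.95, 0.01), strat_B=(0.9, 0.95, 0.01))
        assert malthusian_parameter(p) == pytest.approx(0.02, rel=1e-9)

    def test_plastic_population_interior_bounds(self, rng):
        for _ in range(200):
            p = random_params(rng)
            lam = malthusian_parameter(p)
            lo, hi = sorted((p.lambda_A, p.lambda_B))
            assert lo - 1e-9 <= lam <= hi + 1e-9

    def test_matches_simulated_growth(self):
        p = make_params()
        lam = malthusian_parameter(p)
        traj = simulate(p, t_span=(0, 400), n0=1e4)
        tail = traj.times > 250
        slope = np.polyfit(traj.times[tail], np.log(traj.n_total[tail]), 1)[0]
        assert abs(slope - lam) < 1e-4

    def test_generator_is_rhs_linearization(self):
        from phenoswitch.ode import rhs

        p = make_params()
        J = linear_generator(p)
        y = np.array([123.0, 45.0, 117.0, 20.0])
        d_lin = J @ y
        d_rhs = rhs(0.0, np.append(y, 0.0), p, None)[:4]
        assert np.allclose(d_lin, d_rhs, rtol=1e-12)


class TestAlleeEigenproblem:
    def test_self_consistency_of_fixed_point(self):
        p = make_params(growth=GrowthLaw("malthusian_allee", n=2.0))
        lam, theta = malthusian_parameter_allee(p)
        from phenoswitch.fitness import stable_structure

        y = stable_structure(p)
        assert y[1] / y[0] == pytest.approx(theta, rel=1e-6)

    def test_high_hill_reduces_to_plain_when_theta_below_one(self):
        p = make_params(r_A=0.05, r_B=0.02, d_A=0.01, d_B=0.04,
                        growth=GrowthLaw("malthusian_allee", n=50.0))
        lam, theta = malthusian_parameter_allee(p)
        assert theta < 1.0
        plain = malthusian_parameter(p.replace(growth=GrowthLaw("malthusian")))
        assert lam == pytest.approx(plain, rel=1e-4)

    def test_matches_simulation_slope(self):
        p = make_params(growth=GrowthLaw("malthusian_allee", n=2.0))
        lam, _ = malthusian_parameter_allee(p)
        traj = simulate(p, t_span=(0, 500), n0=1e4)
        tail = traj.times > 300
        slope = np.polyfit(traj.times[tail], np.log(traj.n_total[tail]), 1)[0]
        assert abs(slope - lam) < 1e-3


class TestBasicReproductionNumber:
    def test_single_type_scalar_ratio(self):
        p = make_params(strat_A=NO_SWITCH, strat_B=NO_SWITCH,
                        r_A=0.04, d_A=0.01, r_B=0.01, d_B=0.05)
        assert basic_reproduction_number(p) == pytest.approx(
            2 * 0.04 / (0.04 + 0.01))

    def test_boundary_of_sign_relation(self):
        p = make_params(r_A=0.03, d_A=0.03, r_B=0.02, d_B=0.02)
        assert basic_reproduction_number(p) == pytest.approx(1.0, abs=1e-9)

    def test_sign_relation_random_draws(self, rng):
        for _ in range(300):  # the full 1000-draw sweep runs in acceptance
            p = random_params(rng)
            lam = malthusian_parameter(p)
            r0 = basic_reproduction_number(p)
            assert np.sign(lam) == np.sign(r0 - 1.0) or abs(lam) < 1e-12


class TestSensitiveFraction:
    def test_no_switching_pure_sensitive(self):
        p = make_params(strat_A=NO_SWITCH, strat_B=NO_SWITCH,
                        r_A=0.05, d_A=0.01, r_B=0.02, d_B=0.03)
        assert sensitive_fraction_stable(p) == pytest.approx(1.0, abs=1e-6)

    def test_symmetric_half(self):
        p = make_params(r_A=0.04, r_B=0.04, d_A=0.02, d_B=0.02,
                        strat_A=(0.9, 0.95, 0.01), strat_B=(0.9, 0.95, 0.01))
        assert sensitive_fraction_stable(p) == pytest.approx(0.5, rel=1e-9)

    def test_strictly_decreasing_in_sensitive_death(self):
        fracs = [sensitive_fraction_stable(make_params(d_A=d))
                 for d in (0.005, 0.01, 0.02, 0.03)]
        assert np.all(np.diff(fracs) < 0)

    def test_sensitive_share_higher_under_unlimited_growth(self):
        """Resource limitation favours the tolerant phenotype: for a
        growing population the capacity-limited sensitive share at day 500
        sits below the unlimited (stable-age) share, and both erode as the
        sensitive death rate rises."""
        kw = dict(r_A=0.04, r_B=0.035, d_B=0.015, d_A_max=0.2,
                  strat_A=(0.9, 0.95, 0.01), strat_B=(0.0, 0.9, 1e-3))
        d_grid = (0.02, 0.03)
        stable = [sensitive_fraction_stable(make_params(d_A=d, **kw))
                  for d in d_grid]
        limited = [sensitive_fraction_limited(
            make_params(d_A=d, growth=GrowthLaw("logistic", K=1e5), **kw),
            horizon_days=500, n0=1e3) for d in d_grid]
        assert np.all(np.diff(stable) < 0)
        assert np.all(np.diff(limited) < 0)
        for s_, l_ in zip(stable, limited):
            assert l_ < s_

    def test_limited_requires_logistic(self):
        with pytest.raises(ValueError):
            sensitive_fraction_limited(make_params())


class TestFloquet:
    def setup_method(self):
        self.pk = PKParams(t_half=11.0)
        self.p = make_params(r_A=0.07, r_B=0.005, d_A=0.04, d_B=0.04,
                             d_A_max=0.15, strat_A=(0.0, 0.95, 0.01),
                             strat_B=(0.2, 0.8, 0.01))

    def test_zero_dose_autonomous_limit(self):
        T = 72.0
        lam = malthusian_parameter(self.p)
        rho = treated_period_multiplier(self.p, self.pk, 0.0, T)
        assert rho == pytest.approx(np.exp(lam * T), rel=1e-6)

    def test_saturation_limit_small_half_effect(self):
        pk = PKParams(t_half=11.0, c_half=1e-8)
        T = 72.0
        rho = treated_period_multiplier(self.p, pk, 5.0, T)
        treated = self.p.replace(d_A=self.p.d_A_max)
        lam_star = malthusian_parameter(treated)
        # drug saturated except right at the trough; close to the limit
        assert np.log(rho) / T == pytest.approx(lam_star, abs=5e-3)

    def test_monotone_decreasing_in_dose(self, rng):
        T = 96.0
        for _ in range(5):
            p = random_params(rng)
            doses = [0.0, 0.5, 2.0, 8.0]
            rhos = [treated_period_multiplier(p, self.pk, d, T) for d in doses]
            assert np.all(np.diff(rhos) < 0)

    def test_bisection_postcondition(self):
        T = 72.0
        res = min_effective_dose(self.p, self.pk, T)
        assert res.feasible
        assert abs(res.rho - 1.0) < 1e-4
        assert treated_period_multiplier(self.p, self.pk, 1.01 * res.dose, T) < 1.0

    def test_already_decaying_needs_no_dose(self):
        p = make_params(r_A=0.02, r_B=0.01, d_A=0.04, d_B=0.04, d_A_max=0.1,
                        strat_A=(0.0, 0.95, 0.01), strat_B=(0.2, 0.8, 0.01))
        res = min_effective_dose(p, self.pk, 72.0)
        assert res.dose == 0.0 and res.feasible

    def test_ineffective_drug_infeasible(self):
        p = self.p.replace(d_A_max=self.p.d_A)
        res = min_effective_dose(p, self.pk, 72.0, cap=100.0)
        assert not res.feasible and res.capped

    def test_dose_scale_reference(self):
        assert dose_scale_reference(self.p) == pytest.approx(0.15 - 0.04)


class TestSensitivityStructure:
    """Which subpopulation's fitness matters more depends on the strategy."""

    @staticmethod
    def _lam_p(lam_a, lam_b, strat_B, r_floor=0.05):
        # equal division rates; the intrinsic fitnesses are set via the
        # death rates, so swapping (lam_A, lam_B) is a label swap
        r = r_floor + max(lam_a, lam_b, 0.0)
        p = make_params(r_A=r, d_A=r - lam_a, r_B=r, d_B=r - lam_b,
                        d_A_max=r - lam_a + 0.1,
                        strat_A=(0.9, 0.95, 0.01), strat_B=strat_B)
        return malthusian_parameter(p)

    @pytest.mark.parametrize("strat_B, tolerant_dominates", [
        ((0.95, 1.0, 0.01), True),   # stay: tolerant fitness matters more
        ((0.0, 0.9, 0.01), False),   # switch: sensitive fitness matters more
    ])
    def test_finite_difference_sensitivities(self, strat_B, tolerant_dominates):
        lam0, h = 0.01, 1e-5
        dA = (self._lam_p(lam0 + h, lam0, strat_B)
              - self._lam_p(lam0 - h, lam0, strat_B)) / (2 * h)
        dB = (self._lam_p(lam0, lam0 + h, strat_B)
              - self._lam_p(lam0, lam0 - h, strat_B)) / (2 * h)
        assert (dB > dA) == tolerant_dominates

    def test_symmetric_strategy_symmetric_surface(self):
        sym = (0.9, 0.95, 0.01)
        for la, lb in ((0.02, -0.01), (0.015, 0.005), (-0.005, 0.01)):
            assert self._lam_p(la, lb, sym) == pytest.approx(
                self._lam_p(lb, la, sym), rel=1e-9, abs=1e-12)
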