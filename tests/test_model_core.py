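"""Closed-form kinetics: MT statistics, capture cone, impingement rate,
attachment competition, and force assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from stoichspindle import (
    CentrosomeState,
    ForceGenerator,
    MotorMTParams,
    attachment_probabilities,
    cfg_force,
    cone_fraction,
    impingement_rate,
    kappa_for_radius,
    mt_steady_state_stats,
    net_forces,
)
from stoichspindle.model_core import attachment_probability_ode_rhs

from .oracles import gillespie_occupancy_se, discrete_event_impingement_rate


class TestMTSteadyState:
    def test_defaults_give_ten_thousand_mts(self, default_params):
        stats = mt_steady_state_stats(default_params)
        assert stats["mt_count"] == pytest.approx(10_000)
        assert stats["density_at_zero"] == pytest.approx(500.0)

    def test_mean_length_matches_quadrature_of_length_density(self, default_params):
        # independent oracle: <l> = int l psi(l) dl / int psi(l) dl with
        # psi(l) = (gamma/Vg) exp(-l lambda / Vg)
        g, v, lam = 250.0, 0.5, 0.025
        psi = lambda l: (g / v) * np.exp(-l * lam / v)
        num, _ = quad(lambda l: l * psi(l), 0, np.inf)
        den, _ = quad(psi, 0, np.inf)
        stats = mt_steady_state_stats(default_params)
        assert stats["mean_length"] == pytest.approx(num / den, rel=1e-8)
        assert stats["mean_length"] == pytest.approx(20.0)

    def test_count_inversely_proportional_to_catastrophe(self):
        doubled = MotorMTParams(catastrophe_rate=0.05)
        assert mt_steady_state_stats(doubled)["mt_count"] == pytest.approx(5_000)

    @pytest.mark.parametrize("field", [
        "nucleation_rate", "growth_speed", "catastrophe_rate",
        "detachment_rate", "capture_radius", "pull_force"])
    def test_nonpositive_parameters_rejected(self, field):
        with pytest.raises(ValueError):
            MotorMTParams(**{field: 0.0})


class TestConeFraction:
    def test_hemisphere_limit_near_contact(self):
        assert cone_fraction(1e-9, 1.0, 1.5) == pytest.approx(0.5, abs=1e-6)

    def test_edge_on_disk_captures_nothing(self):
        assert cone_fraction(10.0, 0.0, 1.5) == 0.0

    def test_reference_value_and_monte_carlo_solid_angle(self, rng):
        chi = cone_fraction(10.0, 1.0, 1.5)
        assert chi == pytest.approx(5.532e-3, rel=1e-3)
        # oracle: fraction of isotropic directions within the cone
        n = 2_000_000
        cos_t = rng.uniform(-1, 1, n)
        cos_cone = 10.0 / np.hypot(10.0, 1.5)
        frac = np.mean(cos_t > cos_cone)
        se = np.sqrt(frac * (1 - frac) / n)
        assert abs(chi - frac) < 3 * se

    def test_monotone_decreasing_in_distance(self):
        d = np.linspace(0.5, 40, 200)
        chi = cone_fraction(d, 1.0, 1.5)
        assert np.all(np.diff(chi) < 0)

    def test_negative_incidence_clamped_to_zero(self):
        assert cone_fraction(5.0, -0.3, 1.5) == 0.0

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            cone_fraction(0.0, 1.0, 1.5)


class TestImpingementRate:
    def test_reference_values_exact_and_approx(self, default_params):
        exact = impingement_rate(10.0, 1.0, default_params, form="exact")
        approx = impingement_rate(10.0, 1.0, default_params, form="approx")
        assert exact == pytest.approx(0.8388, rel=1e-3)
        assert approx == pytest.approx(0.8529, rel=1e-3)
        assert abs(approx - exact) / exact < 0.02  # r/d = 0.15

    def test_matches_discrete_event_oracle(self, default_params, rng):
        rate, se = discrete_event_impingement_rate(
            10.0, default_params, t_end=40_000.0, rng=rng)
        exact = impingement_rate(10.0, 1.0, default_params)
        assert abs(exact - rate) < 3 * se

    def test_vanishes_at_large_distance(self, default_params):
        assert impingement_rate(1e4, 1.0, default_params) < 1e-30

    def test_bounded_by_half_nucleation_rate(self, default_params):
        d = np.geomspace(1e-3, 50, 100)
        om = impingement_rate(d, 1.0, default_params)
        assert np.all(om <= default_params.nucleation_rate / 2 + 1e-12)

    def test_approx_converges_to_exact_for_small_disk(self, default_params):
        for d in [15.0, 30.0, 60.0]:
            if default_params.capture_radius / d <= 0.1:
                ex = impingement_rate(d, 1.0, default_params, form="exact")
                ap = impingement_rate(d, 1.0, default_params, form="approx")
                assert abs(ap - ex) / ex < 0.01

    def test_coincident_points_rejected(self, default_params):
        with pytest.raises(ValueError):
            impingement_rate(0.0, 1.0, default_params)


class TestAttachmentProbabilities:
    def test_equal_on_off_rates_give_half(self):
        assert attachment_probabilities(np.array([0.1]), 0.1)[0] == pytest.approx(0.5)

    def test_single_centrosome_reference_value(self):
        p = attachment_probabilities(np.array([0.8388]), 0.1)[0]
        assert p == pytest.approx(0.8935, rel=1e-3)

    def test_two_equidistant_centrosomes_split_and_reduce(self):
        p = attachment_probabilities(np.array([0.8388, 0.8388]), 0.1)
        assert p[0] == pytest.approx(p[1])
        assert p[0] == pytest.approx(0.4719, rel=1e-3)
        single = attachment_probabilities(np.array([0.8388]), 0.1)[0]
        assert p[0] < single

    def test_matches_gillespie_site_occupancy(self, rng):
        # single- and two-centrosome occupancies vs CTMC simulation
        for omegas in ([0.8388], [0.8388, 0.8388], [0.3, 0.05]):
            mean, se = gillespie_occupancy_se(omegas, 0.1, t_end=30_000.0, rng=rng)
            p = attachment_probabilities(np.array(omegas), 0.1)
            assert np.all(np.abs(p - mean) < 3 * se + 1e-4)

    def test_quasi_steady_is_fixed_point_of_explicit_dynamics(self):
        om = np.array([0.4, 0.7])
        p = attachment_probabilities(om, 0.1)
        rhs = attachment_probability_ode_rhs(p, om, 0.1)
        assert np.allclose(rhs, 0.0, atol=1e-12)

    @given(st.lists(st.floats(0, 50), min_size=1, max_size=5),
           st.floats(1e-4, 10))
    @settings(max_examples=100, deadline=None)
    def test_probabilities_normalized_and_competition_monotone(self, omegas, kappa):
        om = np.array(omegas)
        p = attachment_probabilities(om, kappa)
        assert np.all((p >= 0) & (p < 1))
        assert p.sum() < 1 + 1e-12
        # unoccupied probability completes the distribution
        p_unbound = kappa / (om.sum() + kappa)
        assert p.sum() + p_unbound == pytest.approx(1.0)
        # adding a competitor never increases an existing probability
        p_plus = attachment_probabilities(np.append(om, 1.0), kappa)
        assert np.all(p_plus[:-1] <= p + 1e-12)

    def test_nonpositive_kappa_rejected(self):
        with pytest.raises(ValueError):
            attachment_probabilities(np.array([1.0]), 0.0)


class TestForces:
    def test_zero_probability_zero_force(self, default_params):
        f = cfg_force(0.0, np.array([1.0, 0, 0]), default_params)
        assert np.allclose(f, 0)

    def test_stoichiometric_force_bounded_by_f0(self, default_params):
        f = cfg_force(0.8935, np.array([1.0, 0, 0]), default_params)
        assert np.linalg.norm(f) == pytest.approx(8.935)
        assert np.linalg.norm(f) <= default_params.pull_force

    def test_nonstoichiometric_force_is_mean_occupancy_times_f0(self, default_params):
        f = cfg_force(None, np.array([0, 0, 1.0]), default_params,
                      mode="nonstoichiometric", omega=0.8388)
        assert np.linalg.norm(f) == pytest.approx(83.88)
        assert np.linalg.norm(f) > default_params.pull_force

    def test_near_contact_stoichiometric_slower_than_nonstoichiometric(
            self, default_params):
        # destabilizing feedback: non-stoichiometric force diverges as
        # d -> 0 while the stoichiometric force saturates below f0
        d = np.geomspace(0.05, 5, 30)
        om = impingement_rate(d, 1.0, default_params)
        p = om / (om + default_params.detachment_rate)
        f_st = default_params.pull_force * p
        f_ns = default_params.pull_force * om / default_params.detachment_rate
        assert np.all(f_st <= default_params.pull_force)
        assert f_ns[0] / f_st[0] > 100
        growth_st = f_st[0] / f_st[-1]
        growth_ns = f_ns[0] / f_ns[-1]
        assert growth_ns > 10 * growth_st


def _plane_cfgs():
    cfgs = []
    i = 0
    for z in (+15.0, -15.0):
        for gx in (-15.0, 15.0):
            for gy in (-15.0, 15.0):
                cfgs.append(ForceGenerator(
                    id=i, position=np.array([gx, gy, z]),
                    outward_normal=np.array([0.0, 0.0, np.sign(z)]),
                    side="posterior"))
                i += 1
    return cfgs


class TestNetForces:
    def test_mirror_symmetry_cancels_transverse_components(self, default_params):
        cfgs = _plane_cfgs()
        c = [CentrosomeState(np.array([0.0, 0.0, 3.0]))]
        F, _ = net_forces(c, cfgs, default_params)
        assert abs(F[0, 0]) < 1e-9 and abs(F[0, 1]) < 1e-9

    def test_two_plane_restoring_force(self, default_params):
        cfgs = _plane_cfgs()
        c = [CentrosomeState(np.array([0.0, 0.0, -4.0]))]
        F, _ = net_forces(c, cfgs, default_params)
        assert F[0, 2] > 0  # displaced down, pushed back up

    def test_total_equals_sum_of_per_cfg_forces(self, default_params):
        cfgs = _plane_cfgs()
        c = [CentrosomeState(np.array([1.0, -2.0, 3.0])),
             CentrosomeState(np.array([-1.0, 2.0, -3.0]))]
        F, sol = net_forces(c, cfgs, default_params)
        rebuilt = (default_params.pull_force
                   * sol.probability[..., None] * sol.direction).sum(axis=1)
        assert np.allclose(F, rebuilt, atol=1e-12)

    def test_inactive_centrosome_excluded_from_competition(self, default_params):
        cfgs = _plane_cfgs()
        both = [CentrosomeState(np.array([0.0, 0.0, 5.0])),
                CentrosomeState(np.array([0.0, 0.0, -5.0]))]
        _, sol_both = net_forces(both, cfgs, default_params)
        both[1].active = False
        _, sol_one = net_forces(both, cfgs, default_params)
        assert np.all(sol_one.probability[1] == 0)
        assert np.all(sol_one.probability[0] >= sol_both.probability[0] - 1e-12)
        assert np.any(sol_one.probability[0] > sol_both.probability[0] + 1e-6)

    def test_empty_cfg_set_rejected(self, default_params):
        with pytest.raises(ValueError):
            net_forces([CentrosomeState(np.zeros(3) + 1.0)], [], default_params)


def test_kappa_rescaling_preserves_attachment_probability():
    k = kappa_for_radius(0.1, 1.5, 0.1)
    assert k == pytest.approx(4.4e-4, rel=0.02)
    # direct check: with Omega ~ r^2, P(r, kappa) equals P(r', kappa')
    om_old, om_new = 1.5**2, 0.1**2
    p1 = om_old / (om_old + 0.1)
    p2 = om_new / (om_new + k)
    assert p1 == pytest.approx(p2, rel=1e-12)
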