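"""Reaction-network topology, mass-action derivatives and stiff integration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import expm

from mblkin import (
    RateConstantSet,
    Reaction,
    ReactionScheme,
    Species,
    build_nitrocefin_scheme,
    integrate,
    mass_action_rates,
    rate_limiting_step,
)
from mblkin.errors import ConfigurationError
from mblkin.schemes import path_flux_fractions, scheme_from_yaml, scheme_to_yaml


class TestTopology:
    def test_linear_scheme_structure(self, linear_scheme):
        assert linear_scheme.id == "linear"
        assert set(linear_scheme.species_names) == {"E", "S", "ES", "EI", "P"}
        assert linear_scheme.rate_labels == ("k1", "k-1", "k2", "k3")

    def test_branched_scheme_adds_direct_channel(self, branched_scheme):
        assert branched_scheme.rate_labels == ("k1", "k-1", "k2", "k3", "k4")
        direct = branched_scheme.reactions[2]
        assert direct.reactants == ("ES",) and direct.products == ("E", "P")

    def test_build_is_deterministic(self):
        assert build_nitrocefin_scheme("linear") == build_nitrocefin_scheme("linear")

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            build_nitrocefin_scheme("cyclic")

    def test_duplicate_species_rejected(self):
        sp = (
            Species("E", "enzyme"),
            Species("E", "substrate"),
            Species("P", "product"),
        )
        with pytest.raises(ConfigurationError, match="unique"):
            ReactionScheme("custom", sp, (), ("E",), ("E", "P"))

    def test_nonconserving_reaction_rejected(self):
        sp = (
            Species("E", "enzyme"),
            Species("S", "substrate"),
            Species("P", "product"),
        )
        rxn = (Reaction(("S",), ("P", "P"), "k1"),)
        with pytest.raises(ConfigurationError, match="conserve"):
            ReactionScheme("custom", sp, rxn, ("E",), ("S", "P"))

    def test_negative_rate_rejected(self):
        with pytest.raises(ConfigurationError, match="negative"):
            RateConstantSet({"k1": -1.0})

    def test_yaml_round_trip(self, branched_scheme, branched_rates):
        text = scheme_to_yaml(branched_scheme, branched_rates)
        scheme2, rates2 = scheme_from_yaml(text)
        assert scheme2 == branched_scheme
        assert rates2.values == branched_rates.values


class TestMassActionRates:
    def test_zero_rates_give_zero_derivatives(self, branched_scheme):
        k = RateConstantSet({lab: 0.0 for lab in branched_scheme.rate_labels})
        dx = mass_action_rates(branched_scheme, k, {"E": 3.0, "S": 2.0, "ES": 1.0, "EI": 1.0, "P": 0.0})
        assert np.all(dx == 0.0)

    def test_single_bimolecular_term(self, linear_scheme):
        k = RateConstantSet({"k1": 1.0, "k-1": 0.0, "k2": 0.0, "k3": 0.0})
        dx = mass_action_rates(linear_scheme, k, {"E": 1.0, "S": 1.0})
        by_name = dict(zip(linear_scheme.species_names, dx))
        assert by_name["E"] == by_name["S"] == -1.0
        assert by_name["ES"] == 1.0

    def test_missing_rate_label_is_configuration_error(self, branched_scheme):
        with pytest.raises(ConfigurationError, match="missing"):
            mass_action_rates(branched_scheme, RateConstantSet({"k1": 1.0}), {"E": 1.0, "S": 1.0})

    def test_derivatives_match_short_step_integration(self, branched_scheme, branched_rates, rng):
        state = dict(zip(branched_scheme.species_names, rng.uniform(0.1, 5.0, 5)))
        dx = mass_action_rates(branched_scheme, branched_rates, state)
        h = 1e-7
        traj = integrate(branched_scheme, branched_rates, state, [0.0, h], rtol=1e-12, atol=1e-14)
        fd = (traj.concentrations[1] - traj.concentrations[0]) / h
        np.testing.assert_allclose(fd, dx, rtol=1e-4, atol=1e-8)

    def test_conservation_groups_have_zero_net_rate(self, branched_scheme, branched_rates, rng):
        state = dict(zip(branched_scheme.species_names, rng.uniform(0.0, 10.0, 5)))
        dx = dict(zip(branched_scheme.species_names, mass_action_rates(branched_scheme, branched_rates, state)))
        assert abs(sum(dx[n] for n in branched_scheme.enzyme_group)) < 1e-12
        assert abs(sum(dx[n] for n in branched_scheme.substrate_group)) < 1e-12


class TestIntegrate:
    def test_zero_rates_constant_trajectory(self, linear_scheme):
        k = RateConstantSet({lab: 0.0 for lab in linear_scheme.rate_labels})
        traj = integrate(linear_scheme, k, {"E": 2.0, "S": 3.0}, np.linspace(0, 10, 20))
        assert np.allclose(traj.concentrations, traj.concentrations[0])

    def test_initial_condition_reproduced_at_t0(self, branched_scheme, branched_rates):
        traj = integrate(branched_scheme, branched_rates, {"E": 50.0, "S": 50.0}, np.linspace(0, 5, 50))
        assert traj["E"][0] == 50.0 and traj["S"][0] == 50.0 and traj["P"][0] == 0.0

    def test_pseudo_first_order_closed_form(self, linear_scheme):
        # E0 >> S0 and only binding active: S(t) = S0 exp(-k1 E0 t).
        # Enzyme depletion perturbs the exponent by at most k1*S0*t, so a
        # deep excess is needed for the closed form to hold to 1e-6.
        k = RateConstantSet({"k1": 0.02, "k-1": 0.0, "k2": 0.0, "k3": 0.0})
        e0, s0 = 500.0, 1e-5
        times = np.linspace(0, 0.5, 40)
        traj = integrate(linear_scheme, k, {"E": e0, "S": s0}, times, rtol=1e-11, atol=1e-16)
        expected = s0 * np.exp(-k["k1"] * e0 * times)
        np.testing.assert_allclose(traj["S"], expected, rtol=1e-6)

    def test_matrix_exponential_oracle_pseudo_first_order(self, linear_scheme):
        """In the E0 >> S0 limit the network is linear; expm is an exact oracle."""
        k = RateConstantSet({"k1": 1e-6, "k-1": 2.0, "k2": 5.0, "k3": 1.3})
        e0, s0 = 1e7, 1.0
        times = np.linspace(0, 3, 30)
        traj = integrate(linear_scheme, k, {"E": e0, "S": s0}, times, rtol=1e-11, atol=1e-13)
        # linearised system over x = (S, ES, EI, P) with E frozen at E0
        a = np.array(
            [
                [-k["k1"] * e0, k["k-1"], 0.0, 0.0],
                [k["k1"] * e0, -(k["k-1"] + k["k2"]), 0.0, 0.0],
                [0.0, k["k2"], -k["k3"], 0.0],
                [0.0, 0.0, k["k3"], 0.0],
            ]
        )
        x0 = np.array([s0, 0.0, 0.0, 0.0])
        for i, t in enumerate(times):
            ref = expm(a * t) @ x0
            got = np.array([traj["S"][i], traj["ES"][i], traj["EI"][i], traj["P"][i]])
            np.testing.assert_allclose(got, ref, rtol=1e-6, atol=s0 * 1e-8)

    def test_branched_with_zero_direct_channel_matches_linear(self, linear_scheme, branched_scheme):
        times = np.linspace(0, 20, 100)
        k_lin = RateConstantSet({"k1": 1.0, "k-1": 10.0, "k2": 5.0, "k3": 1.4})
        k_br = RateConstantSet({"k1": 1.0, "k-1": 10.0, "k2": 0.0, "k3": 5.0, "k4": 1.4})
        t_lin = integrate(linear_scheme, k_lin, {"E": 50.0, "S": 50.0}, times)
        t_br = integrate(branched_scheme, k_br, {"E": 50.0, "S": 50.0}, times)
        for name in ("E", "S", "ES", "EI", "P"):
            np.testing.assert_allclose(t_br[name], t_lin[name], rtol=1e-6, atol=1e-7)

    def test_times_must_start_at_zero_and_increase(self, linear_scheme, branched_rates):
        k = RateConstantSet({"k1": 1.0, "k-1": 1.0, "k2": 1.0, "k3": 1.0})
        with pytest.raises(ValueError):
            integrate(linear_scheme, k, {"E": 1.0, "S": 1.0}, [1.0, 2.0])
        with pytest.raises(ValueError):
            integrate(linear_scheme, k, {"E": 1.0, "S": 1.0}, [0.0, 2.0, 1.0])

    def test_long_format_export(self, linear_scheme):
        k = RateConstantSet({"k1": 1.0, "k-1": 1.0, "k2": 1.0, "k3": 1.0})
        traj = integrate(linear_scheme, k, {"E": 1.0, "S": 1.0}, np.linspace(0, 1, 5))
        df = traj.to_frame()
        assert list(df.columns) == ["time_s", "species", "concentration_uM"]
        assert len(df) == 5 * 5

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(
        logk=st.lists(st.floats(-2.0, 2.0), min_size=5, max_size=5),
        e0=st.floats(1.0, 100.0),
        s0=st.floats(1.0, 100.0),
    )
    def test_conservation_and_nonnegativity(self, logk, e0, s0):
        """Enzyme and substrate-group totals stay constant; no real negatives."""
        scheme = build_nitrocefin_scheme("branched")
        k = RateConstantSet(dict(zip(scheme.rate_labels, 10.0 ** np.array(logk))))
        traj = integrate(scheme, k, {"E": e0, "S": s0}, np.linspace(0, 50, 60))
        tot_e = sum(traj[n] for n in scheme.enzyme_group)
        tot_s = sum(traj[n] for n in scheme.substrate_group)
        np.testing.assert_allclose(tot_e, e0, rtol=1e-8)
        np.testing.assert_allclose(tot_s, s0, rtol=1e-8)
        assert traj.concentrations.min() >= -1e-9


class TestRateLimitingStep:
    def test_linear_intermediate_decay_slowest(self, linear_scheme):
        k = RateConstantSet({"k1": 1.0, "k-1": 10.0, "k2": 50.0, "k3": 1.3})
        assert rate_limiting_step(linear_scheme, k) == "k3"

    def test_branched_intermediate_decay_slowest(self, branched_scheme, branched_rates):
        assert rate_limiting_step(branched_scheme, branched_rates) == "k4"

    def test_tie_resolves_to_first_reaction(self, linear_scheme):
        k = RateConstantSet({"k1": 1.0, "k-1": 10.0, "k2": 2.0, "k3": 2.0})
        assert rate_limiting_step(linear_scheme, k) == "k2"

    def test_negligible_flux_branch_ignored(self, branched_scheme):
        # direct channel slower than intermediate decay but carrying ~0.2% of flux
        k = RateConstantSet({"k1": 1.0, "k-1": 10.0, "k2": 0.01, "k3": 5.0, "k4": 1.4})
        assert rate_limiting_step(branched_scheme, k) == "k4"

    def test_flux_fractions_split_at_branch_point(self, branched_scheme, branched_rates):
        frac = path_flux_fractions(branched_scheme, branched_rates)
        assert frac["k2"] == pytest.approx(12.0 / 16.0)
        assert frac["k3"] == frac["k4"] == pytest.approx(4.0 / 16.0)
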