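"""Network structure, flux/control laws and rate-balance arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cyberlipid as cl
from cyberlipid.network import (
    KineticParameters,
    UNMEASURED_INTERMEDIATES,
    assemble_rhs,
)
from cyberlipid.simulation import make_fast_rhs


def _named_params(network, **overrides):
    """A valid parameter set with every registry entry at a default."""
    base = {}
    for name in network.param_names:
        if name.startswith("X0_"):
            base[name] = 0.3
        elif name.startswith("Km"):
            base[name] = 5.0
        else:
            base[name] = 0.1
    base.update(overrides)
    return KineticParameters(base)


class TestStructure:
    def test_epa_variant_has_13_states(self, epa_network):
        assert epa_network.n_states == 13
        assert len(epa_network.metabolites) == 9
        assert len(epa_network.enzymes) == 4

    def test_dha_variant_topology(self, dha_network):
        controlled = {
            (r.substrate, r.product) for r in dha_network.controlled
        }
        assert controlled == {("AA", "PGH2"), ("DHA", "PD")}
        # PD is a terminal sink: nothing consumes it
        assert not any(r.substrate == "PD" for r in dha_network.reactions)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="XYZ"):
            cl.build_default_network("XYZ")

    def test_parameter_count_matches_registry_enumeration(self, epa_network):
        # independent enumeration: rate constants + degradations + ATP pair
        # + synthesis constants + initial enzyme levels
        n = (
            len(epa_network.reactions)
            + len(epa_network.degradation)
            + 2
            + sum(2 + 2 * len(s.terms) for s in epa_network.synthesis)
            + len(epa_network.enzymes)
        )
        assert cl.count_parameters(epa_network) == n == 41

    def test_removing_a_degradation_parameter_drops_count_by_one(self):
        net = cl.build_default_network("EPA")
        net.degradation.pop("PGJ2")
        from cyberlipid.network import _register_params

        net.param_names = _register_params(net)
        assert cl.count_parameters(net) == 40

    def test_controlled_reactions_are_the_cox_conversions(self, epa_network):
        assert all(r.enzyme == "eCOX" for r in epa_network.controlled)
        assert all(r.atp_modulated for r in epa_network.controlled)
        assert len(epa_network.controlled) == 2


class TestFluxes:
    def test_flux_is_mass_action_in_enzyme_and_substrate(self, epa_network):
        p = _named_params(epa_network, kPGH2=0.1)
        rho = cl.compute_fluxes(
            epa_network, {"eCOX": 2.0}, p, {"AA": 5.0, "EPA": 0.0}
        )
        assert rho[0] == pytest.approx(1.0)  # 0.1 * 2 * 5
        assert rho[1] == 0.0

    def test_zero_substrate_or_enzyme_zeroes_flux(self, epa_network):
        p = _named_params(epa_network)
        rho = cl.compute_fluxes(
            epa_network, {"eCOX": 0.0}, p, {"AA": 7.0, "EPA": 3.0}
        )
        assert np.all(rho == 0.0)

    def test_negative_concentration_rejected(self, epa_network):
        p = _named_params(epa_network)
        with pytest.raises(ValueError, match="negative"):
            cl.compute_fluxes(
                epa_network, {"eCOX": 1.0}, p, {"AA": -1.0, "EPA": 0.0}
            )


class TestControlLaws:
    @pytest.mark.parametrize(
        "rho, u, v",
        [
            ((3.0, 3.0), (0.5, 0.5), (1.0, 1.0)),
            ((5.0, 0.0), (1.0, 0.0), (1.0, 0.0)),
            ((2.0, 6.0), (0.25, 0.75), (1.0 / 3.0, 1.0)),
            ((0.0, 0.0), (0.5, 0.5), (1.0, 1.0)),  # degenerate convention
        ],
    )
    def test_matching_and_proportion_laws(self, rho, u, v):
        ctrl = cl.cybernetic_controls(np.array(rho))
        assert ctrl.u == pytest.approx(u)
        assert ctrl.v == pytest.approx(v)

    @settings(max_examples=200, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1e6, allow_nan=False),
            min_size=2,
            max_size=6,
        ).filter(lambda xs: sum(xs) > 0)
    )
    def test_control_invariants_on_random_fluxes(self, rho):
        ctrl = cl.cybernetic_controls(np.array(rho))
        assert ctrl.u.sum() == pytest.approx(1.0)
        assert ctrl.v.max() == pytest.approx(1.0)
        assert np.all((0.0 <= ctrl.u) & (ctrl.u <= 1.0))
        assert np.all((0.0 <= ctrl.v) & (ctrl.v <= 1.0))


class TestMetaboliteBalance:
    def test_zero_state_zero_inputs_gives_zero_derivatives(self, epa_network):
        p = _named_params(epa_network)
        state = {s: 0.0 for s in epa_network.state_names}
        subs = {"AA": 0.0, "EPA": 0.0, "ATP": 0.0}
        ctrl = cl.cybernetic_controls(np.zeros(2))
        d = cl.metabolite_rhs(epa_network, state, p, subs, ctrl)
        assert all(v == 0.0 for v in d.values())

    def test_production_only_limit(self, epa_network):
        # degradations and downstream constants zeroed: the PGH2 balance
        # reduces exactly to its production term v*k*[AA]*[eCOX]
        p = _named_params(
            epa_network, gPGH2=0.0, kPGD2=0.0, kPGE2=0.0, kATP=0.0, kPGH2=0.7
        )
        state = {s: 0.0 for s in epa_network.state_names}
        state.update({"eCOX": 1.5, "PGH2": 3.0})
        subs = {"AA": 2.0, "EPA": 0.0, "ATP": 0.0}
        ctrl = cl.ControlVariables(u=np.array([1.0, 0.0]), v=np.array([1.0, 0.0]))
        d = cl.metabolite_rhs(epa_network, state, p, subs, ctrl)
        assert d["PGH2"] == pytest.approx(0.7 * 2.0 * 1.5)

    def test_pgh2_balance_worked_example(self, epa_network):
        # v=0.5, k=1, AA=2, eCOX=1, kATP=1, ATP=1, g=0.1, PGH2=10,
        # downstream constants 0  ->  0.5*1*2*1*2 - 1 = 1
        p = _named_params(
            epa_network, kPGH2=1.0, kATP=1.0, gPGH2=0.1, kPGD2=0.0, kPGE2=0.0
        )
        state = {s: 0.0 for s in epa_network.state_names}
        state.update({"eCOX": 1.0, "PGH2": 10.0})
        subs = {"AA": 2.0, "EPA": 0.0, "ATP": 1.0}
        ctrl = cl.ControlVariables(u=np.array([1.0, 0.0]), v=np.array([0.5, 0.0]))
        d = cl.metabolite_rhs(epa_network, state, p, subs, ctrl)
        assert d["PGH2"] == pytest.approx(1.0)

    def test_downstream_outflux_matches_conversion_terms(self, epa_network):
        # total flux out of PGH2 into PGD2/PGE2 equals the two conversion
        # terms of the PGH2 balance (mass-flux consistency)
        p = _named_params(epa_network, gPGH2=0.0, kPGH2=0.0, kPGH3=0.0)
        state = {s: 0.0 for s in epa_network.state_names}
        state.update({"PGH2": 4.0, "ePtgds": 0.5, "ePtges": 0.25})
        subs = {"AA": 0.0, "EPA": 0.0, "ATP": 0.0}
        ctrl = cl.cybernetic_controls(np.zeros(2))
        d = cl.metabolite_rhs(epa_network, state, p, subs, ctrl)
        expected_out = p["kPGD2"] * 4.0 * 0.5 + p["kPGE2"] * 4.0 * 0.25
        assert -d["PGH2"] == pytest.approx(expected_out)
        assert d["PGD2"] + d["PGE2"] == pytest.approx(expected_out)

    def test_missing_parameter_is_named(self, epa_network):
        p = _named_params(epa_network)
        bad = KineticParameters(
            {k: v for k, v in p.as_dict().items() if k != "gPGJ2"}
        )
        state = {s: 1.0 for s in epa_network.state_names}
        subs = {"AA": 1.0, "EPA": 1.0, "ATP": 0.0}
        ctrl = cl.cybernetic_controls(np.array([1.0, 1.0]))
        with pytest.raises(KeyError, match="gPGJ2"):
            cl.metabolite_rhs(epa_network, state, bad, subs, ctrl)


class TestEnzymeBalance:
    def test_constitutive_only_limit(self, epa_network):
        p = _named_params(epa_network)
        overrides = {}
        for s in epa_network.synthesis:
            overrides[s.alpha] = 0.2
            for t in s.terms:
                overrides[t.k_e] = 0.0
        p = p.replace(**overrides)
        state = {s: 0.0 for s in epa_network.state_names}
        subs = {"AA": 0.0, "EPA": 0.0, "ATP": 0.0}
        ctrl = cl.cybernetic_controls(np.zeros(2))
        d = cl.enzyme_rhs(epa_network, state, p, subs, ctrl)
        assert all(v == pytest.approx(0.2) for v in d.values())

    def test_michaelis_menten_saturation(self, epa_network):
        p = _named_params(epa_network, alpha_eCOX=0.0, beta_eCOX=0.0,
                          kePGH2=2.0, kePGH3=0.0, KmAA=1.0)
        state = {s: 0.0 for s in epa_network.state_names}
        subs = {"AA": 1e9, "EPA": 0.0, "ATP": 0.0}
        ctrl = cl.ControlVariables(u=np.array([1.0, 0.0]), v=np.array([1.0, 0.0]))
        d = cl.enzyme_rhs(epa_network, state, p, subs, ctrl)
        assert d["eCOX"] == pytest.approx(2.0, rel=1e-6)

    def test_ecox_balance_worked_example(self, epa_network):
        # alpha=0, u=0.5, ke=2, Km=1, AA=1, beta=0.1, eCOX=10
        # -> 0.5*2*0.5 - 1 = -0.5
        p = _named_params(
            epa_network,
            alpha_eCOX=0.0, kePGH2=2.0, KmAA=1.0, kePGH3=0.0, beta_eCOX=0.1,
        )
        state = {s: 0.0 for s in epa_network.state_names}
        state["eCOX"] = 10.0
        subs = {"AA": 1.0, "EPA": 0.0, "ATP": 0.0}
        ctrl = cl.ControlVariables(u=np.array([0.5, 0.0]), v=np.array([1.0, 0.0]))
        d = cl.enzyme_rhs(epa_network, state, p, subs, ctrl)
        assert d["eCOX"] == pytest.approx(-0.5)

    def test_zero_km_with_zero_driver_rejected(self, epa_network):
        p = _named_params(epa_network, KmAA=0.0)
        state = {s: 0.0 for s in epa_network.state_names}
        subs = {"AA": 0.0, "EPA": 0.0, "ATP": 0.0}
        ctrl = cl.cybernetic_controls(np.zeros(2))
        with pytest.raises(ValueError, match="KmAA"):
            cl.enzyme_rhs(epa_network, state, p, subs, ctrl)


class TestAssembledRHS:
    def test_zero_state_yields_alpha_in_enzyme_slots(self, epa_network):
        p = _named_params(epa_network)
        subs = lambda t: {"AA": 0.0, "EPA": 0.0}
        d = assemble_rhs(0.0, np.zeros(13), p, epa_network, subs, atp0=0.0)
        assert d.shape == (13,)
        n_met = len(epa_network.metabolites)
        assert np.all(d[:n_met] == 0.0)
        for i, spec in enumerate(epa_network.synthesis):
            assert d[n_met + i] == pytest.approx(p[spec.alpha])

    def test_non_finite_state_rejected(self, epa_network):
        p = _named_params(epa_network)
        y = np.zeros(13)
        y[3] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            assemble_rhs(0.0, y, p, epa_network, lambda t: {"AA": 0, "EPA": 0}, 1.0)

    @pytest.mark.parametrize("variant", ["EPA", "DHA"])
    def test_fast_rhs_matches_reference(self, variant, spec, truth):
        net = cl.build_default_network(variant)
        params = (
            truth
            if variant == "EPA"
            else cl.gen_true_params(cl.SyntheticSpec(seed=3), net)
        )
        prof = cl.gen_substrate_profiles(
            "EPA" if variant == "EPA" else "DHA", spec if variant == "EPA" else cl.SyntheticSpec(seed=3)
        )
        fast = make_fast_rhs(net, params, prof)
        sub_fn = prof.interpolator()
        rng = np.random.default_rng(42)
        for _ in range(20):
            y = rng.uniform(0.0, 5.0, net.n_states)
            t = rng.uniform(0.0, 60.0)
            np.testing.assert_allclose(
                fast(t, y),
                assemble_rhs(t, y, params, net, sub_fn, prof.atp0),
                rtol=1e-12,
                atol=1e-14,
            )

    def test_rhs_matches_finite_difference_of_fine_simulation(
        self, epa_network, truth, profiles
    ):
        # derivative at t must match (x(t+h)-x(t))/h of a tightly solved
        # trajectory to O(h)
        prof = profiles["EPA"]
        h = 1e-3
        t0 = 12.0
        traj = cl.simulate(
            epa_network, truth, prof,
            t_eval=np.array([0.0, t0, t0 + h]), rtol=1e-10, atol=1e-12,
        )
        fd = (traj.states[2] - traj.states[1]) / h
        rhs = make_fast_rhs(epa_network, truth, prof)
        np.testing.assert_allclose(rhs(t0, traj.states[1]), fd, rtol=1e-2, atol=1e-8)


class TestSwitchRelations:
    def test_simplified_v_worked_example(self):
        assert cl.simplified_v(4.0, 1.0, 1.0, 2.0) == pytest.approx((1.0, 0.5))

    def test_simplified_v_is_ecox_independent(self, epa_network):
        rng = np.random.default_rng(5)
        p = _named_params(epa_network, kPGH2=0.3, kPGH3=0.9)
        for _ in range(50):
            aa, epa = rng.uniform(0.0, 50.0, 2)
            expected = cl.simplified_v(aa, epa, 0.3, 0.9)
            for ecox in (1e-6, 1.0, 10.0):
                rho = cl.compute_fluxes(
                    epa_network, {"eCOX": ecox}, p, {"AA": aa, "EPA": epa}
                )
                ctrl = cl.cybernetic_controls(rho)
                np.testing.assert_allclose(ctrl.v, expected, rtol=1e-12)

    def test_switch_point_gives_unit_pair(self):
        k2, k3 = 0.2, 0.5
        ratio = cl.switch_ratio(k2, k3)
        assert ratio == pytest.approx(2.5)
        epa = 4.0
        assert cl.simplified_v(ratio * epa, epa, k2, k3) == pytest.approx((1.0, 1.0))

    def test_equal_constants_give_unit_ratio(self):
        assert cl.switch_ratio(0.7, 0.7) == pytest.approx(1.0)

    def test_zero_kpgh2_rejected(self):
        with pytest.raises(ValueError):
            cl.switch_ratio(0.0, 1.0)

    def test_both_zero_products_degenerate(self):
        assert cl.simplified_v(0.0, 0.0, 1.0, 1.0) == (1.0, 1.0)


def test_simulated_trajectories_stay_nonnegative(true_trajectories):
    for traj in true_trajectories.values():
        assert traj.states.min() >= -1e-8


def test_dha_variant_is_epa_structure_with_pd_sink(epa_network, dha_network):
    # shared AA branch identical; 3-series branch replaced by the PD sink
    aa_branch = {
        (r.substrate, r.product)
        for r in epa_network.reactions
        if "3" not in r.product
    }
    dha_branch = {(r.substrate, r.product) for r in dha_network.reactions}
    assert aa_branch - {("AA", "PGH2")} == dha_branch - {("AA", "PGH2"), ("DHA", "PD")}
    assert set(dha_network.metabolites) == (
        set(epa_network.metabolites) - {"PGH3", "PGD3", "PGE3"}
    ) | {"PD"}
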