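"""Engine tests: Hill transfer functions, gates, ODE assembly, parser."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smcnet.network import (HillParams, NetworkModel, NetworkSyntaxError,
                            Reaction, SpeciesNode, Term, hill_constants,
                            node_drive, or_fold, parse_network,
                            reaction_activation, rhs, serialize_network,
                            simulate, steady_state, transfer_act,
                            transfer_inhib)
from smcnet.synthetic import RandomNetworkSpec, gen_random_network


class TestHillConstants:
    def test_model_default_parameterization(self):
        # closed forms evaluated independently: e = 0.52**1.4,
        # beta = (e-1)/(2e-1), k = (beta-1)**(1/1.4)
        beta, k = hill_constants(1.4, 0.52)
        e = 0.52 ** 1.4
        assert beta == pytest.approx((e - 1) / (2 * e - 1), abs=1e-12)
        assert k == pytest.approx((beta - 1) ** (1 / 1.4), abs=1e-12)
        assert beta == pytest.approx(3.00797, abs=1e-4)
        assert k == pytest.approx(1.64534, abs=1e-4)

    @given(n=st.floats(0.5, 4.0), ec50=st.floats(0.05, 0.8))
    @settings(max_examples=200, deadline=None)
    def test_normalization_constraints(self, n, ec50):
        # wherever the gain is defined, f_act(ec50)=1/2 and f_act(1)=1
        if ec50 ** n >= 0.5:
            with pytest.raises(ValueError):
                hill_constants(n, ec50)
            return
        hill = HillParams(n=n, ec50=ec50)
        assert transfer_act(ec50, hill) == pytest.approx(0.5, abs=1e-9)
        assert transfer_act(1.0, hill) == pytest.approx(1.0, abs=1e-9)
        assert transfer_act(0.0, hill) == 0.0
        assert hill.beta > 1.0 and hill.k > 0.0

    def test_domain_error_when_half_max_too_high(self):
        # 0.7**1.4 = 0.607 > 1/2: no normalizable transfer function
        with pytest.raises(ValueError, match="1/2"):
            hill_constants(1.4, 0.7)

    @pytest.mark.parametrize("bad", [(0.0, 0.3), (1.0, 0.0), (1.0, 1.0)])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            hill_constants(*bad)


class TestTransfer:
    @given(x=st.floats(0.0, 1.0))
    @settings(max_examples=100, deadline=None)
    def test_act_plus_inhib_is_one(self, x):
        hill = HillParams()
        assert (transfer_act(x, hill) + transfer_inhib(x, hill)
                == pytest.approx(1.0, abs=1e-12))

    def test_monotone_and_bounded(self):
        hill = HillParams()
        x = np.linspace(0, 1, 500)
        f = transfer_act(x, hill)
        assert np.all(np.diff(f) >= 0)
        assert f.min() >= 0 and f.max() <= 1 + 1e-12


class TestGates:
    HILL = HillParams()

    def test_and_gate_is_weighted_product(self):
        # two activating inputs held at their half-max levels
        r = Reaction(target="C", terms=(Term("A"), Term("B")), weight=1.0)
        state = {"A": self.HILL.ec50, "B": self.HILL.ec50}
        assert reaction_activation(r, state, self.HILL) == pytest.approx(0.25)

    def test_input_reaction_returns_weight(self):
        # the mechanical-stress input weight of the tuned model
        r = Reaction(target="Stress", terms=(), weight=0.24054)
        assert reaction_activation(r, {}, self.HILL) == 0.24054

    def test_inhibitor_at_full_activation_silences_gate(self):
        r = Reaction(target="C", terms=(Term("A"), Term("B", inhibiting=True)))
        assert reaction_activation(r, {"A": 1.0, "B": 1.0}, self.HILL) == \
            pytest.approx(0.0, abs=1e-12)

    def test_or_fold_identities(self):
        assert or_fold([0.5, 0.5]) == pytest.approx(0.75)
        assert or_fold([0.3, 1.0, 0.2]) == pytest.approx(1.0)
        assert or_fold([0.37]) == 0.37
        assert or_fold([]) == 0.0

    @given(vals=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=6))
    @settings(max_examples=200, deadline=None)
    def test_or_fold_is_permutation_invariant(self, vals):
        base = or_fold(vals)
        assert 0.0 <= base <= 1.0
        assert or_fold(list(reversed(vals))) == pytest.approx(base, abs=1e-12)

    def test_node_drive_rejects_mixed_targets(self):
        r1 = Reaction(target="C", terms=(Term("A"),))
        r2 = Reaction(target="D", terms=(Term("A"),))
        with pytest.raises(ValueError):
            node_drive([r1, r2], {"A": 0.5}, self.HILL)


class TestOde:
    def test_rhs_zero_at_steady_point(self, small_model):
        steady = steady_state(small_model)
        assert np.abs(rhs(small_model, steady)).max() < 1e-6

    def test_isolated_input_relaxes_to_weight(self):
        m = parse_network("species X role=input\n=> X w=0.5\n")
        res = simulate(m)
        assert res.steady[0] == pytest.approx(0.5, abs=1e-6)
        # derivative at zero state equals the drive itself
        assert rhs(m, np.array([0.0]))[0] == pytest.approx(0.5)

    def test_saturated_chain_reaches_one(self):
        m = parse_network("species X role=input\nspecies B\n=> X w=1\nX => B\n")
        assert steady_state(m)[1] == pytest.approx(1.0, abs=1e-6)

    def test_relaxation_sign(self, small_model):
        # activation above its drive decays
        high = np.array([1.0, 1.0, 1.0, 1.0])
        dy = rhs(small_model, high)
        # B's drive is 0.85*f(1) < 1 and C's gate is silenced by !B
        assert dy[2] < 0 and dy[3] < 0

    def test_tau_rescaling_preserves_steady_state(self, small_model):
        from dataclasses import replace
        doubled = replace(small_model, species=tuple(
            replace(s, tau=2.0 * s.tau) for s in small_model.species))
        a = steady_state(small_model)
        b = steady_state(doubled, t_end=80.0)
        assert np.allclose(a, b, atol=1e-5)

    def test_lyapunov_reintegration(self, small_model):
        steady = steady_state(small_model, tol=1e-8)
        again = simulate(small_model, y0=steady, t_end=10.0)
        assert np.abs(again.states - steady[:, None]).max() < 1e-7

    def test_peaks_dominate_steady(self, small_model):
        res = simulate(small_model)
        assert np.all(res.peaks >= res.steady - 1e-12)
        assert len(res.times) >= 400


class TestBoundednessFuzz:
    @pytest.mark.parametrize("seed", range(8))
    def test_random_networks_stay_in_unit_box(self, seed):
        spec = RandomNetworkSpec(n_species=7, n_reactions=11, seed=seed)
        model = gen_random_network(spec)
        res = simulate(model, t_end=30.0)
        assert res.states.min() >= -1e-6
        assert res.states.max() <= 1.0 + 1e-6


class TestParser:
    def test_simple_rule(self):
        m = parse_network("species A\nspecies B\nspecies C\nA & !B => C\n")
        (r,) = m.reactions
        assert r.target == "C"
        assert r.terms == (Term("A", False), Term("B", True))

    def test_or_rules_collate_by_target(self, small_model):
        m = parse_network(
            "species A\nspecies B\nspecies D\nA => D\nB => D w=0.5\n")
        assert len(m.incoming("D")) == 2

    def test_undeclared_species_error_names_offender(self):
        with pytest.raises(NetworkSyntaxError, match="'Z'"):
            parse_network("species A\nA => Z\n")

    def test_duplicate_declaration_rejected(self):
        with pytest.raises(NetworkSyntaxError, match="duplicate"):
            parse_network("species A\nspecies A\n")

    def test_syntax_error_carries_line_number(self):
        with pytest.raises(NetworkSyntaxError, match="line 2"):
            parse_network("species A\nwhat is this\n")

    def test_roundtrip_identity(self, small_model):
        text = serialize_network(small_model)
        again = serialize_network(parse_network(text))
        assert text == again

    def test_model_invariants_enforced(self):
        with pytest.raises(ValueError):
            NetworkModel(species=(SpeciesNode("A"),),
                         reactions=(Reaction(target="B"),))
        with pytest.raises(ValueError):
            SpeciesNode("A", y_max=1.5)
        with pytest.raises(ValueError):
            SpeciesNode("A", tau=0.0)


class TestUniformParameterEquivalence:
    def test_explicit_default_hill_is_bitwise_identical(self, small_model):
        from dataclasses import replace
        explicit = replace(small_model, reactions=tuple(
            replace(r, hill=small_model.defaults)
            for r in small_model.reactions))
        a = steady_state(small_model)
        b = steady_state(explicit)
        assert np.array_equal(a, b)
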