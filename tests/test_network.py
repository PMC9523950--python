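"""Network definition: conductance table, FHM1 transform, synapse kinetics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fhmnet.network import (AMPA_ON_EXC, AMPA_ON_INH, GABA_KINETICS,
                            ConductanceSet, FHM1Params, NeuronParams,
                            SynapseKinetics, apply_fhm1, build_connectivity,
                            synaptic_current, synaptic_trace_increment,
                            trace_peak_time, wt_conductances)


class TestConductances:
    @pytest.mark.parametrize("field,value", [
        ("g_gaba_inh", 2.70), ("g_gaba_exc", 2.01),
        ("g_ampa_inh", 0.233), ("g_ampa_exc", 0.178),
        ("g_thal_s_inh", 0.317), ("g_thal_s_exc", 0.234),
        ("g_thal_nb_inh", 0.317), ("g_thal_nb_exc", 0.234),
        ("g_noise_inh", 0.317), ("g_noise_exc", 0.234),
    ])
    def test_wild_type_table(self, field, value):
        assert getattr(wt_conductances(), field) == value

    def test_noise_shares_thalamic_strengths(self):
        g = wt_conductances()
        assert g.g_noise_inh == g.g_thal_s_inh
        assert g.g_noise_exc == g.g_thal_s_exc

    def test_negative_conductance_rejected(self):
        with pytest.raises(ValueError):
            ConductanceSet(g_gaba_inh=-0.1)


class TestFHM1Transform:
    def test_identity_at_zero(self):
        base = wt_conductances()
        assert apply_fhm1(base, FHM1Params(0, 0, 0)) == base

    def test_symmetric_tc_reduces_to_plain_increase(self):
        out = apply_fhm1(wt_conductances(), FHM1Params(0, 30, 0))
        assert out.g_thal_s_inh == pytest.approx(0.317 * 1.30)
        assert out.g_thal_s_exc == pytest.approx(0.234 * 1.30)

    def test_reference_asymmetric_factors(self):
        f = FHM1Params(0, 30, 40)
        assert f.alpha == pytest.approx(1.4)
        assert f.thal_inh_factor == pytest.approx(1.35)
        assert f.thal_exc_factor == pytest.approx(1.25)

    @given(tc=st.floats(0.1, 200), tca=st.floats(0, 300))
    @settings(max_examples=200, deadline=None)
    def test_asymmetry_identities(self, tc, tca):
        """Inh/exc increase ratio equals alpha; mean increase equals TC/100."""
        f = FHM1Params(0, tc, tca)
        inh_incr = f.thal_inh_factor - 1.0
        exc_incr = f.thal_exc_factor - 1.0
        assert inh_incr / exc_incr == pytest.approx(f.alpha, rel=1e-9)
        assert (inh_incr + exc_incr) / 2 == pytest.approx(tc / 100.0, rel=1e-9)

    @given(cc=st.floats(0, 200), tc=st.floats(0, 200), tca=st.floats(0, 300))
    @settings(max_examples=100, deadline=None)
    def test_gaba_never_changes(self, cc, tc, tca):
        base = wt_conductances()
        out = apply_fhm1(base, FHM1Params(cc, tc, tca))
        assert out.g_gaba_inh == base.g_gaba_inh
        assert out.g_gaba_exc == base.g_gaba_exc

    def test_ic_scales_both_recurrent_targets(self):
        out = apply_fhm1(wt_conductances(), FHM1Params(40, 0, 0))
        assert out.g_ampa_inh == pytest.approx(0.233 * 1.4)
        assert out.g_ampa_exc == pytest.approx(0.178 * 1.4)

    def test_narrowband_untouched_by_default(self):
        base = wt_conductances()
        out = apply_fhm1(base, FHM1Params(40, 30, 40))
        assert out.g_thal_nb_inh == base.g_thal_nb_inh
        assert out.g_thal_nb_exc == base.g_thal_nb_exc

    def test_narrowband_scaling_switch(self):
        f = FHM1Params(0, 30, 40, scale_narrowband=True)
        out = apply_fhm1(wt_conductances(), f)
        assert out.g_thal_nb_inh == pytest.approx(0.317 * 1.35)


class TestConnectivity:
    def test_zero_probability_empty(self):
        assert build_connectivity(10, 5, 0.0, seed=1).adjacency.nnz == 0

    def test_full_probability_complete(self):
        conn = build_connectivity(3, 2, 1.0, seed=1)
        assert conn.adjacency.nnz == 5 * 4  # all ordered non-self pairs

    def test_no_self_connections(self):
        conn = build_connectivity(50, 10, 0.5, seed=2)
        assert conn.adjacency.diagonal().sum() == 0

    def test_density_within_binomial_tolerance(self):
        conn = build_connectivity(400, 100, 0.2, seed=3)
        n_pairs = 500 * 499
        se = np.sqrt(0.2 * 0.8 / n_pairs)
        assert abs(conn.density - 0.2) < 3 * se

    def test_reproducible_under_seed(self):
        a = build_connectivity(30, 10, 0.3, seed=9)
        b = build_connectivity(30, 10, 0.3, seed=9)
        assert (a.adjacency != b.adjacency).nnz == 0

    def test_bad_arguments(self):
        with pytest.raises(ValueError):
            build_connectivity(0, 5, 0.2, seed=1)
        with pytest.raises(ValueError):
            build_connectivity(5, 5, 1.5, seed=1)


class TestSynapse:
    def test_current_zero_at_reversal(self):
        assert synaptic_current(1.0, 2.0, -80.0, -80.0) == 0.0

    def test_ampa_depolarizing_gaba_hyperpolarizing(self):
        # positive current depolarizes in tau dV/dt = ... + I/g_leak
        assert synaptic_current(0.2, 1.0, -70.0, 0.0) > 0
        assert synaptic_current(2.0, 1.0, -60.0, -80.0) < 0

    def test_trace_zero_at_arrival_and_infinity(self):
        kin = AMPA_ON_EXC
        assert synaptic_trace_increment(kin.tau_l, 0.0, kin, 20.0) == 0.0
        assert synaptic_trace_increment(1e6, 0.0, kin, 20.0) == pytest.approx(0.0)

    @pytest.mark.parametrize("kin,tau_m", [(GABA_KINETICS, 20.0),
                                           (AMPA_ON_EXC, 20.0),
                                           (AMPA_ON_INH, 10.0)])
    def test_peak_at_closed_form_time(self, kin, tau_m):
        tpk = trace_peak_time(kin)
        t = np.linspace(kin.tau_l, kin.tau_l + 30.0, 30001)
        s = synaptic_trace_increment(t, 0.0, kin, tau_m)
        assert t[np.argmax(s)] - kin.tau_l == pytest.approx(tpk, abs=2e-3)

    def test_degenerate_kinetics_rejected(self):
        with pytest.raises(ValueError):
            SynapseKinetics(tau_l=1.0, tau_r=2.0, tau_d=2.0, V_syn=0.0)

    @pytest.mark.parametrize("kin,tau_m", [(GABA_KINETICS, 20.0),
                                           (AMPA_ON_INH, 10.0)])
    def test_two_state_update_matches_closed_form(self, kin, tau_m):
        """The engine's exponential two-state recursion reproduces the
        delayed difference-of-exponentials on a 50 ms grid."""
        dt = 0.05
        steps = int(50 / dt)
        c = tau_m / (kin.tau_d - kin.tau_r)
        fd, fr = np.exp(-dt / kin.tau_d), np.exp(-dt / kin.tau_r)
        d = r = 0.0
        got = np.empty(steps)
        arrival = 100  # spike arrives (after latency) at step 100
        for i in range(steps):
            d *= fd
            r *= fr
            if i == arrival:
                d += c
                r += c
            got[i] = d - r
        t = np.arange(steps) * dt
        want = synaptic_trace_increment(t, arrival * dt - kin.tau_l, kin, tau_m)
        assert np.max(np.abs(got - want)) < 1e-6

    def test_neuron_params_invariants(self):
        with pytest.raises(ValueError):
            NeuronParams(tau_m=-1.0, g_leak=25.0)
        with pytest.raises(ValueError):
            NeuronParams(tau_m=20.0, g_leak=25.0, V_thresh=-60.0, V_reset=-52.0)
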