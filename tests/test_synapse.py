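"""Tests for the composite synaptic-space model and its pointwise pieces."""

import math

import numpy as np
import pytest

from ecbnet.params import GoodwinParams, SynapseParams
from ecbnet.synapse import (
    GoodwinState,
    SynapticSpaceState,
    mglur5_drive,
    mix_crosstalk,
    norm_sigmoid,
    on_excitatory_spike,
    on_inhibitory_spike,
    on_post_spike,
    produce_ecb,
    sigmoid,
    spine_calcium_drive,
    step_goodwin,
    step_synaptic_space,
    update_cb1r_count,
)


class TestSigmoids:
    def test_midpoint_is_half(self):
        for C in (0.3, 10.0, 42.0):
            assert sigmoid(0.5, C, 0.5) == pytest.approx(0.5)

    def test_direct_evaluation(self):
        assert sigmoid(0.0, 10.0, 0.5) == pytest.approx(1 / (1 + math.exp(5)), rel=1e-9)
        assert sigmoid(0.0, 10.0, 0.5) == pytest.approx(0.006693, abs=1e-6)

    def test_saturates_toward_one(self):
        assert sigmoid(1e3, 10.0, 0.5) == pytest.approx(1.0)

    def test_normalisation_endpoints(self):
        assert norm_sigmoid(0.0, 10.0, 0.5) == pytest.approx(0.0, abs=1e-12)
        assert norm_sigmoid(1.0, 10.0, 0.5) == pytest.approx(1.0, abs=1e-12)

    def test_odd_symmetry_about_midpoint(self):
        assert norm_sigmoid(0.5, 10.0, 0.5) == pytest.approx(0.5)

    def test_degenerate_gain_rejected(self):
        with pytest.raises(ValueError):
            norm_sigmoid(0.3, 0.0, 0.5)


class TestDrives:
    def test_mglur5_only_surplus(self):
        assert mglur5_drive(0.2, 0.2) == 0.0  # equality: condition false
        assert mglur5_drive(0.6, 0.2) == pytest.approx(0.4 * 1600)
        assert mglur5_drive(0.0, 0.5) == 0.0

    def test_spine_calcium_arithmetic(self):
        assert spine_calcium_drive(0.0, 0.0, 0.5) == 0.0
        assert spine_calcium_drive(0.1, 0.0, 0.01) == pytest.approx(0.075)
        # negative VSCC bracket is rectified for tiny spines
        assert spine_calcium_drive(0.1, 0.01, 0.002) == pytest.approx(8.0)


class TestEcbProduction:
    def test_no_calcium_no_ecb(self):
        e_sp, e_de = produce_ecb(0.0, 5.0, 0.0)
        assert e_sp == 0.0 and e_de == 0.0

    def test_mglur5_prerequisite(self):
        e_sp, _ = produce_ecb(1.0, 0.0, None)
        assert e_sp == pytest.approx(0.0, abs=1e-12)

    def test_saturation_endpoints(self):
        e_sp, e_de = produce_ecb(1.0, 1.0, 1.0)
        assert e_sp == pytest.approx(1.0)
        assert e_de == pytest.approx(1.0)

    def test_outputs_bounded(self):
        e_sp, e_de = produce_ecb(500.0, 500.0, 500.0)
        assert e_sp <= 1.0 and e_de <= 1.0

    def test_crosstalk_mixing(self):
        glut, gaba = mix_crosstalk(1.0, 0.0, True)
        assert (glut, gaba) == (pytest.approx(0.75), pytest.approx(0.25))
        glut, gaba = mix_crosstalk(0.4, 0.4, True)
        assert glut == pytest.approx(0.4) and gaba == pytest.approx(0.4)

    def test_glut_only_passthrough(self):
        glut, gaba = mix_crosstalk(0.8, 0.0, False)
        assert glut == pytest.approx(0.8) and gaba == 0.0


class TestGoodwin:
    def test_frozen_inhibitor_fixed_points(self):
        """With GZ pinned at 0: GX* = k1/(K1 k2) = 10, GY* = k3 GX*/k4 = 150."""
        gp = GoodwinParams(k5=0.0, k6=0.0)  # freeze GZ at its initial 0
        s = GoodwinState()
        for _ in range(40000):
            s = step_goodwin(s, 1.0, 10.0, 0.05, gp)
        assert s.GX == pytest.approx(10.0, rel=1e-3)
        assert s.GY == pytest.approx(150.0, rel=1e-3)
        count, _ = update_cb1r_count(s, 0.0)
        assert count == pytest.approx(1.0)  # 150*0.0067 = 1.005, clamped

    def test_unbound_zero_gives_negligible_gz_drive(self):
        gp = GoodwinParams()
        drive = gp.k5 * sigmoid(0.0, gp.G_C, gp.G_D)
        assert drive < 1e-5
        s = GoodwinState(GX=1.0, GY=1.0, GZ=5.0)
        s2 = step_goodwin(s, 0.0, 10.0, 0.001, gp)
        assert s2.GZ <= s.GZ + 1e-9

    def test_zero_kinetics_constant_state(self):
        gp = GoodwinParams(k1_glut=0.0, k2=0.0, k3=0.0, k4=0.0, k5=0.0, k6=0.0)
        s = GoodwinState(GX=1.0, GY=2.0, GZ=3.0)
        s2 = step_goodwin(s, 0.5, 0.0, 0.01, gp)
        assert (s2.GX, s2.GY, s2.GZ) == (1.0, 2.0, 3.0)

    def test_invalid_hill_exponent(self):
        with pytest.raises(ValueError):
            step_goodwin(GoodwinState(), 0.0, 10.0, 0.001,
                         GoodwinParams(hill_n=0.0))

    def test_cb1r_count_clamped(self):
        count, unbound = update_cb1r_count(GoodwinState(GY=150.0), 0.3)
        assert count == 1.0
        assert unbound == pytest.approx(0.7)
        count, unbound = update_cb1r_count(GoodwinState(GY=30.0), 0.9)
        assert unbound == 0.0  # occupancy exceeds the count


class TestSpikeHandlers:
    def test_excitatory_release_and_drives(self):
        s = SynapticSpaceState.create(n_ampar=0.2, avail_init=0.6)
        s2 = on_excitatory_spike(s)
        assert s2.cleft.glutamate.value == pytest.approx(0.6)
        assert s2.pending.ampar == pytest.approx(0.2 * 1.28)
        assert s2.pending.mglur5 == pytest.approx(0.4 * 1600)

    def test_excitatory_release_empty_pool(self):
        s = SynapticSpaceState.create(n_ampar=0.2, avail_init=0.0)
        s2 = on_excitatory_spike(s)
        assert s2.cleft.glutamate.value == 0.0
        assert s2.pending.ampar == 0.0 and s2.pending.mglur5 == 0.0

    def test_nmdar_open_input_excludes_fresh_release(self):
        """Residual cleft glutamate before this release drives P(open)."""
        s = SynapticSpaceState.create(n_ampar=0.2, avail_init=0.6)
        s = s.__class__(**{**s.__dict__})  # copy
        import dataclasses
        s = dataclasses.replace(
            s, cleft=dataclasses.replace(
                s.cleft, glutamate=dataclasses.replace(s.cleft.glutamate, value=0.3)))
        s2 = on_excitatory_spike(s)
        assert s2.cleft.glutamate.value == pytest.approx(0.9)
        # cleft after release minus the fresh quantum = 0.3
        drive = max(s2.cleft.glutamate.value - s2.pending.released_glut, 0.0)
        assert drive == pytest.approx(0.3)

    def test_inhibitory_release(self):
        s = SynapticSpaceState.create(has_gaba=True, n_gabar=0.7, avail_init=0.4)
        s2 = on_inhibitory_spike(s)
        assert s2.cleft.gaba.value == pytest.approx(0.4)
        assert s2.pending.gabar == pytest.approx(0.4 * 1.6)

    def test_inhibitory_zero_receptors_still_fills_cleft(self):
        s = SynapticSpaceState.create(has_gaba=True, n_gabar=0.0, avail_init=0.4)
        s2 = on_inhibitory_spike(s)
        assert s2.pending.gabar == 0.0
        assert s2.cleft.gaba.value == pytest.approx(0.4)

    def test_inhibitory_spike_on_glut_only_synapse_fails(self):
        s = SynapticSpaceState.create(has_gaba=False)
        with pytest.raises(ValueError):
            on_inhibitory_spike(s)

    def test_post_spike_drives(self):
        import dataclasses
        s = SynapticSpaceState.create(has_gaba=True)
        s = dataclasses.replace(
            s, spine=dataclasses.replace(
                s.spine, p_nmdar_open=dataclasses.replace(
                    s.spine.p_nmdar_open, value=0.5)))
        s2 = on_post_spike(s)
        assert s2.pending.nmdar == pytest.approx(0.5 * 0.32)
        assert s2.pending.dend_ca == pytest.approx(s.params.omega_dend_vscc)

    def test_post_spike_zero_open_probability(self):
        s = SynapticSpaceState.create()
        s2 = on_post_spike(s)
        assert s2.pending.nmdar == 0.0


class TestStepSynapticSpace:
    def test_quiescent_fixed_points(self):
        """No spikes ever: cleft empties, pools and k1 recover to their maxima."""
        p = SynapseParams()
        s = SynapticSpaceState.create(p, has_gaba=True, avail_init=0.3,
                                      cb1r_init=0.0)
        import dataclasses
        s = dataclasses.replace(
            s, gaba_bouton=dataclasses.replace(
                s.gaba_bouton, k1_state=dataclasses.replace(
                    s.gaba_bouton.k1_state, value=4.0)))
        dt = 0.01
        for _ in range(3000):
            s = step_synaptic_space(s, dt)
        assert s.cleft.glutamate.value == pytest.approx(0.0, abs=1e-9)
        assert s.glut_bouton.available_glutamate.value == pytest.approx(2.0, abs=1e-2)
        assert s.gaba_bouton.k1_state.value == pytest.approx(10.0, abs=1e-2)

    def test_ecb_domains_memoryless(self):
        """Zero traces => zero eCB on the same step, regardless of history."""
        s = SynapticSpaceState.create(has_gaba=True)
        s = on_excitatory_spike(s)
        s = step_synaptic_space(s, 0.001)
        # wipe the production inputs
        import dataclasses
        z = dataclasses.replace
        s = z(s, spine=z(s.spine,
                         calcium=z(s.spine.calcium, rise_value=0.0, decay_value=0.0),
                         mglur5=z(s.spine.mglur5, rise_value=0.0, decay_value=0.0)),
              dend=z(s.dend, calcium=z(s.dend.calcium, rise_value=0.0, decay_value=0.0)))
        s = step_synaptic_space(s, 0.001)
        assert s.cleft.ecb_glut_domain == pytest.approx(0.0, abs=1e-12)
        assert s.cleft.ecb_gaba_domain == pytest.approx(0.0, abs=1e-12)

    def test_glut_only_never_produces_gaba_domain_ecb(self):
        s = SynapticSpaceState.create(has_gaba=False, n_ampar=0.2, avail_init=2.0,
                                      cb1r_init=1.0)
        for i in range(2000):
            if i % 100 == 0:
                s = on_excitatory_spike(s)
            s = step_synaptic_space(s, 0.001)
        assert s.cleft.ecb_gaba_domain == 0.0
        assert s.cleft.ecb_glut_domain > 0.0  # sanity: the glut domain is live

    def test_suppression_lowers_available_glutamate(self):
        """Sustained eCB strictly depresses the pool below its ceiling of 2."""
        import dataclasses
        p = SynapseParams()
        s = SynapticSpaceState.create(p, n_ampar=0.5, avail_init=2.0, cb1r_init=1.0)
        # drive production hard: pin calcium and mGluR5 high via spikes
        for i in range(20000):
            if i % 20 == 0:
                s = on_excitatory_spike(s)
            s = step_synaptic_space(s, 0.001)
        assert s.glut_bouton.available_glutamate.value < 2.0 - 0.1
        assert s.cleft.ecb_glut_domain > 0.0

    def test_process_x_suppresses_k1_and_recovers(self):
        """Active GABA CB1R drives X and pulls k1 below 10; with X silenced
        k1 relaxes back to its ceiling."""
        import dataclasses
        z = dataclasses.replace
        p = SynapseParams()
        s = SynapticSpaceState.create(p, has_gaba=True, cb1r_init=1.0)
        # force a sustained CB1R activation trace on the GABA bouton
        s = z(s, gaba_bouton=z(s.gaba_bouton,
                               cb1r_activation=z(s.gaba_bouton.cb1r_activation,
                                                 rise_value=1.0, decay_value=1.0)))
        for _ in range(12000):
            s = z(s, gaba_bouton=z(s.gaba_bouton,
                                   cb1r_activation=z(s.gaba_bouton.cb1r_activation,
                                                     rise_value=1.0, decay_value=1.0)))
            s = step_synaptic_space(s, 0.01)
        k1_suppressed = s.gaba_bouton.k1_state.value
        assert k1_suppressed < 10.0 - 1.0
        # X has unity DC gain onto its drive of 5 * trace
        assert s.gaba_bouton.x_process.decay_value == pytest.approx(5.0, abs=0.5)
        # silence X: zero the trace and let the system relax
        s = z(s, gaba_bouton=z(s.gaba_bouton,
                               cb1r_activation=z(s.gaba_bouton.cb1r_activation,
                                                 rise_value=0.0, decay_value=0.0),
                               x_process=z(s.gaba_bouton.x_process,
                                           rise_value=0.0, decay_value=0.0)))
        prev = s.gaba_bouton.k1_state.value
        for _ in range(5000):
            s = z(s, gaba_bouton=z(s.gaba_bouton,
                                   cb1r_activation=z(s.gaba_bouton.cb1r_activation,
                                                     rise_value=0.0, decay_value=0.0),
                                   x_process=z(s.gaba_bouton.x_process,
                                               rise_value=0.0, decay_value=0.0)))
            s = step_synaptic_space(s, 0.01)
            assert s.gaba_bouton.k1_state.value >= prev - 1e-9  # monotone recovery
            prev = s.gaba_bouton.k1_state.value
        assert s.gaba_bouton.k1_state.value == pytest.approx(10.0, abs=1e-2)

    def test_bounds_hold_under_random_spiking(self):
        rng = np.random.default_rng(11)
        s = SynapticSpaceState.create(has_gaba=True, n_ampar=0.5, n_gabar=0.5,
                                      cb1r_init=0.8, avail_init=1.5)
        for _ in range(2000):
            if rng.random() < 0.02:
                s = on_excitatory_spike(s)
            if rng.random() < 0.02:
                s = on_inhibitory_spike(s)
            if rng.random() < 0.05:
                s = on_post_spike(s)
            s = step_synaptic_space(s, 0.001)
            assert 0.0 <= s.glut_bouton.available_glutamate.value <= 2.0
            assert 0.0 <= s.gaba_bouton.available_gaba.value <= 2.0
            assert 0.0 <= s.glut_bouton.cb1r_count <= 1.0
            assert 0.0 <= s.glut_bouton.cb1r_unbound <= 1.0
            assert 0.0 <= s.spine.p_nmdar_open.value <= 1.0
            assert 0.0 <= s.gaba_bouton.k1_state.value <= 10.0
            assert s.cleft.glutamate.value >= 0.0
            assert 0.0 <= s.cleft.ecb_glut_domain <= 1.0

    def test_gaba_bouton_requires_dendrite(self):
        from ecbnet.synapse import GABABoutonState, GlutBoutonState, CleftState, SpineState
        p = SynapseParams()
        with pytest.raises(ValueError):
            SynapticSpaceState(
                glut_bouton=GlutBoutonState.create(p),
                spine=SpineState.create(p),
                cleft=CleftState.create(p),
                gaba_bouton=GABABoutonState.create(p),
                dend=None,
                params=p,
            )
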