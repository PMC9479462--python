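"""Model parameters for the endocannabinoid synapse model.

All non-temporal quantities are in arbitrary units (a.u.); time constants are
in seconds.  The defaults describe a cortico-striatal synaptic space: a
glutamatergic bouton facing a spine across a shared cleft, optionally paired
with a GABAergic bouton facing a dendritic-shaft compartment, with retrograde
endocannabinoid (eCB) signalling onto presynaptic CB1 receptors and a
Goodwin-type gene-regulation loop controlling the CB1R count.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass


@dataclass(frozen=True)
class GoodwinParams:
    """Parameters of the CB1R Goodwin loop (mRNA GX -> protein GY -| GZ).

    ``tau_g`` scales all three equations; ``k1`` is the maximum mRNA
    production rate (fixed at 10 for glutamatergic boutons, dynamically
    suppressed by process X on GABAergic boutons); GZ is driven through a
    sigmoid of the unbound CB1R count scaled by ``omega_unbound_gz``.
    """

    tau_g: float = 20.0  # s
    K1: float = 1.0
    k1_glut: float = 10.0
    k2: float = 1.0
    k3: float = 15.0
    k4: float = 1.0
    k5: float = 15.0
    k6: float = 0.001
    G_C: float = 0.3  # sigmoid gain for the GZ drive
    G_D: float = 50.0  # sigmoid midpoint for the GZ drive
    hill_n: float = 2.0  # Hill exponent on GZ in the mRNA production term


@dataclass(frozen=True)
class SynapseParams:
    """All per-synapse constants: time constants, weights and bounds."""

    # -- available neurotransmitter (recovery + eCB adaptation) --------------
    tau_avail: float = 4.28  # s
    avail_max: float = 2.0  # a.u., also the upper bound
    # Adaptation rate of available transmitter per unit of CB1R activation
    # (min of cleft-domain eCB and #CB1R), in a.u. per second.  Negative:
    # CB1R activation suppresses release.
    phi_avail: float = -0.5

    # -- presynaptic CB1R activation trace (both bouton types) ---------------
    tau_cb1r_rise: float = 4.0
    tau_cb1r_decay: float = 22.5

    # -- process X (GABA bouton only) and the k1 it adapts --------------------
    tau_x_rise: float = 4.0
    tau_x_decay: float = 22.5
    omega_cb1r_x: float = 5.0  # GABA CB1R trace -> X drive
    tau_k1: float = 4.28
    k1_max: float = 10.0
    phi_k1: float = -1.0  # a.u. per second per unit of X

    # -- spine receptor kinetics ----------------------------------------------
    tau_ampar_rise: float = 0.004
    tau_ampar_decay: float = 0.030
    tau_mglur5_rise: float = 0.25
    tau_mglur5_decay: float = 0.25
    tau_nmdar_rise: float = 0.02
    tau_nmdar_decay: float = 0.10
    tau_spine_ca_rise: float = 0.010
    tau_spine_ca_decay: float = 0.008

    # -- dendritic compartment kinetics ---------------------------------------
    tau_gabar_rise: float = 0.0008
    tau_gabar_decay: float = 0.0130
    tau_dend_ca_rise: float = 0.010
    tau_dend_ca_decay: float = 0.008

    # -- cleft accumulators ----------------------------------------------------
    tau_cleft_glut: float = 0.045
    tau_cleft_gaba: float = 0.005
    tau_p_nmdar_open: float = 0.100

    # -- component weights -------------------------------------------------
    omega_ampar: float = 1.28
    omega_mglur5: float = 1600.0
    omega_nmdar: float = 0.32
    omega_spine_vscc: float = 125.0
    omega_nmdar_ca: float = 800.0
    # Dendritic VSCC drive per back-propagating spike step.  The leaky
    # rise/decay calcium kinetics (tau 10/8 ms) discount a per-spike drive by
    # the firing duty cycle f*dt, so this weight is scaled such that baseline
    # postsynaptic rates (~10^2 Hz) place dendritic calcium in the eCB
    # production sigmoid's sensitive range around D = 0.5.
    omega_dend_vscc: float = 3.0
    omega_gabar: float = -1.6  # sign applied at neuron integration
    omega_gy_cb1r: float = 0.0067  # GY -> #CB1R
    omega_unbound_gz: float = 400.0  # CB1R_unbound -> GZ sigmoid argument

    # -- eCB production and crosstalk ----------------------------------------
    cross: float = 0.25  # fraction of eCB crossing between the two domains
    ecb_C: float = 10.0  # eCB production sigmoid gain
    ecb_D: float = 0.5  # eCB production sigmoid midpoint

    goodwin: GoodwinParams = dataclasses.field(default_factory=GoodwinParams)

    def replace(self, **kwargs) -> "SynapseParams":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **kwargs)

    def validate(self) -> None:
        for name in (
            "tau_avail", "tau_cb1r_rise", "tau_cb1r_decay", "tau_x_rise",
            "tau_x_decay", "tau_k1", "tau_ampar_rise", "tau_ampar_decay",
            "tau_mglur5_rise", "tau_mglur5_decay", "tau_nmdar_rise",
            "tau_nmdar_decay", "tau_spine_ca_rise", "tau_spine_ca_decay",
            "tau_gabar_rise", "tau_gabar_decay", "tau_dend_ca_rise",
            "tau_dend_ca_decay", "tau_cleft_glut", "tau_cleft_gaba",
            "tau_p_nmdar_open",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.goodwin.hill_n <= 0:
            raise ValueError("Goodwin hill_n must be positive")
        if self.goodwin.tau_g <= 0:
            raise ValueError("Goodwin tau_g must be positive")
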