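"""The composite synaptic-space model.

A synaptic space couples a glutamatergic bouton, a shared cleft and a spine;
2 of every 8 spaces additionally carry a GABAergic bouton and a dendritic
compartment.  Retrograde endocannabinoids (eCBs) are produced on demand —
in the spine when both calcium and mGluR5 are active, in the dendrite from
calcium alone — diffuse instantaneously into two cleft domains with partial
crosstalk, and occupy presynaptic CB1 receptors, suppressing
neurotransmitter release.  The *unbound* receptor remainder — the count
minus the larger of the current eCB occupancy and its slow activation trace
— feeds a Goodwin gene-regulation loop that limits the receptor count;
GABAergic boutons additionally run process X, which suppresses the loop's
maximum mRNA production rate k1.

Spike-gated component inputs enter their form ODEs as the input ``I`` held
for the spike's timestep (the cleft is the exception: the full released
amount is added to it, so release bookkeeping is exact).  The pointwise
functions here operate equally on scalars and numpy arrays; the dataclass
API composes them into a single steppable synapse used in tests and small
simulations, while :mod:`ecbnet.network` drives the same kernels over whole
populations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .forms import (
    AlphaState,
    LeakyAccumulatorState,
    RecoveryAdaptState,
    step_alpha,
    step_leaky,
    step_recovery_adapt,
)
from .params import GoodwinParams, SynapseParams

__all__ = [
    "sigmoid",
    "norm_sigmoid",
    "mglur5_drive",
    "spine_calcium_drive",
    "produce_ecb",
    "mix_crosstalk",
    "GoodwinState",
    "step_goodwin",
    "update_cb1r_count",
    "GlutBoutonState",
    "GABABoutonState",
    "CleftState",
    "SpineState",
    "DendCompartmentState",
    "PendingDrives",
    "SynapticSpaceState",
    "on_excitatory_spike",
    "on_inhibitory_spike",
    "on_post_spike",
    "step_synaptic_space",
]


# ---------------------------------------------------------------------------
# pointwise operations
# ---------------------------------------------------------------------------

def sigmoid(x, C, D):
    """Logistic sigmoid ``1 / (1 + exp(-C*(x - D)))``."""
    return 1.0 / (1.0 + np.exp(-C * (np.asarray(x, dtype=float) - D)))


def norm_sigmoid(x, C, D):
    """Sigmoid rescaled affinely so that 0 maps to 0 and 1 maps to 1."""
    s0 = sigmoid(0.0, C, D)
    s1 = sigmoid(1.0, C, D)
    denom = s1 - s0
    if denom == 0:
        raise ValueError("degenerate sigmoid: S(1) == S(0)")
    return (sigmoid(x, C, D) - s0) / denom


def mglur5_drive(released, n_ampar, omega_mglur5: float = 1600.0):
    """Drive onto mGluR5 from glutamate released beyond the AMPAR number.

    Only the surplus ``released - n_ampar`` (when strictly positive)
    activates mGluR5.
    """
    surplus = np.asarray(released, dtype=float) - n_ampar
    return np.where(surplus > 0, surplus * omega_mglur5, 0.0)


def spine_calcium_drive(
    ampar_trace,
    nmdar_trace,
    n_ampar,
    omega_spine_vscc: float = 125.0,
    omega_nmdar_ca: float = 800.0,
):
    """Calcium influx drive A' from AMPAR and NMDAR depolarisation.

    The AMPAR contribution scales with spine size (number of AMPARs) through
    the VSCC weight; the bracket is rectified at zero so tiny spines cannot
    produce a negative flux.
    """
    vscc = np.maximum(omega_spine_vscc * np.asarray(n_ampar, dtype=float) - 0.5, 0.0)
    return np.asarray(ampar_trace, dtype=float) * vscc + np.asarray(
        nmdar_trace, dtype=float
    ) * omega_nmdar_ca


def produce_ecb(
    spine_ca,
    mglur5_trace,
    dend_ca=None,
    C: float = 10.0,
    D: float = 0.5,
):
    """Instantaneous eCB production in the spine and dendritic compartment.

    Spine production is gated by *both* prerequisites — calcium multiplied by
    the (normalised-sigmoid) mGluR5 activity — while dendritic production
    requires calcium alone.  Both outputs are clamped to [0, 1]; production
    is memoryless and must be recomputed every step.
    """
    ecb_spine = norm_sigmoid(
        np.asarray(spine_ca, dtype=float) * norm_sigmoid(mglur5_trace, C, D), C, D
    )
    ecb_spine = np.clip(ecb_spine, 0.0, 1.0)
    if dend_ca is None:
        return ecb_spine, np.zeros_like(ecb_spine)
    ecb_dend = np.clip(norm_sigmoid(dend_ca, C, D), 0.0, 1.0)
    return ecb_spine, ecb_dend


def mix_crosstalk(ecb_spine, ecb_dend, has_gaba, cross: float = 0.25):
    """Mix the two eCB sources into the glutamate- and GABA-facing domains.

    With a paired bouton a fraction ``cross`` of each source reaches the
    opposite domain; a glutamate-only synapse passes the spine eCB straight
    through and has no GABA domain.
    """
    ecb_spine = np.asarray(ecb_spine, dtype=float)
    ecb_dend = np.asarray(ecb_dend, dtype=float)
    has_gaba = np.asarray(has_gaba)
    glut = np.where(
        has_gaba, ecb_spine * (1.0 - cross) + ecb_dend * cross, ecb_spine
    )
    gaba = np.where(
        has_gaba, ecb_dend * (1.0 - cross) + ecb_spine * cross, 0.0
    )
    return glut, gaba


# ---------------------------------------------------------------------------
# Goodwin gene-regulation loop
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GoodwinState:
    """mRNA (GX), protein (GY) and transcriptional inhibitor (GZ) levels."""

    GX: float = 0.0
    GY: float = 0.0
    GZ: float = 0.0

    @staticmethod
    def from_cb1r(cb1r: float, gp: GoodwinParams,
                  omega_gy_cb1r: float = 0.0067) -> "GoodwinState":
        """Initial loop state for a sampled receptor count.

        The protein matches the receptor count, the mRNA sits at the
        protein-balance point, and the transcriptional inhibitor starts at
        zero (nothing has bound yet).
        """
        gy = cb1r / omega_gy_cb1r
        return GoodwinState(GX=gy * gp.k4 / gp.k3, GY=gy, GZ=0.0)


def goodwin_rates(GX, GY, GZ, cb1r_unbound, k1, gp: GoodwinParams,
                  omega_unbound_gz: float = 400.0):
    """Time derivatives of the Goodwin loop (per second)."""
    dGX = (k1 / (gp.K1 + np.power(np.asarray(GZ, dtype=float), gp.hill_n))
           - gp.k2 * GX) / gp.tau_g
    dGY = (gp.k3 * GX - gp.k4 * GY) / gp.tau_g
    dGZ = (gp.k5 * sigmoid(np.asarray(cb1r_unbound, dtype=float) * omega_unbound_gz,
                           gp.G_C, gp.G_D)
           - gp.k6 * GZ) / gp.tau_g
    return dGX, dGY, dGZ


def step_goodwin(
    state: GoodwinState,
    cb1r_unbound: float,
    k1: float,
    dt: float,
    gp: GoodwinParams | None = None,
    omega_unbound_gz: float = 400.0,
) -> GoodwinState:
    """Advance the Goodwin loop one explicit-Euler step (non-negative)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    gp = gp or GoodwinParams()
    if gp.hill_n <= 0:
        raise ValueError("hill_n must be positive")
    dGX, dGY, dGZ = goodwin_rates(
        state.GX, state.GY, state.GZ, cb1r_unbound, k1, gp, omega_unbound_gz
    )
    return GoodwinState(
        GX=max(state.GX + dt * float(dGX), 0.0),
        GY=max(state.GY + dt * float(dGY), 0.0),
        GZ=max(state.GZ + dt * float(dGZ), 0.0),
    )


def update_cb1r_count(goodwin: GoodwinState | float, cb1r_activation,
                      omega_gy_cb1r: float = 0.0067):
    """CB1R count from the Goodwin protein, and the unbound remainder.

    ``#CB1R = clip(GY * omega, 0, 1)``; the unbound fraction is the count
    minus the portion currently activated by cleft eCB, clamped to [0, 1].
    """
    gy = goodwin.GY if isinstance(goodwin, GoodwinState) else goodwin
    count = np.clip(np.asarray(gy, dtype=float) * omega_gy_cb1r, 0.0, 1.0)
    unbound = np.clip(count - np.asarray(cb1r_activation, dtype=float), 0.0, 1.0)
    return count, unbound


# ---------------------------------------------------------------------------
# composite state containers
# ---------------------------------------------------------------------------

def _alpha(p: SynapseParams, which: str, upper=math.inf) -> AlphaState:
    tr = getattr(p, f"tau_{which}_rise")
    td = getattr(p, f"tau_{which}_decay")
    return AlphaState(tau_rise=tr, tau_decay=td, upper_bound=upper)


@dataclass(frozen=True)
class GlutBoutonState:
    available_glutamate: RecoveryAdaptState
    cb1r_activation: AlphaState
    goodwin: GoodwinState
    cb1r_count: float = 0.0
    cb1r_unbound: float = 0.0

    @staticmethod
    def create(p: SynapseParams, cb1r_init: float = 0.0,
               avail_init: float | None = None) -> "GlutBoutonState":
        avail = RecoveryAdaptState(
            value=p.avail_max if avail_init is None else avail_init,
            tau=p.tau_avail, max_value=p.avail_max,
            adapt_rate_phi=p.phi_avail, upper_bound=p.avail_max,
        )
        return GlutBoutonState(
            available_glutamate=avail,
            cb1r_activation=_alpha(p, "cb1r"),
            goodwin=GoodwinState.from_cb1r(cb1r_init, p.goodwin, p.omega_gy_cb1r),
            cb1r_count=cb1r_init,
            cb1r_unbound=cb1r_init,
        )


@dataclass(frozen=True)
class GABABoutonState:
    available_gaba: RecoveryAdaptState
    cb1r_activation: AlphaState
    goodwin: GoodwinState
    x_process: AlphaState
    k1_state: RecoveryAdaptState
    cb1r_count: float = 0.0
    cb1r_unbound: float = 0.0

    @staticmethod
    def create(p: SynapseParams, cb1r_init: float = 0.0,
               avail_init: float | None = None,
               k1_init: float | None = None) -> "GABABoutonState":
        avail = RecoveryAdaptState(
            value=p.avail_max if avail_init is None else avail_init,
            tau=p.tau_avail, max_value=p.avail_max,
            adapt_rate_phi=p.phi_avail, upper_bound=p.avail_max,
        )
        k1 = RecoveryAdaptState(
            value=p.k1_max if k1_init is None else k1_init,
            tau=p.tau_k1, max_value=p.k1_max,
            adapt_rate_phi=p.phi_k1, upper_bound=p.k1_max,
        )
        return GABABoutonState(
            available_gaba=avail,
            cb1r_activation=_alpha(p, "cb1r"),
            goodwin=GoodwinState.from_cb1r(cb1r_init, p.goodwin, p.omega_gy_cb1r),
            x_process=_alpha(p, "x"),
            k1_state=k1,
            cb1r_count=cb1r_init,
            cb1r_unbound=cb1r_init,
        )


@dataclass(frozen=True)
class CleftState:
    glutamate: LeakyAccumulatorState
    gaba: LeakyAccumulatorState
    ecb_glut_domain: float = 0.0  # instantaneous, recomputed every step
    ecb_gaba_domain: float = 0.0

    @staticmethod
    def create(p: SynapseParams) -> "CleftState":
        return CleftState(
            glutamate=LeakyAccumulatorState(tau=p.tau_cleft_glut),
            gaba=LeakyAccumulatorState(tau=p.tau_cleft_gaba),
        )


@dataclass(frozen=True)
class SpineState:
    ampar: AlphaState
    mglur5: AlphaState
    nmdar: AlphaState
    p_nmdar_open: LeakyAccumulatorState
    calcium: AlphaState
    n_ampar: float = 0.5

    @staticmethod
    def create(p: SynapseParams, n_ampar: float = 0.5) -> "SpineState":
        return SpineState(
            ampar=_alpha(p, "ampar"),
            mglur5=_alpha(p, "mglur5"),
            nmdar=_alpha(p, "nmdar"),
            p_nmdar_open=LeakyAccumulatorState(tau=p.tau_p_nmdar_open, upper_bound=1.0),
            calcium=_alpha(p, "spine_ca"),
            n_ampar=n_ampar,
        )


@dataclass(frozen=True)
class DendCompartmentState:
    gabar: AlphaState
    calcium: AlphaState
    n_gabar: float = 0.5

    @staticmethod
    def create(p: SynapseParams, n_gabar: float = 0.5) -> "DendCompartmentState":
        return DendCompartmentState(
            gabar=_alpha(p, "gabar"),
            calcium=_alpha(p, "dend_ca"),
            n_gabar=n_gabar,
        )


@dataclass(frozen=True)
class PendingDrives:
    """Spike-gated drives waiting to be consumed by the next continuous step.

    Spike handlers fill these; :func:`step_synaptic_space` applies each as
    the corresponding form's input for one timestep and clears them.
    ``released_glut`` records the amount added to the cleft this step so the
    NMDAR open-probability input can exclude the fresh quantum.
    """

    ampar: float = 0.0
    mglur5: float = 0.0
    nmdar: float = 0.0
    gabar: float = 0.0
    dend_ca: float = 0.0
    released_glut: float = 0.0


@dataclass(frozen=True)
class SynapticSpaceState:
    """Full per-synapse state; GABA bouton and dendrite are present together."""

    glut_bouton: GlutBoutonState
    spine: SpineState
    cleft: CleftState
    gaba_bouton: Optional[GABABoutonState] = None
    dend: Optional[DendCompartmentState] = None
    pending: PendingDrives = field(default_factory=PendingDrives)
    params: SynapseParams = field(default_factory=SynapseParams)

    def __post_init__(self):
        if (self.gaba_bouton is None) != (self.dend is None):
            raise ValueError("GABA bouton and dendritic compartment must co-occur")

    @property
    def has_gaba(self) -> bool:
        return self.gaba_bouton is not None

    @staticmethod
    def create(
        params: SynapseParams | None = None,
        has_gaba: bool = False,
        n_ampar: float = 0.5,
        n_gabar: float = 0.5,
        cb1r_init: float = 0.0,
        avail_init: float | None = None,
    ) -> "SynapticSpaceState":
        p = params or SynapseParams()
        return SynapticSpaceState(
            glut_bouton=GlutBoutonState.create(p, cb1r_init, avail_init),
            spine=SpineState.create(p, n_ampar),
            cleft=CleftState.create(p),
            gaba_bouton=GABABoutonState.create(p, cb1r_init, avail_init) if has_gaba else None,
            dend=DendCompartmentState.create(p, n_gabar) if has_gaba else None,
            params=p,
        )


# ---------------------------------------------------------------------------
# event handlers
# ---------------------------------------------------------------------------

def on_excitatory_spike(state: SynapticSpaceState) -> SynapticSpaceState:
    """Presynaptic glutamate release: fill the cleft and set receptor drives.

    The bouton releases its full available glutamate into the cleft; the
    bound portion ``min(released, #AMPAR)`` drives AMPARs and the surplus
    drives mGluR5 during this step.
    """
    p = state.params
    released = state.glut_bouton.available_glutamate.value
    cleft = replace(
        state.cleft,
        glutamate=replace(state.cleft.glutamate,
                          value=state.cleft.glutamate.value + released),
    )
    pending = replace(
        state.pending,
        ampar=state.pending.ampar + min(released, state.spine.n_ampar) * p.omega_ampar,
        mglur5=state.pending.mglur5
        + float(mglur5_drive(released, state.spine.n_ampar, p.omega_mglur5)),
        released_glut=state.pending.released_glut + released,
    )
    return replace(state, cleft=cleft, pending=pending)


def on_inhibitory_spike(state: SynapticSpaceState) -> SynapticSpaceState:
    """Presynaptic GABA release into the cleft; drives GABARs by magnitude.

    The GABAR trace is kept non-negative; the inhibitory sign of the GABAR
    weight is applied when the neuron integrates its synapses.
    """
    if not state.has_gaba:
        raise ValueError("inhibitory spike delivered to a glutamate-only synapse")
    p = state.params
    released = state.gaba_bouton.available_gaba.value
    cleft = replace(
        state.cleft,
        gaba=replace(state.cleft.gaba, value=state.cleft.gaba.value + released),
    )
    pending = replace(
        state.pending,
        gabar=state.pending.gabar
        + min(released, state.dend.n_gabar) * abs(p.omega_gabar),
    )
    return replace(state, cleft=cleft, pending=pending)


def on_post_spike(state: SynapticSpaceState) -> SynapticSpaceState:
    """Back-propagating action potential: NMDAR and dendritic calcium drives."""
    p = state.params
    pending = replace(
        state.pending,
        nmdar=state.pending.nmdar
        + state.spine.p_nmdar_open.value * p.omega_nmdar,
        dend_ca=state.pending.dend_ca + (p.omega_dend_vscc if state.dend else 0.0),
    )
    return replace(state, pending=pending)


# ---------------------------------------------------------------------------
# per-step continuous update
# ---------------------------------------------------------------------------

def step_synaptic_space(state: SynapticSpaceState, dt: float) -> SynapticSpaceState:
    """Advance the synaptic space by one timestep.

    Sub-update order: (1) recompute the instantaneous eCB domains, (2)
    advance the Goodwin loops and CB1R counts using the unbound fraction
    (count minus the larger of current eCB occupancy and the CB1R
    activation trace), (3) advance every dynamical form with its drive —
    pending spike-gated drives are consumed here — (4) bounds are clamped
    within each stepper.  Spike events
    (:func:`on_excitatory_spike` etc.) are applied before this continuous
    update within the same step.
    """
    p = state.params
    spine, cleft, glut = state.spine, state.cleft, state.glut_bouton
    gaba, dend = state.gaba_bouton, state.dend
    pend = state.pending

    # (1) instantaneous eCB production and crosstalk
    ecb_spine, ecb_dend = produce_ecb(
        spine.calcium.decay_value,
        spine.mglur5.decay_value,
        dend.calcium.decay_value if dend is not None else None,
        p.ecb_C, p.ecb_D,
    )
    ecb_glut, ecb_gaba = mix_crosstalk(ecb_spine, ecb_dend, state.has_gaba, p.cross)
    ecb_glut, ecb_gaba = float(ecb_glut), float(ecb_gaba)
    cleft = replace(cleft, ecb_glut_domain=ecb_glut, ecb_gaba_domain=ecb_gaba)

    # (2) Goodwin loops and CB1R counts; unbound = count minus the
    # cleft-domain eCB currently occupying receptors
    act_g = glut.cb1r_activation.decay_value
    unbound_g = float(np.clip(glut.cb1r_count - max(ecb_glut, act_g), 0.0, 1.0))
    gw_g = step_goodwin(glut.goodwin, unbound_g, p.goodwin.k1_glut, dt,
                        p.goodwin, p.omega_unbound_gz)
    count_g, unbound_g = update_cb1r_count(gw_g, max(ecb_glut, act_g),
                                           p.omega_gy_cb1r)

    if gaba is not None:
        act_b = gaba.cb1r_activation.decay_value
        unbound_b = float(np.clip(gaba.cb1r_count - max(ecb_gaba, act_b), 0.0, 1.0))
        gw_b = step_goodwin(gaba.goodwin, unbound_b, gaba.k1_state.value, dt,
                            p.goodwin, p.omega_unbound_gz)
        count_b, unbound_b = update_cb1r_count(gw_b, max(ecb_gaba, act_b),
                                               p.omega_gy_cb1r)

    # (3) advance all forms; CB1R activation suppresses release
    glut = replace(
        glut,
        goodwin=gw_g,
        cb1r_count=float(count_g),
        cb1r_unbound=float(unbound_g),
        available_glutamate=step_recovery_adapt(
            glut.available_glutamate, min(ecb_glut, float(count_g)), dt),
        cb1r_activation=step_alpha(glut.cb1r_activation,
                                   min(ecb_glut, float(count_g)), dt),
    )

    if gaba is not None:
        x = step_alpha(gaba.x_process,
                       gaba.cb1r_activation.decay_value * p.omega_cb1r_x, dt)
        gaba = replace(
            gaba,
            goodwin=gw_b,
            cb1r_count=float(count_b),
            cb1r_unbound=float(unbound_b),
            available_gaba=step_recovery_adapt(
                gaba.available_gaba, min(ecb_gaba, float(count_b)), dt),
            cb1r_activation=step_alpha(gaba.cb1r_activation,
                                       min(ecb_gaba, float(count_b)), dt),
            x_process=x,
            k1_state=step_recovery_adapt(gaba.k1_state, x.decay_value, dt),
        )
        dend = replace(
            dend,
            gabar=step_alpha(dend.gabar, pend.gabar, dt),
            calcium=step_alpha(dend.calcium, pend.dend_ca, dt),
        )

    ca_drive = float(
        spine_calcium_drive(spine.ampar.decay_value, spine.nmdar.decay_value,
                            spine.n_ampar, p.omega_spine_vscc, p.omega_nmdar_ca)
    )
    # NMDAR open probability tracks residual cleft glutamate (the fresh
    # quantum released this step is excluded)
    p_open_drive = max(cleft.glutamate.value - pend.released_glut, 0.0)
    spine = replace(
        spine,
        ampar=step_alpha(spine.ampar, pend.ampar, dt),
        mglur5=step_alpha(spine.mglur5, pend.mglur5, dt),
        nmdar=step_alpha(spine.nmdar, pend.nmdar, dt),
        calcium=step_alpha(spine.calcium, ca_drive, dt),
        p_nmdar_open=step_leaky(spine.p_nmdar_open, p_open_drive, dt),
    )
    cleft = replace(
        cleft,
        glutamate=step_leaky(cleft.glutamate, 0.0, dt),
        gaba=step_leaky(cleft.gaba, 0.0, dt),
    )
    return replace(state, glut_bouton=glut, spine=spine, cleft=cleft,
                   gaba_bouton=gaba, dend=dend, pending=PendingDrives())
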