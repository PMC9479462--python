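"""Network construction and simulation.

A population of leaky integrate-and-fire neurons is driven through synaptic
spaces (:mod:`ecbnet.synapse`) by independent homogeneous Poisson inputs.
Each glutamatergic pathway listens to one random excitatory input channel and
each GABAergic pathway to one random inhibitory channel; every neuron owns a
fixed number of spines (default 80) of which a fixed subset (default 20)
also carry a GABAergic bouton and dendritic compartment.  Back-propagating
action potentials are delivered to all of a neuron's spines and dendritic
compartments within the firing step.

The engine advances all synapses as flat numpy arrays with the same exact
exponential updates as the scalar steppers in :mod:`ecbnet.forms`, in the
same sub-step order as :func:`ecbnet.synapse.step_synaptic_space`.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .forms import alpha_coefficients
from .params import SynapseParams

__all__ = [
    "NetworkConfig",
    "NeuronState",
    "PerturbationSpec",
    "SimulationResult",
    "Network",
    "build_network",
    "generate_poisson_spikes",
    "step_neuron",
]

#: trace variables the engine can sample (per glutamatergic / GABAergic bouton)
GLUT_VARS = (
    "excess_glut", "avail_glut", "cb1r_glut", "cleft_glut",
    "cum_release_glut", "cum_excess_release_glut", "spine_ca", "ecb_glut",
)
GABA_VARS = (
    "excess_gaba", "avail_gaba", "cb1r_gaba", "cleft_gaba",
    "cum_release_gaba", "k1_gaba", "x_gaba", "ecb_gaba",
)
DEFAULT_RECORD = (
    "excess_glut", "excess_gaba", "avail_glut", "avail_gaba",
    "cb1r_glut", "cb1r_gaba", "cleft_glut",
    "cum_release_glut", "cum_excess_release_glut", "cum_release_gaba",
    "k1_gaba",
)


@dataclass(frozen=True)
class NetworkConfig:
    """Sizes, rates, weights and integrator settings for one simulation."""

    n_neurons: int = 100
    n_exc_inputs: int = 100
    n_inh_inputs: int = 100
    spines_per_neuron: int = 80
    dends_per_neuron: int = 20
    n_glut_synapses: Optional[int] = None  # derived if omitted
    n_gaba_synapses: Optional[int] = None
    exc_rate_range: tuple = (1.0, 20.0)  # Hz, per-channel uniform draw
    inh_rate_range: tuple = (1.0, 20.0)
    global_exc_weight: float = 1.0
    global_inh_weight: float = 1.0
    dt: float = 0.001  # s
    duration: float = 50.0  # s
    sample_interval: float = 0.01  # s
    seed: int = 0
    membrane_tau: float = 0.02  # s
    threshold: float = 0.4  # a.u.
    reset: float = 0.0
    refractory: float = 0.002  # s
    params: SynapseParams = field(default_factory=SynapseParams)

    def __post_init__(self):
        ng = self.n_neurons * self.spines_per_neuron
        nb = self.n_neurons * self.dends_per_neuron
        if self.n_glut_synapses is None:
            object.__setattr__(self, "n_glut_synapses", ng)
        if self.n_gaba_synapses is None:
            object.__setattr__(self, "n_gaba_synapses", nb)
        self.validate()

    def validate(self) -> None:
        if self.n_glut_synapses != self.n_neurons * self.spines_per_neuron:
            raise ValueError(
                "n_glut_synapses must equal n_neurons * spines_per_neuron "
                f"({self.n_neurons} * {self.spines_per_neuron})"
            )
        if self.n_gaba_synapses != self.n_neurons * self.dends_per_neuron:
            raise ValueError(
                "n_gaba_synapses must equal n_neurons * dends_per_neuron"
            )
        if self.dends_per_neuron > self.spines_per_neuron:
            raise ValueError("dends_per_neuron cannot exceed spines_per_neuron")
        if self.n_exc_inputs < 1 or self.n_inh_inputs < 1 or self.n_neurons < 1:
            raise ValueError("network must have at least one neuron and input")
        if self.dt <= 0 or self.duration < 0 or self.sample_interval <= 0:
            raise ValueError("dt and sample_interval must be positive, duration >= 0")
        if min(self.exc_rate_range) < 0 or min(self.inh_rate_range) < 0:
            raise ValueError("rates must be non-negative")
        if self.membrane_tau <= 0:
            raise ValueError("membrane_tau must be positive")
        self.params.validate()

    def replace(self, **kwargs) -> "NetworkConfig":
        d = dataclasses.asdict(self)
        # asdict recurses into params; keep the dataclass instance instead
        d["params"] = kwargs.pop("params", self.params)
        # derived counts must be re-derived when sizes change
        if any(k in kwargs for k in ("n_neurons", "spines_per_neuron", "dends_per_neuron")):
            d["n_glut_synapses"] = None
            d["n_gaba_synapses"] = None
        d.update(kwargs)
        d["exc_rate_range"] = tuple(d["exc_rate_range"])
        d["inh_rate_range"] = tuple(d["inh_rate_range"])
        return NetworkConfig(**d)


@dataclass
class NeuronState:
    """Leaky integrate-and-fire neuron."""

    membrane: float = 0.0
    threshold: float = 1.0
    reset: float = 0.0
    tau: float = 0.02
    refractory: float = 0.002
    last_spike_time: float = -math.inf


def step_neuron(state: NeuronState, summed_drive: float, dt: float,
                t: float = 0.0):
    """Advance a neuron one step; returns ``(state, spiked)``.

    The membrane relaxes exactly toward the summed synaptic drive
    (``tau * dV/dt = -V + D``); a threshold crossing resets the membrane and
    opens the refractory window during which integration is suspended.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t_next = t + dt
    if t_next - state.last_spike_time < state.refractory:
        return dataclasses.replace(state, membrane=state.reset), False
    v = summed_drive + (state.membrane - summed_drive) * math.exp(-dt / state.tau)
    if v >= state.threshold:
        return dataclasses.replace(
            state, membrane=state.reset, last_spike_time=t_next
        ), True
    return dataclasses.replace(state, membrane=v), False


@dataclass(frozen=True)
class PerturbationSpec:
    """A timed change to targeted glutamatergic synapses.

    AMPAR number may be set or scaled (LTP/LTD), and the driving excitatory
    rate may be set or scaled (the synapse is detached onto a private Poisson
    stream from the perturbation time onward).
    """

    time: float
    synapse_ids: tuple
    n_ampar_value: Optional[float] = None
    n_ampar_scale: Optional[float] = None
    rate_value: Optional[float] = None
    rate_scale: Optional[float] = None

    def __post_init__(self):
        object.__setattr__(self, "synapse_ids", tuple(int(i) for i in self.synapse_ids))
        if self.time <= 0:
            raise ValueError("perturbation time must be positive")


def generate_poisson_spikes(rate: float, duration: float,
                            rng: np.random.Generator) -> np.ndarray:
    """Event times of a homogeneous Poisson process on [0, duration)."""
    if rate < 0:
        raise ValueError("rate must be non-negative")
    n = rng.poisson(rate * duration)
    return np.sort(rng.uniform(0.0, duration, size=n))


# ---------------------------------------------------------------------------


@dataclass
class SimulationResult:
    """Sampled traces and spike records from one simulation run."""

    config: NetworkConfig
    times: np.ndarray
    data: dict
    glut_meta: pd.DataFrame
    gaba_meta: pd.DataFrame
    neuron_spikes: list
    spike_log: Optional[pd.DataFrame] = None

    def var(self, name: str) -> np.ndarray:
        """Trace array for a recorded variable, shape (n_samples, n_entities)."""
        return self.data[name]

    def final_window_mean(self, name: str, window: float = 5.0) -> np.ndarray:
        """Per-entity mean of a variable over the final ``window`` seconds."""
        mask = self.times >= self.times[-1] - window + 1e-12
        return self.data[name][mask].mean(axis=0)

    def cumulative_between(self, name: str, t0: float, t1: float) -> np.ndarray:
        """Increment of a cumulative variable over (t0, t1], per entity."""
        trace = self.data[name]
        a = np.array([np.interp(t0, self.times, trace[:, j])
                      for j in range(trace.shape[1])])
        b = np.array([np.interp(t1, self.times, trace[:, j])
                      for j in range(trace.shape[1])])
        return b - a

    def neuron_rates(self, t0: float = 0.0) -> np.ndarray:
        """Mean firing rate of each neuron from t0 to the end of the run."""
        span = max(self.times[-1] - t0, 1e-12)
        return np.array([np.sum(s >= t0) / span for s in self.neuron_spikes])

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format (time, entity_id, variable, value) table of all traces."""
        frames = []
        for name, arr in self.data.items():
            n = arr.shape[1]
            frames.append(pd.DataFrame({
                "time": np.repeat(self.times, n),
                "entity_id": np.tile(np.arange(n), len(self.times)),
                "variable": name,
                "value": arr.ravel(),
            }))
        return pd.concat(frames, ignore_index=True)


class Network:
    """A built network: connectivity, rates and initial conditions.

    Construction and every run are reproducible from the configuration seed;
    randomness is split into named substreams (connectivity, rates, initial
    conditions, excitatory/inhibitory spike trains, perturbation streams) so
    components can be regenerated independently.
    """

    def __init__(self, config: NetworkConfig):
        config.validate()
        self.config = config
        ss = np.random.SeedSequence(config.seed)
        (self._ss_conn, self._ss_rates, self._ss_init,
         self._ss_exc, self._ss_inh, self._ss_pert) = ss.spawn(6)
        self._build()

    # -- construction -------------------------------------------------------

    def _build(self):
        cfg = self.config
        rng = np.random.default_rng(self._ss_conn)
        ng = cfg.n_glut_synapses
        nb = cfg.n_gaba_synapses
        spn = cfg.spines_per_neuron
        dpn = cfg.dends_per_neuron

        # synapse g belongs to neuron g // spines_per_neuron
        self.neuron_of_glut = np.repeat(np.arange(cfg.n_neurons), spn)
        # each pathway listens to one random input channel
        self.exc_channel = rng.integers(0, cfg.n_exc_inputs, size=ng)
        # per neuron, a random subset of its spines is paired with a GABA
        # bouton + dendritic compartment
        pair = np.concatenate([
            n * spn + np.sort(rng.permutation(spn)[:dpn])
            for n in range(cfg.n_neurons)
        ]) if nb else np.empty(0, dtype=int)
        self.pair_idx = pair.astype(int)
        self.neuron_of_gaba = self.neuron_of_glut[self.pair_idx] if nb else np.empty(0, dtype=int)
        self.inh_channel = rng.integers(0, cfg.n_inh_inputs, size=nb)
        self.has_gaba = np.zeros(ng, dtype=bool)
        self.has_gaba[self.pair_idx] = True

        rng_rates = np.random.default_rng(self._ss_rates)
        self.exc_channel_rates = rng_rates.uniform(*cfg.exc_rate_range,
                                                   size=cfg.n_exc_inputs)
        self.inh_channel_rates = rng_rates.uniform(*cfg.inh_rate_range,
                                                   size=cfg.n_inh_inputs)
        self.glut_rates = self.exc_channel_rates[self.exc_channel]
        self.gaba_rates = self.inh_channel_rates[self.inh_channel]

        # random initial conditions: recovery/adaptation components and
        # receptor counts uniform within their bounds, traces at zero
        rng_init = np.random.default_rng(self._ss_init)
        p = cfg.params
        self.init_avail_glut = rng_init.uniform(0.0, p.avail_max, size=ng)
        self.init_avail_gaba = rng_init.uniform(0.0, p.avail_max, size=nb)
        self.init_n_ampar = rng_init.uniform(0.0, 1.0, size=ng)
        self.init_n_gabar = rng_init.uniform(0.0, 1.0, size=nb)
        self.init_cb1r_glut = rng_init.uniform(0.0, 1.0, size=ng)
        self.init_cb1r_gaba = rng_init.uniform(0.0, 1.0, size=nb)
        self.init_k1_gaba = rng_init.uniform(0.0, p.k1_max, size=nb)

    # -- simulation ---------------------------------------------------------

    def run(
        self,
        perturbations: Sequence[PerturbationSpec] = (),
        duration: Optional[float] = None,
        record_vars: Sequence[str] = DEFAULT_RECORD,
        sample_interval: Optional[float] = None,
        record_spikes: bool = False,
    ) -> SimulationResult:
        cfg = self.config
        p = cfg.params
        gp = p.goodwin
        dt = cfg.dt
        duration = cfg.duration if duration is None else duration
        interval = cfg.sample_interval if sample_interval is None else sample_interval
        stride = max(int(round(interval / dt)), 1)
        n_steps = int(round(duration / dt))
        ng, nb, nn = cfg.n_glut_synapses, cfg.n_gaba_synapses, cfg.n_neurons

        for v in record_vars:
            if v not in GLUT_VARS and v not in GABA_VARS:
                raise ValueError(f"unknown record variable: {v}")
        for spec in perturbations:
            if spec.time >= duration:
                raise ValueError("perturbation time must fall within the run")
            for i in spec.synapse_ids:
                if not 0 <= i < ng:
                    raise ValueError(f"perturbation targets unknown synapse {i}")

        # --- mutable state (fresh copy per run; same seed -> same run) ------
        avail_g = self.init_avail_glut.copy()
        avail_b = self.init_avail_gaba.copy()
        n_ampar = self.init_n_ampar.copy()
        n_gabar = self.init_n_gabar.copy()
        cb1r_g = self.init_cb1r_glut.copy()
        cb1r_b = self.init_cb1r_gaba.copy()
        k1_b = self.init_k1_gaba.copy()
        GY_g = cb1r_g / p.omega_gy_cb1r
        GX_g = GY_g * gp.k4 / gp.k3
        GZ_g = np.zeros(ng)
        GY_b = cb1r_b / p.omega_gy_cb1r
        GX_b = GY_b * gp.k4 / gp.k3
        GZ_b = np.zeros(nb)

        zg = np.zeros
        ampar_r, ampar_d = zg(ng), zg(ng)
        mglur5_r, mglur5_d = zg(ng), zg(ng)
        nmdar_r, nmdar_d = zg(ng), zg(ng)
        ca_r, ca_d = zg(ng), zg(ng)
        trace_g_r, trace_g_d = zg(ng), zg(ng)  # glut CB1R activation
        trace_b_r, trace_b_d = zg(nb), zg(nb)  # GABA CB1R activation
        x_r, x_d = zg(nb), zg(nb)
        gabar_r, gabar_d = zg(nb), zg(nb)
        dca_r, dca_d = zg(nb), zg(nb)
        cleft_g, cleft_b = zg(ng), zg(nb)
        p_open = zg(ng)
        cum_rel_g, cum_exrel_g, cum_rel_b = zg(ng), zg(ng), zg(nb)
        ampar_dr, mglur5_dr, nmdar_dr = zg(ng), zg(ng), zg(ng)
        rel_step = zg(ng)
        gabar_dr, dca_dr = zg(nb), zg(nb)
        V = np.full(nn, cfg.reset, dtype=float)
        last_spike = np.full(nn, -np.inf)
        neuron_spikes: list = [[] for _ in range(nn)]

        # --- precomputed update coefficients --------------------------------
        co_ampar = alpha_coefficients(p.tau_ampar_rise, p.tau_ampar_decay, dt)
        co_mglur5 = alpha_coefficients(p.tau_mglur5_rise, p.tau_mglur5_decay, dt)
        co_nmdar = alpha_coefficients(p.tau_nmdar_rise, p.tau_nmdar_decay, dt)
        co_ca = alpha_coefficients(p.tau_spine_ca_rise, p.tau_spine_ca_decay, dt)
        co_trace = alpha_coefficients(p.tau_cb1r_rise, p.tau_cb1r_decay, dt)
        co_x = alpha_coefficients(p.tau_x_rise, p.tau_x_decay, dt)
        co_gabar = alpha_coefficients(p.tau_gabar_rise, p.tau_gabar_decay, dt)
        co_dca = alpha_coefficients(p.tau_dend_ca_rise, p.tau_dend_ca_decay, dt)
        e_avail = math.exp(-dt / p.tau_avail)
        e_k1 = math.exp(-dt / p.tau_k1)
        e_cg = math.exp(-dt / p.tau_cleft_glut)
        e_cb = math.exp(-dt / p.tau_cleft_gaba)
        e_po = math.exp(-dt / p.tau_p_nmdar_open)
        e_m = math.exp(-dt / cfg.membrane_tau)
        s0 = 1.0 / (1.0 + math.exp(p.ecb_C * p.ecb_D))
        s1 = 1.0 / (1.0 + math.exp(-p.ecb_C * (1.0 - p.ecb_D)))
        inv_span = 1.0 / (s1 - s0)

        def nsig(x):
            # normalised production sigmoid, precomputed endpoints
            return (1.0 / (1.0 + np.exp(-p.ecb_C * (x - p.ecb_D))) - s0) * inv_span

        pair = self.pair_idx
        neuron_b = self.neuron_of_gaba
        abs_gabar = abs(p.omega_gabar)
        gabar_sign = -1.0 if p.omega_gabar < 0 else 1.0
        wE, wI = cfg.global_exc_weight, cfg.global_inh_weight

        # --- input spike trains --------------------------------------------
        rng_exc = np.random.default_rng(self._ss_exc)
        rng_inh = np.random.default_rng(self._ss_inh)
        rng_pert = np.random.default_rng(self._ss_pert)
        counts_e = rng_exc.poisson(self.exc_channel_rates * dt,
                                   size=(n_steps, cfg.n_exc_inputs)) if n_steps else None
        counts_i = rng_inh.poisson(self.inh_channel_rates * dt,
                                   size=(n_steps, cfg.n_inh_inputs)) if n_steps else None
        chan_g, chan_b = self.exc_channel, self.inh_channel

        pert_by_step: dict = {}
        for spec in perturbations:
            pert_by_step.setdefault(int(round(spec.time / dt)), []).append(spec)
        override_ids = np.empty(0, dtype=int)
        override_rates = np.empty(0)

        # --- recording ------------------------------------------------------
        n_samples = n_steps // stride + 1
        times = np.arange(n_samples) * (stride * dt)
        data = {v: np.empty((n_samples, ng if v in GLUT_VARS else nb))
                for v in record_vars}
        spike_rows: list = []

        def sample(row):
            src = {
                "excess_glut": lambda: avail_g - n_ampar,
                "avail_glut": lambda: avail_g,
                "cb1r_glut": lambda: cb1r_g,
                "cleft_glut": lambda: cleft_g,
                "cum_release_glut": lambda: cum_rel_g,
                "cum_excess_release_glut": lambda: cum_exrel_g,
                "spine_ca": lambda: ca_d,
                "ecb_glut": lambda: ecb_glut_last,
                "excess_gaba": lambda: avail_b - n_gabar,
                "avail_gaba": lambda: avail_b,
                "cb1r_gaba": lambda: cb1r_b,
                "cleft_gaba": lambda: cleft_b,
                "cum_release_gaba": lambda: cum_rel_b,
                "k1_gaba": lambda: k1_b,
                "x_gaba": lambda: x_d,
                "ecb_gaba": lambda: ecb_gaba_last,
            }
            for v in record_vars:
                data[v][row] = src[v]()

        ecb_glut_last = np.zeros(ng)
        ecb_gaba_last = np.zeros(nb)
        sample(0)
        row = 1

        hill_n, K1, tg = gp.hill_n, gp.K1, gp.tau_g
        k2, k3, k4, k5, k6 = gp.k2, gp.k3, gp.k4, gp.k5, gp.k6

        for step in range(n_steps):
            t_next = (step + 1) * dt

            # perturbations scheduled at this step (applied before inputs)
            if step in pert_by_step:
                for spec in pert_by_step[step]:
                    ids = np.asarray(spec.synapse_ids, dtype=int)
                    if spec.n_ampar_value is not None:
                        n_ampar[ids] = spec.n_ampar_value
                    if spec.n_ampar_scale is not None:
                        n_ampar[ids] *= spec.n_ampar_scale
                    if spec.rate_value is not None or spec.rate_scale is not None:
                        new = (np.full(ids.size, spec.rate_value)
                               if spec.rate_value is not None
                               else self.glut_rates[ids] * spec.rate_scale)
                        override_ids = np.concatenate([override_ids, ids])
                        override_rates = np.concatenate([override_rates, new])

            # -- presynaptic spikes ----------------------------------------
            ce = counts_e[step][chan_g]
            if override_ids.size:
                ce = ce.copy()
                ce[override_ids] = rng_pert.poisson(override_rates * dt)
            active = ce > 0
            rel_step[:] = 0.0
            ampar_dr[:] = 0.0
            mglur5_dr[:] = 0.0
            if active.any():
                cef = ce.astype(float)
                rel = cef * avail_g
                surplus = np.maximum(avail_g - n_ampar, 0.0)
                cum_rel_g += rel
                cum_exrel_g += cef * surplus
                cleft_g += rel
                rel_step[:] = rel
                ampar_dr[:] = cef * np.minimum(avail_g, n_ampar) * p.omega_ampar
                mglur5_dr[:] = cef * surplus * p.omega_mglur5
                if record_spikes:
                    idx = np.nonzero(active)[0]
                    for i in idx:
                        spike_rows.append((t_next, int(i), "exc", float(avail_g[i] * ce[i])))

            if nb:
                gabar_dr[:] = 0.0
                ci = counts_i[step][chan_b]
                if (ci > 0).any():
                    cif = ci.astype(float)
                    relb = cif * avail_b
                    cum_rel_b += relb
                    cleft_b += relb
                    gabar_dr[:] = cif * np.minimum(avail_b, n_gabar) * abs_gabar
                    if record_spikes:
                        for i in np.nonzero(ci > 0)[0]:
                            spike_rows.append((t_next, int(i), "inh", float(avail_b[i] * ci[i])))

            # -- (1) instantaneous eCB domains -----------------------------
            e_sp = np.clip(nsig(ca_d * np.clip(nsig(mglur5_d), 0.0, None)), 0.0, 1.0)
            ecb_glut = e_sp.copy()
            if nb:
                e_de = np.clip(nsig(dca_d), 0.0, 1.0)
                ecb_glut[pair] = e_sp[pair] * (1.0 - p.cross) + e_de * p.cross
                ecb_gaba = e_de * (1.0 - p.cross) + e_sp[pair] * p.cross
            else:
                ecb_gaba = np.empty(0)
            ecb_glut_last, ecb_gaba_last = ecb_glut, ecb_gaba

            # -- (2) Goodwin loops and CB1R counts; unbound = count minus
            # the cleft-domain eCB currently occupying receptors ---------
            unb = np.clip(cb1r_g - np.maximum(ecb_glut, trace_g_d), 0.0, 1.0)
            sig = 1.0 / (1.0 + np.exp(-gp.G_C * (unb * p.omega_unbound_gz - gp.G_D)))
            dGX = (gp.k1_glut / (K1 + GZ_g ** hill_n) - k2 * GX_g) / tg
            dGY = (k3 * GX_g - k4 * GY_g) / tg
            GZ_g += dt * ((k5 * sig - k6 * GZ_g) / tg)
            GX_g += dt * dGX
            GY_g += dt * dGY
            np.maximum(GX_g, 0.0, out=GX_g)
            np.maximum(GY_g, 0.0, out=GY_g)
            np.maximum(GZ_g, 0.0, out=GZ_g)
            cb1r_g = np.clip(GY_g * p.omega_gy_cb1r, 0.0, 1.0)

            if nb:
                unb_b = np.clip(cb1r_b - np.maximum(ecb_gaba, trace_b_d), 0.0, 1.0)
                sig_b = 1.0 / (1.0 + np.exp(-gp.G_C * (unb_b * p.omega_unbound_gz - gp.G_D)))
                dGX = (k1_b / (K1 + GZ_b ** hill_n) - k2 * GX_b) / tg
                dGY = (k3 * GX_b - k4 * GY_b) / tg
                GZ_b += dt * ((k5 * sig_b - k6 * GZ_b) / tg)
                GX_b += dt * dGX
                GY_b += dt * dGY
                np.maximum(GX_b, 0.0, out=GX_b)
                np.maximum(GY_b, 0.0, out=GY_b)
                np.maximum(GZ_b, 0.0, out=GZ_b)
                cb1r_b = np.clip(GY_b * p.omega_gy_cb1r, 0.0, 1.0)

            # -- (3) advance forms -----------------------------------------
            # available transmitter: recovery + suppression by occupied CB1R
            z_g = np.minimum(ecb_glut, cb1r_g)
            target = p.avail_max + p.tau_avail * z_g * p.phi_avail
            avail_g = target + (avail_g - target) * e_avail
            np.clip(avail_g, 0.0, p.avail_max, out=avail_g)

            # presynaptic CB1R activation trace (slow memory of eCB binding)
            er, ed, c = co_trace
            u = trace_g_r - z_g
            trace_g_d = z_g + (trace_g_d - z_g) * ed + u * c
            trace_g_r = z_g + u * er
            np.maximum(trace_g_d, 0.0, out=trace_g_d)

            if nb:
                z_b = np.minimum(ecb_gaba, cb1r_b)
                target = p.avail_max + p.tau_avail * z_b * p.phi_avail
                avail_b = target + (avail_b - target) * e_avail
                np.clip(avail_b, 0.0, p.avail_max, out=avail_b)

                old_trace_b = trace_b_d
                u = trace_b_r - z_b
                trace_b_d = z_b + (trace_b_d - z_b) * ed + u * c
                trace_b_r = z_b + u * er
                np.maximum(trace_b_d, 0.0, out=trace_b_d)

                # process X driven by the GABA bouton's CB1R activation
                xer, xed, xc = co_x
                xdrive = old_trace_b * p.omega_cb1r_x
                u = x_r - xdrive
                x_d = xdrive + (x_d - xdrive) * xed + u * xc
                x_r = xdrive + u * xer
                np.maximum(x_d, 0.0, out=x_d)

                # GABA Goodwin k1: recovery to ceiling + X-driven suppression
                target = p.k1_max + p.tau_k1 * x_d * p.phi_k1
                k1_b = target + (k1_b - target) * e_k1
                np.clip(k1_b, 0.0, p.k1_max, out=k1_b)

                er2, ed2, c2 = co_gabar
                u = gabar_r - gabar_dr
                gabar_d = gabar_dr + (gabar_d - gabar_dr) * ed2 + u * c2
                gabar_r = gabar_dr + u * er2
                er2, ed2, c2 = co_dca
                u = dca_r - dca_dr
                dca_d = dca_dr + (dca_d - dca_dr) * ed2 + u * c2
                dca_r = dca_dr + u * er2
                np.maximum(dca_d, 0.0, out=dca_d)
                dca_dr[:] = 0.0

            # spine receptor traces decay; calcium is driven by A'
            ca_drive = (ampar_d * np.maximum(p.omega_spine_vscc * n_ampar - 0.5, 0.0)
                        + nmdar_d * p.omega_nmdar_ca)
            er2, ed2, c2 = co_ampar
            u = ampar_r - ampar_dr
            ampar_d = ampar_dr + (ampar_d - ampar_dr) * ed2 + u * c2
            ampar_r = ampar_dr + u * er2
            er2, ed2, c2 = co_mglur5
            u = mglur5_r - mglur5_dr
            mglur5_d = mglur5_dr + (mglur5_d - mglur5_dr) * ed2 + u * c2
            mglur5_r = mglur5_dr + u * er2
            er2, ed2, c2 = co_nmdar
            u = nmdar_r - nmdar_dr
            nmdar_d = nmdar_dr + (nmdar_d - nmdar_dr) * ed2 + u * c2
            nmdar_r = nmdar_dr + u * er2
            nmdar_dr[:] = 0.0
            er2, ed2, c2 = co_ca
            u = ca_r - ca_drive
            ca_d = ca_drive + (ca_d - ca_drive) * ed2 + u * c2
            ca_r = ca_drive + u * er2
            np.maximum(ca_d, 0.0, out=ca_d)

            # NMDAR open probability tracks residual cleft glutamate
            p_drive = np.maximum(cleft_g - rel_step, 0.0)
            p_open = p_drive + (p_open - p_drive) * e_po
            np.clip(p_open, 0.0, 1.0, out=p_open)
            cleft_g *= e_cg
            if nb:
                cleft_b *= e_cb

            # -- neurons ----------------------------------------------------
            sumE = (ampar_d + nmdar_d).reshape(nn, cfg.spines_per_neuron).sum(axis=1)
            sumI = (np.bincount(neuron_b, weights=gabar_d, minlength=nn)
                    if nb else 0.0)
            drive = wE * sumE + gabar_sign * wI * sumI
            refr = (t_next - last_spike) < cfg.refractory
            V = drive + (V - drive) * e_m
            V[refr] = cfg.reset
            spiked = V >= cfg.threshold
            if spiked.any():
                V[spiked] = cfg.reset
                last_spike[spiked] = t_next
                for i in np.nonzero(spiked)[0]:
                    neuron_spikes[i].append(t_next)
                sg = spiked[self.neuron_of_glut]
                nmdar_dr[:] = sg * p_open * p.omega_nmdar
                if nb:
                    sb = spiked[neuron_b]
                    dca_dr[:] = sb * p.omega_dend_vscc

            if (step + 1) % stride == 0:
                sample(row)
                row += 1

        glut_meta = pd.DataFrame({
            "synapse_id": np.arange(ng),
            "neuron": self.neuron_of_glut,
            "channel": self.exc_channel,
            "rate_hz": self.glut_rates,
            "n_ampar": self.init_n_ampar,
            "has_gaba": self.has_gaba,
        })
        gaba_meta = pd.DataFrame({
            "synapse_id": np.arange(nb),
            "glut_synapse_id": self.pair_idx,
            "neuron": self.neuron_of_gaba,
            "channel": self.inh_channel,
            "rate_hz": self.gaba_rates,
            "n_gabar": self.init_n_gabar,
        })
        spike_log = (pd.DataFrame(spike_rows,
                                  columns=["time", "synapse_id", "kind", "released"])
                     if record_spikes else None)
        return SimulationResult(
            config=self.config,
            times=times,
            data=data,
            glut_meta=glut_meta,
            gaba_meta=gaba_meta,
            neuron_spikes=[np.asarray(s) for s in neuron_spikes],
            spike_log=spike_log,
        )


def build_network(config: NetworkConfig, rng_seed: Optional[int] = None) -> Network:
    """Build a network from a configuration (optionally overriding the seed)."""
    if rng_seed is not None:
        config = config.replace(seed=rng_seed)
    return Network(config)
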