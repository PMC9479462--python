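"""Result-generating analyses: excess neurotransmitter, steady-state timing,
synapse grouping, glutamate flux under perturbation, and the E/I sweep.

Excess neurotransmitter is the signed mismatch between what a bouton releases
and what the postsynaptic receptor population can bind; its per-synapse trace
is the primary readout of the eCB homeostat.  Flux experiments quantify the
metabolic burden of clearing glutamate released beyond the AMPAR population
after plasticity- or input-rate perturbations, and the E/I sweep measures
steady-state CB1R counts as the global excitation/inhibition balance shifts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .network import Network, NetworkConfig, PerturbationSpec, SimulationResult

__all__ = [
    "excess",
    "time_to_steady_state",
    "steady_state_summary",
    "classify_synapse_groups",
    "glutamate_flux",
    "flux_experiment",
    "ei_sweep",
    "SweepResult",
]

GROUP_LABELS = ("timely-strong", "timely-weak", "untimely-strong", "untimely-weak")


def excess(released, n_receptors):
    """Signed excess neurotransmitter: released amount minus receptor number.

    Positive means more transmitter was released than the receptor population
    can bind; negative means less.
    """
    return np.asarray(released, dtype=float) - np.asarray(n_receptors, dtype=float)


def time_to_steady_state(times, values, window: float = 5.0) -> float:
    """First time a trace enters the one-SD band of its final-window mean.

    The mean and standard deviation are taken over the final ``window``
    seconds; the steady-state time is the first sample time at which the
    trace falls inside the band [mean - SD, mean + SD].  First entry is the
    right reading for traces that approach their steady state monotonically
    (the regime the homeostat produces) and degrades gracefully to ~0 for
    stationary noise, where a stay-inside-forever rule would instead latch
    onto the last random excursion near the end of the trace.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.ndim != 1 or times.shape != values.shape:
        raise ValueError("times and values must be aligned 1-D arrays")
    if times[-1] - times[0] <= window:
        raise ValueError("trace must be longer than the steady-state window")
    tail = times >= times[-1] - window + 1e-12
    mu = values[tail].mean()
    sd = values[tail].std()
    inside = np.abs(values - mu) <= sd + 1e-12
    idx = np.nonzero(inside)[0]
    if idx.size == 0:  # cannot happen: the final window brackets its own mean
        return float(times[-1])
    return float(times[idx[0]])


def steady_state_summary(result: SimulationResult, kind: str = "glut",
                         window: float = 5.0) -> pd.DataFrame:
    """Per-synapse time to steady state and steady-state excess.

    ``kind`` selects glutamatergic ("glut") or GABAergic ("gaba") boutons.
    """
    var = f"excess_{kind}"
    trace = result.var(var)
    times = result.times
    tail = times >= times[-1] - window + 1e-12
    mu = trace[tail].mean(axis=0)
    sd = trace[tail].std(axis=0)
    inside = np.abs(trace - mu) <= sd + 1e-12
    first = inside.argmax(axis=0)  # first entry into the final-window band
    never = ~inside.any(axis=0)
    tts = times[first]
    tts = np.where(never, times[-1], tts)
    meta = result.glut_meta if kind == "glut" else result.gaba_meta
    df = pd.DataFrame({
        "synapse_id": np.arange(trace.shape[1]),
        "time_to_steady": tts,
        "steady_excess": mu,
        "rate_hz": meta["rate_hz"].to_numpy(),
        "n_receptors": meta["n_ampar" if kind == "glut" else "n_gabar"].to_numpy(),
    })
    df["kind"] = kind
    return df


def classify_synapse_groups(summaries: pd.DataFrame) -> pd.DataFrame:
    """Label synapses by the median splits of timing and control strength.

    "Timely" synapses reach steady state no later than the median time;
    "strong" control means the absolute steady-state excess is at or below
    its median.  Ties fall on the low ("timely"/"strong") side.
    """
    if len(summaries) < 2:
        raise ValueError("need at least two synapses to form groups")
    df = summaries.copy()
    t_med = df["time_to_steady"].median()
    e_med = df["steady_excess"].abs().median()
    timely = df["time_to_steady"] <= t_med
    strong = df["steady_excess"].abs() <= e_med
    df["group"] = np.select(
        [timely & strong, timely & ~strong, ~timely & strong],
        ["timely-strong", "timely-weak", "untimely-strong"],
        default="untimely-weak",
    )
    return df


def glutamate_flux(amounts, times, t_perturb: float, t_steady: float) -> float:
    """Sum per-event amounts over the window (t_perturb, t_steady].

    The caller chooses the per-event quantity: raw released glutamate for
    total turnover, or the per-spike excess for the clearance burden.
    """
    if t_perturb >= t_steady:
        raise ValueError("t_perturb must precede t_steady")
    amounts = np.asarray(amounts, dtype=float)
    times = np.asarray(times, dtype=float)
    mask = (times > t_perturb) & (times <= t_steady)
    return float(amounts[mask].sum())


@dataclass
class FluxCondition:
    name: str
    perturbations: tuple


def flux_experiment(
    config: NetworkConfig,
    t_perturb: float,
    target_ids: Optional[Sequence[int]] = None,
    ltd_scale: float = 0.5,
    ltp_scale: float = 2.0,
    rate_scale: float = 2.0,
    window: float = 5.0,
) -> pd.DataFrame:
    """Matched-seed perturbation runs measuring per-synapse glutamate flux.

    Four conditions are simulated from the same seed: baseline (no
    perturbation), LTD (AMPAR number scaled down), LTP (scaled up), and LTD
    combined with an increased driving rate.  For each perturbed synapse the
    flux is the excess glutamate released (per-spike ``max(released -
    #AMPAR, 0)``) accumulated from the perturbation to the synapse's new
    steady state, found by the one-SD criterion on the post-perturbation
    excess trace; windows that never re-settle are truncated at the end of
    the run and flagged.  Total released glutamate over the same window is
    reported alongside as a cross-check estimator.
    """
    if config.duration - t_perturb <= window:
        raise ValueError(
            "the post-perturbation segment must be longer than the "
            f"steady-state window ({window} s); increase duration or move "
            "t_perturb earlier"
        )
    net = Network(config)
    ng = config.n_glut_synapses
    # default: perturb a quarter of the glutamatergic synapses so the rest of
    # the network provides an unperturbed context
    ids = (tuple(range(0, ng, 4)) if target_ids is None
           else tuple(int(i) for i in target_ids))
    conditions = [
        FluxCondition("baseline", ()),
        FluxCondition("ltd", (PerturbationSpec(t_perturb, ids, n_ampar_scale=ltd_scale),)),
        FluxCondition("ltp", (PerturbationSpec(t_perturb, ids, n_ampar_scale=ltp_scale),)),
        FluxCondition("ltd_rate_up", (
            PerturbationSpec(t_perturb, ids, n_ampar_scale=ltd_scale,
                             rate_scale=rate_scale),
        )),
    ]
    rows = []
    for cond in conditions:
        res = net.run(perturbations=cond.perturbations)
        times = res.times
        seg = times >= t_perturb
        exc_tr = res.var("excess_glut")[:, ids]
        cum_ex = res.var("cum_excess_release_glut")[:, ids]
        cum_tot = res.var("cum_release_glut")[:, ids]
        seg_times = times[seg]
        for j, sid in enumerate(ids):
            tts = time_to_steady_state(seg_times, exc_tr[seg, j], window=window)
            truncated = bool(np.isclose(tts, seg_times[-1]))
            flux_ex = float(np.interp(tts, times, cum_ex[:, j])
                            - np.interp(t_perturb, times, cum_ex[:, j]))
            flux_tot = float(np.interp(tts, times, cum_tot[:, j])
                             - np.interp(t_perturb, times, cum_tot[:, j]))
            rows.append({
                "condition": cond.name,
                "synapse_id": sid,
                "t_steady": tts,
                "flux_excess": flux_ex,
                "flux_total": flux_tot,
                "truncated": truncated,
            })
    return pd.DataFrame(rows)


@dataclass
class SweepResult:
    """Steady-state CB1R counts across a grid of global E/I weights."""

    table: pd.DataFrame  # one row per grid point

    def percentages(self) -> pd.DataFrame:
        return self.table[["exc_weight", "inh_weight", "ei_ratio",
                           "glut_cb1r_pct", "gaba_cb1r_pct"]]


def ei_sweep(
    base_config: NetworkConfig,
    exc_weights: Sequence[float],
    inh_weights: Sequence[float] = (1.0,),
    window: float = 5.0,
) -> SweepResult:
    """Run the network over a grid of global E/I weights.

    For every (excitatory, inhibitory) weight pair the model is run to its
    horizon, the final-window mean CB1R count is averaged over glutamatergic
    and GABAergic boutons separately, and each class is expressed as a
    percentage of its maximum across the grid.
    """
    exc_weights = list(exc_weights)
    inh_weights = list(inh_weights)
    if not exc_weights or not inh_weights:
        raise ValueError("weight lists must be non-empty")
    if min(exc_weights) <= 0 or min(inh_weights) <= 0:
        raise ValueError("global weights must be positive")
    rows = []
    for wi in inh_weights:
        for we in exc_weights:
            cfg = base_config.replace(global_exc_weight=we, global_inh_weight=wi)
            res = Network(cfg).run(record_vars=("cb1r_glut", "cb1r_gaba"))
            rows.append({
                "exc_weight": we,
                "inh_weight": wi,
                "ei_ratio": we / wi,
                "glut_cb1r_mean": float(res.final_window_mean("cb1r_glut", window).mean()),
                "gaba_cb1r_mean": float(res.final_window_mean("cb1r_gaba", window).mean()),
            })
    table = pd.DataFrame(rows)
    for cls in ("glut", "gaba"):
        m = table[f"{cls}_cb1r_mean"].max()
        table[f"{cls}_cb1r_pct"] = 100.0 * table[f"{cls}_cb1r_mean"] / (m if m > 0 else 1.0)
    return SweepResult(table=table)
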