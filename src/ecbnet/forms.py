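"""Canonical one- and two-state dynamical primitives.

Every component of the synapse model is one of four forms:

* **alpha form** -- a bi-exponential rise/decay cascade,
  ``tau_rise * da'/dt = -a' + I`` and ``tau_decay * da/dt = -a + a'``,
  used for receptor activation traces, calcium transients, presynaptic CB1R
  activation and process X.  Spike inputs are delivered as impulses that
  increment the rise state; sustained inputs enter as the drive ``I``.
* **recovery form** -- first-order relaxation to a ceiling,
  ``tau * dv/dt = v_max - v``.
* **adaptation form** -- a constant-rate drift ``dv/dt = Z * phi``; where a
  component carries both recovery and adaptation (available transmitter, the
  GABA Goodwin k1) the two rates are summed into one linear ODE.
* **leaky accumulator** -- ``tau * dv/dt = -v + I``, used for cleft
  transmitter levels and the NMDAR open probability.

All updates are the exact exponential solution of the (affine) ODE for a
drive held constant over the step, so the default 1 ms step is accurate even
for the fastest time constants.  Bounds are enforced by projection (clamping)
after each step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "AlphaState",
    "RecoveryAdaptState",
    "LeakyAccumulatorState",
    "step_alpha",
    "kick_alpha",
    "step_recovery_adapt",
    "step_leaky",
    "alpha_coefficients",
    "alpha_advance",
    "recovery_adapt_advance",
    "leaky_advance",
]


# ---------------------------------------------------------------------------
# low-level array kernels (shared by the scalar API and the network engine)
# ---------------------------------------------------------------------------

def alpha_coefficients(tau_rise: float, tau_decay: float, dt: float):
    """Precompute the exact-update coefficients for the alpha cascade.

    Returns ``(er, ed, c)`` such that, with deviations ``u = rise - I`` and
    ``v = decay - I`` from the common fixed point ``I``::

        u(t+dt) = u * er
        v(t+dt) = v * ed + u * c

    For distinct time constants ``c = tau_rise * (er - ed) / (tau_rise -
    tau_decay)``; the equal-tau limit is handled separately.
    """
    if tau_rise <= 0 or tau_decay <= 0:
        raise ValueError("alpha form time constants must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    er = math.exp(-dt / tau_rise)
    ed = math.exp(-dt / tau_decay)
    if math.isclose(tau_rise, tau_decay, rel_tol=1e-12):
        c = (dt / tau_decay) * ed
    else:
        c = tau_rise * (er - ed) / (tau_rise - tau_decay)
    return er, ed, c


def alpha_advance(rise, decay, drive, er, ed, c):
    """Advance the alpha cascade one step using precomputed coefficients."""
    u = rise - drive
    v = decay - drive
    new_rise = drive + u * er
    new_decay = drive + v * ed + u * c
    return new_rise, new_decay


def recovery_adapt_advance(value, z, phi, tau, vmax, dt):
    """Exact step of ``dv/dt = (vmax - v)/tau + z*phi`` for constant z."""
    target = vmax + tau * z * phi
    return target + (value - target) * math.exp(-dt / tau)


def leaky_advance(value, drive, tau, dt):
    """Exact step of ``tau * dv/dt = -v + I`` for constant drive."""
    decay = math.exp(-dt / tau)
    return drive + (value - drive) * decay


def _clamp(x, lo, hi):
    return np.clip(x, lo, hi)


# ---------------------------------------------------------------------------
# scalar state containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlphaState:
    """Two-state bi-exponential trace (rise current feeding a decay current)."""

    rise_value: float = 0.0
    decay_value: float = 0.0
    tau_rise: float = 1.0
    tau_decay: float = 1.0
    lower_bound: float = 0.0
    upper_bound: float = math.inf

    def __post_init__(self):
        if self.tau_rise <= 0 or self.tau_decay <= 0:
            raise ValueError("alpha form time constants must be positive")


@dataclass(frozen=True)
class RecoveryAdaptState:
    """Value relaxing to ``max_value`` with an additive adaptation drift.

    ``adapt_rate_phi`` is in a.u. per second per unit of the adaptation
    signal Z; the combined rate is ``(max_value - v)/tau + Z*phi``.
    """

    value: float = 0.0
    tau: float = 1.0
    max_value: float = 1.0
    adapt_rate_phi: float = 0.0
    lower_bound: float = 0.0
    upper_bound: float = math.inf

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("recovery form tau must be positive")
        if self.max_value > self.upper_bound:
            raise ValueError("max_value must not exceed upper_bound")


@dataclass(frozen=True)
class LeakyAccumulatorState:
    """Leaky integrator ``tau * dv/dt = -v + I``."""

    value: float = 0.0
    tau: float = 1.0
    lower_bound: float = 0.0
    upper_bound: float = math.inf

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("leaky form tau must be positive")


# ---------------------------------------------------------------------------
# steppers
# ---------------------------------------------------------------------------

def step_alpha(state: AlphaState, drive: float, dt: float) -> AlphaState:
    """Advance an alpha form one step under a sustained drive ``I``.

    The drive is held constant over the step and both stages are advanced
    with the exact matrix-exponential update; the output (decay) state is
    clamped to the form's bounds.
    """
    er, ed, c = alpha_coefficients(state.tau_rise, state.tau_decay, dt)
    rise, decay = alpha_advance(state.rise_value, state.decay_value, drive, er, ed, c)
    decay = float(_clamp(decay, state.lower_bound, state.upper_bound))
    return replace(state, rise_value=float(rise), decay_value=decay)


def kick_alpha(state: AlphaState, amount: float) -> AlphaState:
    """Deliver a spike impulse: increment the rise state by ``amount``."""
    return replace(state, rise_value=state.rise_value + amount)


def step_recovery_adapt(state: RecoveryAdaptState, Z: float, dt: float) -> RecoveryAdaptState:
    """Advance a recovery+adaptation form one step for constant Z."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    v = recovery_adapt_advance(
        state.value, Z, state.adapt_rate_phi, state.tau, state.max_value, dt
    )
    v = float(_clamp(v, state.lower_bound, state.upper_bound))
    return replace(state, value=v)


def step_leaky(state: LeakyAccumulatorState, drive: float, dt: float) -> LeakyAccumulatorState:
    """Advance a leaky accumulator one step for constant drive."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    v = leaky_advance(state.value, drive, state.tau, dt)
    v = float(_clamp(v, state.lower_bound, state.upper_bound))
    return replace(state, value=v)
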