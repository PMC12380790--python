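"""Tsodyks-Markram short-term synaptic plasticity.

Each synapse tracks a utilization fraction u (resources ready to release)
and an available-resource fraction x.  Between presynaptic spikes both relax
exponentially (u -> 0 with tau_f, x -> 1 with tau_d) and the postsynaptic
current I decays with tau_s.  An arriving spike triggers, in order:

    u+ = u- + U (1 - u-)          (facilitation jump)
    dI = A u+ x-                  (released current)
    x+ = x- (1 - u+)              (resource depletion)

Facilitating, depressing and pseudo-linear behaviour are all obtained from
the same equations by the (U, tau_f, tau_d) triplet.  Depressing synapses
transmit progressively less per spike as the presynaptic rate rises — the
synaptic-suppression mechanism by which high-frequency stimulation
functionally disconnects its target from the rest of the network.

Decay uses the exact exponential map per step (unconditionally stable and
analytically testable) rather than an Euler approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class TMState:
    """State vectors (any matching shape): u, x in [0, 1], PSC i_psc."""

    u: np.ndarray
    x: np.ndarray
    i_psc: np.ndarray

    def copy(self) -> "TMState":
        return TMState(self.u.copy(), self.x.copy(), self.i_psc.copy())


def tm_init(shape) -> TMState:
    """Fully recovered, silent state: u = 0, x = 1, I = 0."""
    return TMState(u=np.zeros(shape), x=np.ones(shape), i_psc=np.zeros(shape))


def tm_decay(state: TMState, params, dt: float, factors=None) -> TMState:
    """One step of spike-free relaxation (exact exponentials), in place.

    ``params`` supplies tau_f, tau_d, tau_s as scalars or arrays
    broadcastable to the state shape.  ``factors`` may carry precomputed
    ``(e^-dt/tau_f, e^-dt/tau_d, e^-dt/tau_s)`` to avoid recomputing the
    exponentials in per-step loops.
    """
    if factors is not None:
        ef, ed, es = factors
    else:
        ef = np.exp(-dt / np.asarray(params.tau_f, dtype=float))
        ed = np.exp(-dt / np.asarray(params.tau_d, dtype=float))
        es = np.exp(-dt / np.asarray(params.tau_s, dtype=float))
    state.u *= ef
    state.x += (1.0 - state.x) * (1.0 - ed)
    state.i_psc *= es
    return state


def tm_spike_update(state: TMState, params, spike_mask) -> TMState:
    """Apply the spike-triggered jumps to the flagged synapses, in place.

    ``spike_mask`` marks presynaptic spikes arriving this step (boolean,
    broadcastable to the state shape).  ΔI uses the post-jump u and the
    pre-jump x, per the standard jump ordering.
    """
    m = np.asarray(spike_mask, dtype=bool)
    if not m.any():
        return state
    U = np.broadcast_to(np.asarray(params.U, dtype=float), state.u.shape)
    A = np.broadcast_to(np.asarray(params.A, dtype=float), state.u.shape)
    m = np.broadcast_to(m, state.u.shape)
    u_plus = state.u + U * (1.0 - state.u)
    delta_i = A * u_plus * state.x
    state.i_psc = np.where(m, state.i_psc + delta_i, state.i_psc)
    state.x = np.where(m, state.x * (1.0 - u_plus), state.x)
    state.u = np.where(m, u_plus, state.u)
    return state


def tm_steady_state(params, rate_hz: float):
    """Closed-form fixed point of the spike-to-spike map under periodic drive.

    For inter-spike period T = 1000 / rate_hz ms:

        u_ss = U / (1 - (1 - U) e^(-T/tau_f))                (post-jump)
        x_ss = (1 - e^(-T/tau_d)) / (1 - (1 - u_ss) e^(-T/tau_d))   (pre-jump)
        amplitude_ss = A u_ss x_ss

    This is the analytic oracle for periodic-drive simulations; for
    depressing parameters amplitude_ss decreases with rate, quantifying
    synaptic suppression at high stimulation frequencies.
    """
    if rate_hz <= 0:
        raise ValueError("rate_hz must be > 0")
    T = 1000.0 / rate_hz
    U = np.asarray(params.U, dtype=float)
    ef = np.exp(-T / np.asarray(params.tau_f, dtype=float))
    ed = np.exp(-T / np.asarray(params.tau_d, dtype=float))
    u_ss = U / (1.0 - (1.0 - U) * ef)
    x_ss = (1.0 - ed) / (1.0 - (1.0 - u_ss) * ed)
    amplitude = np.asarray(params.A, dtype=float) * u_ss * x_ss
    return u_ss, x_ss, amplitude


def aggregate_psc(weights, class_psc):
    """Weighted PSC summation over source structures and source neurons.

    ``weights`` and ``class_psc`` are parallel sequences: for each source
    projection, a dense (n_post, n_pre) weight matrix and the (delayed)
    per-source-neuron PSC vector of length n_pre.  Returns the per-neuron
    synaptic input current, linear in both weights and PSCs.
    """
    total = None
    for w, p in zip(weights, class_psc, strict=True):
        w = np.asarray(w, dtype=float)
        p = np.asarray(p, dtype=float)
        if w.ndim != 2 or p.ndim != 1 or w.shape[1] != p.shape[0]:
            raise ValueError(f"shape mismatch: weights {w.shape} vs psc {p.shape}")
        contrib = w @ p
        total = contrib if total is None else total + contrib
    if total is None:
        raise ValueError("no projections given")
    return total
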