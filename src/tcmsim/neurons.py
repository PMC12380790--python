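"""Izhikevich neuron dynamics: drift, noisy Euler stepping, reset, populations.

The membrane equation is the standard quadratic Izhikevich form

    dv/dt = 0.04 v^2 + 5 v - u + 140 + I
    du/dt = a (b v - u)

with a discontinuous reset when v crosses a (noisy) peak threshold:
v -> c, u -> u + d.  Gaussian membrane noise xi(t) is added to v once per
step; the threshold comparison uses an independent Gaussian perturbation
zeta drawn per neuron per step (v >= v_peak + zeta).

Two noise conventions are supported.  ``per_step`` adds N(0, sigma) directly
each step — the historically used form in which the noise term is *not*
multiplied by dt; its effective strength depends on dt.  ``sqrt_dt`` (the
default) scales the increment by sqrt(dt), the Euler-Maruyama form whose
ensemble variance grows as sigma^2 * t independently of the step size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class NumericalBlowupError(RuntimeError):
    """State became non-finite during integration."""

    def __init__(self, step: int, detail: str = ""):
        self.step = step
        super().__init__(f"non-finite neuron state at step {step}{detail}")


@dataclass
class NeuronState:
    v: np.ndarray   # membrane voltage, mV
    u: np.ndarray   # recovery variable

    def copy(self) -> "NeuronState":
        return NeuronState(self.v.copy(), self.u.copy())


@dataclass
class NeuronArrays:
    """Per-neuron Izhikevich parameters for one population (or the whole
    network when concatenated)."""

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    d: np.ndarray
    v_peak: np.ndarray
    bias: np.ndarray

    @property
    def n(self) -> int:
        return self.a.shape[0]


def izhikevich_drift(v, u, i_total, b):
    """Instantaneous (dv/dt, du/dt) of the quadratic Izhikevich model.

    Pure function; ``i_total`` is the summed input current (bias + synaptic
    + background + stimulation).  du/dt needs ``a`` only as a scale factor,
    so it is returned unscaled as (b*v - u); callers multiply by ``a``.
    """
    v = np.asarray(v, dtype=float)
    u = np.asarray(u, dtype=float)
    i_total = np.asarray(i_total, dtype=float)
    if v.shape != u.shape or (i_total.shape not in ((), v.shape)):
        raise ValueError(f"shape mismatch: v {v.shape}, u {u.shape}, I {i_total.shape}")
    dv = 0.04 * v * v + 5.0 * v - u + 140.0 + i_total
    du = np.asarray(b, dtype=float) * v - u
    return dv, du


def step_neurons(state: NeuronState, i_total, params: NeuronArrays,
                 dt: float, rng: np.random.Generator, *,
                 rng_theta: np.random.Generator | None = None,
                 sigma_v: float = 0.0, sigma_theta: float = 0.0,
                 noise_mode: str = "sqrt_dt", drift: bool = True,
                 check_finite: bool = False, step: int = -1):
    """Advance all neurons one explicit-Euler step; detect and apply resets.

    Returns ``(spike_mask, v_record)`` and mutates ``state`` in place.
    ``v_record`` is the voltage clamped to v_peak for spiking neurons — the
    conventional value to store in traces so spikes have uniform height.
    ``drift=False`` freezes the deterministic part (noise-only integration),
    used to verify the stochastic integrator in isolation.

    Exactly two RNG draws of size n are consumed per call (membrane noise,
    then threshold noise) regardless of sigma values, so noise streams stay
    aligned when one source is switched off.
    """
    v, u = state.v, state.u
    n = v.shape[0]
    xi = rng.standard_normal(n)
    zeta = (rng_theta if rng_theta is not None else rng).standard_normal(n)
    if drift:
        dv = 0.04 * v * v + 5.0 * v - u + 140.0 + i_total
        du = params.a * (params.b * v - u)
        v = v + dt * dv
        u = u + dt * du
    if sigma_v > 0.0:
        scale = sigma_v * np.sqrt(dt) if noise_mode == "sqrt_dt" else sigma_v
        v = v + scale * xi
    spike = v >= params.v_peak + sigma_theta * zeta
    v_record = np.where(spike, params.v_peak, v)
    if np.any(spike):
        v = np.where(spike, params.c, v)
        u = np.where(spike, u + params.d, u)
    state.v, state.u = v, u
    if check_finite and not (np.all(np.isfinite(v)) and np.all(np.isfinite(u))):
        raise NumericalBlowupError(step)
    return spike, v_record


def make_population(n_neurons: int, archetype, heterogeneity_scale: float,
                    excitatory: bool, bias_current: float,
                    rng: np.random.Generator):
    """Realize per-neuron parameter arrays and the initial state.

    Heterogeneity follows the standard Izhikevich randomization, scaled by
    ``heterogeneity_scale`` (s): excitatory cells get c += 15 s r^2,
    d -= 6 s r^2; inhibitory cells get a += 0.08 s r, b -= 0.05 s r, with
    r ~ U(0,1) per neuron.  s = 0 yields identical neurons.  Initial
    conditions are v0 = c, u0 = b * v0.  ``n_neurons = 0`` produces empty
    (but valid) arrays — a deactivated population.
    """
    if n_neurons < 0:
        raise ValueError("n_neurons must be >= 0")
    r = rng.random(n_neurons)
    s = heterogeneity_scale
    a = np.full(n_neurons, archetype.a)
    b = np.full(n_neurons, archetype.b)
    c = np.full(n_neurons, archetype.c)
    d = np.full(n_neurons, archetype.d)
    if excitatory:
        c = c + 15.0 * s * r * r
        d = d - 6.0 * s * r * r
    else:
        a = a + 0.08 * s * r
        b = b - 0.05 * s * r
    params = NeuronArrays(
        a=a, b=b, c=c, d=d,
        v_peak=np.full(n_neurons, archetype.v_peak),
        bias=np.full(n_neurons, float(bias_current)),
    )
    v0 = c.copy()
    state = NeuronState(v=v0, u=b * v0)
    return params, state
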