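"""Naive per-neuron, per-synapse-pair reference engine.

An independent, deliberately un-optimized implementation of the same model
used to validate the vectorized engine: Tsodyks-Markram state is kept for
every individual (presynaptic, postsynaptic) pair and synapse class, the
spike train driving each projection is explicitly delay-shifted at the
synapse (rather than at PSC read-out), synaptic input is accumulated with
explicit per-neuron dot products, and the membrane update runs as a scalar
loop over neurons.  Noise is drawn from the same named substreams in the
same order as the vectorized engine, so the two implementations see
identical random numbers and must produce identical spike trains (state
trajectories agree to floating-point summation-order differences).

Intended for small networks and oracle tests only; cost grows with the
number of synapse pairs.
"""

from __future__ import annotations

import numpy as np

from .config import STRUCTURES, SimulationConfig
from .network import build_network, rng_streams
from .stimulus import dbs_waveform


def simulate_reference(cfg: SimulationConfig):
    """Run the model with the naive engine.

    Returns a dict with ``spike_ids``, ``spike_times_ms`` (time-sorted, ids
    ascending within a step), and the full voltage history ``v`` of shape
    (n_steps, n_neurons) with spikes clamped to v_peak.
    """
    streams = rng_streams(cfg.seed)
    net = build_network(cfg, streams)
    rng_mem, rng_theta = streams["membrane"], streams["threshold"]
    rng_bg = streams["background"]

    n = net.n_total
    n_steps = int(round(cfg.duration_s * 1000.0 / cfg.dt_ms))
    dt = cfg.dt_ms
    noise = cfg.noise

    v = net.init_state.v.copy()
    u = net.init_state.u.copy()
    pars = net.params

    # Per-pair TM state: (src, dst) -> dict of (3, n_dst, n_src) arrays.
    tm_u, tm_x, tm_i = {}, {}, {}
    ef, ed, es = {}, {}, {}
    for (src, dst) in net.weights:
        n_src, n_dst = net.sizes[src], net.sizes[dst]
        shape = (3, n_dst, n_src)
        tm_u[(src, dst)] = np.zeros(shape)
        tm_x[(src, dst)] = np.ones(shape)
        tm_i[(src, dst)] = np.zeros(shape)
        sl = net.slices[src]
        # class params are per presynaptic neuron; broadcast over dst rows
        ef[(src, dst)] = np.exp(-dt / net.tm_params.tau_f[:, sl])[:, None, :]
        ed[(src, dst)] = np.exp(-dt / net.tm_params.tau_d[:, sl])[:, None, :]
        es[(src, dst)] = np.exp(-dt / net.tm_params.tau_s[:, sl])[:, None, :]

    wave = dbs_waveform(cfg.dbs, cfg.duration_s, cfg.dt_ms)
    target = STRUCTURES[cfg.dbs.target_structure - 1]
    spike_history: list = []          # boolean (n,) per step
    out_ids, out_steps = [], []
    v_hist = np.empty((n_steps, n))

    for step in range(n_steps):
        # (1) advance each projection's pair state to step - delay and read PSC
        i_syn = np.zeros(n)
        for (src, dst), w in net.weights.items():
            d = max(net.delays_steps[(src, dst)], 1)  # delay 0: one-step latency
            s_past = step - d
            if s_past >= 0:
                tm_u[(src, dst)] *= ef[(src, dst)]
                tm_x[(src, dst)] += (1.0 - tm_x[(src, dst)]) * (1.0 - ed[(src, dst)])
                tm_i[(src, dst)] *= es[(src, dst)]
                pre = spike_history[s_past][net.slices[src]]
                if pre.any():
                    sl = net.slices[src]
                    U = net.tm_params.U[:, sl][:, None, :]
                    A = net.tm_params.A[:, sl][:, None, :]
                    m = np.broadcast_to(pre[None, None, :], tm_u[(src, dst)].shape)
                    u_plus = tm_u[(src, dst)] + U * (1.0 - tm_u[(src, dst)])
                    delta = A * u_plus * tm_x[(src, dst)]
                    tm_i[(src, dst)] = np.where(m, tm_i[(src, dst)] + delta,
                                                tm_i[(src, dst)])
                    tm_x[(src, dst)] = np.where(m, tm_x[(src, dst)] * (1.0 - u_plus),
                                                tm_x[(src, dst)])
                    tm_u[(src, dst)] = np.where(m, u_plus, tm_u[(src, dst)])
            mix = net.mixes[(src, dst)]
            psc = (mix[0] * tm_i[(src, dst)][0] + mix[1] * tm_i[(src, dst)][1]
                   + mix[2] * tm_i[(src, dst)][2])      # (n_dst, n_src)
            dst_sl = net.slices[dst]
            for row, gid in enumerate(range(dst_sl.start, dst_sl.stop)):
                i_syn[gid] += float(np.dot(w[row], psc[row]))

        # (2) bias + background + DBS
        i_total = pars.bias + i_syn
        if noise.background_enabled and noise.background_rate_hz > 0:
            p = noise.background_rate_hz * dt / 1000.0
            ev = rng_bg.random(n) < p
            i_total = i_total + noise.background_amplitude * ev
        if step < wave.shape[0] and wave[step] != 0.0 and target in net.slices:
            i_total = i_total.copy()
            i_total[net.slices[target]] += wave[step]

        # (3) scalar membrane update, same draw order as the engine
        xi = rng_mem.standard_normal(n)
        zeta = rng_theta.standard_normal(n)
        if noise.membrane_noise_std > 0:
            scale = (noise.membrane_noise_std * np.sqrt(dt)
                     if noise.noise_mode == "sqrt_dt" else noise.membrane_noise_std)
        else:
            scale = 0.0
        spikes = np.zeros(n, dtype=bool)
        for i in range(n):
            vi, ui = v[i], u[i]
            dv = 0.04 * vi * vi + 5.0 * vi - ui + 140.0 + i_total[i]
            du = pars.a[i] * (pars.b[i] * vi - ui)
            vi = vi + dt * dv
            ui = ui + dt * du
            if scale != 0.0:
                vi = vi + scale * xi[i]
            if vi >= pars.v_peak[i] + noise.threshold_noise_std * zeta[i]:
                spikes[i] = True
                v_hist[step, i] = pars.v_peak[i]
                vi = pars.c[i]
                ui = ui + pars.d[i]
            else:
                v_hist[step, i] = vi
            v[i], u[i] = vi, ui

        spike_history.append(spikes)
        if spikes.any():
            ids = np.nonzero(spikes)[0]
            out_ids.append(ids)
            out_steps.append(np.full(ids.shape[0], step))

    ids = np.concatenate(out_ids) if out_ids else np.empty(0, dtype=int)
    steps = np.concatenate(out_steps) if out_steps else np.empty(0, dtype=int)
    return {"spike_ids": ids, "spike_times_ms": (steps + 1) * dt, "v": v_hist}
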