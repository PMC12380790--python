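"""Assemble the six-population network from a validated configuration.

Connectivity is all-to-all between every ordered structure pair with a
non-zero gain: each individual weight is gain(src->dst) / N_src scaled by a
uniform jitter factor (1 + jitter * eta), eta ~ U(-1, 1).  Division by the
presynaptic count keeps total input magnitudes invariant under population
resizing.  Neuron self-loops are excluded; weights inherit the sign of the
source gain (>= 0 excitatory, <= 0 inhibitory).  Conduction delays are
rounded to an integer number of time steps.

Randomness is drawn from named substreams of the master seed (weights,
heterogeneity, membrane, threshold, background) so that toggling one noise
source never shifts the draws of another.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np

from .config import (EXCITATORY, STRUCTURES, SYNAPSE_CLASSES, SimulationConfig,
                     validate_config)
from .neurons import NeuronArrays, NeuronState, make_population

#: Fixed substream order off the master seed.
STREAM_NAMES = ("weights", "heterogeneity", "membrane", "threshold", "background")


def rng_streams(seed: int) -> dict:
    """Named, independent `numpy` generators deterministically derived from
    one master seed."""
    children = np.random.SeedSequence(seed).spawn(len(STREAM_NAMES))
    return {name: np.random.default_rng(ss)
            for name, ss in zip(STREAM_NAMES, children)}


@dataclass
class TMClassParams:
    """Per-(class, presynaptic neuron) TM parameter arrays, shape (3, n).

    ``A`` holds the *magnitude* of the absolute synaptic response; the sign
    of each connection is carried once, by the weight matrix.
    """

    U: np.ndarray
    tau_f: np.ndarray
    tau_d: np.ndarray
    tau_s: np.ndarray
    A: np.ndarray


@dataclass
class NetworkInstance:
    cfg: SimulationConfig
    names: list                      # live structure names, canonical order
    sizes: dict                      # name -> n_neurons (live only)
    slices: dict                     # name -> slice into the global arrays
    params: NeuronArrays             # global per-neuron Izhikevich parameters
    init_state: NeuronState
    structure_id: np.ndarray         # global per-neuron structure id (1..6)
    weights: dict                    # (src, dst) -> (n_dst, n_src) matrix
    delays_steps: dict               # (src, dst) -> int >= 0
    mixes: dict                      # (src, dst) -> (3,) class fractions
    tm_params: TMClassParams         # per presynaptic neuron, shape (3, n)
    excitatory_mask: np.ndarray      # global per-neuron bool

    @property
    def n_total(self) -> int:
        return self.params.n

    @property
    def max_delay_steps(self) -> int:
        return max(self.delays_steps.values(), default=0)

    def neuron_index(self, global_id: int):
        """Map a global neuron id to (structure name, local index)."""
        for name in self.names:
            sl = self.slices[name]
            if sl.start <= global_id < sl.stop:
                return name, global_id - sl.start
        raise KeyError(f"global id {global_id} out of range")

    def global_id(self, name: str, local: int) -> int:
        sl = self.slices[name]
        if not 0 <= local < sl.stop - sl.start:
            raise KeyError(f"local index {local} out of range for {name}")
        return sl.start + local


def build_network(cfg: SimulationConfig, streams=None) -> NetworkInstance:
    """Realize neurons, weights, delays and synapse parameter arrays.

    Deterministic given (cfg, cfg.seed).  Deactivated populations
    (n_neurons = 0) contribute no rows or columns anywhere.
    """
    violations = validate_config(cfg)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    if streams is None:
        streams = rng_streams(cfg.seed)
    rng_w = streams["weights"]
    rng_h = streams["heterogeneity"]

    pops = {p.name: p for p in cfg.populations}
    names = [s for s in STRUCTURES if pops[s].n_neurons > 0]
    sizes = {n: pops[n].n_neurons for n in names}

    # --- neurons -----------------------------------------------------------
    param_parts, state_parts, ids = [], [], []
    slices, offset = {}, 0
    for name in [s for s in STRUCTURES if s in names]:
        spec = pops[name]
        arch = cfg.neuron_params[spec.neuron_archetype]
        pa, st = make_population(spec.n_neurons, arch, arch.heterogeneity_scale,
                                 spec.excitatory, spec.bias_current, rng_h)
        param_parts.append(pa)
        state_parts.append(st)
        ids.append(np.full(spec.n_neurons, spec.structure_id))
        slices[name] = slice(offset, offset + spec.n_neurons)
        offset += spec.n_neurons

    def cat(attr):
        arrs = [getattr(p, attr) for p in param_parts]
        return np.concatenate(arrs) if arrs else np.empty(0)

    params = NeuronArrays(a=cat("a"), b=cat("b"), c=cat("c"), d=cat("d"),
                          v_peak=cat("v_peak"), bias=cat("bias"))
    init_state = NeuronState(
        v=np.concatenate([s.v for s in state_parts]) if state_parts else np.empty(0),
        u=np.concatenate([s.u for s in state_parts]) if state_parts else np.empty(0))
    structure_id = np.concatenate(ids) if ids else np.empty(0, dtype=int)
    exc_mask = np.concatenate(
        [np.full(sizes[n], EXCITATORY[n]) for n in names]
    ) if names else np.empty(0, dtype=bool)

    # --- weights, delays, mixes -------------------------------------------
    gain = cfg.connectivity.weight_gain
    delay = cfg.connectivity.delay_ms
    jitter = cfg.connectivity.weight_jitter
    weights, delays_steps, mixes = {}, {}, {}
    for si, src in enumerate(STRUCTURES):
        for di, dst in enumerate(STRUCTURES):
            if src not in names or dst not in names:
                continue
            g = gain[si][di]
            if g == 0.0:
                continue
            n_src, n_dst = sizes[src], sizes[dst]
            eta = rng_w.uniform(-1.0, 1.0, size=(n_dst, n_src))
            w = (g / n_src) * (1.0 + jitter * eta)
            if src == dst:
                np.fill_diagonal(w, 0.0)
            weights[(src, dst)] = w
            d_ms = delay[si][di]
            steps = int(round(d_ms / cfg.dt_ms))
            if abs(d_ms - steps * cfg.dt_ms) > 0.1 * cfg.dt_ms:
                warnings.warn(
                    f"delay {src}->{dst} = {d_ms} ms rounded to {steps} steps "
                    f"at dt = {cfg.dt_ms} ms", UserWarning, stacklevel=2)
            delays_steps[(src, dst)] = steps
            mixes[(src, dst)] = np.array([
                cfg.connectivity.synapse_mix[f"{src}->{dst}"][c]
                for c in SYNAPSE_CLASSES])

    # sign constraints, exhaustive
    for (src, _dst), w in weights.items():
        if EXCITATORY[src]:
            assert np.all(w >= 0.0), f"negative weight from excitatory {src}"
        else:
            assert np.all(w <= 0.0), f"positive weight from inhibitory {src}"

    # --- per-presynaptic-neuron TM class parameters ------------------------
    n_total = params.n
    shape = (len(SYNAPSE_CLASSES), n_total)
    tm = TMClassParams(U=np.empty(shape), tau_f=np.empty(shape),
                       tau_d=np.empty(shape), tau_s=np.empty(shape),
                       A=np.empty(shape))
    for name in names:
        suffix = "_exc" if EXCITATORY[name] else "_inh"
        sl = slices[name]
        for ci, cls in enumerate(SYNAPSE_CLASSES):
            sp = cfg.synapse_params[cls + suffix]
            tm.U[ci, sl] = sp.U
            tm.tau_f[ci, sl] = sp.tau_f
            tm.tau_d[ci, sl] = sp.tau_d
            tm.tau_s[ci, sl] = sp.tau_s
            tm.A[ci, sl] = abs(sp.A)

    return NetworkInstance(
        cfg=cfg, names=names, sizes=sizes, slices=slices, params=params,
        init_state=init_state, structure_id=structure_id, weights=weights,
        delays_steps=delays_steps, mixes=mixes, tm_params=tm,
        excitatory_mask=exc_mask)


def deactivate_population(cfg: SimulationConfig, name: str) -> SimulationConfig:
    """Return a copy of ``cfg`` with the named structure's size set to 0.

    The rebuilt network then has no neurons, weights or synapse states for
    that structure, and simulation proceeds without it.
    """
    if name not in STRUCTURES:
        raise KeyError(f"unknown structure {name!r}; expected one of {STRUCTURES}")
    out = copy.deepcopy(cfg)
    for p in out.populations:
        if p.name == name:
            p.n_neurons = 0
    return out


def network_summary(net: NetworkInstance) -> str:
    """Plain-text provenance dump: sizes, gains, delays."""
    lines = [f"total neurons: {net.n_total}"]
    for name in net.names:
        kind = "exc" if EXCITATORY[name] else "inh"
        lines.append(f"  {name:>3} ({kind}): {net.sizes[name]} neurons")
    lines.append("projections (gain/Nsrc mean weight, delay steps):")
    for (src, dst), w in sorted(net.weights.items()):
        lines.append(f"  {src:>3} -> {dst:<3}  mean_w={w.mean():+.5f}  "
                     f"delay={net.delays_steps[(src, dst)]}")
    return "\n".join(lines)
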