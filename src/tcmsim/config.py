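"""Model configuration: parameter schema, defaults, validation and (de)serialization.

The simulator is fully described by a :class:`SimulationConfig`: six neuronal
populations (three excitatory cortical layers S/M/D, cortical interneurons CI,
thalamo-cortical relay TCR and thalamic reticular nucleus TRN), per-archetype
Izhikevich neuron parameters, per-class Tsodyks-Markram synapse parameters,
a 6x6 connectivity gain/delay specification, noise sources, and a DBS pulse
protocol.  Units are mV and ms throughout, with currents on Izhikevich's
dimensionless scale.

Population sizes, noise levels and the stimulation protocol follow the
reference 540-neuron parkinsonian network (100 neurons per structure except
TRN with 40; 12 s runs, DBS onset at 6 s, membrane noise std 0.5, threshold
noise std 0.1, Poissonian background disabled).  Connectivity gains, delays
and the DBS pulse amplitude are documented stand-ins calibrated so that the
default network expresses beta-band synchronized activity and the
frequency-dependent response to stimulation; every value is overridable.
"""

from __future__ import annotations

import copy
import dataclasses
import hashlib
import math
import warnings
from dataclasses import dataclass, field
from typing import Any

import yaml

SCHEMA_VERSION = 1

#: Canonical structure order; structure_id j = index + 1.
STRUCTURES = ("S", "M", "D", "CI", "TRN", "TCR")

#: Which structures are excitatory (glutamatergic) vs inhibitory (GABAergic).
EXCITATORY = {"S": True, "M": True, "D": True, "CI": False, "TRN": False, "TCR": True}

SYNAPSE_CLASSES = ("facilitating", "depressing", "pseudo_linear")

DEFAULT_SIZES = {"S": 100, "M": 100, "D": 100, "CI": 100, "TRN": 40, "TCR": 100}


class ConfigFormatError(ValueError):
    """A config file/dict is structurally unreadable (missing or unknown keys,
    wrong types).  Distinct from semantic validation failures, which are
    reported as messages by :func:`validate_config`."""


@dataclass
class PopulationSpec:
    structure_id: int
    name: str
    n_neurons: int
    excitatory: bool
    neuron_archetype: str
    bias_current: float


@dataclass
class NeuronParams:
    """Izhikevich parameters for one archetype.

    ``heterogeneity_scale`` sets the magnitude of the standard per-neuron
    randomization (excitatory cells: c, d perturbed by r^2; inhibitory cells:
    a, b perturbed by r, r ~ U(0,1)); 0 gives identical neurons.
    """

    a: float
    b: float
    c: float
    d: float
    v_peak: float = 30.0
    heterogeneity_scale: float = 1.0


@dataclass
class SynapseParams:
    """Tsodyks-Markram parameters for one synapse class.

    U is the utilization increment per spike; tau_f/tau_d/tau_s (ms) are the
    recovery constants of u, x and the PSC; A is the absolute synaptic
    response, signed by the presynaptic type (>=0 excitatory, <=0 inhibitory).
    """

    U: float
    tau_f: float
    tau_d: float
    tau_s: float
    A: float


@dataclass
class ConnectivitySpec:
    weight_gain: list        # 6x6 nested list, [source][target], signed by source type
    delay_ms: list           # 6x6 nested list, [source][target], >= 0
    weight_jitter: float     # relative uniform spread of individual weights, [0, 1)
    synapse_mix: dict        # "SRC->DST" -> {class: fraction}, rows sum to 1


@dataclass
class NoiseSpec:
    membrane_noise_std: float = 0.5
    threshold_noise_std: float = 0.1
    noise_mode: str = "sqrt_dt"          # "per_step" or "sqrt_dt"
    background_rate_hz: float = 0.0
    background_amplitude: float = 1.0
    background_enabled: bool = False


@dataclass
class DBSProtocol:
    frequency_hz: float = 130.0
    amplitude: float = 100.0
    pulse_width_ms: float = 0.3
    onset_s: float = 6.0
    offset_s: float = 12.0
    target_structure: int = 3            # D
    biphasic: bool = False


@dataclass
class SimulationConfig:
    duration_s: float
    dt_ms: float
    seed: int
    populations: list
    neuron_params: dict                  # archetype -> NeuronParams
    synapse_params: dict                 # class name -> SynapseParams
    connectivity: ConnectivitySpec
    noise: NoiseSpec
    dbs: DBSProtocol
    record_traces: bool = False
    trace_stride: int = 10
    schema_version: int = SCHEMA_VERSION


# ---------------------------------------------------------------------------
# Defaults
# ---------------------------------------------------------------------------

#: Canonical Izhikevich archetypes used as documented placeholders for the
#: per-population parameters (regular spiking for the excitatory structures,
#: fast spiking for CI, low-threshold spiking for TRN).
ARCHETYPES = {
    "RS": NeuronParams(a=0.02, b=0.2, c=-65.0, d=8.0),
    "FS": NeuronParams(a=0.1, b=0.2, c=-65.0, d=2.0),
    "LTS": NeuronParams(a=0.02, b=0.25, c=-65.0, d=2.0),
}

_DEFAULT_ARCHETYPE = {
    "S": "RS", "M": "RS", "D": "RS", "CI": "FS", "TRN": "LTS", "TCR": "RS",
}

# Subthreshold bias currents: every archetype sits below its rheobase so the
# isolated network is silent without noise (RS/FS rheobase ~4, LTS ~1).
_DEFAULT_BIAS = {"S": 3.5, "M": 3.5, "D": 3.5, "CI": 3.5, "TRN": 0.8, "TCR": 3.5}

# Canonical cortical short-term-plasticity triplets (facilitating, depressing,
# pseudo-linear), PSC decay 3 ms at excitatory and 11 ms at inhibitory
# terminals.  A carries the sign of the presynaptic type.
_DEFAULT_SYNAPSES = {
    "facilitating_exc": SynapseParams(U=0.09, tau_f=138.0, tau_d=670.0, tau_s=3.0, A=1.0),
    "depressing_exc": SynapseParams(U=0.5, tau_f=17.0, tau_d=671.0, tau_s=3.0, A=1.0),
    "pseudo_linear_exc": SynapseParams(U=0.29, tau_f=33.0, tau_d=330.0, tau_s=3.0, A=1.0),
    "facilitating_inh": SynapseParams(U=0.09, tau_f=138.0, tau_d=670.0, tau_s=11.0, A=-1.0),
    "depressing_inh": SynapseParams(U=0.5, tau_f=17.0, tau_d=671.0, tau_s=11.0, A=-1.0),
    "pseudo_linear_inh": SynapseParams(U=0.29, tau_f=33.0, tau_d=330.0, tau_s=11.0, A=-1.0),
}

# Connectivity gains [source][target]; signed by source type; magnitudes are
# calibrated stand-ins (see module docstring).  Layer D is the hub: the
# cortico-thalamo-cortical loop (D <-> TCR, 8 ms each way) and the strong
# D -> S/M projections, shaped by the shared CI inhibition, generate and
# distribute the parkinsonian beta rhythm, so suppressing D's output
# synapses (high-frequency stimulation) desynchronizes the whole cortex.
_DEFAULT_GAIN = {
    "S":   {"S": 40.0, "M": 40.0, "D": 120.0, "CI": 120.0, "TRN": 0.0, "TCR": 0.0},
    "M":   {"S": 40.0, "M": 40.0, "D": 120.0, "CI": 120.0, "TRN": 0.0, "TCR": 0.0},
    "D":   {"S": 160.0, "M": 160.0, "D": 80.0, "CI": 120.0, "TRN": 120.0, "TCR": 200.0},
    "CI":  {"S": -240.0, "M": -240.0, "D": -240.0, "CI": -80.0, "TRN": 0.0, "TCR": 0.0},
    "TRN": {"S": 0.0, "M": 0.0, "D": 0.0, "CI": 0.0, "TRN": -60.0, "TCR": -240.0},
    "TCR": {"S": 80.0, "M": 80.0, "D": 200.0, "CI": 80.0, "TRN": 120.0, "TCR": 0.0},
}

_CORTICAL = ("S", "M", "D", "CI")


def _default_delay(src: str, dst: str) -> float:
    src_cortical = src in _CORTICAL
    dst_cortical = dst in _CORTICAL
    return 1.0 if src_cortical == dst_cortical else 8.0


# Synapse-class mixture per source type: excitatory projections are dominated
# by depressing synapses (the substrate of high-frequency synaptic
# suppression); inhibitory ones lean pseudo-linear.
_DEFAULT_MIX = {
    True: {"facilitating": 0.1, "depressing": 0.8, "pseudo_linear": 0.1},
    False: {"facilitating": 0.1, "depressing": 0.3, "pseudo_linear": 0.6},
}


def default_config(seed: int = 1) -> SimulationConfig:
    """The reference 540-neuron configuration: 12 s run, DBS (130 Hz by
    default) switched on at second 6 in layer D, membrane noise std 0.5,
    threshold noise std 0.1, Poissonian background disabled."""
    populations = []
    for idx, name in enumerate(STRUCTURES):
        populations.append(PopulationSpec(
            structure_id=idx + 1,
            name=name,
            n_neurons=DEFAULT_SIZES[name],
            excitatory=EXCITATORY[name],
            neuron_archetype=_DEFAULT_ARCHETYPE[name],
            bias_current=_DEFAULT_BIAS[name],
        ))
    gain = [[_DEFAULT_GAIN[s][d] for d in STRUCTURES] for s in STRUCTURES]
    delay = [[_default_delay(s, d) for d in STRUCTURES] for s in STRUCTURES]
    mix = {
        f"{s}->{d}": dict(_DEFAULT_MIX[EXCITATORY[s]])
        for s in STRUCTURES for d in STRUCTURES
    }
    return SimulationConfig(
        duration_s=12.0,
        dt_ms=0.1,
        seed=seed,
        populations=populations,
        neuron_params={k: copy.deepcopy(v) for k, v in ARCHETYPES.items()},
        synapse_params=copy.deepcopy(_DEFAULT_SYNAPSES),
        connectivity=ConnectivitySpec(
            weight_gain=gain,
            delay_ms=delay,
            weight_jitter=0.2,
            synapse_mix=mix,
        ),
        noise=NoiseSpec(),
        dbs=DBSProtocol(),
        record_traces=False,
    )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def _is_finite(x) -> bool:
    return isinstance(x, (int, float)) and math.isfinite(x)


def validate_config(cfg: SimulationConfig) -> list[str]:
    """Return one message per violated invariant; an empty list means valid.

    Never mutates ``cfg``.  A dt above 0.5 ms triggers a ``UserWarning`` (the
    quadratic membrane term can blow up under explicit Euler at large steps)
    but is not a hard violation.
    """
    v: list[str] = []

    names_seen = set()
    for p in cfg.populations:
        tag = f"population {p.name!r}"
        if p.name not in STRUCTURES:
            v.append(f"{tag}: unknown structure name")
            continue
        names_seen.add(p.name)
        expected_id = STRUCTURES.index(p.name) + 1
        if p.structure_id != expected_id:
            v.append(f"{tag}: structure_id {p.structure_id} != canonical {expected_id}")
        if not isinstance(p.n_neurons, int) or p.n_neurons < 0:
            v.append(f"{tag}: n_neurons must be a non-negative integer")
        if p.excitatory != EXCITATORY[p.name]:
            kind = "excitatory" if EXCITATORY[p.name] else "inhibitory"
            v.append(f"{tag}: must be {kind}")
        if p.neuron_archetype not in cfg.neuron_params:
            v.append(f"{tag}: undefined neuron_archetype {p.neuron_archetype!r}")
        if not _is_finite(p.bias_current):
            v.append(f"{tag}: bias_current must be finite")
    missing = set(STRUCTURES) - names_seen
    if missing:
        v.append(f"populations: missing structures {sorted(missing)}")

    for arch, np_ in cfg.neuron_params.items():
        tag = f"neuron_params[{arch!r}]"
        for fld in ("a", "b", "c", "d", "v_peak"):
            if not _is_finite(getattr(np_, fld)):
                v.append(f"{tag}: {fld} must be finite")
        if _is_finite(np_.a) and np_.a <= 0:
            v.append(f"{tag}: a must be > 0")
        if _is_finite(np_.v_peak) and _is_finite(np_.c) and np_.v_peak <= np_.c:
            v.append(f"{tag}: v_peak must exceed c")
        if not _is_finite(np_.heterogeneity_scale) or np_.heterogeneity_scale < 0:
            v.append(f"{tag}: heterogeneity_scale must be >= 0")

    for cls, sp in cfg.synapse_params.items():
        tag = f"synapse_params[{cls!r}]"
        if not (_is_finite(sp.U) and 0 < sp.U <= 1):
            v.append(f"{tag}: U must lie in (0, 1]")
        for fld in ("tau_f", "tau_d", "tau_s"):
            val = getattr(sp, fld)
            if not _is_finite(val) or val <= 0:
                v.append(f"{tag}: {fld} must be > 0")
        if not _is_finite(sp.A):
            v.append(f"{tag}: A must be finite")
        elif cls.endswith("_exc") and sp.A < 0:
            v.append(f"{tag}: A must be >= 0 for an excitatory class")
        elif cls.endswith("_inh") and sp.A > 0:
            v.append(f"{tag}: A must be <= 0 for an inhibitory class")

    conn = cfg.connectivity
    n = len(STRUCTURES)
    gain_ok = (isinstance(conn.weight_gain, list) and len(conn.weight_gain) == n
               and all(isinstance(r, list) and len(r) == n for r in conn.weight_gain))
    delay_ok = (isinstance(conn.delay_ms, list) and len(conn.delay_ms) == n
                and all(isinstance(r, list) and len(r) == n for r in conn.delay_ms))
    if not gain_ok:
        v.append("connectivity.weight_gain: must be a 6x6 matrix")
    if not delay_ok:
        v.append("connectivity.delay_ms: must be a 6x6 matrix")
    if gain_ok:
        for i, src in enumerate(STRUCTURES):
            for j, dst in enumerate(STRUCTURES):
                g = conn.weight_gain[i][j]
                if not _is_finite(g):
                    v.append(f"connectivity.weight_gain[{src}->{dst}]: must be finite")
                elif EXCITATORY[src] and g < 0:
                    v.append(f"connectivity.weight_gain[{src}->{dst}]: "
                             "excitatory-source gain must be >= 0")
                elif not EXCITATORY[src] and g > 0:
                    v.append(f"connectivity.weight_gain[{src}->{dst}]: "
                             "inhibitory-source gain must be <= 0")
    if delay_ok:
        for i, src in enumerate(STRUCTURES):
            for j, dst in enumerate(STRUCTURES):
                d = conn.delay_ms[i][j]
                if not _is_finite(d) or d < 0:
                    v.append(f"connectivity.delay_ms[{src}->{dst}]: must be >= 0")
    if not (_is_finite(conn.weight_jitter) and 0 <= conn.weight_jitter < 1):
        v.append("connectivity.weight_jitter: must lie in [0, 1)")
    expected_pairs = {f"{s}->{d}" for s in STRUCTURES for d in STRUCTURES}
    if set(conn.synapse_mix) != expected_pairs:
        v.append("connectivity.synapse_mix: must contain exactly the 36 "
                 "'SRC->DST' structure pairs")
    for pair, row in conn.synapse_mix.items():
        if set(row) != set(SYNAPSE_CLASSES):
            v.append(f"connectivity.synapse_mix[{pair!r}]: classes must be "
                     f"{sorted(SYNAPSE_CLASSES)}")
            continue
        total = sum(row.values())
        if any(frac < 0 for frac in row.values()) or abs(total - 1.0) > 1e-12:
            v.append(f"connectivity.synapse_mix[{pair!r}]: fractions must be "
                     f"non-negative and sum to 1 (got {total})")

    noise = cfg.noise
    if not (_is_finite(noise.membrane_noise_std) and noise.membrane_noise_std >= 0):
        v.append("noise.membrane_noise_std: must be >= 0")
    if not (_is_finite(noise.threshold_noise_std) and noise.threshold_noise_std >= 0):
        v.append("noise.threshold_noise_std: must be >= 0")
    if noise.noise_mode not in ("per_step", "sqrt_dt"):
        v.append("noise.noise_mode: must be 'per_step' or 'sqrt_dt'")
    if not (_is_finite(noise.background_rate_hz) and noise.background_rate_hz >= 0):
        v.append("noise.background_rate_hz: must be >= 0")

    dbs = cfg.dbs
    if not (_is_finite(dbs.frequency_hz) and dbs.frequency_hz >= 0):
        v.append("dbs.frequency_hz: must be >= 0")
    if not (_is_finite(dbs.pulse_width_ms) and dbs.pulse_width_ms > 0):
        v.append("dbs.pulse_width_ms: must be > 0")
    elif dbs.frequency_hz > 0 and dbs.pulse_width_ms >= 1000.0 / dbs.frequency_hz:
        v.append("dbs.pulse_width_ms: must be shorter than the pulse period")
    if not (_is_finite(dbs.onset_s) and dbs.onset_s >= 0):
        v.append("dbs.onset_s: must be >= 0")
    if not (_is_finite(dbs.offset_s) and dbs.offset_s >= dbs.onset_s):
        v.append("dbs.offset_s: must be >= onset_s")
    if dbs.target_structure not in range(1, len(STRUCTURES) + 1):
        v.append("dbs.target_structure: must be a structure id in 1..6")

    if not (_is_finite(cfg.duration_s) and cfg.duration_s > 0):
        v.append("duration_s: must be > 0")
    if not (_is_finite(cfg.dt_ms) and cfg.dt_ms > 0):
        v.append("dt_ms: must be > 0")
    else:
        steps = cfg.duration_s * 1000.0 / cfg.dt_ms
        if abs(steps - round(steps)) > 1e-6:
            v.append("duration_s / dt_ms: must yield an integer step count")
        if cfg.dt_ms > 0.5:
            warnings.warn(
                "dt_ms > 0.5 ms: the quadratic Izhikevich term can diverge "
                "under explicit Euler at large steps", UserWarning, stacklevel=2)
    if not isinstance(cfg.trace_stride, int) or cfg.trace_stride < 1:
        v.append("trace_stride: must be a positive integer")

    return v


# ---------------------------------------------------------------------------
# Serialization (YAML, strict keys)
# ---------------------------------------------------------------------------

_NESTED = {
    "populations": PopulationSpec,
    "neuron_params": NeuronParams,
    "synapse_params": SynapseParams,
    "connectivity": ConnectivitySpec,
    "noise": NoiseSpec,
    "dbs": DBSProtocol,
}


def _from_dict(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise ConfigFormatError(f"{path}: expected a mapping")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigFormatError(f"{path}: unknown key(s) {sorted(unknown)}")
    kwargs = {}
    for name, f in fields.items():
        if name not in data:
            if f.default is not dataclasses.MISSING or \
                    f.default_factory is not dataclasses.MISSING:  # type: ignore[misc]
                continue
            raise ConfigFormatError(f"{path}: missing field {name!r}")
        kwargs[name] = data[name]
    return cls(**kwargs)


def config_from_dict(data: dict) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a plain nested dict, rejecting
    unknown keys and naming any missing field."""
    if not isinstance(data, dict):
        raise ConfigFormatError("config: expected a mapping at top level")
    data = dict(data)
    if "populations" in data:
        if not isinstance(data["populations"], list):
            raise ConfigFormatError("populations: expected a list")
        data["populations"] = [
            _from_dict(PopulationSpec, p, f"populations[{i}]")
            for i, p in enumerate(data["populations"])
        ]
    for key, cls in (("neuron_params", NeuronParams),
                     ("synapse_params", SynapseParams)):
        if key in data:
            if not isinstance(data[key], dict):
                raise ConfigFormatError(f"{key}: expected a mapping")
            data[key] = {
                k: _from_dict(cls, v, f"{key}[{k!r}]")
                for k, v in data[key].items()
            }
    for key, cls in (("connectivity", ConnectivitySpec),
                     ("noise", NoiseSpec), ("dbs", DBSProtocol)):
        if key in data:
            data[key] = _from_dict(cls, data[key], key)
    cfg = _from_dict(SimulationConfig, data, "config")
    if cfg.schema_version != SCHEMA_VERSION:
        raise ConfigFormatError(
            f"schema_version: expected {SCHEMA_VERSION}, got {cfg.schema_version}")
    return cfg


def config_to_dict(cfg: SimulationConfig) -> dict:
    return dataclasses.asdict(cfg)


def save_config(cfg: SimulationConfig, path) -> None:
    """Serialize ``cfg`` as YAML; ``load_config(save_config(cfg))`` is a
    field-for-field identity."""
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)


def load_config(path) -> SimulationConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data)


def config_fingerprint(cfg: SimulationConfig) -> str:
    """Stable SHA-256 over the canonical serialized form (seed included)."""
    blob = yaml.safe_dump(config_to_dict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def population_by_name(cfg: SimulationConfig, name: str) -> PopulationSpec:
    for p in cfg.populations:
        if p.name == name:
            return p
    raise KeyError(f"no population named {name!r}")
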