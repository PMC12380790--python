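"""DBS pulse-train generation and targeted injection.

The stimulation current is a train of monophasic rectangular pulses (an
optional charge-balanced biphasic mode appends a negative phase of equal
width) delivered intracellularly to every neuron of the target structure —
layer D by default — and to no other neuron.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import DBSProtocol, STRUCTURES


@dataclass
class PulseTrain:
    pulse_onsets_ms: np.ndarray
    width_ms: float
    amplitude: float
    n_steps: int
    dt_ms: float


def make_pulse_train(protocol: DBSProtocol, duration_s: float,
                     dt_ms: float) -> PulseTrain:
    """Pulse onset times at exact period 1000/f ms within [onset_s, offset_s),
    clipped to the simulation span."""
    n_steps = int(round(duration_s * 1000.0 / dt_ms))
    if protocol.frequency_hz <= 0 or protocol.amplitude == 0:
        onsets = np.empty(0)
    else:
        period = 1000.0 / protocol.frequency_hz
        if protocol.pulse_width_ms >= period:
            raise ValueError("pulse width must be shorter than the pulse period")
        t0 = protocol.onset_s * 1000.0
        t1 = min(protocol.offset_s, duration_s) * 1000.0
        k = np.arange(max(0, int(np.ceil((t1 - t0) / period))))
        onsets = t0 + k * period
        onsets = onsets[onsets < t1]
    return PulseTrain(pulse_onsets_ms=onsets, width_ms=protocol.pulse_width_ms,
                      amplitude=protocol.amplitude, n_steps=n_steps, dt_ms=dt_ms)


def dbs_waveform(protocol: DBSProtocol, duration_s: float, dt_ms: float) -> np.ndarray:
    """Per-step stimulation current; sample i (time i*dt) carries the pulse
    amplitude iff its time lies in [pulse_onset, pulse_onset + width)."""
    train = make_pulse_train(protocol, duration_s, dt_ms)
    wave = np.zeros(train.n_steps)
    if train.pulse_onsets_ms.size == 0:
        return wave
    period = 1000.0 / protocol.frequency_hz
    t = np.arange(train.n_steps) * dt_ms
    t0 = protocol.onset_s * 1000.0
    t1 = min(protocol.offset_s, duration_s) * 1000.0
    window = (t >= t0) & (t < t1)
    phase = (t - t0) % period
    wave[window & (phase < train.width_ms)] = train.amplitude
    if protocol.biphasic:
        neg = window & (phase >= train.width_ms) & (phase < 2 * train.width_ms)
        wave[neg] = -train.amplitude
    return wave


def apply_dbs(step_value: float, network, out=None) -> np.ndarray:
    """Per-neuron current increment for one step: ``step_value`` on every
    neuron of the protocol's target structure (Kronecker-delta targeting),
    zero elsewhere.  A deactivated target receives nothing."""
    if out is None:
        out = np.zeros(network.n_total)
    else:
        out[:] = 0.0
    target = STRUCTURES[network.cfg.dbs.target_structure - 1]
    if step_value != 0.0 and target in network.slices:
        out[network.slices[target]] = step_value
    return out


def waveform_to_csv(protocol: DBSProtocol, duration_s: float, dt_ms: float,
                    path) -> None:
    """Export the waveform as (time_ms, current) CSV for inspection."""
    wave = dbs_waveform(protocol, duration_s, dt_ms)
    t = np.arange(wave.shape[0]) * dt_ms
    np.savetxt(path, np.column_stack([t, wave]), delimiter=",",
               header="time_ms,current", comments="", fmt="%.6g")
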