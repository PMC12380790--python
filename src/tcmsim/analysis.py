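"""Quantifying network states: LFP proxy, synchrony, spectral beta power.

The raw model output is a spike raster.  To turn the qualitative
synchronized-vs-desynchronized contrast into numbers we use two standard,
parameter-light statistics:

* **Population synchrony** — the Golomb-Hansel coherence

      chi = sqrt( Var_t[ mean_i s_i(t) ] / mean_i Var_t[ s_i(t) ] )

  over Gaussian-smoothed (5 ms) single-neuron spike signals: 1 for
  perfectly identical signals, tending to 0 for independent ones as the
  population grows.  chi is invariant to uniform amplitude scaling.

* **Beta-band power** — a Welch averaged periodogram (2 s Hann windows, 50%
  overlap) of the population activity proxy (mean-subtracted 1 ms binned
  population spike count, or the population-mean voltage when traces were
  recorded), integrated over 13-30 Hz; total power is integrated over
  [1 Hz, Nyquist].

Epoch comparison defaults to [1, 6) s (pre-DBS) vs [7, 12) s (DBS on at
6 s with a 1 s settle-in margin), matching the standard 12 s protocol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy.ndimage import gaussian_filter1d

from .engine import SimulationResult

BETA_BAND = (13.0, 30.0)
CORTICAL_STRUCTURES = ("S", "M", "D", "CI")
DEFAULT_EPOCHS = {"pre": (1.0, 6.0), "dbs": (7.0, 12.0)}


@dataclass
class EpochMetrics:
    epoch: str
    t_start_ms: float
    t_end_ms: float
    structure: str
    synchrony_chi: float
    mean_rate_hz: float
    beta_power: float
    total_power: float


def _binned_signals(result: SimulationResult, structure: str,
                    t0_ms: float, t1_ms: float, bin_ms: float) -> np.ndarray:
    """Per-neuron spike-count signals, shape (n_neurons, n_bins)."""
    if structure not in result.sizes:
        raise KeyError(f"structure {structure!r} not present in this run")
    n = result.sizes[structure]
    ids, times = result.spikes_of(structure)
    n_bins = int(round((t1_ms - t0_ms) / bin_ms))
    sig = np.zeros((n, n_bins))
    m = (times >= t0_ms) & (times < t1_ms)
    if m.any():
        bins = ((times[m] - t0_ms) / bin_ms).astype(int)
        np.add.at(sig, (ids[m], bins), 1.0)
    return sig


def lfp_proxy(result: SimulationResult, structure: str, bin_ms: float = 1.0,
              t0_ms: float = 0.0, t1_ms: float | None = None,
              source: str = "spikes"):
    """Mean-subtracted population activity time series for one structure.

    ``source='spikes'`` (default) bins the population spike count;
    ``source='traces'`` uses the population-mean membrane voltage (requires
    ``record_traces``).  Returns ``(t_ms, series)``; an empty spike record
    yields a zero series.
    """
    if t1_ms is None:
        t1_ms = result.duration_s * 1000.0
    if source == "traces":
        if result.traces is None:
            raise ValueError("no traces recorded; rerun with record_traces=True")
        if structure not in result.slices:
            raise KeyError(f"structure {structure!r} not present in this run")
        a, b = result.slices[structure]
        t = result.traces["t_ms"]
        m = (t >= t0_ms) & (t < t1_ms)
        series = result.traces["v"][m, a:b].mean(axis=1)
        return t[m], series - series.mean()
    sig = _binned_signals(result, structure, t0_ms, t1_ms, bin_ms)
    series = sig.sum(axis=0)
    t = t0_ms + (np.arange(series.shape[0]) + 0.5) * bin_ms
    return t, series - series.mean()


def chi_from_signals(signals: np.ndarray) -> float:
    """Golomb-Hansel coherence of an (n_signals, n_t) array.

    Returns 0.0 when no signal has temporal variance (an entirely silent or
    constant population has no synchrony to speak of).
    """
    signals = np.asarray(signals, dtype=float)
    if signals.ndim != 2 or signals.shape[0] < 2:
        raise ValueError("need a 2-D array with at least two signals")
    mean_sig = signals.mean(axis=0)
    num = mean_sig.var()
    den = signals.var(axis=1).mean()
    if den <= 0.0:
        return 0.0
    return float(np.sqrt(num / den))


def synchrony_index(result: SimulationResult, structure: str,
                    epoch_ms: tuple, bin_ms: float = 1.0,
                    smooth_ms: float = 5.0) -> float:
    """Population synchrony chi of one structure over ``epoch_ms``.

    Spike trains are binned at ``bin_ms`` and smoothed with a Gaussian
    kernel of width ``smooth_ms`` before the coherence is computed.
    """
    t0, t1 = epoch_ms
    if t1 - t0 < 500.0:
        raise ValueError("epoch must span at least 500 ms")
    if t1 - t0 < 4 * smooth_ms:
        raise ValueError("epoch shorter than the smoothing kernel")
    sig = _binned_signals(result, structure, t0, t1, bin_ms)
    if sig.shape[0] < 2:
        raise ValueError("need at least two neurons")
    sig = gaussian_filter1d(sig, sigma=smooth_ms / bin_ms, axis=1)
    return chi_from_signals(sig)


def band_power(series: np.ndarray, dt_ms: float,
               band: tuple = BETA_BAND) -> tuple:
    """(band, total) spectral power of a regularly sampled series.

    Welch averaged periodogram with 2 s Hann windows and 50% overlap; the
    band integral runs over ``band`` and the total over [1 Hz, Nyquist].
    """
    series = np.asarray(series, dtype=float)
    fs = 1000.0 / dt_ms
    if series.shape[0] * dt_ms < 2000.0:
        raise ValueError("need at least 2 s of samples")
    if band[1] > fs / 2 or band[0] <= 0:
        raise ValueError(f"band {band} outside (0, Nyquist={fs / 2}]")
    nperseg = int(round(2000.0 / dt_ms))
    freqs, psd = sp_signal.welch(series, fs=fs, window="hann",
                                 nperseg=nperseg, noverlap=nperseg // 2)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    in_total = (freqs >= 1.0) & (freqs <= fs / 2)
    bp = float(np.trapezoid(psd[in_band], freqs[in_band]))
    tp = float(np.trapezoid(psd[in_total], freqs[in_total]))
    return bp, tp


def epoch_metrics(result: SimulationResult, label: str, t0_s: float,
                  t1_s: float, structure: str, bin_ms: float = 1.0) -> EpochMetrics:
    t0, t1 = t0_s * 1000.0, t1_s * 1000.0
    chi = synchrony_index(result, structure, (t0, t1), bin_ms=bin_ms)
    _, proxy = lfp_proxy(result, structure, bin_ms=bin_ms, t0_ms=t0, t1_ms=t1)
    bp, tp = band_power(proxy, bin_ms)
    _, times = result.spikes_of(structure)
    n_spk = int(((times >= t0) & (times < t1)).sum())
    rate = n_spk / result.sizes[structure] / (t1_s - t0_s)
    return EpochMetrics(epoch=label, t_start_ms=t0, t_end_ms=t1,
                        structure=structure, synchrony_chi=chi,
                        mean_rate_hz=rate, beta_power=bp, total_power=tp)


def compare_epochs(result: SimulationResult, epochs: dict | None = None,
                   structures=None, bin_ms: float = 1.0) -> pd.DataFrame:
    """Per-epoch, per-structure metrics table.

    ``epochs`` maps label -> (t0_s, t1_s); the defaults ([1,6) pre, [7,12)
    DBS) exclude a 1 s settle-in after both run start and DBS onset.
    Epochs must be disjoint and inside the simulated span.
    """
    if epochs is None:
        epochs = DEFAULT_EPOCHS
    spans = sorted(epochs.items(), key=lambda kv: kv[1][0])
    for label, (t0, t1) in spans:
        if not (0 <= t0 < t1 <= result.duration_s):
            raise ValueError(f"epoch {label!r} [{t0}, {t1}) outside the run span")
    for (la, (_, e_a)), (lb, (s_b, _)) in zip(spans, spans[1:]):
        if e_a > s_b:
            raise ValueError(f"epochs {la!r} and {lb!r} overlap")
    if structures is None:
        structures = result.structure_names
    rows = [epoch_metrics(result, label, t0, t1, s, bin_ms=bin_ms)
            for label, (t0, t1) in epochs.items() for s in structures]
    return pd.DataFrame([r.__dict__ for r in rows])


def epoch_ratios(metrics: pd.DataFrame, baseline: str = "pre") -> pd.DataFrame:
    """Per-structure chi and beta-power ratios of every epoch against the
    baseline epoch (identical data in both epochs gives ratios of 1)."""
    base = metrics[metrics.epoch == baseline].set_index("structure")
    if base.empty:
        raise ValueError(f"no baseline epoch {baseline!r} in the table")
    out = []
    for label in metrics.epoch.unique():
        if label == baseline:
            continue
        cur = metrics[metrics.epoch == label].set_index("structure")
        for s in cur.index:
            out.append({
                "epoch": label, "structure": s,
                "chi_ratio": cur.loc[s, "synchrony_chi"]
                / max(base.loc[s, "synchrony_chi"], 1e-12),
                "beta_ratio": cur.loc[s, "beta_power"]
                / max(base.loc[s, "beta_power"], 1e-12),
            })
    return pd.DataFrame(out)


def cortical_mean_chi(result: SimulationResult, epoch_s: tuple,
                      structures=CORTICAL_STRUCTURES) -> float:
    """Mean synchrony over the cortical structures in one epoch (seconds)."""
    t0, t1 = epoch_s[0] * 1000.0, epoch_s[1] * 1000.0
    vals = [synchrony_index(result, s, (t0, t1))
            for s in structures if s in result.sizes]
    return float(np.mean(vals))


def raster_plot(result: SimulationResult, path, dbs_onset_s: float | None = None,
                title: str | None = None) -> None:
    """Spike raster, neurons grouped by structure (S, M, D, CI, TRN, TCR
    top to bottom), DBS onset marked; written to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 6))
    yticks, ylabels = [], []
    for name in result.structure_names:
        a, b = result.slices[name]
        ids, times = result.spikes_of(name)
        if ids.size:
            ax.plot(times / 1000.0, ids + a, ".", markersize=1.0)
        ax.axhline(b - 0.5, color="0.8", linewidth=0.5)
        yticks.append((a + b) / 2)
        ylabels.append(name)
    if dbs_onset_s is not None:
        ax.axvline(dbs_onset_s, color="r", linestyle="--", linewidth=1.0,
                   label="DBS onset")
        ax.legend(loc="upper right")
    ax.set_yticks(yticks)
    ax.set_yticklabels(ylabels)
    ax.set_ylim(-0.5, max((b for _, b in result.slices.values()), default=1) - 0.5)
    ax.set_xlim(0, result.duration_s)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("neuron (grouped by structure)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
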