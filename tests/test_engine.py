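"""Simulation engine: quiescence, delays, determinism, oracle equivalence,
background events, dt robustness."""

import numpy as np
import pytest

import tcmsim as t
from tcmsim.config import NoiseSpec
from tcmsim.engine import Engine, sample_background_events
from tests.conftest import make_toy_config


class TestQuiescence:
    def test_zero_noise_zero_input_silent(self):
        cfg = make_toy_config(noise=False, duration_s=0.5)
        for p in cfg.populations:
            p.bias_current = 0.0
        cfg.dbs.amplitude = 0.0
        res = t.simulate(cfg)
        assert res.n_spikes == 0

    def test_engine_psc_stays_zero_without_spikes(self):
        cfg = make_toy_config(noise=False, duration_s=0.1)
        for p in cfg.populations:
            p.bias_current = 0.0
        eng = Engine(cfg)
        for _ in range(eng.n_steps):
            eng.update_time_step()
        assert np.all(eng.tm.i_psc == 0.0)
        assert np.all(eng.buffer == 0.0)


class TestDelayPropagation:
    def test_spike_first_affects_target_after_delay(self):
        """A presynaptic spike at step s first perturbs the target's membrane
        at step s + k for a k-step conduction delay."""
        delay_ms = 2.0
        k = int(delay_ms / 0.1)
        cfg = make_toy_config(sizes={"S": 1, "M": 1}, noise=False,
                              duration_s=0.2)
        si, mi = t.STRUCTURES.index("S"), t.STRUCTURES.index("M")
        for i in range(6):
            for j in range(6):
                cfg.connectivity.weight_gain[i][j] = 0.0
        cfg.connectivity.weight_gain[si][mi] = 50.0
        cfg.connectivity.delay_ms[si][mi] = delay_ms
        for p in cfg.populations:
            p.bias_current = 10.0 if p.name == "S" else 0.0
        cfg.record_traces = True
        cfg.trace_stride = 1
        res = t.simulate(cfg)
        ids, times = res.spikes_of("S")
        assert ids.size > 0
        first_spike_step = int(round(times[0] / 0.1)) - 1
        # baseline: same run with the projection silenced
        cfg0 = make_toy_config(sizes={"S": 1, "M": 1}, noise=False,
                               duration_s=0.2)
        for i in range(6):
            for j in range(6):
                cfg0.connectivity.weight_gain[i][j] = 0.0
        for p in cfg0.populations:
            p.bias_current = 10.0 if p.name == "S" else 0.0
        cfg0.record_traces = True
        cfg0.trace_stride = 1
        res0 = t.simulate(cfg0)
        m_col = res.slices["M"][0]
        dv = np.abs(res.traces["v"][:, m_col] - res0.traces["v"][:, m_col])
        first_effect_step = int(np.argmax(dv > 0))
        assert first_effect_step == first_spike_step + k


class TestOracleEquivalence:
    def test_spike_trains_identical(self, toy_run_pair):
        """Vectorized engine reproduces the naive per-pair reference spike
        train exactly under shared noise draws (10^4 steps, 30 neurons)."""
        vec, ref = toy_run_pair
        assert vec.n_spikes == ref["spike_ids"].size
        assert np.array_equal(vec.spike_ids, ref["spike_ids"])
        assert np.allclose(vec.spike_times_ms, ref["spike_times_ms"])

    def test_voltage_trajectories_match(self, toy_run_pair):
        """State trajectories agree to summation-order rounding."""
        vec, ref = toy_run_pair
        assert np.abs(vec.traces["v"] - ref["v"]).max() < 1e-8

    def test_zero_noise_equivalence(self):
        """Deterministic (noise-free, bias-driven) regime: exact agreement."""
        from tcmsim.reference import simulate_reference
        cfg = make_toy_config(noise=False, duration_s=0.5)
        for p in cfg.populations:
            p.bias_current = 6.0 if p.name in ("S", "TCR") else 2.0
        ref = simulate_reference(cfg)
        res = t.simulate(cfg)
        assert np.array_equal(res.spike_ids, ref["spike_ids"])
        assert np.allclose(res.spike_times_ms, ref["spike_times_ms"])
        assert res.n_spikes > 0


class TestDeterminism:
    def test_identical_runs_byte_identical_csv(self, tmp_path):
        paths = []
        for i in range(2):
            res = t.simulate(make_toy_config(duration_s=0.5))
            p = tmp_path / f"run{i}.csv"
            res.save_spikes_csv(p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_seed_changes_spikes(self):
        r1 = t.simulate(make_toy_config(seed=1, duration_s=0.5))
        r2 = t.simulate(make_toy_config(seed=2, duration_s=0.5))
        assert (r1.n_spikes != r2.n_spikes
                or not np.array_equal(r1.spike_times_ms, r2.spike_times_ms))

    def test_toggling_background_keeps_membrane_stream(self):
        """Substream discipline: enabling the (zero-amplitude) background
        does not shift membrane/threshold noise draws."""
        base = make_toy_config(duration_s=0.3)
        alt = make_toy_config(duration_s=0.3)
        alt.noise.background_enabled = True
        alt.noise.background_rate_hz = 50.0
        alt.noise.background_amplitude = 0.0
        r1, r2 = t.simulate(base), t.simulate(alt)
        assert np.array_equal(r1.spike_ids, r2.spike_ids)
        assert np.array_equal(r1.spike_times_ms, r2.spike_times_ms)


class TestBackground:
    def test_rate_zero_no_events(self):
        noise = NoiseSpec(background_rate_hz=0.0, background_amplitude=1.0,
                          background_enabled=True)
        rng = np.random.default_rng(0)
        for _ in range(100):
            assert np.all(sample_background_events(noise, 50, 0.1, rng) == 0.0)

    def test_poisson_mean_count(self):
        """Mean event count over r*T >= 1000 matches the Poisson rate within
        5% (Monte Carlo)."""
        noise = NoiseSpec(background_rate_hz=100.0, background_amplitude=2.0,
                          background_enabled=True)
        rng = np.random.default_rng(7)
        n, steps, dt = 200, 10_000, 0.1          # 1 s per neuron
        total = 0
        for _ in range(steps):
            total += int((sample_background_events(noise, n, dt, rng) != 0).sum())
        per_neuron = total / n
        assert per_neuron == pytest.approx(100.0, rel=0.05)

    def test_disabled_by_default(self):
        cfg = make_toy_config()
        assert cfg.noise.background_enabled is False


class TestResultObject:
    def test_times_are_dt_multiples_and_sorted(self):
        res = t.simulate(make_toy_config(duration_s=0.5))
        steps = res.spike_times_ms / res.dt_ms
        assert np.allclose(steps, np.round(steps))
        assert np.all(np.diff(res.spike_times_ms) >= 0)

    def test_spike_ids_are_live_neurons(self):
        res = t.simulate(make_toy_config(duration_s=0.5))
        assert np.all(res.spike_ids >= 0)
        assert np.all(res.spike_ids < res.n_neurons)

    def test_dataframe_structure_labels(self):
        res = t.simulate(make_toy_config(duration_s=0.5))
        df = res.spikes_dataframe()
        assert list(df.columns) == ["neuron_id", "structure", "time_ms"]
        assert set(df["structure"]).issubset(set(res.structure_names))


def test_hdf5_round_trip(tmp_path):
    h5py = pytest.importorskip("h5py")
    cfg = make_toy_config(duration_s=0.3)
    cfg.record_traces = True
    res = t.simulate(cfg)
    path = tmp_path / "run.h5"
    res.save_hdf5(path)
    with h5py.File(path) as f:
        assert np.array_equal(f["spikes/neuron_id"][:], res.spike_ids)
        assert f.attrs["seed"] == res.seed
        assert f["traces/v"].shape == res.traces["v"].shape


def test_dt_robustness_sqrt_dt_mode():
    """Halving dt changes the default network's mean rate by < 15% in the
    dt-invariant noise mode (down-scaled run)."""
    rates = []
    for dt in (0.1, 0.05):
        cfg = t.default_config(seed=3)
        cfg.duration_s = 2.0
        cfg.dt_ms = dt
        cfg.dbs.frequency_hz = 0.0
        res = t.simulate(cfg)
        m = res.spike_times_ms >= 500.0
        rates.append(m.sum() / res.n_neurons / 1.5)
    assert rates[1] == pytest.approx(rates[0], rel=0.15)
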