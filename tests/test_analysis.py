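"""Synchrony coherence, LFP proxy, spectral band power, epoch comparison."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter1d

import tcmsim as t
from tcmsim.analysis import (band_power, chi_from_signals, compare_epochs,
                             epoch_ratios, lfp_proxy, raster_plot,
                             synchrony_index)
from tcmsim.engine import SimulationResult


def make_result(spike_ids, times_ms, sizes, duration_s=4.0, dt_ms=0.1):
    """Hand-built SimulationResult for surrogate spike data."""
    order = np.argsort(times_ms, kind="stable")
    slices, off = {}, 0
    names = [n for n in t.STRUCTURES if n in sizes]
    for n in names:
        slices[n] = (off, off + sizes[n])
        off += sizes[n]
    sid = np.zeros(off, dtype=int)
    for i, n in enumerate(t.STRUCTURES):
        if n in slices:
            a, b = slices[n]
            sid[a:b] = i + 1
    ids = np.asarray(spike_ids, dtype=int)[order]
    return SimulationResult(
        spike_ids=ids, spike_times_ms=np.asarray(times_ms)[order],
        spike_structure_ids=sid[ids] if ids.size else np.empty(0, dtype=int),
        structure_names=names, sizes=dict(sizes), slices=slices,
        seed=0, dt_ms=dt_ms, duration_s=duration_s, config_fingerprint="x")


def periodic_result(n_neurons=20, period_ms=50.0, duration_s=4.0, jitter=None,
                    seed=0):
    rng = np.random.default_rng(seed)
    ids, times = [], []
    for i in range(n_neurons):
        t_spk = np.arange(period_ms, duration_s * 1000.0, period_ms)
        if jitter:
            t_spk = t_spk + rng.normal(0, jitter, t_spk.size)
        ids.extend([i] * t_spk.size)
        times.extend(t_spk)
    return make_result(ids, times, {"S": n_neurons}, duration_s)


class TestChi:
    def test_identical_trains_give_one(self):
        res = periodic_result()
        assert synchrony_index(res, "S", (0, 4000)) == pytest.approx(1.0)

    def test_independent_poisson_low(self):
        """100 independent 10 Hz Poisson trains: finite-size chi < 0.3."""
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            ids, times = [], []
            for i in range(100):
                n = rng.poisson(40)                  # 10 Hz x 4 s
                ids.extend([i] * n)
                times.extend(rng.uniform(0, 4000.0, n))
            res = make_result(ids, times, {"S": 100})
            assert synchrony_index(res, "S", (0, 4000)) < 0.3

    def test_synchronized_exceeds_independent(self):
        for n in (10, 30, 100):
            sync = periodic_result(n_neurons=n)
            rng = np.random.default_rng(n)
            ids, times = [], []
            for i in range(n):
                ids.extend([i] * 80)
                times.extend(rng.uniform(0, 4000.0, 80))
            indep = make_result(ids, times, {"S": n})
            assert (synchrony_index(sync, "S", (0, 4000))
                    > synchrony_index(indep, "S", (0, 4000)))

    def test_amplitude_scaling_invariance(self):
        rng = np.random.default_rng(0)
        sig = rng.random((20, 2000))
        sig = gaussian_filter1d(sig, 5.0, axis=1)
        assert chi_from_signals(7.3 * sig) == pytest.approx(chi_from_signals(sig))

    def test_silent_population_zero(self):
        assert chi_from_signals(np.zeros((5, 100))) == 0.0

    def test_epoch_too_short(self):
        res = periodic_result()
        with pytest.raises(ValueError, match="500 ms"):
            synchrony_index(res, "S", (0, 400))


class TestBandPower:
    def test_beta_sinusoid_concentrated(self):
        dt = 1.0
        tt = np.arange(8000) * dt / 1000.0
        series = np.sin(2 * np.pi * 20.0 * tt)
        bp, tp = band_power(series, dt)
        assert bp / tp >= 0.90

    def test_out_of_band_sinusoid(self):
        dt = 1.0
        tt = np.arange(8000) * dt / 1000.0
        series = np.sin(2 * np.pi * 50.0 * tt)
        bp, tp = band_power(series, dt)
        assert bp / tp < 0.05

    def test_white_noise_flat_fraction(self):
        """Beta fraction of white noise ~ band width / total width."""
        dt = 1.0
        fracs = []
        for seed in range(10):
            series = np.random.default_rng(seed).normal(size=16000)
            bp, tp = band_power(series, dt)
            fracs.append(bp / tp)
        expected = (30.0 - 13.0) / (500.0 - 1.0)
        assert np.mean(fracs) == pytest.approx(expected, rel=0.10)

    def test_additive_over_disjoint_bands(self):
        series = np.random.default_rng(1).normal(size=8000)
        lo, _ = band_power(series, 1.0, band=(13.0, 20.0))
        hi, _ = band_power(series, 1.0, band=(20.0, 30.0))
        full, _ = band_power(series, 1.0, band=(13.0, 30.0))
        assert lo + hi == pytest.approx(full, rel=0.02)

    def test_band_outside_nyquist(self):
        with pytest.raises(ValueError, match="Nyquist"):
            band_power(np.zeros(4000), 1.0, band=(400.0, 600.0))

    def test_too_short_series(self):
        with pytest.raises(ValueError, match="2 s"):
            band_power(np.zeros(500), 1.0)


class TestLfpProxy:
    def test_empty_record_zero_series(self):
        res = make_result([], [], {"S": 10})
        _, series = lfp_proxy(res, "S")
        assert np.all(series == 0.0)

    def test_periodic_train_20hz_fundamental(self):
        res = periodic_result(n_neurons=1, period_ms=50.0)
        _, series = lfp_proxy(res, "S")
        from scipy import signal as ss
        f, p = ss.welch(series, fs=1000.0, nperseg=2048)
        peak = f[np.argmax(p[(f > 2)].__array__()) + int((f <= 2).sum())]
        assert peak == pytest.approx(20.0, abs=1.0)

    def test_linearity_in_counts(self):
        res1 = periodic_result(n_neurons=5)
        res2 = periodic_result(n_neurons=10)   # doubled identical trains
        _, s1 = lfp_proxy(res1, "S")
        _, s2 = lfp_proxy(res2, "S")
        assert np.allclose(s2, 2.0 * s1)

    def test_unknown_structure(self):
        res = make_result([], [], {"S": 10})
        with pytest.raises(KeyError):
            lfp_proxy(res, "D")


class TestCompareEpochs:
    def test_identical_epochs_unit_ratios(self):
        """Surrogate data repeating exactly in both epochs: all ratios 1."""
        base = periodic_result(n_neurons=10, duration_s=8.0, jitter=3.0)
        half = base.spike_times_ms < 4000.0
        ids = np.concatenate([base.spike_ids[half], base.spike_ids[half]])
        times = np.concatenate([base.spike_times_ms[half],
                                base.spike_times_ms[half] + 4000.0])
        res = make_result(ids, times, {"S": 10}, duration_s=8.0)
        metrics = compare_epochs(res, {"pre": (0.0, 4.0), "dbs": (4.0, 8.0)})
        ratios = epoch_ratios(metrics)
        assert ratios["chi_ratio"].to_numpy() == pytest.approx(1.0)
        assert ratios["beta_ratio"].to_numpy() == pytest.approx(1.0)

    def test_rejects_overlap(self):
        res = periodic_result(duration_s=4.0)
        with pytest.raises(ValueError, match="overlap"):
            compare_epochs(res, {"a": (0.0, 2.5), "b": (2.0, 4.0)})

    def test_rejects_out_of_range(self):
        res = periodic_result(duration_s=4.0)
        with pytest.raises(ValueError, match="span"):
            compare_epochs(res, {"a": (0.0, 2.0), "b": (2.0, 9.0)})

    def test_metrics_table_shape(self, default_run_130):
        metrics = compare_epochs(default_run_130,
                                 {"pre": (1.0, 3.0), "dbs": (4.0, 6.0)})
        assert len(metrics) == 2 * len(default_run_130.structure_names)
        assert (metrics["beta_power"] <= metrics["total_power"] + 1e-9).all()
        assert (metrics["synchrony_chi"] >= 0).all()
        assert (metrics["mean_rate_hz"] >= 0).all()


class TestRaster:
    def test_raster_file_written(self, default_run_130, tmp_path):
        path = tmp_path / "raster.png"
        raster_plot(default_run_130, path, dbs_onset_s=3.0)
        assert path.exists() and path.stat().st_size > 0

    def test_empty_record_no_crash(self, tmp_path):
        res = make_result([], [], {"S": 5, "M": 5})
        path = tmp_path / "empty.png"
        raster_plot(res, path)
        assert path.exists()
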