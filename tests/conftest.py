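"""Shared fixtures: small configurations and reusable runs."""

import numpy as np
import pytest

import tcmsim as t


def make_toy_config(seed=7, duration_s=1.0, sizes=None, noise=True):
    """A three-population miniature network (S, CI, TCR by default) spanning
    excitatory/inhibitory sources and cortical/thalamic delays."""
    if sizes is None:
        sizes = {"S": 10, "CI": 10, "TCR": 10}
    cfg = t.default_config(seed=seed)
    for p in cfg.populations:
        p.n_neurons = sizes.get(p.name, 0)
    cfg.duration_s = duration_s
    cfg.dbs.frequency_hz = 0.0
    if not noise:
        cfg.noise.membrane_noise_std = 0.0
        cfg.noise.threshold_noise_std = 0.0
    return cfg


@pytest.fixture(scope="session")
def toy_cfg():
    return make_toy_config()


@pytest.fixture(scope="session")
def toy_run_pair():
    """Vectorized and reference runs of the same toy config (noise on),
    with full traces; shared by the oracle-equivalence tests."""
    from tcmsim.reference import simulate_reference

    cfg = make_toy_config()
    ref = simulate_reference(cfg)
    cfg2 = make_toy_config()
    cfg2.record_traces = True
    cfg2.trace_stride = 1
    vec = t.simulate(cfg2)
    return vec, ref


@pytest.fixture(scope="session")
def default_run_130():
    """One full default run (130 Hz DBS), reused by analysis tests."""
    cfg = t.default_config(seed=11)
    cfg.duration_s = 6.0
    cfg.dbs.onset_s = 3.0
    cfg.dbs.offset_s = 6.0
    return t.simulate(cfg)
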