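"""Shared fixtures: axes, schedules and a small trained model.

The trained model is session-scoped — a reduced instance (np=64, sp=16,
N=2) trained for two runs of 20 epochs on 5e4 fresh FIDs each, reused by
every test that needs a learned reconstruction.
"""

import numpy as np
import pytest

from nusnet import fid_model, reconstruction, schedules, training


@pytest.fixture(scope="session")
def axis64():
    return fid_model.AxisMeta(sw=5100.0, n_points=64)


@pytest.fixture(scope="session")
def sched_64_16(axis64):
    return schedules.poisson_gap_schedule(64, 16, seed=0)


@pytest.fixture(scope="session")
def trained_model_64(axis64, sched_64_16):
    """Reduced-instance trained model: (params, history, config)."""
    config = training.TrainConfig(
        schedule=sched_64_16, axis=axis64, n_cells=2, n_fids=50_000,
        epochs_per_run=20, max_runs=2, mse_stop=0.0, mae_stop=0.0,
        batch_size=256, seed=7)
    params, history = training.train(config)
    return params, history, config


@pytest.fixture(scope="session")
def fixture_axes():
    direct = fid_model.AxisMeta(sw=12000.0, n_points=128, obs=700.0,
                                carrier=4.77)
    indirect = fid_model.AxisMeta(sw=5100.0, n_points=64, obs=70.95,
                                  carrier=108.0)
    return direct, indirect


@pytest.fixture(scope="session")
def hsqc_fixture(fixture_axes):
    """Noise-free HSQC-like 2D time-domain fixture."""
    direct, indirect = fixture_axes
    return reconstruction.make_fixture_2d(
        reconstruction.hsqc_like_peaks(), direct, indirect)


@pytest.fixture(scope="session")
def full_processed(hsqc_fixture):
    """The conventionally processed (fully sampled) fixture spectrum."""
    spec = reconstruction.ft_direct(hsqc_fixture)
    spec = reconstruction.apply_indirect_window(spec)
    return reconstruction.ft_indirect(spec)


@pytest.fixture(scope="session")
def full_schedule_64():
    return schedules.SamplingSchedule(indices=np.arange(64), n_points=64,
                                      kind="custom")
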