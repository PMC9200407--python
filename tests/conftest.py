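"""Shared fixtures.

The end-to-end study fixture is session-scoped: it runs the full pipeline
once on a two-subject synthetic study with theta and beta traveling waves
injected 40% of the time, and several tests interrogate different aspects
of the same run.
"""

import numpy as np
import pytest

import insulawaves as iw


@pytest.fixture(scope="session")
def scatter_xy():
    """Well-spread 2-D electrode positions for circular-linear fits."""
    rng = np.random.default_rng(42)
    return rng.uniform(-10.0, 10.0, size=(8, 2))


@pytest.fixture(scope="session")
def small_layout():
    return iw.make_electrode_layout(2, 8, (3.5, 5.53), seed=1)


@pytest.fixture(scope="session")
def endtoend_config():
    """Study conditions for the end-to-end run: theta (7.5 Hz) and beta
    (22 Hz) planar waves at ~0.7 m/s on each subject's left probes, bursting
    40% of the time, on a 1/f^2 background with AP gradients, line noise
    and transient artifacts; 48 s at 500 Hz keeps the run desk-sized."""
    return iw.default_config(
        n_subjects=2, electrodes_per_subject=16,
        sampling_rate=500.0, duration=48.0,
        artifact_rate_per_min=1.0, seed=2026)


@pytest.fixture(scope="session")
def endtoend_run(endtoend_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("run")
    return iw.run_study(endtoend_config, out_dir=out), out
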