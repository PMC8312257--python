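import numpy as np
import pytest

import rcstream as rc


@pytest.fixture(scope="session")
def clean_config():
    """A short session with no transport impairment at all."""
    return rc.SimulationConfig(
        duration=30.0,
        td_fs=250,
        drop_probability=0.0,
        reorder_probability=0.0,
        pgt_jitter_sd=0.0,
        systemtick_drift_ppm=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def impaired_config():
    """A session with the default transport trouble, fixed seed."""
    return rc.SimulationConfig(duration=60.0, seed=7)


@pytest.fixture(scope="session")
def clean_session(clean_config):
    return rc.simulate_session(clean_config)


@pytest.fixture(scope="session")
def impaired_session(impaired_config):
    return rc.simulate_session(impaired_config)


@pytest.fixture(scope="session")
def clean_folder(tmp_path_factory, clean_session):
    contents, truth = clean_session
    folder = tmp_path_factory.mktemp("clean_session")
    rc.write_session(folder, contents, truth)
    return folder


@pytest.fixture(scope="session")
def impaired_folder(tmp_path_factory, impaired_session):
    contents, truth = impaired_session
    folder = tmp_path_factory.mktemp("impaired_session")
    rc.write_session(folder, contents, truth)
    return folder


@pytest.fixture(scope="session")
def clean_processed(clean_folder):
    return rc.process_session(clean_folder)


@pytest.fixture(scope="session")
def impaired_processed(impaired_folder):
    return rc.process_session(impaired_folder)


def surviving_sample_indices(truth: rc.GroundTruth, stream: str) -> np.ndarray:
    """Indices (into the generated stream) of samples that reached JSON."""
    idx = [
        np.arange(p["start"], p["start"] + p["n_samples"])
        for p in truth.packet_log[stream]
        if not p["dropped"]
    ]
    out = np.concatenate(idx) if idx else np.empty(0, dtype=int)
    out.sort()
    return out
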