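"""Shared fixtures: small probes, rendered micro-recordings."""

import numpy as np
import pytest

from spikegraph import simulate
from spikegraph.drift_profiles import generate_drift
from spikegraph.io import ProbeGeometry, RecordingHandle


@pytest.fixture(scope="session")
def probe16():
    return simulate.make_probe(16)


@pytest.fixture(scope="session")
def probe8_line():
    """Single-column probe, 20-um pitch."""
    y = np.arange(8) * 20.0
    return ProbeGeometry(np.zeros(8), y, np.arange(8))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def micro_recording(tmp_path_factory, probe16):
    """30-s, 16-channel rendered recording with 6 units and no drift.

    Session-scoped: several tests read it; rendering takes a few
    seconds.
    """
    out = tmp_path_factory.mktemp("micro") / "micro.bin"
    bank = simulate.generate_waveform_bank(6, probe16, seed=7,
                                           sigma_range=(10, 20))
    truth = simulate.generate_spike_trains(bank, 30.0, seed=8,
                                           min_single_norm=14.0)
    prof = generate_drift("none", 30.0, seed=9,
                          probe_span=probe16.y.max())
    rec = simulate.render_recording(bank, truth, prof, probe16, out,
                                    seed=10)
    return {"rec": rec, "truth": truth, "bank": bank, "geom": probe16,
            "path": out}


def write_raw_int16(path, array):
    """(n_samples, n_channels) int16 -> flat binary file."""
    np.asarray(array, np.int16).tofile(path)
    return path
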