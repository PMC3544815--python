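"""Shared fixtures: small synthetic cells, streams and binned responses.

Everything is generated programmatically with fixed seeds; expensive
objects are session-scoped.
"""

import numpy as np
import pytest

import vretina as vr
from vretina import stimulus as stim
from vretina.population import make_test_ensemble


@pytest.fixture(scope="session")
def basis():
    return vr.raised_cosine_basis()


@pytest.fixture(scope="session")
def truth_cell():
    """One ON ground-truth cell with a saturating nonlinearity."""
    return vr.make_population(vr.PopulationSpec(n_cells=1, seed=3))[0]


@pytest.fixture(scope="session")
def small_population():
    return vr.make_population(vr.PopulationSpec(n_cells=4, seed=11))


@pytest.fixture(scope="session")
def labelled_stream():
    """A 30-segment test stream with a gray lead-in, plus its label track."""
    ens = make_test_ensemble(30, (32, 32), 21)
    movie, labels = stim.assemble_stream(ens)
    lead = stim.make_uniform_gray(duration=1.4, geometry=(32, 32))
    movie = lead.concatenate(movie)
    labels = np.concatenate(
        [np.full(lead.n_frames, stim.GRAY_LABEL, dtype=object), labels])
    return movie, labels


@pytest.fixture(scope="session")
def binned_responses(truth_cell, labelled_stream):
    """64 trials of the truth cell on the stream, binned at 62.5 ms."""
    movie, labels = labelled_stream
    rates = vr.firing_rate(truth_cell, movie)
    raster = vr.sample_spikes(rates, 64, movie.frame_dt, seed=5)
    return vr.bin_counts(raster, labels, 1.0 / 16, frame_rate=movie.frame_rate)
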