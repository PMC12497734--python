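import numpy as np
import pytest

from measeq import Layout, SpikeTrainSet, default_layout_4q


@pytest.fixture(scope="session")
def layout():
    return default_layout_4q()


@pytest.fixture
def two_electrode_layout(layout):
    """A minimal two-electrode layout reusing default positions/clusters."""
    ids = (layout.electrodes[0], layout.electrodes[16])  # one per cluster 1 and 2
    return Layout(ids, layout.positions, layout.clusters)


def make_poisson_set(layout, rate, duration, seed, min_isi=1e-3):
    """Independent Poisson trains with a small enforced minimum ISI."""
    rng = np.random.default_rng(seed)
    trains = {}
    for e in layout.electrodes:
        n = rng.poisson(rate * duration)
        t = np.sort(rng.uniform(0, duration, n))
        if t.size > 1:
            keep = np.concatenate([[True], np.diff(t) > min_isi])
            t = t[keep]
        trains[e] = t
    return SpikeTrainSet(layout, trains, duration)
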