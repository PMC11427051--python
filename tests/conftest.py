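import numpy as np
import pytest

from spikemodes import CellMeta, SpikeTrain


@pytest.fixture
def pacemaker_train() -> SpikeTrain:
    """Perfectly regular 2-Hz train over 180 s."""
    times = np.arange(0.25, 180.0, 0.5)
    return SpikeTrain(times=times, t0=0.0, duration=180.0, meta=CellMeta("pace"))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)


def make_train(times, duration=None, t0=0.0, cell_id="cell") -> SpikeTrain:
    times = np.asarray(times, dtype=float)
    if duration is None:
        duration = (times[-1] - t0 + 1.0) if times.size else 1.0
    return SpikeTrain(times=times, t0=t0, duration=duration, meta=CellMeta(cell_id))
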