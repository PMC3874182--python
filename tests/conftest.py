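import numpy as np
import pytest

import smtrace as sm


@pytest.fixture
def quiet_noise():
    """Noiseless sampling at the standard 5 Hz grid."""
    return sm.NoiseModel(sigma=0.0)


@pytest.fixture
def default_noise():
    return sm.NoiseModel()


@pytest.fixture
def no_settle():
    """Segmentation params for single-phase synthetic traces."""
    return sm.SegmentationParams(settle=0.0, overlap=0.0)


@pytest.fixture
def piecewise_trace_factory():
    def make(piece_durations, slopes, level0=100.0, dt=0.2, force=56.0, sigma=0.0, seed=0):
        assert len(piece_durations) == len(slopes)
        t = np.arange(0.0, sum(piece_durations), dt)
        y = np.empty_like(t)
        t0, y0 = 0.0, level0
        knots = []
        for dur, sl in zip(piece_durations, slopes):
            sel = (t >= t0 - 1e-9) & (t < t0 + dur - 1e-9)
            y[sel] = y0 + sl * (t[sel] - t0)
            y0 += sl * dur
            t0 += dur
            knots.append(t0)
        if sigma > 0:
            y = y + np.random.default_rng(seed).normal(0, sigma, len(t))
        trace = sm.Trace(t, y, np.full_like(t, force))
        return trace, knots[:-1]

    return make
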