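import numpy as np
import pytest

import flimca as fc
from flimca.decay import DecayHistogram


@pytest.fixture(scope="session")
def model():
    return fc.OGB1


@pytest.fixture(scope="session")
def binning():
    return fc.DecayBinning()


def noiseless_histogram(ca, model, binning, scale=1e12):
    """Expected (shot-noise-free) decay histogram at a clamped [Ca2+]."""
    probs = fc.decay_bin_probabilities(ca, model, binning)
    return DecayHistogram(binning.edges, probs * scale)


def noiseless_ntc(ca, model, binning):
    return fc.compute_ntc(noiseless_histogram(ca, model, binning))


@pytest.fixture(scope="session")
def truth_curve(model, binning):
    """Calibration fitted to the noiseless NTC values of the default ladder.

    For the two-state decay model the NTC-vs-log[Ca] relation is an exact
    hill-1 logistic, so this curve is the generator's ground truth.
    """
    from flimca.pipeline import DEFAULT_CALIBRATION_LADDER

    levels = np.array(DEFAULT_CALIBRATION_LADDER)
    ntcs = [noiseless_ntc(lv, model, binning) for lv in levels]
    return fc.fit_calibration(levels, ntcs, binning=binning)
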