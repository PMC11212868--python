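import numpy as np
import pytest

from cardionuc import coupling
from cardionuc.images import generate_nucleus_image
from cardionuc.presets import image_preset, trace_preset
from cardionuc.traces import generate_traces


@pytest.fixture(scope="session")
def wt_rat_trace():
    """One noiseless wild-type rat pacing cycle."""
    return generate_traces(trace_preset("WT_rat", n_cycles=1), 1)[0]


@pytest.fixture(scope="session")
def wt_rat_result(wt_rat_trace):
    return coupling.analyze_trace(wt_rat_trace)


@pytest.fixture(scope="session")
def clean_nucleus_image():
    """Noiseless wild-type mouse nucleus render (channels, truth)."""
    return generate_nucleus_image(image_preset("WT_mouse", noise_sd=0.0))


@pytest.fixture(scope="session")
def protrusion_image():
    """Noiseless N195K nucleus with a planted tip protrusion."""
    return generate_nucleus_image(
        image_preset("N195K", noise_sd=0.0, protrusion_present=True))
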