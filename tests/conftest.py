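import numpy as np
import pytest

from aopwv import (
    PropagationSpec,
    TemplateWaveform,
    propagate,
    sample_acquisition,
)


@pytest.fixture(scope="session")
def template():
    return TemplateWaveform()


@pytest.fixture(scope="session")
def clean_plane_set(template):
    """Noiseless 25-plane set at 8 m/s, 50-frame sampling (no reflection)."""
    spec = PropagationSpec(pwv_true=8.0)
    dense, truth = propagate(template, spec)
    curves = sample_acquisition(dense, 50, 0.0, 0)
    return curves, truth


@pytest.fixture(scope="session")
def dense_plane_set(template):
    """Dense (1-ms) noiseless plane set at 8 m/s."""
    spec = PropagationSpec(pwv_true=8.0)
    return propagate(template, spec)


def shifted_pair(template, shift_ms, n_frames=50, noise_sd=0.0, seed=0):
    """Two curves: the template and a copy delayed by shift_ms, sampled."""
    spec = PropagationSpec(
        pwv_true=100.0 / shift_ms if shift_ms else 5.0,
        distances=(0.0, 100.0),
        noise_sd=noise_sd,
        n_frames=n_frames,
        seed=seed,
    )
    dense, _ = propagate(template, spec)
    if shift_ms == 0:
        dense = [dense[0], dense[0]]
    return sample_acquisition(dense, n_frames, noise_sd, seed)
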