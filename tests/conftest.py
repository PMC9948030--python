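import numpy as np
import pytest

import sinedsc as sd


@pytest.fixture(scope="session")
def noiseless_phantom() -> sd.Phantom:
    return sd.generate_phantom(sd.PhantomSpec(tsnr_target=None))


@pytest.fixture(scope="session")
def noiseless_result(noiseless_phantom) -> sd.PipelineResult:
    ph = noiseless_phantom
    return sd.quantify(ph.echoes, ph.truth.labels, gas=ph.gas)


@pytest.fixture(scope="session")
def noisy_phantom() -> sd.Phantom:
    return sd.generate_phantom(sd.PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def noisy_result(noisy_phantom) -> sd.PipelineResult:
    ph = noisy_phantom
    return sd.quantify(ph.echoes, ph.truth.labels, gas=ph.gas)


@pytest.fixture(scope="session")
def deconvolution_curves() -> dict:
    return sd.generate_deconvolution_curves(seed=3)


def sinusoid_echo(
    pp_percent: float,
    te: float = 0.035,
    tr: float = 1.5,
    period: float = 60.0,
    n_frames: int = 160,
    baseline: float = 100.0,
    delay: float = 0.0,
    shape: tuple = (1, 1, 1),
) -> sd.EchoSeries:
    """Single-voxel (or broadcast) BOLD sinusoid with given peak-to-peak %."""
    t = tr * np.arange(n_frames)
    s = baseline * (1.0 + 0.005 * pp_percent * np.sin(2 * np.pi * (t - delay) / period))
    data = np.broadcast_to(s, shape + (n_frames,)).copy()
    return sd.EchoSeries(data, te=te, tr=tr)
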