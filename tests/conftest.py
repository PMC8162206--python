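import numpy as np
import pytest

from arspec import SinusoidComponent, generate_msw


def random_mixture(n_tones: int, fs: float, n_samples: int, seed: int):
    """Random noiseless sinusoid mixture with well-separated tones.

    Frequencies are drawn in [10, 480] Hz with pairwise separation >= 5 Hz,
    amplitudes in [0.5, 2], phases in (-pi, pi]. Returns (record, components).
    """
    rng = np.random.default_rng(seed)
    freqs: list[float] = []
    while len(freqs) < n_tones:
        f = rng.uniform(10.0, 480.0)
        if all(abs(f - g) >= 5.0 for g in freqs):
            freqs.append(f)
    comps = [
        SinusoidComponent(f, rng.uniform(0.5, 2.0), rng.uniform(-np.pi, np.pi))
        for f in freqs
    ]
    return generate_msw(comps, fs, n_samples), comps


@pytest.fixture
def two_tone_record():
    comps = [SinusoidComponent(50.0, 1.0, 0.3), SinusoidComponent(120.0, 1.0, -1.0)]
    return generate_msw(comps, 1000.0, 1000), comps
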