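import numpy as np
import pytest

from nirmoist import GeneratorConfig, generate_dataset, sg_first_derivative


@pytest.fixture(scope="session")
def small_dataset():
    """120 synthetic spectra at 125 channels with default band structure."""
    return generate_dataset(GeneratorConfig(n_samples=120, seed=7))


@pytest.fixture(scope="session")
def small_derivative(small_dataset):
    return sg_first_derivative(small_dataset)


@pytest.fixture(scope="session")
def small_xy(small_derivative):
    """Derivative matrix and moisture on the fraction scale used for modeling."""
    return small_derivative.absorbance, small_derivative.moisture / 100.0


def planted_signal(seed: int, n: int = 120, p: int = 62,
                   informative: tuple[int, int] = (10, 40), snr: float = 20.0):
    """Gaussian channels where only two carry the response, at a given SNR."""
    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, 1.0, (n, p))
    signal = x[:, informative[0]] + x[:, informative[1]]
    noise_sd = np.sqrt(np.var(signal) / snr)
    y = signal + rng.normal(0.0, noise_sd, n)
    return x, y
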