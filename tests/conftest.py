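import numpy as np
import pytest

from ms2pred.chem import AA_ALPHABET, PeptideIon


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA_ALPHABET), size=length))


def random_tryptic(rng: np.random.Generator, length: int, charge: int = 2) -> PeptideIon:
    body = random_sequence(rng, length - 1)
    return PeptideIon(body + ("K" if rng.random() < 0.5 else "R"), charge)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def noiseless_config():
    from ms2pred.synthetic import SyntheticConfig

    return SyntheticConfig(
        n_peptides=60,
        min_length=9,
        max_length=11,
        charges=(2, 3),
        replicates=3,
        sigma=0.0,
        noise_peak_rate=0.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def noiseless_library(noiseless_config, tmp_path_factory):
    from ms2pred.synthetic import generate_library

    path = tmp_path_factory.mktemp("lib") / "noiseless.msp"
    generate_library(noiseless_config, path)
    return path


@pytest.fixture(scope="session")
def noisy_library(tmp_path_factory):
    from ms2pred.synthetic import SyntheticConfig, generate_library

    config = SyntheticConfig(
        n_peptides=40,
        min_length=9,
        max_length=10,
        charges=(2,),
        replicates=4,
        sigma=0.2,
        noise_peak_rate=2.0,
        seed=7,
    )
    path = tmp_path_factory.mktemp("lib") / "noisy.msp"
    generate_library(config, path)
    return config, path
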