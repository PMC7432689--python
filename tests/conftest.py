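import numpy as np
import pytest

from lncfusion import (GeneratorConfig, HexamerTable, LabeledDataset,
                       Transcript, fast_config, generate_benchmark)


def random_sequence(rng: np.random.Generator, length: int,
                    alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=length))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture
def make_transcripts():
    def factory(n: int, length_range=(100, 1000), seed=0, alphabet="ACGT"):
        gen = np.random.default_rng(seed)
        return [
            Transcript(id=f"t{i}",
                       seq=random_sequence(gen, int(gen.integers(*length_range)),
                                           alphabet))
            for i in range(n)
        ]
    return factory


@pytest.fixture(scope="session")
def small_benchmark() -> LabeledDataset:
    """200 transcripts (100/class), shortish, reused across model tests."""
    config = GeneratorConfig(n_per_class=100, length_range=(200, 700), seed=7)
    data, _ = generate_benchmark(config)
    return data


@pytest.fixture(scope="session")
def tiny_config():
    """Config small enough that full training takes a few seconds."""
    return fast_config(maxlen=250, pretrain_epochs=6, fusion_epochs=4,
                      finetune_epochs=2, batch_size=32, seed=3)


@pytest.fixture
def uniform_table() -> HexamerTable:
    f = np.full(4096, 1.0 / 4096)
    return HexamerTable(f.copy(), f.copy())


@pytest.fixture
def random_table(rng) -> HexamerTable:
    fc = rng.random(4096) + 0.01
    fnc = rng.random(4096) + 0.01
    return HexamerTable(fc / fc.sum(), fnc / fnc.sum())
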