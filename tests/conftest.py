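import pytest

from ipaw.synthetic_fixtures import (
    SpectrumBenchSpec,
    ToyGenomeSpec,
    make_spectra,
    make_toy_genome,
)

TOY_SEED = 7
BENCH_SEED = 3


@pytest.fixture(scope="session")
def toy_genome():
    return make_toy_genome(ToyGenomeSpec(), seed=TOY_SEED)


@pytest.fixture(scope="session")
def spectrum_bench():
    return make_spectra(SpectrumBenchSpec(), seed=BENCH_SEED)
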