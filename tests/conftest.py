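import pytest

from metexpand.fixtures import generate_toy_universe, load_benchmark
from metexpand.pipeline import run_universe


@pytest.fixture(scope="session")
def benchmark():
    candidates, ref, formulas = load_benchmark()
    return candidates, ref, formulas


@pytest.fixture(scope="session")
def toy():
    return generate_toy_universe(seed=1)


@pytest.fixture(scope="session")
def toy_result(toy):
    return run_universe(toy)
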