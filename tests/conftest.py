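import logging

import numpy as np
import pytest

logging.getLogger("hairpinhunter").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_rna(rng, length, p=None):
    return "".join(rng.choice(list("ACGU"), size=length, p=p))


@pytest.fixture(scope="session")
def mirna_bench():
    """Packaged seed-42 miRNA discovery benchmark (shared; ~20 s)."""
    from hairpinhunter.pipeline import run_mirna_benchmark

    return run_mirna_benchmark(42)


@pytest.fixture(scope="session")
def lncrna_bench():
    from hairpinhunter.pipeline import run_lncrna_benchmark

    return run_lncrna_benchmark(42)


@pytest.fixture(scope="session")
def target_bench():
    from hairpinhunter.pipeline import run_target_benchmark

    return run_target_benchmark(42)
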