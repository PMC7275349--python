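import numpy as np
import pytest

from pathdr.model import RunConfig
from pathdr.synth import SynthConfig, generate_world
from pathdr.validate import run_benchmark, validate_benchmark


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_world():
    """A scaled-down synthetic world for fast unit-level checks."""
    cfg = SynthConfig(
        n_genes=400,
        n_pathways=12,
        pathway_size_range=(6, 10),
        n_diseases=3,
        drivers_per_disease=3,
        n_random_drugs=5,
        seed=7,
    )
    return generate_world(cfg)


@pytest.fixture(scope="session")
def default_benchmark():
    """The standard seeded benchmark pushed through the whole pipeline."""
    run = run_benchmark(SynthConfig(seed=11), RunConfig(seed=11))
    report = validate_benchmark(run, n_boot_auc=200)
    return run, report


@pytest.fixture(scope="session")
def null_benchmark():
    """Signal-free control: planted drugs decoupled from their labels."""
    cfg = SynthConfig(seed=11, n_diseases=40, n_random_drugs=0, decouple_drugs=True)
    run = run_benchmark(cfg, RunConfig(seed=11))
    report = validate_benchmark(run, n_boot_auc=200)
    return run, report
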