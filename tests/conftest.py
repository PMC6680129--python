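from pathlib import Path

import pytest

from hybridase.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def clean_study(tmp_path_factory):
    """Error-free simulated study: truth labels are exact by construction."""
    cfg = SimulationConfig(
        n_genes=30, depth=60, error_rate=0.0, seed=11,
        ase_fraction=0.2, splice_fraction=0.5, ass_fraction=0.5,
    )
    out = tmp_path_factory.mktemp("clean_study")
    return simulate_study(cfg, out)


@pytest.fixture(scope="session")
def noisy_study(tmp_path_factory):
    """Simulated study at default (non-zero) sequencing error."""
    cfg = SimulationConfig(n_genes=25, depth=60, seed=23, imprinted_fraction=0.1)
    out = tmp_path_factory.mktemp("noisy_study")
    return simulate_study(cfg, out)


@pytest.fixture(scope="session")
def tests_dir() -> Path:
    return Path(__file__).parent
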