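import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/oracles.py

from symbioscreen.simulate import SimulationConfig, emit_dataset


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A 6-genome, 30-family synthetic dataset with ground truth."""
    outdir = tmp_path_factory.mktemp("sim_small")
    config = SimulationConfig(n_genomes=6, n_cogs=30, apni_pair_length=20_000, seed=11)
    truth = emit_dataset(config, outdir, overwrite=True)
    return config, truth, outdir
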