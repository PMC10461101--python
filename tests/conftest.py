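from __future__ import annotations

import pytest

from mirwoodnet import simulate_and_configure, run_all
from mirwoodnet.config import SyntheticConfig


@pytest.fixture(scope="session")
def zero_noise_run(tmp_path_factory):
    """Full pipeline on the zero-noise planted dataset (shared, read-only)."""
    cfg = SyntheticConfig(seed=11).zero_noise()
    workdir = tmp_path_factory.mktemp("zero_noise")
    truth, run_cfg = simulate_and_configure(cfg, workdir)
    result = run_all(run_cfg)
    return cfg, truth, result


@pytest.fixture(scope="session")
def small_genome(tmp_path_factory):
    """Genome bundle only (no reads/pipeline), default noise."""
    from mirwoodnet.synth import make_genome

    cfg = SyntheticConfig(seed=5)
    return cfg, make_genome(cfg)
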