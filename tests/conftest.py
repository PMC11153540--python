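import numpy as np
import pytest

from morphorate.synthetic_data import SimulationConfig, make_fixture


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """A default 8-tip synthetic dataset shared across read-only tests."""
    out = tmp_path_factory.mktemp("fixture")
    cfg = SimulationConfig(n_tips=8, seed=11, n_specimens_per_tip=5)
    make_fixture(cfg, out, force=True)
    return out


def random_configs(rng, n, k, spread=0.3):
    """Random non-degenerate landmark configurations around a k-gon."""
    theta = 2 * np.pi * np.arange(k) / k
    base = np.column_stack([np.cos(theta), np.sin(theta)])
    return [base + rng.normal(0, spread, (k, 2)) for _ in range(n)]
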