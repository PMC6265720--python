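import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from siterates.pipeline import PipelineConfig, run_all
from siterates.simulate import SimulationConfig, simulate_family


@pytest.fixture(scope="session")
def small_family():
    """A modest simulated family with ground truth (10 taxa, 200 sites)."""
    cfg = SimulationConfig(n_taxa=10, n_sites=200, seed=42)
    return simulate_family(cfg, "small")


@pytest.fixture(scope="session")
def calibrated_run(tmp_path_factory):
    """The calibrated 20-family synthetic pipeline run: disorder x2.0,
    coil x1.3, linker x1.5, disordered-structured x0.5, noise 0.05."""
    workdir = tmp_path_factory.mktemp("calibrated")
    cfg = PipelineConfig(n_families=20, seed=1)
    return run_all(cfg, workdir)
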