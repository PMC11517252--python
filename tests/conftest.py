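import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from eep.pipeline import PipelineConfig, run_all
from eep.simdata import SimulationConfig, simulate_library

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    """A small but fully featured library: 3 promoters x 14 fragments."""
    return SimulationConfig(n_promoters=3, n_enhancers=10, n_controls=8,
                            barcodes_per_combination=8, depth_cdna=1e6,
                            depth_pdna=1e6, seed=11)


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simulate_library(small_config)


@pytest.fixture(scope="session")
def small_bundle(small_config, tmp_path_factory):
    cfg = PipelineConfig(outdir=str(tmp_path_factory.mktemp("run")), seed=11)
    cfg.simulation = small_config
    return run_all(cfg)


@pytest.fixture()
def toy_assignments():
    """Hand-built assignment table with one ambiguous and one duplicated barcode."""
    rows = [
        # barcode, promoter, frag1, orient1, frag2, orient2
        ("AAAA", "P01", "E001", "+", "C001", "+"),
        ("CCCC", "P01", "E001", "+", "C002", "+"),
        ("GGGG", "P01", "E002", "+", "C001", "+"),
        ("GGGG", "P01", "E002", "+", "C002", "+"),  # ambiguous: two frag2 ids
        ("TTTT", "P01", "C001", "+", "C002", "+"),
        ("TTTT", "P01", "C001", "+", "C002", "+"),  # exact duplicate row
    ]
    return pd.DataFrame(rows, columns=["barcode", "promoter", "frag1",
                                       "orient1", "frag2", "orient2"])


@pytest.fixture()
def rng():
    return np.random.default_rng(20240101)
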