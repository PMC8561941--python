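import numpy as np
import pytest

from lmdlink.io_data import make_table
from lmdlink import synth


@pytest.fixture
def small_tables():
    """Tiny consistent tripartite tables (a triangle plus a pendant pair)."""
    lnc_dis = make_table(
        "lncRNA", "disease", [("L1", "D1"), ("L1", "D2"), ("L2", "D1")]
    )
    lnc_mir = make_table("lncRNA", "miRNA", [("L1", "M1"), ("L2", "M1")])
    mir_dis = make_table("miRNA", "disease", [("M1", "D1")])
    return lnc_dis, lnc_mir, mir_dis


@pytest.fixture(scope="session")
def synth_small():
    """Moderate planted-structure dataset shared by pipeline-level tests."""
    cfg = synth.SynthConfig(n_lnc=60, n_mir=30, n_dis=30, seed=7)
    return synth.generate(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
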