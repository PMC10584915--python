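import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`

from presnrna.synthetic import SimConfig, make_family, make_nss_template


@pytest.fixture(scope="session")
def template():
    """One planted-NSS template: (sequence, structure, sm interval)."""
    return make_nss_template(seed=1)


@pytest.fixture(scope="session")
def small_family():
    """Low-divergence 4-species family without decoys (fast to fold)."""
    cfg = SimConfig.default(seed=7, n_species=4, divergence=0.03,
                            decoy_fragment_rate=0.0, decoy_smless_rate=0.0)
    return make_family(cfg)


@pytest.fixture(scope="session")
def decoy_family():
    """Family with known injected decoys for filter accounting."""
    cfg = SimConfig.default(seed=3, n_species=4,
                            decoy_fragment_rate=0.5, decoy_smless_rate=0.4)
    return make_family(cfg)
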