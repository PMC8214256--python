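import numpy as np
import pytest

from bsaqtl.sim import SimConfig
from bsaqtl.pipeline import simulate_study


@pytest.fixture(scope="session")
def tiny_config() -> SimConfig:
    """Small but complete study: one strong QTL on a 2×3-Mb genome."""
    return SimConfig(
        chrom_lengths=(3_000_000, 3_000_000),
        variant_density=0.4,
        n_lines=200,
        bulk_size=20,
        qtl_chrom="chr1",
        qtl_pos=1_500_000,
        target_pve=0.5,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_study(tiny_config):
    return simulate_study(tiny_config)
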