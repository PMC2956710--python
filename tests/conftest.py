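import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from sagekit.synth import AtlasConfig, generate_atlas


@pytest.fixture(scope="session")
def balanced_atlas():
    """Small atlas with five balanced, well-separated trend groups."""
    config = AtlasConfig(
        seed=7,
        n_tag_types=300,
        library_size=6_000,
        trend_mix=(0.2, 0.2, 0.2, 0.2, 0.2),
        effect_size=4.0,
    )
    return generate_atlas(config)


@pytest.fixture(scope="session")
def clean_read_atlas():
    """Tiny atlas plus contamination-free raw reads for round-trip checks."""
    config = AtlasConfig(
        seed=3,
        n_tag_types=120,
        library_size=2_000,
        n_replicates=1,
        trend_mix=(0.2, 0.2, 0.2, 0.2, 0.2),
        frac_bad=0.0,
        frac_low_qf=0.0,
        frac_ldt=0.0,
        frac_duplicate_ditags=0.0,
    )
    return generate_atlas(config)
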