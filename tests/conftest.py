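import numpy as np
import pytest

from halogwas.annotate import CdsRecord


@pytest.fixture
def toy_cds():
    """Six hand-placed CDS features on one scaffold, both strands."""
    return [
        CdsRecord("chr", 1000, 1600, "+", "g1", product="p1", cog_class="G"),
        CdsRecord("chr", 1900, 2400, "-", "g2", product="p2", cog_class="K"),
        CdsRecord("chr", 3200, 3600, "+", "g3", product="p3", cog_class="G"),
        CdsRecord("chr", 120, 300, "-", "g4", product="p4"),
        CdsRecord("chr", 4000, 4200, "+", "g5", product="p5", cog_class="M"),
        CdsRecord("chr", 4800, 4900, "+", "g6", product="p6", cog_class="G"),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
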