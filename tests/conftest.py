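import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from siwr import toy_graph


# Degrees of the 6-node worked example: v1..v6 -> 3, 3, 2, 2, 1, 1.
# The published tabulation chains each column from the previous column at its
# printed 4-decimal precision: W sums the rounded edge weights (5.1700 =
# 2.5850 + 2.5850, where the exact value is 5.169925 -> 5.1699) and W+ sums
# the rounded W column (22.4348 = 7.3399 + 8.3399 + 5.1700 + 1.5850, exact
# 22.4346).  The entropy column matches exact full-precision arithmetic.
TOY_TABLE = {
    # node: (strength W, neighborhood strength W+, entropy E)
    "v1": (7.3399, 22.4348, 1.8161),
    "v2": (8.3399, 24.4348, 1.9309),
    "v3": (5.1700, 20.8498, 1.5579),
    "v4": (3.5850, 12.9249, 1.2067),
    "v5": (1.0000, 4.5850, 0.7567),
    "v6": (1.5850, 8.9249, 0.6748),
}

TOY_EDGE_WEIGHTS = {
    ("v1", "v2"): 3.1699,
    ("v1", "v3"): 2.5850,
    ("v1", "v6"): 1.5850,
    ("v2", "v3"): 2.5850,
    ("v2", "v4"): 2.5850,
    ("v4", "v5"): 1.0000,
}


@pytest.fixture
def toy():
    return toy_graph()
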