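import numpy as np
import pytest

from ismrisk import ReachabilityMatrix, datasets, ssim_to_initial, transitive_closure

# The published final reachability matrix for the 17 blood-supply-chain key
# risks (element order as elicited). Frozen from print; the acceptance test
# checks the computed closure against it cell-for-cell.
PUBLISHED_FINAL_ORDER = (
    "R98 R7 R100 R102 R67 R13 R40 R11 R35 R62 R49 R1 R5 R63 R16 R20 R87".split()
)
PUBLISHED_FINAL_ROWS = """\
1 1 1 1 1 1 1 1 1 0 1 1 1 0 1 1 0
1 1 1 1 1 1 1 1 1 0 1 1 1 0 1 1 0
1 1 1 1 1 1 1 1 1 0 1 1 1 0 1 1 0
1 1 1 1 1 1 1 1 1 0 1 1 1 0 1 1 0
1 1 1 1 1 1 1 1 1 0 1 1 1 0 1 1 0
1 1 1 1 1 1 1 1 1 0 1 1 1 0 1 1 0
0 0 0 0 0 0 1 0 0 0 0 0 0 0 0 0 0
1 1 1 1 1 1 1 1 1 0 1 1 1 0 1 1 0
0 0 0 0 0 0 1 0 1 0 0 0 0 0 0 0 0
1 1 1 1 1 1 1 1 1 1 1 1 1 1 1 1 0
1 1 1 1 1 1 1 1 1 0 1 1 1 0 1 1 0
0 0 0 0 0 0 1 0 1 0 0 1 0 0 0 0 0
1 1 1 1 1 1 1 1 1 0 1 1 1 0 1 1 0
1 1 1 1 1 1 1 1 1 0 1 1 1 1 1 1 0
0 0 0 0 0 0 1 0 1 0 0 0 0 0 1 0 0
1 1 1 1 1 1 1 1 1 0 1 1 1 0 1 1 0
1 1 1 1 1 1 1 1 1 0 1 1 1 0 1 1 1
"""

TEN_RISK_GROUP = frozenset(
    ["R5", "R7", "R11", "R13", "R20", "R49", "R67", "R98", "R100", "R102"]
)


@pytest.fixture(scope="session")
def published_final() -> ReachabilityMatrix:
    vals = np.array(
        [[int(x) for x in row.split()] for row in PUBLISHED_FINAL_ROWS.strip().splitlines()],
        dtype=bool,
    )
    return ReachabilityMatrix(PUBLISHED_FINAL_ORDER, vals)


@pytest.fixture(scope="session")
def bsc_register():
    return datasets.load_bsc_register()


@pytest.fixture(scope="session")
def bsc_degrees():
    return datasets.load_bsc_degrees()


@pytest.fixture(scope="session")
def bsc_ssim():
    return datasets.load_bsc_ssim()


@pytest.fixture(scope="session")
def bsc_final(bsc_ssim):
    """Final reachability matrix computed from the bundled SSIM."""
    return transitive_closure(ssim_to_initial(bsc_ssim))
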