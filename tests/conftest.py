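import numpy as np
import pytest

from fltpet import synthetic


@pytest.fixture(scope="session")
def reference_cohort():
    """The default 12-patient synthetic cohort (one primary + 0-3 nodes each,
    three scans per lesion)."""
    return synthetic.generate_cohort(synthetic.reference_cohort_config(seed=11))


@pytest.fixture(scope="session")
def mixed_fixture():
    """Well-conditioned simulated lesion data for mixed-model cross-checks:
    15 patients x 4 lesions, strong patient heterogeneity."""
    rng = np.random.default_rng(42)
    n_pat, m = 15, 4
    pats = np.repeat(np.arange(n_pat), m)
    b = rng.normal(0, 0.1, n_pat)[pats]
    nodes = (np.arange(n_pat * m) % 2).astype(float)
    z = 0.05 - 0.12 * nodes + b + rng.normal(0, 0.07, n_pat * m)
    y0 = 10 ** rng.normal(0.3, 0.2, n_pat * m)
    y1 = y0 * 10**z
    return y0, y1, pats, nodes
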