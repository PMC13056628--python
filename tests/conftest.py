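import numpy as np
import pandas as pd
import pytest

from mmconn.core import NodeScheme, default_node_scheme


@pytest.fixture(scope="session")
def scheme():
    return default_node_scheme()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_scheme(n_per_hemi: int, affiliations=None) -> NodeScheme:
    """Small synthetic scheme for unit tests (n_per_hemi nodes per side)."""
    rows = []
    for h, H in (("left", "L"), ("right", "R")):
        for i in range(n_per_hemi):
            aff = affiliations[i] if affiliations else "Frontotemporal"
            rows.append({"index": len(rows), "name": f"{H}_r{i}", "hemisphere": h,
                         "affiliation": aff, "kind": "cortical"})
    return NodeScheme(pd.DataFrame(rows))


@pytest.fixture
def tiny_scheme():
    return make_scheme(3)


def random_symmetric(n, rng, positive=False):
    w = rng.normal(size=(n, n))
    if positive:
        w = np.abs(w)
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0.0)
    return w
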