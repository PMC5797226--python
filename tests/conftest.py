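import numpy as np
import pytest

from topomorph import (CONTROL_PARAMS, PersistenceBarcode, generate_random_tree,
                       make_fixture_swc)
from dataclasses import replace


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    d = tmp_path_factory.mktemp("swc_fixtures")
    make_fixture_swc(d)
    return d


@pytest.fixture(scope="session")
def control_tree():
    return generate_random_tree(CONTROL_PARAMS)


def random_barcode(rng, n_bars=None):
    """A synthetic barcode shaped like a radial-distance barcode."""
    if n_bars is None:
        n_bars = int(rng.integers(1, 12))
    births = rng.uniform(5, 60, size=n_bars)
    deaths = births * rng.uniform(0.0, 0.9, size=n_bars)
    return PersistenceBarcode(np.column_stack([births, deaths]))


def outgoing_trees(n, start_seed=0):
    """First n seeded control trees whose branches are all outgoing."""
    from topomorph import is_outgoing
    out, s = [], start_seed
    while len(out) < n:
        t = generate_random_tree(replace(CONTROL_PARAMS, seed=s))
        if is_outgoing(t):
            out.append(t)
        s += 1
    return out
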