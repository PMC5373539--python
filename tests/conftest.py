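import dendropy
import numpy as np
import pandas as pd
import pytest

import thermotrait as tt


def newick_tree(text: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=text, schema="newick")
    tree.is_rooted = True
    return tree


@pytest.fixture
def three_tip_tree():
    """((A:1,B:1):1,C:2) -- VCV and patristic values known by inspection."""
    return newick_tree("((A:1,B:1):1,C:2);")


@pytest.fixture
def star_tree():
    """Five tips radiating from the root with equal branch lengths."""
    return newick_tree("(A:2,B:2,C:2,D:2,E:2);")


@pytest.fixture
def imbalanced_tree():
    """Fully pectinate (caterpillar) 16-tip tree, unit branch lengths."""
    text = "t1:1"
    for i in range(2, 17):
        text = f"({text},t{i}:{i - 1}):1"
    return newick_tree(text[:-2] + ";")


@pytest.fixture(scope="session")
def yule16():
    """One fixed 16-tip pure-birth tree reused across calibration tests."""
    return tt.simulate_tree(16, 1.0, seed=42)


@pytest.fixture
def example_curve():
    """Noiseless Gompertz curve, parameters (A=1.0, mu=0.5, lam=1.0, y0=0.05)."""
    days = (0.0, 1.0, 2.0, 3.0, 5.0, 7.0, 10.0)
    y = tt.gompertz(np.asarray(days), 1.0, 0.5, 1.0, 0.05)
    return tt.GrowthCurve("iso", "sub", 18.0, days, tuple(float(v) for v in y), 3)


@pytest.fixture
def small_plate():
    """Tiny plate table: 2 isolates x 2 substrates, triplicate, two temps."""
    cfg = tt.SimulationConfig(n_taxa=3, n_substrates=2, seed=11,
                              temperatures=(18.0, 26.0))
    table, truth = tt.simulate_plate_experiment(cfg)
    return table, truth
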