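import numpy as np
import pytest

from hgtscreen.phylo_engine import SubstitutionModel


@pytest.fixture(scope="session")
def model():
    """Default equal-exchangeability amino-acid model (rate-homogeneous)."""
    return SubstitutionModel()


def random_newick(labels, rng, bl_low=0.05, bl_high=0.5):
    """Random binary tree over the given labels via random joins."""
    nodes = list(labels)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        la, lb = rng.uniform(bl_low, bl_high, size=2)
        joined = f"({a}:{la:.4f},{b}:{lb:.4f})"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(joined)
    return nodes[0] + ";"
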