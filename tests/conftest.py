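import numpy as np
import pytest

from sushibelt import CompartmentTree, TransportSystem, build_cable, build_tree


def random_tree(rng: np.random.Generator, n: int) -> CompartmentTree:
    """Random rooted tree with parents drawn uniformly among earlier nodes."""
    parent = np.full(n, -1)
    parent[1:] = [rng.integers(0, i) for i in range(1, n)]
    lengths = rng.uniform(0.5, 2.0, size=n)
    return build_tree(parent, lengths)


def random_system(
    rng: np.random.Generator,
    n: int,
    reversible: bool = False,
    absorbing: bool = False,
) -> TransportSystem:
    tree = random_tree(rng, n)
    a = rng.uniform(0.2, 1.5, size=n - 1)
    b = rng.uniform(0.2, 1.5, size=n - 1)
    c = d = None
    if reversible:
        c = rng.uniform(0.05, 0.5, size=n)
        d = rng.uniform(0.05, 0.5, size=n)
    elif absorbing:
        c = np.where(rng.random(n) < 0.4, rng.uniform(0.05, 0.5, size=n), 0.0)
        if not np.any(c > 0):
            c[rng.integers(n)] = 0.2
    u0 = rng.uniform(0.0, 1.0, size=n)
    return TransportSystem(tree, a, b, c=c, d=d, u0=u0)


@pytest.fixture
def rng():
    return np.random.default_rng(20231117)


@pytest.fixture
def cable100():
    return build_cable(100, 800.0)


@pytest.fixture
def branched_tree():
    """Three-section fixture: basal branch plus apical trunk and distal tuft.

    Returns (tree, basal, trunk, distal) where the last three are index
    slices of the respective sections.
    """
    n_sec = 15
    parents = [-1]
    for j in range(n_sec):  # basal chain off the soma
        parents.append(0 if j == 0 else len(parents) - 1)
    trunk_start = len(parents)
    for j in range(n_sec):  # apical trunk off the soma
        parents.append(0 if j == 0 else len(parents) - 1)
    trunk_end = len(parents) - 1
    distal_start = len(parents)
    for j in range(n_sec):  # distal tuft continuing the trunk
        parents.append(trunk_end if j == 0 else len(parents) - 1)
    n = len(parents)
    tree = build_tree(parents, np.full(n, 1.0))
    return (
        tree,
        slice(1, trunk_start),
        slice(trunk_start, distal_start),
        slice(distal_start, n),
    )
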