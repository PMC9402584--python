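import numpy as np
import pytest

from paleofin.io import read_newick_string


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def three_tip_tree():
    return read_newick_string("((A:1,B:1):1,C:2);")


def random_tree_newick(n_tips: int, rng, max_bl: float = 2.0) -> str:
    """Random binary topology with uniform branch lengths (test helper)."""
    items = [f"t{i}" for i in range(n_tips)]
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        b = items.pop(j)
        a = items.pop(i)
        la, lb = rng.uniform(0.1, max_bl, size=2)
        items.append(f"({a}:{la:.4f},{b}:{lb:.4f})")
    return items[0] + ";"


def random_simple_polygon(rng, n: int = 12, concave: bool = False) -> np.ndarray:
    """Random star-shaped (hence simple) polygon around the origin."""
    angles = np.sort(rng.uniform(0, 2 * np.pi, size=n))
    radii = rng.uniform(1.0, 2.0, size=n)
    if concave:
        radii[rng.integers(n)] *= 0.3
    return np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])
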