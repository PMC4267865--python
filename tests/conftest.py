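import numpy as np
import pandas as pd
import pytest

from phyloinv import synthetic_data as sd
from phyloinv.phylo_core import DatedTree


@pytest.fixture
def three_tip_tree():
    """((A:1,B:1):1,C:2); depth 2, ultrametric."""
    return DatedTree.from_newick_string("((A:1,B:1):1,C:2);")


@pytest.fixture
def random_tree():
    """Factory for reproducible random ultrametric trees."""

    def make(n_tips=20, depth=50.0, seed=0):
        return sd.simulate_tree(n_tips, depth, seed)

    return make


@pytest.fixture(scope="session")
def small_bundle():
    """Small synthetic dataset shared by the slower integration tests."""
    cfg = sd.SimConfig(
        n_tips=250,
        n_squares=12,
        plots_per_square=8,
        grid_side=12,
        seed=11,
    )
    return sd.simulate_dataset(cfg), cfg


# ---------------------------------------------------------------------- #
# independent brute-force oracles (kept deliberately naive)
# ---------------------------------------------------------------------- #
def bruteforce_distance(tree: DatedTree, a: str, b: str) -> float:
    """Patristic distance as (root->a) + (root->b) - 2*(root->mrca)."""
    ia, ib = tree.tip_id(a), tree.tip_id(b)

    def path_to_root(i):
        out = [i]
        while tree.parent[i] != -1:
            i = int(tree.parent[i])
            out.append(i)
        return out

    pa, pb = path_to_root(ia), path_to_root(ib)
    mrca = next(n for n in pa if n in set(pb))

    def dist_to(node, anc):
        d = 0.0
        while node != anc:
            d += tree.length[node]
            node = int(tree.parent[node])
        return d

    return dist_to(ia, mrca) + dist_to(ib, mrca)


def bruteforce_contrast_sum(tree: DatedTree, trait: dict) -> float:
    """Recursive weighted down-pass, independent of the vectorized one."""
    bt = tree.resolve_polytomies()
    pos = bt.length[bt.length > 0]
    eps = 1e-8 * (pos.mean() if pos.size else 1.0)
    tip_of = dict(zip(bt.tip_ids.tolist(), bt.tip_labels))
    total = [0.0]

    def down(node):
        # returns (value, adjusted branch length above node)
        if not bt.children[node]:
            v = bt.length[node]
            return float(trait[tip_of[node]]), (v if v > 0 else eps)
        (x1, v1), (x2, v2) = (down(c) for c in bt.children[node])
        total[0] += abs(x1 - x2)
        val = (x1 / v1 + x2 / v2) / (1 / v1 + 1 / v2)
        v = bt.length[node]
        return val, (v if v > 0 else eps) + v1 * v2 / (v1 + v2)

    down(0)
    return total[0]
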