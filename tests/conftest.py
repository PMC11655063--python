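import numpy as np
import pytest

from organrep import Clone, LineageTree


def make_clone(
    v="IGHV1-1",
    j="IGHJ2",
    cdrh3="CARDYW",
    mouse="m1",
    counts=None,
    frequencies=None,
    clonotype_id=None,
):
    return Clone(
        key=(v, j, cdrh3),
        mouse_id=mouse,
        counts=dict(counts or {"spleen": 1}),
        frequencies=dict(frequencies or {"spleen": 1.0}),
        clonotype_id=clonotype_id,
    )


def random_yule_tree(rng, n_tips, organs, mouse="m1", blen_mean=0.05, prefix="s"):
    """Random bifurcating tree with i.i.d. random tip organ labels."""
    from organrep.simulate import _yule_topology

    parent, length, _ = _yule_topology(rng, n_tips, blen_mean)
    n = len(parent)
    children = [[] for _ in range(n)]
    for v in range(1, n):
        children[parent[v]].append(v)
    names = [None] * n
    organ_labels = [None] * n
    tip_no = 0
    for v in range(n):
        if not children[v]:
            tip_no += 1
            names[v] = f"{prefix}{tip_no}"
            organ_labels[v] = organs[rng.integers(len(organs))]
    return LineageTree(parent, length, names, organ_labels, mouse_id=mouse)


def brute_force_parsimony(tree, organs):
    """Exhaustive minimum-change count over all internal labelings."""
    import itertools

    state_index = {o: i for i, o in enumerate(organs)}
    internal = [v for v in range(tree.n_nodes) if tree.children[v]]
    fixed = {t: state_index[tree.organs[t]] for t in tree.tips}
    best = None
    for combo in itertools.product(range(len(organs)), repeat=len(internal)):
        labels = dict(fixed)
        labels.update(zip(internal, combo))
        changes = sum(
            1
            for v in range(tree.n_nodes)
            if tree.parent[v] >= 0 and labels[v] != labels[tree.parent[v]]
        )
        if best is None or changes < best:
            best = changes
    return best


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
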