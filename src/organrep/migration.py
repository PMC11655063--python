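"""Directional organ transitions on B-cell lineage trees.

Internal-node organ states are reconstructed by maximum parsimony (Sankoff
dynamic programming with unit transition cost).  The switch proportion (SP)
statistic for an ordered organ pair (x -> y) is the number of parent-to-child
label changes x -> y summed over all trees, divided by the total number of
changes.  Enrichment is tested by permutation: organ labels are shuffled
within each tree (or pooled among trees within a mouse), delta = observed SP -
permuted SP is recorded per replicate, and the one-sided p-value is the
proportion of replicates with delta <= 0.  To control false positives, each
replicate first down-samples every tree to a maximum tip-to-change ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .trees import LineageTree

__all__ = [
    "filter_trees_input",
    "parsimony_reconstruct",
    "reorder_polytomies",
    "sp_statistic",
    "sp_test",
    "ParsimonyResult",
    "SPResult",
]

_INF = float("inf")


# ---------------------------------------------------------------------------
# Sankoff machinery on array-backed trees


def _tip_states(tree: LineageTree, state_index: Mapping[str, int]) -> list[int]:
    """Tip organ states in ``tree.tips`` order."""
    return [state_index[tree.organs[t]] for t in tree.tips]


def _sankoff_costs(
    children: Sequence[Sequence[int]],
    postorder: Sequence[int],
    tip_state_by_node: Sequence[int],
    n_states: int,
) -> list[list[float]]:
    """Bottom-up minimum-change cost vectors (unit transition cost)."""
    costs: list = [None] * len(children)
    for v in postorder:
        kids = children[v]
        if not kids:
            c = [_INF] * n_states
            c[tip_state_by_node[v]] = 0.0
        else:
            c = [0.0] * n_states
            for u in kids:
                cu = costs[u]
                m = min(cu) + 1.0
                for s in range(n_states):
                    cs = cu[s]
                    c[s] += cs if cs < m else m
        costs[v] = c
    return costs


def _traceback(
    children: Sequence[Sequence[int]],
    parent: Sequence[int],
    postorder: Sequence[int],
    costs: Sequence[Sequence[float]],
    n_states: int,
) -> list[int]:
    """One most-parsimonious labeling.

    Ambiguities are resolved by preferring the parent's state (delaying
    transitions toward the tips), then the lowest state index (lexicographic
    organ order).
    """
    labels = [-1] * len(children)
    root = postorder[-1]
    rc = costs[root]
    best = min(rc)
    labels[root] = rc.index(best)
    for v in reversed(postorder):
        if v == root:
            continue
        p = labels[parent[v]]
        cv = costs[v]
        bt, bc = p, cv[p]
        for t in range(n_states):
            cand = cv[t] + (0.0 if t == p else 1.0)
            if cand < bc:
                bc, bt = cand, t
        labels[v] = bt
    return labels


def _transition_counts(
    children: Sequence[Sequence[int]],
    parent: Sequence[int],
    postorder: Sequence[int],
    tip_state_by_node: Sequence[int],
    n_states: int,
) -> np.ndarray:
    """Directional change-count matrix of one MP reconstruction."""
    costs = _sankoff_costs(children, postorder, tip_state_by_node, n_states)
    labels = _traceback(children, parent, postorder, costs, n_states)
    counts = np.zeros((n_states, n_states), dtype=float)
    root = postorder[-1]
    for v in postorder:
        if v == root:
            continue
        a, b = labels[parent[v]], labels[v]
        if a != b:
            counts[a, b] += 1.0
    return counts


def _min_changes(
    children: Sequence[Sequence[int]],
    postorder: Sequence[int],
    tip_state_by_node: Sequence[int],
    n_states: int,
) -> int:
    costs = _sankoff_costs(children, postorder, tip_state_by_node, n_states)
    return int(min(costs[postorder[-1]]))


def _states_by_node(tree: LineageTree, tip_states: Sequence[int]) -> list[int]:
    by_node = [-1] * tree.n_nodes
    for t, s in zip(tree.tips, tip_states):
        by_node[t] = s
    return by_node


# ---------------------------------------------------------------------------
# Public operations


def filter_trees_input(
    clone_sequences: Mapping[str, Sequence],
    max_size: int = 100,
    min_size: int = 10,
    min_reads: Optional[int] = 3,
    seed: Optional[int] = None,
) -> tuple[dict, dict]:
    """Filter per-clone sequence sets before lineage-tree analysis.

    Rules, applied in order per clone: sequences with fewer than ``min_reads``
    supporting reads are discarded (skipped when ``min_reads`` is None or a
    sequence has no ``count``); clones larger than ``max_size`` sequences are
    down-sampled uniformly at random to ``max_size``; clones with fewer than
    ``min_size`` sequences or with sequences from only one organ are removed.

    ``clone_sequences`` maps a clone id to a list of objects with ``organ``
    and (optionally) ``count`` attributes.  Returns (filtered mapping, report).
    """
    rng = np.random.default_rng(seed)
    out: dict = {}
    report = {
        "dropped_low_read_sequences": 0,
        "downsampled_clones": 0,
        "removed_small_clones": 0,
        "removed_single_organ_clones": 0,
    }
    for clone_id, seqs in clone_sequences.items():
        seqs = list(seqs)
        if min_reads is not None:
            kept = [
                s
                for s in seqs
                if getattr(s, "count", None) is None or s.count >= min_reads
            ]
            report["dropped_low_read_sequences"] += len(seqs) - len(kept)
            seqs = kept
        if len(seqs) > max_size:
            idx = sorted(rng.choice(len(seqs), size=max_size, replace=False))
            seqs = [seqs[i] for i in idx]
            report["downsampled_clones"] += 1
        if len(seqs) < min_size:
            report["removed_small_clones"] += 1
            continue
        if len({s.organ for s in seqs}) < 2:
            report["removed_single_organ_clones"] += 1
            continue
        out[clone_id] = seqs
    return out, report


@dataclass
class ParsimonyResult:
    """Maximum-parsimony ancestral organ reconstruction of one tree."""

    node_labels: list  # organ label per node index (tree order)
    n_changes: int
    transition_counts: pd.DataFrame  # directional organ x organ change counts


def parsimony_reconstruct(
    tree: LineageTree,
    organs: Optional[Sequence[str]] = None,
    strategy: str = "prefer_parent",
) -> ParsimonyResult:
    """Reconstruct internal organ labels minimising the number of changes.

    ``strategy`` controls how ambiguous most-parsimonious labelings are
    handled: ``prefer_parent`` (default) returns the single labeling whose
    ties resolve toward the parent state then lexicographic organ order;
    ``average`` averages transition counts over *all* most-parsimonious
    labelings (small trees only; node_labels then come from prefer_parent).
    """
    organs = sorted(tree.organ_set) if organs is None else list(organs)
    state_index = {o: i for i, o in enumerate(organs)}
    S = len(organs)
    by_node = _states_by_node(tree, _tip_states(tree, state_index))
    costs = _sankoff_costs(tree.children, tree.postorder, by_node, S)
    n_changes = int(min(costs[tree.root]))
    labels = _traceback(tree.children, tree.parent, tree.postorder, costs, S)

    if strategy == "prefer_parent":
        counts = np.zeros((S, S), dtype=float)
        for v in tree.postorder:
            if v == tree.root:
                continue
            a, b = labels[tree.parent[v]], labels[v]
            if a != b:
                counts[a, b] += 1.0
    elif strategy == "average":
        counts = _average_mp_counts(tree, costs, S)
    else:
        raise ValidationError(f"unknown strategy {strategy!r}")

    return ParsimonyResult(
        node_labels=[organs[labels[v]] for v in range(tree.n_nodes)],
        n_changes=n_changes,
        transition_counts=pd.DataFrame(counts, index=organs, columns=organs),
    )


def _average_mp_counts(
    tree: LineageTree, costs: Sequence[Sequence[float]], S: int, limit: int = 100000
) -> np.ndarray:
    """Transition counts averaged over every most-parsimonious labeling."""
    root = tree.root
    min_cost = min(costs[root])
    total = np.zeros((S, S), dtype=float)
    n_labelings = 0

    labels = [-1] * tree.n_nodes
    # preorder over nodes for recursive enumeration
    preorder = list(reversed(tree.postorder))

    def options(v: int, p_state: int) -> list[int]:
        cv = costs[v]
        if v == root:
            return [s for s in range(S) if cv[s] == min_cost]
        best = min(cv[t] + (0.0 if t == p_state else 1.0) for t in range(S))
        return [
            t for t in range(S) if cv[t] + (0.0 if t == p_state else 1.0) == best
        ]

    def recurse(i: int) -> None:
        nonlocal n_labelings
        if n_labelings >= limit:
            raise ValidationError(
                "too many most-parsimonious labelings to enumerate; "
                "use strategy='prefer_parent'"
            )
        if i == len(preorder):
            counts = np.zeros((S, S), dtype=float)
            for v in tree.postorder:
                if v == root:
                    continue
                a, b = labels[tree.parent[v]], labels[v]
                if a != b:
                    counts[a, b] += 1.0
            total[:, :] += counts
            n_labelings += 1
            return
        v = preorder[i]
        p_state = -1 if v == root else labels[tree.parent[v]]
        for s in options(v, p_state):
            labels[v] = s
            recurse(i + 1)
        labels[v] = -1

    recurse(0)
    return total / n_labelings


def reorder_polytomies(tree: LineageTree, tol: float = 1e-12) -> LineageTree:
    """Greedy NNI reordering of zero-length internal-branch clusters.

    Within clusters of internal nodes joined by (near-)zero-length branches,
    nearest-neighbor-interchange moves are applied while they reduce the
    parsimony change count; the returned tree's minimum change count is never
    larger than the input's.  Deterministic given node order; trees without
    zero-length internal branches are returned unchanged.
    """
    zero_edges = [
        v
        for v in range(tree.n_nodes)
        if tree.parent[v] >= 0 and tree.children[v] and tree.length[v] <= tol
    ]
    if not zero_edges:
        return tree
    zero_edge_set = set(zero_edges)

    organs = sorted(tree.organ_set)
    state_index = {o: i for i, o in enumerate(organs)}
    S = len(organs)
    parent = list(tree.parent)
    children = [list(c) for c in tree.children]
    by_node = _states_by_node(tree, _tip_states(tree, state_index))
    root = tree.root

    def postorder_of() -> list[int]:
        order: list[int] = []
        stack = [(root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                order.append(node)
            else:
                stack.append((node, True))
                for c in reversed(children[node]):
                    stack.append((c, False))
        return order

    def score() -> int:
        return _min_changes(children, postorder_of(), by_node, S)

    def swap(x: int, y: int) -> None:
        px, py = parent[x], parent[y]
        children[px][children[px].index(x)] = y
        children[py][children[py].index(y)] = x
        parent[x], parent[y] = py, px

    def candidate_moves() -> list[tuple[int, int]]:
        moves: list[tuple[int, int]] = []
        for v in zero_edges:
            u = parent[v]
            # exchange a child of v with a sibling subtree of v
            for a in children[u]:
                if a == v:
                    continue
                for b in children[v]:
                    moves.append((a, b))
            # exchange children across two zero-length sibling clades
            # (covers polytomies whose cluster passes through the parent)
            for w in children[u]:
                if w <= v or w not in zero_edge_set:
                    continue
                for b in children[v]:
                    for c in children[w]:
                        moves.append((b, c))
        return moves

    best = score()
    improved = True
    passes = 0
    while improved and passes < 50:
        improved = False
        passes += 1
        restart = True
        while restart:
            restart = False
            for a, b in candidate_moves():
                swap(a, b)
                s = score()
                if s < best:
                    best = s
                    improved = True
                    restart = True  # child lists changed; re-enumerate moves
                    break
                swap(b, a)  # revert

    return LineageTree(
        parent,
        tree.length,
        tree.names,
        tree.organs,
        clonotype_id=tree.clonotype_id,
        mouse_id=tree.mouse_id,
        attrs=tree.attrs,
    )


def sp_statistic(
    trees: Iterable[LineageTree],
    organs: Optional[Sequence[str]] = None,
    strategy: str = "prefer_parent",
) -> pd.DataFrame:
    """Directional switch-proportion matrix over a set of lineage trees.

    SP[x, y] is the fraction of all parsimony-inferred organ changes that go
    x -> y; entries sum to 1.  All-NaN (with a warning) when no tree contains
    a transition.
    """
    trees = list(trees)
    if not trees:
        raise ValidationError("sp_statistic requires at least one tree")
    if organs is None:
        organs = sorted(set().union(*(t.organ_set for t in trees)))
    total = np.zeros((len(organs), len(organs)), dtype=float)
    for t in trees:
        total += parsimony_reconstruct(t, organs=organs, strategy=strategy).transition_counts.values
    tot = total.sum()
    if tot == 0:
        warnings.warn("no organ transitions in any tree; SP undefined")
        total[:] = np.nan
    else:
        total /= tot
    return pd.DataFrame(total, index=list(organs), columns=list(organs))


@dataclass
class SPResult:
    """Switch-proportion permutation-test result.

    ``observed`` holds the SP matrix of the unpermuted, un-down-sampled trees;
    ``p_values[x, y]`` is the proportion of replicates with delta <= 0 for the
    pair x -> y (symmetric matrices in among_trees mode, where transitions are
    summed over both directions).
    """

    organs: list
    observed: pd.DataFrame
    p_values: pd.DataFrame
    deltas: np.ndarray  # (replicates, n_organs, n_organs)
    replicates: int
    mode: str
    seed: Optional[int]

    def significant_pairs(self, alpha: float = 0.05) -> list[tuple[str, str]]:
        out = []
        for i, a in enumerate(self.organs):
            for j, b in enumerate(self.organs):
                if i != j and self.p_values.iloc[i, j] < alpha:
                    out.append((a, b))
        return out


def _sp_from_counts(counts: np.ndarray, mode: str = "within_tree") -> np.ndarray:
    """Normalise directional change counts into an SP matrix.

    In among_trees mode the matrix is symmetrised (both directions summed,
    shown at [i, j] and [j, i]) but still normalised by the total change
    count, so the upper triangle sums to 1.
    """
    tot = counts.sum()
    if tot == 0:
        return np.zeros_like(counts)
    if mode == "among_trees":
        return (counts + counts.T) / tot
    return counts / tot


def sp_test(
    trees: Sequence[LineageTree],
    replicates: int = 1000,
    mode: str = "within_tree",
    tip_change_ratio_cap: float = 20.0,
    seed: Optional[int] = None,
    organs: Optional[Sequence[str]] = None,
    reorder: bool = True,
) -> SPResult:
    """Permutation test for directional enrichment of organ transitions.

    Per replicate, every tree is down-sampled (tips pruned uniformly at
    random, topology collapsed, never re-estimated) until its tip count is at
    most ``tip_change_ratio_cap`` times its parsimony change count; the
    observed SP (real labels) and a permuted SP are then computed on the same
    down-sampled trees and their difference delta recorded per organ pair.

    ``mode='within_tree'`` shuffles tip labels within each tree and tests
    ordered (directional) pairs; ``mode='among_trees'`` pools tip labels among
    trees within each mouse and tests unordered pairs (transitions summed over
    both directions).  p[pair] = (# replicates with delta <= 0) / replicates.
    """
    trees = list(trees)
    if not trees:
        raise ValidationError("sp_test requires at least one tree")
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    if tip_change_ratio_cap <= 0:
        raise ValidationError("tip_change_ratio_cap must be positive")
    if mode not in ("within_tree", "among_trees"):
        raise ValidationError(f"unknown mode {mode!r}")

    if reorder:
        trees = [reorder_polytomies(t) for t in trees]
    if organs is None:
        organs = sorted(set().union(*(t.organ_set for t in trees)))
    organs = list(organs)
    state_index = {o: i for i, o in enumerate(organs)}
    S = len(organs)
    rng = np.random.default_rng(seed)

    # headline observed SP on the full trees
    full_counts = np.zeros((S, S), dtype=float)
    preps = []
    for t in trees:
        by_node = _states_by_node(t, _tip_states(t, state_index))
        full_counts += _transition_counts(t.children, t.parent, t.postorder, by_node, S)
        preps.append(t)
    total_changes = full_counts.sum()
    if total_changes > 0:
        observed = _sp_from_counts(full_counts, mode)
    else:
        observed = np.full((S, S), np.nan)
    observed_df = pd.DataFrame(observed, index=organs, columns=organs)

    if total_changes == 0:
        warnings.warn("no organ transitions; SP test p-values are undefined")
        nan = np.full((S, S), np.nan)
        return SPResult(
            organs=organs,
            observed=observed_df,
            p_values=pd.DataFrame(nan, index=organs, columns=organs),
            deltas=np.zeros((0, S, S)),
            replicates=replicates,
            mode=mode,
            seed=seed,
        )

    mouse_groups: dict[str, list[int]] = {}
    for i, t in enumerate(trees):
        mouse_groups.setdefault(t.mouse_id, []).append(i)

    deltas = np.zeros((replicates, S, S), dtype=float)
    for r in range(replicates):
        rep_trees = []
        for t in trees:
            tip_states = _tip_states(t, state_index)
            by_node = _states_by_node(t, tip_states)
            changes = _min_changes(t.children, t.postorder, by_node, S)
            if changes > 0 and t.n_tips > tip_change_ratio_cap * changes:
                k = max(2, int(tip_change_ratio_cap * changes))
                keep = sorted(rng.choice(t.tips, size=k, replace=False))
                t = t.prune_to_tips(keep)
                tip_states = _tip_states(t, state_index)
            rep_trees.append((t, tip_states))

        obs_counts = np.zeros((S, S), dtype=float)
        perm_counts = np.zeros((S, S), dtype=float)
        for t, tip_states in rep_trees:
            obs_counts += _transition_counts(
                t.children, t.parent, t.postorder, _states_by_node(t, tip_states), S
            )
        if mode == "within_tree":
            for t, tip_states in rep_trees:
                shuffled = [tip_states[i] for i in rng.permutation(len(tip_states))]
                perm_counts += _transition_counts(
                    t.children, t.parent, t.postorder, _states_by_node(t, shuffled), S
                )
        else:  # among_trees: pool labels per mouse, reshuffle across trees
            for indices in mouse_groups.values():
                group = [rep_trees[i] for i in indices]
                pooled = [s for _, ts in group for s in ts]
                order = rng.permutation(len(pooled))
                pos = 0
                for t, ts in group:
                    k = len(ts)
                    shuffled = [pooled[order[pos + i]] for i in range(k)]
                    pos += k
                    perm_counts += _transition_counts(
                        t.children, t.parent, t.postorder, _states_by_node(t, shuffled), S
                    )
        deltas[r] = _sp_from_counts(obs_counts, mode) - _sp_from_counts(perm_counts, mode)

    p = (deltas <= 0).mean(axis=0)
    p_df = pd.DataFrame(p, index=organs, columns=organs)
    np.fill_diagonal(p_df.values, np.nan)
    return SPResult(
        organs=organs,
        observed=observed_df,
        p_values=p_df,
        deltas=deltas,
        replicates=replicates,
        mode=mode,
        seed=seed,
    )
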