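"""Array-backed rooted lineage trees with organ-labeled tips.

The root represents the most basal ancestral node of the clonal lineage; the
unmutated germline sequence sits (implicitly) above the root and carries no
organ state, so edges to it are never counted as organ transitions.  The
array layout (parent pointers plus a cached postorder) keeps ancestral-state
reconstruction cheap enough to run inside permutation loops.
"""

from __future__ import annotations

from typing import Optional, Sequence

from .errors import ValidationError

__all__ = ["LineageTree"]


class LineageTree:
    """Rooted tree over ``n_nodes`` nodes indexed 0..n-1.

    Parameters
    ----------
    parent
        parent[i] is the parent index of node i; the root has parent -1.
    length
        Branch length of the edge above each node (substitutions per site,
        informational only; 0.0 above the root).
    names
        Tip names (None for internal nodes).
    organs
        Tip organ labels (None for internal nodes).
    """

    __slots__ = (
        "parent",
        "children",
        "length",
        "names",
        "organs",
        "root",
        "postorder",
        "tips",
        "clonotype_id",
        "mouse_id",
        "attrs",
    )

    def __init__(
        self,
        parent: Sequence[int],
        length: Sequence[float],
        names: Sequence[Optional[str]],
        organs: Sequence[Optional[str]],
        clonotype_id: str = "",
        mouse_id: str = "m1",
        attrs: Optional[dict] = None,
    ):
        n = len(parent)
        if not (len(length) == len(names) == len(organs) == n):
            raise ValidationError("parent/length/names/organs must have equal length")
        self.parent = list(parent)
        self.length = [float(x) for x in length]
        self.names = list(names)
        self.organs = list(organs)
        self.clonotype_id = clonotype_id
        self.mouse_id = mouse_id
        self.attrs = dict(attrs or {})

        roots = [i for i, p in enumerate(self.parent) if p < 0]
        if len(roots) != 1:
            raise ValidationError(f"tree must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                self.children[p].append(i)
        self.tips = [i for i in range(n) if not self.children[i]]
        for t in self.tips:
            if self.organs[t] is None:
                raise ValidationError(f"tip {self.names[t] or t} has no organ label")
        self.postorder = self._compute_postorder()

    def _compute_postorder(self) -> list[int]:
        order: list[int] = []
        stack = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                order.append(node)
            else:
                stack.append((node, True))
                for c in reversed(self.children[node]):
                    stack.append((c, False))
        return order

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    @property
    def tip_organs(self) -> list[str]:
        return [self.organs[t] for t in self.tips]

    @property
    def organ_set(self) -> set:
        return {self.organs[t] for t in self.tips}

    def copy(self) -> "LineageTree":
        return LineageTree(
            self.parent,
            self.length,
            self.names,
            self.organs,
            clonotype_id=self.clonotype_id,
            mouse_id=self.mouse_id,
            attrs=self.attrs,
        )

    def with_tip_organs(self, organs_by_tip: Sequence[str]) -> "LineageTree":
        """Copy of the tree with tip organ labels replaced (in ``self.tips`` order)."""
        organs = list(self.organs)
        for t, o in zip(self.tips, organs_by_tip):
            organs[t] = o
        return LineageTree(
            self.parent,
            self.length,
            self.names,
            organs,
            clonotype_id=self.clonotype_id,
            mouse_id=self.mouse_id,
            attrs=self.attrs,
        )

    def prune_to_tips(self, keep_tips: Sequence[int]) -> "LineageTree":
        """Subtree spanned by ``keep_tips`` (node indices of tips to retain).

        Internal nodes left with a single child are collapsed and their branch
        lengths summed; a unary root is collapsed into its child.
        """
        keep = set(keep_tips)
        if not keep:
            raise ValidationError("cannot prune to zero tips")
        for t in keep:
            if self.children[t]:
                raise ValidationError(f"node {t} is not a tip")

        # nodes on a root->kept-tip path
        retain = set()
        for t in keep:
            v = t
            while v >= 0 and v not in retain:
                retain.add(v)
                v = self.parent[v]

        new_parent: list[int] = []
        new_length: list[float] = []
        new_names: list[Optional[str]] = []
        new_organs: list[Optional[str]] = []

        def add_node(parent_idx: int, length: float, name, organ) -> int:
            new_parent.append(parent_idx)
            new_length.append(length)
            new_names.append(name)
            new_organs.append(organ)
            return len(new_parent) - 1

        def build(old: int, parent_idx: int, carried: float) -> None:
            kids = [c for c in self.children[old] if c in retain]
            if not kids:  # kept tip
                add_node(parent_idx, carried + self.length[old], self.names[old], self.organs[old])
                return
            if len(kids) == 1:  # collapse unary internal node
                build(kids[0], parent_idx, carried + self.length[old])
                return
            idx = add_node(parent_idx, carried + self.length[old], self.names[old], self.organs[old])
            for c in kids:
                build(c, idx, 0.0)

        # collapse a chain of unary nodes below the root
        start = self.root
        while True:
            kids = [c for c in self.children[start] if c in retain]
            if len(kids) == 1 and start not in keep:
                start = kids[0]
            else:
                break
        if not self.children[start] or start in keep:
            # degenerate single-tip "tree"
            add_node(-1, 0.0, self.names[start], self.organs[start])
        else:
            idx = add_node(-1, 0.0, self.names[start], self.organs[start])
            for c in [c for c in self.children[start] if c in retain]:
                build(c, idx, 0.0)

        return LineageTree(
            new_parent,
            new_length,
            new_names,
            new_organs,
            clonotype_id=self.clonotype_id,
            mouse_id=self.mouse_id,
            attrs=self.attrs,
        )

    def to_newick(self) -> str:
        """Newick string with tip names and branch lengths."""

        def fmt(x: float) -> str:
            return format(x, "g")

        def render(v: int) -> str:
            if not self.children[v]:
                return f"{self.names[v] or 'tip%d' % v}:{fmt(self.length[v])}"
            inner = ",".join(render(c) for c in self.children[v])
            if v == self.root:
                return f"({inner})"
            return f"({inner}):{fmt(self.length[v])}"

        return render(self.root) + ";"

    def __repr__(self) -> str:
        return (
            f"LineageTree({self.n_tips} tips, organs={sorted(self.organ_set)}, "
            f"clonotype={self.clonotype_id!r}, mouse={self.mouse_id!r})"
        )
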