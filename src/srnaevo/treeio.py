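"""Rooted phylogeny container and queries.

The working tree is a rooted phylogeny with branch lengths in amino-acid
substitutions per position.  It is immutable input for the rest of the
pipeline: no branch-length re-estimation, no re-rooting.  Internal nodes
without labels are auto-named deterministically by post-order index
("N0001", "N0002", ...) so that gain nodes are referable across runs.
Polytomies are kept as-is; zero-length branches are allowed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterator

import dendropy

__all__ = [
    "Phylogeny",
    "TreeNode",
    "NewickParseError",
    "TreeValidationError",
    "parse_newick",
    "write_newick",
    "ancestor_chain",
    "patristic_distance",
    "prune_to",
    "read_label_list",
]


class NewickParseError(ValueError):
    """Malformed newick input."""


class TreeValidationError(ValueError):
    """Structurally invalid tree (duplicate leaves, empty prune result, ...)."""


@dataclass
class TreeNode:
    name: str
    parent: str | None
    children: list[str] = field(default_factory=list)
    length: float = 0.0  # branch length to parent; 0.0 for the root

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Phylogeny:
    """Identifier-addressed rooted tree.

    ``nodes`` maps node name -> :class:`TreeNode`.  Exactly one node has
    ``parent is None`` (the root).  Leaf labels are unique by construction.
    """

    nodes: dict[str, TreeNode]
    root: str

    # -- queries -----------------------------------------------------------

    def leaves(self) -> list[str]:
        return [n.name for n in self.postorder() if n.is_leaf]

    def leaf_set(self) -> set[str]:
        return {n for n, nd in self.nodes.items() if nd.is_leaf}

    def postorder(self) -> Iterator[TreeNode]:
        stack: list[tuple[str, bool]] = [(self.root, False)]
        while stack:
            name, expanded = stack.pop()
            node = self.nodes[name]
            if expanded or node.is_leaf:
                yield node
            else:
                stack.append((name, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = self.nodes[stack.pop()]
            yield node
            stack.extend(reversed(node.children))

    def ancestor_chain(self, leaf: str) -> list[str]:
        """Node names from the leaf's parent up to and including the root."""
        if leaf not in self.nodes:
            raise KeyError(f"unknown leaf {leaf!r}")
        chain = []
        cur = self.nodes[leaf].parent
        while cur is not None:
            chain.append(cur)
            cur = self.nodes[cur].parent
        return chain

    def patristic_distance(self, node: str, leaf: str) -> float:
        """Sum of branch lengths from ``node`` down to ``leaf``.

        ``node`` must be the leaf itself or one of its ancestors.
        """
        if node not in self.nodes:
            raise KeyError(f"unknown node {node!r}")
        dist = 0.0
        cur = leaf
        while cur != node:
            nd = self.nodes[cur]
            if nd.parent is None:
                raise ValueError(
                    f"node {node!r} is not on the ancestor chain of {leaf!r}"
                )
            dist += nd.length
            cur = nd.parent
        return dist

    def depth(self, node: str) -> float:
        """Distance from the root to ``node``."""
        dist = 0.0
        cur = node
        while self.nodes[cur].parent is not None:
            dist += self.nodes[cur].length
            cur = self.nodes[cur].parent
        return dist

    def clade_leaves(self, node: str) -> set[str]:
        """Leaf labels below (and including, if a leaf) ``node``."""
        out: set[str] = set()
        stack = [node]
        while stack:
            nd = self.nodes[stack.pop()]
            if nd.is_leaf:
                out.add(nd.name)
            else:
                stack.extend(nd.children)
        return out

    # -- editing -----------------------------------------------------------

    def prune_to(self, keep: set[str], exclude: set[str] = frozenset()) -> "Phylogeny":
        """Restrict to leaves ``keep - exclude``, collapsing unifurcations.

        Patristic distances between retained leaves are preserved exactly
        (collapsed branch lengths are summed).
        """
        retained = (set(keep) & self.leaf_set()) - set(exclude)
        if not retained:
            raise TreeValidationError("pruning would remove every leaf")
        nodes = {n: TreeNode(v.name, v.parent, list(v.children), v.length)
                 for n, v in self.nodes.items()}

        # drop unwanted leaves, then iteratively strip childless internals
        changed = True
        while changed:
            changed = False
            for name in list(nodes):
                nd = nodes[name]
                if not nd.children and name not in retained:
                    if nd.parent is not None:
                        nodes[nd.parent].children.remove(name)
                    del nodes[name]
                    changed = True

        # collapse degree-2 internal nodes (non-root): merge into child
        for name in list(nodes):
            nd = nodes.get(name)
            if nd is None or nd.parent is None or len(nd.children) != 1:
                continue
            child = nodes[nd.children[0]]
            child.length += nd.length
            child.parent = nd.parent
            parent = nodes[nd.parent]
            parent.children[parent.children.index(name)] = child.name
            del nodes[name]

        root = next(n for n, v in nodes.items() if v.parent is None)
        # a unifurcating root is collapsed into its child
        while len(nodes[root].children) == 1:
            child = nodes[root].children[0]
            del nodes[root]
            nodes[child].parent = None
            nodes[child].length = 0.0
            root = child
        return Phylogeny(nodes=nodes, root=root)

    # -- serialization -----------------------------------------------------

    def to_newick(self) -> str:
        def fmt(name: str) -> str:
            nd = self.nodes[name]
            if nd.is_leaf:
                return f"{nd.name}:{nd.length:.10g}"
            inner = ",".join(fmt(c) for c in nd.children)
            return f"({inner}){nd.name}:{nd.length:.10g}"

        return fmt(self.root) + ";"


def _validate(tree: Phylogeny) -> Phylogeny:
    leaves = [n.name for n in tree.postorder() if n.is_leaf]
    dupes = {x for x in leaves if leaves.count(x) > 1}
    if dupes:
        raise TreeValidationError(f"duplicate leaf labels: {sorted(dupes)}")
    for nd in tree.nodes.values():
        if nd.length < 0:
            raise TreeValidationError(f"negative branch length at {nd.name!r}")
    return tree


def parse_newick(text: str) -> Phylogeny:
    """Parse a newick string into a :class:`Phylogeny`.

    Unlabeled internal nodes get deterministic post-order names
    ("N0001"...).  Duplicate leaf labels raise
    :class:`TreeValidationError`; syntax errors raise
    :class:`NewickParseError` carrying the tokenizer's position message.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            suppress_leaf_node_taxa=True,  # duplicate labels reach our validator
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickParseError(f"malformed newick: {exc}") from exc

    nodes: dict[str, TreeNode] = {}
    names: dict[int, str] = {}
    counter = 0
    for dnode in dtree.postorder_node_iter():
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon else dnode.label
            if label is None:
                raise NewickParseError("leaf without a label")
        else:
            label = dnode.label
            if label is None:
                counter += 1
                label = f"N{counter:04d}"
        if label in nodes:
            raise TreeValidationError(f"duplicate node label: {label!r}")
        names[id(dnode)] = label
        length = dnode.edge.length if dnode.edge.length is not None else 0.0
        nodes[label] = TreeNode(name=label, parent=None, length=float(length))
    for dnode in dtree.postorder_node_iter():
        label = names[id(dnode)]
        for child in dnode.child_nodes():
            cname = names[id(child)]
            nodes[label].children.append(cname)
            nodes[cname].parent = label
    root = names[id(dtree.seed_node)]
    nodes[root].length = float(dtree.seed_node.edge.length or 0.0)
    return _validate(Phylogeny(nodes=nodes, root=root))


def write_newick(tree: Phylogeny) -> str:
    """Serialize; ``parse_newick(write_newick(t))`` is isomorphic to ``t``.

    A single-leaf tree is written as ``"A:0.0;"`` (leaf-as-root dialect).
    """
    return tree.to_newick()


def ancestor_chain(tree: Phylogeny, leaf: str) -> list[str]:
    return tree.ancestor_chain(leaf)


def patristic_distance(tree: Phylogeny, node: str, leaf: str) -> float:
    return tree.patristic_distance(node, leaf)


def prune_to(tree: Phylogeny, keep: set[str], exclude: set[str] = frozenset()) -> Phylogeny:
    return tree.prune_to(keep, exclude)


def read_label_list(path) -> set[str]:
    """Read an exclusion/keep list: one label per line, '#' comments allowed."""
    out = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line)
    return out
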