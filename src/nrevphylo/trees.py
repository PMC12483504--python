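"""Rooted phylogenetic trees: Newick I/O, rerooting, and tree surgery.

The internal representation is a plain node/pointer tree kept deliberately
small; Newick parsing is delegated to dendropy and only the structure is
converted.  Branch lengths are in expected substitutions per site.
"""

from __future__ import annotations

import io

import dendropy

from .errors import DomainError, FormatError, LabellingError


class Node:
    __slots__ = ("children", "parent", "length", "name")

    def __init__(self, name=None, length=0.0):
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.length: float = length
        self.name = name

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return not self.children


class RootedTree:
    """A rooted topology with branch lengths and uniquely labelled tips."""

    def __init__(self, root: Node):
        self.root = root
        labels = [t.name for t in self.tips()]
        if len(set(labels)) != len(labels):
            raise DomainError("tip labels must be unique")
        if any(n.length < 0 for n in self.preorder() if n is not root):
            raise DomainError("branch lengths must be >= 0")

    # -- traversal --------------------------------------------------------
    def preorder(self):
        stack = [self.root]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(reversed(n.children))

    def postorder(self):
        out = list(self.preorder())
        return reversed(out)

    def tips(self):
        return [n for n in self.preorder() if n.is_tip]

    def tip_labels(self):
        return [t.name for t in self.tips()]

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    def branches(self):
        """All non-root nodes (each owns the branch to its parent)."""
        return [n for n in self.preorder() if n.parent is not None]

    # -- manipulation -----------------------------------------------------
    def copy(self) -> "RootedTree":
        def clone(n: Node) -> Node:
            m = Node(n.name, n.length)
            for c in n.children:
                m.add(clone(c))
            return m
        return RootedTree(clone(self.root))

    def scale_branches(self, s: float) -> "RootedTree":
        t = self.copy()
        for n in t.preorder():
            n.length *= s
        return t

    def total_length(self) -> float:
        return sum(n.length for n in self.branches())

    # -- Newick -----------------------------------------------------------
    @classmethod
    def from_newick(cls, text: str, require_rooted: bool = False) -> "RootedTree":
        try:
            dtree = dendropy.Tree.get(data=text, schema="newick",
                                      preserve_underscores=True)
        except Exception as exc:  # dendropy raises assorted parse errors
            raise FormatError(f"malformed Newick: {exc}") from exc

        def convert(dnode) -> Node:
            n = Node(name=dnode.taxon.label if dnode.taxon else None,
                     length=dnode.edge.length if dnode.edge.length is not None else 0.0)
            for c in dnode.child_nodes():
                n.add(convert(c))
            return n

        root = convert(dtree.seed_node)
        root.length = 0.0
        if require_rooted and len(root.children) != 2:
            raise FormatError(
                f"tree is not rooted: basal node has degree {len(root.children)}, expected 2")
        return cls(root)

    def to_newick(self) -> str:
        def write(n: Node) -> str:
            if n.is_tip:
                core = _quote(n.name or "")
            else:
                core = "(" + ",".join(write(c) for c in n.children) + ")"
                if n.name:
                    core += _quote(n.name)
            if n.parent is not None:
                core += f":{n.length:.10g}"
            return core
        return write(self.root) + ";"

    # -- rooting ----------------------------------------------------------
    def reroot_at_node(self, node: Node) -> "RootedTree":
        """Reverse parent pointers so ``node`` becomes the root.  Branch
        lengths travel with their edges; the old root is suppressed if it
        is left with a single child."""
        if node.parent is None:
            return self
        path = []
        n = node
        while n is not None:
            path.append(n)
            n = n.parent
        orig_len = [n.length for n in path]
        for i, (child, parent) in enumerate(zip(path, path[1:])):
            parent.children.remove(child)
            child.add(parent)
            parent.length = orig_len[i]
        node.parent = None
        node.length = 0.0
        # suppress a degree-2 old root
        old_root = path[-1]
        if len(old_root.children) == 1 and old_root.parent is not None:
            child = old_root.children[0]
            child.length += old_root.length
            grand = old_root.parent
            grand.children[grand.children.index(old_root)] = child
            child.parent = grand
        return RootedTree(node)

    def find_tip(self, label: str) -> Node:
        for t in self.tips():
            if t.name == label:
                return t
        raise LabellingError(f"tip {label!r} not found in tree")


def root_with_outgroup(tree: RootedTree, outgroup: str) -> RootedTree:
    """Root on the outgroup's pendant edge, then drop the outgroup.

    The node where the outgroup attaches becomes the root of the returned
    ingroup tree, matching the convention of rooting a maximum-likelihood
    tree with an added outgroup sequence and analysing it 'minus the
    rooting sequence'.
    """
    work = tree.copy()
    og = work.find_tip(outgroup)
    attach = og.parent
    if attach is None:
        raise DomainError("cannot root: the outgroup is the entire tree")
    rerooted = work.reroot_at_node(attach)
    rerooted.root.children.remove(og)
    root = rerooted.root
    if len(root.children) == 1:
        root = root.children[0]
        root.parent = None
        root.length = 0.0
    return RootedTree(root)


def read_newick(path, require_rooted: bool = False) -> RootedTree:
    with open(path) as fh:
        return RootedTree.from_newick(fh.read(), require_rooted=require_rooted)


def write_newick(tree: RootedTree, path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"[{header}]\n")
        fh.write(tree.to_newick() + "\n")


def _quote(label: str) -> str:
    if any(ch in label for ch in " ()[]:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


# -- unrooted views ---------------------------------------------------------

def unrooted_splits(tree: RootedTree) -> dict:
    """Bipartition -> branch-length map of the unrooted view of ``tree``.

    Each non-root edge contributes the split (tips below vs the rest).
    The two edges meeting at a bifurcating root describe the same split;
    their lengths are summed, as when the root is suppressed.  Splits are
    keyed by the side not containing a fixed reference tip, so the two
    orientations of a bipartition collide.  Pendant (single-tip) splits
    are included.
    """
    labels = sorted(tree.tip_labels())
    ref = labels[0]
    full = frozenset(labels)
    below: dict[int, frozenset] = {}
    splits: dict[frozenset, float] = {}
    order = list(tree.postorder())
    for n in order:
        if n.is_tip:
            below[id(n)] = frozenset([n.name])
        else:
            s = frozenset().union(*(below[id(c)] for c in n.children))
            below[id(n)] = s
    for n in tree.branches():
        side = below[id(n)]
        if ref in side:
            side = full - side
        if not side or side == full:
            continue
        splits[side] = splits.get(side, 0.0) + n.length
    return splits


def nni_neighbors(tree: RootedTree):
    """All trees one nearest-neighbour interchange away (unrooted moves,
    performed on the rooted tree with the root position kept).

    For each internal edge (parent u, internal child v), exchanging one
    child of v with one sibling of v yields the two alternative resolutions
    of that edge.  Yields (tree, description, affected) triples, where
    ``affected`` lists the preorder indices (in the candidate tree) of the
    nodes whose branches the swap touches; inputs are copied.
    """
    base = tree.copy()
    nodes = list(base.preorder())
    for vi, v in enumerate(nodes):
        u = v.parent
        if v.is_tip or u is None:
            continue
        siblings = [s for s in u.children if s is not v]
        if not siblings:
            continue
        for ci in range(len(v.children)):
            t = tree.copy()
            tn = list(t.preorder())
            v2, u2 = tn[vi], tn[vi].parent
            s2 = [x for x in u2.children if x is not v2][0]
            c2 = v2.children[ci]
            # swap c2 and s2
            u2.children[u2.children.index(s2)] = c2
            v2.children[v2.children.index(c2)] = s2
            c2.parent, s2.parent = u2, v2
            cand = RootedTree(t.root)
            pre = list(cand.preorder())
            touched = [n for n in (v2, u2, s2, c2) if n.parent is not None]
            affected = [pre.index(n) for n in touched]
            yield cand, f"nni@{vi}.{ci}", affected
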