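"""Rooted tree data model, Newick I/O, bipartitions and topology utilities.

The :class:`Tree` here is deliberately small: a parent/child node structure
with optional branch lengths (non-negative) and optional per-branch support
values in [0, 100].  Newick parsing is delegated to :mod:`dendropy`; writing,
bipartition extraction, canonicalization, rooted-topology enumeration,
Robinson-Foulds distances and root-to-tip path sums are implemented directly
on the node structure.
"""

from __future__ import annotations

import io
from typing import Iterable, Iterator

import dendropy


class TreeError(Exception):
    """Base class for tree-related errors."""


class NewickParseError(TreeError):
    """Malformed Newick input."""


class TreeValidationError(TreeError):
    """Structurally invalid tree (duplicate labels, bad lengths, ...)."""


class Node:
    """A node in a rooted tree; ``length``/``support`` describe its incoming edge."""

    __slots__ = ("label", "length", "support", "children", "parent", "segments")

    def __init__(self, label=None, length=None, support=None):
        self.label = label
        self.length = length
        self.support = support
        self.children: list[Node] = []
        self.parent: Node | None = None
        # per-edge (species_branch, duration) log filled in by the simulator
        self.segments = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["Node"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def preorder(self) -> Iterator["Node"]:
        yield self
        for child in self.children:
            yield from child.preorder()

    def leaves(self) -> Iterator["Node"]:
        for node in self.postorder():
            if node.is_leaf():
                yield node

    def leaf_labels(self) -> frozenset:
        return frozenset(leaf.label for leaf in self.leaves())

    def copy(self) -> "Node":
        dup = Node(self.label, self.length, self.support)
        dup.segments = None if self.segments is None else list(self.segments)
        for child in self.children:
            dup.add_child(child.copy())
        return dup

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"<Node {self.label or '*'} len={self.length}>"


class Tree:
    """Rooted leaf-labeled tree; ``unit`` tags what the branch lengths mean."""

    def __init__(self, root: Node, unit: str | None = None, validate: bool = True):
        self.root = root
        self.unit = unit
        if validate:
            self.validate()

    def validate(self) -> None:
        labels = [leaf.label for leaf in self.root.leaves()]
        if any(lab is None or lab == "" for lab in labels):
            raise TreeValidationError("every leaf must carry a non-empty label")
        if len(labels) != len(set(labels)):
            dupes = sorted({lab for lab in labels if labels.count(lab) > 1})
            raise TreeValidationError(f"duplicate leaf label(s): {', '.join(dupes)}")
        for node in self.root.postorder():
            if node.length is not None and node.length < 0:
                raise TreeValidationError(f"negative branch length on {node.label or 'internal node'}")
            if node.support is not None and not (0 <= node.support <= 100):
                raise TreeValidationError(f"support {node.support} outside [0, 100]")

    # -- convenience ------------------------------------------------------
    def leaf_labels(self) -> frozenset:
        return self.root.leaf_labels()

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self.root.leaves())

    def find_leaf(self, label: str) -> Node:
        for leaf in self.root.leaves():
            if leaf.label == label:
                return leaf
        raise TreeError(f"leaf {label!r} not found")

    def copy(self) -> "Tree":
        return Tree(self.root.copy(), unit=self.unit, validate=False)

    def has_polytomy(self) -> bool:
        return any(len(n.children) > 2 for n in self.root.postorder())

    def __repr__(self):  # pragma: no cover
        return f"<Tree n={self.n_leaves} unit={self.unit}>"


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def _from_dendropy(dnode) -> Node:
    label = dnode.taxon.label if dnode.taxon is not None else dnode.label
    support = None
    if dnode.child_nodes() and dnode.label is not None:
        # internal-node label position doubles as a support value (dialect default)
        try:
            value = float(dnode.label)
        except ValueError:
            value = None
        if value is not None and 0 <= value <= 100:
            support = value
            label = None
    node = Node(label=label, length=dnode.edge.length, support=support)
    for child in dnode.child_nodes():
        node.add_child(_from_dendropy(child))
    return node


def parse_newick(text: str, unit: str | None = None) -> Tree:
    """Parse one Newick string into a :class:`Tree`.

    Internal-node labels that look like numbers in [0, 100] are interpreted
    as branch support values.  Raises :class:`NewickParseError` with position
    information on malformed input and :class:`TreeValidationError` on
    duplicate leaf labels.
    """
    if not text or not text.strip():
        raise NewickParseError("empty Newick string")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several DataError subclasses
        pos = ""
        line = getattr(exc, "line_num", None)
        col = getattr(exc, "col_num", None)
        if line is not None or col is not None:
            pos = f" (line {line}, column {col})"
        raise NewickParseError(f"malformed Newick{pos}: {exc}") from exc
    root = _from_dendropy(dtree.seed_node)
    root.length = dtree.seed_node.edge.length  # may be None; kept as-is
    return Tree(root, unit=unit)


def _needs_quoting(label: str) -> bool:
    return any(ch in label for ch in "(),:;[] \t'")


def _format_label(label: str) -> str:
    if _needs_quoting(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _write_node(node: Node, canonical: bool) -> str:
    if node.is_leaf():
        out = _format_label(node.label)
    else:
        children = node.children
        if canonical:
            children = sorted(children, key=lambda c: min(c.leaf_labels()))
        out = "(" + ",".join(_write_node(c, canonical) for c in children) + ")"
        if node.support is not None:
            out += format(node.support, ".17g")
        elif node.label is not None:
            out += _format_label(node.label)
    if node.length is not None:
        out += ":" + format(node.length, ".17g")
    return out


def write_newick(tree: Tree, canonical: bool = False) -> str:
    """Serialize to Newick; ``canonical=True`` sorts children deterministically."""
    return _write_node(tree.root, canonical) + ";"


def read_newick_file(path, unit: str | None = None) -> list[Tree]:
    """Read a file with one or more Newick trees (one per line or ;-separated)."""
    with open(path) as fh:
        text = fh.read()
    trees = []
    for chunk in text.replace("\n", " ").split(";"):
        if chunk.strip():
            trees.append(parse_newick(chunk + ";", unit=unit))
    return trees


def write_newick_file(trees: Iterable[Tree], path, canonical: bool = False) -> None:
    with open(path, "w") as fh:
        for tree in trees:
            fh.write(write_newick(tree, canonical=canonical) + "\n")


# ---------------------------------------------------------------------------
# Bipartitions and RF distance
# ---------------------------------------------------------------------------

class Bipartition:
    """Unordered split of the full taxon set into two non-empty sides."""

    __slots__ = ("side1", "side2")

    def __init__(self, a, b):
        a, b = frozenset(a), frozenset(b)
        if not a or not b:
            raise TreeValidationError("bipartition sides must be non-empty")
        if a & b:
            raise TreeValidationError("bipartition sides must be disjoint")
        # canonical order: side containing the lexicographically smallest label first
        if min(a) <= min(b):
            self.side1, self.side2 = a, b
        else:
            self.side1, self.side2 = b, a

    @property
    def taxa(self) -> frozenset:
        return self.side1 | self.side2

    def conflicts_with(self, other: "Bipartition") -> bool:
        """True if the two splits (on the same taxon set) cannot coexist in one tree."""
        for x in (self.side1, self.side2):
            for y in (other.side1, other.side2):
                if not (x & y):
                    return False
        return True

    def __eq__(self, other):
        return isinstance(other, Bipartition) and self.side1 == other.side1 and self.side2 == other.side2

    def __hash__(self):
        return hash((self.side1, self.side2))

    def __str__(self):
        return ",".join(sorted(self.side1)) + "|" + ",".join(sorted(self.side2))

    def __repr__(self):  # pragma: no cover
        return f"Bipartition({self})"


def bipartitions(tree: Tree) -> set[Bipartition]:
    """Non-trivial splits of the unrooted interpretation, one per internal edge."""
    all_leaves = tree.leaf_labels()
    n = len(all_leaves)
    if n < 4:
        return set()
    out: set[Bipartition] = set()
    for node in tree.root.postorder():
        if node is tree.root or node.is_leaf():
            continue
        clade = node.leaf_labels()
        if 2 <= len(clade) <= n - 2:
            out.add(Bipartition(clade, all_leaves - clade))
    return out


def rf_distance(t1: Tree, t2: Tree, normalized: bool = False,
                prune_to_common: bool = False) -> float:
    """Robinson-Foulds distance on the unrooted interpretation.

    The normalized variant divides the symmetric-difference count by
    ``2 * (n - 3)`` so that two fully resolved trees sharing no splits score 1.
    """
    l1, l2 = t1.leaf_labels(), t2.leaf_labels()
    if l1 != l2:
        if not prune_to_common:
            raise TreeError("trees have different leaf sets (set prune_to_common=True to prune)")
        common = l1 & l2
        if len(common) < 4:
            raise TreeError("fewer than 4 shared leaves")
        t1, t2 = prune(t1, common), prune(t2, common)
    b1, b2 = bipartitions(t1), bipartitions(t2)
    d = len(b1 ^ b2)
    if normalized:
        n = len(t1.leaf_labels())
        if n < 4:
            return 0.0
        return d / (2 * (n - 3))
    return float(d)


def root_to_tip_lengths(tree: Tree) -> dict[str, float]:
    """Sum of branch lengths on the root-to-leaf path, per leaf label."""
    out: dict[str, float] = {}

    def walk(node: Node, acc: float):
        if node is not tree.root:
            if node.length is None:
                raise TreeError(f"missing branch length above {node.label or 'internal node'}")
            acc += node.length
        if node.is_leaf():
            out[node.label] = acc
        for child in node.children:
            walk(child, acc)

    walk(tree.root, 0.0)
    return out


# ---------------------------------------------------------------------------
# Rerooting, pruning
# ---------------------------------------------------------------------------

def reroot_on_outgroup(tree: Tree, outgroup: str) -> Tree:
    """Return a copy rooted on the outgroup's pendant edge.

    The new root has the outgroup leaf as one child (keeping the pendant edge
    length) and the rest of the tree as the other (zero-length attachment).
    The original root is suppressed if it becomes a degree-2 node.
    """
    if outgroup not in tree.leaf_labels():
        raise TreeError(f"outgroup {outgroup!r} not among leaves")
    work = tree.copy()
    # adjacency with per-edge (length, support)
    adj: dict[int, list] = {}
    nodes: dict[int, Node] = {}
    edges: dict[frozenset, tuple] = {}

    def reg(node):
        nodes[id(node)] = node
        adj.setdefault(id(node), [])

    for node in work.root.postorder():
        reg(node)
        if node.parent is not None:
            key = frozenset((id(node), id(node.parent)))
            edges[key] = (node.length, node.support)
            adj[id(node)].append(id(node.parent))
            adj.setdefault(id(node.parent), []).append(id(node))

    # suppress the old root if it is a degree-2 junction in the unrooted view
    old_root = work.root
    if len(old_root.children) == 2:
        a, b = old_root.children
        la = a.length if a.length is not None else 0.0
        lb = b.length if b.length is not None else 0.0
        merged_len = None if (a.length is None and b.length is None) else la + lb
        merged_sup = a.support if a.support is not None else b.support
        for key in (frozenset((id(a), id(old_root))), frozenset((id(b), id(old_root)))):
            edges.pop(key)
        adj[id(a)].remove(id(old_root))
        adj[id(b)].remove(id(old_root))
        adj[id(a)].append(id(b))
        adj[id(b)].append(id(a))
        adj.pop(id(old_root))
        edges[frozenset((id(a), id(b)))] = (merged_len, merged_sup)

    og = next(n for n in nodes.values() if n.is_leaf() and n.label == outgroup)
    if id(og) not in adj:  # pragma: no cover - og cannot be the suppressed root
        raise TreeError("outgroup cannot be the root")
    neighbor_id = adj[id(og)][0]
    og_edge = edges[frozenset((id(og), neighbor_id))]

    new_root = Node()
    built: dict[int, Node] = {}

    def build(nid: int, parent_id: int | None) -> Node:
        src = nodes[nid]
        fresh = Node(src.label if src.is_leaf() else None)
        built[nid] = fresh
        for other in adj[nid]:
            if other == parent_id:
                continue
            if nid == neighbor_id and parent_id is None and other == id(og):
                continue
            child = build(other, nid)
            length, support = edges[frozenset((nid, other))]
            child.length, child.support = length, support
            fresh.add_child(child)
        return fresh

    og_child = Node(outgroup, length=og_edge[0], support=og_edge[1])
    rest = build(neighbor_id, None)
    rest.length = 0.0 if og_edge[0] is not None else None
    rest.support = og_edge[1]
    new_root.add_child(og_child)
    new_root.add_child(rest)
    return Tree(new_root, unit=tree.unit, validate=False)


def prune(tree: Tree, keep) -> Tree:
    """Restrict to the given leaf labels, preserving path lengths."""
    keep = frozenset(keep)
    missing = keep - tree.leaf_labels()
    if missing:
        raise TreeError(f"labels not in tree: {', '.join(sorted(missing))}")
    work = tree.copy()

    def rec(node: Node) -> Node | None:
        if node.is_leaf():
            return node if node.label in keep else None
        kept = [rec(c) for c in node.children]
        kept = [c for c in kept if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            child = kept[0]
            if node.length is not None and child.length is not None:
                child.length = child.length + node.length
            elif node.length is not None:
                child.length = node.length
            return child
        node.children = []
        for c in kept:
            node.add_child(c)
        return node

    new_root = rec(work.root)
    if new_root is None:
        raise TreeError("nothing left after pruning")
    new_root.parent = None
    return Tree(new_root, unit=tree.unit, validate=False)


# ---------------------------------------------------------------------------
# Canonical topology identifiers and enumeration
# ---------------------------------------------------------------------------

def _canon_node(node: Node) -> str:
    if node.is_leaf():
        return node.label
    parts = sorted((_canon_node(c) for c in node.children),
                   key=lambda s: (min_leaf_of_canon(s), s))
    return "(" + ",".join(parts) + ")"


def min_leaf_of_canon(canon: str) -> str:
    return min(canon.replace("(", "").replace(")", "").split(","))


def canonical_topology_id(tree: Tree, outgroup: str) -> str:
    """Branch-length-free canonical ID of the ingroup topology, rooted on the outgroup.

    Two trees get the same ID iff they share the same rooted ingroup topology
    regardless of child order, branch lengths or input rooting.
    """
    rooted = reroot_on_outgroup(tree, outgroup)
    ingroup_parts = [c for c in rooted.root.children
                     if not (c.is_leaf() and c.label == outgroup)]
    canons = sorted((_canon_node(c) for c in ingroup_parts),
                    key=lambda s: (min_leaf_of_canon(s), s))
    if len(canons) == 1:
        return canons[0]
    return "(" + ",".join(canons) + ")"


def double_factorial(k: int) -> int:
    out = 1
    while k > 1:
        out *= k
        k -= 2
    return out


def _insert_everywhere(shape, label):
    """All ways to attach a new leaf to a rooted shape (nested 2-tuples / str)."""
    yield (shape, label)  # attach on the root edge
    if isinstance(shape, tuple):
        a, b = shape
        for na in _insert_everywhere(a, label):
            yield (na, b)
        for nb in _insert_everywhere(b, label):
            yield (a, nb)


def _shape_to_canon(shape) -> str:
    if isinstance(shape, str):
        return shape
    parts = sorted((_shape_to_canon(s) for s in shape),
                   key=lambda s: (min_leaf_of_canon(s), s))
    return "(" + ",".join(parts) + ")"


def enumerate_rooted_topologies(ingroup_labels) -> list[str]:
    """All rooted binary leaf-labeled topologies on the ingroup; count = (2k-3)!!.

    The outgroup is implicit at the root, so these IDs match
    :func:`canonical_topology_id` output for fully resolved trees.
    """
    labels = sorted(set(ingroup_labels))
    k = len(labels)
    if k < 2:
        raise TreeError("need at least 2 ingroup labels")
    if k > 8:
        raise TreeError(f"refusing to enumerate {k} ingroup taxa "
                        f"((2k-3)!! = {double_factorial(2 * k - 3)} topologies); limit is 8")
    shapes = [labels[0]]
    for label in labels[1:]:
        shapes = [new for shape in shapes for new in _insert_everywhere(shape, label)]
    ids = [_shape_to_canon(s) for s in shapes]
    assert len(ids) == len(set(ids)) == double_factorial(2 * k - 3)
    return sorted(ids)
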