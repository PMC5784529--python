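"""Phylogenetic tree data model, Newick I/O and rooting/distance/pruning primitives.

The :class:`GeneTree` here is deliberately small: a rooted (or
rooted-by-convention) tree of :class:`Node` objects carrying a label, a
branch length on the edge to the parent (``None`` when absent — never
silently zero), an optional support value in [0, 100], and an ordered child
list.  Child order is preserved on I/O but carries no meaning; every
set-valued result is order-independent.  Multifurcations are legal
everywhere.

Two Newick support dialects are accepted on input — a numeric internal-node
label (the form ML programs emit) and a bracketed comment such as ``[95]``
or ``[&support=95]`` — and the internal-label form is emitted.
"""

from __future__ import annotations

import re
from typing import Callable, Iterable, Iterator

from .errors import NewickParseError, TreeError

__all__ = [
    "Node",
    "GeneTree",
    "parse_newick",
    "write_newick",
    "read_newick_file",
    "write_newick_file",
    "trees_equal",
]


class Node:
    """A tree node.

    Attributes
    ----------
    label : str or None
        Unique and non-empty for leaves; optional for internal nodes.
    length : float or None
        Branch length (substitutions/site) on the edge to the parent;
        ``None`` when absent and always ``None`` for the root.
    support : float or None
        Support value in [0, 100] for the edge above this node.
    children : list of Node
    parent : Node or None
    """

    __slots__ = ("label", "length", "support", "children", "parent")

    def __init__(self, label=None, length=None, support=None, children=None, parent=None):
        self.label = label
        self.length = length
        self.support = support
        self.children: list[Node] = []
        self.parent = parent
        if children:
            for c in children:
                self.add_child(c)

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(reversed(n.children))

    def postorder(self) -> Iterator["Node"]:
        # iterative to survive deep ladder trees
        out: list[Node] = []
        stack = [self]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        yield from reversed(out)

    def leaves(self) -> list["Node"]:
        return [n for n in self.preorder() if n.is_leaf]

    def path_to_root(self) -> list["Node"]:
        path = [self]
        while path[-1].parent is not None:
            path.append(path[-1].parent)
        return path

    def __repr__(self):  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<Node {self.label!r} {kind} len={self.length}>"


class GeneTree:
    """A rooted phylogeny with labelled leaves, branch lengths and supports."""

    def __init__(self, root: Node):
        self.root = root
        root.parent = None
        root.length = None
        self._index: dict[str, Node] | None = None

    # -- basic accessors ---------------------------------------------------

    def nodes(self) -> Iterator[Node]:
        return self.root.preorder()

    def leaves(self) -> list[Node]:
        return self.root.leaves()

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.nodes() if not n.is_leaf]

    def _leaf_index(self) -> dict[str, Node]:
        if self._index is None:
            self._index = {n.label: n for n in self.leaves()}
        return self._index

    def find_leaf(self, label: str) -> Node:
        try:
            return self._leaf_index()[label]
        except KeyError:
            raise TreeError(f"leaf label not found in tree: {label!r}") from None

    def __contains__(self, label: str) -> bool:
        return label in self._leaf_index()

    def invalidate(self) -> None:
        """Drop cached indices after a structural mutation."""
        self._index = None

    def total_length(self) -> float:
        return sum(n.length for n in self.nodes() if n.length is not None)

    def copy(self) -> "GeneTree":
        def clone(n: Node) -> Node:
            c = Node(label=n.label, length=n.length, support=n.support)
            for ch in n.children:
                c.add_child(clone(ch))
            return c

        return GeneTree(clone(self.root))

    # -- Newick ------------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "GeneTree":
        return parse_newick(text)

    def to_newick(self) -> str:
        return write_newick(self)

    # -- MRCA and distances ------------------------------------------------

    def mrca(self, labels: Iterable[str]) -> Node:
        """Deepest node whose leaf set contains all the given leaf labels."""
        labels = list(labels)
        if not labels:
            raise TreeError("mrca requires at least one leaf label")
        paths = [self.find_leaf(lb).path_to_root() for lb in labels]
        common = set(map(id, paths[0]))
        for p in paths[1:]:
            common &= set(map(id, p))
        # first ancestor of the first leaf that is common to all = deepest
        for n in paths[0]:
            if id(n) in common:
                return n
        raise TreeError("tree is disconnected")  # pragma: no cover

    def _edge_length(self, child: Node) -> float:
        if child.length is None:
            who = child.label or "<internal node>"
            raise TreeError(f"missing branch length on edge above {who!r}")
        return child.length

    def distance(self, a: str, b: str) -> float:
        """Patristic distance: sum of branch lengths on the unique a–b path."""
        if a == b:
            self.find_leaf(a)
            return 0.0
        na, nb = self.find_leaf(a), self.find_leaf(b)
        anc = self.mrca([a, b])
        total = 0.0
        # canonical summation order keeps the result exactly symmetric in a, b
        for start in sorted((na, nb), key=lambda n: n.label):
            n = start
            while n is not anc:
                total += self._edge_length(n)
                n = n.parent
        return total

    def patristic_matrix(self) -> dict[tuple[str, str], float]:
        """All leaf-pair patristic distances (both orientations plus zero diagonal)."""
        labels = self.leaf_labels()
        out: dict[tuple[str, str], float] = {}
        for i, a in enumerate(labels):
            out[(a, a)] = 0.0
            for b in labels[i + 1 :]:
                d = self.distance(a, b)
                out[(a, b)] = out[(b, a)] = d
        return out

    # -- rooting -----------------------------------------------------------

    def midpoint_root(self) -> "GeneTree":
        """Root at the midpoint of the longest leaf-to-leaf path.

        Returns a new tree; the input is untouched.  The resulting root
        minimises the maximum root-to-leaf distance.  Leaf set, topology
        (up to root placement) and total branch length are preserved.  When
        several diameter paths tie, the one whose (sorted) endpoint pair is
        lexicographically smallest is used; a midpoint that falls exactly on
        an existing node makes that node the root rather than inserting a
        zero-length edge.
        """
        t = self.copy()
        leaves = t.leaves()
        if len(leaves) < 2:
            raise TreeError("midpoint rooting requires at least 2 leaves")
        for n in t.nodes():
            if n is not t.root and n.length is None:
                raise TreeError(
                    f"midpoint rooting requires branch lengths; missing above {n.label!r}"
                )
        labels = sorted(t.leaf_labels())
        best: tuple[str, str] | None = None
        diameter = -1.0
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                d = t.distance(a, b)
                if d > diameter:
                    diameter, best = d, (a, b)
                # ties resolved by the sorted order of iteration: first hit wins
        a, b = best
        na, nb = t.find_leaf(a), t.find_leaf(b)
        anc = t.mrca([a, b])
        up = []  # nodes a .. anc
        n = na
        while n is not anc:
            up.append(n)
            n = n.parent
        down = []  # anc-side path down to b, excluding anc
        n = nb
        while n is not anc:
            down.append(n)
            n = n.parent
        down.reverse()
        # positions measured from leaf a
        path = up + [anc] + down
        pos = [0.0]
        for n in up:
            pos.append(pos[-1] + n.length)
        for n in down:
            pos.append(pos[-1] + n.length)
        target = diameter / 2.0
        eps = 1e-12 * max(1.0, diameter)
        for i, n in enumerate(path):
            if abs(pos[i] - target) <= eps:
                t._reroot_at_node(n)
                return t
        for i in range(len(path) - 1):
            lo, hi = pos[i], pos[i + 1]
            if lo < target < hi:
                u, v = path[i], path[i + 1]
                child = v if v.parent is u else u
                cpos = pos[i + 1] if child is v else pos[i]
                t._reroot_at_edge(child, dist_from_child=abs(cpos - target))
                return t
        raise TreeError("midpoint position not found on diameter path")  # pragma: no cover

    def _reroot_at_edge(self, child: Node, dist_from_child: float) -> None:
        """Insert a new root splitting the edge above `child`."""
        parent = child.parent
        length = child.length
        if parent is None or length is None:
            raise TreeError("cannot reroot: edge has no parent or no length")
        if not (0.0 <= dist_from_child <= length):
            raise TreeError("reroot position outside the edge")
        parent.children.remove(child)
        mid = Node(length=length - dist_from_child, support=child.support)
        parent.add_child(mid)
        mid.children.append(child)
        child.parent = mid
        child.length = dist_from_child
        self._reroot_at_node(mid)

    def _reroot_at_node(self, node: Node) -> None:
        """Make `node` the root by reversing the edges on its path to the old root."""
        if node is self.root:
            return
        path = node.path_to_root()  # node .. old_root
        for i in range(len(path) - 1):
            path[i + 1].children.remove(path[i])
        # reverse edges top-down so original edge attributes are read before overwrite
        for i in range(len(path) - 1, 0, -1):
            parent, new_parent = path[i], path[i - 1]
            new_parent.children.append(parent)
            parent.parent = new_parent
            parent.length = path[i - 1].length
            parent.support = path[i - 1].support
        node.parent = None
        node.length = None
        node.support = None
        old_root = path[-1]
        if len(old_root.children) == 1:
            only = old_root.children[0]
            holder = old_root.parent
            if only.length is not None or old_root.length is not None:
                only.length = (only.length or 0.0) + (old_root.length or 0.0)
            holder.children[holder.children.index(old_root)] = only
            only.parent = holder
        self.root = node
        self.invalidate()

    # -- pruning -----------------------------------------------------------

    def prune_to_leaves(self, keep: Callable[[str], bool]) -> "GeneTree":
        """New tree keeping only leaves whose label satisfies `keep`.

        Unary internal nodes left behind are collapsed with branch lengths
        summed, so patristic distances between retained leaves are
        unchanged.
        """

        def rebuild(n: Node) -> Node | None:
            if n.is_leaf:
                if keep(n.label):
                    return Node(label=n.label, length=n.length, support=n.support)
                return None
            kept = [c for c in (rebuild(ch) for ch in n.children) if c is not None]
            if not kept:
                return None
            if len(kept) == 1:
                child = kept[0]
                if child.length is not None or n.length is not None:
                    child.length = (child.length or 0.0) + (n.length or 0.0)
                return child
            out = Node(label=n.label, length=n.length, support=n.support)
            for c in kept:
                out.add_child(c)
            return out

        new_root = rebuild(self.root)
        if new_root is None:
            raise TreeError("no retained leaves after pruning")
        return GeneTree(new_root)


# ---------------------------------------------------------------------------
# Newick parsing


_NUMBER_RE = re.compile(r"[-+]?(\d+\.?\d*|\.\d+)([eE][-+]?\d+)?")
_LABEL_STOP = set("():,;[]' \t\n\r")


def parse_newick(text: str) -> GeneTree:
    """Parse one Newick tree.

    Accepts optional branch lengths after ``:``, support either as a numeric
    internal-node label or as a bracketed comment (``[95]``,
    ``[&support=95]``), quoted labels, and multifurcations.  A trailing
    semicolon is tolerated absent.  Unbalanced parentheses, duplicate leaf
    labels and negative branch lengths raise :class:`NewickParseError`
    naming the offending position.
    """
    s = text
    i = 0
    n_chars = len(s)
    seen_leaves: set[str] = set()

    def err(msg: str, pos: int):
        raise NewickParseError(msg, pos)

    def skip_ws():
        nonlocal i
        while i < n_chars and s[i] in " \t\n\r":
            i += 1

    def peek() -> str:
        return s[i] if i < n_chars else ""

    def parse_comment() -> float | None:
        """Consume a bracketed comment; return a support value if it holds one."""
        nonlocal i
        start = i
        i += 1  # consume '['
        depth = 1
        buf = []
        while i < n_chars and depth:
            if s[i] == "[":
                depth += 1
            elif s[i] == "]":
                depth -= 1
                if depth == 0:
                    break
            buf.append(s[i])
            i += 1
        if depth:
            err("unterminated '[' comment", start)
        i += 1  # consume ']'
        content = "".join(buf).lstrip("&")
        if "=" in content:
            content = content.rsplit("=", 1)[1]
        try:
            val = float(content)
        except ValueError:
            return None
        return val if 0.0 <= val <= 100.0 else None

    def parse_label() -> tuple[str | None, int]:
        nonlocal i
        skip_ws()
        start = i
        if peek() == "'":
            i += 1
            buf = []
            while i < n_chars:
                if s[i] == "'":
                    if i + 1 < n_chars and s[i + 1] == "'":  # escaped quote
                        buf.append("'")
                        i += 2
                        continue
                    i += 1
                    return "".join(buf), start
                buf.append(s[i])
                i += 1
            err("unterminated quoted label", start)
        buf = []
        while i < n_chars and s[i] not in _LABEL_STOP:
            buf.append(s[i])
            i += 1
        label = "".join(buf)
        return (label if label else None), start

    def parse_length(pos_hint: int) -> float:
        nonlocal i
        skip_ws()
        m = _NUMBER_RE.match(s, i)
        if not m:
            err("expected a branch length after ':'", i)
        val = float(m.group(0))
        if val < 0:
            err(f"negative branch length {m.group(0)}", i)
        i = m.end()
        return val

    def parse_clade() -> Node:
        nonlocal i
        skip_ws()
        node = Node()
        open_pos = i
        if peek() == "(":
            i += 1
            while True:
                node.add_child(parse_clade())
                skip_ws()
                c = peek()
                if c == ",":
                    i += 1
                    continue
                if c == ")":
                    i += 1
                    break
                if c == "" or c == ";":
                    err("unexpected end of clade: unbalanced parentheses", open_pos)
                err(f"expected ',' or ')' but found {c!r}", i)
        label, label_pos = parse_label()
        support = None
        skip_ws()
        if peek() == "[":
            support = parse_comment()
        skip_ws()
        if peek() == ":":
            i += 1
            node.length = parse_length(i)
        skip_ws()
        if peek() == "[":
            sup = parse_comment()
            support = support if sup is None else sup
        if node.is_leaf:
            if not label:
                err("leaf without a label", label_pos)
            if label in seen_leaves:
                err(f"duplicate leaf label {label!r}", label_pos)
            seen_leaves.add(label)
            node.label = label
        else:
            # numeric internal label in [0,100] is a support value (ML dialect)
            num = None
            if label is not None:
                try:
                    num = float(label)
                except ValueError:
                    num = None
            if num is not None and 0.0 <= num <= 100.0:
                node.support = num
            else:
                node.label = label
        if support is not None:
            node.support = support
        return node

    skip_ws()
    if not s[i:]:
        err("empty Newick string", 0)
    root = parse_clade()
    skip_ws()
    if peek() == ";":
        i += 1
    skip_ws()
    if i < n_chars:
        err(f"unexpected trailing characters {s[i:i+10]!r}", i)
    root.length = None
    return GeneTree(root)


def _fmt_length(x: float) -> str:
    return format(x, ".10g")


def _fmt_support(x: float) -> str:
    return format(int(x)) if float(x).is_integer() else format(x, ".10g")


def write_newick(tree: GeneTree) -> str:
    """Serialise to Newick; supports are written as internal-node labels."""

    def render(n: Node) -> str:
        if n.is_leaf:
            out = n.label
        else:
            out = "(" + ",".join(render(c) for c in n.children) + ")"
            if n.support is not None:
                out += _fmt_support(n.support)
            elif n.label:
                out += n.label
        if n.length is not None:
            out += ":" + _fmt_length(n.length)
        return out

    return render(tree.root) + ";"


def read_newick_file(path) -> list[GeneTree]:
    """Read Newick trees from a file: one per line, or several ';'-separated."""
    with open(path, encoding="utf-8") as fh:
        blob = fh.read()
    trees = []
    for chunk in blob.split(";"):
        if chunk.strip():
            trees.append(parse_newick(chunk + ";"))
    if not trees:
        raise NewickParseError(f"no trees found in {path}", 0)
    return trees


def write_newick_file(trees: Iterable[GeneTree], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in trees:
            fh.write(write_newick(t) + "\n")


# ---------------------------------------------------------------------------
# structural comparison (used by round-trip guarantees and tests)


def _node_map(tree: GeneTree):
    out = {}
    for n in tree.nodes():
        leafset = frozenset(lf.label for lf in (n.leaves() if not n.is_leaf else [n]))
        children = frozenset(
            frozenset(lf.label for lf in (c.leaves() if not c.is_leaf else [c]))
            for c in n.children
        )
        out[leafset] = (n.length, n.support, children)
    return out


def trees_equal(a: GeneTree, b: GeneTree, tol: float = 1e-9) -> bool:
    """Structural equality: same leaf sets, topology, supports, lengths within tol."""
    ma, mb = _node_map(a), _node_map(b)
    if ma.keys() != mb.keys():
        return False
    for key, (la, sa, ca) in ma.items():
        lb, sb, cb = mb[key]
        if ca != cb or sa != sb:
            return False
        if (la is None) != (lb is None):
            return False
        if la is not None and abs(la - lb) > tol:
            return False
    return True
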