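"""Distance-based phylogeny: hamming distances, neighbor joining, midpoint
rooting, and the square-root branch-length display transform.

Neighbor joining follows the Saitou-Nei agglomeration with the standard
Q-criterion; ties are broken on the lowest index pair so output is
deterministic, and negative branch lengths are clamped to 0 with the total
deficit recorded in the tree metadata. On additive matrices the
reconstruction is exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .alleles import parse_allele, AlleleParseError
from .proteins import GAP, ProteinAlignment

__all__ = [
    "DistanceMatrix",
    "PhyloTree",
    "TreeNode",
    "hamming",
    "hamming_matrix",
    "midpoint_root",
    "neighbor_joining",
    "parse_newick",
    "sqrt_branch_transform",
    "write_newick",
]


@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0  # branch length to the parent
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def copy(self) -> "TreeNode":
        return TreeNode(
            name=self.name,
            length=self.length,
            children=[c.copy() for c in self.children],
        )


@dataclass
class PhyloTree:
    root: TreeNode
    rooted: bool = False
    metadata: dict = field(default_factory=dict)

    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.root.leaves()]

    def leaf_depths(self) -> dict[str, float]:
        depths: dict[str, float] = {}

        def walk(node: TreeNode, depth: float) -> None:
            depth += node.length
            if node.is_leaf:
                depths[node.name] = depth
            for c in node.children:
                walk(c, depth)

        walk(self.root, -self.root.length)
        return depths


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.array_equal(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal is not zero")
        if np.any(self.d < 0):
            raise ValueError("negative distances")

    def value(self, a: str, b: str) -> float:
        return float(self.d[self.labels.index(a), self.labels.index(b)])


def hamming(a: str, b: str) -> int:
    """Differing columns between two aligned rows; gap-vs-gap is not a
    difference, gap-vs-residue is."""
    if len(a) != len(b):
        raise ValueError("rows of unequal length")
    return sum(1 for x, y in zip(a, b) if x != y)


def _is_null_name(label: str) -> bool:
    try:
        return parse_allele(label).is_null
    except AlleleParseError:
        return False


def hamming_matrix(
    aln: ProteinAlignment,
    exclude: Iterable[str] = (),
    exclude_nulls: bool = False,
) -> DistanceMatrix:
    """Pairwise hamming distances over alignment rows.

    ``exclude`` drops rows by name (e.g. partial-coverage sequences);
    ``exclude_nulls`` additionally drops N-suffixed allele names.
    """
    dropped = set(exclude)
    labels = [
        name
        for name in sorted(aln.rows)
        if name not in dropped and not (exclude_nulls and _is_null_name(name))
    ]
    if not labels:
        raise ValueError("no rows left after exclusions")
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = hamming(aln.rows[labels[i]], aln.rows[labels[j]])
    return DistanceMatrix(labels=labels, d=d)


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining; deterministic, additive-exact.

    Returns an unrooted tree (represented with a trifurcating root for
    n >= 3). For n < 3 a degenerate tree is returned and flagged.
    """
    labels = dm.labels
    n = len(labels)
    metadata: dict = {"negative_branch_deficit": 0.0}

    nodes: dict[int, TreeNode] = {
        i: TreeNode(name=label) for i, label in enumerate(labels)
    }
    if n == 1:
        metadata["degenerate"] = True
        return PhyloTree(root=nodes[0], rooted=False, metadata=metadata)
    if n == 2:
        half = float(dm.d[0, 1]) / 2.0
        nodes[0].length = nodes[1].length = half
        root = TreeNode(children=[nodes[0], nodes[1]])
        metadata["degenerate"] = True
        return PhyloTree(root=root, rooted=False, metadata=metadata)

    D: dict[int, dict[int, float]] = {
        i: {j: float(dm.d[i, j]) for j in range(n) if j != i} for i in range(n)
    }
    active = list(range(n))
    next_id = n

    def clamp(x: float) -> float:
        if x < 0:
            metadata["negative_branch_deficit"] += -x
            return 0.0
        return x

    while len(active) > 2:
        m = len(active)
        r = {i: sum(D[i][k] for k in active if k != i) for i in active}
        best_q = math.inf
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (m - 2) * D[i][j] - r[i] - r[j]
                if q < best_q:  # strict: first (lowest-index) pair wins ties
                    best_q = q
                    best = (i, j)
        i, j = best
        dij = D[i][j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        nodes[i].length = clamp(li)
        nodes[j].length = clamp(lj)
        u = next_id
        next_id += 1
        nodes[u] = TreeNode(children=[nodes[i], nodes[j]])
        D[u] = {}
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (D[i][k] + D[j][k] - dij)
            D[u][k] = duk
            D[k][u] = duk
        active = [k for k in active if k not in (i, j)] + [u]

    a, b = active
    # attach the remaining node to the last internal node (trifurcating root)
    internal, other = (a, b) if nodes[a].children else (b, a)
    nodes[other].length = clamp(D[a][b])
    nodes[internal].children.append(nodes[other])
    return PhyloTree(root=nodes[internal], rooted=False, metadata=metadata)


def _adjacency(root: TreeNode) -> dict[int, list[tuple[int, float]]]:
    """Undirected edge list keyed by node id."""
    adj: dict[int, list[tuple[int, float]]] = {}

    def walk(node: TreeNode) -> None:
        adj.setdefault(id(node), [])
        for c in node.children:
            adj.setdefault(id(c), [])
            adj[id(node)].append((id(c), c.length))
            adj[id(c)].append((id(node), c.length))
            walk(c)

    walk(root)
    return adj


def _collect_nodes(root: TreeNode) -> dict[int, TreeNode]:
    out = {id(root): root}
    for c in root.children:
        out.update(_collect_nodes(c))
    return out


def midpoint_root(tree: PhyloTree) -> PhyloTree:
    """Root at the midpoint of the longest leaf-to-leaf path.

    The two farthest leaves end up equidistant from the root. With all-zero
    branch lengths the root is placed on an arbitrary edge and flagged.
    """
    root = tree.root.copy()
    nodes = _collect_nodes(root)
    adj = _adjacency(root)
    leaves = [id(l) for l in root.leaves()]
    if len(leaves) < 2:
        return PhyloTree(root=root, rooted=True, metadata=dict(tree.metadata))

    def distances_from(src: int) -> tuple[dict[int, float], dict[int, int]]:
        dist = {src: 0.0}
        prev: dict[int, int] = {}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    prev[v] = u
                    stack.append(v)
        return dist, prev

    # deterministic farthest pair: maximize distance, tie-break on names
    def leaf_name(i: int) -> str:
        return nodes[i].name or ""

    best = None
    for x in sorted(leaves, key=leaf_name):
        dist, prev = distances_from(x)
        for y in sorted(leaves, key=leaf_name):
            if y == x:
                continue
            key = (dist[y], leaf_name(x), leaf_name(y))
            if best is None or key > best[0]:
                best = (key, x, y, prev)
    (path_len, _, _), x, y, prev = best

    metadata = dict(tree.metadata)
    if path_len == 0:
        metadata["arbitrary_root"] = True

    # walk the x..y path accumulating distance until the midpoint edge
    path = [y]
    while path[-1] != x:
        path.append(prev[path[-1]])
    path.reverse()  # x .. y

    def edge_len(u: int, v: int) -> float:
        for w, l in adj[u]:
            if w == v:
                return l
        raise KeyError("not an edge")

    half = path_len / 2.0
    acc = 0.0
    u = v = None
    offset = 0.0
    for a, b in zip(path, path[1:]):
        l = edge_len(a, b)
        if acc + l >= half or (a, b) == (path[-2], path[-1]):
            u, v = a, b
            offset = half - acc  # distance from u along edge (u,v)
            break
        acc += l

    # re-orient the tree around a new root placed on edge (u, v)
    def orient(node_id: int, parent_id: int | None, length: float) -> TreeNode:
        node = nodes[node_id]
        new = TreeNode(name=node.name, length=length)
        for w, l in adj[node_id]:
            if w != parent_id:
                new.children.append(orient(w, node_id, l))
        return new

    total = edge_len(u, v)
    new_root = TreeNode(
        children=[orient(u, v, offset), orient(v, u, total - offset)]
    )
    # prune pass-through nodes created by removing the old trifurcation is
    # unnecessary: the old root keeps its >=2 remaining children.
    return PhyloTree(root=new_root, rooted=True, metadata=metadata)


def sqrt_branch_transform(tree: PhyloTree) -> PhyloTree:
    """Square-root every branch length (display only; topology unchanged)."""

    def walk(node: TreeNode) -> TreeNode:
        return TreeNode(
            name=node.name,
            length=math.sqrt(node.length),
            children=[walk(c) for c in node.children],
        )

    metadata = dict(tree.metadata)
    metadata["display_transform"] = "sqrt"
    return PhyloTree(root=walk(tree.root), rooted=tree.rooted, metadata=metadata)


# --------------------------------------------------------------------------
# Newick serialization

_NEEDS_QUOTES = set(":;,()[]' \t\n")


def _format_label(name: str) -> str:
    if any(ch in _NEEDS_QUOTES for ch in name):
        return "'" + name.replace("'", "''") + "'"
    return name


def _format_length(x: float) -> str:
    return f"{x:.6g}"


def write_newick(tree: PhyloTree) -> str:
    """Serialize with 6-significant-digit branch lengths; byte-stable under
    write -> parse -> write."""

    def fmt(node: TreeNode, top: bool) -> str:
        if node.is_leaf:
            body = _format_label(node.name or "")
        else:
            body = "(" + ",".join(fmt(c, False) for c in node.children) + ")"
            if node.name:
                body += _format_label(node.name)
        if not top:
            body += ":" + _format_length(node.length)
        return body

    return fmt(tree.root, True) + ";"


def parse_newick(text: str) -> PhyloTree:
    """Minimal newick parser matching :func:`write_newick` output."""
    s = text.strip()
    if not s.endswith(";"):
        raise ValueError("newick string must end with ';'")
    s = s[:-1]
    pos = 0

    def parse_label() -> str:
        nonlocal pos
        if pos < len(s) and s[pos] == "'":
            pos += 1
            out = []
            while pos < len(s):
                if s[pos] == "'":
                    if pos + 1 < len(s) and s[pos + 1] == "'":
                        out.append("'")
                        pos += 2
                        continue
                    pos += 1
                    return "".join(out)
                out.append(s[pos])
                pos += 1
            raise ValueError("unterminated quoted label")
        start = pos
        while pos < len(s) and s[pos] not in ":;,()":
            pos += 1
        return s[start:pos]

    def parse_node() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                if pos >= len(s):
                    raise ValueError("unbalanced parentheses")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
            label = parse_label()
            node.name = label or None
        else:
            node.name = parse_label() or None
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",();":
                pos += 1
            node.length = float(s[start:pos])
        return node

    root = parse_node()
    if pos != len(s):
        raise ValueError(f"trailing characters at offset {pos}")
    return PhyloTree(root=root, rooted=len(root.children) == 2)
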