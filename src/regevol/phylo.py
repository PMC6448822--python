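"""Distance-based phylogenetics: p-distance, JC69, neighbor joining, bootstrap.

Neighbor joining follows the Saitou-Nei agglomeration on the Q-criterion,
with two documented conventions: ties in the Q minimum are broken by the
lexicographically smallest (i, j) label-index pair, and negative branch
lengths are clamped to zero with a warning.  For an additive distance matrix
the tree's path distances reproduce the input exactly.

Bootstrap support for each internal bipartition of the full-data tree is the
percentage of column-resampled replicate trees that contain the same
bipartition (leaf-set encoding, so it is invariant to taxon order).

A k-mer dotplot is provided for promoter comparison: every exact shared
w-mer start pair, plus the fraction of the first sequence covered by at
least one match.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

GAP_CHARS = frozenset("-.")


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances with a zero diagonal."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError(f"matrix shape {self.d.shape} does not fit {n} labels")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("non-finite distances")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("diagonal is not zero")
        if np.any(self.d < -1e-12):
            raise ValueError("negative distances")


def _encode(msa: Sequence[tuple[str, str]]) -> tuple[list[str], np.ndarray]:
    labels = [r[0] for r in msa]
    rows = [r[1].upper() for r in msa]
    length = len(rows[0])
    if any(len(r) != length for r in rows):
        raise ValueError("ragged alignment")
    arr = np.frombuffer("".join(rows).encode(), dtype=np.uint8).reshape(len(rows), length)
    return labels, arr


_GAP_CODES = np.frombuffer("-.".encode(), dtype=np.uint8)


def _pairwise_p(arr: np.ndarray) -> np.ndarray:
    """Proportion of differing sites under pairwise deletion of gaps."""
    n = arr.shape[0]
    is_gap = np.isin(arr, _GAP_CODES)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~(is_gap[i] | is_gap[j])
            comparable = int(both.sum())
            if comparable == 0:
                raise ValueError(f"rows {i} and {j} share no comparable sites")
            diff = int((arr[i, both] != arr[j, both]).sum())
            d[i, j] = d[j, i] = diff / comparable
    return d


def p_distance(msa: Sequence[tuple[str, str]]) -> DistanceMatrix:
    """Pairwise p-distances (pairwise deletion) from an aligned set of records."""
    if len(msa) < 3:
        raise ValueError("need at least 3 taxa")
    labels, arr = _encode(msa)
    return DistanceMatrix(labels, _pairwise_p(arr))


def jc_correct(p: float) -> float:
    """Jukes-Cantor correction d = -(3/4) ln(1 - 4p/3); valid for 0 <= p < 0.75."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        raise ValueError("saturated")
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def jc_distance(msa: Sequence[tuple[str, str]]) -> DistanceMatrix:
    """JC69-corrected distances from an alignment."""
    dm = p_distance(msa)
    corrected = np.zeros_like(dm.d)
    n = len(dm.labels)
    for i in range(n):
        for j in range(i + 1, n):
            corrected[i, j] = corrected[j, i] = jc_correct(dm.d[i, j])
    return DistanceMatrix(dm.labels, corrected)


@dataclass
class TreeNode:
    """One node of an (unrooted) NJ tree; ``length`` is the edge above it."""

    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class PhyloTree:
    """Unrooted NJ tree stored rooted at the final trifurcation."""

    root: TreeNode
    labels: list[str]

    def leaf_names(self) -> set[str]:
        return {leaf.name for leaf in self.root.leaves()}

    def bipartitions(self) -> set[frozenset[str]]:
        """Internal bipartitions, each encoded as the side not containing a
        fixed reference taxon (the first label)."""
        all_leaves = frozenset(self.leaf_names())
        ref = sorted(all_leaves)[0]
        out: set[frozenset[str]] = set()
        for node, _parent in _walk_with_parent(self.root):
            if node is self.root or node.is_leaf():
                continue
            side = frozenset(leaf.name for leaf in node.leaves())
            if ref in side:
                side = all_leaves - side
            if 2 <= len(side) <= len(all_leaves) - 2:
                out.add(side)
        return out

    def internal_nodes(self) -> list[TreeNode]:
        return [
            n for n, _ in _walk_with_parent(self.root)
            if n is not self.root and not n.is_leaf()
        ]

    def path_distance(self, a: str, b: str) -> float:
        """Sum of branch lengths on the path between two leaves."""
        path_a = _path_to_leaf(self.root, a)
        path_b = _path_to_leaf(self.root, b)
        if path_a is None or path_b is None:
            raise KeyError(f"leaf not found: {a if path_a is None else b}")
        common = 0
        for x, y in zip(path_a, path_b):
            if x is y:
                common += 1
            else:
                break
        return sum(n.length for n in path_a[common:]) + sum(n.length for n in path_b[common:])

    def to_newick(self, with_supports: bool = True) -> str:
        return _newick(self.root, with_supports, is_root=True) + ";"


def _walk_with_parent(node: TreeNode, parent: TreeNode | None = None):
    yield node, parent
    for child in node.children:
        yield from _walk_with_parent(child, node)


def _path_to_leaf(node: TreeNode, name: str) -> list[TreeNode] | None:
    if node.is_leaf():
        return [node] if node.name == name else None
    for child in node.children:
        sub = _path_to_leaf(child, name)
        if sub is not None:
            return [node] + sub
    return None


def _newick(node: TreeNode, with_supports: bool, is_root: bool = False) -> str:
    if node.is_leaf():
        return f"{node.name}:{node.length:.6g}"
    inner = ",".join(_newick(c, with_supports) for c in node.children)
    label = ""
    if with_supports and node.support is not None and not is_root:
        label = f"{node.support:g}"
    if is_root:
        return f"({inner}){label}"
    return f"({inner}){label}:{node.length:.6g}"


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Neighbor joining (Saitou-Nei) with deterministic tie-breaking.

    Ties in the Q minimum are broken by the lexicographically smallest
    (i, j) pair of current node indices; negative branch lengths are clamped
    to 0 with a warning.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    D = dm.d.copy()
    nodes: list[TreeNode] = [TreeNode(name=l) for l in dm.labels]
    active = list(range(n))

    def clamp(x: float) -> float:
        if x < 0:
            warnings.warn("negative NJ branch length clamped to 0", stacklevel=3)
            return 0.0
        return x

    while len(active) > 3:
        r = len(active)
        sub = D[np.ix_(active, active)]
        rowsum = sub.sum(axis=1)
        best = None
        best_q = np.inf
        for a in range(r):
            for b in range(a + 1, r):
                q = (r - 2) * sub[a, b] - rowsum[a] - rowsum[b]
                if q < best_q - 1e-12:
                    best_q, best = q, (a, b)
        a, b = best
        i, j = active[a], active[b]
        li = clamp(0.5 * sub[a, b] + (rowsum[a] - rowsum[b]) / (2 * (r - 2)))
        lj = clamp(sub[a, b] - (0.5 * sub[a, b] + (rowsum[a] - rowsum[b]) / (2 * (r - 2))))
        ni, nj_ = nodes[i], nodes[j]
        ni.length, nj_.length = li, lj
        new = TreeNode(children=[ni, nj_])
        # grow D with the new node's distances
        newdist = np.zeros(D.shape[0] + 1)
        for k in active:
            if k in (i, j):
                continue
            newdist[k] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, : len(newdist) - 1] = newdist[:-1]
        D[: len(newdist) - 1, -1] = newdist[:-1]
        nodes.append(new)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    i, j, k = active
    d01, d02, d12 = D[i, j], D[i, k], D[j, k]
    nodes[i].length = clamp(0.5 * (d01 + d02 - d12))
    nodes[j].length = clamp(0.5 * (d01 + d12 - d02))
    nodes[k].length = clamp(0.5 * (d02 + d12 - d01))
    root = TreeNode(children=[nodes[i], nodes[j], nodes[k]])
    return PhyloTree(root=root, labels=list(dm.labels))


def bootstrap_support(
    msa: Sequence[tuple[str, str]],
    replicates: int = 100,
    seed: int = 0,
    model: str = "p",
) -> PhyloTree:
    """NJ tree from the full alignment with bootstrap supports on internal edges.

    Columns are resampled with replacement ``replicates`` times; the support
    of each internal bipartition of the full-data tree is the percentage of
    replicate trees containing it.  Reproducible for a fixed seed.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if model not in ("p", "jc"):
        raise ValueError(f"unknown distance model {model!r}")
    labels, arr = _encode(msa)

    def _dm(a: np.ndarray) -> DistanceMatrix:
        p = _pairwise_p(a)
        if model == "jc":
            n = len(labels)
            for x in range(n):
                for y in range(x + 1, n):
                    p[x, y] = p[y, x] = jc_correct(p[x, y])
        return DistanceMatrix(list(labels), p)

    tree = nj_tree(_dm(arr))
    target = {bp: 0 for bp in tree.bipartitions()}
    rng = np.random.default_rng(seed)
    length = arr.shape[1]
    for _ in range(replicates):
        idx = rng.integers(0, length, size=length)
        rep_tree = nj_tree(_dm(arr[:, idx]))
        rep_bps = rep_tree.bipartitions()
        for bp in target:
            if bp in rep_bps:
                target[bp] += 1

    all_leaves = frozenset(tree.leaf_names())
    ref = sorted(all_leaves)[0]
    for node in tree.internal_nodes():
        side = frozenset(leaf.name for leaf in node.leaves())
        if ref in side:
            side = all_leaves - side
        if side in target:
            node.support = 100.0 * target[side] / replicates
    return tree


# --- dotplot ------------------------------------------------------------------------------

@dataclass
class DotplotResult:
    """Exact shared w-mer start pairs between two sequences."""

    w: int
    matches: list[tuple[int, int]]
    alignable_fraction: float


def dotplot(a: str, b: str, w: int = 10) -> DotplotResult:
    """All (i, j) pairs with ``a[i:i+w] == b[j:j+w]``, plus coverage of ``a``.

    ``alignable_fraction`` is the fraction of positions of ``a`` covered by at
    least one matched w-mer.
    """
    if w < 1:
        raise ValueError("word size must be >= 1")
    a, b = a.upper(), b.upper()
    if len(a) < w or len(b) < w:
        raise ValueError("both sequences must be at least w long")
    index: dict[str, list[int]] = {}
    for j in range(len(b) - w + 1):
        index.setdefault(b[j : j + w], []).append(j)
    matches: list[tuple[int, int]] = []
    covered = np.zeros(len(a), dtype=bool)
    for i in range(len(a) - w + 1):
        for j in index.get(a[i : i + w], ()):
            matches.append((i, j))
            covered[i : i + w] = True
    return DotplotResult(w=w, matches=matches,
                         alignable_fraction=float(covered.sum()) / len(a))


def plot_dotplot(result: DotplotResult, path: str, title: str = "") -> None:
    """Scatter the match pairs to an image file (optional convenience)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    if result.matches:
        xs, ys = zip(*result.matches)
        ax.scatter(xs, ys, s=1, marker=".")
    ax.set_xlabel("sequence A position")
    ax.set_ylabel("sequence B position")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
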