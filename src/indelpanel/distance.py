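"""Otsuka-Ochiai dissimilarity, UPGMA and neighbor-joining trees, and
locus-level bootstrap support.

The Otsuka-Ochiai coefficient is the cosine similarity of binary
allele-presence profiles: for accessions i and j, with a = columns scored 1
in both, b = 1 in i only, c = 1 in j only,

    d_ij = 1 - a / sqrt((a + b) * (a + c)).

Columns where either accession is missing are excluded pairwise (scoring a
missing call as absence would bias a downward).  A pair with no shared
scoreable presences ((a+b)(a+c) = 0) is assigned the maximal dissimilarity 1.

Bootstrap resampling is over *marker loci*, not individual binary columns: a
marker's two allele columns are one statistical observation and move
together.  Replicate b of a run with seed s uses the independent RNG stream
seeded by (s, b), so increasing the replicate count never reshuffles earlier
replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix, TreeNode

from .markers import BinaryAlleleMatrix

__all__ = [
    "ochiai_dissimilarity",
    "upgma",
    "neighbor_joining",
    "bootstrap_support",
    "tree_bipartitions",
    "write_phylip",
]


def ochiai_dissimilarity(bm: BinaryAlleleMatrix) -> DistanceMatrix:
    x = bm.cells
    if x.shape[0] < 2:
        raise ValueError("need >= 2 accessions")
    valid = ~np.isnan(x)
    all_missing = ~valid.any(axis=1)
    if all_missing.any():
        bad = [bm.accession_ids[i] for i in np.flatnonzero(all_missing)]
        raise ValueError(f"accessions with all-missing profiles: {bad}")
    p = np.where(valid, np.nan_to_num(x), 0.0)  # presence, zero where missing
    v = valid.astype(float)
    a = p @ p.T
    ab = p @ v.T          # presences of i among columns scored in both
    ac = ab.T
    denom = ab * ac
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(denom > 0, a / np.sqrt(denom), 0.0)
    undefined = int(np.sum(denom[np.triu_indices_from(denom, k=1)] == 0))
    if undefined:
        warnings.warn(
            f"{undefined} accession pair(s) share no scoreable presence; "
            "assigned maximal dissimilarity 1",
            stacklevel=2,
        )
    d = 1.0 - sim
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)  # symmetrize float noise
    return DistanceMatrix(d, ids=bm.accession_ids)


def _linkage_to_tree(lk: np.ndarray, ids: list[str]) -> TreeNode:
    """Ultrametric TreeNode from a scipy linkage matrix: node height = half
    the merge distance, branch length = parent height - child height."""
    n = len(ids)
    nodes: dict[int, tuple[TreeNode, float]] = {
        i: (TreeNode(name=ids[i]), 0.0) for i in range(n)
    }
    for k, (a, b, dist, _cnt) in enumerate(lk):
        left, hl = nodes.pop(int(a))
        right, hr = nodes.pop(int(b))
        h = dist / 2.0
        left.length = h - hl
        right.length = h - hr
        nodes[n + k] = (TreeNode(children=[left, right]), h)
    root, _ = nodes.popitem()[1], None
    tree = root[0]
    tree.length = None
    return tree


def upgma(dm: DistanceMatrix) -> TreeNode:
    """Average-linkage (UPGMA) tree; rooted and ultrametric."""
    lk = average(squareform(dm.data, checks=False))
    return _linkage_to_tree(lk, list(dm.ids))


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining.

    Exact on additive distances.  Negative branch lengths are clamped to zero
    with the deficit moved to the sibling edge (topology unchanged).  For
    n < 3 a trivial tree is returned with a warning.
    """
    ids = list(dm.ids)
    n = len(ids)
    if n < 3:
        warnings.warn("neighbor joining needs >= 3 leaves; returning trivial tree",
                      stacklevel=2)
        children = [TreeNode(name=i, length=dm.data[0, 1] / 2.0) for i in ids]
        return TreeNode(children=children)
    d = dm.data.astype(float).copy()
    nodes = [TreeNode(name=i) for i in ids]
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        fi, fj = np.unravel_index(np.argmin(q), q.shape)
        if fi > fj:
            fi, fj = fj, fi
        i, j = active[fi], active[fj]
        dij = sub[fi, fj]
        li = 0.5 * dij + (r[fi] - r[fj]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            li, lj = 0.0, dij
        if lj < 0:
            li, lj = dij, 0.0
        nodes[i].length = li
        nodes[j].length = lj
        parent = TreeNode(children=[nodes[i], nodes[j]])
        # distances from the new node to the remaining ones
        new_row = 0.5 * (d[i, :] + d[j, :] - dij)
        d = np.vstack([d, new_row])
        d = np.hstack([d, np.append(new_row, 0.0)[:, None]])
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]
    # resolve the last three with the three-point formulas
    i, j, k = active
    dij, dik, djk = d[i, j], d[i, k], d[j, k]
    li = max(0.0, 0.5 * (dij + dik - djk))
    lj = max(0.0, 0.5 * (dij + djk - dik))
    lk = max(0.0, 0.5 * (dik + djk - dij))
    for idx, ln in ((i, li), (j, lj), (k, lk)):
        nodes[idx].length = ln
    return TreeNode(children=[nodes[i], nodes[j], nodes[k]])


def tree_bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions of the leaf set, canonicalized as the side
    that does not contain the lexicographically smallest leaf."""
    leaves = {t.name for t in tree.tips()}
    ref = min(leaves)
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(side) > len(leaves) - 2:
            continue
        if ref in side:
            side = frozenset(leaves - side)
        parts.add(side)
    return parts


@dataclass
class SupportedTree:
    tree: TreeNode
    supports: dict[frozenset, float]  # bipartition -> % of replicates
    n_replicates: int

    def newick(self) -> str:
        return str(self.tree).strip()


def _marker_resample(bm: BinaryAlleleMatrix, rng: np.random.Generator) -> BinaryAlleleMatrix:
    markers = bm.marker_ids
    pick = rng.integers(0, len(markers), size=len(markers))
    cols: list[int] = []
    col_ids: list[tuple[str, str]] = []
    for b, mi in enumerate(pick):
        for c in bm.marker_columns(markers[mi]):
            cols.append(c)
            col_ids.append((f"{markers[mi]}#{b}", bm.column_ids[c][1]))
    return BinaryAlleleMatrix(list(bm.accession_ids), col_ids, bm.cells[:, cols])


def bootstrap_support(
    bm: BinaryAlleleMatrix,
    method: str = "nj",
    n_replicates: int = 100,
    seed: int = 0,
) -> SupportedTree:
    """Point-estimate tree with locus-bootstrap bipartition support (%)."""
    if n_replicates < 1:
        raise ValueError("need >= 1 replicate")
    if len(bm.marker_ids) < 2:
        raise ValueError("need >= 2 loci to bootstrap")
    builders = {"upgma": upgma, "nj": neighbor_joining}
    if method not in builders:
        raise ValueError(f"method must be one of {sorted(builders)}")
    build = builders[method]
    point = build(ochiai_dissimilarity(bm))
    target = tree_bipartitions(point)
    counts = {part: 0 for part in target}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # undefined pairs in sparse replicates
        for b in range(n_replicates):
            rng = np.random.default_rng([seed, b])
            rep = build(ochiai_dissimilarity(_marker_resample(bm, rng)))
            parts = tree_bipartitions(rep)
            for part in target:
                if part in parts:
                    counts[part] += 1
    supports = {p: 100.0 * c / n_replicates for p, c in counts.items()}
    # annotate internal nodes with their support value
    leaves = {t.name for t in point.tips()}
    ref = min(leaves)
    for node in point.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(side) > len(leaves) - 2:
            continue
        key = side if ref not in side else frozenset(leaves - side)
        node.name = f"{supports[key]:g}"
    return SupportedTree(point, supports, n_replicates)


def write_phylip(dm: DistanceMatrix, path) -> None:
    """Square PHYLIP distance-matrix export."""
    with open(path, "w") as fh:
        fh.write(f"{dm.shape[0]}\n")
        for i, name in enumerate(dm.ids):
            row = " ".join(f"{v:.6f}" for v in dm.data[i])
            fh.write(f"{name[:10]:<10} {row}\n")
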