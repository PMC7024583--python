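"""Tree construction and manipulation for proteome dendrograms.

UPGMA (size-weighted average linkage; rooted, ultrametric) and
neighbor joining (Saitou-Nei with the Studier-Keppler criterion; unrooted)
build trees from Jaccard distance matrices. Further utilities: midpoint
rooting, cophenetic (leaf-to-leaf path) distances, a least-squares
ultrametric projection with non-negativity/monotonicity constraints on
node heights, Newick round-tripping, and a tree-fit diagnostic comparing
tree distances against the original dissimilarities.

Trees are :class:`skbio.TreeNode` objects throughout; distance matrices
are :class:`skbio.DistanceMatrix`.
"""

from __future__ import annotations

import io
import logging
from pathlib import Path

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.optimize import minimize
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as _skbio_nj

logger = logging.getLogger(__name__)

#: absolute tolerance for declaring a tree ultrametric
ULTRAMETRIC_TOL = 1e-8


# ---------------------------------------------------------------------------
# construction


def upgma_linkage(d: DistanceMatrix) -> tuple[np.ndarray, list[str]]:
    """SciPy linkage matrix for UPGMA (average linkage) on ``d``.

    The linkage form is kept available because the bootstrap drivers cut
    and re-cluster thousands of resampled matrices; converting each one to
    a tree object would dominate the run time.
    """
    if len(d.ids) < 2:
        raise ValueError("UPGMA needs at least two objects")
    if np.isnan(d.data).any():
        raise ValueError("distance matrix contains NaN")
    return linkage(squareform(d.data, checks=False), method="average"), list(d.ids)


def tree_from_linkage(z: np.ndarray, ids: list[str]) -> TreeNode:
    """Rooted ultrametric tree from a SciPy linkage matrix.

    Node heights are half the merge distances, so cophenetic distances on
    the tree equal the linkage merge distances.
    """
    n = len(ids)
    nodes: list[TreeNode] = [TreeNode(name=str(x)) for x in ids]
    heights = [0.0] * n
    for a, b, dist, _ in z:
        h = dist / 2.0
        left, right = nodes[int(a)], nodes[int(b)]
        left.length = h - heights[int(a)]
        right.length = h - heights[int(b)]
        parent = TreeNode(children=[left, right])
        nodes.append(parent)
        heights.append(h)
    root = nodes[-1]
    root.length = None
    return root


def upgma(d: DistanceMatrix) -> TreeNode:
    """UPGMA dendrogram: iteratively merge the closest pair, averaging
    distances weighted by cluster size; heights are half distances, so the
    output is ultrametric by construction."""
    z, ids = upgma_linkage(d)
    return tree_from_linkage(z, ids)


def neighbor_joining(d: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; returns an unrooted tree.

    Negative estimated branch lengths (possible on non-additive input) are
    clamped to zero and the total clamped deficit logged.
    """
    if len(d.ids) < 3:
        raise ValueError("neighbor joining needs at least three objects")
    if np.isnan(d.data).any():
        raise ValueError("distance matrix contains NaN")
    t = _skbio_nj(d, neg_as_zero=False)
    deficit = 0.0
    for node in t.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            deficit -= node.length
            node.length = 0.0
    if deficit > 0:
        logger.info("clamped negative NJ branch lengths (total deficit %.6g)", deficit)
    return t


def midpoint_root(t: TreeNode) -> TreeNode:
    """Root at the midpoint of the longest leaf-to-leaf path."""
    tips = list(t.tips())
    if len(tips) == 2:
        half = sum(x.length or 0.0 for x in tips) / 2.0
        a = TreeNode(name=tips[0].name, length=half)
        b = TreeNode(name=tips[1].name, length=half)
        return TreeNode(children=[a, b])
    dm = t.tip_tip_distances()
    if dm.data.max() == 0:
        logger.warning("zero-diameter tree; midpoint rooting is arbitrary")
        rooted = t.copy()
        if len(rooted.children) > 2:
            first = rooted.children[0]
            rooted = rooted.root_at(first, branch_attrs=[])
        return rooted
    return t.root_at_midpoint(branch_attrs=[])


# ---------------------------------------------------------------------------
# distances on trees


def cophenetic_matrix(t: TreeNode) -> DistanceMatrix:
    """Leaf-to-leaf path-length (cophenetic) distance matrix."""
    return t.tip_tip_distances()


def is_ultrametric(t: TreeNode, tol: float = ULTRAMETRIC_TOL) -> bool:
    """True iff all root-to-tip path lengths agree within ``tol``."""
    depths = []
    for tip in t.tips():
        d, node = 0.0, tip
        while node is not t:
            d += node.length or 0.0
            node = node.parent
        depths.append(d)
    return max(depths) - min(depths) <= tol


def node_heights(t: TreeNode) -> dict[TreeNode, float]:
    """Height of every node = maximum path length down to a descendant tip."""
    h: dict[TreeNode, float] = {}
    for node in t.postorder():
        if node.is_tip():
            h[node] = 0.0
        else:
            h[node] = max(h[c] + (c.length or 0.0) for c in node.children)
    return h


def nnls_ultrametric(t: TreeNode) -> TreeNode:
    """Least-squares ultrametric projection preserving topology.

    Fits a height ``h(v) >= 0`` to every internal node (leaves at height 0,
    ``h(parent) >= h(child)``) minimising

        sum_{i<j} (D_ij - 2 h(mrca(i, j)))^2

    where D is the cophenetic matrix of the input tree. The quadratic is
    separable over internal nodes (each leaf pair has exactly one MRCA), so
    this is a weighted isotonic regression on the tree partial order; it is
    solved with SLSQP from a feasible warm start and is exact (objective 0)
    on already-ultrametric input. The returned tree has the same topology
    with branch lengths ``h(parent) - h(child)``.
    """
    tree = t.copy()
    tips = list(tree.tips())
    if len(tips) < 2:
        raise ValueError("need at least two leaves")
    dm = tree.tip_tip_distances()
    pos = {name: k for k, name in enumerate(dm.ids)}

    internal: list[TreeNode] = [nd for nd in tree.postorder() if not nd.is_tip()]
    index = {nd: i for i, nd in enumerate(internal)}

    # per-node target t_v = mean(D_ij)/2 over pairs whose MRCA is v
    targets = np.zeros(len(internal))
    weights = np.zeros(len(internal))
    tipsets: dict[TreeNode, list[int]] = {}
    for nd in tree.postorder():
        if nd.is_tip():
            tipsets[nd] = [pos[nd.name]]
            continue
        child_sets = [tipsets[c] for c in nd.children]
        s_sum = 0.0
        n_pairs = 0
        for a in range(len(child_sets)):
            for b in range(a + 1, len(child_sets)):
                ia = np.asarray(child_sets[a])
                ib = np.asarray(child_sets[b])
                block = dm.data[np.ix_(ia, ib)]
                s_sum += block.sum()
                n_pairs += block.size
        i = index[nd]
        weights[i] = n_pairs
        targets[i] = s_sum / (2.0 * n_pairs)
        tipsets[nd] = [k for cs in child_sets for k in cs]

    # feasible warm start: running max of targets up the tree
    x0 = targets.copy()
    for nd in internal:
        for c in nd.children:
            if not c.is_tip():
                x0[index[nd]] = max(x0[index[nd]], x0[index[c]])

    cons = []
    for nd in internal:
        for c in nd.children:
            if not c.is_tip():
                ip, ic = index[nd], index[c]
                cons.append(
                    {"type": "ineq", "fun": (lambda x, a=ip, b=ic: x[a] - x[b]),
                     "jac": (lambda x, a=ip, b=ic, m=len(internal):
                             np.eye(1, m, a)[0] - np.eye(1, m, b)[0])}
                )

    def obj(x):
        r = x - targets
        return float(np.dot(weights * r, r))

    def grad(x):
        return 2.0 * weights * (x - targets)

    if cons:
        res = minimize(
            obj, x0, jac=grad, method="SLSQP", constraints=cons,
            bounds=[(0.0, None)] * len(internal),
            options={"maxiter": 500, "ftol": 1e-14},
        )
        h = res.x
        # repair any infinitesimal constraint violation from the solver
        for nd in internal:
            for c in nd.children:
                if not c.is_tip():
                    h[index[nd]] = max(h[index[nd]], h[index[c]])
    else:
        h = np.maximum(x0, 0.0)

    for nd in internal:
        for c in nd.children:
            hc = 0.0 if c.is_tip() else h[index[c]]
            c.length = h[index[nd]] - hc
    tree.length = None
    return tree


def tree_fit_diagnostic(t: TreeNode, d: DistanceMatrix) -> dict[str, float]:
    """How well tree distances reproduce the original dissimilarities.

    Returns Pearson correlation and the normalised stress
    sqrt(sum (d_tree - d)^2 / sum d^2) over leaf pairs; used to judge NJ
    vs UPGMA suitability for a given matrix.
    """
    dt = t.tip_tip_distances()
    if set(dt.ids) != set(d.ids):
        raise ValueError(
            f"leaf sets differ: {sorted(set(dt.ids) ^ set(d.ids))}"
        )
    order = list(d.ids)
    dt = dt.filter(order)
    iu = np.triu_indices(len(order), k=1)
    a, b = dt.data[iu], d.data[iu]
    denom = float(np.sum(b**2))
    stress = float(np.sqrt(np.sum((a - b) ** 2) / denom)) if denom > 0 else np.nan
    corr = float(pearsonr(a, b).statistic) if np.std(a) > 0 and np.std(b) > 0 else np.nan
    return {"correlation": corr, "stress": stress}


# ---------------------------------------------------------------------------
# Newick I/O


def read_newick(source) -> TreeNode:
    """Parse Newick from a file path or a literal string.

    Underscores in unquoted labels are kept verbatim (not turned into
    spaces), matching how sample/species codes are written here.
    """
    if isinstance(source, (str, Path)) and "(" not in str(source):
        return TreeNode.read(str(source), format="newick", convert_underscores=False)
    return TreeNode.read(
        io.StringIO(str(source)), format="newick", convert_underscores=False
    )


def write_newick(t: TreeNode, path=None) -> str:
    """Serialise to Newick; returns the text, optionally also writing a file."""
    buf = io.StringIO()
    t.write(buf, format="newick")
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text
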