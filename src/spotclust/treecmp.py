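"""Quantitative concordance between two trees over the same leaves.

Four complementary views:

* **Robinson-Foulds distance** — the number of non-trivial bipartitions
  implied by exactly one of the two unrooted trees; normalised by
  2(n - 3), the maximum for fully resolved binary trees.
* **Fowlkes-Mallows profile** — both (ultrametric) trees are cut into k
  clusters by merge height for k = 2..n-2 and the compositional
  similarity Bk = Tk / sqrt(Pk Qk) of the two cuts is computed from their
  contingency matrix, together with the analytic mean and variance of Bk
  under the permutation null (random relabelling of one cut) and a
  one-sided rejection threshold.
* **Cophenetic correlation** — Pearson correlation of the two trees'
  leaf-pair path-length vectors.
* **Normalised cophenetic matrices** — each tree's cophenetic distances
  expressed as fractions of its own maximum, for direct side-by-side
  reading of relative distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, pearsonr
from skbio import DistanceMatrix, TreeNode

from spotclust.trees import cophenetic_matrix, node_heights


# ---------------------------------------------------------------------------
# bipartitions and Robinson-Foulds


def bipartition_sets(t: TreeNode) -> set[frozenset[frozenset[str]]]:
    """Non-trivial bipartitions of an unrooted tree as {side1, side2} pairs."""
    leaves = frozenset(x.name for x in t.tips())
    n = len(leaves)
    out = set()
    for node in t.non_tips(include_self=False):
        side = frozenset(x.name for x in node.tips())
        if 2 <= len(side) <= n - 2:
            out.add(frozenset({side, leaves - side}))
    return out


def _check_leaf_sets(t1: TreeNode, t2: TreeNode) -> int:
    l1 = {x.name for x in t1.tips()}
    l2 = {x.name for x in t2.tips()}
    if l1 != l2:
        raise ValueError(f"leaf sets differ: {sorted(l1 ^ l2)}")
    return len(l1)


def robinson_foulds(t1: TreeNode, t2: TreeNode) -> tuple[int, float]:
    """Raw and normalised Robinson-Foulds distance between unrooted trees.

    RF is the size of the symmetric difference of the two non-trivial
    bipartition sets. The normaliser is 2(n - 3) when both trees are fully
    resolved, else the total number of non-trivial bipartitions present.
    """
    n = _check_leaf_sets(t1, t2)
    s1, s2 = bipartition_sets(t1), bipartition_sets(t2)
    rf = len(s1 ^ s2)
    full = 2 * (n - 3)
    denom = full if len(s1) == len(s2) == n - 3 else len(s1) + len(s2)
    nrf = rf / denom if denom else 0.0
    return rf, nrf


# ---------------------------------------------------------------------------
# height cuts and the Fowlkes-Mallows profile


def cut_tree(t: TreeNode, k: int) -> dict[str, int]:
    """Cut a rooted tree into k clusters by node height.

    The k - 1 highest internal nodes (height = max path length to a
    descendant tip; ties broken by the lexicographically smallest
    descendant tip label) are "opened"; the maximal subtrees below them
    are the clusters. For an ultrametric dendrogram this is the usual cut
    of the merge hierarchy. Returns leaf label -> 0-based cluster id.
    """
    tips = [x.name for x in t.tips()]
    n = len(tips)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range 1..{n}")
    h = node_heights(t)
    internal = [nd for nd in t.non_tips(include_self=True)]
    internal.sort(key=lambda nd: (-h[nd], min(x.name for x in nd.tips())))
    opened = set(internal[: k - 1])
    # greedy repair: "opened" must be upward-closed (a node cannot be opened
    # under an unopened parent); with monotone heights the sort guarantees it
    labels: dict[str, int] = {}
    cluster = 0

    def assign(node):
        nonlocal cluster
        if node in opened:
            for c in node.children:
                assign(c)
        else:
            for x in ([node] if node.is_tip() else node.tips()):
                labels[x.name] = cluster
            cluster += 1

    assign(t)
    return labels


def _bk_from_labels(lab1: np.ndarray, lab2: np.ndarray):
    n = len(lab1)
    k1, k2 = lab1.max() + 1, lab2.max() + 1
    mm = np.bincount(lab1 * k2 + lab2, minlength=k1 * k2).reshape(k1, k2).astype(float)
    tk = (mm**2).sum() - n
    pk = (mm.sum(axis=1) ** 2).sum() - n
    qk = (mm.sum(axis=0) ** 2).sum() - n
    return tk, pk, qk, mm


def fm_null_moments(row_sizes, col_sizes, n: int) -> tuple[float, float]:
    """Mean and SD of Bk under random permutation of one labelling.

    Closed-form moments in terms of Pk = sum m_i (m_i - 1),
    Pk' = sum m_i (m_i - 1)(m_i - 2) and likewise Qk, Qk' for the other
    cut (verified against a Monte-Carlo permutation null in the tests).
    """
    mi = np.asarray(row_sizes, dtype=float)
    mj = np.asarray(col_sizes, dtype=float)
    pk = (mi * (mi - 1)).sum()
    qk = (mj * (mj - 1)).sum()
    if pk == 0 or qk == 0:
        raise ValueError("degenerate cut (all singletons or a single cluster)")
    pk1 = (mi * (mi - 1) * (mi - 2)).sum()
    qk1 = (mj * (mj - 1) * (mj - 2)).sum()
    e = np.sqrt(pk * qk) / (n * (n - 1))
    var = (
        2.0 / (n * (n - 1))
        + 4.0 * pk1 * qk1 / (n * (n - 1) * (n - 2) * pk * qk)
        + (pk - 2 - 4 * pk1 / pk) * (qk - 2 - 4 * qk1 / qk)
        / (n * (n - 1) * (n - 2) * (n - 3))
        - pk * qk / (n * (n - 1)) ** 2
    )
    return float(e), float(np.sqrt(max(var, 0.0)))


@dataclass
class FMProfile:
    """Bk profile over k with permutation-null moments and thresholds."""

    k: list[int]
    bk: list[float]
    e_null: list[float]
    sd_null: list[float]
    threshold: list[float]
    significant: list[bool]
    alpha: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.k,
                "Bk": self.bk,
                "E_null": self.e_null,
                "sd_null": self.sd_null,
                "threshold": self.threshold,
                "significant": self.significant,
            }
        )


def fowlkes_mallows_profile(t1: TreeNode, t2: TreeNode, alpha: float = 0.05) -> FMProfile:
    """Bk between height-cuts of two rooted trees for k = 2..n-2.

    For each k both trees are cut into k clusters, Bk = Tk / sqrt(Pk Qk)
    is computed from the k x k contingency matrix, and the analytic
    permutation-null mean/SD give a one-sided rejection threshold
    E[Bk] + z_(1-alpha) * sd. Degenerate cuts (Pk or Qk = 0) are omitted.
    """
    n = _check_leaf_sets(t1, t2)
    order = sorted(x.name for x in t1.tips())
    z = norm.ppf(1 - alpha)
    ks, bks, es, sds, thr, sig = [], [], [], [], [], []
    for k in range(2, n - 1):
        c1 = cut_tree(t1, k)
        c2 = cut_tree(t2, k)
        lab1 = np.array([c1[x] for x in order])
        lab2 = np.array([c2[x] for x in order])
        tk, pk, qk, mm = _bk_from_labels(lab1, lab2)
        if pk == 0 or qk == 0:
            continue
        bk = tk / np.sqrt(pk * qk)
        e, sd = fm_null_moments(mm.sum(axis=1), mm.sum(axis=0), n)
        ks.append(k)
        bks.append(float(bk))
        es.append(e)
        sds.append(sd)
        thr.append(e + z * sd)
        sig.append(bool(bk > e + z * sd))
    return FMProfile(ks, bks, es, sds, thr, sig, alpha)


# ---------------------------------------------------------------------------
# cophenetic comparisons


def cophenetic_correlation(t1: TreeNode, t2: TreeNode) -> float:
    """Pearson correlation of the two trees' cophenetic distance vectors."""
    _check_leaf_sets(t1, t2)
    order = sorted(x.name for x in t1.tips())
    d1 = cophenetic_matrix(t1).filter(order).data
    d2 = cophenetic_matrix(t2).filter(order).data
    iu = np.triu_indices(len(order), k=1)
    a, b = d1[iu], d2[iu]
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("cophenetic distances have zero variance")
    return float(pearsonr(a, b).statistic)


def normalized_cophenetic(t: TreeNode) -> DistanceMatrix:
    """Cophenetic distances as fractions of the tree's maximum distance."""
    dm = cophenetic_matrix(t)
    mx = dm.data.max()
    if mx == 0:
        raise ValueError("tree has zero total length; cannot normalise")
    return DistanceMatrix(dm.data / mx, dm.ids)


# ---------------------------------------------------------------------------
# combined report


@dataclass
class TreeComparisonReport:
    rf: int
    nrf: float
    cophenetic_corr: float
    fm_profile: FMProfile
    norm_cophenetic_1: DistanceMatrix
    norm_cophenetic_2: DistanceMatrix
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "rf": self.rf,
            "nrf": self.nrf,
            "cophenetic_correlation": self.cophenetic_corr,
            "fm_profile": self.fm_profile.to_frame().to_dict(orient="list"),
            "notes": self.notes,
        }


def compare_trees(
    t1: TreeNode, t2: TreeNode, alpha: float = 0.05, ultrametricize: bool = True
) -> TreeComparisonReport:
    """Full concordance report between two trees on the same leaf set.

    RF is computed on the trees as given (unrooted reading); the FM
    profile, cophenetic correlation and normalised matrices use the
    least-squares ultrametric projections unless ``ultrametricize`` is
    disabled (the correlation of the raw trees is then reported instead).
    """
    from spotclust.trees import is_ultrametric, midpoint_root, nnls_ultrametric

    rf, nrf = robinson_foulds(t1, t2)
    notes = []

    def prep(t):
        if not ultrametricize:
            return t
        rooted = t if len(t.children) == 2 else midpoint_root(t)
        if is_ultrametric(rooted):
            return rooted
        notes.append("tree projected to ultrametric by constrained least squares")
        return nnls_ultrametric(rooted)

    u1, u2 = prep(t1), prep(t2)
    return TreeComparisonReport(
        rf=rf,
        nrf=nrf,
        cophenetic_corr=cophenetic_correlation(u1, u2),
        fm_profile=fowlkes_mallows_profile(u1, u2, alpha=alpha),
        norm_cophenetic_1=normalized_cophenetic(u1),
        norm_cophenetic_2=normalized_cophenetic(u2),
        notes=notes,
    )
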