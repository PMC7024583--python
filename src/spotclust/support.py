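"""Branch support for proteome dendrograms by feature resampling.

Two estimators are provided, both resampling protein spots (the features;
the trees cluster samples or species):

* **Approximately unbiased (AU) p-values** by multiscale bootstrap: spots
  are resampled at a grid of relative sizes ``r``, the bootstrap
  proportion ``BP(r)`` of each full-data clade is recorded per scale, and
  the two-parameter model ``psi(r) = v*sqrt(r) + c/sqrt(r)`` is fitted to
  the probit-transformed proportions ``psi(r) = Phi^-1(1 - BP(r))`` by
  maximum binomial likelihood (weighted least squares as starting point
  and fallback). Then ``AU = 1 - Phi(v - c)`` and the bias-corrected
  ordinary proportion is ``BP_corrected = 1 - Phi(v + c)``; ``v`` is the
  signed distance of the data from the region boundary and ``c`` its
  curvature. Standard errors come from the delta method on the binomial
  Fisher information.

* **Ordinary (Felsenstein) bootstrap proportions** at full resample size
  for every non-trivial bipartition of the reference NJ tree.

Clade identity is label-set based (bitmask internally), so support values
are invariant to tree rotations and to sample column order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.optimize import minimize
from scipy.stats import norm
from skbio import TreeNode

from spotclust.dissimilarity import jaccard_binary
from spotclust.spot_data import SpotMatrix
from spotclust.trees import neighbor_joining, tree_from_linkage, upgma_linkage

#: default relative resample sizes for the multiscale bootstrap
DEFAULT_SCALES: tuple[float, ...] = tuple(round(0.5 + 0.1 * i, 1) for i in range(10))


@dataclass
class SupportRecord:
    """Fitted support for one clade (or bipartition) of the full-data tree."""

    clade: frozenset[str]
    scales: tuple[float, ...]
    bp: np.ndarray  # bootstrap proportion per scale
    v: float = np.nan  # signed distance
    c: float = np.nan  # curvature
    au: float = np.nan
    bp_corrected: float = np.nan
    se_au: float = np.nan
    fit: str = "mle"  # mle | wls | degenerate | fallback

    @property
    def bp_at_1(self) -> float:
        """Plain bootstrap proportion at (or nearest to) full resample size."""
        i = int(np.argmin(np.abs(np.asarray(self.scales) - 1.0)))
        return float(self.bp[i])


# ---------------------------------------------------------------------------
# fast internals (bitmask clades, inline Jaccard)


def _fast_jaccard(x: np.ndarray) -> np.ndarray:
    """Condensed-form-free Jaccard between columns of binary x (float64 out)."""
    xf = x.astype(np.float64)
    inter = xf.T @ xf
    sizes = xf.sum(axis=0)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - inter / union
    d[union == 0] = 0.0
    np.fill_diagonal(d, 0.0)
    return d


def _linkage_clades(z: np.ndarray, n: int) -> list[int]:
    """Bitmasks of the merged clusters of a linkage matrix (size 2..n)."""
    masks = [1 << i for i in range(n)]
    out = []
    for a, b, *_ in z:
        m = masks[int(a)] | masks[int(b)]
        masks.append(m)
        out.append(m)
    return out


def _tree_bipartitions(t: TreeNode, pos: dict[str, int]) -> list[int]:
    """Canonical bitmasks of non-trivial bipartitions of an (unrooted) tree.

    Each internal edge splits the leaves in two; the side not containing
    leaf 0 is the canonical mask. Trivial splits (single leaf either side)
    are skipped.
    """
    n = len(pos)
    full = (1 << n) - 1
    out = []
    masks: dict[TreeNode, int] = {}
    for node in t.postorder():
        if node.is_tip():
            masks[node] = 1 << pos[node.name]
            continue
        m = 0
        for c in node.children:
            m |= masks[c]
        masks[node] = m
        if node.is_root():
            continue
        mm = m if not (m & 1) else (full ^ m)
        if 2 <= bin(mm).count("1") <= n - 2:
            out.append(mm)
    return out


def _clade_labels(mask: int, ids: list[str]) -> frozenset[str]:
    return frozenset(ids[i] for i in range(len(ids)) if mask >> i & 1)


def _resample_masks(x: np.ndarray, idx: np.ndarray, method: str,
                    pos: dict[str, int]) -> set[int]:
    """Clade/bipartition masks of the tree built from resampled spots."""
    d = _fast_jaccard(x[idx])
    if method == "upgma":
        z = linkage(squareform(d, checks=False), method="average")
        n = d.shape[0]
        return {m for m in _linkage_clades(z, n)}
    from skbio import DistanceMatrix

    ids = sorted(pos, key=pos.get)
    t = neighbor_joining(DistanceMatrix(d, ids))
    return set(_tree_bipartitions(t, pos))


# ---------------------------------------------------------------------------
# AU model fitting


def _fit_au(counts: np.ndarray, b: int, scales: np.ndarray) -> dict:
    """Fit the two-parameter multiscale model to per-scale clade counts."""
    bp = counts / b
    if np.all(counts == b):
        return dict(v=-np.inf, c=0.0, au=1.0, bp_corrected=1.0, se_au=0.0,
                    fit="degenerate")
    if np.all(counts == 0):
        return dict(v=np.inf, c=0.0, au=0.0, bp_corrected=0.0, se_au=0.0,
                    fit="degenerate")
    inf = (counts > 0) & (counts < b)
    if inf.sum() < 2:
        # too few informative scales for the two-parameter fit
        i = int(np.argmin(np.abs(scales - 1.0)))
        au = float(bp[i])
        return dict(v=np.nan, c=np.nan, au=au, bp_corrected=au, se_au=np.nan,
                    fit="fallback")

    r = scales[inf]
    k = counts[inf].astype(float)
    sq = np.sqrt(r)
    design = np.column_stack([sq, 1.0 / sq])
    psi = norm.ppf(1.0 - k / b)

    # WLS start: weights = B phi(psi)^2 / (bp (1-bp))
    p_obs = k / b
    w = b * norm.pdf(psi) ** 2 / (p_obs * (1.0 - p_obs))
    wd = design * w[:, None]
    try:
        theta = np.linalg.solve(design.T @ wd, wd.T @ psi)
    except np.linalg.LinAlgError:
        i = int(np.argmin(np.abs(scales - 1.0)))
        au = float(bp[i])
        return dict(v=np.nan, c=np.nan, au=au, bp_corrected=au, se_au=np.nan,
                    fit="fallback")

    def nll(t):
        x = design @ t
        p = np.clip(1.0 - norm.cdf(x), 1e-12, 1.0 - 1e-12)
        return -np.sum(k * np.log(p) + (b - k) * np.log1p(-p))

    def grad(t):
        x = design @ t
        p = np.clip(1.0 - norm.cdf(x), 1e-12, 1.0 - 1e-12)
        # d nll / d x_r = phi(x) * (k/p - (B-k)/(1-p))
        gx = norm.pdf(x) * (k / p - (b - k) / (1.0 - p))
        return design.T @ gx

    res = minimize(nll, theta, jac=grad, method="BFGS",
                   options={"gtol": 1e-8, "maxiter": 200})
    fit = "mle"
    if res.success and np.isfinite(res.x).all():
        theta = res.x
    else:
        fit = "wls"
    v, c = float(theta[0]), float(theta[1])

    au = float(1.0 - norm.cdf(v - c))
    bp_c = float(1.0 - norm.cdf(v + c))

    # delta-method SE from the binomial Fisher information
    x = design @ theta
    p = np.clip(1.0 - norm.cdf(x), 1e-12, 1.0 - 1e-12)
    fw = b * norm.pdf(x) ** 2 / (p * (1.0 - p))
    info = design.T @ (design * fw[:, None])
    try:
        cov = np.linalg.inv(info)
        var = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
        se_au = float(norm.pdf(v - c) * np.sqrt(max(var, 0.0)))
    except np.linalg.LinAlgError:
        se_au = np.nan
    return dict(v=v, c=c, au=au, bp_corrected=bp_c, se_au=se_au, fit=fit)


# ---------------------------------------------------------------------------
# public drivers


def multiscale_bootstrap_support(
    m: SpotMatrix,
    method: str = "upgma",
    scales: tuple[float, ...] = DEFAULT_SCALES,
    b: int = 10_000,
    seed: int = 0,
) -> tuple[list[SupportRecord], TreeNode]:
    """AU support for every non-trivial clade of the full-data tree.

    Spots are resampled with replacement at each relative size in
    ``scales`` (``round(r * n_spots)`` spots per replicate, ``b``
    replicates per scale, an independent seeded substream per scale so
    results do not depend on execution order). Returns the fitted support
    records plus the full-data tree.

    Parameters
    ----------
    m : SpotMatrix
        Binary spots x objects matrix; objects (columns) are clustered.
    method : {"upgma", "nj"}
        Clustering applied to Jaccard distances within each replicate.
    """
    if method not in ("upgma", "nj"):
        raise ValueError(f"unknown clustering method {method!r}")
    if len(scales) < 2:
        raise ValueError("need at least two resampling scales")
    # canonical column order: support depends only on label sets, so make
    # tie-breaking inside replicates independent of input column order
    m = m.subset_samples(sorted(m.sample_ids))
    n = m.n_samples
    pos = {s: i for i, s in enumerate(m.sample_ids)}
    d0 = jaccard_binary(m)

    if method == "upgma":
        z, ids = upgma_linkage(d0)
        tree = tree_from_linkage(z, ids)
        ref = [mk for mk in _linkage_clades(z, n) if 2 <= bin(mk).count("1") < n]
    else:
        tree = neighbor_joining(d0)
        ref = _tree_bipartitions(tree, pos)

    scales_arr = np.asarray(scales, dtype=float)
    counts = np.zeros((len(ref), len(scales)), dtype=np.int64)
    x = m.values
    n_spots = m.n_spots
    for si, r in enumerate(scales_arr):
        rng = np.random.default_rng([seed, si])
        m_r = max(1, int(round(r * n_spots)))
        for _ in range(b):
            idx = rng.integers(0, n_spots, m_r)
            got = _resample_masks(x, idx, method, pos)
            for ci, mk in enumerate(ref):
                if mk in got:
                    counts[ci, si] += 1

    records = []
    for ci, mk in enumerate(ref):
        fitted = _fit_au(counts[ci], b, scales_arr)
        records.append(
            SupportRecord(
                clade=_clade_labels(mk, m.sample_ids),
                scales=tuple(scales_arr),
                bp=counts[ci] / b,
                **fitted,
            )
        )
    return records, tree


def felsenstein_bootstrap_support(
    m: SpotMatrix, b: int = 1_000, seed: int = 0, method: str = "nj"
) -> tuple[list[SupportRecord], TreeNode]:
    """Ordinary bootstrap proportions at full resample size.

    Resamples spots with replacement (``n_spots`` each time), rebuilds the
    tree, and reports the fraction of replicates containing each
    non-trivial bipartition (NJ) or clade (UPGMA) of the full-data tree.
    """
    if method not in ("upgma", "nj"):
        raise ValueError(f"unknown clustering method {method!r}")
    m = m.subset_samples(sorted(m.sample_ids))
    n = m.n_samples
    pos = {s: i for i, s in enumerate(m.sample_ids)}
    d0 = jaccard_binary(m)
    if method == "upgma":
        z, ids = upgma_linkage(d0)
        tree = tree_from_linkage(z, ids)
        ref = [mk for mk in _linkage_clades(z, n) if 2 <= bin(mk).count("1") < n]
    else:
        tree = neighbor_joining(d0)
        ref = _tree_bipartitions(tree, pos)

    counts = np.zeros(len(ref), dtype=np.int64)
    rng = np.random.default_rng([seed, 0])
    x = m.values
    for _ in range(b):
        idx = rng.integers(0, m.n_spots, m.n_spots)
        got = _resample_masks(x, idx, method, pos)
        for ci, mk in enumerate(ref):
            if mk in got:
                counts[ci] += 1

    records = [
        SupportRecord(
            clade=_clade_labels(mk, m.sample_ids),
            scales=(1.0,),
            bp=np.array([counts[ci] / b]),
            au=np.nan,
            fit="felsenstein",
        )
        for ci, mk in enumerate(ref)
    ]
    return records, tree


# ---------------------------------------------------------------------------
# reporting


def support_table(records: list[SupportRecord]) -> pd.DataFrame:
    """Tabular report: one row per clade with AU, BP, v, c and SE."""
    rows = []
    for r in records:
        rows.append(
            {
                "clade": ";".join(sorted(r.clade)),
                "size": len(r.clade),
                "au": r.au,
                "bp": r.bp_at_1,
                "bp_corrected": r.bp_corrected,
                "v": r.v,
                "c": r.c,
                "se_au": r.se_au,
                "fit": r.fit,
            }
        )
    return pd.DataFrame(rows)


def annotate_tree_support(
    tree: TreeNode, records: list[SupportRecord], value: str = "au", scale: float = 100
) -> TreeNode:
    """Copy of ``tree`` with internal nodes labelled by support * scale.

    ``value`` selects the AU p-value or the plain bootstrap proportion;
    matching is by tip-label set, so any rotation of the tree works.
    """
    by_clade = {r.clade: r for r in records}
    out = tree.copy()
    for node in out.non_tips(include_self=False):
        key = frozenset(t.name for t in node.tips())
        rec = by_clade.get(key)
        if rec is None:
            continue
        val = rec.au if value == "au" else rec.bp_at_1
        if np.isfinite(val):
            node.name = f"{val * scale:.0f}"
    return out
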