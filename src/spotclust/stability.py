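"""Clusterwise bootstrap stability of flat cuts of a dendrogram.

Samples (columns) are resampled with replacement; each bootstrap data set
is reclustered (UPGMA on Jaccard distances) and cut into k clusters for
every requested k. Each original cluster C is then scored against the
bootstrap partition by its best Jaccard match,

    J(C) = max_D |C & D| / |C | D|,

computed over the *distinct* samples drawn in that iteration (original
clusters are restricted to drawn samples; iterations in which C has no
drawn member are skipped for C, not scored zero). Aggregated over
iterations this yields a mean stability J per cluster, its SD, a recovery
probability (fraction of iterations with J > 0.75 — "stable, successfully
recovered") and a dissolution probability (fraction with J < 0.5 —
"dissolved", membership uncertain).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from spotclust.dissimilarity import jaccard_binary
from spotclust.spot_data import SpotMatrix
from spotclust.support import _fast_jaccard

logger = logging.getLogger(__name__)

#: J above this marks a stable, successfully recovered cluster
RECOVERY_THRESHOLD = 0.75
#: J below this marks a dissolved cluster
DISSOLUTION_THRESHOLD = 0.5


@dataclass
class StabilityRecord:
    """Bootstrap stability of one cluster of one k-cut."""

    n_cl: int  # number of clusters in the cut
    cl_id: int  # 1-based cluster index within the cut
    members: frozenset[str]
    mean_j: float
    sd_j: float
    recover_prob: float  # fraction of iterations with J > 0.75
    dissolved_prob: float  # fraction of iterations with J < 0.5
    n_eval: int  # iterations in which the cluster had drawn members


def _cut_labels(z: np.ndarray, ks: list[int]) -> dict[int, np.ndarray]:
    return {k: fcluster(z, t=k, criterion="maxclust") for k in ks}


def _best_jaccard(orig: np.ndarray, boot: np.ndarray, n_orig: int, n_boot: int):
    """Best-match Jaccard of each original cluster vs all bootstrap clusters.

    ``orig``/``boot`` are 0-based label vectors over the same distinct
    drawn samples. Returns an array of length ``n_orig`` with NaN for
    original clusters with no drawn member.
    """
    cont = np.bincount(orig * n_boot + boot, minlength=n_orig * n_boot).reshape(
        n_orig, n_boot
    )
    sz_o = cont.sum(axis=1)
    sz_b = cont.sum(axis=0)
    union = sz_o[:, None] + sz_b[None, :] - cont
    with np.errstate(invalid="ignore", divide="ignore"):
        jac = cont / union
    best = np.where(sz_o > 0, np.nanmax(np.where(union > 0, jac, 0.0), axis=1), np.nan)
    return best


def bootstrap_cluster_stability(
    m: SpotMatrix,
    k_range=range(2, 13),
    b: int = 10_000,
    seed: int = 0,
    exhaustive: bool = False,
) -> list[StabilityRecord]:
    """Clusterwise bootstrap stability for UPGMA/Jaccard k-cuts.

    Parameters
    ----------
    m : SpotMatrix
        Binary spots x samples matrix; samples are clustered and resampled.
    k_range : iterable of int
        Numbers of clusters to cut the dendrogram into (each k <= n).
    b : int
        Bootstrap iterations (ignored when ``exhaustive`` is set).
    exhaustive : bool
        Enumerate all n**n resamples instead of sampling — exact but only
        feasible for tiny n; used to validate the Monte-Carlo estimator.
    """
    n = m.n_samples
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty k_range")
    if ks[-1] > n:
        raise ValueError(f"k={ks[-1]} exceeds the number of samples ({n})")
    if ks[0] < 1:
        raise ValueError("k must be >= 1")

    # canonical sample order makes the resampling stream, and hence the
    # whole report, independent of input column order
    m = m.subset_samples(sorted(m.sample_ids))
    d0 = jaccard_binary(m)
    z0 = linkage(squareform(d0.data, checks=False), method="average")
    # original cut labels, aligned to d0.ids == m.sample_ids
    orig_labels = _cut_labels(z0, ks)

    sums = {k: np.zeros(k) for k in ks}
    sqsums = {k: np.zeros(k) for k in ks}
    n_eval = {k: np.zeros(k, dtype=np.int64) for k in ks}
    n_rec = {k: np.zeros(k, dtype=np.int64) for k in ks}
    n_dis = {k: np.zeros(k, dtype=np.int64) for k in ks}

    if exhaustive:
        draws = itertools.product(range(n), repeat=n)
    else:
        rng = np.random.default_rng([seed, 0])
        draws = (rng.integers(0, n, n) for _ in range(b))

    x = m.values
    for idx in draws:
        idx = np.asarray(idx)
        distinct, first_pos = np.unique(idx, return_index=True)
        d_boot = _fast_jaccard(x[:, idx])
        if len(distinct) < 2:
            # a single distinct sample: every cluster containing it is
            # recovered exactly; others are skipped
            for k in ks:
                ol = orig_labels[k][distinct] - 1
                sums[k][ol] += 1.0
                sqsums[k][ol] += 1.0
                n_eval[k][ol] += 1
                n_rec[k][ol] += 1
            continue
        z = linkage(squareform(d_boot, checks=False), method="average")
        for k in ks:
            kk = min(k, len(distinct))
            boot = fcluster(z, t=kk, criterion="maxclust")
            # collapse duplicates: each distinct sample takes the cluster of
            # its first occurrence in the draw (set semantics)
            boot_d = boot[first_pos] - 1
            orig_d = orig_labels[k][distinct] - 1
            best = _best_jaccard(orig_d, boot_d, k, boot_d.max() + 1)
            got = np.isfinite(best)
            cl = np.nonzero(got)[0]
            j = best[got]
            sums[k][cl] += j
            sqsums[k][cl] += j**2
            n_eval[k][cl] += 1
            n_rec[k][cl] += j > RECOVERY_THRESHOLD
            n_dis[k][cl] += j < DISSOLUTION_THRESHOLD

    skipped = sum(int((n_eval[k] == 0).sum()) for k in ks)
    if skipped:
        logger.info("%d (k, cluster) combinations never drawn; reported as NaN", skipped)

    records: list[StabilityRecord] = []
    ids = np.asarray(m.sample_ids)
    for k in ks:
        lab = orig_labels[k]
        # tied merge heights can make the k-cut produce fewer than k
        # clusters; report the clusters that actually exist
        for cl in (np.unique(lab) - 1):
            ne = int(n_eval[k][cl])
            if ne:
                mean = sums[k][cl] / ne
                var = max(sqsums[k][cl] / ne - mean**2, 0.0)
                sd = float(np.sqrt(var * ne / (ne - 1))) if ne > 1 else 0.0
            else:
                mean, sd = np.nan, np.nan
            records.append(
                StabilityRecord(
                    n_cl=k,
                    cl_id=cl + 1,
                    members=frozenset(ids[lab == cl + 1]),
                    mean_j=float(mean),
                    sd_j=sd,
                    recover_prob=n_rec[k][cl] / ne if ne else np.nan,
                    dissolved_prob=n_dis[k][cl] / ne if ne else np.nan,
                    n_eval=ne,
                )
            )
    return records


def stability_table(records: list[StabilityRecord]) -> pd.DataFrame:
    """Stability report with columns n_cl, cl_id, mean_j, sd_j,
    recover_prob, dissolved_prob, cl_cont (semicolon-joined members)."""
    return pd.DataFrame(
        {
            "n_cl": [r.n_cl for r in records],
            "cl_id": [r.cl_id for r in records],
            "mean_j": [r.mean_j for r in records],
            "sd_j": [r.sd_j for r in records],
            "recover_prob": [r.recover_prob for r in records],
            "dissolved_prob": [r.dissolved_prob for r in records],
            "cl_cont": [";".join(sorted(r.members)) for r in records],
        }
    )


def first_appearance(records: list[StabilityRecord]) -> pd.DataFrame:
    """For each distinct cluster composition, the smallest cut (n_cl) at
    which it appears and its recovery probability there."""
    best: dict[frozenset, StabilityRecord] = {}
    for r in sorted(records, key=lambda r: r.n_cl):
        if r.members not in best:
            best[r.members] = r
    return pd.DataFrame(
        {
            "cl_cont": [";".join(sorted(k)) for k in best],
            "first_n_cl": [r.n_cl for r in best.values()],
            "recover_prob": [r.recover_prob for r in best.values()],
        }
    )
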