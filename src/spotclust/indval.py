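"""Taxon-specific marker discovery by indicator-value (IndVal) analysis.

For a target group of samples versus its complement, each spot's
group-equalized indicator value is

    IndVal_g = sqrt(A_g * B),   A_g = f1 / (f1 + f2),   B = f1,

where ``f_k`` is the spot's occurrence frequency within group k. The
group-equalized specificity ``A_g`` weights both groups equally
regardless of their sizes, removing the bias of unbalanced designs;
``B`` is the sensitivity (probability of finding the spot given the
sample is in the target group). Significance comes from a free
permutation of group labels (all spots share the same permutations), and
p-values are corrected across spots by the Benjamini-Hochberg step-up.
The raw specificity ``A`` = P(sample in target | spot present) is also
reported; a "perfect" marker has A = 1 and B = 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from spotclust.spot_data import SampleAnnotation, SpotMatrix

logger = logging.getLogger(__name__)

#: switch to complete enumeration when the number of distinct label
#: arrangements C(n, n1) does not exceed this
ENUMERATION_LIMIT = 20_000
_STAT_TIE_TOL = 1e-12


@dataclass
class TargetCluster:
    """A named two-group contrast: target samples vs all the rest."""

    name: str
    members: list[str]

    def indicator(self, sample_ids: list[str]) -> np.ndarray:
        mem = set(self.members)
        ind = np.array([s in mem for s in sample_ids], dtype=bool)
        if not ind.any():
            raise ValueError(f"target {self.name!r}: no member sample present")
        if ind.all():
            raise ValueError(f"target {self.name!r}: complement is empty")
        return ind

    @classmethod
    def from_annotation(
        cls, ann: SampleAnnotation, name: str, **conditions
    ) -> "TargetCluster":
        return cls(name, ann.samples_where(**conditions))


def _stats_from_counts(k1, k2, n1, n2):
    """(A_g, B, stat) from per-group presence counts; vectorised over spots."""
    f1 = k1 / n1
    f2 = k2 / n2
    tot = f1 + f2
    with np.errstate(invalid="ignore", divide="ignore"):
        a_g = np.where(tot > 0, f1 / tot, 0.0)
    return a_g, f1, np.sqrt(a_g * f1)


def indval_group_equalized(m: SpotMatrix, target: TargetCluster) -> pd.DataFrame:
    """Group-equalized indicator statistics per spot.

    Returns a DataFrame indexed by spot id with columns ``A_g`` (equalized
    specificity), ``B`` (sensitivity) and ``stat`` = sqrt(A_g * B). Spots
    absent everywhere score 0 (logged).
    """
    ind = target.indicator(m.sample_ids)
    n1, n2 = int(ind.sum()), int((~ind).sum())
    k1 = m.values[:, ind].sum(axis=1)
    k2 = m.values[:, ~ind].sum(axis=1)
    n_absent = int(((k1 + k2) == 0).sum())
    if n_absent:
        logger.info("%d spots absent from every sample score IndVal 0", n_absent)
    a_g, b_, stat = _stats_from_counts(k1, k2, n1, n2)
    return pd.DataFrame({"A_g": a_g, "B": b_, "stat": stat}, index=m.spot_ids)


def permutation_pvalues(
    m: SpotMatrix,
    target: TargetCluster,
    n_perm: int = 9_999,
    seed: int = 0,
    enumeration_limit: int = ENUMERATION_LIMIT,
) -> pd.DataFrame:
    """Permutation p-values for the group-equalized IndVal statistic.

    Group labels are permuted freely, the same permutation applied to all
    spots. When the number of distinct target assignments C(n, n1) is at
    most ``enumeration_limit``, all are enumerated and the p-value is the
    exact tail fraction; otherwise ``n_perm`` random permutations are
    drawn and p = (1 + #{permuted stat >= observed}) / (1 + n_perm).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    ind = target.indicator(m.sample_ids)
    n = len(ind)
    n1, n2 = int(ind.sum()), int((~ind).sum())
    x = m.values.astype(np.int64)
    tot = x.sum(axis=1)
    obs = _stats_from_counts(x[:, ind].sum(axis=1), tot - x[:, ind].sum(axis=1), n1, n2)[2]

    def tail_counts(membership: np.ndarray) -> np.ndarray:
        """#{arrangements with stat >= observed} given a (n_arr x n) 0/1
        membership matrix of target assignments."""
        ge = np.zeros(m.n_spots, dtype=np.int64)
        xf = x.astype(np.float64)
        for lo in range(0, membership.shape[0], 2048):
            blk = membership[lo : lo + 2048].astype(np.float64)
            k1 = xf @ blk.T  # spots x arrangements
            stat = _stats_from_counts(k1, tot[:, None] - k1, n1, n2)[2]
            ge += (stat >= obs[:, None] - _STAT_TIE_TOL).sum(axis=1)
        return ge

    n_arr = math.comb(n, n1)
    if n_arr <= enumeration_limit:
        membership = np.zeros((n_arr, n), dtype=np.int8)
        for row, combo in enumerate(combinations(range(n), n1)):
            membership[row, list(combo)] = 1
        p = tail_counts(membership) / n_arr
        exact = True
    else:
        # a free label permutation is equivalent to a uniform random
        # target subset of size n1, which is what the statistic sees
        rng = np.random.default_rng([seed, 0])
        keys = rng.random((n_perm, n))
        idx = np.argpartition(keys, n1 - 1, axis=1)[:, :n1]
        membership = np.zeros((n_perm, n), dtype=np.int8)
        np.put_along_axis(membership, idx, 1, axis=1)
        p = (1.0 + tail_counts(membership)) / (1.0 + n_perm)
        exact = False
    return pd.DataFrame({"stat": obs, "p_perm": p, "exact": exact}, index=m.spot_ids)


def benjamini_hochberg(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size and ((p < 0).any() or (p > 1).any() or np.isnan(p).any()):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def marker_table(
    m: SpotMatrix,
    targets: list[TargetCluster],
    alpha: float = 0.05,
    n_perm: int = 9_999,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full marker screen over a list of target clusters.

    For each target: group-equalized IndVal per spot, permutation
    p-values, BH correction across spots (within the target), raw
    specificity A = P(target | spot present), sensitivity B, and flags
    ``is_marker`` (p_adj <= alpha) and ``is_perfect`` (marker with
    A = 1 and B = 1).

    Returns
    -------
    records : DataFrame
        One row per (spot, target).
    summary : DataFrame
        Per-target counts of significant and perfect markers.
    """
    rec_frames = []
    summary_rows = []
    for ti, target in enumerate(targets):
        ind = target.indicator(m.sample_ids)
        iv = indval_group_equalized(m, target)
        pv = permutation_pvalues(m, target, n_perm=n_perm, seed=seed + ti)
        k1 = m.values[:, ind].sum(axis=1)
        ktot = m.values.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            a_raw = np.where(ktot > 0, k1 / ktot, 0.0)
        p_adj = benjamini_hochberg(pv["p_perm"].to_numpy())
        df = pd.DataFrame(
            {
                "spot_id": m.spot_ids,
                "target": target.name,
                "stat": iv["stat"].to_numpy(),
                "A_g": iv["A_g"].to_numpy(),
                "A": a_raw,
                "B": iv["B"].to_numpy(),
                "p_perm": pv["p_perm"].to_numpy(),
                "p_adj": p_adj,
            }
        )
        df["is_marker"] = df["p_adj"] <= alpha
        df["is_perfect"] = df["is_marker"] & (df["A"] == 1.0) & (df["B"] == 1.0)
        rec_frames.append(df)
        summary_rows.append(
            {
                "target": target.name,
                "n_members": int(ind.sum()),
                "n_markers": int(df["is_marker"].sum()),
                "n_perfect_markers": int(df["is_perfect"].sum()),
            }
        )
    records = pd.concat(rec_frames, ignore_index=True)
    return records, pd.DataFrame(summary_rows)
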