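"""Jaccard-family dissimilarities for binary and frequency profiles.

The binary Jaccard dissimilarity between two presence sets is one minus
intersection over union; the quantitative generalisation used here is the
Ruzicka (Soergel) form 1 - sum(min)/sum(max), which reduces exactly to the
binary index on 0/1 input. Pairs with an empty union are scored 0 by
convention (two all-absent profiles are "identical") and logged, since
that situation is biologically degenerate.
"""

from __future__ import annotations

import logging

import numpy as np
from skbio import DistanceMatrix

from spotclust.spot_data import FrequencyMatrix, SpotMatrix

logger = logging.getLogger(__name__)


def _as_distance_matrix(d: np.ndarray, ids) -> DistanceMatrix:
    d = np.asarray(d, dtype=float)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix((d + d.T) / 2.0, list(ids))


def jaccard_binary(m: SpotMatrix) -> DistanceMatrix:
    """Pairwise Jaccard dissimilarity between the columns of a binary matrix.

    d(x, y) = 1 - |x & y| / |x | y| over spots.
    """
    if m.n_samples < 2:
        raise ValueError("need at least two objects to form a distance matrix")
    x = m.values.astype(np.float64)
    inter = x.T @ x
    sizes = x.sum(axis=0)
    union = sizes[:, None] + sizes[None, :] - inter
    empty = union == 0
    if empty.sum() > len(sizes):  # off-diagonal empty unions
        logger.warning(
            "%d object pairs share no spots at all; their Jaccard "
            "dissimilarity is set to 0 by convention",
            int((empty.sum() - len(sizes)) // 2),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - inter / union
    d[empty] = 0.0
    return _as_distance_matrix(d, m.sample_ids)


def jaccard_quantitative(f: FrequencyMatrix) -> DistanceMatrix:
    """Ruzicka dissimilarity between frequency profiles.

    d(x, y) = 1 - sum_s min(x_s, y_s) / sum_s max(x_s, y_s); identical to
    ``jaccard_binary`` whenever the input happens to be 0/1.
    """
    if len(f.group_ids) < 2:
        raise ValueError("need at least two objects to form a distance matrix")
    x = f.values  # spots x groups
    mins = np.minimum(x[:, :, None], x[:, None, :]).sum(axis=0)
    maxs = np.maximum(x[:, :, None], x[:, None, :]).sum(axis=0)
    empty = maxs == 0
    if empty.sum() > x.shape[1]:
        logger.warning(
            "%d object pairs are all-zero; Ruzicka dissimilarity set to 0 "
            "by convention", int((empty.sum() - x.shape[1]) // 2),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - mins / maxs
    d[empty] = 0.0
    return _as_distance_matrix(d, f.group_ids)


def distance_to_tsv(dm: DistanceMatrix, path) -> None:
    """Write a distance matrix as a square TSV with an id header."""
    import pandas as pd

    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).rename_axis("id").to_csv(
        path, sep="\t"
    )


def distance_to_phylip(dm: DistanceMatrix, path) -> None:
    """Write a PHYLIP-style lower-triangle distance file."""
    with open(path, "w") as fh:
        fh.write(f"{len(dm.ids)}\n")
        for i, name in enumerate(dm.ids):
            row = "\t".join(f"{dm.data[i, j]:.10g}" for j in range(i))
            fh.write(f"{name}\t{row}\n" if row else f"{name}\n")
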