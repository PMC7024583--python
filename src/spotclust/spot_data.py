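"""Data model and I/O for binary protein-spot detection tables.

A 2D-gel experiment yields, per sample, a set of detected protein spots.
The analysis unit here is strictly binary: spot present or absent in a
sample. Tables come in two flavours: replicate-level (one column per
technical replicate of a sample) and sample-level. Replicate tables are
consolidated with a reliability rule: a spot counts as detected in a sample
if it shows up in at least two technical replicates of that sample, or in
one replicate there and at least one replicate of some other sample.
Species-level "consensus proteomes" are the per-species union of sample
detections, and occurrence-frequency matrices record the fraction of a
group's samples carrying each spot.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: tokens accepted as "detected" when parsing spot tables
DEFAULT_TRUTHY = frozenset({"1", "+", "present"})
#: tokens accepted as "not detected"
DEFAULT_FALSY = frozenset({"0", "-", "absent", ""})


def _check_unique(ids, what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} id: {x!r}")
        seen.add(x)


@dataclass
class SpotMatrix:
    """Binary spot x sample detection matrix.

    Parameters
    ----------
    spot_ids : list of str
        Opaque spot labels (one per row).
    sample_ids : list of str
        Sample labels (one per column).
    values : ndarray of shape (n_spots, n_samples)
        Entries in {0, 1}; 1 means the spot was detected in the sample.
    """

    spot_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.spot_ids = [str(s) for s in self.spot_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.spot_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.spot_ids)} spots x {len(self.sample_ids)} samples"
            )
        bad = ~np.isin(self.values, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-binary value {self.values[i, j]!r} at "
                f"spot {self.spot_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )
        self.values = self.values.astype(np.int8)
        _check_unique(self.spot_ids, "spot")
        _check_unique(self.sample_ids, "sample")

    @property
    def n_spots(self) -> int:
        return len(self.spot_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.spot_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SpotMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def to_tsv(self, path) -> None:
        self.to_frame().rename_axis("spot_id").to_csv(path, sep="\t")

    def subset_samples(self, sample_ids: list[str]) -> "SpotMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return SpotMatrix(self.spot_ids, list(sample_ids), self.values[:, idx])


@dataclass
class ReplicateTable:
    """Binary spot x technical-replicate matrix.

    Columns are annotated with (sample_id, replicate_index) pairs; every
    sample must contribute at least one replicate column.
    """

    spot_ids: list[str]
    columns: list[tuple[str, int]]  # (sample_id, replicate_index)
    values: np.ndarray

    def __post_init__(self):
        self.spot_ids = [str(s) for s in self.spot_ids]
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.spot_ids), len(self.columns)):
            raise ValueError("matrix shape does not match id lists")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("replicate table must be binary")
        self.values = self.values.astype(np.int8)
        _check_unique(self.spot_ids, "spot")
        _check_unique(self.columns, "replicate column")
        if not self.columns:
            raise ValueError("replicate table has no columns")

    @property
    def sample_ids(self) -> list[str]:
        out = []
        for sid, _ in self.columns:
            if sid not in out:
                out.append(sid)
        return out


@dataclass
class SampleAnnotation:
    """Per-sample factors: species, higher clades, location, sex, body part.

    Stored as a DataFrame indexed by sample_id. ``species`` is required;
    any further columns (genus, subgenus, species_group, location, sex,
    body_part, ...) are available as grouping factors.
    """

    table: pd.DataFrame

    SEX_LEVELS = frozenset({"f", "m"})
    BODY_PART_LEVELS = frozenset({"so", "pe"})

    def __post_init__(self):
        if "sample_id" in self.table.columns:
            self.table = self.table.set_index("sample_id")
        self.table.index = self.table.index.astype(str)
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()][0]
            raise ValueError(f"duplicate annotation row for sample {dup!r}")
        if "species" not in self.table.columns:
            raise ValueError("annotation must include a 'species' column")
        for col, levels in (("sex", self.SEX_LEVELS), ("body_part", self.BODY_PART_LEVELS)):
            if col in self.table.columns:
                bad = set(self.table[col].dropna()) - levels
                if bad:
                    raise ValueError(f"unknown {col} level(s): {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def factors(self) -> list[str]:
        return list(self.table.columns)

    def factor(self, name: str) -> pd.Series:
        if name not in self.table.columns:
            raise KeyError(f"unknown annotation factor {name!r}; have {self.factors}")
        return self.table[name]

    def require_samples(self, sample_ids) -> None:
        missing = [s for s in sample_ids if s not in self.table.index]
        if missing:
            raise ValueError(f"samples without annotation: {missing}")

    def samples_where(self, **conditions) -> list[str]:
        """Sample ids matching all ``factor=value`` (or ``factor=[v1, v2]``) conditions."""
        mask = pd.Series(True, index=self.table.index)
        for fac, val in conditions.items():
            col = self.factor(fac)
            if isinstance(val, (list, tuple, set, frozenset)):
                mask &= col.isin(list(val))
            else:
                mask &= col == val
        return list(self.table.index[mask])

    @classmethod
    def read(cls, path) -> "SampleAnnotation":
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
        return cls(pd.read_csv(path, sep=sep, dtype=str))

    def to_tsv(self, path) -> None:
        self.table.rename_axis("sample_id").to_csv(path, sep="\t")


@dataclass
class FrequencyMatrix:
    """Spot x group matrix of occurrence frequencies in [0, 1].

    Entry (spot, group) is the fraction of the group's samples in which the
    spot was detected.
    """

    spot_ids: list[str]
    group_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.spot_ids), len(self.group_ids)):
            raise ValueError("matrix shape does not match id lists")
        if (self.values < 0).any() or (self.values > 1).any():
            raise ValueError("frequencies must lie in [0, 1]")
        _check_unique(self.spot_ids, "spot")
        _check_unique(self.group_ids, "group")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.spot_ids, columns=self.group_ids)

    def to_tsv(self, path) -> None:
        self.to_frame().rename_axis("spot_id").to_csv(path, sep="\t")

    def threshold(self) -> SpotMatrix:
        """Binary presence matrix: 1 wherever the frequency is positive."""
        return SpotMatrix(self.spot_ids, self.group_ids, (self.values > 0).astype(np.int8))


_REP_SUFFIX = re.compile(r"^(?P<sample>.+?)[._](?:r|rep)?(?P<rep>\d+)$")


def _parse_cell(tok: str, truthy, falsy, spot: str, col: str):
    tok = tok.strip()
    if tok in truthy:
        return 1
    if tok in falsy:
        return 0
    raise ValueError(
        f"cell {tok!r} at spot {spot!r}, column {col!r} is not a recognised "
        f"presence/absence token (truthy: {sorted(truthy)})"
    )


def read_spot_table(
    path,
    annotation_path,
    truthy=DEFAULT_TRUTHY,
    falsy=DEFAULT_FALSY,
):
    """Read a spot detection table plus its sample annotations.

    The table is CSV or TSV (by extension), first column = spot id, header
    = sample or replicate labels. A header cell that matches an annotated
    sample id verbatim is a sample-level column; otherwise it must look
    like ``<sample>_<k>``, ``<sample>.<k>``, ``<sample>_r<k>`` or
    ``<sample>_rep<k>`` for an annotated sample — then the whole table is
    treated as replicate-level. Mixed tables are rejected.

    Returns
    -------
    (SpotMatrix or ReplicateTable, SampleAnnotation)
    """
    ann = SampleAnnotation.read(annotation_path)
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str).fillna("")
    known = set(ann.sample_ids)

    parsed_cols: list[tuple[str, int] | None] = []
    any_rep = False
    for col in df.columns:
        if col in known:
            parsed_cols.append(None)
            continue
        m = _REP_SUFFIX.match(col)
        if m and m.group("sample") in known:
            parsed_cols.append((m.group("sample"), int(m.group("rep"))))
            any_rep = True
        else:
            raise ValueError(
                f"column {col!r} matches no annotated sample "
                f"(annotated: {sorted(known)})"
            )

    spot_ids = [str(s) for s in df.index]
    vals = np.empty(df.shape, dtype=np.int8)
    for j, col in enumerate(df.columns):
        for i, spot in enumerate(spot_ids):
            vals[i, j] = _parse_cell(df.iat[i, j], truthy, falsy, spot, col)

    if any_rep:
        cols = []
        for col, parsed in zip(df.columns, parsed_cols):
            # sample-level columns inside a replicate table become replicate 1
            cols.append(parsed if parsed is not None else (col, 1))
        return ReplicateTable(spot_ids, cols, vals), ann
    return SpotMatrix(spot_ids, list(df.columns), vals), ann


def consolidate_replicates(reps: ReplicateTable) -> SpotMatrix:
    """Collapse technical replicates into sample-level detections.

    A spot is detected in sample ``s`` iff it appears in >= 2 replicates of
    ``s``, or in >= 1 replicate of ``s`` and >= 1 replicate of some other
    sample. Spots failing the rule in every sample are dropped (and the
    drop count logged) so downstream spot totals stay auditable.
    """
    if reps.values.size == 0:
        raise ValueError("empty replicate table")
    samples = reps.sample_ids
    counts = np.zeros((len(reps.spot_ids), len(samples)), dtype=np.int32)
    col_of = {s: k for k, s in enumerate(samples)}
    for j, (sid, _) in enumerate(reps.columns):
        counts[:, col_of[sid]] += reps.values[:, j]

    seen_anywhere = counts > 0
    n_samples_with = seen_anywhere.sum(axis=1, keepdims=True)
    present = (counts >= 2) | (seen_anywhere & (n_samples_with >= 2))

    keep = present.any(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "reliability rule dropped %d of %d spots (detected in a single "
            "replicate of a single sample only)", n_dropped, len(reps.spot_ids),
        )
    spot_ids = [s for s, k in zip(reps.spot_ids, keep) if k]
    return SpotMatrix(spot_ids, samples, present[keep].astype(np.int8))


def _group_columns(m: SpotMatrix, ann: SampleAnnotation, group_by: str):
    ann.require_samples(m.sample_ids)
    fac = ann.factor(group_by)
    groups: dict[str, list[int]] = {}
    for j, sid in enumerate(m.sample_ids):
        groups.setdefault(str(fac[sid]), []).append(j)
    for g, idx in groups.items():
        if not idx:
            raise ValueError(f"group {g!r} has no samples")
    return groups


def consensus_proteomes(
    m: SpotMatrix, ann: SampleAnnotation, group_by: str = "species"
) -> SpotMatrix:
    """Per-group union proteomes: spot present in a group iff present in any
    of its samples."""
    groups = _group_columns(m, ann, group_by)
    ids = list(groups)
    vals = np.column_stack([m.values[:, groups[g]].any(axis=1) for g in ids])
    return SpotMatrix(m.spot_ids, ids, vals.astype(np.int8))


def occurrence_frequency(
    m: SpotMatrix, ann: SampleAnnotation, group_by: str = "species"
) -> FrequencyMatrix:
    """Per-group spot occurrence frequencies: detected-sample count / group size."""
    groups = _group_columns(m, ann, group_by)
    ids = list(groups)
    vals = np.column_stack(
        [m.values[:, groups[g]].mean(axis=1) for g in ids]
    )
    return FrequencyMatrix(m.spot_ids, ids, vals)
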