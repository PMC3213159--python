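"""Barcode read and array-intensity quantification.

Turns raw reads (mismatch-tolerant demultiplexing and tag mapping) or array
feature tables (outlier-robust averaging, quantile normalization, saturation
correction) into per-sample relative strain abundances.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._seq import encode, encode_many, min_pairwise_distance, pack_tags
from .errors import MalformedReadError
from .saturation import desaturate, saturate  # noqa: F401  (re-exported)
from .synthetic_pool import (
    INDEX_LEN,
    READ_LEN,
    TAG_LEN,
    TAG_SLICE,
    StrainSpec,
)

# sentinels returned by the scalar mapping helpers
UNASSIGNED = "UNASSIGNED"
UNMAPPED = "UNMAPPED"
AMBIGUOUS = "AMBIGUOUS"

_MAX_INDEX_MM = 1
_MAX_TAG_MM = 2


# -- demultiplexing --------------------------------------------------------

def demultiplex(read: str, indexes: Mapping[str, str],
                offset: int = 0) -> str:
    """Assign a read to a sample by its multiplex index, tolerating one mismatch.

    Returns the sample of the unique index at minimal qualifying distance
    (<= 1), or :data:`UNASSIGNED` when no index qualifies or two or more tie
    at the minimum.
    """
    if len(read) < offset + INDEX_LEN:
        raise MalformedReadError("read shorter than index layout")
    obs = encode(read[offset:offset + INDEX_LEN])
    best: list[str] = []
    best_d = _MAX_INDEX_MM + 1
    for idx, sample in indexes.items():
        d = int((obs != encode(idx)).sum())
        if d < best_d:
            best, best_d = [sample], d
        elif d == best_d:
            best.append(sample)
    if best_d > _MAX_INDEX_MM or len(best) != 1:
        return UNASSIGNED
    return best[0]


def map_tag(observed_tag: str, catalog: Iterable[StrainSpec],
            tag_class: str = "up") -> str:
    """Map a 20-bp tag to a strain, tolerating two mismatches.

    Returns the strain of the unique catalog tag within Hamming distance 2;
    :data:`AMBIGUOUS` when two or more catalog tags are within 2 (reads that
    do not map uniquely are discarded); :data:`UNMAPPED` when none is.
    """
    if len(observed_tag) != TAG_LEN:
        raise MalformedReadError(f"tag must be {TAG_LEN} bp")
    obs = encode(observed_tag)
    hits: list[str] = []
    for strain in catalog:
        tag = strain.up_tag if tag_class == "up" else strain.down_tag
        if int((obs != encode(tag)).sum()) <= _MAX_TAG_MM:
            hits.append(strain.strain_id)
            if len(hits) > 1:
                return AMBIGUOUS
    if not hits:
        return UNMAPPED
    return hits[0]


# -- vectorized internals --------------------------------------------------

def _demux_matrix(obs: np.ndarray, index_mat: np.ndarray) -> np.ndarray:
    """Per-read index assignment: row index into index_mat, or -1."""
    n = obs.shape[0]
    out = np.full(n, -1, dtype=np.int64)
    chunk = max(1, 4_000_000 // max(1, index_mat.shape[0] * INDEX_LEN))
    for lo in range(0, n, chunk):
        sub = obs[lo:lo + chunk]
        d = (sub[:, None, :] != index_mat[None, :, :]).sum(axis=2)
        dmin = d.min(axis=1)
        ties = (d == dmin[:, None]).sum(axis=1)
        ok = (dmin <= _MAX_INDEX_MM) & (ties == 1)
        res = np.where(ok, d.argmin(axis=1), -1)
        out[lo:lo + sub.shape[0]] = res
    return out


def _map_tags_matrix(obs: np.ndarray, tag_mat: np.ndarray,
                     catalog_is_separated: bool) -> np.ndarray:
    """Per-read tag assignment: row index into tag_mat, -1 unmapped, -2 ambiguous.

    When catalog tags are pairwise separated by > 2*max_mismatch, an exact
    match is provably unique, so exact hits take a hash fast path and only
    the mismatched remainder goes through the full Hamming scan.
    """
    n = obs.shape[0]
    out = np.full(n, -1, dtype=np.int64)
    todo = np.arange(n)

    if catalog_is_separated and n:
        keys = pack_tags(tag_mat)
        order = np.argsort(keys)
        obs_keys = pack_tags(obs)
        pos = np.searchsorted(keys[order], obs_keys)
        pos = np.clip(pos, 0, len(keys) - 1)
        exact = keys[order][pos] == obs_keys
        out[exact] = order[pos[exact]]
        todo = np.flatnonzero(~exact)

    if todo.size:
        chunk = max(1, 20_000_000 // max(1, tag_mat.shape[0] * TAG_LEN))
        for lo in range(0, todo.size, chunk):
            sel = todo[lo:lo + chunk]
            d = (obs[sel][:, None, :] != tag_mat[None, :, :]).sum(axis=2)
            within = d <= _MAX_TAG_MM
            n_within = within.sum(axis=1)
            res = np.where(
                n_within == 0, -1,
                np.where(n_within > 1, -2, d.argmin(axis=1)),
            )
            out[sel] = res
    return out


# -- counting --------------------------------------------------------------

@dataclass
class TagCounts:
    """Per-sample tag counts with full read accounting.

    ``n_assigned + n_discarded_index + n_discarded_unmapped +
    n_discarded_ambiguous`` equals the number of reads processed; malformed
    (short) reads are counted under ``n_discarded_unmapped``.
    """

    sample: str
    counts: dict[tuple[str, str], int] = field(default_factory=dict)
    n_assigned: int = 0
    n_discarded_ambiguous: int = 0
    n_discarded_unmapped: int = 0
    n_discarded_index: int = 0

    @property
    def n_total(self) -> int:
        return (self.n_assigned + self.n_discarded_ambiguous
                + self.n_discarded_unmapped + self.n_discarded_index)

    def validate(self) -> None:
        if sum(self.counts.values()) != self.n_assigned:
            raise ValueError("counts do not sum to n_assigned")

    def class_counts(self, tag_class: str) -> pd.Series:
        data = {sid: c for (sid, cls), c in self.counts.items()
                if cls == tag_class}
        return pd.Series(data, dtype=float)


def count_tags(
    reads,
    catalog: list[StrainSpec],
    indexes: Mapping[str, str],
    sample: str,
    tag_class: str = "up",
) -> TagCounts:
    """Count tags for one sample's read set.

    ``reads`` is a list of read strings or the uint8 matrix from the
    simulator. Reads whose index does not uniquely resolve to ``sample``
    are discarded under the index counter; tags then map with up to two
    mismatches (non-unique maps discarded as ambiguous). Never raises on a
    bad read — everything is counted.
    """
    tc = TagCounts(sample=sample)

    if isinstance(reads, np.ndarray):
        mat = reads
    else:
        reads = list(reads)
        good = [r for r in reads if len(r) >= READ_LEN]
        tc.n_discarded_unmapped += len(reads) - len(good)
        mat = (encode_many([r[:READ_LEN] for r in good])
               if good else np.empty((0, READ_LEN), dtype=np.uint8))
    if mat.size == 0:
        return tc

    index_list = list(indexes.items())
    index_mat = encode_many([idx for idx, _ in index_list])
    demux = _demux_matrix(mat[:, :INDEX_LEN], index_mat)
    sample_of = np.array([s for _, s in index_list])
    mine = (demux >= 0) & (sample_of[np.clip(demux, 0, None)] == sample)
    tc.n_discarded_index += int((~mine).sum())

    tag_mat = encode_many(
        [s.up_tag if tag_class == "up" else s.down_tag for s in catalog]
    )
    separated = (
        len(catalog) < 2
        or min_pairwise_distance(tag_mat) > 2 * _MAX_TAG_MM
    )
    mapped = _map_tags_matrix(mat[mine][:, TAG_SLICE], tag_mat, separated)

    tc.n_discarded_unmapped += int((mapped == -1).sum())
    tc.n_discarded_ambiguous += int((mapped == -2).sum())
    hits = mapped[mapped >= 0]
    tc.n_assigned += int(hits.size)
    if hits.size:
        binc = np.bincount(hits, minlength=len(catalog))
        for i in np.flatnonzero(binc):
            tc.counts[(catalog[i].strain_id, tag_class)] = int(binc[i])
    tc.validate()
    return tc


def count_fastq(path, catalog, indexes, sample, tag_class="up") -> TagCounts:
    """Count tags from a FASTQ file (see :func:`count_tags`)."""
    from Bio import SeqIO

    reads = [str(rec.seq) for rec in SeqIO.parse(str(path), "fastq")]
    return count_tags(reads, catalog, indexes, sample, tag_class)


# -- array feature summarization ------------------------------------------

def summarize_features(
    features: pd.DataFrame,
    min_features: int = 3,
    mad_factor: float = 5.0,
) -> pd.DataFrame:
    """Average replicate features per tag, excluding clear outliers.

    A feature is an outlier when ``|x - median| > mad_factor * MAD`` among
    its tag's replicates (raw median absolute deviation). Tags with fewer
    than ``min_features`` surviving features are flagged low quality; a tag
    whose features are all excluded is reported missing (NaN), never raised.

    Returns a frame indexed by (tag_id, tag_class) with columns
    mean_intensity, n_used, low_quality.
    """
    if features.empty:
        return pd.DataFrame(
            columns=["mean_intensity", "n_used", "low_quality"]
        ).rename_axis(["tag_id", "tag_class"])

    def _one(vals: np.ndarray) -> tuple[float, int]:
        med = np.median(vals)
        mad = np.median(np.abs(vals - med))
        keep = np.abs(vals - med) <= mad_factor * mad
        if not keep.any():
            return np.nan, 0
        return float(vals[keep].mean()), int(keep.sum())

    rows = {}
    for key, sub in features.groupby(["tag_id", "tag_class"], sort=True):
        mean, n_used = _one(sub["intensity"].to_numpy(dtype=float))
        rows[key] = (mean, n_used, n_used < min_features)
    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=["mean_intensity", "n_used", "low_quality"]
    )
    out.index = pd.MultiIndex.from_tuples(out.index, names=["tag_id", "tag_class"])
    return out


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force identical value distributions across columns (arrays).

    Each column's sorted values are replaced by the row-wise mean of all
    sorted columns; within-column rank order is preserved, ties resolved by
    average rank. Missing cells are imputed at the column median for the
    normalization and restored to missing afterward. A single column is
    returned unchanged.
    """
    if matrix.shape[1] <= 1:
        return matrix.copy()
    mask = matrix.isna()
    work = matrix.copy()
    for col in work.columns:
        med = work[col].median()
        work[col] = work[col].fillna(med)
    if work.isna().any().any():
        raise ValueError("a column is entirely missing; cannot normalize")
    values = work.to_numpy(dtype=float)
    n = values.shape[0]
    mean_sorted = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(values.shape[1]):
        ranks = rankdata(values[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, mean_sorted)
    result = pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return result.mask(mask)


# -- abundance -------------------------------------------------------------

@dataclass
class NormalizedAbundance:
    """Per-sample relative strain abundances, per tag class and combined."""

    sample: str
    per_class: dict[str, pd.Series]
    combined: pd.Series


def to_abundance(
    data: TagCounts | Mapping[str, pd.Series],
    catalog: list[StrainSpec] | None = None,
    sample: str | None = None,
) -> NormalizedAbundance:
    """Convert tag counts or normalized intensities to relative abundances.

    Per tag class, abundance is value / column total; the combined strain
    abundance is the mean of the up and down class abundances where both are
    usable, else whichever is. Raises when every provided class column sums
    to zero.
    """
    if isinstance(data, TagCounts):
        universe = ([s.strain_id for s in catalog] if catalog is not None
                    else sorted({sid for sid, _ in data.counts}))
        per_class_raw = {}
        for cls in ("up", "down"):
            col = data.class_counts(cls).reindex(universe).fillna(0.0)
            per_class_raw[cls] = col
        sample = sample or data.sample
    else:
        per_class_raw = {cls: pd.Series(col, dtype=float)
                         for cls, col in data.items()}
        sample = sample or ""

    per_class = {}
    for cls, col in per_class_raw.items():
        total = col.sum(skipna=True)
        if total > 0:
            per_class[cls] = col / total
    if not per_class:
        raise ValueError("zero column total in every tag class")

    combined = pd.concat(per_class.values(), axis=1).mean(axis=1, skipna=True)
    return NormalizedAbundance(sample=sample, per_class=per_class,
                               combined=combined)


def write_counts(counts: Iterable[TagCounts], path) -> None:
    """TSV count table: sample, strain, up_count, down_count."""
    rows = []
    for tc in counts:
        strains = sorted({sid for sid, _ in tc.counts})
        for sid in strains:
            rows.append(
                (tc.sample, sid,
                 tc.counts.get((sid, "up"), 0), tc.counts.get((sid, "down"), 0))
            )
    pd.DataFrame(
        rows, columns=["sample", "strain_id", "up_count", "down_count"]
    ).to_csv(path, sep="\t", index=False)


def write_run_log(counts: Iterable[TagCounts], path) -> None:
    rows = [
        (tc.sample, tc.n_total, tc.n_assigned, tc.n_discarded_index,
         tc.n_discarded_unmapped, tc.n_discarded_ambiguous)
        for tc in counts
    ]
    pd.DataFrame(
        rows,
        columns=["sample", "n_total", "n_assigned", "n_discarded_index",
                 "n_discarded_unmapped", "n_discarded_ambiguous"],
    ).to_csv(path, sep="\t", index=False)


__all__ = [
    "UNASSIGNED",
    "UNMAPPED",
    "AMBIGUOUS",
    "demultiplex",
    "map_tag",
    "count_tags",
    "count_fastq",
    "TagCounts",
    "summarize_features",
    "quantile_normalize",
    "saturate",
    "desaturate",
    "NormalizedAbundance",
    "to_abundance",
    "write_counts",
    "write_run_log",
]
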