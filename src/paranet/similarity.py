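"""Reading similarity hit tables and building top-scoring-sequence datasets.

A TSS=k dataset keeps, for every query, its k best non-self subjects below
the homology e-value cutoff (default 1e-5), ranked by descending bit score
(ties broken by ascending e-value, then lexicographic subject id, so the
ranking is deterministic even when scores saturate).  For k2 > k1 the k1
list is a prefix of the k2 list, which makes the per-k network family
nested.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

import pandas as pd

from .simulate import HIT_COLUMNS

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 1e-5


class HitTableParseError(ValueError):
    """Raised for malformed rows in a tabular hit file."""


@dataclass(frozen=True)
class SimilarityHit:
    query_id: str
    subject_id: str
    evalue: float
    bitscore: float


@dataclass(frozen=True)
class TSSDataset:
    """Ranked top-k subject lists per query at the homology cutoff."""

    k: int
    cutoff: float
    lists: Mapping[str, tuple[str, ...]]
    subjects_only: frozenset[str] = field(default_factory=frozenset)
    scores: Mapping[tuple[str, str], tuple[float, float]] = field(
        default_factory=dict
    )  # (query, subject) -> (bitscore, evalue)

    def vertices(self) -> frozenset[str]:
        verts = set(self.lists)
        for subs in self.lists.values():
            verts.update(subs)
        verts.update(self.subjects_only)
        return frozenset(verts)


def _rows_to_frame(hits) -> pd.DataFrame:
    if isinstance(hits, pd.DataFrame):
        return hits
    return pd.DataFrame(
        [(h.query_id, h.subject_id, h.evalue, h.bitscore) for h in hits],
        columns=["qseqid", "sseqid", "evalue", "bitscore"],
    )


def read_hit_table(source: str | Path | TextIO) -> pd.DataFrame:
    """Read a 12-column tabular (BLAST outfmt 6) hit file.

    Comment lines starting with ``#`` are skipped.  Multiple HSPs for one
    (query, subject) pair are collapsed to the row with the lowest e-value
    (tie: highest bit score).  Self rows are retained here; they are removed
    when TSS datasets are built.
    """
    close = False
    if isinstance(source, (str, Path)):
        handle = open(source)
        close = True
    else:
        handle = source
    rows = []
    try:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split("\t")
            if len(parts) == 1:
                parts = stripped.split()
            if len(parts) < 12:
                raise HitTableParseError(
                    f"line {lineno}: expected 12 tab-separated columns, got {len(parts)}"
                )
            try:
                evalue = float(parts[10])
                bitscore = float(parts[11])
            except ValueError as exc:
                raise HitTableParseError(
                    f"line {lineno}: non-numeric evalue/bitscore: {exc}"
                ) from None
            if evalue < 0:
                raise HitTableParseError(f"line {lineno}: negative e-value")
            rows.append((parts[0], parts[1], evalue, bitscore))
    finally:
        if close:
            handle.close()
    if not rows:
        warnings.warn("hit table is empty", stacklevel=2)
        logger.warning("hit table contained no rows")
    frame = pd.DataFrame(rows, columns=["qseqid", "sseqid", "evalue", "bitscore"])
    return collapse_best_hsp(frame)


def collapse_best_hsp(hits: pd.DataFrame) -> pd.DataFrame:
    """Keep one row per (query, subject): lowest e-value, then highest score."""
    if hits.empty:
        return hits.reset_index(drop=True)
    ordered = hits.sort_values(
        ["qseqid", "sseqid", "evalue", "bitscore"],
        ascending=[True, True, True, False],
        kind="mergesort",
    )
    return ordered.drop_duplicates(["qseqid", "sseqid"], keep="first").reset_index(
        drop=True
    )


def rank_hits(hits: pd.DataFrame, cutoff: float = DEFAULT_CUTOFF) -> pd.DataFrame:
    """Qualifying non-self hits of each query in rank order."""
    frame = collapse_best_hsp(_rows_to_frame(hits))
    if frame.empty:
        return frame
    frame = frame[(frame["evalue"] < cutoff) & (frame["qseqid"] != frame["sseqid"])]
    return frame.sort_values(
        ["qseqid", "bitscore", "evalue", "sseqid"],
        ascending=[True, False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)


def build_tss_dataset(
    hits, k: int, cutoff: float = DEFAULT_CUTOFF
) -> TSSDataset:
    """Build the TSS=k dataset from a hit table.

    Queries with no qualifying hit are absent from the per-query lists (the
    "solitary" proteins); subjects that never appear as queries are tracked
    so the network vertex set is identical across k.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    frame = _rows_to_frame(hits)
    ranked = rank_hits(frame, cutoff)
    lists: dict[str, tuple[str, ...]] = {}
    if not ranked.empty:
        for query, group in ranked.groupby("qseqid", sort=True):
            lists[query] = tuple(group["sseqid"].head(k))
    # every id with >= 1 qualifying hit is a vertex at every k, whether or
    # not it makes a top-k list -- keeps the vertex set constant across k
    subjects_only = frozenset(set(ranked["sseqid"]) - set(lists)) if not ranked.empty else frozenset()
    scores = {}
    if not ranked.empty:
        listed = {(q, s) for q, subs in lists.items() for s in subs}
        for row in ranked.itertuples(index=False):
            if (row.qseqid, row.sseqid) in listed:
                scores[(row.qseqid, row.sseqid)] = (
                    float(row.bitscore),
                    float(row.evalue),
                )
    return TSSDataset(
        k=k, cutoff=cutoff, lists=lists, subjects_only=subjects_only, scores=scores
    )


def tss_to_frame(tss: TSSDataset) -> pd.DataFrame:
    """Export a TSS dataset as a ranked (query, rank, subject, score) table."""
    rows = []
    for query, subjects in sorted(tss.lists.items()):
        for rank, subject in enumerate(subjects, start=1):
            bitscore, evalue = tss.scores.get((query, subject), (float("nan"),) * 2)
            rows.append((query, rank, subject, bitscore, evalue))
    return pd.DataFrame(
        rows, columns=["query_id", "rank", "subject_id", "bitscore", "evalue"]
    )


def hits_from_records(records: Iterable[SimilarityHit]) -> pd.DataFrame:
    return _rows_to_frame(list(records))


def write_hit_table(hits: pd.DataFrame, path: str | Path) -> None:
    frame = hits.copy()
    for col in HIT_COLUMNS:
        if col not in frame.columns:
            frame[col] = 0
    frame[HIT_COLUMNS].to_csv(path, sep="\t", header=False, index=False)
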