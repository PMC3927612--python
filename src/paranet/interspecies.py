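"""Clustering query proteins by shared best hit in a target proteome.

Two query-proteome genes that duplicated after the target species diverged
share a single ortholog there, so both give their best match to the same
target entry; grouping queries by best subject therefore recovers paralog
clusters, and the target species ordered by divergence time localize each
duplication between two splits.  Incomplete target proteomes mimic gene
loss and reassign queries to paralog or epaktolog anchors instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .similarity import DEFAULT_CUTOFF, collapse_best_hsp, _rows_to_frame

CLUSTERED = "clustered"
ONE_TO_ONE = "one_to_one"
ABSENT = "absent"
UNRESOLVED = "UNRESOLVED"


@dataclass(frozen=True)
class BestHitMap:
    """Best qualifying subject per query against one target proteome."""

    target_species_id: str
    best: Mapping[str, str]


@dataclass(frozen=True)
class InterspeciesCluster:
    target_species_id: str
    anchor_subject_id: str
    members: tuple[str, ...]


def best_hits(
    hits,
    cutoff: float = DEFAULT_CUTOFF,
    target_species_id: str = "",
) -> BestHitMap:
    """Best match per query at e < cutoff.

    Best = highest bit score; ties broken by lowest e-value, then
    lexicographically smallest subject id.  Queries with no qualifying hit
    are absent from the map.
    """
    frame = collapse_best_hsp(_rows_to_frame(hits))
    best: dict[str, str] = {}
    if not frame.empty:
        qualifying = frame[frame["evalue"] < cutoff]
        ranked = qualifying.sort_values(
            ["qseqid", "bitscore", "evalue", "sseqid"],
            ascending=[True, False, True, True],
            kind="mergesort",
        )
        top = ranked.drop_duplicates("qseqid", keep="first")
        best = dict(zip(top["qseqid"], top["sseqid"]))
    return BestHitMap(target_species_id=target_species_id, best=best)


def cluster_by_best_hit(
    bh: BestHitMap,
) -> tuple[list[InterspeciesCluster], list[tuple[str, str]]]:
    """Group queries whose best match is the same target entry.

    Returns (clusters with >= 2 members, one-to-one matches).  The clusters
    equal the weak components of the bipartite query/best-subject graph
    restricted to query vertices; 1:1 matches are putative orthologs.
    """
    groups: dict[str, list[str]] = {}
    for query, subject in bh.best.items():
        groups.setdefault(subject, []).append(query)
    clusters = []
    singles = []
    for subject in sorted(groups):
        members = tuple(sorted(groups[subject]))
        if len(members) >= 2:
            clusters.append(
                InterspeciesCluster(
                    target_species_id=bh.target_species_id,
                    anchor_subject_id=subject,
                    members=members,
                )
            )
        else:
            singles.append((members[0], subject))
    return clusters, sorted(singles)


def cluster_profile_across_species(
    hit_tables: Mapping[str, pd.DataFrame],
    divergence_order: Sequence[str],
    cutoff: float = DEFAULT_CUTOFF,
) -> pd.DataFrame:
    """Cluster counts per target species, ordered by divergence time.

    ``divergence_order`` lists target species ids from the most distant
    split to the most recent; a species with an empty hit table reports
    zeros.
    """
    if not divergence_order:
        raise ValueError("need at least one target species")
    rows = []
    for species in divergence_order:
        table = hit_tables.get(species)
        if table is None or len(table) == 0:
            rows.append(
                {"species": species, "n_clusters_ge2": 0, "n_clustered_queries": 0}
            )
            continue
        clusters, _ = cluster_by_best_hit(
            best_hits(table, cutoff, target_species_id=species)
        )
        rows.append(
            {
                "species": species,
                "n_clusters_ge2": len(clusters),
                "n_clustered_queries": sum(len(c.members) for c in clusters),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class DuplicationInterval:
    """Divergence interval bracketing a gene duplication.

    ``older_bound_my`` is exclusive and ``younger_bound_my`` inclusive;
    ``open_older`` marks intervals where every sampled species clustered the
    query (the duplication may predate the oldest split).  ``status`` is
    ``UNRESOLVED`` for non-monotone clustering patterns, which arise from
    incomplete target proteomes.
    """

    older_bound_my: float | None
    younger_bound_my: float
    open_older: bool
    status: str = "OK"


def duplication_timing(
    pattern: Mapping[str, str],
    divergence_order: Sequence[tuple[str, float]],
) -> DuplicationInterval:
    """Infer when a clustered query's duplication happened.

    ``pattern`` maps target species id to ``clustered`` / ``one_to_one`` /
    ``absent``; ``divergence_order`` gives (species, divergence time in My)
    from oldest to youngest split.  Walking toward the present, the
    duplication falls between the youngest split still clustering the query
    and the oldest split with a 1:1 match.  A pattern that returns to
    ``clustered`` after a 1:1 match is flagged UNRESOLVED.
    """
    observed = [
        (species, t, pattern[species])
        for species, t in divergence_order
        if pattern.get(species, ABSENT) != ABSENT
    ]
    if not observed:
        raise ValueError("query was not observed in any sampled species")
    last_clustered: float | None = None
    first_one_to_one: float | None = None
    for _, t, status in observed:
        if status == CLUSTERED:
            if first_one_to_one is not None:
                return DuplicationInterval(
                    older_bound_my=None,
                    younger_bound_my=float("nan"),
                    open_older=False,
                    status=UNRESOLVED,
                )
            last_clustered = t
        elif status == ONE_TO_ONE and first_one_to_one is None:
            first_one_to_one = t
    if first_one_to_one is None:
        # clustered down to the youngest split: the duplication is more
        # recent than every sampled divergence
        return DuplicationInterval(
            older_bound_my=last_clustered,
            younger_bound_my=0.0,
            open_older=False,
        )
    # 1:1 everywhere: the duplication predates the oldest sampled split,
    # so the interval is open toward the past
    return DuplicationInterval(
        older_bound_my=last_clustered,
        younger_bound_my=first_one_to_one,
        open_older=last_clustered is None,
    )


def clusters_to_frame(clusters: Sequence[InterspeciesCluster]) -> pd.DataFrame:
    rows = [
        {
            "species": c.target_species_id,
            "anchor_subject": c.anchor_subject_id,
            "member": m,
            "n_members": len(c.members),
        }
        for c in clusters
        for m in c.members
    ]
    return pd.DataFrame(
        rows, columns=["species", "anchor_subject", "member", "n_members"]
    )
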