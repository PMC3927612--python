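"""Domain architectures, their alignment and the classification of DA
differences between homologous proteins.

A domain architecture (DA) is the ordered list of domain-family tokens kept
at a given e-value cutoff after overlap elimination.  Homolog pairs are
compared at four cutoffs (1e-2 .. 1e-5); at each cutoff the two token lists
are aligned by longest common subsequence and every unmatched domain is
classified by its position relative to the shared domains: N-terminal,
C-terminal or internal, with an extra tandem copy of a shared family
counted as a duplication difference instead.  Aggregates over many pairs --
cluster DA homogeneity, the positional distribution of differences, the
domain-count-difference spectrum and the percent-DA-change-per-My rate
bound -- are the quantities the downstream analyses report.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

N_TERMINAL = "N_TERMINAL"
C_TERMINAL = "C_TERMINAL"
INTERNAL = "INTERNAL"
DUPLICATION = "DUPLICATION"
UNASSIGNED = "UNASSIGNED"
IDENTICAL = "IDENTICAL"

CATEGORIES = (N_TERMINAL, C_TERMINAL, INTERNAL, DUPLICATION, UNASSIGNED, IDENTICAL)

TYPE1 = "TYPE1"
TYPE2 = "TYPE2"
TYPE3 = "TYPE3"
TYPE_NA = "NA"

DEFAULT_CUTOFFS = (1e-2, 1e-3, 1e-4, 1e-5)
PRIMARY_CUTOFF = 1e-5

OVERLAP_TOLERANCE = 0.30  # max allowed overlap, fraction of the shorter hit


@dataclass(frozen=True)
class DomainArchitecture:
    protein_id: str
    cutoff: float
    domains: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.domains)


@dataclass(frozen=True)
class DAAlignment:
    """LCS alignment of two DAs over family tokens.

    ``matches`` are (index in A, index in B) pairs, strictly increasing on
    both sides; the unmatched index tuples cover the rest.
    """

    matches: tuple[tuple[int, int], ...]
    unmatched_a: tuple[int, ...]
    unmatched_b: tuple[int, ...]


@dataclass(frozen=True)
class DADifferenceRecord:
    protein_id_a: str
    protein_id_b: str
    categories: Mapping[float, frozenset[str]]
    n_domain_diff: int
    transition_type: str


def build_architecture(
    annotations: pd.DataFrame | Iterable[Mapping],
    cutoff: float = PRIMARY_CUTOFF,
    protein_id: str | None = None,
) -> DomainArchitecture:
    """DA of one protein: threshold, eliminate overlaps, order by start.

    Hits are accepted greedily in order of ascending e-value (ties: longer
    hit, then smaller start); a hit is rejected when it overlaps an already
    accepted hit by more than 30% of the shorter hit's length.
    """
    frame = (
        annotations
        if isinstance(annotations, pd.DataFrame)
        else pd.DataFrame(list(annotations))
    )
    if frame.empty:
        return DomainArchitecture(protein_id or "", cutoff, ())
    ids = frame["protein_id"].unique() if "protein_id" in frame else []
    if protein_id is None:
        if len(ids) > 1:
            raise ValueError("annotations must belong to a single protein")
        protein_id = str(ids[0]) if len(ids) else ""
    elif len(ids):
        frame = frame[frame["protein_id"] == protein_id]
    if (frame["start"] > frame["end"]).any():
        raise ValueError(f"protein {protein_id!r}: annotation with start > end")
    frame = frame[frame["evalue"] < cutoff]
    if frame.empty:
        return DomainArchitecture(protein_id, cutoff, ())
    frame = frame.assign(_len=frame["end"] - frame["start"] + 1)
    frame = frame.sort_values(
        ["evalue", "_len", "start"], ascending=[True, False, True], kind="mergesort"
    )
    accepted: list[tuple[int, int, str]] = []
    for row in frame.itertuples(index=False):
        ok = True
        for a_start, a_end, _ in accepted:
            overlap = min(row.end, a_end) - max(row.start, a_start) + 1
            if overlap <= 0:
                continue
            shorter = min(row.end - row.start + 1, a_end - a_start + 1)
            if overlap > OVERLAP_TOLERANCE * shorter:
                ok = False
                break
        if ok:
            accepted.append((int(row.start), int(row.end), str(row.family_id)))
    accepted.sort()
    return DomainArchitecture(
        protein_id, cutoff, tuple(fam for _, _, fam in accepted)
    )


def align_architectures(
    da_a: DomainArchitecture | Sequence[str],
    da_b: DomainArchitecture | Sequence[str],
) -> DAAlignment:
    """Longest common subsequence of the two family-token lists.

    Among equal-length LCSs the leftmost one (greedily smallest indices in
    A, then in B) is chosen for determinism.
    """
    a = tuple(da_a.domains if isinstance(da_a, DomainArchitecture) else da_a)
    b = tuple(da_b.domains if isinstance(da_b, DomainArchitecture) else da_b)
    na, nb = len(a), len(b)
    # suffix LCS lengths
    lcs = [[0] * (nb + 1) for _ in range(na + 1)]
    for i in range(na - 1, -1, -1):
        for j in range(nb - 1, -1, -1):
            if a[i] == b[j]:
                lcs[i][j] = lcs[i + 1][j + 1] + 1
            else:
                lcs[i][j] = max(lcs[i + 1][j], lcs[i][j + 1])
    matches = []
    i = j = 0
    while i < na and j < nb:
        if a[i] == b[j] and lcs[i][j] == lcs[i + 1][j + 1] + 1:
            matches.append((i, j))
            i += 1
            j += 1
        elif lcs[i + 1][j] >= lcs[i][j + 1]:
            i += 1
        else:
            j += 1
    matched_a = {m[0] for m in matches}
    matched_b = {m[1] for m in matches}
    return DAAlignment(
        matches=tuple(matches),
        unmatched_a=tuple(k for k in range(na) if k not in matched_a),
        unmatched_b=tuple(k for k in range(nb) if k not in matched_b),
    )


def _classify_side(
    tokens: Sequence[str],
    matched: Sequence[int],
    unmatched: Sequence[int],
) -> set[str]:
    categories: set[str] = set()
    matched_set = set(matched)
    first, last = min(matched), max(matched)
    for idx in unmatched:
        # tandem-run rule: an extra, contiguous copy of a family that also
        # has a matched copy in the same run is a duplication difference
        lo = idx
        while lo > 0 and tokens[lo - 1] == tokens[idx]:
            lo -= 1
        hi = idx
        while hi < len(tokens) - 1 and tokens[hi + 1] == tokens[idx]:
            hi += 1
        if any(k in matched_set for k in range(lo, hi + 1)):
            categories.add(DUPLICATION)
        elif idx < first:
            categories.add(N_TERMINAL)
        elif idx > last:
            categories.add(C_TERMINAL)
        else:
            categories.add(INTERNAL)
    return categories


def classify_difference(
    alignment: DAAlignment,
    da_a: DomainArchitecture | Sequence[str],
    da_b: DomainArchitecture | Sequence[str],
) -> frozenset[str]:
    """Category set for one pair of DAs at one cutoff.

    IDENTICAL when nothing is unmatched; UNASSIGNED when nothing could be
    matched; otherwise the union over all unmatched domains of their
    positional category, with tandem extra copies of a shared family
    labelled DUPLICATION instead of a positional category.
    """
    a = tuple(da_a.domains if isinstance(da_a, DomainArchitecture) else da_a)
    b = tuple(da_b.domains if isinstance(da_b, DomainArchitecture) else da_b)
    if not alignment.unmatched_a and not alignment.unmatched_b:
        return frozenset({IDENTICAL})
    if not alignment.matches:
        return frozenset({UNASSIGNED})
    categories: set[str] = set()
    categories |= _classify_side(
        a, [m[0] for m in alignment.matches], alignment.unmatched_a
    )
    categories |= _classify_side(
        b, [m[1] for m in alignment.matches], alignment.unmatched_b
    )
    return frozenset(categories)


def transition_type(count_a: int, count_b: int) -> str:
    """Type of a single-domain count transition.

    TYPE1 for 1<->2 domains, TYPE2 for 2<->3, TYPE3 for N<->N+1 with N>2;
    NA when the counts do not differ by exactly one.
    """
    if count_a < 0 or count_b < 0:
        raise ValueError("domain counts must be >= 0")
    if abs(count_a - count_b) != 1:
        return TYPE_NA
    smaller = min(count_a, count_b)
    if smaller == 1:
        return TYPE1
    if smaller == 2:
        return TYPE2
    if smaller >= 3:
        return TYPE3
    return TYPE_NA


def compare_pair(
    da_a: DomainArchitecture | Sequence[str],
    da_b: DomainArchitecture | Sequence[str],
) -> frozenset[str]:
    return classify_difference(align_architectures(da_a, da_b), da_a, da_b)


def classify_pair_multicutoff(
    annotations_a: pd.DataFrame,
    annotations_b: pd.DataFrame,
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
    primary_cutoff: float = PRIMARY_CUTOFF,
    protein_id_a: str | None = None,
    protein_id_b: str | None = None,
) -> DADifferenceRecord:
    """Build, align and classify one homolog pair at every cutoff.

    The domain-count difference and transition type are taken at the primary
    (most stringent) cutoff.
    """
    categories: dict[float, frozenset[str]] = {}
    counts: dict[float, tuple[int, int, str, str]] = {}
    for cutoff in cutoffs:
        da_a = build_architecture(annotations_a, cutoff, protein_id_a)
        da_b = build_architecture(annotations_b, cutoff, protein_id_b)
        categories[cutoff] = compare_pair(da_a, da_b)
        counts[cutoff] = (len(da_a), len(da_b), da_a.protein_id, da_b.protein_id)
    ca, cb, pid_a, pid_b = counts[primary_cutoff]
    return DADifferenceRecord(
        protein_id_a=pid_a or (protein_id_a or ""),
        protein_id_b=pid_b or (protein_id_b or ""),
        categories=categories,
        n_domain_diff=abs(ca - cb),
        transition_type=transition_type(ca, cb) if min(ca, cb) >= 1 else TYPE_NA,
    )


def aggregate_homogeneity(
    clusters: Sequence[Sequence[str]],
    architectures: Mapping[str, DomainArchitecture | Sequence[str]],
) -> tuple[float, float]:
    """DA homogeneity of clusters at the primary cutoff.

    Returns (percent of clusters whose members all share an identical DA,
    percent of within-cluster pairwise comparisons that differ).  Clusters
    with fewer than two members are skipped with a warning.
    """
    n_clusters = 0
    n_homogeneous = 0
    n_pairs = 0
    n_diff = 0
    for cluster in clusters:
        members = list(cluster)
        if len(members) < 2:
            warnings.warn(
                f"skipping cluster of size {len(members)}", stacklevel=2
            )
            continue
        n_clusters += 1
        homogeneous = True
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                n_pairs += 1
                cats = compare_pair(architectures[a], architectures[b])
                if cats != frozenset({IDENTICAL}):
                    n_diff += 1
                    homogeneous = False
        if homogeneous:
            n_homogeneous += 1
    if n_clusters == 0:
        return (float("nan"), float("nan"))
    return (100.0 * n_homogeneous / n_clusters, 100.0 * n_diff / n_pairs)


def positional_distribution(
    records: Sequence[DADifferenceRecord],
    stratify_by_transition: bool = False,
) -> pd.DataFrame:
    """Proportions of the positional categories over all cutoff assignments.

    Each of a record's four per-cutoff assignments contributes each of its
    categories once (so the total can exceed four per pair); proportions are
    taken over non-IDENTICAL assignments.  With ``stratify_by_transition``
    the distribution is computed separately for TYPE1/2/3 records.
    """
    if not records:
        raise ValueError("no difference records supplied")
    groups: dict[str, dict[str, int]] = {}
    for record in records:
        key = record.transition_type if stratify_by_transition else "ALL"
        counter = groups.setdefault(key, {c: 0 for c in CATEGORIES})
        for cats in record.categories.values():
            for cat in cats:
                counter[cat] += 1
    rows = []
    for key, counter in sorted(groups.items()):
        total = sum(v for c, v in counter.items() if c != IDENTICAL)
        for cat in CATEGORIES:
            if cat == IDENTICAL:
                continue
            rows.append(
                {
                    "group": key,
                    "category": cat,
                    "count": counter[cat],
                    "proportion_pct": (100.0 * counter[cat] / total) if total else float("nan"),
                }
            )
    frame = pd.DataFrame(rows)
    if frame["count"].sum() == 0:
        warnings.warn("all assignments were IDENTICAL", stacklevel=2)
    return frame


def domain_count_diff_distribution(
    records: Sequence[DADifferenceRecord],
) -> pd.DataFrame:
    """Frequencies of |domain count difference| binned as 1, 2, 3, >=4."""
    if not records:
        raise ValueError("no difference records supplied")
    bins = {"1": 0, "2": 0, "3": 0, ">=4": 0}
    for record in records:
        d = record.n_domain_diff
        if d <= 0:
            continue
        key = str(d) if d < 4 else ">=4"
        bins[key] += 1
    total = sum(bins.values())
    if total == 0:
        warnings.warn("no pair differs in domain count", stacklevel=2)
    return pd.DataFrame(
        [
            {
                "n_domain_diff": key,
                "count": v,
                "proportion_pct": (100.0 * v / total) if total else float("nan"),
            }
            for key, v in bins.items()
        ]
    )


@dataclass(frozen=True)
class RateEstimate:
    """Lower bound on the percent-DA-change rate per million years.

    The divergence time is an upper bound on the age of the clustered
    duplications, so pct / t is a lower bound on the rate.
    """

    pct_da_diff: float
    t_upper_my: float
    rate_lb: float


def _round_sig(x: float, sig: int = 2) -> float:
    if x == 0:
        return 0.0
    return float(f"{x:.{sig}g}")


def rate_per_my(pct_da_diff: float, t_upper_my: float) -> RateEstimate:
    """Percent DA change per My (2 significant figures)."""
    if t_upper_my <= 0:
        raise ValueError("divergence time upper bound must be positive")
    if not 0 <= pct_da_diff <= 100:
        raise ValueError("pct_da_diff must be a percentage in [0, 100]")
    return RateEstimate(
        pct_da_diff=pct_da_diff,
        t_upper_my=t_upper_my,
        rate_lb=_round_sig(pct_da_diff / t_upper_my, 2),
    )


def read_annotation_table(path) -> pd.DataFrame:
    """Read a domain annotation TSV (protein_id, family_id, start, end, evalue)."""
    frame = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        names=["protein_id", "family_id", "start", "end", "evalue"],
        header=None,
        dtype={"protein_id": str, "family_id": str},
    )
    # tolerate a header row
    if len(frame) and str(frame.iloc[0]["start"]) == "start":
        frame = frame.iloc[1:].reset_index(drop=True)
    frame["start"] = frame["start"].astype(int)
    frame["end"] = frame["end"].astype(int)
    frame["evalue"] = frame["evalue"].astype(float)
    return frame


DOMTBL_COLUMNS = {
    "target_name": 0,
    "query_name": 3,
    "i_evalue": 12,
    "ali_from": 17,
    "ali_to": 18,
}


def read_domtblout(path) -> pd.DataFrame:
    """Read HMMER domtblout-style rows into the shared annotation schema.

    The query (protein) name, target (domain family) name, per-domain
    independent e-value and alignment coordinates map onto
    (protein_id, family_id, evalue, start, end).
    """
    rows = []
    with open(path) as handle:
        for line in handle:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            rows.append(
                {
                    "protein_id": parts[DOMTBL_COLUMNS["query_name"]],
                    "family_id": parts[DOMTBL_COLUMNS["target_name"]],
                    "start": int(parts[DOMTBL_COLUMNS["ali_from"]]),
                    "end": int(parts[DOMTBL_COLUMNS["ali_to"]]),
                    "evalue": float(parts[DOMTBL_COLUMNS["i_evalue"]]),
                }
            )
    return pd.DataFrame(
        rows, columns=["protein_id", "family_id", "start", "end", "evalue"]
    )
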