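"""Recombination-bin linkage mapping from marker scoring strings.

Markers scored across an inbred (single-seed descent) population carry
a "scoring string": one genotype call per line, from {A, B, H, -}.
Markers inherited together have identical strings up to missing data,
so a linkage map can be built without conventional multipoint mapping:
cluster markers with similar strings, order each cluster by the rank
of the best orthologue hit in a model species, merge runs of identical
calls into recombination bins, reject markers that break collinearity,
and iterate until the unmapped pool is stable.  Bin positions are
ordinal, not centiMorgan-scaled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Marker",
    "RecombinationBin",
    "LinkageMap",
    "string_similarity",
    "cluster_markers",
    "order_and_bin",
    "assemble_map",
    "graphical_genotype",
    "markers_from_frame",
]

MISSING = "-"
_CALLS = ("A", "B", "H", MISSING)


@dataclass(frozen=True)
class Marker:
    """One scored polymorphism: id, per-line calls, orthologue rank.

    ``rank`` is the ordinal position of the marker's best model-species
    gene hit; markers with no orthologue hit are excluded before
    mapping.  ``linkage_group`` carries the model chromosome (one group
    per chromosome).
    """

    id: str
    scoring: str
    rank: float
    genome: str = "?"
    unigene: str = ""
    linkage_group: str = "LG1"

    def __post_init__(self):
        bad = set(self.scoring) - set(_CALLS)
        if bad:
            raise ValueError(f"marker {self.id}: illegal calls {bad}")


@dataclass
class RecombinationBin:
    """Markers with mutually consistent calls, inherited as one unit."""

    bin_id: str
    markers: list[Marker]
    consensus: str
    position: int | None = None

    def __len__(self) -> int:
        return len(self.markers)


@dataclass
class LinkageMap:
    """Ordered recombination bins per linkage group plus unplaced pool."""

    groups: dict[str, list[RecombinationBin]] = field(default_factory=dict)
    unplaced: list[Marker] = field(default_factory=list)

    @property
    def n_bins(self) -> int:
        return sum(len(bins) for bins in self.groups.values())

    @property
    def n_markers(self) -> int:
        return sum(len(b) for bins in self.groups.values() for b in bins)

    def to_frame(self) -> pd.DataFrame:
        """Marker table: marker -> bin -> linkage group -> position."""
        rows = []
        for lg, bins in self.groups.items():
            for b in bins:
                for m in b.markers:
                    rows.append(
                        dict(
                            marker=m.id,
                            unigene=m.unigene,
                            genome=m.genome,
                            linkage_group=lg,
                            bin=b.bin_id,
                            position=b.position,
                            rank=m.rank,
                        )
                    )
        return pd.DataFrame(
            rows,
            columns=[
                "marker", "unigene", "genome", "linkage_group",
                "bin", "position", "rank",
            ],
        )


def string_similarity(s1: str, s2: str) -> float | None:
    """Fraction of agreeing calls over co-called positions.

    Positions where either string is missing ('-') are ignored; with no
    co-called positions the similarity is undefined and None returned.
    """
    if len(s1) != len(s2):
        raise ValueError("scoring strings differ in length")
    a = np.frombuffer(s1.encode(), dtype=np.uint8)
    b = np.frombuffer(s2.encode(), dtype=np.uint8)
    called = (a != ord(MISSING)) & (b != ord(MISSING))
    n = int(called.sum())
    if n == 0:
        return None
    return float(np.sum((a == b) & called)) / n


def _encode(markers: Sequence[Marker]) -> np.ndarray:
    mat = np.array([list(m.scoring) for m in markers], dtype="<U1")
    return mat


def _pairwise_links(mat: np.ndarray, min_similarity: float) -> np.ndarray:
    """Boolean (n, n) matrix of similarity >= threshold (vectorized)."""
    called = mat != MISSING
    n = mat.shape[0]
    link = np.zeros((n, n), dtype=bool)
    for i in range(n):
        both = called[i] & called
        co = both.sum(axis=1)
        agree = ((mat[i] == mat) & both).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            sim = np.where(co > 0, agree / np.maximum(co, 1), -1.0)
        link[i] = sim >= min_similarity
    return link


def cluster_markers(
    pool: Sequence[Marker], min_similarity: float = 0.9
) -> list[list[Marker]]:
    """Single-linkage clusters of markers by scoring-string similarity.

    Markers are lexicographically pre-sorted by id so the clustering is
    deterministic regardless of input order.  Markers whose strings are
    entirely missing can join nothing and come back as singletons.
    """
    markers = sorted(pool, key=lambda m: m.id)
    if not markers:
        return []
    mat = _encode(markers)
    link = _pairwise_links(mat, min_similarity)
    n = len(markers)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in np.nonzero(link[i])[0]:
            if j <= i:
                continue
            ri, rj = find(i), find(int(j))
            if ri != rj:
                parent[max(ri, rj)] = min(ri, rj)
    clusters: dict[int, list[Marker]] = {}
    for i, m in enumerate(markers):
        clusters.setdefault(find(i), []).append(m)
    return [clusters[r] for r in sorted(clusters)]


def _compatible(consensus: list[str], scoring: str) -> bool:
    for c, s in zip(consensus, scoring):
        if c != MISSING and s != MISSING and c != s:
            return False
    return True


def _merge(consensus: list[str], scoring: str) -> None:
    for i, s in enumerate(scoring):
        if s != MISSING:
            consensus[i] = s


def _weighted_lis(values: Sequence[float], weights: Sequence[int]) -> list[int]:
    """Indices of the max-weight non-decreasing subsequence (O(n^2) DP).

    Deterministic: ties are resolved toward the earliest predecessor.
    """
    n = len(values)
    best = list(weights)
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            if values[j] <= values[i] and best[j] + weights[i] > best[i]:
                best[i] = best[j] + weights[i]
                prev[i] = j
    if n == 0:
        return []
    end = int(np.argmax(best))
    out = []
    i = end
    while i >= 0:
        out.append(i)
        i = prev[i]
    return out[::-1]


def _chain_runs(ordered: Sequence[Marker]) -> list[dict]:
    """Maximal runs of mutually consistent calls along the rank order."""
    runs: list[dict] = []
    for m in ordered:
        if runs and _compatible(runs[-1]["consensus"], m.scoring):
            _merge(runs[-1]["consensus"], m.scoring)
            runs[-1]["markers"].append(m)
        else:
            runs.append(dict(consensus=list(m.scoring), markers=[m]))
    return runs


def order_and_bin(
    cluster: Sequence[Marker],
) -> tuple[list[RecombinationBin], list[Marker]]:
    """Order a cluster by orthologue rank, bin runs, reject discordants.

    Markers are sorted by orthologue rank (ties by id) and chained into
    maximal runs of mutually consistent calls.  Each run is anchored at
    the median rank of its members; a singleton run whose calls match a
    larger run elsewhere is instead anchored at that run's median --
    such a marker most plausibly has a wrong orthologue rank, since an
    inheritance pattern rarely reappears alone away from its locus.
    The collinearity filter keeps the maximum-weight non-decreasing
    subsequence of run anchors and rejects the remaining markers back
    to the pool.  Surviving adjacent runs with consistent calls merge
    into recombination bins.  Markers with entirely missing strings are
    always rejected.
    """
    usable = [m for m in cluster if set(m.scoring) != {MISSING}]
    rejected = [m for m in cluster if set(m.scoring) == {MISSING}]
    if not usable:
        return [], rejected
    ordered = sorted(usable, key=lambda m: (m.rank, m.id))
    runs = _chain_runs(ordered)
    anchors = []
    for i, run in enumerate(runs):
        own = float(np.median([m.rank for m in run["markers"]]))
        if len(run["markers"]) == 1:
            cons = "".join(run["consensus"])
            matches = [
                j for j, other in enumerate(runs)
                if j != i
                and len(other["markers"]) >= 2
                and _compatible(other["consensus"], cons)
            ]
            if matches:
                j = max(matches, key=lambda j: (len(runs[j]["markers"]), -abs(j - i)))
                own = float(np.median([m.rank for m in runs[j]["markers"]]))
        anchors.append(own)
    keep = set(_weighted_lis(anchors, [len(r["markers"]) for r in runs]))
    for i, run in enumerate(runs):
        if i not in keep:
            rejected.extend(run["markers"])
    bins: list[RecombinationBin] = []
    consensus: list[str] = []
    current: list[Marker] = []
    for i in sorted(keep):
        run = runs[i]
        cons = "".join(run["consensus"])
        if current and _compatible(consensus, cons):
            _merge(consensus, cons)
            current.extend(run["markers"])
        else:
            if current:
                bins.append(
                    RecombinationBin(
                        bin_id=f"bin{len(bins):04d}",
                        markers=current,
                        consensus="".join(consensus),
                    )
                )
            current = list(run["markers"])
            consensus = list(cons)
    if current:
        bins.append(
            RecombinationBin(
                bin_id=f"bin{len(bins):04d}",
                markers=current,
                consensus="".join(consensus),
            )
        )
    return bins, rejected


def _split_segments(
    bins: list[RecombinationBin],
    max_rank_gap: float,
    link_similarity: float,
) -> list[list[RecombinationBin]]:
    """Split an ordered bin list at collinearity discontinuities.

    Within one genomic block, consecutive bins carry near-contiguous
    model-gene ranks AND near-identical scoring strings (they differ
    only by the crossovers between them).  A jump in rank larger than
    ``max_rank_gap``, or a drop in consensus similarity below
    ``link_similarity``, marks a rearrangement junction: two regions
    adjacent in the model genome but far apart in the mapped genome,
    or vice versa.
    """
    segments: list[list[RecombinationBin]] = []
    for b in bins:
        if segments:
            prev = segments[-1][-1]
            gap = min(m.rank for m in b.markers) - max(
                m.rank for m in prev.markers
            )
            sim = string_similarity(prev.consensus, b.consensus)
            if gap > max_rank_gap or sim is None or sim < link_similarity:
                segments.append([b])
                continue
        if not segments:
            segments.append([b])
        else:
            segments[-1].append(b)
    return segments


def _chain_segments(
    segments: list[list[RecombinationBin]],
    link_similarity: float,
) -> list[list[RecombinationBin]]:
    """Order segments by genetic linkage of their terminal bins.

    Greedily joins chain endpoints whose terminal-bin consensus strings
    are most similar (at or above ``link_similarity``): in a mapping
    population, bins adjacent in the genome differ only by the few
    crossovers between them, so facing block ends are far more alike
    than random bin pairs.  Returns chains of segments; segments a
    chain traverses backwards come reversed.
    """
    # each chain is a list of bins; endpoints are its first/last bin
    chains: list[list[RecombinationBin]] = [list(seg) for seg in segments]
    while len(chains) > 1:
        best = None
        for i in range(len(chains)):
            for j in range(len(chains)):
                if i == j:
                    continue
                # join tail of i to head of j (reversals enumerated by
                # trying all four end combinations via chain reversal)
                for flip_i in (False, True):
                    for flip_j in (False, True):
                        tail = chains[i][0 if flip_i else -1]
                        head = chains[j][-1 if flip_j else 0]
                        sim = string_similarity(tail.consensus, head.consensus)
                        if sim is None or sim < link_similarity:
                            continue
                        key = (-sim, i, j, flip_i, flip_j)
                        if best is None or key < best:
                            best = key
        if best is None:
            break
        _, i, j, flip_i, flip_j = best
        left = chains[i][::-1] if flip_i else chains[i]
        right = chains[j][::-1] if flip_j else chains[j]
        merged = left + right
        chains = [
            c for k, c in enumerate(chains) if k not in (i, j)
        ] + [merged]
    return chains


def _median_rank(b: RecombinationBin) -> float:
    return float(np.median([m.rank for m in b.markers]))


def assemble_map(
    pool: Sequence[Marker],
    min_similarity: float = 0.9,
    max_iter: int = 10,
    max_rank_gap: float = 5.0,
    link_similarity: float | None = None,
) -> LinkageMap:
    """Iterate cluster -> order/bin until the unmapped pool is stable.

    Each iteration clusters the remaining pool, orders and bins every
    cluster, and returns collinearity-rejected markers to the pool.
    Accepted bin runs are split into collinear segments at orthologue-
    rank discontinuities; within a linkage group, segments are then
    ordered by genetic linkage (chaining terminal bins by scoring-
    string similarity), so a rearranged model-genome order cannot
    impose itself between blocks.  Chains a linkage group cannot
    connect genetically are ordered by mean orthologue rank.  Each
    final chain is oriented so that its terminal median ranks ascend
    (global chromosome orientation is not identifiable from the
    population itself).  An empty pool yields an empty map.
    """
    if link_similarity is None:
        # chain joins happen exactly where marker-clustering similarity
        # dips (block junctions), so the link threshold sits lower
        link_similarity = min_similarity - 0.1
    remaining = list(pool)
    accepted: list[tuple[str, list[RecombinationBin]]] = []
    for _ in range(max_iter):
        if not remaining:
            break
        n_before = len(remaining)
        next_pool: list[Marker] = []
        for cluster in cluster_markers(remaining, min_similarity):
            bins, rejected = order_and_bin(cluster)
            next_pool.extend(rejected)
            if bins:
                lg = bins[0].markers[0].linkage_group
                accepted.append((lg, bins))
        remaining = next_pool
        if len(remaining) == n_before:
            break
    lmap = LinkageMap(unplaced=remaining)
    by_group: dict[str, list[list[RecombinationBin]]] = {}
    for lg, bins in accepted:
        by_group.setdefault(lg, []).extend(
            _split_segments(bins, max_rank_gap, link_similarity)
        )
    for lg in sorted(by_group):
        chains = _chain_segments(by_group[lg], link_similarity)
        oriented: list[tuple[float, list[RecombinationBin]]] = []
        for chain in chains:
            if _median_rank(chain[0]) > _median_rank(chain[-1]):
                chain = chain[::-1]
            mean_rank = float(
                np.mean([m.rank for b in chain for m in b.markers])
            )
            oriented.append((mean_rank, chain))
        ordered: list[RecombinationBin] = []
        for _, chain in sorted(oriented, key=lambda t: t[0]):
            ordered.extend(chain)
        for pos, b in enumerate(ordered):
            b.position = pos
            b.bin_id = f"{lg}_bin{pos:04d}"
        lmap.groups[lg] = ordered
    return lmap


def graphical_genotype(lmap: LinkageMap) -> pd.DataFrame:
    """Consensus call per (bin, line) for manual inspection.

    The consensus at a line is the unique non-missing member call
    (bins guarantee consistency at co-called positions).
    """
    rows = []
    index = []
    for lg, bins in lmap.groups.items():
        for b in bins:
            index.append(b.bin_id)
            rows.append(list(b.consensus))
    n_lines = len(rows[0]) if rows else 0
    return pd.DataFrame(
        rows, index=index, columns=[f"line_{i+1:02d}" for i in range(n_lines)]
    )


def markers_from_frame(
    scoring: pd.DataFrame,
    ranks: Mapping[str, float],
    genomes: Mapping[str, str] | None = None,
    linkage_groups: Mapping[str, str] | None = None,
) -> list[Marker]:
    """Build markers from a scoring table (markers x lines) and ranks.

    Rows without a rank (no orthologue hit) are dropped, mirroring the
    upstream filter that retains only markers with model-species hits.
    """
    markers = []
    for mid, row in scoring.iterrows():
        if mid not in ranks:
            continue
        markers.append(
            Marker(
                id=str(mid),
                scoring="".join(row.values.tolist()),
                rank=float(ranks[mid]),
                genome=(genomes or {}).get(mid, "?"),
                unigene=str(mid),
                linkage_group=(linkage_groups or {}).get(mid, "LG1"),
            )
        )
    return markers
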