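"""Interhomoeologue polymorphisms and peak-height fold estimation.

Aligning the three homoeologous transcripts of a triplet exposes
interhomoeologue polymorphisms (IHPs): gap-free alignment columns at
which exactly one subgenome's base differs from the base shared by the
other two.  When a single PCR product amplifies all three transcripts
from cDNA and is Sanger-sequenced, each IHP appears as a double peak
whose heights are proportional to the transcript abundances -- the
variant base to the variant genome's transcripts, the shared base to
the other two genomes' pooled transcripts.  Comparing mean peak-height
ratios between genomes therefore estimates relative homoeologue
expression without qRT-PCR; under no dominance all three genomes'
ratios are roughly equal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

import biotite.sequence.align as balign

from .simsearch import SearchParams, _as_bseq

__all__ = [
    "IHP",
    "PeakRatio",
    "align_triplet",
    "call_ihps",
    "find_primer_sites",
    "estimate_genome_folds",
]

GENOMES = ("A", "B", "D")
GAP = "-"


@dataclass(frozen=True)
class IHP:
    """One interhomoeologue polymorphism (2:1 base pattern column)."""

    column: int
    variant_genome: str
    variant_base: str
    ancestral_base: str


@dataclass(frozen=True)
class PeakRatio:
    """Trace peak heights at one IHP; ratio = variant / ancestral."""

    ihp: IHP
    variant_height: float
    ancestral_height: float

    @property
    def ratio(self) -> float:
        if self.ancestral_height <= 0 or self.variant_height < 0:
            raise ValueError("peak heights must be positive")
        return self.variant_height / self.ancestral_height


def _pairwise_global(s1: str, s2: str, params: SearchParams):
    matrix = params.substitution_matrix()
    alns = balign.align_optimal(
        _as_bseq(s1),
        _as_bseq(s2),
        matrix,
        gap_penalty=(params.gap_open, params.gap_extend),
        local=False,
        terminal_penalty=True,
        max_number=1,
    )
    return alns[0]


def _aligned_strings(aln, s1: str, s2: str) -> tuple[str, str]:
    t = aln.trace
    row1 = "".join(s1[i] if i >= 0 else GAP for i in t[:, 0])
    row2 = "".join(s2[i] if i >= 0 else GAP for i in t[:, 1])
    return row1, row2


def align_triplet(
    seq_a: str,
    seq_b: str,
    seq_d: str,
    params: SearchParams | None = None,
) -> list[str]:
    """Progressive three-row alignment of a homoeologue triplet.

    A and B are aligned globally first; D is then aligned to the A-B
    consensus (A's base where present, else B's) and its gaps are
    spliced into all three rows.  Identical inputs give a gap-free
    identity alignment.  Returns the three aligned strings (A, B, D).
    """
    params = params or SearchParams()
    seq_a, seq_b, seq_d = (s.upper() for s in (seq_a, seq_b, seq_d))
    aln_ab = _pairwise_global(seq_a, seq_b, params)
    row_a, row_b = _aligned_strings(aln_ab, seq_a, seq_b)
    consensus = "".join(
        a if a != GAP else b for a, b in zip(row_a, row_b)
    )
    aln_cd = _pairwise_global(consensus, seq_d, params)
    t = aln_cd.trace
    out_a, out_b, out_d = [], [], []
    for ci, di in t:
        if ci >= 0:
            out_a.append(row_a[ci])
            out_b.append(row_b[ci])
        else:
            out_a.append(GAP)
            out_b.append(GAP)
        out_d.append(seq_d[di] if di >= 0 else GAP)
    return ["".join(out_a), "".join(out_b), "".join(out_d)]


def call_ihps(alignment: Sequence[str]) -> tuple[list[IHP], dict[str, int]]:
    """IHPs from a three-row alignment, plus skipped-column counts.

    A column qualifies when it is gap-free and exactly one genome's
    base differs from the identical base of the other two.  Gap columns
    and triallelic columns are skipped and counted.
    """
    if len(alignment) != 3:
        raise ValueError("expected a three-row alignment")
    row_a, row_b, row_d = alignment
    if not (len(row_a) == len(row_b) == len(row_d)):
        raise ValueError("alignment rows differ in length")
    ihps: list[IHP] = []
    counts = {"monomorphic": 0, "gap": 0, "triallelic": 0, "ihp": 0}
    for col, bases in enumerate(zip(row_a, row_b, row_d)):
        if GAP in bases:
            counts["gap"] += 1
            continue
        uniq = set(bases)
        if len(uniq) == 1:
            counts["monomorphic"] += 1
            continue
        if len(uniq) == 3:
            counts["triallelic"] += 1
            continue
        # exactly two distinct bases: find the lone genome
        for gi, g in enumerate(GENOMES):
            others = [bases[j] for j in range(3) if j != gi]
            if others[0] == others[1] and bases[gi] != others[0]:
                ihps.append(
                    IHP(
                        column=col,
                        variant_genome=g,
                        variant_base=bases[gi],
                        ancestral_base=others[0],
                    )
                )
                counts["ihp"] += 1
                break
    return ihps, counts


def find_primer_sites(
    alignment: Sequence[str],
    length: int = 20,
    max_mismatches: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Candidate common primer windows and amplicon spans.

    A window of ``length`` alignment columns qualifies when it contains
    no gaps and at most ``max_mismatches`` non-identical columns, so a
    single primer pair can amplify all three transcripts.  Qualifying
    windows are merged into runs; for each ordered pair of runs the
    widest amplicon (forward primer at the start of the earlier run,
    reverse at the end of the later) is reported with its enclosed IHP
    count.

    Returns ``(windows, amplicons)`` tables.
    """
    row_a, row_b, row_d = alignment
    n = len(row_a)
    ihps, _ = call_ihps(alignment)
    ihp_cols = np.zeros(n, dtype=int)
    for ihp in ihps:
        ihp_cols[ihp.column] = 1
    cum_ihp = np.concatenate([[0], np.cumsum(ihp_cols)])
    bad = np.array(
        [
            (GAP in (a, b, d)) or len({a, b, d}) > 1
            for a, b, d in zip(row_a, row_b, row_d)
        ],
        dtype=int,
    )
    gaps = np.array(
        [GAP in (a, b, d) for a, b, d in zip(row_a, row_b, row_d)], dtype=int
    )
    cum_bad = np.concatenate([[0], np.cumsum(bad)])
    cum_gap = np.concatenate([[0], np.cumsum(gaps)])
    starts = []
    for s in range(0, n - length + 1):
        if cum_gap[s + length] - cum_gap[s] > 0:
            continue
        if cum_bad[s + length] - cum_bad[s] <= max_mismatches:
            starts.append(s)
    windows = pd.DataFrame(
        dict(
            start=starts,
            end=[s + length for s in starts],
            mismatches=[int(cum_bad[s + length] - cum_bad[s]) for s in starts],
        )
    )
    # merge adjacent qualifying windows into runs
    runs: list[tuple[int, int]] = []
    for s in starts:
        if runs and s <= runs[-1][1]:
            runs[-1] = (runs[-1][0], s)
        else:
            runs.append((s, s))
    amp_rows = []
    for i in range(len(runs)):
        for j in range(i + 1, len(runs)):
            fwd_start = runs[i][0]
            rev_start = runs[j][1]
            if rev_start < fwd_start + length:
                continue
            inner0 = fwd_start + length
            inner1 = rev_start
            amp_rows.append(
                dict(
                    forward_start=fwd_start,
                    reverse_end=rev_start + length,
                    amplicon_length=rev_start + length - fwd_start,
                    n_ihps=int(cum_ihp[inner1] - cum_ihp[inner0]),
                )
            )
    amplicons = pd.DataFrame(
        amp_rows,
        columns=["forward_start", "reverse_end", "amplicon_length", "n_ihps"],
    )
    if len(amplicons):
        amplicons = amplicons.sort_values(
            ["n_ihps", "amplicon_length"], ascending=[False, True]
        ).reset_index(drop=True)
    return windows, amplicons


def estimate_genome_folds(
    peaks,
    method: str = "mean",
) -> tuple[pd.Series, pd.DataFrame]:
    """Aggregate peak-height ratios per genome and derive fold changes.

    ``peaks`` is a table with columns ``variant_genome`` and ``ratio``
    (or a sequence of :class:`PeakRatio`).  Per-genome aggregates are
    arithmetic means of ratios (``method='median'`` for medians).

    Because the variant peak reports one genome's transcripts and the
    shared peak the other two genomes' pooled transcripts, the ratio
    ``r_g = a_g / (S - a_g)`` (with S the total abundance), so the
    genome's abundance share is recovered as ``r_g / (1 + r_g)`` and
    ``fold(g1, g2)`` is the quotient of shares -- this estimates the
    underlying transcript-abundance fold directly.  Genomes with no
    IHPs yield NaN aggregates and NaN folds for their pairs.  Under no
    expression dominance all shares are equal and all folds ~1.
    """
    if not isinstance(peaks, pd.DataFrame):
        peaks = pd.DataFrame(
            [
                dict(variant_genome=p.ihp.variant_genome, ratio=p.ratio)
                for p in peaks
            ]
        )
    agg_fn = np.mean if method == "mean" else np.median
    if method not in ("mean", "median"):
        raise ValueError("method must be 'mean' or 'median'")
    agg = pd.Series(
        {
            g: (
                float(agg_fn(peaks.loc[peaks["variant_genome"] == g, "ratio"]))
                if (peaks["variant_genome"] == g).any()
                else np.nan
            )
            for g in GENOMES
        }
    )
    share = agg / (1.0 + agg)
    rows = []
    for g1 in GENOMES:
        for g2 in GENOMES:
            if g1 == g2:
                continue
            ok = (
                np.isfinite(share[g1])
                and np.isfinite(share[g2])
                and share[g2] > 0
            )
            rows.append(
                dict(
                    genome_1=g1,
                    genome_2=g2,
                    fold=share[g1] / share[g2] if ok else np.nan,
                )
            )
    return agg, pd.DataFrame(rows)
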