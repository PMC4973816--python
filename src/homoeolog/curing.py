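"""Iterative reference curing from reads of a closer relative.

When the only available reference for a subgenome comes from a proxy
taxon, reads from a more closely related genome can be used to
"cure" it: align the reads, find reference positions where the read
consensus disagrees, substitute the consensus base, and repeat until no
further bases change (or a cycle cap is reached).  Correction is
substitution-only, so sequence lengths never change, and reads are
re-mapped from scratch each cycle so corrections can recruit new reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .simsearch import ReadMapper

__all__ = [
    "CuringParams",
    "PileupColumn",
    "CuringReport",
    "build_pileup",
    "pileup_columns",
    "cure_cycle",
    "cure",
]

_BASE_ORDER = "ACGTN"
_BASE_INDEX = {b: i for i, b in enumerate(_BASE_ORDER)}


@dataclass(frozen=True)
class CuringParams:
    """Mapping and consensus thresholds for curing.

    A base is corrected only where coverage reaches ``min_depth`` and
    the consensus base reaches ``min_fraction`` of the column's reads.
    ``min_identity`` is the read-mapping acceptance cutoff.
    """

    min_depth: int = 4
    min_fraction: float = 0.5
    min_identity: float = 0.90
    word_size: int = 11


DEFAULT_CURING = CuringParams()


@dataclass(frozen=True)
class PileupColumn:
    """Base counts among reads covering one reference position."""

    reference_id: str
    position: int
    counts: tuple[int, int, int, int, int]  # A, C, G, T, N
    reference_base: str

    @property
    def coverage(self) -> int:
        return sum(self.counts)


@dataclass
class CuringReport:
    """Per-cycle substitution counts from a curing run."""

    per_cycle: list[int] = field(default_factory=list)
    cycles: int = 0

    @property
    def total_changed(self) -> int:
        return sum(self.per_cycle)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(cycle=range(1, self.cycles + 1), n_changed=self.per_cycle)
        )


def _read_seqs(reads) -> list[str]:
    out = []
    for r in reads:
        out.append(r[1] if isinstance(r, (tuple, list)) else str(r))
    return out


def build_pileup(
    reference: Mapping[str, str],
    reads,
    params: CuringParams = DEFAULT_CURING,
    mapper: ReadMapper | None = None,
) -> dict[str, np.ndarray]:
    """Base-count pileup per reference from best-reference read mapping.

    Each read is assigned to its unique best reference at or above
    ``min_identity`` (ambiguous reads tying across references are
    discarded rather than guessed).  Returns ``{reference id: (L, 5)
    count array}`` over A/C/G/T/N; only references with coverage appear.
    """
    if mapper is None:
        mapper = ReadMapper(
            reference,
            word_size=params.word_size,
            min_identity=params.min_identity,
        )
    piles: dict[str, np.ndarray] = {}
    for seq in _read_seqs(reads):
        ties = mapper.candidates(seq)
        if len(ties) != 1:
            continue
        rid, _, offset = ties[0]
        ref = reference[rid]
        if rid not in piles:
            piles[rid] = np.zeros((len(ref), 5), dtype=np.int32)
        codes = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
        r0 = max(0, -offset)
        r1 = min(len(codes), len(ref) - offset)
        if r1 <= r0:
            continue
        pos = np.arange(r0 + offset, r1 + offset)
        idx = np.full(r1 - r0, 4, dtype=np.int64)  # default N
        for b, i in _BASE_INDEX.items():
            idx[codes[r0:r1] == ord(b)] = i
        np.add.at(piles[rid], (pos, idx), 1)
    return piles


def pileup_columns(
    piles: Mapping[str, np.ndarray], reference: Mapping[str, str]
) -> Iterator[PileupColumn]:
    """Iterate covered positions of a pileup as :class:`PileupColumn`."""
    for rid in sorted(piles):
        arr = piles[rid]
        ref = reference[rid]
        for pos in np.nonzero(arr.sum(axis=1))[0]:
            yield PileupColumn(
                reference_id=rid,
                position=int(pos),
                counts=tuple(int(c) for c in arr[pos]),
                reference_base=ref[pos],
            )


def cure_cycle(
    reference: Mapping[str, str],
    reads,
    params: CuringParams = DEFAULT_CURING,
) -> tuple[dict[str, str], int]:
    """One round of alignment and substitution correction.

    At every column with coverage >= ``min_depth`` whose consensus base
    (ties resolved toward the current reference base, then
    alphabetically; N never wins) differs from the reference and
    reaches ``min_fraction`` of the coverage, the reference base is
    replaced.  Returns the corrected reference and the number of bases
    changed.
    """
    piles = build_pileup(reference, reads, params)
    new_ref = dict(reference)
    n_changed = 0
    for rid, arr in piles.items():
        ref = np.frombuffer(new_ref[rid].encode(), dtype=np.uint8).copy()
        acgt = arr[:, :4]
        coverage = arr.sum(axis=1)
        top = acgt.max(axis=1)
        cons_idx = acgt.argmax(axis=1)  # ties -> alphabetical (first argmax)
        cons_base = np.frombuffer(b"ACGT", dtype=np.uint8)[cons_idx]
        ref_idx = np.full(len(ref), -1)
        for b, i in _BASE_INDEX.items():
            ref_idx[ref == ord(b)] = i
        # a tie that includes the reference base keeps the reference
        ref_count = np.where(
            (ref_idx >= 0) & (ref_idx < 4),
            acgt[np.arange(len(ref)), np.clip(ref_idx, 0, 3)],
            -1,
        )
        change = (
            (coverage >= params.min_depth)
            & (top > 0)
            & (cons_base != ref)
            & (ref_count < top)
            & (top >= params.min_fraction * coverage)
        )
        if change.any():
            ref[change] = cons_base[change]
            n_changed += int(change.sum())
            new_ref[rid] = ref.tobytes().decode()
    return new_ref, n_changed


def cure(
    reference: Mapping[str, str],
    reads,
    max_cycles: int = 6,
    params: CuringParams = DEFAULT_CURING,
) -> tuple[dict[str, str], CuringReport]:
    """Repeat :func:`cure_cycle` until convergence or ``max_cycles``.

    Stops early at the first cycle that changes zero bases.
    """
    report = CuringReport()
    current = dict(reference)
    for _ in range(max_cycles):
        current, n = cure_cycle(current, reads, params)
        report.per_cycle.append(n)
        report.cycles += 1
        if n == 0:
            break
    return current, report
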