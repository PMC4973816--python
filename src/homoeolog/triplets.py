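"""Homoeologue triplet identification by three-way reciprocal best hit.

A triplet is one unigene from each subgenome (A, B, D) such that all
three pairwise reciprocal-best-hit relations hold at the E-value
threshold.  Because best hits are unique, every unigene belongs to at
most one triplet.  Triplet genomic position is taken from the A-genome
member by convention (the three subgenome orders are essentially
identical along the pseudomolecules).
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from . import simsearch
from .simsearch import SearchParams

__all__ = ["find_triplets", "compare_triplet_panels"]


def find_triplets(
    a_seqs: Mapping[str, str],
    b_seqs: Mapping[str, str],
    d_seqs: Mapping[str, str],
    params: SearchParams | None = None,
    positions: Mapping[str, tuple[str, int]] | None = None,
) -> pd.DataFrame:
    """Triplets from three-way reciprocal best hits.

    ``(a, b, d)`` is emitted iff reciprocal-best holds for A-B, A-D and
    B-D at ``params.evalue_threshold``.  ``positions`` optionally maps
    A-member ids to ``(linkage_group, position)``; output is sorted by
    position, then A id.  Empty inputs yield an empty table.
    """
    params = params or simsearch.DEFAULT_PARAMS
    cols = ["a_id", "b_id", "d_id", "linkage_group", "position"]
    if not a_seqs or not b_seqs or not d_seqs:
        return pd.DataFrame(columns=cols)
    rb_ab = dict(simsearch.reciprocal_best(a_seqs, b_seqs, params))
    rb_ad = dict(simsearch.reciprocal_best(a_seqs, d_seqs, params))
    rb_bd = dict(simsearch.reciprocal_best(b_seqs, d_seqs, params))
    rows = []
    for a_id in sorted(a_seqs):
        b_id = rb_ab.get(a_id)
        d_id = rb_ad.get(a_id)
        if b_id is None or d_id is None:
            continue
        if rb_bd.get(b_id) != d_id:
            continue
        lg, pos = (positions or {}).get(a_id, (None, None))
        rows.append(
            dict(a_id=a_id, b_id=b_id, d_id=d_id, linkage_group=lg, position=pos)
        )
    df = pd.DataFrame(rows, columns=cols)
    if len(df) and df["position"].notna().any():
        df = df.sort_values(["position", "a_id"]).reset_index(drop=True)
    return df


def compare_triplet_panels(
    panel1: pd.DataFrame,
    panel2: pd.DataFrame,
    sequences: Mapping[str, str],
    params: SearchParams | None = None,
) -> pd.DataFrame:
    """Per-genome match percentages between two triplet panels.

    For each genome column (a_id, b_id, d_id), the members of one panel
    are matched to the members of the other by reciprocal best hit on
    their sequences; the forward percentage is the fraction of panel1
    members with a reciprocal partner in panel2, and vice versa.

    Returns a table with columns genome, forward_pct, reverse_pct,
    n_panel1, n_panel2.
    """
    params = params or simsearch.DEFAULT_PARAMS
    rows = []
    for genome, col in (("A", "a_id"), ("B", "b_id"), ("D", "d_id")):
        ids1 = [i for i in panel1[col] if i in sequences]
        ids2 = [i for i in panel2[col] if i in sequences]
        set1 = {i: sequences[i] for i in ids1}
        set2 = {i: sequences[i] for i in ids2}
        if set1 and set2:
            pairs = simsearch.reciprocal_best(set1, set2, params)
            matched1 = {x for x, _ in pairs}
            matched2 = {y for _, y in pairs}
        else:
            matched1, matched2 = set(), set()
        fwd = 100.0 * len(matched1) / len(set1) if set1 else 0.0
        rev = 100.0 * len(matched2) / len(set2) if set2 else 0.0
        rows.append(
            dict(
                genome=genome,
                forward_pct=fwd,
                reverse_pct=rev,
                n_panel1=len(set1),
                n_panel2=len(set2),
            )
        )
    return pd.DataFrame(rows)
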