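"""Synteny-based pseudomolecule construction and unigene placement.

A model genome with a high-quality gene order can be rearranged, block
by block, into "pseudomolecules" representing the hypothetical gene
order of a target genome: the model sequence is split at midpoints
between the alignment anchors that delimit rearranged collinearity
blocks, the blocks are re-ordered and re-oriented according to the
span of linkage-map recombination bins they carry, and transcript
assemblies (unigenes) are placed on the result by best sequence
similarity.  Redundant placements (splice forms of one locus) are
collapsed to the longest unigene.

Coordinates are 0-based half-open internally; exported tables are
1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import kendalltau

from . import simsearch
from .simsearch import SearchParams, SequenceDatabase

__all__ = [
    "CollinearityBlock",
    "Pseudomolecule",
    "split_reference",
    "assign_bin_spans",
    "order_segments",
    "place_unigenes",
    "reduce_redundancy",
    "collinearity_dotplot",
]


@dataclass
class CollinearityBlock:
    """A contiguous slice of the model genome mapping to one map region.

    ``start``/``end`` are base-pair coordinates (0-based half-open)
    after midpoint splitting.  ``bin_first``/``bin_last`` are the map
    positions of the recombination bins spanned by the block's distal
    markers; a decreasing span means the block is inverted in the
    target genome.
    """

    block_id: str
    chrom: str
    start: int
    end: int
    orientation: str = "+"
    linkage_group: str | None = None
    bin_first: int | None = None
    bin_last: int | None = None


@dataclass
class Pseudomolecule:
    """An ordered, oriented sequence of collinearity blocks."""

    name: str
    blocks: list[CollinearityBlock]
    gene_order: pd.DataFrame  # gene_id, position (ordinal), coordinate, block_id


def split_reference(
    model_table: pd.DataFrame,
    anchors: pd.DataFrame,
) -> tuple[list[CollinearityBlock], pd.DataFrame]:
    """Split a model genome into blocks midway between distal anchors.

    ``model_table`` has one row per gene: gene_id, chrom, start, end
    (0-based half-open bp).  ``anchors`` has one row per block:
    block_id, chrom, anchor_start, anchor_end -- the outermost alignment
    (HSP) coordinates of the block's distal markers.  Cut points fall at
    ``floor((end_i + start_{i+1}) / 2)`` between consecutive anchors on
    a chromosome, so every model gene lands in exactly one block (genes
    are assigned by their start coordinate).  Overlapping anchors are an
    error.

    Returns the blocks and a copy of ``model_table`` with a
    ``block_id`` column.
    """
    blocks: list[CollinearityBlock] = []
    table = model_table.copy()
    table["block_id"] = None
    for chrom, sub in anchors.groupby("chrom"):
        sub = sub.sort_values("anchor_start")
        starts = sub["anchor_start"].to_numpy()
        ends = sub["anchor_end"].to_numpy()
        if (starts[1:] < ends[:-1]).any():
            raise ValueError(f"overlapping distal anchors on {chrom}")
        genes = table[table["chrom"] == chrom]
        chrom_end = int(genes["end"].max()) if len(genes) else int(ends[-1])
        cuts = [0]
        for i in range(len(sub) - 1):
            cuts.append(int((ends[i] + starts[i + 1]) // 2))
        cuts.append(max(chrom_end, int(ends[-1])))
        for i, (_, row) in enumerate(sub.iterrows()):
            blk = CollinearityBlock(
                block_id=str(row["block_id"]),
                chrom=chrom,
                start=cuts[i],
                end=cuts[i + 1],
            )
            blocks.append(blk)
            in_block = (
                (table["chrom"] == chrom)
                & (table["start"] >= blk.start)
                & (table["start"] < blk.end)
            )
            table.loc[in_block, "block_id"] = blk.block_id
    unassigned = table["block_id"].isna()
    if unassigned.any():
        # genes on chromosomes without anchors stay unassigned
        missing_chroms = set(table.loc[unassigned, "chrom"]) - set(anchors["chrom"])
        if set(table.loc[unassigned, "chrom"]) - missing_chroms:
            raise AssertionError("gene escaped block partition")
    return blocks, table


def assign_bin_spans(
    blocks: Sequence[CollinearityBlock],
    marker_positions: pd.DataFrame,
) -> list[CollinearityBlock]:
    """Attach linkage-group/bin spans to blocks from placed markers.

    ``marker_positions`` columns: chrom, coord (model bp), linkage_group,
    bin_position.  For each block, the bin positions of the markers at
    its two extremities define (bin_first, bin_last).
    """
    for blk in blocks:
        inside = marker_positions[
            (marker_positions["chrom"] == blk.chrom)
            & (marker_positions["coord"] >= blk.start)
            & (marker_positions["coord"] < blk.end)
        ].sort_values("coord")
        if len(inside) == 0:
            continue
        blk.linkage_group = str(inside["linkage_group"].iloc[0])
        blk.bin_first = int(inside["bin_position"].iloc[0])
        blk.bin_last = int(inside["bin_position"].iloc[-1])
    return list(blocks)


def order_segments(
    blocks: Sequence[CollinearityBlock],
    gene_assignment: pd.DataFrame,
) -> dict[str, Pseudomolecule]:
    """Re-order and re-orient blocks by their recombination-bin span.

    Within each linkage group, blocks are sorted by the smaller end of
    their bin span; a block whose bin span decreases along the model
    coordinate (bin_first > bin_last) is inverted.  ``gene_assignment``
    is the block-annotated model table from :func:`split_reference`.
    Blocks without a bin span (no markers) are dropped with their genes.

    Returns one :class:`Pseudomolecule` per linkage group, with genes at
    ordinal positions and cumulative coordinates.
    """
    by_group: dict[str, list[CollinearityBlock]] = {}
    for blk in blocks:
        if blk.bin_first is None or blk.linkage_group is None:
            continue
        by_group.setdefault(blk.linkage_group, []).append(blk)
    out: dict[str, Pseudomolecule] = {}
    for lg in sorted(by_group):
        ordered = sorted(
            by_group[lg],
            key=lambda b: (min(b.bin_first, b.bin_last), b.block_id),
        )
        rows = []
        position = 0
        coordinate = 0
        for blk in ordered:
            blk.orientation = "-" if blk.bin_first > blk.bin_last else "+"
            genes = gene_assignment[
                gene_assignment["block_id"] == blk.block_id
            ].sort_values("start", ascending=blk.orientation == "+")
            for _, g in genes.iterrows():
                span = int(g["end"]) - int(g["start"])
                rows.append(
                    dict(
                        gene_id=g["gene_id"],
                        position=position,
                        coordinate=coordinate,
                        block_id=blk.block_id,
                        orientation=blk.orientation,
                    )
                )
                position += 1
                coordinate += span
        out[lg] = Pseudomolecule(
            name=lg,
            blocks=ordered,
            gene_order=pd.DataFrame(
                rows,
                columns=[
                    "gene_id", "position", "coordinate", "block_id", "orientation",
                ],
            ),
        )
    return out


def place_unigenes(
    unigenes: Mapping[str, str],
    model_genes: Mapping[str, str],
    gene_positions: pd.DataFrame,
    params: SearchParams | None = None,
    genome_of: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Place unigenes on pseudomolecules by best similarity hit.

    Each unigene is searched against the model gene sequences; the best
    hit at or below the E-value threshold gives the unigene the hit
    gene's pseudomolecule and position (``gene_positions`` columns:
    gene_id, pseudomolecule, position).  Unigenes with no passing hit
    are returned separately as unplaced -- they remain usable as a
    mapping reference even without an inferred position.
    """
    params = params or simsearch.DEFAULT_PARAMS
    db = SequenceDatabase(model_genes)
    pos_by_gene = gene_positions.set_index("gene_id")
    rows = []
    unplaced: list[str] = []
    for uid in sorted(unigenes):
        hit = simsearch.best_hit(unigenes[uid], db, params, query_id=uid)
        if hit is None or hit.subject_id not in pos_by_gene.index:
            unplaced.append(uid)
            continue
        g = pos_by_gene.loc[hit.subject_id]
        genome = (genome_of or {}).get(uid, uid.split("_", 1)[0])
        rows.append(
            dict(
                unigene_id=uid,
                genome=genome,
                model_gene=hit.subject_id,
                pseudomolecule=g["pseudomolecule"],
                position=int(g["position"]),
                length=len(unigenes[uid]),
                evalue=hit.evalue,
                bit_score=hit.bit_score,
            )
        )
    placed = pd.DataFrame(
        rows,
        columns=[
            "unigene_id", "genome", "model_gene", "pseudomolecule",
            "position", "length", "evalue", "bit_score",
        ],
    )
    return placed, unplaced


def reduce_redundancy(placed: pd.DataFrame) -> pd.DataFrame:
    """Keep one unigene per locus: the longest, ties by lexical id.

    A locus is the combination of genome, best-hit model gene and
    placement position -- multiple unigenes there are treated as splice
    forms of one gene.  Idempotent; never increases the row count.
    """
    if len(placed) == 0:
        return placed.copy()
    df = placed.sort_values(
        ["length", "unigene_id"], ascending=[False, True]
    )
    out = df.drop_duplicates(
        subset=["genome", "model_gene", "pseudomolecule", "position"],
        keep="first",
    )
    return out.sort_values("unigene_id").reset_index(drop=True)


def collinearity_dotplot(
    order1: Mapping[str, int],
    order2: Mapping[str, int],
    matching: Mapping[str, str] | None = None,
    ax=None,
    path=None,
    title: str = "Collinearity",
):
    """Dot plot of shared gene ordinal positions plus Kendall tau.

    ``matching`` maps ids of ``order1`` to ids of ``order2``; by default
    shared keys are matched by identity.  Returns ``(figure, tau)``.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if matching is None:
        shared = sorted(set(order1) & set(order2))
        pairs = [(order1[g], order2[g]) for g in shared]
    else:
        pairs = [
            (order1[a], order2[b])
            for a, b in matching.items()
            if a in order1 and b in order2
        ]
    if not pairs:
        raise ValueError("no shared genes between orders")
    x, y = zip(*pairs)
    tau = kendalltau(x, y).statistic if len(pairs) > 1 else 1.0
    if ax is None:
        fig, ax = plt.subplots(figsize=(5, 5))
    else:
        fig = ax.figure
    ax.scatter(x, y, s=4, alpha=0.6, linewidths=0)
    ax.set_xlabel("order 1")
    ax.set_ylabel("order 2")
    ax.set_title(f"{title} (Kendall tau = {tau:.3f})")
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig, float(tau)
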