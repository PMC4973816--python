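"""Read mapping, counting and RPKM quantification.

Reads from each accession are mapped to the combined three-subgenome
unigene reference; counts are normalized to RPKM (reads per kilobase
of transcript per million aligned reads).  Because the three subgenome
references descend from different proxy taxa, mapping efficiency can
differ systematically between subgenomes; a per-genome normalization
multiplies each subgenome's values by the ratio of the mean per-genome
mapped total to that subgenome's mapped total, per accession.

Reads equidistant between homoeologues are assigned uniformly at
random under a fixed seed, deliberately reproducing the mild
cross-mapping signal distortion seen with near-identical homoeologous
stretches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .simsearch import ReadMapper

__all__ = [
    "MapParams",
    "ExpressionMatrix",
    "downsample",
    "map_and_count",
    "rpkm",
    "per_genome_normalize",
    "genome_of",
    "quantify_panel",
]


@dataclass(frozen=True)
class MapParams:
    """Read-assignment parameters."""

    word_size: int = 11
    min_identity: float = 0.95
    seed: int = 0


def genome_of(unigene_id: str) -> str:
    """Subgenome letter from the id prefix (A_/B_/D_)."""
    return unigene_id.split("_", 1)[0]


@dataclass
class ExpressionMatrix:
    """Counts and RPKM per unigene x accession, with mapping totals."""

    counts: pd.DataFrame  # unigene x accession raw counts
    rpkm: pd.DataFrame  # unigene x accession RPKM
    lengths: pd.Series  # unigene -> length (bases)
    mapped_total: pd.Series  # accession -> reads mapped
    per_genome_totals: pd.DataFrame  # genome x accession mapped reads
    unmapped: pd.Series  # accession -> reads not assigned


def downsample(reads: Sequence, n: int, seed: int = 0) -> list:
    """Uniform sample of ``n`` reads without replacement (order kept).

    Returns the input unchanged when ``n`` covers it.
    """
    reads = list(reads)
    if n >= len(reads):
        return reads
    if n <= 0:
        return []
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(reads), size=n, replace=False))
    return [reads[i] for i in idx]


def _read_seqs(reads) -> list[str]:
    return [r[1] if isinstance(r, (tuple, list)) else str(r) for r in reads]


def map_and_count(
    reads_by_accession: Mapping[str, Sequence],
    reference: Mapping[str, str],
    params: MapParams = MapParams(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign each read to its best reference unigene and count.

    Ties between equally good references are broken uniformly at
    random under ``params.seed``.  Returns ``(counts, stats)``:
    counts is unigene x accession; stats has one row per accession
    with total, mapped, unmapped and per-genome mapped reads.
    """
    if not reference:
        raise ValueError("empty reference")
    mapper = ReadMapper(
        reference, word_size=params.word_size, min_identity=params.min_identity
    )
    ids = sorted(reference)
    accs = list(reads_by_accession)
    counts = pd.DataFrame(0, index=ids, columns=accs, dtype=int)
    stats_rows = []
    for ai, acc in enumerate(accs):
        rng = np.random.default_rng(
            np.random.SeedSequence((params.seed, ai))
        )
        seqs = _read_seqs(reads_by_accession[acc])
        mapped = 0
        for seq in seqs:
            res = mapper.map_read(seq, rng)
            if res is None:
                continue
            rid, _ = res
            counts.loc[rid, acc] += 1
            mapped += 1
        row = dict(
            accession=acc,
            total=len(seqs),
            mapped=mapped,
            unmapped=len(seqs) - mapped,
        )
        stats_rows.append(row)
    stats = pd.DataFrame(stats_rows)
    genome = pd.Series({u: genome_of(u) for u in ids})
    per_genome = counts.groupby(genome).sum()
    for g in per_genome.index:
        stats[f"mapped_{g}"] = per_genome.loc[g, stats["accession"]].to_numpy()
    return counts, stats


def rpkm(
    counts: pd.DataFrame,
    lengths: Mapping[str, int] | pd.Series,
    mapped_total: Mapping[str, int] | pd.Series,
) -> pd.DataFrame:
    """RPKM = count / (length/1000) / (mapped_total/1e6).

    ``mapped_total`` is per accession: all reads aligned to the whole
    combined reference.  Accessions with zero mapped reads get zeros.
    """
    lengths = pd.Series(lengths).reindex(counts.index)
    if lengths.isna().any():
        raise ValueError("missing lengths for some unigenes")
    totals = pd.Series(mapped_total).reindex(counts.columns).astype(float)
    kb = lengths.to_numpy(dtype=float)[:, None] / 1000.0
    denom = totals.to_numpy()[None, :] / 1e6
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = counts.to_numpy(dtype=float) / kb / denom
    vals[:, totals.to_numpy() <= 0] = 0.0
    return pd.DataFrame(vals, index=counts.index, columns=counts.columns)


def per_genome_normalize(
    rpkm_matrix: pd.DataFrame,
    per_genome_totals: pd.DataFrame,
) -> pd.DataFrame:
    """Correct unequal per-subgenome mapping efficiency.

    Values of genome-g unigenes are multiplied, per accession, by
    ``mean_over_genomes(mapped totals) / mapped total of g``.  Equal
    totals leave the matrix unchanged.
    """
    factors = per_genome_totals.mean(axis=0) / per_genome_totals
    out = rpkm_matrix.copy()
    genome = pd.Index([genome_of(u) for u in out.index])
    for g in per_genome_totals.index:
        sel = genome == g
        out.loc[sel] = out.loc[sel].to_numpy() * factors.loc[g].to_numpy()[None, :]
    return out


def quantify_panel(
    reads_by_accession: Mapping[str, Sequence],
    reference: Mapping[str, str],
    params: MapParams = MapParams(),
) -> ExpressionMatrix:
    """Full quantification: map, count, RPKM, per-genome totals."""
    counts, stats = map_and_count(reads_by_accession, reference, params)
    lengths = pd.Series({u: len(s) for u, s in reference.items()})
    mapped_total = stats.set_index("accession")["mapped"]
    genome_cols = [c for c in stats.columns if c.startswith("mapped_") and c != "mapped"]
    per_genome = stats.set_index("accession")[genome_cols].T
    per_genome.index = [c.replace("mapped_", "") for c in genome_cols]
    mat = rpkm(counts, lengths, mapped_total)
    return ExpressionMatrix(
        counts=counts,
        rpkm=mat,
        lengths=lengths.reindex(counts.index),
        mapped_total=mapped_total,
        per_genome_totals=per_genome,
        unmapped=stats.set_index("accession")["unmapped"],
    )
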