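"""Synthetic data generators for the homoeologue-dominance pipeline.

Every input the pipeline consumes can be generated here with known
ground truth: three homoeologous transcript sets with controlled
inter-subgenome divergence, an expression panel with planted dominance
and repression blocks, error-bearing sequencing reads, a single-seed
descent (SSD) genotype matrix with Poisson crossovers, a rearranged
model-genome gene order, and Sanger-style trace peak heights at
interhomoeologue polymorphisms.

Defaults mirror the dimensions of the study system the pipeline was
built for: a 54-accession hexaploid diversity panel, a 47-line SSD
mapping population, 100-base reads, and A/B lineages roughly twice as
diverged from each other as either is from D.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SimConfig",
    "SimulatedTruth",
    "ExpressionBlock",
    "simulate_subgenomes",
    "plant_expression",
    "simulate_reads",
    "write_fastq",
    "write_fasta",
    "simulate_ssd_population",
    "simulate_rearranged_reference",
    "simulate_trace_peaks",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
GENOMES = ("A", "B", "D")


@dataclass(frozen=True)
class ExpressionBlock:
    """A planted block of expression-level dominance or repression.

    ``fold`` multiplies (dominance) or divides (repression) the named
    subgenome's abundance for triplet indices in ``[start, end)``.
    """

    genome: str
    start: int
    end: int
    fold: float


def _as_blocks(blocks) -> tuple[ExpressionBlock, ...]:
    out = []
    for b in blocks or ():
        if isinstance(b, ExpressionBlock):
            out.append(b)
        else:
            out.append(ExpressionBlock(*b))
    return tuple(out)


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Rates are per site / per base probabilities in [0, 1].
    ``divergence_ab`` is the expected A-B pairwise divergence (each
    lineage receives half of it independently); ``divergence_d`` is the
    D lineage's substitution rate from the common ancestor.  Fold
    effects in blocks must be >= 1 (a fold of exactly 1 plants no
    effect and yields a 'none' truth label).
    """

    n_triplets: int = 200
    n_accessions: int = 54
    divergence_ab: float = 0.03
    divergence_d: float = 0.02
    read_length: int = 100
    reads_per_accession: int = 20_000
    error_rate: float = 0.005
    dominance_blocks: tuple = ()
    repression_blocks: tuple = ()
    expression_sd: float = 0.3
    n_ssd_lines: int = 47
    missing_rate: float = 0.02
    recombination_rate: float = 0.002
    het_rate: float = 0.0
    private_fraction: float = 0.10
    gene_length_range: tuple[int, int] = (400, 800)
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        self.dominance_blocks = _as_blocks(self.dominance_blocks)
        self.repression_blocks = _as_blocks(self.repression_blocks)
        for name in (
            "divergence_ab", "divergence_d", "error_rate", "missing_rate",
            "private_fraction", "het_rate",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_triplets < 1:
            raise ValueError("n_triplets must be >= 1")
        for blk in self.dominance_blocks + self.repression_blocks:
            if blk.fold < 1:
                raise ValueError(f"fold {blk.fold} must be >= 1")
            if blk.genome not in GENOMES:
                raise ValueError(f"unknown genome {blk.genome!r}")
            if not (0 <= blk.start < blk.end <= self.n_triplets):
                raise ValueError(
                    f"block [{blk.start}, {blk.end}) outside "
                    f"[0, {self.n_triplets})"
                )

    def rng(self, stream: int = 0) -> np.random.Generator:
        """Independent deterministic stream per generator stage."""
        return np.random.default_rng(np.random.SeedSequence((self.seed, stream)))

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["dominance_blocks"] = [list(asdict(b).values()) for b in self.dominance_blocks]
        d["repression_blocks"] = [list(asdict(b).values()) for b in self.repression_blocks]
        d["gene_length_range"] = list(self.gene_length_range)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["gene_length_range"] = tuple(d.get("gene_length_range", (400, 800)))
        return cls(**d)


@dataclass
class SimulatedTruth:
    """Ground truth recorded by the generators for recovery tests."""

    true_triplets: pd.DataFrame  # columns a_id, b_id, d_id, position
    true_order: list[str]  # triplet keys (ancestor gene names) in genome order
    sequences: dict[str, dict[str, str]]  # genome -> {unigene id: sequence}
    gene_lengths: dict[str, int]
    private: dict[str, tuple[str, ...]]  # ancestor gene -> genomes lacking it
    true_expression: np.ndarray | None = None  # (n_triplets, 3, n_accessions)
    true_classification: pd.DataFrame | None = None  # genome, direction per triplet


def _random_seq_codes(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site with probability ``rate`` to a different base."""
    out = codes.copy()
    hit = np.nonzero(rng.random(len(codes)) < rate)[0]
    if len(hit):
        # pick one of the three other bases uniformly
        cur_idx = np.searchsorted(_BASES, out[hit])
        shift = rng.integers(1, 4, size=len(hit))
        out[hit] = _BASES[(cur_idx + shift) % 4]
    return out


def expected_pairwise_identity(r1: float, r2: float) -> float:
    """Expected identity between two lineages with per-site rates r1, r2.

    Each lineage independently substitutes a site to one of the three
    other bases; two independently substituted sites agree with
    probability 1/3.
    """
    both = r1 * r2
    neither = (1 - r1) * (1 - r2)
    return neither + both / 3.0


def simulate_subgenomes(config: SimConfig):
    """Generate three homoeologous transcript sets from random ancestors.

    Returns ``(a_seqs, b_seqs, d_seqs, truth)``.  A fraction of genes
    (``private_fraction``) is deleted from one or two subgenomes so
    that non-triplet code paths are exercised; those genes do not
    appear in ``truth.true_triplets``.
    """
    r_ab = config.divergence_ab / 2.0
    rates = {"A": r_ab, "B": r_ab, "D": config.divergence_d}
    worst = min(
        expected_pairwise_identity(rates[g1], rates[g2])
        for g1, g2 in (("A", "B"), ("A", "D"), ("B", "D"))
    )
    if worst < 0.60:
        raise ValueError(
            f"expected pairwise identity {worst:.2f} < 0.60; "
            "reciprocal-best-hit orthology is unreliable at this divergence"
        )
    rng = config.rng(1)
    lo, hi = config.gene_length_range
    seqs = {g: {} for g in GENOMES}
    lengths: dict[str, int] = {}
    private: dict[str, tuple[str, ...]] = {}
    triplet_rows = []
    order = []
    n_private = int(round(config.private_fraction * config.n_triplets))
    private_idx = set(
        rng.choice(config.n_triplets, size=n_private, replace=False).tolist()
    ) if n_private else set()
    for i in range(config.n_triplets):
        gene = f"g{i:05d}"
        order.append(gene)
        length = int(rng.integers(lo, hi + 1))
        ancestor = _random_seq_codes(rng, length)
        missing: tuple[str, ...] = ()
        if i in private_idx:
            k = int(rng.integers(1, 3))  # delete from 1 or 2 genomes
            missing = tuple(sorted(rng.choice(GENOMES, size=k, replace=False)))
            private[gene] = missing
        ids = {}
        for g in GENOMES:
            if g in missing:
                continue
            uid = f"{g}_{gene}"
            seqs[g][uid] = _mutate(ancestor, rates[g], rng).tobytes().decode()
            lengths[uid] = length
            ids[g] = uid
        if not missing:
            triplet_rows.append(
                dict(a_id=ids["A"], b_id=ids["B"], d_id=ids["D"], position=i)
            )
    truth = SimulatedTruth(
        true_triplets=pd.DataFrame(
            triplet_rows, columns=["a_id", "b_id", "d_id", "position"]
        ),
        true_order=order,
        sequences=seqs,
        gene_lengths=lengths,
        private=private,
    )
    return seqs["A"], seqs["B"], seqs["D"], truth


def plant_expression(truth: SimulatedTruth, config: SimConfig) -> np.ndarray:
    """Plant baseline abundances plus dominance/repression blocks.

    Returns an ``(n_triplets, 3, n_accessions)`` abundance array over
    genomes (A, B, D); also stored on ``truth.true_expression`` with
    labels on ``truth.true_classification``.  Baselines are log-normal
    per triplet and shared by the three homoeologues; accession-level
    noise is multiplicative log-normal with sd ``expression_sd`` on the
    natural-log scale.
    """
    n = config.n_triplets
    blocks = list(config.dominance_blocks) + list(config.repression_blocks)
    # reject overlapping planted blocks on the same genome
    for g in GENOMES:
        spans = sorted(
            (b.start, b.end) for b in blocks if b.genome == g
        )
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError(
                    f"overlapping planted blocks on genome {g}: "
                    f"[{s1},{e1}) and [{s2},{e2})"
                )
    rng = config.rng(2)
    baseline = np.exp(
        rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=n)
    )
    expected = np.repeat(baseline[:, None], 3, axis=1)  # (n, 3)
    labels = [None] * n
    gidx = {g: i for i, g in enumerate(GENOMES)}
    for b in config.dominance_blocks:
        expected[b.start : b.end, gidx[b.genome]] *= b.fold
        if b.fold > 1:
            for i in range(b.start, b.end):
                labels[i] = (b.genome, "up")
    for b in config.repression_blocks:
        expected[b.start : b.end, gidx[b.genome]] /= b.fold
        if b.fold > 1:
            for i in range(b.start, b.end):
                labels[i] = (b.genome, "down")
    noise = rng.normal(0.0, config.expression_sd, size=(n, 3, config.n_accessions)) \
        if config.expression_sd > 0 else np.zeros((n, 3, config.n_accessions))
    abundances = expected[:, :, None] * np.exp(noise)
    truth.true_expression = abundances
    truth.true_classification = pd.DataFrame(
        dict(
            triplet=list(range(n)),
            genome=[lab[0] if lab else None for lab in labels],
            direction=[lab[1] if lab else None for lab in labels],
        )
    )
    return abundances


def simulate_reads(
    sequences: Mapping[str, str],
    abundances: Mapping[str, float],
    config: SimConfig,
    rng: np.random.Generator | None = None,
    n_reads: int | None = None,
) -> list[tuple[str, str, str]]:
    """Draw error-bearing single-end reads from weighted transcripts.

    Sampling probability is abundance x transcript length (longer
    transcripts yield proportionally more fragments); start positions
    are uniform; per-base substitution errors occur at ``error_rate``.
    Returns ``(read id, sequence, quality)`` tuples with constant high
    qualities (the pipeline never consumes quality scores).
    """
    if rng is None:
        rng = config.rng(3)
    n_reads = config.reads_per_accession if n_reads is None else n_reads
    ids = list(sequences.keys())
    L = config.read_length
    lengths = np.array([len(sequences[i]) for i in ids], dtype=float)
    if (lengths < L).any():
        short = [i for i in ids if len(sequences[i]) < L]
        raise ValueError(
            f"read_length {L} exceeds shortest transcript ({short[:3]}...)"
        )
    w = np.array([max(float(abundances.get(i, 0.0)), 0.0) for i in ids])
    w = w * lengths
    total = w.sum()
    reads: list[tuple[str, str, str]] = []
    if total <= 0 or n_reads == 0:
        return reads
    counts = rng.multinomial(n_reads, w / total)
    qual = "I" * L
    for idx in np.nonzero(counts)[0]:
        tid = ids[idx]
        codes = np.frombuffer(sequences[tid].encode(), dtype=np.uint8)
        starts = rng.integers(0, len(codes) - L + 1, size=counts[idx])
        for j, s in enumerate(starts):
            r = codes[s : s + L]
            if config.error_rate > 0:
                r = _mutate(r, config.error_rate, rng)
            reads.append((f"{tid}:{s}:{j}", r.tobytes().decode(), qual))
    return reads


def write_fastq(reads: Sequence[tuple[str, str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def write_fasta(sequences: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for sid, seq in sequences.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def simulate_ssd_population(truth: SimulatedTruth, config: SimConfig) -> pd.DataFrame:
    """Genotype scoring strings for a single-seed descent population.

    Each line is a homozygous mosaic of the two parental genotypes with
    crossovers between adjacent markers following a Poisson process
    (``recombination_rate`` expected crossovers per interval; an odd
    crossover count flips the genotype).  Calls are 'A'/'B', replaced
    by '-' at ``missing_rate`` (and by 'H' at ``het_rate`` for residual
    heterozygosity robustness tests).  Rows are markers in true order;
    columns are lines.
    """
    rng = config.rng(4)
    m = len(truth.true_order)
    n = config.n_ssd_lines
    start = rng.integers(0, 2, size=n)  # 0 -> 'A', 1 -> 'B'
    xovers = rng.poisson(config.recombination_rate, size=(m - 1, n)) if m > 1 \
        else np.zeros((0, n), dtype=int)
    flips = np.cumsum(xovers % 2, axis=0)
    geno = np.vstack([np.zeros((1, n), dtype=int), flips]) + start[None, :]
    calls = np.where(geno % 2 == 0, "A", "B").astype("<U1")
    if config.het_rate > 0:
        calls[rng.random(size=calls.shape) < config.het_rate] = "H"
    if config.missing_rate > 0:
        calls[rng.random(size=calls.shape) < config.missing_rate] = "-"
    cols = [f"line_{i+1:02d}" for i in range(n)]
    return pd.DataFrame(calls, index=list(truth.true_order), columns=cols)


def simulate_rearranged_reference(
    truth: SimulatedTruth,
    n_blocks: int,
    seed: int = 0,
    gene_span: int = 3000,
    gene_spacing: int = 5000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A model-species gene order that is a block rearrangement of truth.

    The target (true) gene order is cut into ``n_blocks`` contiguous
    segments which are permuted and possibly inverted to produce the
    model genome order.  Returns ``(model_table, block_map)``:
    ``model_table`` has one row per gene in model-genome order with
    base-pair coordinates; ``block_map`` records, per block, its gene
    span in the model genome, its target position, and orientation.

    With ``n_blocks=1`` the model order equals the target order.
    """
    order = list(truth.true_order)
    m = len(order)
    if not (1 <= n_blocks <= m):
        raise ValueError("n_blocks must be in [1, number of genes]")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 5)))
    # block boundaries in target order
    if n_blocks == 1:
        bounds = [0, m]
        perm = np.array([0])
        inverted = np.array([False])
    else:
        cuts = np.sort(rng.choice(np.arange(1, m), size=n_blocks - 1, replace=False))
        bounds = [0] + cuts.tolist() + [m]
        perm = rng.permutation(n_blocks)
        inverted = rng.random(n_blocks) < 0.5
    target_blocks = [
        order[bounds[i] : bounds[i + 1]] for i in range(n_blocks)
    ]
    # model genome = permuted (and possibly inverted) target blocks
    rows = []
    block_rows = []
    pos = 0
    for model_rank, tgt_idx in enumerate(perm):
        genes = target_blocks[tgt_idx]
        inv = bool(inverted[model_rank])
        placed = genes[::-1] if inv else genes
        start_pos = pos
        for g in placed:
            rows.append(
                dict(
                    gene_id=f"Bd_{g}",
                    chrom="Bd1",
                    start=pos * gene_spacing,
                    end=pos * gene_spacing + gene_span,
                    strand="-" if inv else "+",
                )
            )
            pos += 1
        block_rows.append(
            dict(
                block_id=f"blk{model_rank:03d}",
                model_gene_start=start_pos,
                model_gene_end=pos,  # half-open gene-index span in model order
                target_rank=int(tgt_idx),
                target_gene_start=bounds[tgt_idx],
                target_gene_end=bounds[tgt_idx + 1],
                orientation="-" if inv else "+",
            )
        )
    model_table = pd.DataFrame(rows)
    block_map = pd.DataFrame(block_rows)
    return model_table, block_map


def simulate_trace_peaks(
    ihps,
    true_abundances: Mapping[str, float],
    noise: float = 0.0,
    seed: int = 0,
    scale: float = 1000.0,
) -> pd.DataFrame:
    """Sanger-style peak heights at interhomoeologue polymorphisms.

    The variant-base peak is proportional to the variant genome's
    transcript abundance; the shared (ancestral) base peak to the sum
    of the other two genomes' abundances.  Multiplicative log-normal
    noise with sd ``noise`` is applied to each height independently.
    ``ihps`` may be a sequence of objects with a ``variant_genome``
    attribute or of genome letters.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 6)))
    rows = []
    for i, ihp in enumerate(ihps):
        g = getattr(ihp, "variant_genome", ihp)
        if g not in GENOMES:
            raise ValueError(f"unknown variant genome {g!r}")
        others = [x for x in GENOMES if x != g]
        var = scale * float(true_abundances[g])
        anc = scale * sum(float(true_abundances[x]) for x in others)
        if noise > 0:
            var *= math.exp(rng.normal(0.0, noise))
            anc *= math.exp(rng.normal(0.0, noise))
        rows.append(
            dict(
                ihp=i,
                variant_genome=g,
                variant_height=var,
                ancestral_height=anc,
                ratio=var / anc if anc > 0 else np.inf,
            )
        )
    return pd.DataFrame(rows)
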