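"""Ground-truth generators for every input class the pipeline consumes.

The pipeline's real inputs (isolate genomes, metagenome bins, read pools,
BGC predictions) live behind sequencing archives; this module emulates each
of them with known ground truth so that every downstream stage is testable
hermetically:

* genomes at controlled pairwise nucleotide divergence (substitution-only,
  so expected identity is exactly 1 - d);
* contig bins assembled as fragmented mixtures of closely related strains;
* shotgun read pools from weighted strain mixtures, with a truth table;
* marker-gene read pools from strain haplotypes with planted SNPs;
* BGC families with controlled protein divergence and terminal truncation.

All generators take an integer seed and are byte-deterministic given it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .core_io import BgcGene, BgcRecord, ContigBin, GenomeRecord

NUCLEOTIDES = np.array(list("ACGT"))
AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Ground-truth carriers
# ---------------------------------------------------------------------------


@dataclass
class MutationLog:
    """Record of every substitution applied by :func:`mutate_genome`."""

    parent_id: str
    child_id: str
    substitutions: list[tuple[str, int, str, str]]  # (contig, pos, from, to)
    realized_divergence: float


@dataclass
class PlantedFamilyLabel:
    """Ground truth attached to each BGC produced by :func:`make_bgc_family`."""

    bgc_id: str
    family_id: str
    truncation_fraction: float
    protein_divergence: float


# ---------------------------------------------------------------------------
# Nucleotide generators
# ---------------------------------------------------------------------------


def random_genome(
    genome_id: str,
    length: int,
    seed: int,
    n_contigs: int = 1,
) -> GenomeRecord:
    """A uniform-random nucleotide genome split into equal-sized contigs."""
    rng = np.random.default_rng(seed)
    bases = rng.choice(NUCLEOTIDES, size=length)
    per = length // n_contigs
    contigs = []
    for i in range(n_contigs):
        start = i * per
        end = length if i == n_contigs - 1 else (i + 1) * per
        contigs.append((f"{genome_id}_c{i}", "".join(bases[start:end])))
    return GenomeRecord(id=genome_id, contigs=contigs)


def mutate_genome(
    parent: GenomeRecord,
    divergence: float,
    seed: int,
    child_id: Optional[str] = None,
) -> tuple[GenomeRecord, MutationLog]:
    """Derive a strain at a fixed substitution divergence from ``parent``.

    Exactly ``round(divergence * genome length)`` positions, chosen uniformly
    without replacement across the whole genome, are substituted to a
    different base. Indels are deliberately excluded so that per-site
    identity between parent and child is analytically ``1 - divergence``.
    """
    if not 0.0 <= divergence < 0.5:
        raise ValueError(f"divergence must lie in [0, 0.5), got {divergence}")
    rng = np.random.default_rng(seed)
    child_id = child_id or f"{parent.id}_d{divergence:g}_s{seed}"

    total = parent.total_length
    n_subs = int(round(divergence * total))
    # map flat genome positions onto (contig, offset)
    boundaries = np.cumsum([len(seq) for _, seq in parent.contigs])
    flat_positions = rng.choice(total, size=n_subs, replace=False)
    flat_positions.sort()

    seqs = {cid: np.frombuffer(seq.encode(), dtype="S1").copy() for cid, seq in parent.contigs}
    log: list[tuple[str, int, str, str]] = []
    for pos in flat_positions:
        ci = int(np.searchsorted(boundaries, pos, side="right"))
        offset = int(pos - (boundaries[ci - 1] if ci else 0))
        cid = parent.contigs[ci][0]
        old = seqs[cid][offset].decode()
        choices = [b for b in "ACGT" if b != old]
        new = choices[rng.integers(len(choices))]
        seqs[cid][offset] = new.encode()
        log.append((cid, offset, old, new))

    child = GenomeRecord(
        id=child_id,
        contigs=[(cid, seqs[cid].tobytes().decode()) for cid, _ in parent.contigs],
    )
    return child, MutationLog(parent.id, child_id, log, n_subs / total)


FragmentLengths = Callable[[np.random.Generator], int]


def normal_fragment_lengths(mean_bp: int, sd_bp: int, min_bp: int = 500) -> FragmentLengths:
    """Truncated-normal contig length model for synthetic bins."""

    def draw(rng: np.random.Generator) -> int:
        return max(min_bp, int(round(rng.normal(mean_bp, sd_bp))))

    return draw


def make_bin(
    sources: Sequence[tuple[GenomeRecord, float]],
    fragment_length_distribution: FragmentLengths | int,
    seed: int,
    n_fragments: int = 50,
    bin_id: str = "bin0",
    specimen_id: str = "spec0",
) -> ContigBin:
    """Assemble a synthetic metagenome bin as fragments of source strains.

    Each contig is a verbatim subsequence of one source genome, the source
    chosen with the given weights; per-contig provenance is recorded on the
    returned bin so downstream assignments can be scored.
    """
    weights = np.array([w for _, w in sources], dtype=float)
    if (weights <= 0).any():
        raise ValueError("source weights must be positive")
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("source weights must sum to 1")
    rng = np.random.default_rng(seed)
    draw_len = (
        (lambda _rng: fragment_length_distribution)
        if isinstance(fragment_length_distribution, int)
        else fragment_length_distribution
    )
    contigs: list[tuple[str, str]] = []
    provenance: list[str] = []
    for i in range(n_fragments):
        si = rng.choice(len(sources), p=weights)
        genome = sources[si][0]
        frag_len = draw_len(rng)
        # pick a contig long enough to host the fragment
        eligible = [(cid, s) for cid, s in genome.contigs if len(s) >= frag_len]
        if not eligible:
            raise ValueError(
                f"fragment of {frag_len} bp exceeds every contig of {genome.id}"
            )
        cid, seq = eligible[rng.integers(len(eligible))]
        start = int(rng.integers(0, len(seq) - frag_len + 1))
        contigs.append((f"{bin_id}_f{i}", seq[start : start + frag_len]))
        provenance.append(genome.id)
    return ContigBin(
        bin_id=bin_id,
        specimen_id=specimen_id,
        contigs=contigs,
        provenance=provenance,
    )


def simulate_reads(
    sources: Sequence[tuple[GenomeRecord, float]],
    n_reads: int,
    read_length: int,
    error_rate: float,
    seed: int,
) -> tuple[list[tuple[str, str]], dict[str, str]]:
    """Shotgun reads from a weighted genome mixture, with a truth table.

    Start positions are uniform, both strands are sampled with probability
    1/2, and sequencing error is substitution-only at the given per-base
    rate. Returns ``(reads, truth)`` where ``truth[read_id]`` names the
    source genome.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if not 0.0 <= error_rate < 0.1:
        raise ValueError("error_rate must lie in [0, 0.1)")
    weights = np.array([w for _, w in sources], dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("source weights must sum to 1")
    for genome, _ in sources:
        shortest = min(len(s) for _, s in genome.contigs)
        if read_length > shortest:
            raise ValueError(
                f"read_length {read_length} exceeds shortest contig of {genome.id}"
            )
    rng = np.random.default_rng(seed)
    reads: list[tuple[str, str]] = []
    truth: dict[str, str] = {}
    for i in range(n_reads):
        si = rng.choice(len(sources), p=weights)
        genome = sources[si][0]
        # weight contigs by length so coverage is uniform across the genome
        lens = np.array([len(s) for _, s in genome.contigs], dtype=float)
        ci = rng.choice(len(genome.contigs), p=lens / lens.sum())
        seq = genome.contigs[ci][1]
        start = int(rng.integers(0, len(seq) - read_length + 1))
        read = seq[start : start + read_length]
        if rng.random() < 0.5:
            read = reverse_complement(read)
        if error_rate > 0:
            arr = np.frombuffer(read.encode(), dtype="S1").copy()
            err = rng.random(read_length) < error_rate
            for pos in np.nonzero(err)[0]:
                old = arr[pos].decode()
                choices = [b for b in "ACGT" if b != old]
                arr[pos] = choices[rng.integers(3)].encode()
            read = arr.tobytes().decode()
        rid = f"read_{i}"
        reads.append((rid, read))
        truth[rid] = genome.id
    return reads, truth


def make_marker_mixture(
    marker: str,
    strain_snp_sets: Sequence[Sequence[tuple[int, str]]],
    proportions: Sequence[float],
    n_reads: int,
    read_length: int,
    seed: int,
    error_rate: float = 0.0,
) -> tuple[list[tuple[str, str]], dict[str, float], dict[str, int]]:
    """Marker-gene reads from a mixture of strain haplotypes.

    Each strain is the reference marker with its SNP list applied
    (``(position, alt_base)`` pairs, 0-based). Returns ``(reads,
    truth_proportions, truth_counts)`` keyed by strain label ``strain<i>``.
    """
    if len(strain_snp_sets) != len(proportions):
        raise ValueError("one proportion per strain required")
    props = np.array(proportions, dtype=float)
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    haplotypes: list[str] = []
    for si, snps in enumerate(strain_snp_sets):
        seen: dict[int, str] = {}
        hap = list(marker)
        for pos, alt in snps:
            if not 0 <= pos < len(marker):
                raise ValueError(f"SNP position {pos} outside marker")
            if pos in seen and seen[pos] != alt:
                raise ValueError(
                    f"strain {si} defines contradictory alleles at position {pos}"
                )
            seen[pos] = alt
            hap[pos] = alt
        haplotypes.append("".join(hap))
    if read_length > len(marker):
        raise ValueError("read_length exceeds marker length")

    rng = np.random.default_rng(seed)
    reads: list[tuple[str, str]] = []
    counts = {f"strain{i}": 0 for i in range(len(haplotypes))}
    for i in range(n_reads):
        si = int(rng.choice(len(haplotypes), p=props))
        hap = haplotypes[si]
        start = int(rng.integers(0, len(hap) - read_length + 1))
        read = hap[start : start + read_length]
        if error_rate > 0:
            chars = list(read)
            for pos in np.nonzero(rng.random(read_length) < error_rate)[0]:
                choices = [b for b in "ACGT" if b != chars[pos]]
                chars[pos] = choices[rng.integers(3)]
            read = "".join(chars)
        if rng.random() < 0.5:
            read = reverse_complement(read)
        reads.append((f"mread_{i}", read))
        counts[f"strain{si}"] += 1
    truth_props = {k: v / n_reads for k, v in counts.items()}
    return reads, truth_props, counts


# ---------------------------------------------------------------------------
# BGC generators
# ---------------------------------------------------------------------------


def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(AMINO_ACIDS, size=length))


def make_prototype_bgc(
    bgc_id: str,
    n_genes: int,
    seed: int,
    gene_length: int = 150,
    product_classes: Optional[set[str]] = None,
    origin_id: str = "isolate0",
    n_core: int = 2,
) -> BgcRecord:
    """A random full-length BGC to seed a planted family."""
    rng = np.random.default_rng(seed)
    genes = [
        BgcGene(f"{bgc_id}_g{i}", random_protein(gene_length, rng), is_core=i < n_core)
        for i in range(n_genes)
    ]
    return BgcRecord(
        bgc_id=bgc_id,
        source="isolate",
        origin_id=origin_id,
        product_classes=product_classes or {"t1pks"},
        genes=genes,
        span_bp=n_genes * gene_length * 3,
    )


def mutate_protein(protein: str, divergence: float, rng: np.random.Generator) -> str:
    """Substitute exactly ``round(divergence * length)`` residues."""
    n_mut = int(round(divergence * len(protein)))
    if n_mut == 0:
        return protein
    positions = rng.choice(len(protein), size=n_mut, replace=False)
    chars = list(protein)
    for pos in positions:
        choices = [a for a in "ACDEFGHIKLMNPQRSTVWY" if a != chars[pos]]
        chars[pos] = choices[rng.integers(len(choices))]
    return "".join(chars)


def make_bgc_family(
    prototype: BgcRecord,
    n_variants: int,
    max_truncation: float,
    max_protein_divergence: float,
    seed: int,
    family_id: Optional[str] = None,
    source: str = "metagenome",
) -> list[tuple[BgcRecord, PlantedFamilyLabel]]:
    """Planted family of BGC variants around a prototype.

    Each variant drops a contiguous terminal run of genes (prefix or suffix
    — mimicking how assembly fragmentation truncates clusters at contig
    edges) with a truncation fraction drawn uniformly on
    ``[0, max_truncation]``, then substitutes residues of the surviving
    proteins at a per-variant divergence drawn uniformly on
    ``[0, max_protein_divergence]``.
    """
    if prototype.n_genes < 4:
        raise ValueError("prototype must have at least 4 genes")
    if not 0.0 <= max_truncation < 1.0:
        raise ValueError("max_truncation must lie in [0, 1)")
    family_id = family_id or f"fam_{prototype.bgc_id}"
    rng = np.random.default_rng(seed)
    out: list[tuple[BgcRecord, PlantedFamilyLabel]] = []
    for vi in range(n_variants):
        trunc = float(rng.uniform(0.0, max_truncation)) if max_truncation > 0 else 0.0
        n_drop = int(round(trunc * prototype.n_genes))
        if n_drop >= prototype.n_genes:
            raise ValueError("truncation would leave no genes")
        if n_drop == 0:
            kept = list(prototype.genes)
        elif rng.random() < 0.5:
            kept = list(prototype.genes[n_drop:])
        else:
            kept = list(prototype.genes[: prototype.n_genes - n_drop])
        div = (
            float(rng.uniform(0.0, max_protein_divergence))
            if max_protein_divergence > 0
            else 0.0
        )
        bgc_id = f"{family_id}_v{vi}"
        genes = [
            BgcGene(f"{bgc_id}_{g.gene_id}", mutate_protein(g.protein, div, rng), g.is_core)
            for g in kept
        ]
        record = BgcRecord(
            bgc_id=bgc_id,
            source=source,
            origin_id=f"specimen_{vi}",
            product_classes=set(prototype.product_classes),
            genes=genes,
            span_bp=sum(len(g.protein) for g in genes) * 3,
        )
        out.append(
            (record, PlantedFamilyLabel(bgc_id, family_id, n_drop / prototype.n_genes, div))
        )
    return out
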