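"""Domain types and on-disk formats for the symbiont-metagenome pipeline.

This module holds the package's core records (genomes, metagenome contig
bins, biosynthetic gene clusters) together with the readers and writers for
every format the pipeline touches: FASTA for nucleotide sequences, a JSON
interchange format for BGCs (the canonical carrier), a best-effort adapter
for antiSMASH-style annotated GenBank, and TSV metadata tables.

Coordinate convention: 0-based half-open everywhere internally; 1-based
coordinates appear only at the GenBank boundary, where Biopython already
performs the conversion.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("symbionet")

#: Nucleotide alphabet accepted by every parser. Ambiguity codes other than
#: N are rejected because downstream identity arithmetic assumes four letters.
NUCLEOTIDE_ALPHABET = frozenset("ACGTN")

#: 20 amino acids plus X (unknown residue) and * (stop, GenBank translations).
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")

#: Product-class families retained by the downstream class filter.
CANONICAL_CLASS_FAMILIES = frozenset(
    {"pks", "nrps", "siderophore", "terpene", "hserlactone", "thiopeptide"}
)

INTERCHANGE_FORMAT_TAG = "symbionet-bgc-1"


class ParseError(ValueError):
    """Raised when an on-disk record violates the documented schema."""


def configure_logging(level: str = "INFO") -> None:
    """Initialise the package logger (used by the CLI entry point)."""
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


def _validate_nucleotide(seq: str, label: str) -> None:
    if not seq:
        raise ParseError(f"empty sequence for {label}")
    bad = set(seq.upper()) - NUCLEOTIDE_ALPHABET
    if bad:
        raise ParseError(
            f"sequence {label} contains disallowed characters {sorted(bad)}; "
            "only A,C,G,T,N are accepted"
        )


@dataclass
class GenomeRecord:
    """A named set of nucleotide contigs (isolate genome or reference)."""

    id: str
    contigs: list[tuple[str, str]]  # (contig_id, sequence)

    def __post_init__(self) -> None:
        ids = [cid for cid, _ in self.contigs]
        if len(ids) != len(set(ids)):
            raise ParseError(f"duplicate contig ids in genome {self.id}")
        for cid, seq in self.contigs:
            _validate_nucleotide(seq, f"{self.id}/{cid}")

    @property
    def total_length(self) -> int:
        return sum(len(seq) for _, seq in self.contigs)

    def sequence_of(self, contig_id: str) -> str:
        for cid, seq in self.contigs:
            if cid == contig_id:
                return seq
        raise KeyError(contig_id)


@dataclass
class ContigBin:
    """A metagenome bin: contigs plus specimen provenance and annotations.

    ``gene_taxa`` carries per-gene taxonomy labels from an injectable oracle
    (each label one of ``bacterial``, ``non-bacterial``, ``unassigned``);
    ``coding_density`` is the fraction of the bin covered by predicted genes.
    Both are optional because they only exist after annotation.
    """

    bin_id: str
    specimen_id: str
    contigs: list[tuple[str, str]]
    coding_density: Optional[float] = None
    gene_taxa: Optional[list[str]] = None
    provenance: Optional[list[str]] = None  # per-contig source genome ids

    def __post_init__(self) -> None:
        ids = [cid for cid, _ in self.contigs]
        if len(ids) != len(set(ids)):
            raise ParseError(f"duplicate contig ids in bin {self.bin_id}")
        for cid, seq in self.contigs:
            _validate_nucleotide(seq, f"{self.bin_id}/{cid}")
        if self.coding_density is not None and not 0.0 <= self.coding_density <= 1.0:
            raise ValueError(
                f"coding_density must lie in [0,1], got {self.coding_density}"
            )
        if self.gene_taxa is not None:
            allowed = {"bacterial", "non-bacterial", "unassigned"}
            bad = set(self.gene_taxa) - allowed
            if bad:
                raise ValueError(f"unknown gene taxonomy labels: {sorted(bad)}")

    @property
    def total_length(self) -> int:
        return sum(len(seq) for _, seq in self.contigs)


@dataclass
class BgcGene:
    gene_id: str
    protein: str
    is_core: bool = False

    def __post_init__(self) -> None:
        if not self.protein:
            raise ParseError(f"gene {self.gene_id} has an empty protein sequence")
        bad = set(self.protein.upper()) - PROTEIN_ALPHABET
        if bad:
            raise ParseError(
                f"gene {self.gene_id} protein contains non-amino-acid "
                f"characters {sorted(bad)}"
            )


@dataclass
class BgcRecord:
    """A biosynthetic gene cluster: ordered genes with protein translations.

    Gene order follows genomic coordinates of the source cluster. ``locus``
    optionally records where on which contig the cluster sits (0-based
    half-open), which the occurrence stage uses to deduplicate evidence.
    """

    bgc_id: str
    source: str  # "isolate" | "metagenome"
    origin_id: str  # strain or specimen id
    product_classes: set[str]
    genes: list[BgcGene]
    span_bp: int
    locus: Optional[tuple[str, int, int]] = None  # (contig_id, start, end)

    def __post_init__(self) -> None:
        if self.source not in {"isolate", "metagenome"}:
            raise ParseError(
                f"BGC {self.bgc_id}: source must be isolate|metagenome, "
                f"got {self.source!r}"
            )
        if not self.genes:
            raise ParseError(f"BGC {self.bgc_id} has no genes")
        self.product_classes = {c.lower() for c in self.product_classes}

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def class_families(self) -> set[str]:
        """Map raw product-class labels onto canonical families.

        antiSMASH subtypes such as ``t1pks`` or ``transatpks`` all belong to
        the ``pks`` family; ``homoserine lactone`` synonyms map to
        ``hserlactone``.
        """
        fams: set[str] = set()
        for label in self.product_classes:
            key = label.replace(" ", "").replace("-", "").replace("_", "")
            if "pks" in key:
                fams.add("pks")
            elif "nrps" in key:
                fams.add("nrps")
            elif "siderophore" in key:
                fams.add("siderophore")
            elif "terpene" in key:
                fams.add("terpene")
            elif "hserlactone" in key or "homoserinelactone" in key:
                fams.add("hserlactone")
            elif "thiopeptide" in key:
                fams.add("thiopeptide")
            else:
                fams.add(key)
        return fams


@dataclass
class AssemblyStats:
    n_contigs: int
    total_bp: int
    n50: int


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta_genome(path: str | Path, genome_id: Optional[str] = None) -> GenomeRecord:
    """Read a nucleotide FASTA file into a :class:`GenomeRecord`."""
    path = Path(path)
    contigs = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not contigs:
        raise ParseError(f"no FASTA records in {path}")
    return GenomeRecord(id=genome_id or path.stem, contigs=contigs)


def write_fasta(path: str | Path, contigs: Iterable[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for cid, seq in contigs:
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_reads_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read unpaired reads from FASTA or FASTQ (detected from the extension)."""
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in {".fastq", ".fq"} else "fasta"
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), fmt)]


# ---------------------------------------------------------------------------
# BGC interchange JSON (canonical carrier)
# ---------------------------------------------------------------------------


def write_bgc_interchange(path: str | Path, records: Sequence[BgcRecord]) -> None:
    """Serialise BGC records to the interchange JSON schema."""
    payload = {
        "format": INTERCHANGE_FORMAT_TAG,
        "clusters": [
            {
                "bgc_id": r.bgc_id,
                "source": r.source,
                "origin_id": r.origin_id,
                "product_classes": sorted(r.product_classes),
                "span_bp": r.span_bp,
                "locus": list(r.locus) if r.locus else None,
                "genes": [
                    {"gene_id": g.gene_id, "protein": g.protein, "is_core": g.is_core}
                    for g in r.genes
                ],
            }
            for r in records
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def parse_bgc_interchange(path: str | Path) -> list[BgcRecord]:
    """Parse BGC records from interchange JSON or annotated GenBank.

    The JSON schema is canonical; files ending in ``.gb``/``.gbk``/``.genbank``
    are routed to the antiSMASH-style GenBank adapter. An empty cluster list
    returns an empty list with a warning (an empty file is not an error).
    """
    path = Path(path)
    if path.suffix.lower() in {".gb", ".gbk", ".genbank"}:
        return parse_antismash_genbank(path)
    try:
        with open(path) as fh:
            text = fh.read()
    except OSError as exc:
        raise ParseError(f"cannot read {path}: {exc}") from exc
    if not text.strip():
        logger.warning("empty BGC interchange file: %s", path)
        return []
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path} is not valid JSON: {exc}") from exc
    clusters = payload.get("clusters", [])
    if not clusters:
        logger.warning("BGC interchange file %s contains no clusters", path)
        return []
    records = []
    for entry in clusters:
        bgc_id = entry.get("bgc_id", "<missing bgc_id>")
        try:
            genes = [
                BgcGene(g["gene_id"], g["protein"], bool(g.get("is_core", False)))
                for g in entry["genes"]
            ]
            locus = tuple(entry["locus"]) if entry.get("locus") else None
            records.append(
                BgcRecord(
                    bgc_id=entry["bgc_id"],
                    source=entry["source"],
                    origin_id=entry["origin_id"],
                    product_classes=set(entry["product_classes"]),
                    genes=genes,
                    span_bp=int(entry["span_bp"]),
                    locus=locus,  # type: ignore[arg-type]
                )
            )
        except (KeyError, TypeError, ParseError) as exc:
            raise ParseError(f"malformed cluster {bgc_id!r} in {path}: {exc}") from exc
    return records


def parse_antismash_genbank(
    path: str | Path, min_contig_bp: int = 500
) -> list[BgcRecord]:
    """Best-effort reader for antiSMASH-style annotated GenBank.

    Each record containing a ``cluster``/``region``/``protocluster`` feature
    yields one :class:`BgcRecord` whose genes are the CDS features inside the
    cluster span, ordered by genomic coordinate. Records shorter than
    ``min_contig_bp`` are skipped (short metagenome contigs carry unreliable
    predictions).
    """
    records: list[BgcRecord] = []
    for gb in SeqIO.parse(str(path), "genbank"):
        if len(gb.seq) < min_contig_bp:
            logger.info("skipping %s: shorter than %d bp", gb.id, min_contig_bp)
            continue
        cluster_feats = [
            f for f in gb.features if f.type in {"cluster", "region", "protocluster"}
        ]
        cds_feats = sorted(
            (f for f in gb.features if f.type == "CDS"),
            key=lambda f: int(f.location.start),
        )
        for idx, cf in enumerate(cluster_feats):
            product = cf.qualifiers.get("product", cf.qualifiers.get("product_class", []))
            classes = set()
            for p in product:
                classes.update(x.strip().lower() for x in p.split("-") if x.strip())
            start, end = int(cf.location.start), int(cf.location.end)
            genes = []
            for cds in cds_feats:
                if int(cds.location.start) >= start and int(cds.location.end) <= end:
                    trans = cds.qualifiers.get("translation")
                    if not trans:
                        continue
                    gene_id = cds.qualifiers.get(
                        "locus_tag", cds.qualifiers.get("gene", [f"cds_{len(genes)}"])
                    )[0]
                    core = "sec_met" in cds.qualifiers or (
                        cds.qualifiers.get("gene_kind", [""])[0] == "biosynthetic"
                    )
                    genes.append(BgcGene(gene_id, trans[0].rstrip("*"), core))
            bgc_id = f"{gb.id}.cluster{idx + 1}"
            if not genes:
                raise ParseError(
                    f"cluster {bgc_id} in {path} has no CDS features with translations"
                )
            records.append(
                BgcRecord(
                    bgc_id=bgc_id,
                    source="metagenome",
                    origin_id=gb.id,
                    product_classes=classes or {"unknown"},
                    genes=genes,
                    span_bp=end - start,
                    locus=(gb.id, start, end),
                )
            )
    return records


# ---------------------------------------------------------------------------
# Metadata tables
# ---------------------------------------------------------------------------


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    """Read a specimen/bin metadata table (TSV with a header row).

    Expected columns include ``specimen_id`` and ``species``; ``bin_id`` and
    ``reference_id`` columns are passed through when present.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "specimen_id" not in df.columns:
        raise ParseError(f"metadata table {path} lacks a specimen_id column")
    return df


# ---------------------------------------------------------------------------
# Assembly statistics
# ---------------------------------------------------------------------------


def compute_assembly_stats(record: GenomeRecord | ContigBin) -> AssemblyStats:
    """N50 and size statistics for a genome or bin.

    N50 is the largest contig length L such that contigs of length >= L sum
    to at least half of the total assembly size.
    """
    lengths = sorted((len(seq) for _, seq in record.contigs), reverse=True)
    if not lengths:
        raise ValueError("cannot compute assembly statistics for an empty record")
    total = sum(lengths)
    running = 0
    n50 = lengths[-1]
    for L in lengths:
        running += L
        if 2 * running >= total:
            n50 = L
            break
    return AssemblyStats(n_contigs=len(lengths), total_bp=total, n50=n50)
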