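"""BGC similarity networking and gene cluster family (GCF) assignment.

Class-filtered BGCs are compared all-versus-all at the protein level. A
directional cluster-to-cluster hit exists when enough of the query's genes
find homologs in the subject; its score rewards both the number of shared
genes and the conservation of their order (synteny). Bidirectional hits are
reliable edges outright. Single-directional hits — typically a fragmented
metagenome cluster hitting a full-length cluster — are retained only after a
stricter per-gene refinement: with n the gene count of the truncated member,
at least n - 2 of its genes must have strict hits (>= 60% identity, >= 80%
coverage of both sequences) in the partner. GCFs are the connected
components of the resulting network.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Optional, Sequence

import edlib
import networkx as nx
from Bio.Align import PairwiseAligner, substitution_matrices

from .core_io import CANONICAL_CLASS_FAMILIES, BgcRecord

logger = logging.getLogger("symbionet")

# loose tier mirrors a default protein-protein search; strict tier is the
# published refinement threshold (60% identity, 80% coverage of both)
LOOSE_IDENTITY, LOOSE_COVERAGE = 30.0, 25.0
STRICT_IDENTITY, STRICT_COVERAGE = 60.0, 80.0


@dataclass
class GeneHit:
    query_gene_id: str
    subject_gene_id: str
    identity_pct: float
    query_coverage_pct: float
    subject_coverage_pct: float
    bitlike_score: float


@dataclass
class DirectionalHit:
    query_bgc: str
    subject_bgc: str
    n_query_genes: int
    shared_genes: int
    synteny_weight: float
    score: float


@dataclass
class GcfNetwork:
    graph: nx.Graph  # nodes: bgc ids; edges carry weight and edge_type
    gcf_of: dict[str, str] = field(default_factory=dict)


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "local"
    return aligner


_ALIGNER = _make_aligner()


#: edit-distance prescreen: the shorter protein must align within the longer
#: at <= this fraction of its length in edits, or the pair is skipped before
#: the (much costlier) scored local alignment. Unrelated proteins sit near
#: 0.9; homologs at the loose identity tier sit well below 0.75.
PRESCREEN_MAX_ED_FRACTION = 0.75


@lru_cache(maxsize=1 << 18)
def _align_cached(query: str, subject: str):
    short, long_ = (query, subject) if len(query) <= len(subject) else (subject, query)
    k = int(len(short) * PRESCREEN_MAX_ED_FRACTION)
    if edlib.align(short, long_, mode="HW", task="distance", k=k)["editDistance"] < 0:
        return None
    try:
        alignments = _ALIGNER.align(query, subject)
        if len(alignments) == 0:
            return None
        best = alignments[0]
    except (ValueError, OverflowError) as exc:
        raise ValueError(f"cannot align protein sequences: {exc}") from exc
    c = best.counts()
    aligned_cols = c.identities + c.mismatches + c.gaps
    if aligned_cols == 0:
        return None
    q_ranges, s_ranges = best.aligned
    q_span = int(q_ranges[-1][1] - q_ranges[0][0])
    s_span = int(s_ranges[-1][1] - s_ranges[0][0])
    return (
        100.0 * c.identities / aligned_cols,
        100.0 * q_span / len(query),
        100.0 * s_span / len(subject),
        float(best.score),
    )


def align_proteins(query: str, subject: str) -> Optional[GeneHit]:
    """Best local alignment statistics for one protein pair (or None).

    Pairs failing a fast edit-distance prescreen are reported as no hit
    without running the scored alignment.
    """
    res = _align_cached(query.upper().rstrip("*"), subject.upper().rstrip("*"))
    if res is None:
        return None
    identity, q_cov, s_cov, score = res
    return GeneHit(
        query_gene_id="",
        subject_gene_id="",
        identity_pct=identity,
        query_coverage_pct=q_cov,
        subject_coverage_pct=s_cov,
        bitlike_score=score,
    )


def gene_hits(a: BgcRecord, b: BgcRecord, tier: str = "loose") -> list[GeneHit]:
    """Best subject hit per query gene, at the loose or strict threshold tier."""
    if tier == "loose":
        min_id, min_cov = LOOSE_IDENTITY, LOOSE_COVERAGE
    elif tier == "strict":
        min_id, min_cov = STRICT_IDENTITY, STRICT_COVERAGE
    else:
        raise ValueError(f"unknown tier {tier!r}")
    hits: list[GeneHit] = []
    for qg in a.genes:
        best: Optional[GeneHit] = None
        for sg in b.genes:
            h = align_proteins(qg.protein, sg.protein)
            if h is None:
                continue
            if (
                h.identity_pct >= min_id
                and h.query_coverage_pct >= min_cov
                and h.subject_coverage_pct >= min_cov
            ):
                if best is None or h.bitlike_score > best.bitlike_score:
                    h.query_gene_id = qg.gene_id
                    h.subject_gene_id = sg.gene_id
                    best = h
        if best is not None:
            hits.append(best)
    return hits


def filter_bgc_classes(records: Sequence[BgcRecord]) -> list[BgcRecord]:
    """Keep clusters of the retained biosynthetic families (and hybrids).

    Retained families: PKS, NRPS, siderophore, terpene, homoserine lactone,
    thiopeptide; a hybrid passes if any of its classes belongs to the set.
    Input order is preserved.
    """
    return [
        r for r in records if r.class_families() & CANONICAL_CLASS_FAMILIES
    ]


def _longest_increasing(seq: Sequence[int]) -> int:
    if not seq:
        return 0
    tails: list[int] = []
    for x in seq:
        i = bisect.bisect_left(tails, x)
        if i == len(tails):
            tails.append(x)
        else:
            tails[i] = x
    return len(tails)


def directional_hit(
    query: BgcRecord, subject: BgcRecord, min_shared: int = 3
) -> Optional[DirectionalHit]:
    """Cluster-to-cluster hit from query into subject.

    ``shared_genes`` counts query genes with a loose-tier homolog in the
    subject; ``synteny_weight`` is the fraction of those homologs whose order
    is conserved (longest run of co-linear hits / shared genes); the score is
    ``shared * (1 + synteny)``. A hit is declared only when at least
    ``min_shared`` genes are shared.
    """
    hits = gene_hits(query, subject, tier="loose")
    shared = len(hits)
    if shared < min_shared:
        return None
    subject_index = {g.gene_id: i for i, g in enumerate(subject.genes)}
    # hits are in query gene order; co-linearity = increasing subject indices
    order = [subject_index[h.subject_gene_id] for h in hits]
    synteny = _longest_increasing(order) / shared
    return DirectionalHit(
        query_bgc=query.bgc_id,
        subject_bgc=subject.bgc_id,
        n_query_genes=query.n_genes,
        shared_genes=shared,
        synteny_weight=synteny,
        score=shared * (1.0 + synteny),
    )


def all_directional_hits(
    records: Sequence[BgcRecord], min_shared: int = 3
) -> list[DirectionalHit]:
    """All-versus-all directional hits over distinct ordered pairs."""
    out = []
    for a in records:
        for b in records:
            if a.bgc_id == b.bgc_id:
                continue
            h = directional_hit(a, b, min_shared=min_shared)
            if h is not None:
                out.append(h)
    return out


def refine_single_directional(
    truncated: BgcRecord, partner: BgcRecord
) -> tuple[bool, int]:
    """The n-2 refinement for a single-directional hit.

    With n the gene count of the truncated member and s its genes with
    strict-tier hits in the partner, the hit is retained iff
    ``s >= max(n - 2, 1)`` (the floor avoids evidence-free edges for tiny
    clusters where n - 2 <= 0). Returns ``(retained, s)``.
    """
    s = len(gene_hits(truncated, partner, tier="strict"))
    n = truncated.n_genes
    return s >= max(n - 2, 1), s


def refine_and_build(
    hits: Iterable[DirectionalHit], records: Sequence[BgcRecord]
) -> GcfNetwork:
    """Build the GCF network from directional hits.

    Pairs with hits in both directions get a ``bidirectional`` edge. Pairs
    with a single-directional hit are re-examined with the strict per-gene
    refinement applied to the truncated member (the cluster with fewer
    genes, the shorter fragment under metagenome fragmentation); surviving
    pairs get a ``refined_single`` edge. GCFs are connected components,
    numbered by descending size then by lexicographically smallest member.
    """
    by_id = {r.bgc_id: r for r in records}
    directed: dict[tuple[str, str], DirectionalHit] = {
        (h.query_bgc, h.subject_bgc): h for h in hits
    }
    graph = nx.Graph()
    for r in records:
        graph.add_node(r.bgc_id, source=r.source, origin=r.origin_id)

    seen_pairs = set()
    for (q, s), h in sorted(directed.items()):
        pair = tuple(sorted((q, s)))
        if pair in seen_pairs:
            continue
        seen_pairs.add(pair)
        back = directed.get((s, q))
        if back is not None:
            weight = (h.score + back.score) / 2.0
            graph.add_edge(q, s, weight=weight, edge_type="bidirectional")
        else:
            truncated, partner = (
                (by_id[q], by_id[s])
                if (by_id[q].n_genes, q) <= (by_id[s].n_genes, s)
                else (by_id[s], by_id[q])
            )
            retained, _ = refine_single_directional(truncated, partner)
            if retained:
                graph.add_edge(q, s, weight=h.score, edge_type="refined_single")

    components = sorted(
        (sorted(c) for c in nx.connected_components(graph)),
        key=lambda c: (-len(c), c[0]),
    )
    gcf_of = {}
    for i, comp in enumerate(components, start=1):
        for node in comp:
            gcf_of[node] = f"GCF_{i}"
            graph.nodes[node]["gcf"] = f"GCF_{i}"
    return GcfNetwork(graph=graph, gcf_of=gcf_of)


def write_graphml(network: GcfNetwork, path) -> None:
    nx.write_graphml(network.graph, path)


def write_sif(network: GcfNetwork, path) -> None:
    """Simple interaction format for viewer import; isolated nodes listed bare."""
    with open(path, "w") as fh:
        for a, b, data in sorted(network.graph.edges(data=True)):
            fh.write(f"{a}\t{data['edge_type']}\t{b}\n")
        for node in sorted(nx.isolates(network.graph)):
            fh.write(f"{node}\n")
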