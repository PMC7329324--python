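"""GCF occurrence across specimens and the fragment-collapse BGC estimator.

Two evidence streams say a GCF is present in a specimen: membership of one
of the specimen's BGCs in the GCF's network component, and translated
(tblastn-like) hits of the GCF's core biosynthetic proteins against the
specimen's assembly at > 50% query coverage and > 90% amino-acid identity.
Evidence is deduplicated at the locus level, so the count for (GCF,
specimen) is the number of distinct genomic loci carrying the pathway — a
value above 1 means multiple subtype copies.

Fragmented assembly inflates raw metagenome BGC counts: one chromosomal
cluster may surface as several partial BGCs. Collapsing fragments that map
to disjoint regions of the same reference cluster in the same specimen
yields the unique-cluster count, whose ratio to the raw matched count is the
inflation factor used to estimate the true number of distinct BGCs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd
from Bio.Seq import Seq

from .bgc_gcf import GcfNetwork, align_proteins, directional_hit, gene_hits
from .core_io import BgcRecord, ContigBin

logger = logging.getLogger("symbionet")


@dataclass
class TranslatedHit:
    protein_id: str
    contig_id: str
    nt_start: int  # 0-based half-open on the forward strand of the contig
    nt_end: int
    frame: int  # 0..2 forward, 3..5 reverse
    identity_pct: float
    coverage_pct: float
    score: float


@dataclass
class GcfEvidence:
    """One locus of evidence that a GCF occurs in a specimen."""

    gcf_id: str
    specimen_id: str
    contig_id: Optional[str]  # None when the source BGC carries no locus
    start: int = 0
    end: int = 0
    kind: str = "network"  # "network" | "search"
    label: str = ""


@dataclass
class OccurrenceMatrix:
    counts: pd.DataFrame  # rows: GCF ids, columns: specimen ids, int counts
    per_specimen: dict[str, dict[str, float]]  # species -> GCF -> mean/specimen


@dataclass
class CollapseResult:
    n_metagenome_bgcs: int
    n_matched_metag: int
    n_matched_reference_bgcs: int
    n_unique_after_collapse: int
    inflation_factor: Optional[float]


# ---------------------------------------------------------------------------
# Translated search
# ---------------------------------------------------------------------------


def _six_frames(seq: str) -> list[tuple[int, str]]:
    frames = []
    s = Seq(seq)
    rc = s.reverse_complement()
    for f in range(3):
        fwd = s[f : f + (len(s) - f) // 3 * 3]
        rev = rc[f : f + (len(s) - f) // 3 * 3]
        frames.append((f, str(fwd.translate())))
        frames.append((3 + f, str(rev.translate())))
    return frames


def translated_search(
    core_proteins: Sequence[tuple[str, str]],
    contigs: ContigBin,
    min_query_coverage: float = 50.0,
    min_identity: float = 90.0,
) -> list[TranslatedHit]:
    """Search proteins against six-frame translations of a bin's contigs.

    A hit is kept iff the local alignment covers more than
    ``min_query_coverage`` percent of the protein at more than
    ``min_identity`` percent amino-acid identity, and the aligned contig
    span contains no stop codon. At most the best hit per protein per
    contig is reported. Thresholds are strict (>), matching the published
    non-specificity filter.
    """
    if not core_proteins:
        raise ValueError("no query proteins given")
    hits: list[TranslatedHit] = []
    frame_cache = {cid: _six_frames(seq) for cid, seq in contigs.contigs}
    for pid, protein in core_proteins:
        for cid, seq in contigs.contigs:
            best: Optional[TranslatedHit] = None
            for frame, trans in frame_cache[cid]:
                h = align_proteins(protein, trans)
                if h is None:
                    continue
                if not (
                    h.identity_pct > min_identity
                    and h.query_coverage_pct > min_query_coverage
                ):
                    continue
                # locate the aligned span in the translated frame to reject
                # spans crossing a stop codon and to derive contig coordinates
                aln = _subject_span(protein, trans)
                if aln is None:
                    continue
                aa_start, aa_end = aln
                if "*" in trans[aa_start:aa_end]:
                    continue
                offset = frame % 3
                if frame < 3:
                    nt_start = offset + 3 * aa_start
                    nt_end = offset + 3 * aa_end
                else:
                    L = len(seq)
                    nt_end = L - (offset + 3 * aa_start)
                    nt_start = L - (offset + 3 * aa_end)
                cand = TranslatedHit(
                    pid, cid, nt_start, nt_end, frame,
                    h.identity_pct, h.query_coverage_pct, h.bitlike_score,
                )
                if best is None or cand.score > best.score:
                    best = cand
            if best is not None:
                hits.append(best)
    return hits


def _subject_span(query: str, subject: str) -> Optional[tuple[int, int]]:
    """Subject-coordinate span of the best local alignment."""
    from .bgc_gcf import _ALIGNER

    alignments = _ALIGNER.align(query.rstrip("*"), subject)
    if len(alignments) == 0:
        return None
    s_ranges = alignments[0].aligned[1]
    if len(s_ranges) == 0:
        return None
    return int(s_ranges[0][0]), int(s_ranges[-1][1])


# ---------------------------------------------------------------------------
# Core protein extraction
# ---------------------------------------------------------------------------


def extract_core_proteins(gcf_members: Sequence[BgcRecord]) -> list[tuple[str, str]]:
    """Core biosynthetic proteins representing one GCF.

    Uses the core-flagged genes of the longest member (most genes; ties by
    span, then isolate source before metagenome, then id — cultivated
    references are the cleaner representatives). When no member carries core
    flags, falls back to the longest member's genes that have strict-tier
    homologs in at least half of the members.
    """
    if not gcf_members:
        raise ValueError("empty GCF")
    longest = min(
        gcf_members,
        key=lambda r: (-r.n_genes, -r.span_bp, r.source != "isolate", r.bgc_id),
    )
    core = [(g.gene_id, g.protein) for g in longest.genes if g.is_core]
    if core:
        return core
    # consensus fallback
    consensus = []
    others = [m for m in gcf_members if m.bgc_id != longest.bgc_id]
    need = len(gcf_members) / 2.0
    for g in longest.genes:
        present = 1  # the longest member itself
        for m in others:
            hits = gene_hits(
                BgcRecord(
                    bgc_id="_probe",
                    source=longest.source,
                    origin_id=longest.origin_id,
                    product_classes=longest.product_classes,
                    genes=[g],
                    span_bp=len(g.protein) * 3,
                ),
                m,
                tier="strict",
            )
            if hits:
                present += 1
        if present >= need:
            consensus.append((g.gene_id, g.protein))
    if not consensus:
        raise ValueError(
            "no core-flagged gene and no protein shared by half the members"
        )
    return consensus


# ---------------------------------------------------------------------------
# Occurrence matrix
# ---------------------------------------------------------------------------


def cluster_search_hits(
    hits: Sequence[TranslatedHit],
    gcf_id: str,
    specimen_id: str,
    max_gap_bp: int = 10_000,
) -> list[GcfEvidence]:
    """Group translated hits into loci: same contig, gaps <= ``max_gap_bp``."""
    out: list[GcfEvidence] = []
    by_contig: dict[str, list[TranslatedHit]] = {}
    for h in hits:
        by_contig.setdefault(h.contig_id, []).append(h)
    for cid, hs in sorted(by_contig.items()):
        hs = sorted(hs, key=lambda h: h.nt_start)
        cur_start, cur_end = hs[0].nt_start, hs[0].nt_end
        for h in hs[1:]:
            if h.nt_start <= cur_end + max_gap_bp:
                cur_end = max(cur_end, h.nt_end)
            else:
                out.append(
                    GcfEvidence(gcf_id, specimen_id, cid, cur_start, cur_end, "search")
                )
                cur_start, cur_end = h.nt_start, h.nt_end
        out.append(GcfEvidence(gcf_id, specimen_id, cid, cur_start, cur_end, "search"))
    return out


def network_evidence(
    network: GcfNetwork,
    records: Sequence[BgcRecord],
    specimen_of_origin: Optional[Mapping[str, str]] = None,
) -> list[GcfEvidence]:
    """Evidence from metagenome BGC membership in network components."""
    by_id = {r.bgc_id: r for r in records}
    out = []
    for bgc_id, gcf_id in network.gcf_of.items():
        rec = by_id.get(bgc_id)
        if rec is None or rec.source != "metagenome":
            continue
        specimen = (
            specimen_of_origin[rec.origin_id]
            if specimen_of_origin is not None
            else rec.origin_id
        )
        if rec.locus:
            cid, start, end = rec.locus
            out.append(GcfEvidence(gcf_id, specimen, cid, start, end, "network", bgc_id))
        else:
            out.append(GcfEvidence(gcf_id, specimen, None, 0, 0, "network", bgc_id))
    return out


def build_occurrence_matrix(
    evidence: Sequence[GcfEvidence],
    species_of_specimen: Mapping[str, str],
) -> OccurrenceMatrix:
    """Count distinct evidence loci per (GCF, specimen) and summarise.

    Evidence items for the same GCF and specimen whose intervals overlap on
    the same contig are deduplicated (network membership and a translated
    hit at the same locus count once). The per-specimen table divides each
    species' total count by its specimen number, so a value of 1 means
    "present once in every specimen" and values above 1 indicate multiple
    subtype loci.
    """
    for ev in evidence:
        if ev.specimen_id not in species_of_specimen:
            raise ValueError(f"specimen {ev.specimen_id} missing from metadata")

    grouped: dict[tuple[str, str], list[GcfEvidence]] = {}
    for ev in evidence:
        grouped.setdefault((ev.gcf_id, ev.specimen_id), []).append(ev)

    counts: dict[tuple[str, str], int] = {}
    for key, evs in grouped.items():
        n = 0
        by_contig: dict[Optional[str], list[GcfEvidence]] = {}
        for ev in evs:
            by_contig.setdefault(ev.contig_id, []).append(ev)
        for cid, group in by_contig.items():
            if cid is None:
                # no coordinates: each distinct label is its own locus
                n += len({ev.label or id(ev) for ev in group})
                continue
            group = sorted(group, key=lambda e: (e.start, e.end))
            cur_end = None
            for ev in group:
                if cur_end is None or ev.start >= cur_end:
                    n += 1
                    cur_end = ev.end
                else:
                    cur_end = max(cur_end, ev.end)
        counts[key] = n

    gcfs = sorted({g for g, _ in counts})
    specimens = sorted(species_of_specimen)
    mat = pd.DataFrame(0, index=gcfs, columns=specimens, dtype=int)
    for (g, s), n in counts.items():
        mat.loc[g, s] = n

    species_groups: dict[str, list[str]] = {}
    for spec, sp in species_of_specimen.items():
        species_groups.setdefault(sp, []).append(spec)
    per_specimen: dict[str, dict[str, float]] = {}
    for sp, specs in sorted(species_groups.items()):
        per_specimen[sp] = {
            g: float(mat.loc[g, specs].sum()) / len(specs) for g in gcfs
        }
    return OccurrenceMatrix(counts=mat, per_specimen=per_specimen)


# ---------------------------------------------------------------------------
# Fragment collapse and unique-BGC estimation
# ---------------------------------------------------------------------------


def _max_overlap_depth(intervals: Sequence[tuple[int, int]]) -> int:
    """Maximum number of intervals covering one point (closed intervals)."""
    events = []
    for a, b in intervals:
        events.append((a, 1))
        events.append((b + 1, -1))
    depth = best = 0
    for _, delta in sorted(events):
        depth += delta
        best = max(best, depth)
    return best


def collapse_fragments(
    metag_bgcs: Sequence[BgcRecord],
    reference_bgcs: Sequence[BgcRecord],
    min_shared: int = 3,
) -> CollapseResult:
    """Collapse fragmented metagenome BGCs onto their reference congeners.

    Each metagenome BGC is assigned to the reference it hits best
    (cluster-to-cluster score; ties lexicographic). Within one specimen and
    one reference, fragments covering disjoint reference gene ranges are
    complementary pieces of a single underlying cluster and merge; fragments
    whose ranges overlap are genuinely distinct copies. The unique count per
    (specimen, reference) is therefore the maximum overlap depth of the
    fragments' reference-gene intervals. Unassigned metagenome BGCs count
    once each.
    """
    assignments: dict[str, tuple[str, tuple[int, int], str]] = {}
    for m in metag_bgcs:
        best = None
        for ref in reference_bgcs:
            h = directional_hit(m, ref, min_shared=min_shared)
            if h is None:
                continue
            if best is None or (-h.score, ref.bgc_id) < (-best[0], best[1]):
                idx = {g.gene_id: i for i, g in enumerate(ref.genes)}
                span = [idx[gh.subject_gene_id] for gh in gene_hits(m, ref, "loose")]
                best = (h.score, ref.bgc_id, (min(span), max(span)))
        if best is not None:
            assignments[m.bgc_id] = (best[1], best[2], m.origin_id)

    n_unassigned = len(metag_bgcs) - len(assignments)
    groups: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for ref_id, span, specimen in assignments.values():
        groups.setdefault((specimen, ref_id), []).append(span)
    n_unique_matched = sum(_max_overlap_depth(v) for v in groups.values())

    n_matched = len(assignments)
    matched_refs = {ref_id for ref_id, _, _ in assignments.values()}
    inflation = n_matched / n_unique_matched if n_unique_matched else None
    return CollapseResult(
        n_metagenome_bgcs=len(metag_bgcs),
        n_matched_metag=n_matched,
        n_matched_reference_bgcs=len(matched_refs),
        n_unique_after_collapse=n_unique_matched + n_unassigned,
        inflation_factor=inflation,
    )


def estimate_total_unique(n_total_metag: int, collapse: CollapseResult) -> Optional[float]:
    """Estimated number of truly distinct BGCs behind a raw metagenome count.

    The inflation factor measured on the matched subset (matched fragments /
    unique clusters after collapse) is extrapolated to the full count:
    ``estimate = n_total / inflation``. Undefined when nothing matched.
    """
    if collapse.inflation_factor is None:
        logger.warning("no matched BGCs: unique-count estimate undefined")
        return None
    return n_total_metag / collapse.inflation_factor
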