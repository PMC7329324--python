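"""Genome average nucleotide identity (gANI/AF) and bin classification.

gANI between a query (metagenome bin or genome) and a reference genome is
computed fragment-wise: the query is cut into consecutive windows (1 kb by
default), each window is aligned semiglobally to the reference on both
strands, and windows whose best alignment reaches the identity floor count
as mapped. Then

    AF   = mapped query bp / total query bp
    gANI = length-weighted mean identity over mapped windows.

A bin is assigned to the cultivated reference with the highest gANI among
references passing AF > 0.5 and gANI > 0.9 (both strict, per the published
cutoffs); gANI >= 0.95 is the conspecificity call. Species-level aggregate
gANI weights member bins by their length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import edlib

from .core_io import ContigBin, GenomeRecord
from .synthetic_data import reverse_complement

logger = logging.getLogger("symbionet")

UNASSIGNED = "UNASSIGNED"

#: Windows shorter than this (trailing remainders of contigs) are skipped:
#: identity estimates on very short windows are too noisy to score.
MIN_TAIL_BP = 100


@dataclass
class AniResult:
    query_id: str
    reference_id: str
    gani: Optional[float]  # None when no window maps
    af: float
    aligned_bp: int


@dataclass
class BinAssignment:
    bin_id: str
    assigned_reference: str  # reference_id or UNASSIGNED
    gani: Optional[float]
    af: Optional[float]


@dataclass
class AggregateAni:
    group_label: str
    total_bin_bp: int
    weighted_gani: float


def _fragments(record: GenomeRecord | ContigBin, fragment_bp: int):
    for _, seq in record.contigs:
        for start in range(0, len(seq), fragment_bp):
            frag = seq[start : start + fragment_bp]
            if len(frag) >= MIN_TAIL_BP:
                yield frag


def compute_ani(
    query: ContigBin | GenomeRecord,
    reference: GenomeRecord,
    fragment_bp: int = 1000,
    min_fragment_identity: float = 0.70,
) -> AniResult:
    """Fragment-based gANI/AF of ``query`` against ``reference``.

    Each window is aligned with infix (semiglobal) edit-distance alignment,
    so the full window is always covered and the identity floor alone
    decides whether it maps. Identity of a window is
    ``1 - edit_distance / window_length``.
    """
    if fragment_bp < 200:
        raise ValueError("fragment_bp must be >= 200")
    if not query.contigs or not reference.contigs:
        raise ValueError("query and reference must be non-empty")

    query_id = query.id if isinstance(query, GenomeRecord) else query.bin_id
    ref_seqs = [seq for _, seq in reference.contigs]

    total_bp = query.total_length
    mapped_bp = 0
    weighted_identity = 0.0
    for frag in _fragments(query, fragment_bp):
        L = len(frag)
        max_ed = int(L * (1.0 - min_fragment_identity)) + 1
        best_ed = -1
        rc = reverse_complement(frag)
        for ref in ref_seqs:
            for probe in (frag, rc):
                res = edlib.align(probe, ref, mode="HW", task="distance", k=max_ed)
                ed = res["editDistance"]
                if ed >= 0 and (best_ed < 0 or ed < best_ed):
                    best_ed = ed
        if best_ed < 0:
            continue
        identity = 1.0 - best_ed / L
        if identity >= min_fragment_identity:
            mapped_bp += L
            weighted_identity += identity * L

    af = mapped_bp / total_bp
    gani = weighted_identity / mapped_bp if mapped_bp else None
    if gani is None:
        logger.warning("no window of %s maps to %s", query_id, reference.id)
    return AniResult(query_id, reference.id, gani, af, mapped_bp)


def assign_bin(
    results: Sequence[AniResult],
    af_min: float = 0.5,
    gani_min: float = 0.9,
) -> BinAssignment:
    """Assign a bin to the best reference passing both cutoffs.

    Both cutoffs are strict inequalities. Among passing references the one
    with maximal gANI wins; ties break by larger AF, then lexicographically
    smaller reference id, so the outcome is deterministic.
    """
    if not results:
        logger.warning("assign_bin called with no ANI results")
        return BinAssignment("<unknown>", UNASSIGNED, None, None)
    bin_ids = {r.query_id for r in results}
    if len(bin_ids) != 1:
        raise ValueError(f"results span multiple query bins: {sorted(bin_ids)}")
    bin_id = results[0].query_id
    passing = [
        r
        for r in results
        if r.gani is not None and r.af > af_min and r.gani > gani_min
    ]
    if not passing:
        return BinAssignment(bin_id, UNASSIGNED, None, None)
    best = min(passing, key=lambda r: (-r.gani, -r.af, r.reference_id))
    return BinAssignment(bin_id, best.reference_id, best.gani, best.af)


def aggregate_gani(
    group_label: str,
    members: Sequence[tuple[float, int]],
) -> AggregateAni:
    """Length-weighted mean gANI over member bins.

    ``members`` are ``(gani, bin_length_bp)`` pairs, one per bin assigned to
    the group (a species-to-reference comparison).
    """
    members = [(g, l) for g, l in members if g is not None]
    total = sum(l for _, l in members)
    if total <= 0:
        raise ValueError("aggregate_gani needs at least one bin with defined gANI")
    weighted = sum(g * l for g, l in members) / total
    return AggregateAni(group_label, total, weighted)


def call_conspecific(gani: float) -> bool:
    """Species-level call: genomes with gANI >= 0.95 are conspecific."""
    if gani is None:
        raise ValueError("gani undefined")
    return gani >= 0.95


def classify_bacterial_bin(
    bin: ContigBin,
    min_coding_density: float = 0.5,
    min_bacterial_fraction: float = 0.60,
    count_unassigned: bool = False,
) -> bool:
    """Decide whether a bin originates from bacteria.

    A bin passes when its coding density exceeds ``min_coding_density`` and
    at least ``min_bacterial_fraction`` of its genes carry a bacterial
    taxonomy label. By default genes the taxonomy oracle left unassigned are
    excluded from the denominator; set ``count_unassigned`` to include them.
    """
    if bin.coding_density is None:
        raise ValueError(f"bin {bin.bin_id}: coding_density is missing")
    if bin.gene_taxa is None:
        raise ValueError(f"bin {bin.bin_id}: gene_taxa annotations are missing")
    if bin.coding_density <= min_coding_density:
        return False
    n_bact = sum(1 for t in bin.gene_taxa if t == "bacterial")
    denom = (
        len(bin.gene_taxa)
        if count_unassigned
        else sum(1 for t in bin.gene_taxa if t != "unassigned")
    )
    if denom == 0:
        return False
    return n_bact / denom >= min_bacterial_fraction
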