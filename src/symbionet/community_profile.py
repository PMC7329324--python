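"""Read mapping and per-species community composition profiles.

Reads are mapped with an explicit contract that mirrors short-read
competitive mapping: a read maps to a reference if its best semiglobal
alignment contains an exact match of at least 22 bp, at most 15 substituted
bases and at most 80 indel bp (all configurable). Each read is assigned
uniquely to the reference with the fewest mismatches (ties: fewest indel bp,
then lexicographic), and composition is the percentage of reads per species,
with rare species pooled into a "minor" category.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import edlib

from .core_io import GenomeRecord
from .synthetic_data import reverse_complement

logger = logging.getLogger("symbionet")

UNMAPPED = "UNMAPPED"
MINOR = "minor"

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass
class ReadAssignment:
    read_id: str
    reference_id: str  # reference id or UNMAPPED
    mismatches: int = 0
    indel_bp: int = 0


@dataclass
class CompositionProfile:
    specimen_id: str
    fractions: dict[str, float] = field(default_factory=dict)  # species -> pct
    unmapped_pct: float = 0.0


def _cigar_stats(cigar: str) -> tuple[int, int, int]:
    """(mismatches, indel_bp, longest_exact_run) from an extended CIGAR."""
    mismatches = indels = longest = 0
    for num, op in _CIGAR_RE.findall(cigar):
        n = int(num)
        if op == "=":
            longest = max(longest, n)
        elif op in "XM" and op == "X":
            mismatches += n
        elif op in "ID":
            indels += n
    return mismatches, indels, longest


def _best_alignment(read: str, reference: GenomeRecord, k: int):
    """Best (mismatches, indel_bp, seed) over both strands and all contigs."""
    best = None
    for probe in (read, reverse_complement(read)):
        for _, seq in reference.contigs:
            res = edlib.align(probe, seq, mode="HW", task="path", k=k)
            if res["editDistance"] < 0:
                continue
            stats = _cigar_stats(res["cigar"])
            if best is None or (stats[0], stats[1]) < (best[0], best[1]):
                best = stats
    return best


def map_reads(
    reads: Sequence[tuple[str, str]],
    references: Sequence[GenomeRecord],
    min_exact_seed: int = 22,
    max_subs: int = 15,
    max_indel: int = 80,
) -> list[ReadAssignment]:
    """Competitively map reads against candidate reference genomes.

    A read maps to a reference iff its best alignment there satisfies the
    seed/substitution/indel contract; its assignment is the reference with
    the fewest mismatches (ties: fewest indel bp, then lexicographically
    smaller reference id). Reads failing the contract everywhere are
    UNMAPPED.
    """
    if not references:
        logger.warning("map_reads called with an empty reference set")
        return [ReadAssignment(rid, UNMAPPED) for rid, _ in reads]
    k = max_subs + max_indel
    out: list[ReadAssignment] = []
    for rid, seq in reads:
        if len(seq) < min_exact_seed:
            raise ValueError(f"read {rid} shorter than the exact-seed minimum")
        candidates = []
        for ref in references:
            best = _best_alignment(seq, ref, k)
            if best is None:
                continue
            mism, indel, seed = best
            if seed >= min_exact_seed and mism <= max_subs and indel <= max_indel:
                candidates.append((mism, indel, ref.id))
        if candidates:
            mism, indel, ref_id = min(candidates)
            out.append(ReadAssignment(rid, ref_id, mism, indel))
        else:
            out.append(ReadAssignment(rid, UNMAPPED))
    return out


def composition(
    assignments: Sequence[ReadAssignment],
    species_of: Mapping[str, str],
    specimen_id: str = "specimen",
    minor_floor_pct: float = 0.5,
) -> CompositionProfile:
    """Per-species read percentages for one specimen.

    Species whose share falls below ``minor_floor_pct`` percent are pooled
    into a single "minor" category (sporadic, unidentified strains). The
    reported percentages plus the unmapped percentage always total 100.
    """
    if not assignments:
        raise ValueError("composition requires at least one read assignment")
    total = len(assignments)
    counts: dict[str, int] = {}
    unmapped = 0
    for a in assignments:
        if a.reference_id == UNMAPPED:
            unmapped += 1
            continue
        if a.reference_id not in species_of:
            raise ValueError(f"no species label for reference {a.reference_id}")
        sp = species_of[a.reference_id]
        counts[sp] = counts.get(sp, 0) + 1
    fractions: dict[str, float] = {}
    minor_pct = 0.0
    for sp in sorted(counts):
        pct = counts[sp] / total * 100.0
        if pct < minor_floor_pct:
            minor_pct += pct
        else:
            fractions[sp] = pct
    if minor_pct > 0:
        fractions[MINOR] = fractions.get(MINOR, 0.0) + minor_pct
    return CompositionProfile(
        specimen_id=specimen_id,
        fractions=fractions,
        unmapped_pct=unmapped / total * 100.0,
    )
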