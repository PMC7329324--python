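"""Window-based strain variation profiling on a single-copy marker gene.

The marker (e.g. DNA gyrase subunit B) is cut into consecutive 50-bp
windows; every read is aligned to the marker and, for each window the read
fully covers, the read's bases over that window define its haplotype
variant. Counting reads per distinct variant per window yields a profile in
which the maximum number of well-supported variants in any window is a
lower bound on the number of strains in the sample, and the rank-ordered
variant fractions estimate the strain mixture.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib

from .synthetic_data import reverse_complement

logger = logging.getLogger("symbionet")


@dataclass
class MarkerWindowProfile:
    marker_id: str
    window_bp: int
    # ordered (start, end, {variant string -> read count}); windows tile the
    # marker without overlap, the last window may be short
    windows: list[tuple[int, int, dict[str, int]]] = field(default_factory=list)
    n_reads_total: int = 0


@dataclass
class StrainSummary:
    min_strains: int
    per_window_major_fraction: list[float]
    mixture_estimate: dict[str, float]  # "rank1", "rank2", ... -> fraction


def _orient_and_place(read: str, marker: str) -> Optional[tuple[str, int]]:
    """Best gapless placement of a read on the marker, either strand.

    Returns ``(oriented_read, marker_start)`` or None when the best
    alignment needs indels (the substitution-only model treats those reads
    as unalignable for window counting).
    """
    best = None
    for probe in (read, reverse_complement(read)):
        res = edlib.align(probe, marker, mode="HW", task="path")
        ed = res["editDistance"]
        if ed < 0:
            continue
        start, end = res["locations"][0]
        gapless = (end - start + 1) == len(probe) and not any(
            op in res["cigar"] for op in "ID"
        )
        if best is None or ed < best[0]:
            best = (ed, probe, start, gapless)
    if best is None or not best[3]:
        return None
    return best[1], best[2]


def window_profile(
    marker: str,
    reads: Sequence[tuple[str, str]],
    window_bp: int = 50,
    min_support: int = 2,
    marker_id: str = "marker",
) -> MarkerWindowProfile:
    """Per-window variant read counts over a marker gene.

    A read contributes only to windows its alignment fully covers, so ragged
    read edges never produce composite variants. Variants supported by fewer
    than ``min_support`` reads are dropped as sequencing noise.
    """
    if len(marker) < window_bp:
        raise ValueError("marker shorter than one window")
    starts = list(range(0, len(marker), window_bp))
    bounds = [(s, min(s + window_bp, len(marker))) for s in starts]
    counts: list[dict[str, int]] = [dict() for _ in bounds]

    any_cover = False
    for _, seq in reads:
        placed = _orient_and_place(seq, marker)
        if placed is None:
            continue
        oriented, mstart = placed
        mend = mstart + len(oriented)
        for wi, (ws, we) in enumerate(bounds):
            if mstart <= ws and mend >= we:
                var = oriented[ws - mstart : we - mstart]
                counts[wi][var] = counts[wi].get(var, 0) + 1
                any_cover = True

    if not any_cover:
        logger.warning("no read fully covers any window of %s", marker_id)

    windows = []
    for (ws, we), c in zip(bounds, counts):
        kept = {v: n for v, n in c.items() if n >= min_support}
        windows.append((ws, we, kept))
    return MarkerWindowProfile(
        marker_id=marker_id,
        window_bp=window_bp,
        windows=windows,
        n_reads_total=len(reads),
    )


def summarize_strains(profile: MarkerWindowProfile) -> StrainSummary:
    """Minimum strain number and rank-pooled mixture estimate.

    ``min_strains`` is the maximum number of supported variants in any
    window — a lower bound on the true strain count, tight when some window
    contains sites discriminating all strains. The mixture estimate pools,
    across polymorphic windows, the fraction of reads in the rank-1 variant,
    the rank-2 variant, and so on, takes the median per rank, and normalises
    the medians to sum to 1.
    """
    populated = [w for w in profile.windows if w[2]]
    if not populated:
        raise ValueError("cannot summarise an empty profile")
    min_strains = max(len(c) for _, _, c in populated)

    major_fracs = []
    rank_fracs: dict[int, list[float]] = {}
    for _, _, c in populated:
        total = sum(c.values())
        ordered = sorted(c.values(), reverse=True)
        major_fracs.append(ordered[0] / total)
        if len(ordered) >= 2:  # polymorphic window
            for rank, n in enumerate(ordered):
                rank_fracs.setdefault(rank, []).append(n / total)

    if rank_fracs:
        medians = {r: statistics.median(v) for r, v in rank_fracs.items()}
        norm = sum(medians.values())
        mixture = {f"rank{r + 1}": m / norm for r, m in sorted(medians.items())}
    else:
        mixture = {"rank1": 1.0}
    return StrainSummary(min_strains, major_fracs, mixture)
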