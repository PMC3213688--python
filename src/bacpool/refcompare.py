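"""Assembly-vs-reference comparison: gaps, misassemblies, penalty, L/N
length statistics, error catalog and Phred-scaled consensus accuracy.

A *gap* is a maximal reference interval not represented by any aligned
contig segment. A *misassembly* is a pair of adjacent segments of the same
contig that are not colinear on the reference (wrong order, wrong strand, or
a reference jump beyond ``colinear_slack``). The consistency *penalty*
weighs misassemblies twice as heavily as gaps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from ._util import merge_intervals, round_half_up
from .alignment import AlignmentSegment, Difference, align_contigs  # noqa: F401  (re-export)

Interval = tuple[int, int]

ERROR_KINDS = ("substitution", "homopolymer_indel", "other_indel")
Q_CAP = 60


@dataclass
class LengthStats:
    """L_p / N_p statistics of a contig (or scaffold) length distribution.

    For each percentage p, N_p is the smallest number of largest units whose
    cumulative length reaches p% of the total, and L_p is the length of the
    smallest unit in that set.
    """

    L: dict[int, int]
    N: dict[int, int]
    total: int
    count: int
    mean: float
    maximum: int


@dataclass
class Misassembly:
    contig_id: str
    contig_pos: int  # junction position on the contig
    ref_intervals: tuple[Interval, Interval]
    strands: tuple[str, str]


@dataclass
class ErrorCatalog:
    counts: dict[str, int]
    total_differences: int
    aligned_ref_bases: int
    error_rate: float
    q_value: int


@dataclass
class ComparisonReport:
    misassemblies: list[Misassembly]
    gaps: list[Interval]
    total_gap_size: int
    penalty: int
    length_stats: LengthStats
    error_catalog: ErrorCatalog | None = None
    segments: list[AlignmentSegment] = field(default_factory=list)

    @property
    def n_misassemblies(self) -> int:
        return len(self.misassemblies)

    @property
    def n_gaps(self) -> int:
        return len(self.gaps)


def find_gaps(segments: list[AlignmentSegment], reference_length: int,
              min_gap: int = 1) -> list[Interval]:
    """Maximal uncovered reference intervals of at least ``min_gap`` bp;
    terminal uncovered intervals count like internal ones."""
    covered = merge_intervals([s.ref_interval for s in segments])
    gaps: list[Interval] = []
    pos = 0
    for a, b in covered:
        if a - pos >= min_gap:
            gaps.append((pos, a))
        pos = max(pos, b)
    if reference_length - pos >= min_gap:
        gaps.append((pos, reference_length))
    return gaps


def _colinear(s1: AlignmentSegment, s2: AlignmentSegment, slack: int) -> bool:
    if s1.strand != s2.strand:
        return False
    if s1.strand == "+":
        # reference must advance with the contig, with a bounded jump
        return (s2.ref_interval[0] >= s1.ref_interval[0]
                and abs(s2.ref_interval[0] - s1.ref_interval[1]) <= slack)
    return (s2.ref_interval[1] <= s1.ref_interval[1]
            and abs(s1.ref_interval[0] - s2.ref_interval[1]) <= slack)


def find_misassemblies(segments: list[AlignmentSegment],
                       colinear_slack: int = 1000) -> list[Misassembly]:
    """Count one misassembly per non-colinear adjacent segment pair within
    each contig (segments ordered along the contig)."""
    by_contig: dict[str, list[AlignmentSegment]] = {}
    for seg in segments:
        by_contig.setdefault(seg.contig_id, []).append(seg)
    out: list[Misassembly] = []
    for cid, segs in sorted(by_contig.items()):
        segs.sort(key=lambda s: s.contig_interval)
        for s1, s2 in zip(segs, segs[1:]):
            if not _colinear(s1, s2, colinear_slack):
                out.append(Misassembly(cid, s1.contig_interval[1],
                                       (s1.ref_interval, s2.ref_interval),
                                       (s1.strand, s2.strand)))
    return out


def penalty(misassemblies: int, gaps: int) -> int:
    """Consistency penalty: 2 points per misassembly, 1 per gap."""
    if misassemblies < 0 or gaps < 0:
        raise ValueError("counts must be non-negative")
    return 2 * misassemblies + gaps


def length_stats(contig_lengths, percentages=(50, 80, 90)) -> LengthStats:
    """L_p and N_p over a length distribution (descending cumulative sums)."""
    lengths = sorted((int(x) for x in contig_lengths), reverse=True)
    if not lengths:
        raise ValueError("length list must be non-empty")
    if lengths[-1] <= 0:
        raise ValueError("all lengths must be positive")
    total = sum(lengths)
    L: dict[int, int] = {}
    N: dict[int, int] = {}
    for p in percentages:
        target = p / 100.0 * total
        cum = 0
        for i, x in enumerate(lengths, start=1):
            cum += x
            if cum >= target:
                L[p], N[p] = x, i
                break
    return LengthStats(L, N, total, len(lengths), total / len(lengths), lengths[0])


def catalog_errors(segments: list[AlignmentSegment]) -> ErrorCatalog:
    """Aggregate base-level differences over aligned segments."""
    aligned = sum(s.ref_span for s in segments)
    if aligned == 0:
        raise ValueError("no aligned reference bases; error rate undefined")
    counts = {kind: 0 for kind in ERROR_KINDS}
    for seg in segments:
        for d in seg.differences:
            counts[d.kind] += 1
    total = sum(counts.values())
    rate = total / aligned
    return ErrorCatalog(counts, total, aligned, rate, phred_q(rate))


def phred_q(error_rate: float, cap: int = Q_CAP) -> int:
    """Phred-scaled accuracy: round(-10 log10 rate), halves up; 0 -> cap."""
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError("error_rate must be in [0, 1]")
    if error_rate == 0.0:
        return cap
    return min(cap, round_half_up(-10.0 * math.log10(error_rate)))


def compare(
    contigs: dict[str, str],
    reference: str,
    min_segment: int = 100,
    min_identity: float = 0.95,
    colinear_slack: int = 1000,
    min_gap: int = 1,
    with_errors: bool = True,
    **align_kwargs,
) -> ComparisonReport:
    """Full assembly-vs-reference comparison for one clone."""
    segments = align_contigs(contigs, reference, min_segment, min_identity,
                             **align_kwargs)
    mis = find_misassemblies(segments, colinear_slack)
    gaps = find_gaps(segments, len(reference), min_gap)
    stats = length_stats([len(s) for s in contigs.values()]) if contigs else None
    catalog = catalog_errors(segments) if (with_errors and segments) else None
    return ComparisonReport(
        misassemblies=mis,
        gaps=gaps,
        total_gap_size=sum(b - a for a, b in gaps),
        penalty=penalty(len(mis), len(gaps)),
        length_stats=stats,
        error_catalog=catalog,
        segments=segments,
    )
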