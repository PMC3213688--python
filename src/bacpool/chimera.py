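"""Chimerism analysis of non-barcoded pool assemblies.

With clone-of-origin labels on the reads, every contig gets an origin
profile: read counts per clone and the fraction contributed by the majority
clone. Contigs whose major fraction falls below 0.96 are classified
chimeric. The module also produces the cumulative-length diagnostic curve,
per-class summary tables, and annotates chimera breakpoints (dominant-clone
switch points) against local k-mer frequency to distinguish repeat-mediated
joins from low-complexity or unique-sequence joins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kmermask import KmerIndex, _canonical

CHIMERA_THRESHOLD = 0.96
MIN_CONTIG_LEN = 1000


@dataclass
class OriginProfile:
    contig_id: str
    length: int
    reads_total: int
    reads_by_bac: dict[str, int]
    major_bac: str
    major_fraction: float


@dataclass
class ClassStats:
    count: int
    total_length: int
    average_length: int
    length_fraction: float


@dataclass
class ChimeraReport:
    non_chimeric: ClassStats
    chimeric: ClassStats
    total_length: int
    threshold: float = CHIMERA_THRESHOLD
    min_len: int = MIN_CONTIG_LEN


@dataclass
class BreakpointAnnotation:
    contig_id: str
    junctions: list[dict] = field(default_factory=list)
    unresolved: bool = False


def contig_origin_profiles(
    membership: dict[str, list[str]],
    read_bacs: dict[str, str],
    contig_lengths: dict[str, int],
    min_len: int = MIN_CONTIG_LEN,
) -> list[OriginProfile]:
    """Per-contig read counts by clone of origin and the major fraction.

    Contigs at or below ``min_len`` bp are excluded (the length filter is
    strictly greater-than); contigs without member reads are skipped.
    Ties for the major clone break to the lexicographically smallest id.
    """
    profiles: list[OriginProfile] = []
    for cid in sorted(membership):
        length = contig_lengths[cid]
        if length <= min_len:
            continue
        counts: dict[str, int] = {}
        for rid in membership[cid]:
            bac = read_bacs[rid]
            counts[bac] = counts.get(bac, 0) + 1
        total = sum(counts.values())
        if total == 0:
            continue
        major = min(b for b in counts if counts[b] == max(counts.values()))
        profiles.append(OriginProfile(cid, length, total, counts, major,
                                      counts[major] / total))
    return profiles


def classify_chimeric(profiles: list[OriginProfile],
                      threshold: float = CHIMERA_THRESHOLD) -> dict[str, bool]:
    """contig_id -> True when chimeric; the boundary is inclusive on the
    non-chimeric side (major fraction >= threshold is non-chimeric)."""
    return {p.contig_id: p.major_fraction < threshold for p in profiles}


def chimera_length_curve(profiles: list[OriginProfile],
                         cutoffs=None) -> list[tuple[float, float]]:
    """Cumulative length fraction of contigs with major fraction >= x, as a
    function of x; monotone non-increasing."""
    if not profiles:
        raise ValueError("need at least one profile")
    if cutoffs is None:
        cutoffs = np.round(np.arange(0.0, 1.0001, 0.02), 4)
    total = sum(p.length for p in profiles)
    out = []
    for x in cutoffs:
        mass = sum(p.length for p in profiles if p.major_fraction >= x)
        out.append((float(x), mass / total))
    return out


def summarize(classifications: dict[str, bool],
              lengths: dict[str, int],
              threshold: float = CHIMERA_THRESHOLD,
              min_len: int = MIN_CONTIG_LEN) -> ChimeraReport:
    """Per-class counts, lengths and length fractions (fractions rounded to
    two decimals); class totals sum to the filtered assembly total."""
    groups = {False: [], True: []}
    for cid, is_chim in classifications.items():
        groups[is_chim].append(lengths[cid])
    total = sum(lengths[cid] for cid in classifications)

    def stats(vals: list[int]) -> ClassStats:
        t = sum(vals)
        return ClassStats(
            count=len(vals),
            total_length=t,
            average_length=int(round(t / len(vals))) if vals else 0,
            length_fraction=round(t / total, 2) if total else 0.0,
        )

    return ChimeraReport(stats(groups[False]), stats(groups[True]), total,
                         threshold, min_len)


# ---------------------------------------------------------------------------
# breakpoint annotation


def _dominant_bac(cover: dict[str, np.ndarray], a: int, b: int) -> tuple[str | None, float]:
    totals = {bac: float(arr[a:b].sum()) for bac, arr in cover.items()}
    grand = sum(totals.values())
    if grand == 0:
        return None, 0.0
    best = min(b for b in totals if totals[b] == max(totals.values()))
    return best, totals[best] / grand


def _is_low_complexity(seq: str) -> bool:
    """Dinucleotide-entropy heuristic for microsatellite/low-complexity DNA."""
    seq = seq.upper()
    if len(seq) < 20:
        return False
    if len(set(seq)) <= 2:
        return True
    dinucs = [seq[i : i + 2] for i in range(len(seq) - 1)]
    top = max(dinucs.count(d) for d in set(dinucs))
    return top / len(dinucs) > 0.4


def annotate_breakpoints(
    contig_id: str,
    contig_seq: str,
    read_positions: list[tuple[str, int, int]],  # (bac_id, start, end) on contig
    kmer_index: KmerIndex,
    mean_depth: float,
    window: int = 500,
    step: int = 100,
    flank_share: float = 0.8,
    high_mult: float = 2.0,
    expect_chimeric: bool = False,
) -> BreakpointAnnotation:
    """Locate dominant-clone switch points and label their repeat context.

    Windowed clone coverage along the contig is scanned for positions where
    the dominant clone changes while holding a share above ``flank_share``
    on both flanks. Each junction is labelled by the local k-mer frequency
    relative to the pool's mean depth: high on both sides -> repeat_only
    context, one side -> nonrep_to_rep, neither but a low-complexity motif
    present -> unknown_low_complexity, otherwise nonrep_to_nonrep.
    """
    n = len(contig_seq)
    cover: dict[str, np.ndarray] = {}
    for row in read_positions:
        bac, a, b = row[-3:]  # rows may carry a leading read_id
        arr = cover.setdefault(bac, np.zeros(n, dtype=np.int32))
        arr[max(0, a) : min(n, b)] += 1

    # dominant clone per window; windows where the leading share is below
    # flank_share (the mixed windows straddling a junction) are skipped, and
    # a junction is called between consecutive *confident* windows that
    # disagree, spanning the uncertain stretch between them
    confident: list[tuple[int, str]] = []
    for start in range(0, max(1, n - window + 1), step):
        bac, share = _dominant_bac(cover, start, min(n, start + window))
        if bac is not None and share >= flank_share:
            confident.append((start, bac))

    junctions: list[dict] = []
    for (s1, b1), (s2, b2) in zip(confident, confident[1:]):
        if b1 == b2:
            continue
        lo = min(n - 1, s1 + window)  # end of the last window dominated by b1
        hi = max(lo + 1, min(n, s2))  # start of the first window dominated by b2
        junctions.append({"interval": (lo, hi), "from_bac": b1, "to_bac": b2})

    k = kmer_index.k
    cutoff = high_mult * mean_depth
    for j in junctions:
        lo, hi = j["interval"]
        left = _local_kmer_freq(contig_seq, max(0, lo - window), lo, kmer_index)
        right = _local_kmer_freq(contig_seq, hi, min(n, hi + window), kmer_index)
        mid = _local_kmer_freq(contig_seq, lo, hi, kmer_index)
        j["kmer_freq"] = {"left": left, "junction": mid, "right": right}
        high_left, high_right = left > cutoff, right > cutoff
        if high_left and high_right:
            j["kind"] = "repeat_only"
        elif high_left or high_right or mid > cutoff:
            j["kind"] = "nonrep_to_rep"
        elif _is_low_complexity(contig_seq[max(0, lo - k) : hi + k]):
            j["kind"] = "unknown_low_complexity"
        else:
            j["kind"] = "nonrep_to_nonrep"
    return BreakpointAnnotation(contig_id, junctions,
                                unresolved=expect_chimeric and not junctions)


def _local_kmer_freq(seq: str, a: int, b: int, index: KmerIndex) -> float:
    """Median pool k-mer count over windows overlapping seq[a:b]."""
    k = index.k
    seq = seq.upper()
    lo = max(0, a - k + 1)
    hi = min(len(seq) - k, b - 1)
    counts = [index[_canonical(seq[i : i + k])] for i in range(lo, hi + 1)]
    return float(np.median(counts)) if counts else 0.0


def split_at_masked_junctions(
    contig_seq: str,
    membership_positions: list[tuple[str, str, int, int]],  # (read_id, bac, start, end)
    masked_intervals: list[tuple[int, int]],
) -> list[list[tuple[str, str, int, int]]]:
    """Partition a contig's reads at masked intervals.

    Stand-in for re-assembling masked reads: a join cannot form across a
    region that masking removed from seeding, so the read population splits
    into the maximal unmasked blocks. Returns one read list per block (reads
    fully inside a masked interval are dropped with the repeat).
    """
    n = len(contig_seq)
    bounds = [0] + [x for a, b in sorted(masked_intervals) for x in (a, b)] + [n]
    blocks = [(bounds[i], bounds[i + 1]) for i in range(0, len(bounds) - 1, 2)]
    out = []
    for lo, hi in blocks:
        block_reads = [r for r in membership_positions if r[2] >= lo and r[3] <= hi]
        if block_reads:
            out.append(block_reads)
    return out
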