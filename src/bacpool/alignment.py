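"""Seed-chain-extend local alignment of contigs against a reference.

The engine anchors exact k-mer matches (default k = 15), chains anchors that
are colinear within a small indel band, extends chains by exact matching,
selects a non-overlapping set of chains per contig by weighted interval
scheduling, and resolves base-level differences inside each chained segment
with edlib. A contig spanning a structural event (translocation, inversion,
large deletion) therefore yields several segments, which is what the
downstream gap/misassembly calling consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib

from ._util import revcomp

Interval = tuple[int, int]


@dataclass
class Difference:
    """One base-level difference between contig and reference."""

    ref_pos: int
    kind: str  # substitution | homopolymer_indel | other_indel
    ref_allele: str
    contig_allele: str


@dataclass
class AlignmentSegment:
    contig_id: str
    contig_interval: Interval
    ref_interval: Interval
    strand: str
    identity: float = 1.0
    differences: list[Difference] = field(default_factory=list)

    @property
    def contig_span(self) -> int:
        return self.contig_interval[1] - self.contig_interval[0]

    @property
    def ref_span(self) -> int:
        return self.ref_interval[1] - self.ref_interval[0]


def build_ref_index(reference: str, k: int = 15, max_hits: int = 10) -> dict[str, list[int]]:
    """Positions of every k-mer of the reference; k-mers with more than
    ``max_hits`` occurrences (tandem/low-complexity tracts) are dropped —
    exact chain extension recovers the bases they would have anchored."""
    index: dict[str, list[int]] = {}
    for i in range(len(reference) - k + 1):
        index.setdefault(reference[i : i + k], []).append(i)
    return {kmer: pos for kmer, pos in index.items() if len(pos) <= max_hits}


@dataclass
class _Chain:
    start_q: int
    start_r: int
    last_q: int
    last_r: int
    n_anchors: int = 1


def _chain_anchors(query: str, index: dict[str, list[int]], k: int,
                   max_join: int, max_chain_indel: int) -> list[_Chain]:
    open_chains: list[_Chain] = []
    finished: list[_Chain] = []
    for q in range(len(query) - k + 1):
        hits = index.get(query[q : q + k])
        if not hits:
            continue
        # retire chains that can no longer be extended
        still_open = []
        for ch in open_chains:
            if q - ch.last_q > max_join:
                finished.append(ch)
            else:
                still_open.append(ch)
        open_chains = still_open
        for r in hits:
            best = None
            for ch in open_chains:
                dq, dr = q - ch.last_q, r - ch.last_r
                if dq > 0 and dr > 0 and abs(dr - dq) <= max_chain_indel:
                    if best is None or ch.last_q > best.last_q:
                        best = ch
            if best is not None:
                best.last_q, best.last_r = q, r
                best.n_anchors += 1
            else:
                open_chains.append(_Chain(q, r, q, r))
    finished.extend(open_chains)
    return finished


def _extend_exact(query: str, ref: str, ch: _Chain, k: int) -> tuple[int, int, int, int]:
    qs, rs = ch.start_q, ch.start_r
    qe, re_ = ch.last_q + k, ch.last_r + k
    while qs > 0 and rs > 0 and query[qs - 1] == ref[rs - 1]:
        qs -= 1
        rs -= 1
    while qe < len(query) and re_ < len(ref) and query[qe] == ref[re_]:
        qe += 1
        re_ += 1
    return qs, qe, rs, re_


def _merge_colinear(spans: list[tuple[int, int, int, int]], slack: int = 40):
    """Merge extended chains on near-identical diagonals that touch/overlap."""
    spans = sorted(spans)
    out: list[list[int]] = []
    for qs, qe, rs, re_ in spans:
        if out:
            pqs, pqe, prs, pre = out[-1]
            diag_ok = abs((rs - qs) - (pre - pqe)) <= slack
            if qs <= pqe + slack and rs <= pre + slack and rs >= prs and diag_ok:
                out[-1] = [pqs, max(pqe, qe), prs, max(pre, re_)]
                continue
        out.append([qs, qe, rs, re_])
    return [tuple(s) for s in out]


def _select_chains(cands: list[tuple[int, ...]],
                   max_overlap: int = 25) -> list[tuple[int, ...]]:
    """Weighted interval scheduling on query intervals, weight = query span.

    ``cands`` rows are (qs, qe, rs, re, strand_flag); returns the subset with
    maximal total query coverage. Neighbouring chains may share up to
    ``max_overlap`` query bases (exact extension can run a few bases past a
    junction by chance), so near-touching chains are treated as compatible.
    """
    cands = sorted(cands, key=lambda c: c[1])
    n = len(cands)
    if n == 0:
        return []
    import bisect

    ends = [c[1] for c in cands]
    best = [0.0] * (n + 1)
    take: list[bool] = [False] * n
    prev_idx = [0] * n
    for i, c in enumerate(cands):
        j = bisect.bisect_right(ends, c[0] + max_overlap, hi=i)
        prev_idx[i] = j
        with_i = best[j] + (c[1] - c[0])
        if with_i > best[i]:
            best[i + 1] = with_i
            take[i] = True
        else:
            best[i + 1] = best[i]
    chosen = []
    i = n
    while i > 0:
        if take[i - 1] and best[i] != best[i - 1]:
            chosen.append(cands[i - 1])
            i = prev_idx[i - 1]
        else:
            i -= 1
    return chosen[::-1]


def _homopolymer_run_len(ref: str, pos: int, base: str, deleted: str = "") -> int:
    """Length of the single-nucleotide run of ``base`` in the reference
    around position ``pos`` (the deleted bases themselves count)."""
    n = 0
    i = pos - 1
    while i >= 0 and ref[i] == base:
        n += 1
        i -= 1
    i = pos + len(deleted)
    n += len(deleted)
    while i < len(ref) and ref[i] == base:
        n += 1
        i += 1
    if deleted:
        return n
    # insertion: also count the reference base at pos itself via loop above
    return n


def _differences_from_alignment(query: str, sub_ref: str, ref: str, rs: int,
                                result: dict, homopoly_min: int) -> list[Difference]:
    """Parse an edlib path over (query, sub_ref) into Differences with
    global reference positions; ``ref`` provides homopolymer-run context."""
    nice = edlib.getNiceAlignment(result, query, sub_ref)
    qa, ta = nice["query_aligned"], nice["target_aligned"]
    diffs: list[Difference] = []
    ref_pos = rs
    i = 0
    while i < len(qa):
        if qa[i] == ta[i]:
            ref_pos += 1
            i += 1
            continue
        if qa[i] != "-" and ta[i] != "-":
            diffs.append(Difference(ref_pos, "substitution", ta[i], qa[i]))
            ref_pos += 1
            i += 1
            continue
        j = i
        while j < len(qa) and (qa[j] == "-" or ta[j] == "-") and qa[j] != ta[j]:
            if (qa[j] == "-") != (qa[i] == "-"):
                break
            j += 1
        if ta[i] == "-":  # insertion in contig
            ins = qa[i:j]
            kind = "other_indel"
            if len(set(ins)) == 1:
                run = _homopolymer_run_len(ref, ref_pos, ins[0])
                if run + len(ins) >= homopoly_min and run >= 1:
                    kind = "homopolymer_indel"
            diffs.append(Difference(ref_pos, kind, "", ins))
        else:  # deletion from contig
            dele = ta[i:j]
            kind = "other_indel"
            if len(set(dele)) == 1:
                run = _homopolymer_run_len(ref, ref_pos, dele[0], deleted=dele)
                if run >= homopoly_min:
                    kind = "homopolymer_indel"
            diffs.append(Difference(ref_pos, kind, dele, ""))
            ref_pos += len(dele)
        i = j
    return diffs


def align_contigs(
    contigs: dict[str, str],
    reference: str,
    min_segment: int = 100,
    min_identity: float = 0.95,
    k: int = 15,
    max_join: int = 120,
    max_chain_indel: int = 30,
    max_hits: int = 10,
    homopoly_min: int = 3,
) -> list[AlignmentSegment]:
    """Chained local alignments of each contig against the reference.

    A contig may yield several segments (one per colinear block); segments
    shorter than ``min_segment`` or below ``min_identity`` are discarded.
    """
    if not reference:
        raise ValueError("reference must be non-empty")
    if not contigs:
        return []
    index = build_ref_index(reference, k, max_hits)
    segments: list[AlignmentSegment] = []
    for cid, contig in contigs.items():
        cands: list[tuple[int, int, int, int, int]] = []
        for flag, query in ((0, contig), (1, revcomp(contig))):
            chains = _chain_anchors(query, index, k, max_join, max_chain_indel)
            spans = [_extend_exact(query, reference, ch, k) for ch in chains
                     if ch.last_q + k - ch.start_q >= min(min_segment, 2 * k)]
            for qs, qe, rs, re_ in _merge_colinear(spans):
                if qe - qs >= min_segment:
                    cands.append((qs, qe, rs, re_, flag))
        for qs, qe, rs, re_, flag in _select_chains(cands):
            query = contig if flag == 0 else revcomp(contig)
            sub_q, sub_r = query[qs:qe], reference[rs:re_]
            if sub_q == sub_r:
                identity, diffs = 1.0, []
            else:
                res = edlib.align(sub_q, sub_r, mode="NW", task="path")
                identity = 1.0 - res["editDistance"] / max(len(sub_q), len(sub_r))
                diffs = _differences_from_alignment(sub_q, sub_r, reference, rs,
                                                    res, homopoly_min)
            if identity < min_identity:
                continue
            if flag == 0:
                c_int = (qs, qe)
            else:
                c_int = (len(contig) - qe, len(contig) - qs)
            segments.append(AlignmentSegment(
                cid, c_int, (rs, re_), "+" if flag == 0 else "-", identity, diffs
            ))
    segments.sort(key=lambda s: (s.contig_id, s.contig_interval))
    return segments
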