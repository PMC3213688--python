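"""Mate-pair scaffolding of per-clone contig sets.

The library's outer separation window is calibrated on a long contig with
1.5x-IQR whiskers. Pairs whose mates land on different contigs, face outward
across a contig end, and whose summed distances to those ends fit inside the
upper whisker become *bridges*; exact-coordinate duplicate pairs are
collapsed first. Bridge support is normalized per clone (mate pairs per
junction / all bridging mate pairs of the clone) and thresholded; the
surviving junctions enter an end-graph (two vertices per contig plus one
directed intra-contig edge) where contig ends bridged to more than one
partner are conflicts. Conflict-free simple paths become scaffolds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median

import networkx as nx

from ._util import revcomp, round_half_up
from .pooltools import WhiskerSummary, whisker_summary
from .refcompare import length_stats

HEAD, TAIL = "head", "tail"


@dataclass
class ReadPlacement:
    read_id: str
    contig_id: str
    start: int
    strand: str
    mate_id: str
    length: int = 36


@dataclass
class BridgeSupport:
    """Mate-pair evidence joining two contig ends."""

    bac_id: str
    contig_a: str
    end_a: str
    contig_b: str
    end_b: str
    mp_count: int
    normalized: float | None = None
    dist_sums: list[int] = field(default_factory=list)

    @property
    def implied_orientation(self) -> str:
        """'same' when b continues a's strand, 'flip' when b is reversed."""
        return "same" if {self.end_a, self.end_b} == {HEAD, TAIL} else "flip"

    @property
    def key(self):
        return (self.bac_id, self.contig_a, self.end_a, self.contig_b, self.end_b)


@dataclass
class Scaffold:
    scaffold_id: str
    members: list[tuple[str, str]]  # (contig_id, orientation)
    gaps: list[int]  # estimated gap after member i (len == members - 1)
    member_length: int

    @property
    def length(self) -> int:
        return self.member_length + sum(self.gaps)

    @property
    def n_contigs(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# placement


def _pointing(placement: ReadPlacement, contig_len: int,
              orientation: str = "outward") -> tuple[str, int]:
    """(contig end the mate points across, distance of its outer coordinate
    to that end). Outward libraries: a minus-strand read faces the tail, a
    plus-strand read faces the head; inward (forward-reverse) libraries are
    the mirror image."""
    minus_faces_tail = orientation == "outward"
    if (placement.strand == "-") == minus_faces_tail:
        return TAIL, contig_len - placement.start
    return HEAD, placement.start + placement.length


def place_mates(pairs, contigs: dict[str, str],
                mismatch_fallback: bool = True) -> tuple[list[ReadPlacement], dict]:
    """Place mate-pair reads on a clone's contig set by exact full-read match.

    A read is placed only when its best placement is unique within the
    contig set; reads matching more than one locus are dropped as ambiguous.
    Reads without an exact hit optionally retry with one mismatch.
    """
    window_index: dict[str, list[tuple[str, int]]] = {}
    lens = {len(p.read1.sequence) for p in pairs} | {len(p.read2.sequence) for p in pairs}
    for L in sorted(lens):
        for cid, seq in contigs.items():
            for i in range(len(seq) - L + 1):
                window_index.setdefault(seq[i : i + L], []).append((cid, i))

    stats = {"placed": 0, "ambiguous": 0, "unplaced": 0}

    def hits_for(seq: str) -> list[tuple[str, int, str]]:
        fwd = [(c, p, "+") for c, p in window_index.get(seq, ())]
        rev = [(c, p, "-") for c, p in window_index.get(revcomp(seq), ())]
        return fwd + rev

    def place(read, mate_id: str) -> ReadPlacement | None:
        hits = hits_for(read.sequence)
        if not hits and mismatch_fallback:
            seen = set()
            for i in range(len(read.sequence)):
                for b in "ACGT":
                    if b == read.sequence[i]:
                        continue
                    mut = read.sequence[:i] + b + read.sequence[i + 1:]
                    for h in hits_for(mut):
                        seen.add(h)
            hits = sorted(seen)
        if len(hits) == 1:
            cid, pos, strand = hits[0]
            stats["placed"] += 1
            return ReadPlacement(read.read_id, cid, pos, strand, mate_id,
                                 len(read.sequence))
        stats["ambiguous" if hits else "unplaced"] += 1
        return None

    placements: list[ReadPlacement] = []
    for pair in pairs:
        for read in (pair.read1, pair.read2):
            p = place(read, pair.pair_id)
            if p is not None:
                placements.append(p)
    return placements, stats


def estimate_insert_bounds(placements: list[ReadPlacement],
                           min_pairs: int = 100) -> WhiskerSummary:
    """Calibrate the library separation window from proper pairs on one
    (long) contig: outer separations summarized with 1.5x-IQR whiskers."""
    by_mate: dict[str, list[ReadPlacement]] = {}
    for p in placements:
        by_mate.setdefault(p.mate_id, []).append(p)
    seps: list[int] = []
    for mates in by_mate.values():
        if len(mates) != 2:
            continue
        a, b = mates
        if a.contig_id != b.contig_id or a.strand == b.strand:
            continue
        left, right = (a, b) if a.start <= b.start else (b, a)
        if left.strand == "-" and right.strand == "+":  # outward-facing
            seps.append(right.start + right.length - left.start)
    if len(seps) < min_pairs:
        raise ValueError(
            f"only {len(seps)} proper pairs on the calibration contig "
            f"(need >= {min_pairs}); choose a longer contig"
        )
    return whisker_summary(seps)


# ---------------------------------------------------------------------------
# bridges


def extract_bridges(
    placements: list[ReadPlacement],
    contig_lengths: dict[str, int],
    bounds: tuple[float, float],
    bac_id: str = "",
    orientation: str = "outward",
) -> tuple[list[BridgeSupport], int]:
    """Aggregate mate pairs into contig-end bridges.

    Keeps pairs whose mates sit on different contigs with the summed
    distances of their outer coordinates to the ends they face within the
    upper bound; exact-coordinate duplicate pairs ("duplicons") collapse to
    one. Returns (bridges, number of duplicates removed).
    """
    _, upper = bounds
    by_mate: dict[str, list[ReadPlacement]] = {}
    for p in placements:
        by_mate.setdefault(p.mate_id, []).append(p)

    seen_coords: set[tuple] = set()
    duplicates = 0
    agg: dict[tuple, BridgeSupport] = {}
    for mate_id, mates in sorted(by_mate.items()):
        if len(mates) != 2:
            continue
        a, b = mates
        if a.contig_id == b.contig_id:
            continue
        coord_key = tuple(sorted(
            ((m.contig_id, m.start, m.strand) for m in (a, b))
        ))
        if coord_key in seen_coords:
            duplicates += 1
            continue
        seen_coords.add(coord_key)
        end_a, dist_a = _pointing(a, contig_lengths[a.contig_id], orientation)
        end_b, dist_b = _pointing(b, contig_lengths[b.contig_id], orientation)
        if dist_a + dist_b > upper:
            continue
        (c1, e1, c2, e2) = (a.contig_id, end_a, b.contig_id, end_b)
        if c2 < c1:
            c1, e1, c2, e2 = c2, e2, c1, e1
        key = (bac_id, c1, e1, c2, e2)
        br = agg.get(key)
        if br is None:
            br = agg[key] = BridgeSupport(bac_id, c1, e1, c2, e2, 0)
        br.mp_count += 1
        br.dist_sums.append(dist_a + dist_b)
    return list(agg.values()), duplicates


def normalize_support(bridges: list[BridgeSupport]) -> tuple[list[BridgeSupport], dict[str, int]]:
    """Normalize each bridge's count to the clone's total bridging MPs;
    normalized values sum to 1 per clone."""
    totals: dict[str, int] = {}
    for br in bridges:
        totals[br.bac_id] = totals.get(br.bac_id, 0) + br.mp_count
    for br in bridges:
        br.normalized = br.mp_count / totals[br.bac_id]
    return bridges, totals


def support_histogram(values, bin_width: float = 0.02) -> list[tuple[float, float, int]]:
    """Right-closed bins (0, w], (w, 2w], ... over (0, 1] for diagnostics."""
    import math

    n_bins = int(math.ceil(1.0 / bin_width))
    counts = [0] * n_bins
    for v in values:
        if not 0 < v <= 1:
            raise ValueError(f"normalized support {v} outside (0, 1]")
        idx = min(n_bins - 1, int(math.ceil(v / bin_width)) - 1)
        counts[idx] += 1
    return [(i * bin_width, (i + 1) * bin_width, c) for i, c in enumerate(counts)]


# ---------------------------------------------------------------------------
# scaffold graph


def build_scaffold_graph(bridges: list[BridgeSupport],
                         contigs: list[str]) -> nx.Graph:
    """End-graph: two vertices per contig joined by an intra-contig edge;
    bridges are undirected edges between end vertices of distinct contigs."""
    g = nx.Graph()
    for cid in contigs:
        g.add_edge((cid, HEAD), (cid, TAIL), kind="contig")
    for br in bridges:
        g.add_edge((br.contig_a, br.end_a), (br.contig_b, br.end_b),
                   kind="bridge", support=br)
    return g


def _resolve_conflicts(bridges: list[BridgeSupport], policy: str,
                       ratio_min: float) -> tuple[list[BridgeSupport], list[dict]]:
    incident: dict[tuple, list[BridgeSupport]] = {}
    for br in bridges:
        incident.setdefault((br.contig_a, br.end_a), []).append(br)
        incident.setdefault((br.contig_b, br.end_b), []).append(br)
    dropped: set[tuple] = set()
    conflicts: list[dict] = []
    for end, incid in sorted(incident.items()):
        if len(incid) < 2:
            continue
        ranked = sorted(incid, key=lambda b: b.normalized or 0, reverse=True)
        resolved = (policy == "ratio"
                    and (ranked[0].normalized or 0)
                    >= ratio_min * (ranked[1].normalized or 0))
        conflicts.append({
            "end": end,
            "options": [b.key for b in ranked],
            "supports": [b.normalized for b in ranked],
            "resolved": resolved,
        })
        losers = ranked[1:] if resolved else ranked
        for b in losers:
            dropped.add(b.key)
    return [b for b in bridges if b.key not in dropped], conflicts


def build_scaffolds(
    bridges: list[BridgeSupport],
    contig_lengths: dict[str, int],
    threshold: float = 0.02,
    conflict_policy: str = "strict",
    ratio_min: float = 2.0,
    insert_median: float = 2825.0,
) -> tuple[list[Scaffold], list[str], list[dict]]:
    """Threshold, resolve conflicts, and read simple paths off the end-graph.

    Returns (scaffolds, unscaffolded contig ids, conflict records). In
    ``strict`` policy every bridge at a multiply-bridged end is removed; in
    ``ratio`` policy the strongest survives if it beats every competitor by
    ``ratio_min``. Gap sizes are the per-junction median of
    (insert median - summed end distances), floored at 1 bp.
    """
    if conflict_policy not in ("strict", "ratio"):
        raise ValueError(f"unknown conflict policy {conflict_policy!r}")
    if any(b.normalized is None for b in bridges):
        raise ValueError("bridges must be normalized first")
    candidates = [b for b in bridges if (b.normalized or 0) > threshold]
    kept, conflicts = _resolve_conflicts(candidates, conflict_policy, ratio_min)
    g = build_scaffold_graph(kept, sorted(contig_lengths))

    scaffolds: list[Scaffold] = []
    unscaffolded: list[str] = []
    for comp in sorted(nx.connected_components(g), key=lambda c: sorted(c)[0]):
        contig_ids = sorted({cid for cid, _end in comp})
        sub = g.subgraph(comp)
        endpoints = sorted(n for n in comp if sub.degree(n) == 1)
        if len(contig_ids) < 2:
            unscaffolded.extend(contig_ids)
            continue
        if not endpoints or any(sub.degree(n) > 2 for n in comp):
            # cycle (or residual branch): leave unscaffolded, report
            unscaffolded.extend(contig_ids)
            conflicts.append({"end": None, "options": contig_ids,
                              "supports": [], "resolved": False,
                              "reason": "cycle"})
            continue
        path = nx.shortest_path(sub, endpoints[0], endpoints[1])
        members: list[tuple[str, str]] = []
        gaps: list[int] = []
        for u, v in zip(path, path[1:]):
            if sub.edges[u, v]["kind"] == "contig":
                cid = u[0]
                members.append((cid, "+" if u[1] == HEAD else "-"))
            else:
                br: BridgeSupport = sub.edges[u, v]["support"]
                if br.dist_sums:
                    gap = round_half_up(median(insert_median - d for d in br.dist_sums))
                else:  # no per-pair distances recorded: floor
                    gap = 1
                gaps.append(max(1, gap))
        member_length = sum(contig_lengths[c] for c, _o in members)
        scaffolds.append(Scaffold(f"scaffold{len(scaffolds):04d}", members,
                                  gaps, member_length))
    return scaffolds, unscaffolded, conflicts


# ---------------------------------------------------------------------------
# before/after statistics


def scaffold_stats(contig_lengths: dict[str, int], scaffolds: list[Scaffold],
                   unscaffolded: list[str]) -> dict:
    """Before/after length statistics and per-metric fold changes.

    "After" units are scaffold lengths (members plus estimated gaps)
    together with the unscaffolded contig lengths. Also reports the
    conservation split of total contig length into scaffolded members and
    leftovers.
    """
    before = length_stats(list(contig_lengths.values()))
    after_units = [s.length for s in scaffolds] + [contig_lengths[c] for c in unscaffolded]
    after = length_stats(after_units)
    fold = {
        **{f"L{p}": round(after.L[p] / before.L[p], 1) for p in before.L},
        **{f"N{p}": round(after.N[p] / before.N[p], 1) for p in before.N},
        "mean": round(after.mean / before.mean, 1),
        "maximum": round(after.maximum / before.maximum, 1),
    }
    scaffolded_len = sum(s.member_length for s in scaffolds)
    leftover_len = sum(contig_lengths[c] for c in unscaffolded)
    total = sum(contig_lengths.values())
    return {
        "before": before,
        "after": after,
        "fold_change": fold,
        "scaffolded_length": scaffolded_len,
        "unscaffolded_length": leftover_len,
        "total_length": total,
        "scaffolded_fraction": round(scaffolded_len / total, 2) if total else 0.0,
    }
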