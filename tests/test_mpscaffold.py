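"""Mate placement, bridge extraction/normalization, conflict handling and
scaffold statistics tests."""

import numpy as np
import pytest

from bacpool import mpscaffold as mp
from bacpool import simulate as sim
from bacpool.mpscaffold import HEAD, TAIL, BridgeSupport, ReadPlacement


def _pl(rid, cid, start, strand, mate, length=36):
    return ReadPlacement(rid, cid, start, strand, mate, length)


@pytest.fixture(scope="module")
def placed_calibration(mp_pool):
    ins = mp_pool.inserts[0]
    own = [p for p in mp_pool.pairs if p.read1.bac_id == ins.bac_id]
    placements, _ = mp.place_mates(own, {"calib": ins.sequence},
                                   mismatch_fallback=False)
    return placements


class TestPlaceMates:
    def test_unique_substring_placed(self, mp_pool):
        pair = sim.simulate_mp_library(mp_pool.inserts[:1], 1,
                                       duplicate_rate=0, seed=9)[0]
        contigs = {"c0": mp_pool.inserts[0].sequence}
        placements, stats = mp.place_mates([pair], contigs)
        assert stats["placed"] == 2
        by_id = {p.read_id: p for p in placements}
        p1 = by_id[pair.read1.read_id]
        assert (p1.start, p1.strand) == (pair.read1.true_start, "-")
        p2 = by_id[pair.read2.read_id]
        assert (p2.start, p2.strand) == (pair.read2.true_start, "+")

    def test_ambiguous_read_dropped(self, mp_pool):
        pair = sim.simulate_mp_library(mp_pool.inserts[:1], 1,
                                       duplicate_rate=0, seed=9)[0]
        seq = mp_pool.inserts[0].sequence
        contigs = {"c0": seq, "c1": seq}  # duplicated contig set
        _, stats = mp.place_mates([pair], contigs)
        assert stats["ambiguous"] == 2 and stats["placed"] == 0

    def test_error_free_library_places_at_truth(self, mp_pool):
        """>= 99% of error-free mates place at their true coordinates."""
        ins = mp_pool.inserts[0]
        own = [p for p in mp_pool.pairs if p.read1.bac_id == ins.bac_id][:400]
        contigs = {cid: s for cid, s in mp_pool.contigs.items()
                   if mp_pool.layout[cid][0][0] == ins.bac_id}
        placements, stats = mp.place_mates(own, contigs, mismatch_fallback=False)
        correct = 0
        for p in placements:
            cid = p.contig_id
            _bac, (a, _b), _s = mp_pool.layout[cid][0]
            read = next(r for pair in own for r in (pair.read1, pair.read2)
                        if r.read_id == p.read_id)
            if p.start + a == read.true_start:
                correct += 1
        placeable = sum(
            1 for pair in own for r in (pair.read1, pair.read2)
            if any(a <= r.true_start and r.true_start + 36 <= b
                   for cid in contigs for _bac, (a, b), _s in mp_pool.layout[cid])
        )
        assert correct >= 0.99 * placeable


class TestInsertBounds:
    def test_simulated_median_recovered(self, placed_calibration):
        w = mp.estimate_insert_bounds(placed_calibration)
        assert 2750 <= w.median <= 2900

    def test_whisker_containment_realistic(self, placed_calibration, mp_pool):
        """Most pairs fall inside the whisker window, as for a real library
        with a minority artifact class (printed value: 87%)."""
        w = mp.estimate_insert_bounds(placed_calibration)
        ins = mp_pool.inserts[0]
        seps = [p.true_separation for p in mp_pool.pairs
                if p.read1.bac_id == ins.bac_id]
        inside = np.mean([(w.lower <= s <= w.upper) for s in seps])
        assert 0.82 <= inside <= 0.95

    def test_identical_separations_collapse_bounds(self):
        placements = []
        for i in range(120):
            placements += [
                _pl(f"m{i}/1", "c", 1000 + 10 * i, "-", f"m{i}"),
                _pl(f"m{i}/2", "c", 1000 + 10 * i + 2789 - 36, "+", f"m{i}"),
            ]
        w = mp.estimate_insert_bounds(placements)
        assert w.lower == w.median == w.upper == 2789

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="longer"):
            mp.estimate_insert_bounds([])


def brute_force_bridges(placements, contig_lengths, upper, bac_id=""):
    """Independent all-pairs oracle for extract_bridges."""
    by_mate = {}
    for p in placements:
        by_mate.setdefault(p.mate_id, []).append(p)
    seen = set()
    agg = {}
    dups = 0
    for mate_id in sorted(by_mate):
        mates = by_mate[mate_id]
        if len(mates) != 2:
            continue
        a, b = mates
        if a.contig_id == b.contig_id:
            continue
        coords = tuple(sorted((m.contig_id, m.start, m.strand) for m in mates))
        if coords in seen:
            dups += 1
            continue
        seen.add(coords)
        ends = []
        dist_sum = 0
        for m in (a, b):
            if m.strand == "-":
                end, d = TAIL, contig_lengths[m.contig_id] - m.start
            else:
                end, d = HEAD, m.start + m.length
            ends.append((m.contig_id, end))
            dist_sum += d
        if dist_sum > upper:
            continue
        (c1, e1), (c2, e2) = sorted(ends)
        agg[(c1, e1, c2, e2)] = agg.get((c1, e1, c2, e2), 0) + 1
    return agg, dups


class TestExtractBridges:
    LENGTHS = {"c1": 10_000, "c2": 8_000}

    def test_same_contig_no_bridge(self):
        placements = [_pl("m0/1", "c1", 100, "-", "m0"),
                      _pl("m0/2", "c1", 2800, "+", "m0")]
        bridges, _ = mp.extract_bridges(placements, self.LENGTHS, (0, 3742))
        assert bridges == []

    def test_distance_sum_rule(self):
        # tail of c1 at 1,000 bp + head of c2 at 2,000 bp: 3,000 <= 3,742
        placements = [_pl("m0/1", "c1", 9_000, "-", "m0"),
                      _pl("m0/2", "c2", 2_000 - 36, "+", "m0")]
        bridges, _ = mp.extract_bridges(placements, self.LENGTHS, (0, 3742))
        (br,) = bridges
        assert (br.contig_a, br.end_a, br.contig_b, br.end_b) == \
            ("c1", TAIL, "c2", HEAD)
        assert br.dist_sums == [3000]
        # push the sum past the bound: dropped
        far = [_pl("m1/1", "c1", 8_000, "-", "m1"),
               _pl("m1/2", "c2", 2_000 - 36, "+", "m1")]
        bridges, _ = mp.extract_bridges(far, self.LENGTHS, (0, 3742))
        assert bridges == []

    def test_duplicate_pairs_collapse(self):
        placements = []
        for mate in ("m0", "m1"):
            placements += [_pl(f"{mate}/1", "c1", 9_500, "-", mate),
                           _pl(f"{mate}/2", "c2", 400, "+", mate)]
        bridges, dups = mp.extract_bridges(placements, self.LENGTHS, (0, 3742))
        assert dups == 1
        assert bridges[0].mp_count == 1

    def test_idempotent_after_duplicate_removal(self, mp_pool):
        ins = mp_pool.inserts[0]
        contigs = {cid: s for cid, s in mp_pool.contigs.items()
                   if mp_pool.layout[cid][0][0] == ins.bac_id}
        lengths = {c: len(s) for c, s in contigs.items()}
        own = [p for p in mp_pool.pairs if p.read1.bac_id == ins.bac_id]
        placements, _ = mp.place_mates(own, contigs, mismatch_fallback=False)
        bridges, dups = mp.extract_bridges(placements, lengths, (0, 3742))
        again, dups2 = mp.extract_bridges(placements, lengths, (0, 3742))
        assert dups2 == dups
        assert {b.key: b.mp_count for b in again} == {b.key: b.mp_count for b in bridges}

    def test_matches_brute_force_oracle(self, mp_pool):
        """Aggregated bridges equal an independent all-pairs filter on real
        simulated placements."""
        ins = mp_pool.inserts[1]
        contigs = {cid: s for cid, s in mp_pool.contigs.items()
                   if mp_pool.layout[cid][0][0] == ins.bac_id}
        lengths = {c: len(s) for c, s in contigs.items()}
        own = [p for p in mp_pool.pairs if p.read1.bac_id == ins.bac_id][:100]
        placements, _ = mp.place_mates(own, contigs, mismatch_fallback=False)
        assert len(placements) <= 200
        bridges, dups = mp.extract_bridges(placements, lengths, (0, 3742))
        oracle, oracle_dups = brute_force_bridges(placements, lengths, 3742)
        assert dups == oracle_dups
        assert {(b.contig_a, b.end_a, b.contig_b, b.end_b): b.mp_count
                for b in bridges} == oracle


class TestNormalizeAndHistogram:
    def _bridge(self, a, b, n, bac="B"):
        return BridgeSupport(bac, a, TAIL, b, HEAD, n)

    def test_single_bridge(self):
        bridges, totals = mp.normalize_support([self._bridge("c1", "c2", 7)])
        assert bridges[0].normalized == 1.0
        assert totals == {"B": 7}

    def test_98_2_split_and_threshold(self):
        bridges, _ = mp.normalize_support(
            [self._bridge("c1", "c2", 98), self._bridge("c3", "c4", 2)]
        )
        assert sorted(b.normalized for b in bridges) == [0.02, 0.98]
        # strictly-greater threshold excludes the 0.02 bridge
        kept = [b for b in bridges if b.normalized > 0.02]
        assert len(kept) == 1 and kept[0].mp_count == 98

    def test_per_bac_sums_to_one(self):
        bridges = [self._bridge("c1", "c2", 5, "A"),
                   self._bridge("c3", "c4", 15, "A"),
                   self._bridge("c5", "c6", 9, "B")]
        bridges, _ = mp.normalize_support(bridges)
        for bac in ("A", "B"):
            assert sum(b.normalized for b in bridges if b.bac_id == bac) == \
                pytest.approx(1.0)

    def test_histogram_edges(self):
        hist = mp.support_histogram([1.0, 1.0, 0.02, 0.021])
        assert hist[0][2] == 1    # 0.02 falls in the first (right-closed) bin
        assert hist[1][2] == 1    # 0.021 in the second
        assert hist[-1][2] == 2   # both 1.0 values in the top bin

    def test_histogram_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            mp.support_histogram([0.0])


class TestBuildScaffolds:
    def _bridges(self, spec):
        bridges = [BridgeSupport("B", a, ea, b, eb, n)
                   for (a, ea, b, eb), n in spec.items()]
        bridges, _ = mp.normalize_support(bridges)
        return bridges

    LENGTHS = {"A": 5_000, "B": 4_000, "C": 6_000}

    def test_no_bridges_all_unscaffolded(self):
        scaffolds, leftovers, conflicts = mp.build_scaffolds([], self.LENGTHS)
        assert scaffolds == [] and sorted(leftovers) == ["A", "B", "C"]

    def test_chain_becomes_one_scaffold(self):
        bridges = self._bridges({("A", TAIL, "B", HEAD): 50,
                                 ("B", TAIL, "C", HEAD): 50})
        scaffolds, leftovers, conflicts = mp.build_scaffolds(bridges, self.LENGTHS)
        assert leftovers == [] and conflicts == []
        (sc,) = scaffolds
        members = sc.members
        assert members in (
            [("A", "+"), ("B", "+"), ("C", "+")],
            [("C", "-"), ("B", "-"), ("A", "-")],
        )
        assert sc.member_length == 15_000

    def test_conflict_strict_vs_ratio(self):
        # A's tail bridged to both B (0.50-strength) and C (0.10)
        bridges = self._bridges({("A", TAIL, "B", HEAD): 50,
                                 ("A", TAIL, "C", HEAD): 10,
                                 ("B", TAIL, "C", TAIL): 40})
        strict, _, conflicts = mp.build_scaffolds(bridges, self.LENGTHS,
                                                  conflict_policy="strict")
        assert any(c["end"] == ("A", TAIL) for c in conflicts)
        assert all("A" not in [m[0] for m in s.members] for s in strict)
        ratio, _, rconf = mp.build_scaffolds(bridges, self.LENGTHS,
                                             conflict_policy="ratio")
        joined = [s for s in ratio
                  if {"A", "B"} <= {m[0] for m in s.members}]
        assert joined and rconf[0]["resolved"]

    def test_ratio_below_minimum_not_resolved(self):
        bridges = self._bridges({("A", TAIL, "B", HEAD): 30,
                                 ("A", TAIL, "C", HEAD): 20})
        scaffolds, leftovers, conflicts = mp.build_scaffolds(
            bridges, self.LENGTHS, conflict_policy="ratio", ratio_min=2.0)
        assert scaffolds == []
        assert not conflicts[0]["resolved"]

    def test_cycle_reported_unscaffolded(self):
        bridges = self._bridges({("A", TAIL, "B", HEAD): 30,
                                 ("B", TAIL, "C", HEAD): 30,
                                 ("C", TAIL, "A", HEAD): 30})
        scaffolds, leftovers, conflicts = mp.build_scaffolds(bridges, self.LENGTHS)
        assert scaffolds == []
        assert sorted(leftovers) == ["A", "B", "C"]
        assert any(c.get("reason") == "cycle" for c in conflicts)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            mp.build_scaffolds([BridgeSupport("B", "A", TAIL, "B", HEAD, 5)],
                               self.LENGTHS)


class TestTruthRecovery:
    def test_strict_scaffolds_reproduce_true_order(self, mp_pool):
        """With abundant error-free mates and unique junction support the
        strict policy recovers the true contig order and orientation."""
        calib = {"calib": mp_pool.inserts[0].sequence}
        own0 = [p for p in mp_pool.pairs
                if p.read1.bac_id == mp_pool.inserts[0].bac_id]
        placed, _ = mp.place_mates(own0, calib, mismatch_fallback=False)
        w = mp.estimate_insert_bounds(placed)
        for ins in mp_pool.inserts:
            contigs = {cid: s for cid, s in mp_pool.contigs.items()
                       if mp_pool.layout[cid][0][0] == ins.bac_id}
            lengths = {c: len(s) for c, s in contigs.items()}
            pairs = [p for p in mp_pool.pairs if p.read1.bac_id == ins.bac_id]
            placements, _ = mp.place_mates(pairs, contigs, mismatch_fallback=False)
            bridges, _ = mp.extract_bridges(placements, lengths,
                                            (w.lower, w.upper), ins.bac_id)
            bridges, _ = mp.normalize_support(bridges)
            scaffolds, leftovers, conflicts = mp.build_scaffolds(bridges, lengths)
            true_order = sorted(lengths, key=lambda c: mp_pool.layout[c][0][1][0])
            assert len(scaffolds) == 1 and not leftovers
            members = [c for c, _o in scaffolds[0].members]
            orients = [o for _c, o in scaffolds[0].members]
            assert (members == true_order and set(orients) == {"+"}) or \
                   (members == true_order[::-1] and set(orients) == {"-"})

    def test_injected_competing_junction(self, mp_pool):
        """A competing bridge at 5:1 support is a conflict under strict
        policy and resolves to the true junction under ratio policy."""
        ins = mp_pool.inserts[0]
        contigs = {cid: s for cid, s in mp_pool.contigs.items()
                   if mp_pool.layout[cid][0][0] == ins.bac_id}
        lengths = {c: len(s) for c, s in contigs.items()}
        pairs = [p for p in mp_pool.pairs if p.read1.bac_id == ins.bac_id]
        placements, _ = mp.place_mates(pairs, contigs, mismatch_fallback=False)
        bridges, _ = mp.extract_bridges(placements, lengths, (0, 3742),
                                        ins.bac_id)
        true_order = sorted(lengths, key=lambda c: mp_pool.layout[c][0][1][0])
        first = next(b for b in bridges
                     if {b.contig_a, b.contig_b} == {true_order[0], true_order[1]})
        # inject a fake competitor at one fifth of the true support
        fake = BridgeSupport(ins.bac_id, first.contig_a, first.end_a,
                             true_order[3], TAIL, max(1, first.mp_count // 5),
                             dist_sums=[2000] * max(1, first.mp_count // 5))
        bridges, _ = mp.normalize_support(bridges + [fake])
        strict, _, sconf = mp.build_scaffolds(bridges, lengths,
                                              conflict_policy="strict")
        conflicted_end = (first.contig_a, first.end_a)
        assert any(c["end"] == conflicted_end for c in sconf)
        assert all(true_order[0] not in [m[0] for m in s.members]
                   or true_order[1] not in [m[0] for m in s.members]
                   for s in strict)
        ratio, _, rconf = mp.build_scaffolds(bridges, lengths,
                                             conflict_policy="ratio")
        rec = next(c for c in rconf if c["end"] == conflicted_end)
        assert rec["resolved"]
        joined = [s for s in ratio
                  if {true_order[0], true_order[1]} <= {m[0] for m in s.members}]
        assert joined


class TestScaffoldStats:
    def test_no_scaffolding_folds_are_one(self):
        lengths = {"a": 10_000, "b": 5_000, "c": 2_000}
        stats = mp.scaffold_stats(lengths, [], list(lengths))
        assert all(v == 1.0 for v in stats["fold_change"].values())
        assert stats["scaffolded_fraction"] == 0.0

    def test_conservation_identity(self, mp_pool):
        ins = mp_pool.inserts[2]
        contigs = {cid: s for cid, s in mp_pool.contigs.items()
                   if mp_pool.layout[cid][0][0] == ins.bac_id}
        lengths = {c: len(s) for c, s in contigs.items()}
        pairs = [p for p in mp_pool.pairs if p.read1.bac_id == ins.bac_id]
        placements, _ = mp.place_mates(pairs, contigs, mismatch_fallback=False)
        bridges, _ = mp.extract_bridges(placements, lengths, (0, 3742), ins.bac_id)
        bridges, _ = mp.normalize_support(bridges)
        scaffolds, leftovers, _ = mp.build_scaffolds(bridges, lengths)
        stats = mp.scaffold_stats(lengths, scaffolds, leftovers)
        assert (stats["scaffolded_length"] + stats["unscaffolded_length"]
                == stats["total_length"] == sum(lengths.values()))

    def test_scaffolding_never_decreases_lp(self, mp_pool):
        for ins in mp_pool.inserts:
            contigs = {cid: s for cid, s in mp_pool.contigs.items()
                       if mp_pool.layout[cid][0][0] == ins.bac_id}
            lengths = {c: len(s) for c, s in contigs.items()}
            pairs = [p for p in mp_pool.pairs if p.read1.bac_id == ins.bac_id]
            placements, _ = mp.place_mates(pairs, contigs, mismatch_fallback=False)
            bridges, _ = mp.extract_bridges(placements, lengths, (0, 3742),
                                            ins.bac_id)
            bridges, _ = mp.normalize_support(bridges)
            scaffolds, leftovers, _ = mp.build_scaffolds(bridges, lengths)
            stats = mp.scaffold_stats(lengths, scaffolds, leftovers)
            for p in (50, 80, 90):
                assert stats["after"].L[p] >= stats["before"].L[p]
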