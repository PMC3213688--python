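"""Synthetic BAC-pool generator.

Emulates the data structure of pooled BAC sequencing experiments: a pool of
~48 large-insert clones that share repeat families, pyrosequencing-style
shotgun reads whose errors are dominated by homopolymer indels, a short-read
mate-pair library with ~3 kb outer separation, and contig sets derived from
the true insert tiling into which structural defects (misassemblies, gaps,
chimeric joins) are injected with full ground truth.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._util import (
    merge_intervals,
    random_sequence,
    revcomp,
    round_half_up,
    spawn_rng,
)

Interval = tuple[int, int]
LayoutSegment = tuple[str, Interval, str]  # (bac_id, reference interval, strand)

REPEAT_KINDS = ("LTR", "tandem", "low_complexity")
CHIMERA_KINDS = ("repeat_only", "nonrep_to_rep", "nonrep_to_nonrep")

#: Read-length regimes. "FLX-like" is a truncated normal; "Titanium-like"
#: mixes a main normal component with a 10% long-read tail uniform on
#: [400, 600] so that the overall mean lands at ~263 bp.
READ_PROFILES = {
    "FLX-like": {"mean": 223.0, "sd": 20.0, "max_len": 310, "long_frac": 0.0},
    "Titanium-like": {
        "mean": 237.0,
        "sd": 25.0,
        "max_len": 600,
        "long_frac": 0.10,
        "long_range": (400, 600),
    },
}

#: Error-class proportions observed for pyrosequencing: roughly 46%
#: homopolymer indels, 27% other indels, 27% substitutions, at a default
#: per-base total of 1%.
DEFAULT_ERROR_MODEL = {
    "homopoly_indel": 0.0046,
    "other_indel": 0.0027,
    "substitution": 0.0027,
}

MIN_READ_LEN = 50


@dataclass(frozen=True)
class RepeatFamily:
    """A repeat family planted into inserts.

    ``divergence`` is the per-base substitution rate applied independently to
    every planted copy; ``copy_count`` is the number of copies per carrying
    insert. Tandem families hold the repeat *unit* (<= 20 bp) as consensus
    and are planted as tiled tracts.
    """

    family_id: str
    consensus: str
    kind: str
    copy_count: int = 1
    divergence: float = 0.02

    def __post_init__(self) -> None:
        if not self.consensus or set(self.consensus) - set("ACGT"):
            raise ValueError(f"{self.family_id}: consensus must be non-empty over ACGT")
        if self.kind not in REPEAT_KINDS:
            raise ValueError(f"{self.family_id}: unknown repeat kind {self.kind!r}")
        if self.kind == "tandem" and len(self.consensus) > 20:
            raise ValueError(f"{self.family_id}: tandem unit must be <= 20 bp")
        if self.copy_count < 1:
            raise ValueError(f"{self.family_id}: copy_count must be >= 1")
        if not 0.0 <= self.divergence <= 0.2:
            raise ValueError(f"{self.family_id}: divergence must be in [0, 0.2]")


@dataclass
class BacInsert:
    bac_id: str
    sequence: str
    repeat_annotations: list[tuple[int, int, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SimRead:
    read_id: str
    bac_id: str
    sequence: str  # clipped (barcode removed), errors applied
    true_start: int
    true_strand: str
    barcode: str | None = None

    @property
    def raw(self) -> str:
        """Sequence as it would come off the machine: barcode + insert part."""
        return (self.barcode or "") + self.sequence

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SimMatePair:
    pair_id: str
    read1: SimRead
    read2: SimRead
    true_separation: int
    is_duplicate: bool = False


@dataclass
class DefectSpec:
    n_misassemblies: int = 0
    n_gaps: int = 0
    n_chimeras: int = 0
    chimera_kinds: tuple[str, ...] = CHIMERA_KINDS

    def __post_init__(self) -> None:
        if min(self.n_misassemblies, self.n_gaps, self.n_chimeras) < 0:
            raise ValueError("defect counts must be non-negative")
        bad = set(self.chimera_kinds) - set(CHIMERA_KINDS)
        if bad:
            raise ValueError(f"unknown chimera kinds: {sorted(bad)}")


@dataclass
class PoolTruth:
    """Full ground truth of one simulated pool."""

    inserts: list[BacInsert]
    repeat_library: list[RepeatFamily]
    reads: list[SimRead]
    pairs: list[SimMatePair]
    contigs: dict[str, str]
    layout: dict[str, list[LayoutSegment]]
    recorded_gaps: dict[str, list[Interval]]  # bac_id -> inter-contig tiling gaps
    injected_defects: list[dict]
    seed: int

    def insert_by_id(self, bac_id: str) -> BacInsert:
        for ins in self.inserts:
            if ins.bac_id == bac_id:
                return ins
        raise KeyError(bac_id)


# ---------------------------------------------------------------------------
# pool construction


def default_repeat_library(rng: np.random.Generator | int = 0) -> list[RepeatFamily]:
    """A small library spanning the three repeat kinds (LTR, tandem TA
    microsatellite, low-complexity tract)."""
    if isinstance(rng, (int, np.integer)):
        rng = spawn_rng(int(rng), 901)
    # young LTR families: copies near-identical, so exact 20-mers are shared
    # across copies and pool k-mer frequency scales with copy number
    return [
        RepeatFamily("LTR1", random_sequence(2000, rng), "LTR", copy_count=2, divergence=0.005),
        RepeatFamily("LTR2", random_sequence(1200, rng), "LTR", copy_count=1, divergence=0.005),
        RepeatFamily("TA1", "TA", "tandem", copy_count=1, divergence=0.0),
        RepeatFamily("LOWC1", "AAAT" * 25, "low_complexity", copy_count=1, divergence=0.05),
    ]


def _diverge(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = list(seq)
    n_mut = rng.binomial(len(arr), rate)
    for pos in rng.choice(len(arr), size=min(n_mut, len(arr)), replace=False):
        old = arr[pos]
        arr[pos] = rng.choice([b for b in "ACGT" if b != old])
    return "".join(arr)


def _repeat_copy(fam: RepeatFamily, rng: np.random.Generator) -> str:
    if fam.kind == "tandem":
        n_units = int(rng.integers(30, 120))
        tract = (fam.consensus * n_units)[: n_units * len(fam.consensus)]
        return _diverge(tract, fam.divergence, rng)
    return _diverge(fam.consensus, fam.divergence, rng)


def make_bac_pool(
    n_bacs: int = 48,
    insert_length_range: Interval = (100_000, 125_000),
    repeat_config: list[RepeatFamily] | None = None,
    shared_repeat_fraction: float = 0.5,
    seed: int = 0,
) -> tuple[list[BacInsert], list[RepeatFamily]]:
    """Generate a pool of BAC inserts with planted, annotated repeat copies.

    A ``shared_repeat_fraction`` of the repeat families is planted into
    several inserts (the cross-clone repeats that drive chimera formation);
    the rest are private to a single insert.
    """
    if n_bacs < 1:
        raise ValueError("n_bacs must be >= 1")
    lo, hi = insert_length_range
    families = list(repeat_config) if repeat_config is not None else []
    longest = max((len(f.consensus) for f in families), default=0)
    if families and lo < 2 * max(longest, 1):
        raise ValueError(
            f"insert length {lo} too short for repeat consensus of {longest} bp"
        )
    rng = spawn_rng(seed, 1)
    inserts = [
        BacInsert(f"BAC{i:03d}", random_sequence(int(rng.integers(lo, hi + 1)), rng))
        for i in range(n_bacs)
    ]

    n_shared = int(round(shared_repeat_fraction * len(families)))
    for idx, fam in enumerate(families):
        shared = idx < n_shared and n_bacs >= 2
        n_carriers = int(rng.integers(2, min(4, n_bacs) + 1)) if shared else 1
        carriers = rng.choice(n_bacs, size=n_carriers, replace=False)
        for ci in carriers:
            ins = inserts[int(ci)]
            for _ in range(fam.copy_count):
                copy = _repeat_copy(fam, rng)
                if len(copy) > len(ins):
                    raise ValueError(
                        f"repeat {fam.family_id} longer than insert {ins.bac_id}"
                    )
                _plant(ins, copy, fam.family_id, rng)
    for ins in inserts:
        ins.repeat_annotations.sort()
    return inserts, families


def _plant(ins: BacInsert, copy: str, family_id: str, rng: np.random.Generator,
           margin: int = 200, max_tries: int = 200) -> None:
    """Place one repeat copy at a position clear of existing annotations."""
    occupied = [(max(0, s - margin), e + margin) for s, e, _ in ins.repeat_annotations]
    occupied = merge_intervals(occupied)
    for _ in range(max_tries):
        start = int(rng.integers(margin, len(ins) - len(copy) - margin))
        span = (start, start + len(copy))
        if not any(a < span[1] and span[0] < b for a, b in occupied):
            ins.sequence = ins.sequence[: span[0]] + copy + ins.sequence[span[1]:]
            ins.repeat_annotations.append((span[0], span[1], family_id))
            return
    raise ValueError(f"could not place repeat {family_id} in {ins.bac_id}")


# ---------------------------------------------------------------------------
# shotgun reads


def _sample_read_length(profile: dict, rng: np.random.Generator) -> int:
    if profile["long_frac"] > 0 and rng.random() < profile["long_frac"]:
        a, b = profile["long_range"]
        return int(rng.integers(a, b + 1))
    while True:
        length = int(round(rng.normal(profile["mean"], profile["sd"])))
        if MIN_READ_LEN <= length <= profile["max_len"]:
            return length


def _apply_errors(seq: str, error_model: dict, rng: np.random.Generator,
                  log: list, read_id: str) -> str:
    """Mutate one read per the three-class error model; log realized errors."""
    total = sum(error_model.values())
    if total <= 0:
        return seq
    n_err = rng.binomial(len(seq), total)
    if n_err == 0:
        return seq
    classes = list(error_model)
    probs = np.array([error_model[c] for c in classes]) / total
    arr = list(seq)
    for _ in range(n_err):
        kind = classes[int(rng.choice(len(classes), p=probs))]
        if kind == "substitution":
            pos = int(rng.integers(0, len(arr)))
            old = arr[pos]
            arr[pos] = str(rng.choice([b for b in "ACGT" if b != old]))
        elif kind == "homopoly_indel":
            pos = _pick_homopolymer_pos(arr, rng)
            if pos is None:
                continue  # no run >= 3 in this read
            _indel_at(arr, pos, rng, duplicate_base=True)
        else:  # other_indel, uniform placement
            pos = int(rng.integers(0, len(arr)))
            _indel_at(arr, pos, rng, duplicate_base=False)
        log.append((read_id, kind))
    return "".join(arr)


def _pick_homopolymer_pos(arr: list[str], rng: np.random.Generator) -> int | None:
    """A position inside a single-nucleotide run of length >= 3, or None."""
    runs = []
    i, n = 0, len(arr)
    while i < n:
        j = i + 1
        while j < n and arr[j] == arr[i]:
            j += 1
        if j - i >= 3:
            runs.append((i, j))
        i = j
    if not runs:
        return None
    a, b = runs[int(rng.integers(0, len(runs)))]
    return int(rng.integers(a, b))


def _indel_at(arr: list[str], pos: int, rng: np.random.Generator,
              duplicate_base: bool) -> None:
    if rng.random() < 0.5 and len(arr) > 1:
        del arr[pos]
    else:
        base = arr[pos] if duplicate_base else str(rng.choice(list("ACGT")))
        arr.insert(pos, base)


def make_barcode_map(bac_ids: list[str], length: int = 10, seed: int = 0) -> dict[str, str]:
    """Distinct fixed-length barcode tags, one per BAC."""
    rng = spawn_rng(seed, 7)
    tags: set[str] = set()
    out = {}
    for bac in bac_ids:
        while True:
            tag = random_sequence(length, rng)
            if tag not in tags:
                tags.add(tag)
                out[bac] = tag
                break
    return out


def simulate_shotgun_reads(
    inserts: list[BacInsert],
    profile: str | dict = "Titanium-like",
    depth: float = 20.0,
    error_model: dict | None = None,
    barcode_map: dict[str, str] | None = None,
    seed: int = 0,
) -> tuple[list[SimRead], list[tuple[str, str]]]:
    """Simulate shotgun reads to the requested fold-coverage per insert.

    Returns the reads and a log of realized errors as (read_id, class) pairs.
    """
    if isinstance(profile, str):
        if profile not in READ_PROFILES:
            raise ValueError(f"unknown read profile {profile!r}")
        prof = dict(READ_PROFILES[profile])
    else:
        prof = {"long_frac": 0.0, **profile}
    if depth < 0:
        raise ValueError("depth must be >= 0")
    model = DEFAULT_ERROR_MODEL if error_model is None else error_model
    rates = list(model.values())
    if any(r < 0 or r >= 1 for r in rates) or sum(rates) >= 1:
        raise ValueError("error rates must be in [0,1) and sum below 1")

    reads: list[SimRead] = []
    error_log: list[tuple[str, str]] = []
    for b_idx, ins in enumerate(inserts):
        rng = spawn_rng(seed, 11, b_idx)
        target = depth * len(ins)
        total = 0
        i = 0
        barcode = barcode_map.get(ins.bac_id) if barcode_map else None
        while total < target:
            length = min(_sample_read_length(prof, rng), len(ins))
            start = int(rng.integers(0, len(ins) - length + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            seq = ins.sequence[start : start + length]
            if strand == "-":
                seq = revcomp(seq)
            read_id = f"{ins.bac_id}_r{i:06d}"
            seq = _apply_errors(seq, model, rng, error_log, read_id)
            reads.append(SimRead(read_id, ins.bac_id, seq, start, strand, barcode))
            total += length
            i += 1
    return reads, error_log


# ---------------------------------------------------------------------------
# mate pairs


def simulate_mp_library(
    inserts: list[BacInsert],
    n_pairs: int,
    separation: dict | None = None,
    read_len: int = 36,
    duplicate_rate: float = 0.05,
    seed: int = 0,
) -> list[SimMatePair]:
    """Simulate an outward-facing mate-pair library.

    The fragment of outer length ``s`` at insert offset ``p`` yields read1 as
    the reverse complement of the leftmost ``read_len`` bases (pointing
    right, across downstream contig ends) and read2 as the rightmost
    ``read_len`` bases on the forward strand (pointing left). A
    ``duplicate_rate`` fraction of the pairs are exact-coordinate copies of
    earlier pairs, flagged in the truth.
    """
    if n_pairs < 0:
        raise ValueError("n_pairs must be >= 0")
    # core component tuned so the mixture quartiles sit ~225 bp around the
    # median; the outlier component models circularization artifacts (a broad
    # flat separation class), giving the library realistic whisker containment
    sep_cfg = {"median": 2825.0, "sd": 278.0, "outlier_frac": 0.15,
               "outlier_range": (200.0, 5450.0), **(separation or {})}
    if sep_cfg["median"] <= 2 * read_len:
        raise ValueError("separation median must exceed 2 x read_len")
    rng = spawn_rng(seed, 23)
    lengths = np.array([len(i) for i in inserts], dtype=float)
    weights = lengths / lengths.sum() if len(inserts) else lengths

    pairs: list[SimMatePair] = []
    originals: list[tuple[int, int, int]] = []  # (insert index, start, sep)
    for i in range(n_pairs):
        if originals and rng.random() < duplicate_rate:
            idx, start, sep = originals[int(rng.integers(0, len(originals)))]
            dup = True
        else:
            idx = int(rng.choice(len(inserts), p=weights))
            ins_len = int(lengths[idx])
            while True:
                if rng.random() < sep_cfg["outlier_frac"]:
                    sep = int(rng.uniform(*sep_cfg["outlier_range"]))
                else:
                    sep = int(round(rng.normal(sep_cfg["median"], sep_cfg["sd"])))
                if 2 * read_len < sep <= ins_len:
                    break
            start = int(rng.integers(0, ins_len - sep + 1))
            originals.append((idx, start, sep))
            dup = False
        ins = inserts[idx]
        end = start + sep
        r1 = SimRead(f"mp{i:07d}/1", ins.bac_id,
                     revcomp(ins.sequence[start : start + read_len]), start, "-")
        r2 = SimRead(f"mp{i:07d}/2", ins.bac_id,
                     ins.sequence[end - read_len : end], end - read_len, "+")
        pairs.append(SimMatePair(f"mp{i:07d}", r1, r2, sep, dup))
    return pairs


# ---------------------------------------------------------------------------
# true contigs and defect injection


def make_true_contigs(
    inserts: list[BacInsert],
    fragmentation: int | tuple[int, int] = (4, 8),
    gap_size_range: Interval = (100, 1500),
    min_contig: int = 2000,
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, list[LayoutSegment]], dict[str, list[Interval]]]:
    """Tile each insert left-to-right into contigs separated by recorded gaps.

    ``fragmentation`` is the number of contigs per insert (fixed int, or an
    inclusive range sampled per insert). Conservation holds exactly: contig
    lengths plus recorded gap bases sum to the insert length.
    """
    rng = spawn_rng(seed, 31)
    contigs: dict[str, str] = {}
    layout: dict[str, list[LayoutSegment]] = {}
    recorded_gaps: dict[str, list[Interval]] = {}
    for ins in inserts:
        if isinstance(fragmentation, int):
            k = fragmentation
        else:
            k = int(rng.integers(fragmentation[0], fragmentation[1] + 1))
        if k < 1:
            raise ValueError("each insert must yield at least one contig")
        gaps = [int(rng.integers(*gap_size_range)) for _ in range(k - 1)]
        usable = len(ins) - sum(gaps)
        if usable < k * min_contig:
            raise ValueError(
                f"{ins.bac_id}: cannot cut {k} contigs of >= {min_contig} bp"
            )
        # partition `usable` into k parts each >= min_contig
        extra = usable - k * min_contig
        cuts = np.sort(rng.integers(0, extra + 1, size=k - 1)) if k > 1 else np.array([], int)
        parts = np.diff(np.concatenate([[0], cuts, [extra]])) + min_contig
        pos = 0
        bac_gaps = []
        for ci, part in enumerate(parts):
            start, end = pos, pos + int(part)
            cid = f"{ins.bac_id}_c{ci:02d}"
            contigs[cid] = ins.sequence[start:end]
            layout[cid] = [(ins.bac_id, (start, end), "+")]
            pos = end
            if ci < k - 1:
                bac_gaps.append((pos, pos + gaps[ci]))
                pos += gaps[ci]
        assert pos == len(ins)
        recorded_gaps[ins.bac_id] = bac_gaps
    return contigs, layout, recorded_gaps


def corrupt_contigs(
    contigs: dict[str, str],
    layout: dict[str, list[LayoutSegment]],
    defects: DefectSpec,
    inserts: list[BacInsert],
    seed: int = 0,
    gap_size_range: Interval = (50, 500),
    margin: int = 1500,
) -> tuple[dict[str, str], dict[str, list[LayoutSegment]], list[dict]]:
    """Inject structural defects into a true contig set, returning ground truth.

    * misassembly: the two halves of one contig are fused in swapped order, so
      the contig aligns as two non-colinear segments while reference coverage
      is unchanged.
    * gap: an internal reference interval (< the misassembly colinearity
      slack) is deleted from one contig, leaving that interval uncovered.
    * chimera: a NEW contig is formed from copies of intervals of two (or
      more) donor BACs; donor contigs are kept, so their coverage is intact.
    """
    rng = spawn_rng(seed, 41)
    by_bac: dict[str, list[str]] = {}
    for cid, segs in layout.items():
        by_bac.setdefault(segs[0][0], []).append(cid)
    if defects.n_chimeras > 0 and len(by_bac) < 2:
        raise ValueError("chimeras require >= 2 BACs")
    ann = {ins.bac_id: list(ins.repeat_annotations) for ins in inserts}
    seqs = {ins.bac_id: ins.sequence for ins in inserts}

    out_contigs = dict(contigs)
    out_layout = {k: list(v) for k, v in layout.items()}
    realized: list[dict] = []

    # contigs eligible for in-place defects: single-segment, long enough,
    # and clear of repeat annotations around the chosen junction
    eligible = [
        cid for cid, segs in layout.items()
        if len(segs) == 1 and len(contigs[cid]) >= 4 * margin
    ]
    need = defects.n_misassemblies + defects.n_gaps
    if need > len(eligible):
        raise ValueError(
            f"need {need} defect-eligible contigs but only {len(eligible)} exist "
            f"(single-segment contigs of >= {4 * margin} bp)"
        )
    targets = [eligible[i] for i in rng.permutation(len(eligible))[:need]]
    mis_targets = targets[: defects.n_misassemblies]
    gap_targets = targets[defects.n_misassemblies :]

    def clear_of_repeats(bac: str, a: int, b: int) -> bool:
        return not any(s < b and a < e for s, e, _ in ann.get(bac, []))

    for cid in mis_targets:
        bac, (a, b), strand = out_layout[cid][0]
        for _ in range(100):
            m = int(rng.integers(a + margin, b - margin))
            if clear_of_repeats(bac, m - 50, m + 50):
                break
        rel = m - a
        seq = out_contigs[cid]
        out_contigs[cid] = seq[rel:] + seq[:rel]
        out_layout[cid] = [(bac, (m, b), strand), (bac, (a, m), strand)]
        realized.append({"kind": "misassembly", "contig_id": cid, "bac_id": bac,
                         "junction_ref": m, "junction_contig": b - m})

    for cid in gap_targets:
        bac, (a, b), strand = out_layout[cid][0]
        g = int(rng.integers(*gap_size_range))
        for _ in range(100):
            c = int(rng.integers(a + margin, b - margin - g))
            if clear_of_repeats(bac, c - 50, c + g + 50):
                break
        rel = c - a
        seq = out_contigs[cid]
        out_contigs[cid] = seq[:rel] + seq[rel + g :]
        out_layout[cid] = [(bac, (a, c), strand), (bac, (c + g, b), strand)]
        realized.append({"kind": "gap", "contig_id": cid, "bac_id": bac,
                         "gap_ref": (c, c + g), "size": g})

    kinds = list(defects.chimera_kinds) or list(CHIMERA_KINDS)
    for i in range(defects.n_chimeras):
        kind = kinds[i % len(kinds)]
        cid = f"CHIM_c{i:02d}"
        rec = _make_chimera(cid, kind, by_bac, out_layout, seqs, ann, rng, margin)
        out_contigs[cid] = rec.pop("sequence")
        out_layout[cid] = rec.pop("layout")
        realized.append(rec)
    return out_contigs, out_layout, realized


def _make_chimera(cid: str, kind: str, by_bac: dict[str, list[str]],
                  layout: dict, seqs: dict[str, str], ann: dict,
                  rng: np.random.Generator, margin: int) -> dict:
    bacs = sorted(by_bac)
    if kind == "repeat_only":
        # use only repeat copies long enough to carry reads on both sides
        min_copy = 1500
        carriers = [b for b in bacs
                    if any(e - s >= min_copy for s, e, _ in ann.get(b, ()))]
        if len(carriers) < 2:
            raise ValueError(
                f"repeat_only chimera requires repeat copies >= {min_copy} bp "
                "in >= 2 BACs"
            )
        b1, b2 = [carriers[int(j)] for j in rng.choice(len(carriers), 2, replace=False)]
        big1 = [a for a in ann[b1] if a[1] - a[0] >= min_copy]
        big2 = [a for a in ann[b2] if a[1] - a[0] >= min_copy]
        s1, e1, _ = big1[int(rng.integers(0, len(big1)))]
        s2, e2, _ = big2[int(rng.integers(0, len(big2)))]
        seq = seqs[b1][s1:e1] + seqs[b2][s2:e2]
        return {"kind": "chimera", "chimera_kind": kind, "contig_id": cid,
                "bacs": (b1, b2), "junction_contig": e1 - s1, "sequence": seq,
                "layout": [(b1, (s1, e1), "+"), (b2, (s2, e2), "+")]}

    b1, b2 = [bacs[int(j)] for j in rng.choice(len(bacs), 2, replace=False)]
    piece = int(rng.integers(3000, 6000))

    def nonrep_interval(bac: str) -> tuple[int, int]:
        n = len(seqs[bac])
        for _ in range(200):
            s = int(rng.integers(margin, n - margin - piece))
            if not any(a < s + piece and s < e for a, e, _ in ann.get(bac, [])):
                return s, s + piece
        raise ValueError(f"no repeat-free interval of {piece} bp in {bac}")

    a1, a2 = nonrep_interval(b1)
    if kind == "nonrep_to_rep":
        # prefer repeat copies long enough to dominate the flank k-mer signal,
        # but accept short (e.g. microsatellite) junctions when that is all
        # the library provides
        min_copy = 1000
        carriers = [b for b in bacs if b != b1 and ann.get(b)]
        if not carriers:
            raise ValueError("nonrep_to_rep chimera requires a repeat-carrying second BAC")
        preferred = [b for b in carriers
                     if any(e - s >= min_copy for s, e, _ in ann[b])]
        b2 = (preferred or carriers)[int(rng.integers(0, len(preferred or carriers)))]
        copies = [a for a in ann[b2] if a[1] - a[0] >= min_copy] or list(ann[b2])
        s2, e2, _ = copies[int(rng.integers(0, len(copies)))]
        # junction lands exactly at the repeat copy; extend past it so the
        # chimera carries repeat plus downstream unique sequence
        c2 = (s2, min(len(seqs[b2]), e2 + piece))
    else:
        c2 = nonrep_interval(b2)
    seq = seqs[b1][a1:a2] + seqs[b2][c2[0] : c2[1]]
    return {"kind": "chimera", "chimera_kind": kind, "contig_id": cid,
            "bacs": (b1, b2), "junction_contig": a2 - a1, "sequence": seq,
            "layout": [(b1, (a1, a2), "+"), (b2, c2, "+")]}


# ---------------------------------------------------------------------------
# whole-pool convenience + read/contig membership


def simulate_pool(
    n_bacs: int = 8,
    insert_length_range: Interval = (100_000, 125_000),
    repeat_config: list[RepeatFamily] | None = None,
    shared_repeat_fraction: float = 0.5,
    profile: str = "Titanium-like",
    depth: float = 20.0,
    error_model: dict | None = None,
    n_pairs: int = 0,
    fragmentation: int | tuple[int, int] = (4, 8),
    defects: DefectSpec | None = None,
    barcoded: bool = True,
    seed: int = 0,
) -> PoolTruth:
    """Run the whole generator: pool, reads, mate pairs, contigs, defects."""
    inserts, library = make_bac_pool(
        n_bacs, insert_length_range, repeat_config, shared_repeat_fraction, seed
    )
    barcode_map = make_barcode_map([i.bac_id for i in inserts], seed=seed) if barcoded else None
    reads, _ = simulate_shotgun_reads(inserts, profile, depth, error_model, barcode_map, seed)
    pairs = simulate_mp_library(inserts, n_pairs, seed=seed) if n_pairs else []
    contigs, layout, gaps = make_true_contigs(inserts, fragmentation, seed=seed)
    realized: list[dict] = []
    if defects is not None:
        contigs, layout, realized = corrupt_contigs(contigs, layout, defects, inserts, seed)
    return PoolTruth(inserts, library, reads, pairs, contigs, layout, gaps, realized, seed)


def assign_reads_to_contigs(truth: PoolTruth, seed: int = 0) -> dict[str, list[str]]:
    """Assign each shotgun read to exactly one contig whose recorded layout
    contains the read's true interval (ties broken at random, seeded).

    This plays the role of the assembler's read placement for origin-profile
    analysis; a read contained in no contig interval is left unassigned.
    """
    rng = spawn_rng(seed, 53)
    # per BAC, list of (contig_id, interval) claims
    claims: dict[str, list[tuple[str, Interval]]] = {}
    for cid, segs in truth.layout.items():
        for bac, (a, b), _strand in segs:
            claims.setdefault(bac, []).append((cid, (a, b)))
    membership: dict[str, list[str]] = {cid: [] for cid in truth.contigs}
    for read in truth.reads:
        lo, hi = read.true_start, read.true_start + len(read)
        hits = [cid for cid, (a, b) in claims.get(read.bac_id, ()) if a <= lo and hi <= b]
        if hits:
            membership[hits[int(rng.integers(0, len(hits)))]].append(read.read_id)
    return membership


def read_positions_on_contig(truth: PoolTruth, membership: dict[str, list[str]],
                             contig_id: str) -> list[tuple[str, str, int, int]]:
    """Project member reads into contig coordinates via the recorded layout.

    Returns (read_id, bac_id, start, end) rows, the membership format the
    chimera breakpoint annotator consumes.
    """
    reads = {r.read_id: r for r in truth.reads}
    rows: list[tuple[str, str, int, int]] = []
    offset = 0
    for bac, (a, b), strand in truth.layout[contig_id]:
        for rid in membership[contig_id]:
            r = reads[rid]
            lo, hi = r.true_start, r.true_start + len(r)
            if r.bac_id == bac and a <= lo and hi <= b:
                if strand == "+":
                    rows.append((rid, bac, offset + lo - a, offset + hi - a))
                else:
                    rows.append((rid, bac, offset + b - hi, offset + b - lo))
        offset += b - a
    return rows
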