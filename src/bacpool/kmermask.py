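"""k-mer frequency indexing of pooled reads and depth-relative repeat masking.

Regions of reads whose 20-mer pool frequency exceeds a multiple of the mean
sequence depth are repetitive in the pool (a repeat at copy number c across
clones at depth d shows k-mer counts near c*d, unique sequence near d);
masking them prevents repeats from seeding cross-clone joins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._util import merge_intervals, revcomp, round_half_up


@dataclass
class KmerIndex:
    k: int
    counts: dict[str, int]
    total_positions: int
    source: str = ""

    def __getitem__(self, kmer: str) -> int:
        return self.counts.get(kmer, 0)


@dataclass
class MaskedRead:
    read_id: str
    sequence: str
    masked_intervals: list[tuple[int, int]] = field(default_factory=list)

    @property
    def masked_bases(self) -> int:
        return sum(b - a for a, b in self.masked_intervals)


def _canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def _iter_reads(reads):
    for r in reads:
        if hasattr(r, "read_id"):
            yield r.read_id, r.sequence
        else:
            yield r


def build_kmer_index(reads, k: int = 20, canonical: bool = True,
                     source: str = "") -> KmerIndex:
    """Count every k-length window over all reads.

    Canonical mode merges each k-mer with its reverse complement (default:
    strandedness of shotgun reads is arbitrary). Windows containing
    ambiguous bases are not counted.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: dict[str, int] = {}
    total = 0
    for _rid, seq in _iter_reads(reads):
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            if canonical:
                kmer = _canonical(kmer)
            counts[kmer] = counts.get(kmer, 0) + 1
            total += 1
    return KmerIndex(k, counts, total, source)


def depth_relative_threshold(mean_depth: float, multiple: float) -> int:
    """Masking threshold as a multiple of the mean sequence depth."""
    if mean_depth <= 0 or multiple <= 0:
        raise ValueError("mean_depth and multiple must be positive")
    return round_half_up(mean_depth * multiple)


def mask_reads(reads, index: KmerIndex, threshold: int,
               canonical: bool = True, hard: bool = False) -> list[MaskedRead]:
    """Mask every base covered by a window whose k-mer count is strictly
    greater than ``threshold``. Soft-masks to lowercase by default; ``hard``
    replaces masked bases with N."""
    k = index.k
    out: list[MaskedRead] = []
    for rid, seq in _iter_reads(reads):
        up = seq.upper()
        intervals = []
        for i in range(len(up) - k + 1):
            kmer = up[i : i + k]
            if "N" in kmer:
                continue
            if canonical:
                kmer = _canonical(kmer)
            if index[kmer] > threshold:
                intervals.append((i, i + k))
        intervals = merge_intervals(intervals)
        chars = list(up)
        for a, b in intervals:
            for j in range(a, b):
                chars[j] = "N" if hard else chars[j].lower()
        out.append(MaskedRead(rid, "".join(chars), intervals))
    return out


def write_index_tsv(index: KmerIndex, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# k={index.k}\ttotal_positions={index.total_positions}\n")
        for kmer in sorted(index.counts):
            fh.write(f"{kmer}\t{index.counts[kmer]}\n")
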