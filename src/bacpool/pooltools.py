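"""Pool bookkeeping: demultiplexing, depth, down-sampling, whisker summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import round_half_up, spawn_rng


@dataclass
class DepthSummary:
    bac_id: str
    total_bases: int
    reference_length: int
    depth: float
    mean_read_length: float


@dataclass
class WhiskerSummary:
    """Quartiles with 1.5x inter-quartile-range whisker bounds."""

    median: float
    q1: float
    q3: float
    iqr: float
    lower: float
    upper: float


def demultiplex(
    reads, barcode_map: dict[str, str]
) -> tuple[dict[str, list], list]:
    """Split reads into per-BAC sets by exact barcode-prefix match.

    ``reads`` may be SimRead objects (their raw, barcode-carrying sequence is
    used and the clipped read is kept) or (read_id, sequence) pairs. Returns
    (per-BAC read lists with the barcode clipped, unassigned list).
    """
    tags = list(barcode_map.values())
    if len(set(tags)) != len(tags):
        raise ValueError("barcode tags must be pairwise distinct")
    by_tag = {tag: bac for bac, tag in barcode_map.items()}
    assigned: dict[str, list] = {bac: [] for bac in barcode_map}
    unassigned: list = []
    for read in reads:
        if hasattr(read, "raw"):
            rid, seq = read.read_id, read.raw
        else:
            rid, seq = read
        for tag, bac in by_tag.items():
            if seq.startswith(tag):
                assigned[bac].append((rid, seq[len(tag):]))
                break
        else:
            unassigned.append((rid, seq))
    return assigned, unassigned


def compute_depth(reads, reference_length: int, bac_id: str = "") -> DepthSummary:
    """Fold-coverage and mean read length of a read set over a reference."""
    if reference_length <= 0:
        raise ValueError("reference_length must be positive")
    lengths = [len(r) if not isinstance(r, tuple) else len(r[1]) for r in reads]
    total = int(sum(lengths))
    mean = total / len(lengths) if lengths else 0.0
    return DepthSummary(bac_id, total, reference_length, total / reference_length, mean)


def downsample(
    reads: list,
    target_depth: float,
    reference_length: int,
    replicates: int = 20,
    seed: int = 0,
) -> list[list]:
    """Independently seeded whole-read subsets approximating a target depth.

    Reads are drawn without replacement in random order until the cumulative
    base count reaches ``target_depth * reference_length``; each replicate's
    total is therefore within one read length of the target.
    """
    lengths = np.array([len(r) if not isinstance(r, tuple) else len(r[1]) for r in reads])
    current = lengths.sum() / reference_length
    if target_depth > current:
        raise ValueError(
            f"target depth {target_depth} exceeds current depth {current:.2f}"
        )
    target_bases = target_depth * reference_length
    out = []
    for rep in range(replicates):
        rng = spawn_rng(seed, 67, rep)
        order = rng.permutation(len(reads))
        cum = np.cumsum(lengths[order])
        n_take = int(np.searchsorted(cum, target_bases)) + 1
        n_take = min(n_take, len(reads))
        out.append([reads[i] for i in order[:n_take]])
    return out


def whisker_summary(values) -> WhiskerSummary:
    """Median, type-7 quartiles and 1.5x IQR whisker bounds.

    Integer inputs get bounds rounded half-up to integers (bp convention).
    """
    vals = np.asarray(values)
    if vals.size < 4:
        raise ValueError("whisker summary requires at least 4 values")
    integral = np.issubdtype(vals.dtype, np.integer)
    q1, med, q3 = np.percentile(vals, [25, 50, 75])  # linear interpolation (type 7)
    iqr = q3 - q1
    lower, upper = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    if integral:
        lower, upper = float(round_half_up(lower)), float(round_half_up(upper))
    return WhiskerSummary(float(med), float(q1), float(q3), float(iqr), lower, upper)
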