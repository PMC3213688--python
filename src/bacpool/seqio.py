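"""Format readers/writers and run manifests.

FASTA/FASTQ go through Biopython (gzip transparently supported), SAM import
through pysam. All coordinates are converted to the internal 0-based,
half-open convention at the boundary.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import time
from pathlib import Path

import pysam
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .mpscaffold import ReadPlacement


def _open_text(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_sequences(path, fmt: str | None = None) -> list[SeqRecord]:
    """Read FASTA or FASTQ records (format inferred from the name if not
    given); gzip is handled transparently."""
    path = Path(path)
    if fmt is None:
        stem = path.name[:-3] if path.suffix == ".gz" else path.name
        fmt = "fastq" if stem.endswith((".fastq", ".fq")) else "fasta"
    with _open_text(path) as fh:
        return list(SeqIO.parse(fh, fmt))


def write_sequences(records, path, fmt: str | None = None,
                    quality: int = 30) -> None:
    """Write sequences as FASTA or FASTQ (constant quality for simulated
    reads). ``records`` may be SeqRecords, (id, seq) pairs, or objects with
    read_id/sequence attributes."""
    path = Path(path)
    if fmt is None:
        stem = path.name[:-3] if path.suffix == ".gz" else path.name
        fmt = "fastq" if stem.endswith((".fastq", ".fq")) else "fasta"
    out = []
    for rec in records:
        if isinstance(rec, SeqRecord):
            sr = rec
        else:
            if hasattr(rec, "read_id"):
                rid, seq = rec.read_id, rec.sequence
            else:
                rid, seq = rec
            sr = SeqRecord(Seq(seq), id=rid, description="")
        if fmt == "fastq" and "phred_quality" not in sr.letter_annotations:
            sr.letter_annotations["phred_quality"] = [quality] * len(sr)
        out.append(sr)
    with _open_text(path, "wt") as fh:
        SeqIO.write(out, fh, fmt)


def read_placements(path, fmt: str | None = None,
                    contig_lengths: dict[str, int] | None = None
                    ) -> tuple[list[ReadPlacement], dict]:
    """Import read placements from SAM (1-based -> 0-based) or TSV.

    Unmapped and secondary/supplementary SAM records are skipped and
    counted. The TSV columns are read_id, contig_id, start (0-based),
    strand, mate_id[, length].
    """
    path = Path(path)
    if fmt is None:
        fmt = "sam" if path.suffix in (".sam", ".bam") else "tsv"
    placements: list[ReadPlacement] = []
    skipped = {"unmapped": 0, "secondary": 0}
    if fmt == "sam":
        with pysam.AlignmentFile(str(path), check_sq=False) as sam:
            for rec in sam:
                if rec.is_unmapped:
                    skipped["unmapped"] += 1
                    continue
                if rec.is_secondary or rec.is_supplementary:
                    skipped["secondary"] += 1
                    continue
                mate = rec.query_name
                length = rec.query_length or (rec.reference_end - rec.reference_start)
                suffix = "/2" if rec.is_read2 else "/1"
                placements.append(ReadPlacement(
                    rec.query_name + suffix, rec.reference_name,
                    rec.reference_start, "-" if rec.is_reverse else "+",
                    mate, length,
                ))
    else:
        with _open_text(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                rid, cid, start, strand, mate = parts[:5]
                length = int(parts[5]) if len(parts) > 5 else 36
                placements.append(ReadPlacement(rid, cid, int(start), strand,
                                                mate, length))
    if contig_lengths is not None:
        for p in placements:
            if p.contig_id not in contig_lengths or not (
                0 <= p.start < contig_lengths[p.contig_id]
            ):
                raise ValueError(
                    f"placement {p.read_id} out of bounds on {p.contig_id}"
                )
    return placements, skipped


def write_placements_tsv(placements: list[ReadPlacement], path) -> None:
    with open(path, "w") as fh:
        fh.write("#read_id\tcontig_id\tstart\tstrand\tmate_id\tlength\n")
        for p in placements:
            fh.write(f"{p.read_id}\t{p.contig_id}\t{p.start}\t{p.strand}"
                     f"\t{p.mate_id}\t{p.length}\n")


def write_truth_tsv(reads, path) -> None:
    """Ground-truth sidecar: read_id, bac_id, start, end, strand."""
    with open(path, "w") as fh:
        fh.write("#read_id\tbac_id\tstart\tend\tstrand\n")
        for r in reads:
            fh.write(f"{r.read_id}\t{r.bac_id}\t{r.true_start}"
                     f"\t{r.true_start + len(r)}\t{r.true_strand}\n")


def write_scaffolds_agp(scaffolds, path) -> None:
    """AGP-style TSV: object, object coordinates, component/gap rows."""
    with open(path, "w") as fh:
        fh.write("#object\tobj_start\tobj_end\tpart\tkind\tcomponent\torientation\n")
        for sc in scaffolds:
            pos, part = 0, 0
            for i, (cid, orient) in enumerate(sc.members):
                # member lengths are derivable downstream; emit order + gaps
                part += 1
                fh.write(f"{sc.scaffold_id}\t{pos}\t.\t{part}\tW\t{cid}\t{orient}\n")
                if i < len(sc.gaps):
                    part += 1
                    fh.write(f"{sc.scaffold_id}\t.\t.\t{part}\tN\t{sc.gaps[i]}\t.\n")


def write_manifest(path, config: dict, seed: int, inputs: dict[str, str] | None = None) -> None:
    """Structured-text run manifest: config, seed, versions, input checksums."""
    import bacpool

    manifest = {
        "tool": "bacpool",
        "version": bacpool.__version__,
        "seed": int(seed),
        "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": config,
        "inputs": {
            name: hashlib.sha256(Path(p).read_bytes()).hexdigest()
            for name, p in (inputs or {}).items()
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def load_config(path) -> dict:
    with open(path) as fh:
        if str(path).endswith(".json"):
            return json.load(fh)
        return yaml.safe_load(fh) or {}
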