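# Methods

This note documents the models implemented by `bacpool`, the parameters
that matter, and the deliberate simplifications of the synthetic-data
generator. Conventions used throughout: coordinates are 0-based half-open;
strands are `+`/`-` with reverse-complement applied on `-`; every
stochastic stage takes an explicit seed and derives independent
sub-generators from it, so identical configuration + seed reproduces output
byte-for-byte.

## The experimental design being emulated

A pool of ~48 bacterial artificial chromosomes (BACs), each carrying a
~100–125 kb genomic insert, is shotgun-sequenced in one run. With per-clone
barcodes the reads can be demultiplexed and each clone assembled on its
own; without barcodes the pool yields a single assembly in which repeat
families shared between inserts can fuse sequence from different clones
into chimeric contigs. A separate non-barcoded ~3 kb mate-pair (MP) library
over the whole pool provides long-range links for scaffolding the per-clone
assemblies.

## Synthetic pools (`simulate`)

**Inserts and repeats.** Insert sequences are i.i.d. uniform A/C/G/T with
lengths uniform in a configurable range (default 100–125 kb). Repeat
families are planted as diverged copies of a consensus: LTR-like families
(kb-scale consensus), tandem microsatellites (unit ≤ 20 bp, tiled into
tracts of 30–120 units) and low-complexity tracts. A configurable fraction
of families is *shared*, i.e. planted into 2–4 clones — these shared copies
are what drives cross-clone chimera formation and k-mer-frequency masking.
Divergence is an independent per-base substitution rate per copy; the
default library uses 0.5% for LTR families so that copies still share most
of their exact 20-mers (young, high-identity repeats — the regime in which
frequency-based masking is informative) and larger values for the
low-complexity family.

**Shotgun reads.** Two read-length regimes are built in.
`"FLX-like"` is a truncated normal (mean 223 bp, sd 20, ceiling 310 bp —
essentially no reads beyond ~310 bp). `"Titanium-like"` is a mixture of a
normal core (mean 237 bp, sd 25) with a 10% long-read component uniform on
400–600 bp; the mixture mean is ≈ 263 bp. The mixture weights were chosen
to reproduce the two regimes' summary statistics (means of ~223 vs ~263 bp,
few FLX reads above 300 bp, a Titanium tail to ~600 bp). Reads are drawn
uniformly over each insert with random strand until the requested
fold-coverage is reached, so realized depth is within one read length of
the target.

**Error model.** Errors come in the three classes characteristic of
pyrosequencing, with defaults in the observed proportions 46% / 27% / 27%
at 1% total per base: *homopolymer indels* (1 bp insertion/deletion placed
only inside single-nucleotide runs of length ≥ 3, insertions duplicating
the run base), *other indels* (1 bp, uniform placement, random inserted
base) and *substitutions* (uniform, to a random different base). Every
realized error is logged with its class, so rate-recovery experiments have
exact truth. No flowgram simulation, no per-base quality model, no
cloning/GC bias — consequences: tests calibrate against the *realized*
error process, and nothing here validates quality-aware methods.

**Barcodes.** Fixed-length (10 bp) distinct uniform-random tags prepended
to reads; demultiplexing is exact-prefix match (one mismatch sends a read
to the unassigned bin). Real barcode designs with error correction are out
of scope; the tag scheme only needs to make clone-of-origin recoverable.

**Mate pairs.** Pairs are 2 × 36 bp, outward-facing (the left read is the
reverse complement of the fragment's leftmost bases, the right read is the
forward strand's rightmost bases), as produced by circularization
libraries. The outer separation is a mixture: a normal core
(median 2,825 bp, sd 278) plus a 15% broad "artifact" component uniform on
200–5,450 bp modelling circularization chimeras and size-selection leakage.
The core sd and artifact weight were set so the mixture's quartiles sit
≈ ±225 bp around the median and ~90% of pairs fall inside the
quartiles ± 1.5×IQR window, matching a real library's containment (printed:
87%) to within a few points. A configurable fraction (default 5%) of pairs
are exact-coordinate duplicates of earlier pairs, flagged in truth —
the "duplicons" that duplicate-removal must collapse.

**True contigs and injected defects.** Each insert is tiled left-to-right
into contigs separated by recorded gaps (conservation is exact: contig
bases + gap bases = insert length). Defects are injected with recorded
coordinates:

- *misassembly*: the two halves of a contig are fused in swapped order (or
  strand-flipped), producing exactly one non-colinear junction while
  leaving reference coverage untouched — so one injected misassembly adds
  exactly one detectable event and zero gaps;
- *gap*: deletion of an internal reference interval of 50–500 bp — below
  the colinearity slack (see below), so it is detected as a gap and never
  double-counted as a misassembly;
- *chimera*: a **new** contig built from copies of intervals of two donor
  clones (donor contigs remain, so their coverage is intact), in three
  kinds: `nonrep_to_nonrep` (two repeat-free intervals), `nonrep_to_rep`
  (junction exactly at a repeat copy, preferring copies ≥ 1 kb so both
  flanks carry signal) and `repeat_only` (two repeat copies ≥ 1.5 kb from
  different clones). Pieces are 3–6 kb, so the minority clone contributes
  far more than 10% of member reads and a read-count classifier has
  headroom over binomial noise.

`assign_reads_to_contigs` plays the assembler's role for origin analysis:
each read is assigned to exactly one contig whose recorded layout contains
its true interval, ties broken uniformly at random (seeded). Pure contigs
therefore stay pure, and chimeras receive reads from both donors in
proportion to interval length.

## Alignment and consistency scoring (`alignment`, `refcompare`)

Contigs are aligned by seed–chain–extend: exact 15-mer anchors against a
reference index (k-mers with > 10 reference hits are dropped; exact
extension recovers the tracts they would have anchored), greedy chaining of
anchors that advance on both sequences with an indel drift ≤ 30 bp and an
anchor spacing ≤ 120 bp, exact extension of chains, merging of co-diagonal
chains, then weighted interval scheduling on contig coordinates to pick a
non-overlapping segment set (neighbouring segments may share up to 25 bp
because exact extension can run a few bases past a junction). Base-level
differences within a segment are resolved with edlib's alignment path; the
chain/segment logic and all downstream calling are independent of it.
Chains are deliberately **not** merged across jumps > 30 bp: an assembly
deletion therefore splits a contig into two colinear segments and the
skipped reference interval is visible as a gap, rather than being absorbed
into one alignment.

- **Gaps**: maximal uncovered reference intervals (≥ 1 bp; terminal
  intervals count).
- **Misassemblies**: per contig, segments ordered along the contig; each
  adjacent pair that is not colinear — same strand, reference advancing in
  contig order, reference jump ≤ `colinear_slack` = 1,000 bp — counts one.
  The slack separates long indels (gaps) from true rearrangements; it is a
  parameter because no canonical value exists.
- **Penalty** = 2·misassemblies + gaps: misassemblies actively misorder
  sequence while gaps merely omit it, hence the double weight.
- **L/N statistics**: sort lengths descending; N_p is the smallest number
  of largest units whose cumulative length reaches p% of the total, L_p the
  length of the last unit admitted. (Note the L/N naming convention here:
  L50 is a length in bp, N50 a count.)
- **Error catalog**: differences per aligned reference base; an indel
  counts as *homopolymer* when it lies in a reference single-nucleotide run
  of length ≥ 3 (the same threshold the generator uses); nearby "other"
  indels are *not* folded into the homopolymer class, since the two classes
  are reported separately. Q = round(−10·log10(rate)) with **half-up**
  rounding (3.09e-4 → Q35, 4.40e-4 → Q34), capped at Q60 when no
  differences are observed.

## k-mer masking (`kmermask`)

A hash index counts every 20-mer over the pool's reads, canonically
(merged with reverse complements) by default since shotgun strand is
arbitrary; windows containing N are skipped. In a pool at mean depth *d*, a
unique 20-mer is seen ≈ *d* times and a repeat at pool copy number *c*
≈ *c·d* times (attenuated by read errors, ≈ ×0.8 for 1% error), so masking
thresholds are expressed as multiples of depth: threshold =
round(depth × multiple), with 1.5× (permissive) and 3× (stringent) the
conventional choices. Every base covered by a window whose count is
**strictly greater** than the threshold is masked (soft-mask lowercase by
default, hard-mask N optional); lowering the threshold can only grow the
masked set.

## Mate-pair scaffolding (`mpscaffold`)

Reads are placed on a clone's contigs by exact full-read match (optional
single-mismatch fallback); only reads whose placement is unique within the
clone's contig set are kept. The separation window is calibrated on one
long contig: outer separations of properly oriented co-placed pairs,
summarized by type-7 quartiles with 1.5×IQR whiskers (integer bp bounds
rounded half-up — quartiles 2,604/3,059 give 1,922..3,742).

A pair bridges two contigs when its mates sit on different contigs facing
outward across an end and the **sum** of both mates' outer-coordinate
distances to those ends is within the upper whisker. Exact-coordinate
duplicate pairs collapse to one before counting. Support is normalized per
clone — MPs on a junction divided by all bridging MPs of the clone — which
makes clones of different depth comparable; normalized values sum to 1 per
clone, and junctions are kept only when **strictly above** the 0.02
threshold (the regime where the support histogram departs from its
log-linear tail; `support_histogram` emits right-closed 0.02 bins for this
diagnostic).

Scaffolding works on an end-graph: two vertices per contig joined by an
intra-contig edge, bridges as undirected edges between end vertices. An end
incident to ≥ 2 surviving bridges is a *conflict*: under the `strict`
policy all its bridges are removed (report only); under the `ratio` policy
the strongest bridge survives if it beats every competitor by ≥ 2×
(`ratio_min`). Remaining components that are simple paths become scaffolds
(orientation read off the entered end); cycles are reported and left
unscaffolded. Gap sizes are per-junction medians of (insert median − summed
end distances), floored at 1 bp — negative implied gaps are floored, not
treated as overlaps, since contig merging is out of scope. Before/after
statistics treat a scaffold (members + estimated gaps) as one unit and fold
changes are rounded to one decimal. Placements are computed independently
per clone, so one MP may legitimately support bridges in several clones, as
happens with a non-barcoded MP library.

## Chimera analysis (`chimera`)

For each contig > 1 kb (strict inequality) with barcode-labelled member
reads, the origin profile records read counts per clone; the *major
fraction* is the share of the most frequent clone (ties to the
lexicographically smallest id; each read counts once). A contig is
**non-chimeric iff major fraction ≥ 0.96** — the boundary is inclusive on
the non-chimeric side, reconciling the two ways the cutoff can be phrased.
The cumulative-length curve (fraction of total length in contigs with
major fraction ≥ x) is the diagnostic that locates this threshold: pure
contigs pile mass near 1.0 while chimeras spread it across lower fractions.
Summaries report per-class counts, total/average lengths and length
fractions rounded to two decimals; class totals partition the filtered
total exactly.

Breakpoints are located by scanning windowed (500 bp window, 100 bp step)
clone coverage for switches of the dominant clone between consecutive
*confident* windows (dominant share ≥ 0.8); the junction interval spans the
uncertain stretch between them, so its position is resolved to roughly the
step size. Each junction is labelled by median local 20-mer frequency
relative to mean depth (> 2× counts as repeat context): high on both
flanks → `repeat_only`, one flank or the junction itself → `nonrep_to_rep`,
neither but a low-complexity motif (dinucleotide-dominance heuristic)
→ `unknown_low_complexity`, else `nonrep_to_nonrep`. The 2× default
reflects the ≈ 0.8× k-mer attrition from read errors at the default error
rate. `split_at_masked_junctions` is the deliberately simple stand-in for
re-assembling masked reads: a contig's read population is split at masked
intervals, modelling that masked repeats cannot seed joins — it shows the
direction of the masking effect, not assembler behaviour.

## Problem sizes and numerical choices

Test and evaluation experiments run at desk scale, chosen as the smallest
sizes at which the checked statistics are well-separated from their noise:
the defect-recovery experiment uses 8 clones × 100–125 kb at 20× with 10
misassemblies, 10 gaps and 6 chimeras (2 of each kind); scaffolder truth
recovery uses 4 clones × 5 contigs with ≥ 50 error-free MPs per true
junction; rate recovery uses ~180 kb of reads per error class at 1e-3 and a
10,000-pair library for the separation median. Competing-junction behaviour
is tested by injecting a synthetic 5:1 competitor directly into the bridge
list, since a repeat-free pool never produces one through placement.

Known limitations: uniform random insert background (no GC structure, no
gene content); substitution-only repeat divergence; 1 bp indels only; no
quality scores; the aligner is built for high-identity desk-scale
comparison, not for diverged genomes; chimera membership comes from ground
truth or external placement tables, never from re-assembly. Passing tests
therefore demonstrate correctness of the scoring, scaffolding and
classification logic under controlled truth — not performance on real
assemblies, where error processes and repeat structure are richer.
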