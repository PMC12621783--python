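# Methods

This note documents the models, decision rules, parameter defaults and
numerical conventions behind `fillet`, and what the synthetic fixtures
do and do not demonstrate.

## Data model and conventions

The curation state bundles the assembly graph (nodes with
homopolymer-compressed lengths and optional sequences, marker counts
and read depth; canonical oriented edges), the path table, the gap
register, graph alignments, per-contig statistics, the scfmap
name mapping and the edit history. Conventions:

- All intervals (BED, PAF, GAF, telomere annotations) are 0-based,
  half-open in memory; rendering is the only place any other convention
  may appear.
- An edge and its reverse-complement flip denote the same adjacency;
  the stored representative is the lexicographically smaller of the
  two, so the edge multiset is closed under GFA symmetry and round
  trips exactly.
- Path strings accept both the suffix orientation dialect
  (`utig4-1+,utig4-2-`) and the walk dialect (`>utig4-1<utig4-2`), and
  gap tokens `[gap]`, `[NkN]`, `[N...N]`; everything is normalised to
  the suffix form with `[NkN]` gaps, default k = 1,000 when no estimate
  exists. Node identifiers are opaque strings.
- Malformed GAF records (interval or walk invariant violations) are
  dropped and counted, never silently ignored; structurally broken
  lines (wrong column counts, unknown segments) are hard errors naming
  the line.
- Timestamps come from an injectable clock, so histories are
  deterministic under test and replay.
- State files are versioned JSON; a version mismatch is an explicit
  error, never a silent coercion.

## Telomere detection

The scanner is a density rule over motif occurrences (default motif
CCCTAA, scanned together with its reverse complement): occurrences at
most `max_gap` = 100 bp apart cluster into a block; a block is reported
when motif bases cover ≥ `min_block_prop` = 0.4 of its span and the
span is at least `min_block_len` = 200 bp. The length floor exists
because isolated chance occurrences of a 6-mer in random sequence would
otherwise form perfect-proportion 6 bp "blocks". Only the terminal
`search_limit` window at each end is scanned.

Detection runs three passes: (1) the raw sequence with a 50 kb search
limit; (2) after masking 2 kb off each end, again at 50 kb; (3) after
masking 4 kb, with a tight 5 kb limit. Masking recovers arrays hidden
behind short non-telomeric tips that break the density rule at the very
end. Blocks from all passes are unioned; a merged block keeps the
maximum motif proportion of its parts (re-running the merge on its own
output is a no-op). A merged block is called a p/q end block when it
starts within `end_window` = 15,000 bp of the respective boundary,
otherwise internal — the same 15 kb boundary used by the
internal-telomere trimming filter, so the two views agree.

Internal-telomere candidates for trimming must additionally have motif
proportion strictly above 0.5 and sit at least 15 kb from both
boundaries.

## Completeness, contiguity, QV

A sequence with telomere blocks at both ends classifies `T2T_CONTIG`
with zero internal N gaps, `T2T_SCAFFOLD` with one or more, and
`SCAFFOLD` when either telomere is missing. The classification is a
pure function of those three facts.

N50 is the length of the shortest contig in the minimal
descending-length prefix whose sum covers half the total; L50 is that
prefix's size.

QV treats each of the k positions overlapping a k-mer as independent:
with E error k-mers among T, the per-base error is
e = 1 − (1 − E/T)^(1/k) and QV = −10·log10(e) (k defaults to 31). Zero
error k-mers yield an infinity sentinel preserved internally and capped
(default 99) only for tabular rendering. QV is monotone non-increasing
in E at fixed T.

## Chromosome assignment and synteny

Alignment blocks below 1 Mb or 99% identity are discarded (both
thresholds configurable; the comparison is inclusive, so a block
exactly at a threshold is retained). Each query contig is assigned the
target with the largest summed retained block length, ties broken
lexicographically for determinism. Orientation uses strand-stratified
base totals with a 2× dominance margin: `+` when forward bases are at
least twice reverse, `-` for the converse, `MIXED` otherwise. The
margin exists because near-balanced strand evidence is common in
real alignments of inverted or rearranged regions and a coin-flip call
would be worse than an honest MIXED. The result is invariant under
permutation of the input blocks.

Counterpart-node ranking sums aligned block length per target node
(self-alignments excluded) and sorts descending, ties by node id.

Non-syntenic regions subtract the union of chromosome-consistent
retained blocks (query chromosome label with haplotype suffix
`_mat/_pat/_hap1/_hap2` stripped must equal the target name) from the
whole-genome BED; output intervals are sorted and disjoint.

## Gap analysis

Gap records are keyed `contig:index:leftNode:rightNode:haplotype`, so
identical flank pairs on different haplotypes remain distinct. A gap at
a path terminus has a null flank on that side and is flagged terminal.

Spanning-walk counting first keeps one alignment per read (highest
MAPQ, ties by larger aligned block, then input order). A read spans
when its walk contains the left flank before the right flank in either
traversal sense; the sub-walk runs from the first left-flank occurrence
to the last right-flank occurrence. A walk and its reverse-complement
traversal are the same key; the canonical form is the lexicographically
smaller rendering, and the forward/reverse split is reported. Totals
are invariant under reversal of every read walk.

Loop copy number is the per-read count of repeat-node traversals
(either orientation) within the spanning sub-walk; the estimate is the
histogram mode, ties broken toward fewer copies (the conservative
reconstruction). No spanning reads is an explicit NO_SUPPORT result.

Node depth counts read presence: a record contributes at most once per
node regardless of how many times its walk revisits it, normalised by
node length in kb. The alternative (counting revisits) would conflate
loop copy number with coverage; a revisit-counting mode was considered
and rejected for that reason.

Split-read rescue considers all alignments per read (no best-per-read
filter — the split is the signal). An alignment anchors a contig end
when it covers more than 5,000 aligned bases, intersects the terminal
5,000 bp window, and has MAPQ above 0. A join is two ends anchored by
the same read; joins with fewer than three supporting reads are flagged
`BELOW_EDGE_THRESHOLD` because the upstream graph builder requires
three reads to emit an edge — exactly the cases worth manual rescue.

Counterpart inference applies when exactly one node of a het bubble is
already used by the other haplotype's path: the unused node is
suggested for this haplotype, marked INFERRED, and never auto-applied
by the low-level API (the scripted pipeline applies it only after read
evidence fails).

## Path editing and event sourcing

`fill_gap` verifies that the first and last fill steps equal the gap's
flanks in both identity and orientation; mismatches are rejected with a
boundary warning unless forced. The gap step is replaced by the fill's
interior; indices of later gaps on the same contig are shifted
accordingly. `delete_gap` reverts a fill (restoring the original gap
token, byte-identical rendering) or retires an open gap from fill
bookkeeping.

Connections do not touch paths when recorded; the writer merges them
(target appended or prepended per `at`, reverse-complemented when
`flip`, joined by a default 1,000 bp gap token). Patch nodes use a
single-read backbone: the supporting read with the highest summed
anchor MAPQ contributes the unaligned interior between its anchors;
abutting or overlapping anchors give a zero-length patch, i.e. an
edge-only join. Support reads are recorded so a multi-read consensus
could be layered on later without changing the interface.

Retention of nodes inside unresolved gaps builds a digraph over
oriented nodes (each canonical edge contributes both traversal arcs;
connections add a synthetic source-end → target-end arc) and flags
descendants(left flank) ∩ ancestors(right flank), union over open gaps,
flanks excluded. Intersection is the default because it captures
exactly the nodes that can lie *between* the flanks; a union mode is
available for the looser reading ("anything upstream or downstream").
The result matches brute-force all-pairs reachability on random graphs.

The writer is deterministic given the state: retained paths in input
order, then `unused_<node>` singleton paths for kept-but-unplaced nodes
(so downstream consensus can still attract their reads), with the
walk-notation twin written alongside. Output gap tokens equal open gaps
plus connections plus two per rDNA patch on retained paths.

Every mutating operation appends exactly one history entry carrying its
full parameters; replaying a history against the initial state with the
same clock reproduces the saved state byte for byte.

rDNA patching replaces a designated gap with
`[gap, morph × copies, gap]` (default two copies of the registered
model rDNA unit): the flanking gaps concede that the exact traversal is
unknown while still representing the array.

## Tuning

Chromosome naming lists nodes of chromosome-assigned paths, flags nodes
used in two or more distinct chromosomes (chrY mapped to chrX first so
pseudoautosomal sharing is not penalised; repeated use within one
chromosome is fine), removes flagged nodes, clusters the remainder by
undirected connectivity, and labels a cluster only when its labelled
members agree on one chromosome. Removal before clustering is
observable: a multi-used bridge node splits its component rather than
leaking a label across.

Sorting parses `<chr>_<hap>` names; natural chromosome order is numeric
ascending, then X, Y, M. `hap` groups by haplotype first, `chr`
interleaves haplotypes per chromosome; nonconforming names sort last in
original order. Reverse complement maps all IUPAC ambiguity codes and
preserves case. Trimmed/flipped/sorted FASTAs are written with
`_trimmed`/`_flipped`/`_sorted` suffixes. PAR masking unions chrY
target intervals of blocks ≥ 10 kb and ≥ 95% identity and replaces
those bases with N; the masked base count equals the measure of the
interval union.

## Synthetic fixtures: what they emulate and what they don't

The generator builds, per chromosome, haplotype-specific telomere nodes
(7.2 kb planted motif arrays at the outer tips), shared homozygous
backbone nodes, heterozygous bubbles, optional shared repeat loops with
per-haplotype copy numbers, deliberately missing arms/edges, and orphan
telomere nodes emitted as their own paths. Node sequences are random at
GC 0.42 with log-uniform lengths of 5–200 kb — roughly a hundredfold
below mammalian chromosome scale, chosen so the whole suite runs in
seconds on one core. Simulated reads follow the true haplotype walk
across each planted gap (reversed with probability 0.5), with planned
support counts recorded as truth; noise reads are single-node walks
that can never span a flank pair, so truth counts are exact rather than
approximate. Everything is byte-deterministic under the seed.

The standard scenario (4 chromosomes, 6 open gaps) plants a loop with
3 maternal / 7 paternal copies carried by 25 and 8 spanning reads, a
read-supported bubble, a counterpart-inference bubble (zero reads
through its own arm), a single-read bubble, a missing-edge gap with
four split reads, and an orphan q-telomere node.

What passing these tests shows: the bookkeeping, counting, decision
rules and writers are exact on inputs whose answer is known. What they
do not show: robustness to real alignment noise (chimeric alignments,
MAPQ miscalibration, homopolymer-compression artefacts), to tangles
deeper than simple bubbles and single-repeat loops, or to erroneous
ground truth — on real data every suggested fill still warrants
inspection of the graph and alignments.

## Pipeline heuristics

The scripted pipeline (`fillet.pipeline`) fills each gap by the first
applicable rule: (1) the best-supported spanning walk meeting
`min_support` (default 1) that is haplotype-consistent; (2) counterpart
bubble inference; (3) a split-read patch node. Haplotype consistency
rejects walks whose interior uses nodes the input paths (or earlier
fills in the same run) place exclusively in the other haplotype; when a
fill is applied, its single-copy interior nodes are marked as taken by
that haplotype while multi-copy traversals (repeats) remain shared.
This prevents a het bubble's counterpart arm — whose reads legitimately
span the shared homozygous flanks — from being stolen across
haplotypes, while leaving repeat loops fillable on both. Contig
connections are analyst decisions passed in explicitly, mirroring how
orphan joins are curated in practice.

## Known limitations

- The telomere density rule is this package's own definition (gap
  100 bp, proportion 0.4, span 200 bp); other scanners draw block
  boundaries slightly differently, so coordinates may differ by a few
  motif units near block edges.
- Threshold comparisons at exact boundary values are inclusive;
  sources that state thresholds as strict inequalities may differ on
  measure-zero cases.
- Patch sequences come from a single backbone read and inherit its
  error profile; they are placeholders for consensus, not polished
  sequence.
- `search_split_reads` works in contig space (one-segment walks with
  path coordinates on the contig); graph-space split detection across
  multi-node walks is not implemented.
- Chromosome orientation for species without a reference is left to an
  explicit flip list; no centromere-based inference is attempted.
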