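# fillet

Interactive curation of graph-based genome assemblies, from quality
assessment to a finished, chromosome-named, telomere-to-telomere (T2T)
assembly.

Graph-based assemblers such as Verkko represent an assembly as a graph —
nodes are homopolymer-compressed sequence segments, edges their oriented
adjacencies — together with haplotype *paths*: ordered, oriented node
walks (with gap tokens) that define each contig. Unresolved repeats,
haplotype ambiguity, and missing nodes or edges leave gaps in those
paths that propagate into the consensus. `fillet` gives the curator a
single persistent state object holding the graph, the path table, the
gap register, long-read graph alignments (GAF) and an append-only edit
history, plus the operations needed to close the gaps and emit corrected
path files for a consensus rerun.

## What it does

**Quality assessment** — density-based telomere motif scanning
(CCCTAA/TTAGGG, three passes with progressive end masking to recover
arrays hidden behind artefactual tips), N-run gap census, three-way
completeness classification (*T2T contig*: both telomeres, no gaps;
*T2T scaffold*: both telomeres, internal gaps; *scaffold* otherwise),
N50/L50, k-mer QV, chromosome assignment from whole-genome alignments
(blocks ≥ 1 Mb at ≥ 99% identity), and synteny subtraction.

The QV follows the standard k-mer survey argument: with *E* of *T*
assembly k-mers absent from the read k-mer database,

    per-base error  e = 1 − (1 − E/T)^(1/k),     QV = −10·log₁₀(e)

**Gap analysis** — gaps are discovered from the path table and keyed by
contig, position, flanking nodes and haplotype. For each gap, long-read
graph alignments are filtered to the best alignment per read and walks
spanning the flanks are counted, merging both traversal senses onto a
canonical orientation. Repeat loops get a copy-number estimate (the
modal number of repeat-node traversals across spanning reads); tangles
get per-node read depth; adjacencies missing from the graph are rescued
with split reads (> 5 kb aligned within 5 kb of each contig end,
MAPQ > 0, with joins under 3 reads flagged — the assembler needs three
to build an edge); and unsupported heterozygous bubbles are resolved by
inference from the counterpart haplotype's path.

**Path editing** — boundary-verified gap fills (first/last fill steps
must match the flanks in identity and orientation), reversible deletes,
contig connections across gap placeholders, patch nodes assembled from
split-read interiors, retention marks, reachability-based retention of
nodes inside unresolved gaps, and a deterministic writer producing the
final path TSV plus its walk-notation twin. Every mutation is an event
in the history; replaying the history reproduces the state exactly.

**Tuning** — internal-telomere discovery (proportion > 0.5, ≥ 15 kb from
a boundary) and trimming, chromosome naming by label propagation over
graph connectivity (multi-used nodes removed first; chrY counted as chrX
so pseudoautosomal nodes survive), renaming, IUPAC-aware reverse
complement flipping, karyotype sorting, and PAR masking (chrY intervals
homologous to chrX at ≥ 10 kb, ≥ 95% identity replaced by N).

**Fixtures** — a deterministic generator of ground-truthed diploid
graphs, path tables, simulated read walks, sequences with planted
telomere arrays, and alignment tables, so the whole workflow is testable
without external data.

## A worked example

```python
from fillet import fixtures, io, pipeline, qc

# a synthetic diploid assembly with six open gaps: a repeat loop on both
# haplotypes (3 vs 7 copies), het bubbles, a missing edge, an orphan
# telomere node
state, truth, extras = fixtures.make_curation_scenario(seed=1)

report = pipeline.run_curation(
    state, "fixed.paths.tsv", "fixed.paths.gaf",
    connections=[("chr4_mat", "chr4_mat_orphan", "right", False)],
    split_gaf=extras["split_gaf"], split_reads=extras["split_reads"],
)
```

This prints nothing itself; `examples/03_fill_and_write.py` runs it and
reports:

```
filled by spanning reads:      4
filled by counterpart inference: 1
filled by split-read patch:    1
connections applied:           1
left unfilled:                 0

final table: 8 paths, 1 gap token(s)
  contig  gaps    t2t_class
chr1_mat     0   T2T_CONTIG
...
chr4_mat     1 T2T_SCAFFOLD
chr4_pat     0   T2T_CONTIG
```

Four gaps close directly from spanning-read walks (including both loop
gaps at the read-supported copy numbers), one paternal bubble closes by
inference from the maternal path, the missing edge closes via a patch
node built from split reads, and the orphan telomere node is joined
across a deliberate gap — the single token left in the final table, so
that contig classifies as a T2T scaffold rather than a T2T contig.

The `examples/` directory has one short script per capability; each
builds its own input and explains the numbers it prints. A thin CLI
(`fillet load|qc|gaps|edit|tune|fixtures`) covers the batchable steps.

## What is out of scope

`fillet` consumes the outputs of external tools and never invokes them:
graph alignment (GraphAligner — the expected upstream invocation uses
diploid-heuristic seeding and multimap retention so alternate walks are
preserved), whole-genome alignment (mashmap/minimap2), k-mer database
construction (Meryl), consensus generation (Verkko), and polishing
variant callers. K-mer QV is computed from count summaries; variant
application, Hi-C map generation and annotation are downstream of this
package.
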