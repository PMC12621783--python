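"""Load an assembly bundle and assess its quality.

Builds a small synthetic diploid bundle (graph + paths + alignments +
consensus FASTA), loads it into a curation state, and runs the QC
battery: telomere detection, gap census, T2T classification, N50 and a
k-mer QV.
"""

import tempfile
from pathlib import Path

from fillet import fixtures, io, qc

tmp = Path(tempfile.mkdtemp())
bundle = fixtures.write_fixture_bundle(tmp / "bundle", seed=1)
state = io.read_bundle(bundle)
print(f"loaded: {len(state.graph)} nodes, {state.graph.n_edges()} edges, "
      f"{len(state.paths)} paths")

seqs = io.read_fasta(bundle / "assembly.fasta")
stats = qc.build_stats_table(seqs)
print(stats.to_string(index=False))
# telo_p/telo_q flag telomere arrays at each end; a contig with both
# telomeres and zero N gaps is a finished T2T contig.

n50, l50, total = qc.contiguity_stats([len(s) for s in seqs.values()])
print(f"\nN50 = {n50:,} bp over {l50} contigs (total {total:,} bp)")

# QV from k-mer counts: of 1M assembly 31-mers, 10 are absent from the
# read k-mer database (candidate base errors).
res = qc.compute_qv(total_kmers=1_000_000, error_kmers=10, k=31)
print(f"QV = {res.qv:.2f} (per-base error {res.per_base_error:.2e})")
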