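"""Finish an assembly: trim an artefactual tip, name, flip and sort.

A contig carries a dense telomere array ~18.8 kb inside the 5' end with
a non-telomeric tip in front of it — the signature of a misplaced read
extending past the true chromosome end.  The tip is trimmed, contigs
are renamed by chromosome, one is reoriented, and the set is sorted.
"""

from fillet import fixtures, qc, tuning

seqs, features = fixtures.make_sequences(
    {"contigA": 250_000, "contigB": 200_000},
    telomere_spec={"contigA": "q", "contigB": "pq"},
    internal_telomere_spec={"contigA": 18_800},
    seed=11,
)

annotations = []
for name, seq in seqs.items():
    annotations += qc.detect_telomeres_multipass(seq, contig=name)
hits = tuning.find_internal_telomeres(
    annotations, {n: len(s) for n, s in seqs.items()}
)
for h in hits:
    print(f"internal telomere on {h.contig}: [{h.start:,}, {h.end:,}) "
          f"prop {h.motif_prop:.2f}, {h.dist_from_end:,} bp from the end")

# trim everything before the validated telomere signal
trim_at = hits[0].start
trimmed = tuning.trim_contig(seqs, "contigA", trim_at, len(seqs["contigA"]))
print(f"contigA: {len(seqs['contigA']):,} -> {len(trimmed['contigA']):,} bp")
cls = qc.build_stats_table({"contigA": trimmed["contigA"]})["t2t_class"][0]
print(f"contigA now classifies as {cls}")

renamed, _ = tuning.rename_contigs(
    trimmed, {"contigA": "chr2_mat", "contigB": "chr1_mat"}
)
flipped = tuning.flip_contigs(renamed, ["chr2_mat"])  # match reference orientation
ordered = tuning.sort_contigs(flipped, sort_by="hap")
print("final record order:", list(ordered))
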