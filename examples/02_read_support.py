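"""Quantify read support for gap traversals.

For each gap the framework counts long reads whose graph-alignment
walks span the flanking nodes, merging both traversal senses, and for
repeat loops estimates the copy number each haplotype traverses.
"""

from fillet import editing, fixtures, gaps as ga

state, truth, extras = fixtures.make_curation_scenario(seed=1)
editing.register_gaps(state)
print(f"{len(state.open_gaps())} open gaps discovered from the path table\n")

# the chr1 repeat loop: maternal reads traverse 3 copies, paternal 7
for contig in ("chr1_mat", "chr1_pat"):
    gap = truth.gap_for(contig, "loop")
    walks = ga.count_spanning_walks(state.gaf, gap.left, gap.right,
                                    graph=state.graph)
    est = ga.estimate_loop_copies(state.gaf, gap.repeat_node, gap.left, gap.right)
    fwd, rev = walks[0].strand_split
    print(f"{contig}: {walks[0].n_reads} spanning reads "
          f"({fwd} forward / {rev} reverse traversals)")
    print(f"  modal copy number of {gap.repeat_node}: {est.modal_copies} "
          f"(histogram {est.copy_histogram})")
# the modal copy count is the number of repeat units to insert into
# that haplotype's path when filling the loop gap.

# node read depth (reads per kb) helps separate haplotype arms in tangles
table = ga.node_depth(state.gaf, state.graph, merge=False)
print("\nmost-covered nodes (reads/kb):")
print(table.nlargest(3, "depth").to_string(index=False))
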