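"""Scripted curation pipeline.

Chains the evidence-driven steps — spanning-walk fills, counterpart-
haplotype inference, split-read patching, analyst-specified contig
connections — and emits the corrected path table.  Each step uses only
read evidence and the graph; nothing here peeks at fixture truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from . import editing, gaps as ga
from .model import CurationState, GapRecord, PathStep

__all__ = ["CurationReport", "auto_fill_gaps", "run_curation"]


@dataclass
class CurationReport:
    filled_by_reads: list[str] = field(default_factory=list)
    filled_by_inference: list[str] = field(default_factory=list)
    filled_by_patch: list[str] = field(default_factory=list)
    connections: list[str] = field(default_factory=list)
    unfilled: list[str] = field(default_factory=list)


def _orient_fill(walk: Sequence[PathStep], gap: GapRecord) -> list[PathStep]:
    """Orient a canonical walk so it runs left flank -> right flank."""
    walk = list(walk)
    if walk[0] == gap.left_flank and walk[-1] == gap.right_flank:
        return walk
    flipped = [s.flipped() for s in reversed(walk)]
    if flipped[0] == gap.left_flank and flipped[-1] == gap.right_flank:
        return flipped
    return walk  # leave as-is; fill_gap will check the boundary


def _bubble_candidates(state: CurationState, gap: GapRecord) -> Optional[list[PathStep]]:
    """The two single-node traversals between the gap's flanks, if the
    flanks enclose a simple het bubble (as oriented steps)."""
    g = editing._oriented_digraph(state)
    left = (gap.left_flank.node_id, gap.left_flank.orient)
    right = (gap.right_flank.node_id, gap.right_flank.orient)
    if left not in g or right not in g:
        return None
    mid = sorted(n for n in g.successors(left) if g.has_edge(n, right))
    steps = [PathStep.node(nid, orient) for nid, orient in mid]
    if len({s.node_id for s in steps}) == 2 and len(steps) == 2:
        return steps
    return None


def _haplotype_node_sets(paths) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for p in paths:
        out.setdefault(p.assignment, set()).update(p.node_ids())
    return out


def _haplotype_consistent(
    hap_nodes: dict[str, set[str]], gap: GapRecord, walk
) -> bool:
    """True unless the walk's interior uses a node the input paths place
    exclusively in the other haplotype — reads through the counterpart
    arm of a het bubble span the shared flanks but must not fill this
    haplotype.  Nodes the assembler left unplaced (repeat loops) are
    fair game for both."""
    own = hap_nodes.get(gap.haplotype, set())
    other = set().union(
        *(nodes for hap, nodes in hap_nodes.items()
          if hap not in (gap.haplotype, "NONE"))
    ) if hap_nodes else set()
    interior = {s.node_id for s in list(walk)[1:-1]}
    return not (interior & (other - own))


def _counterpart_path(state: CurationState, gap: GapRecord):
    """The other-haplotype path sharing both flanking nodes."""
    for p in state.paths:
        if p.name == gap.contig:
            continue
        nodes = set(p.node_ids())
        if gap.left_flank.node_id in nodes and gap.right_flank.node_id in nodes:
            return p
    return None


def auto_fill_gaps(
    state: CurationState,
    min_support: int = 1,
    split_gaf=None,
    split_reads=None,
    infer_from_counterpart: bool = True,
) -> CurationReport:
    """Fill every OPEN gap the evidence supports.

    Order of preference per gap: (1) the best-supported spanning walk
    from the graph alignments, (2) counterpart-haplotype bubble
    inference, (3) a patch node built from split reads anchoring both
    flanks (``split_gaf``/``split_reads``).  Gaps with no usable
    evidence stay OPEN and are listed in the report.
    """
    report = CurationReport()
    best_gaf = ga.best_alignment_per_read(state.gaf)
    patch_serial = 1
    # haplotype exclusivity is judged on the input paths, before fills
    hap_nodes = _haplotype_node_sets(state.paths)

    for gap in list(state.open_gaps()):
        if gap.left_flank is None or gap.right_flank is None:
            report.unfilled.append(gap.gap_id)
            continue

        walks = ga.count_spanning_walks(
            best_gaf, gap.left_flank, gap.right_flank,
            graph=state.graph, filter_best=False,
        )
        usable_walk = next(
            (
                w for w in walks
                if w.n_reads >= min_support
                and _haplotype_consistent(hap_nodes, gap, w.walk)
            ),
            None,
        )
        if usable_walk is not None:
            fill = _orient_fill(usable_walk.walk, gap)
            editing.fill_gap(state, gap.gap_id, fill)
            report.filled_by_reads.append(gap.gap_id)
            # single-copy interior nodes are now spoken for by this
            # haplotype; multi-copy traversals are repeats, still shared
            interior = [s.node_id for s in fill[1:-1]]
            hap_nodes.setdefault(gap.haplotype, set()).update(
                nid for nid in interior if interior.count(nid) == 1
            )
            continue

        if infer_from_counterpart:
            bubble = _bubble_candidates(state, gap)
            other = _counterpart_path(state, gap)
            if bubble and other is not None:
                ids = (bubble[0].node_id, bubble[1].node_id)
                suggestion = ga.highlight_counterpart_assignment(gap, ids, other)
                if suggestion.status == "INFERRED":
                    chosen = next(s for s in bubble if s.node_id == suggestion.node)
                    fill = [gap.left_flank, chosen, gap.right_flank]
                    editing.fill_gap(state, gap.gap_id, fill)
                    report.filled_by_inference.append(gap.gap_id)
                    continue

        if split_gaf is not None and split_reads is not None:
            ends = [
                (gap.left_flank.node_id, "right"),
                (gap.right_flank.node_id, "left"),
            ]
            joins = ga.search_split_reads(split_gaf, ends)
            usable = [j for j in joins if {j.end_a, j.end_b} == set(ends)]
            if usable:
                patch = editing.build_patch_node(
                    split_reads, (ends[0], ends[1]), serial=patch_serial
                )
                patch_serial += 1
                editing.register_patch_node(state, patch)
                fill = [gap.left_flank, PathStep.node(patch.id, "+"), gap.right_flank]
                editing.fill_gap(state, gap.gap_id, fill)
                report.filled_by_patch.append(gap.gap_id)
                continue

        report.unfilled.append(gap.gap_id)
    return report


def run_curation(
    state: CurationState,
    out_paths: str,
    out_gaf: Optional[str] = None,
    connections: Sequence[tuple] = (),
    min_support: int = 1,
    split_gaf=None,
    split_reads=None,
) -> CurationReport:
    """End-to-end curation: discover gaps, fill what the evidence
    supports, apply analyst connection decisions, retain everything
    still reachable inside unresolved gaps, and write the corrected
    path table ready for a consensus rerun."""
    editing.register_gaps(state)
    report = auto_fill_gaps(
        state, min_support=min_support,
        split_gaf=split_gaf, split_reads=split_reads,
    )
    for source, target, at, flip in connections:
        editing.connect_contigs(state, source, target, at=at, flip=flip)
        report.connections.append(f"connection:{source}:{target}")
    keep = [p.name for p in state.paths]
    editing.mark_keep_contigs(state, keep)
    if connections:
        editing.mark_connection_endpoints(state)
    editing.nodes_in_unresolved_gaps(state)
    editing.write_fixed_paths(state, out_paths, out_gaf)
    return report
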