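"""Gap discovery and read-support quantification.

Gaps are found as gap tokens in contig paths; candidate traversals are
then weighed with long-read graph alignments: spanning-walk counting
(both traversal senses merged onto a canonical orientation), repeat loop
copy-number estimation, per-node read depth, and split-read rescue for
adjacencies the graph is missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .model import (
    AssemblyGraph,
    ContigPath,
    GafRecord,
    GapRecord,
    PathStep,
)

__all__ = [
    "WalkCount",
    "LoopEstimate",
    "FillSuggestion",
    "SplitJoin",
    "find_gaps",
    "best_alignment_per_read",
    "count_spanning_walks",
    "estimate_loop_copies",
    "node_depth",
    "search_split_reads",
    "highlight_counterpart_assignment",
]

BELOW_EDGE_THRESHOLD = "BELOW_EDGE_THRESHOLD"


@dataclass
class WalkCount:
    """Read support for one canonical walk between two flanks."""

    walk: tuple[PathStep, ...]
    n_reads: int
    strand_split: tuple[int, int]  # (forward, reverse) traversals

    def render(self) -> str:
        return ",".join(s.render() for s in self.walk)


@dataclass
class LoopEstimate:
    """Modal repeat copy number across spanning reads."""

    repeat_node: str
    flank_a: PathStep
    flank_b: PathStep
    copy_histogram: dict[int, int]
    modal_copies: Optional[int]
    support: int
    status: str = "OK"  # OK | NO_SUPPORT


@dataclass
class FillSuggestion:
    status: str  # INFERRED | NO_SUGGESTION
    node: Optional[str] = None
    note: str = ""


@dataclass
class SplitJoin:
    end_a: tuple[str, str]
    end_b: tuple[str, str]
    reads: list[str]
    flag: Optional[str] = None

    @property
    def n_reads(self) -> int:
        return len(self.reads)


# ---------------------------------------------------------------------------
# gap discovery

def find_gaps(paths: Sequence[ContigPath]) -> list[GapRecord]:
    """One OPEN record per gap step, keyed by contig, position, flanking
    nodes and haplotype so identical flank pairs on different haplotypes
    stay distinct."""
    records: list[GapRecord] = []
    for path in paths:
        for idx in path.gap_indices():
            left = next(
                (path.steps[i] for i in range(idx - 1, -1, -1) if not path.steps[i].is_gap),
                None,
            )
            right = next(
                (path.steps[i] for i in range(idx + 1, len(path.steps)) if not path.steps[i].is_gap),
                None,
            )
            gap_id = ":".join(
                [
                    path.name,
                    str(idx),
                    left.node_id if left else "NA",
                    right.node_id if right else "NA",
                    path.assignment,
                ]
            )
            records.append(
                GapRecord(
                    gap_id=gap_id,
                    contig=path.name,
                    step_index=idx,
                    left_flank=left,
                    right_flank=right,
                    haplotype=path.assignment,
                    original_gap=path.steps[idx],
                    terminal=left is None or right is None,
                )
            )
    return records


# ---------------------------------------------------------------------------
# alignment filtering

def best_alignment_per_read(gaf: Sequence[GafRecord]) -> list[GafRecord]:
    """Keep one alignment per read: highest MAPQ, ties by larger aligned
    block, then input order."""
    best: dict[str, tuple[tuple, GafRecord]] = {}
    for i, rec in enumerate(gaf):
        key = (-rec.mapq, -rec.block_len, i)
        if rec.read_name not in best or key < best[rec.read_name][0]:
            best[rec.read_name] = (key, rec)
    order = {r.read_name: i for i, (_, r) in enumerate(best.values())}
    return [r for _, r in sorted(best.values(), key=lambda kr: kr[0][2])]


# ---------------------------------------------------------------------------
# spanning walks

def _as_step(step: Union[str, PathStep]) -> PathStep:
    if isinstance(step, PathStep):
        return step
    step = step.strip()
    if step[0] in "><":
        return PathStep.node(step[1:], "+" if step[0] == ">" else "-")
    return PathStep.node(step[:-1], step[-1])


def _flip_walk(walk: Sequence[PathStep]) -> list[PathStep]:
    return [s.flipped() for s in reversed(walk)]


def _render(walk: Sequence[PathStep]) -> str:
    return ",".join(s.render() for s in walk)


def canonical_walk(walk: Sequence[PathStep]) -> tuple[PathStep, ...]:
    """A walk and its reverse-complement traversal are the same key; the
    canonical form is the lexicographically smaller rendering."""
    flipped = _flip_walk(walk)
    return tuple(walk) if _render(walk) <= _render(flipped) else tuple(flipped)


def _extract_subwalk(
    walk: Sequence[PathStep], flank_a: PathStep, flank_b: PathStep
) -> Optional[tuple[list[PathStep], str]]:
    """Sub-walk from the first flank_a to the last flank_b, in either
    traversal sense; None when the read does not span."""
    for sense, w in (("+", list(walk)), ("-", _flip_walk(walk))):
        first_a = next((i for i, s in enumerate(w) if s == flank_a), None)
        if first_a is None:
            continue
        last_b = next(
            (i for i in range(len(w) - 1, -1, -1) if w[i] == flank_b), None
        )
        if last_b is None or last_b <= first_a:
            continue
        return w[first_a: last_b + 1], sense
    return None


def count_spanning_walks(
    gaf: Sequence[GafRecord],
    flank_a: Union[str, PathStep],
    flank_b: Union[str, PathStep],
    graph: Optional[AssemblyGraph] = None,
    filter_best: bool = True,
) -> list[WalkCount]:
    """Count reads whose alignment walk spans flank_a ... flank_b.

    Both traversal senses of a read are considered; support is merged
    onto the canonical walk orientation.  Results are sorted by
    descending read count.
    """
    fa, fb = _as_step(flank_a), _as_step(flank_b)
    if graph is not None:
        for f in (fa, fb):
            if f.node_id not in graph:
                raise KeyError(f"flank node {f.node_id!r} not in graph")
    records = best_alignment_per_read(gaf) if filter_best else list(gaf)
    counts: dict[tuple[PathStep, ...], list[int]] = {}
    for rec in records:
        hit = _extract_subwalk(rec.walk, fa, fb)
        if hit is None:
            continue
        sub, sense = hit
        key = canonical_walk(sub)
        fwd_rev = counts.setdefault(key, [0, 0])
        fwd_rev[0 if sense == "+" else 1] += 1
    out = [
        WalkCount(walk, fwd + rev, (fwd, rev))
        for walk, (fwd, rev) in counts.items()
    ]
    out.sort(key=lambda w: (-w.n_reads, w.render()))
    return out


def estimate_loop_copies(
    gaf: Sequence[GafRecord],
    repeat_node: str,
    flank_a: Union[str, PathStep],
    flank_b: Union[str, PathStep],
    filter_best: bool = True,
) -> LoopEstimate:
    """Per spanning read, count traversals of ``repeat_node`` (either
    orientation) between the flanks; report the histogram and its mode
    (ties broken toward fewer copies)."""
    fa, fb = _as_step(flank_a), _as_step(flank_b)
    records = best_alignment_per_read(gaf) if filter_best else list(gaf)
    hist: dict[int, int] = {}
    for rec in records:
        hit = _extract_subwalk(rec.walk, fa, fb)
        if hit is None:
            continue
        copies = sum(1 for s in hit[0] if s.node_id == repeat_node)
        hist[copies] = hist.get(copies, 0) + 1
    if not hist:
        return LoopEstimate(repeat_node, fa, fb, {}, None, 0, status="NO_SUPPORT")
    modal = min(hist, key=lambda c: (-hist[c], c))
    return LoopEstimate(repeat_node, fa, fb, hist, modal, hist[modal])


# ---------------------------------------------------------------------------
# depth

def node_depth(
    gaf: Sequence[GafRecord], graph: AssemblyGraph, merge: bool = True
) -> pd.DataFrame:
    """Reads per kilobase per node.

    A read visiting a node several times within one alignment counts
    once for that record (read-presence semantics, not pileup).
    """
    counts: dict[str, int] = {}
    for rec in gaf:
        for nid in {s.node_id for s in rec.walk}:
            counts[nid] = counts.get(nid, 0) + 1
    rows = []
    for nid in sorted(graph.nodes):
        node = graph.nodes[nid]
        if node.length_hpc == 0:
            raise ValueError(f"node {nid} has zero length")
        reads = counts.get(nid, 0)
        depth = reads / (node.length_hpc / 1000.0)
        if merge:
            node.depth = depth
        rows.append({"node": nid, "reads": reads, "length": node.length_hpc, "depth": depth})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# split reads

def search_split_reads(
    gaf: Sequence[GafRecord],
    contig_ends: Sequence[tuple[str, str]],
    min_aligned: int = 5_000,
    end_window: int = 5_000,
    min_mapq: int = 1,
    min_reads: int = 3,
) -> list[SplitJoin]:
    """Find reads whose split alignments anchor two contig ends.

    The input alignments are read-to-contig (the walk is the single
    contig record, path coordinates in contig space); *all* alignments
    per read are considered.  An alignment qualifies at an end when it
    covers more than ``min_aligned`` bases, intersects the terminal
    ``end_window`` of that end, and has MAPQ above zero.  Joins with
    fewer than ``min_reads`` supporting reads are flagged — the graph
    builder needs at least that many to create an edge.
    """
    wanted = set(contig_ends)
    per_read: dict[str, set[tuple[str, str]]] = {}
    for rec in gaf:
        if rec.mapq < min_mapq:
            continue
        if len(rec.walk) != 1:
            continue
        contig = rec.walk[0].node_id
        aligned = rec.path_end - rec.path_start
        if aligned <= min_aligned:
            continue
        for end in ("left", "right"):
            if (contig, end) not in wanted:
                continue
            if end == "left" and rec.path_start < end_window:
                per_read.setdefault(rec.read_name, set()).add((contig, end))
            elif end == "right" and rec.path_end > rec.path_len - end_window:
                per_read.setdefault(rec.read_name, set()).add((contig, end))

    joins: dict[tuple, list[str]] = {}
    for read in sorted(per_read):
        ends = sorted(per_read[read])
        for i in range(len(ends)):
            for j in range(i + 1, len(ends)):
                joins.setdefault((ends[i], ends[j]), []).append(read)
    out = [
        SplitJoin(a, b, reads, BELOW_EDGE_THRESHOLD if len(reads) < min_reads else None)
        for (a, b), reads in sorted(joins.items())
    ]
    out.sort(key=lambda j: (-j.n_reads, j.end_a, j.end_b))
    return out


# ---------------------------------------------------------------------------
# counterpart-haplotype inference

def highlight_counterpart_assignment(
    gap: GapRecord,
    bubble_nodes: tuple[str, str],
    other_hap_path: ContigPath,
) -> FillSuggestion:
    """When one node of a het bubble is already used by the counterpart
    haplotype, suggest the other node as the fill for this gap.

    The suggestion carries no direct read support (it is an inference
    from the alternate haplotype's path) and is never auto-applied.
    """
    used = set(other_hap_path.node_ids())
    a, b = bubble_nodes
    in_other = [n for n in (a, b) if n in used]
    if len(in_other) == 1:
        unused = b if in_other[0] == a else a
        return FillSuggestion("INFERRED", unused,
                              f"{in_other[0]} already used in {other_hap_path.name}")
    if not in_other:
        return FillSuggestion("NO_SUGGESTION", note="neither bubble node used elsewhere")
    return FillSuggestion(
        "NO_SUGGESTION",
        note=f"conflict: both bubble nodes used in {other_hap_path.name}",
    )
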