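"""Path editing: applying curation decisions to the assembly.

Every mutation goes through the :class:`~fillet.model.CurationState`
history (event sourcing): the operation name and its fully-serialisable
parameters are appended, so replaying the history against the initial
state reproduces the final state exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import networkx as nx
import pandas as pd

from .gaps import find_gaps
from .model import (
    DEFAULT_GAP_LEN,
    DROP,
    KEEP_CONTIG,
    AssemblyGraph,
    ContigPath,
    CurationState,
    EdgeRecord,
    GapRecord,
    NodeRecord,
    PathStep,
)

__all__ = [
    "PatchNode",
    "AnchoredRead",
    "register_gaps",
    "fill_gap",
    "delete_gap",
    "connect_contigs",
    "detect_broken_contigs",
    "build_patch_node",
    "register_patch_node",
    "mark_keep_contigs",
    "mark_connection_endpoints",
    "nodes_in_unresolved_gaps",
    "write_fixed_paths",
    "rdna_patch",
    "replay_history",
]


@dataclass
class Anchor:
    read_start: int
    read_end: int
    mapq: int


@dataclass
class AnchoredRead:
    """A read with one anchor alignment at each side of a missing join."""

    name: str
    sequence: str
    anchor_a: Anchor
    anchor_b: Anchor


@dataclass
class PatchNode:
    """A new node assembled from read sequence to bridge a missing
    adjacency; once registered it behaves like any graph node."""

    id: str
    sequence: str
    joins: tuple[tuple[str, str], tuple[str, str]]
    support: list[str]


# ---------------------------------------------------------------------------
# gap registration

def register_gaps(state: CurationState) -> list[GapRecord]:
    """Discover gaps from the current paths and store them on the state."""
    state.gaps = find_gaps(state.paths) + state.connections()
    state.log("find_gaps", {})
    return state.gaps


def _shift_gap_indices(state: CurationState, contig: str, after: int, delta: int) -> None:
    if delta == 0:
        return
    for g in state.gaps:
        if g.contig == contig and g.step_index > after and g.status != "CONNECTION":
            g.step_index += delta


# ---------------------------------------------------------------------------
# fill / delete

def fill_gap(
    state: CurationState,
    gap_id: str,
    fill_steps: Union[str, Sequence[PathStep]],
    force: bool = False,
) -> CurationState:
    """Replace a gap step with a verified node traversal.

    The first and last fill steps must match the gap's flanking nodes in
    identity and orientation; a mismatch is rejected unless ``force``.
    """
    from .io import parse_path_string, render_path_steps

    if isinstance(fill_steps, str):
        fill_steps = parse_path_string(fill_steps)
    fill_steps = [s for s in fill_steps]
    gap = state.gap_by_id(gap_id)
    if gap.status != "OPEN":
        raise ValueError(f"gap {gap_id} is {gap.status}, not OPEN")
    if len(fill_steps) < 2 or any(s.is_gap for s in fill_steps):
        raise ValueError("fill must be >=2 oriented node steps, no gaps")
    for s in fill_steps:
        if s.node_id not in state.graph:
            raise KeyError(f"fill node {s.node_id!r} not in graph")
    if not force:
        problems = []
        if gap.left_flank is not None and fill_steps[0] != gap.left_flank:
            problems.append(
                f"left boundary {fill_steps[0].render()} != flank {gap.left_flank.render()}"
            )
        if gap.right_flank is not None and fill_steps[-1] != gap.right_flank:
            problems.append(
                f"right boundary {fill_steps[-1].render()} != flank {gap.right_flank.render()}"
            )
        if problems:
            raise ValueError(f"boundary mismatch for {gap_id}: " + "; ".join(problems))

    path = state.path_by_name(gap.contig)
    if not path.steps[gap.step_index].is_gap:
        raise AssertionError(f"gap {gap_id}: step index out of sync")
    interior = fill_steps[1:-1]
    path.steps[gap.step_index: gap.step_index + 1] = interior
    _shift_gap_indices(state, gap.contig, gap.step_index, len(interior) - 1)
    gap.status = "FILLED"
    gap.fill_steps = list(fill_steps)
    state.log(
        "fill_gap",
        {"gap_id": gap_id, "fill": render_path_steps(fill_steps), "force": force},
        gap_id=gap_id,
    )
    return state


def delete_gap(state: CurationState, gap_id: str) -> CurationState:
    """Undo a fill (FILLED -> OPEN, original gap token restored) or
    retire an OPEN gap from fill bookkeeping (-> DELETED)."""
    gap = state.gap_by_id(gap_id)
    if gap.status == "FILLED":
        path = state.path_by_name(gap.contig)
        n_interior = len(gap.fill_steps) - 2
        path.steps[gap.step_index: gap.step_index + n_interior] = [
            gap.original_gap or PathStep.gap(DEFAULT_GAP_LEN)
        ]
        _shift_gap_indices(state, gap.contig, gap.step_index, 1 - n_interior)
        gap.status = "OPEN"
        gap.fill_steps = None
    elif gap.status == "OPEN":
        gap.status = "DELETED"
    else:
        raise ValueError(f"gap {gap_id} is {gap.status}; nothing to delete")
    state.log("delete_gap", {"gap_id": gap_id}, gap_id=gap_id)
    return state


# ---------------------------------------------------------------------------
# connections

def connect_contigs(
    state: CurationState,
    source: str,
    target: str,
    at: str = "right",
    flip: bool = False,
) -> CurationState:
    """Record that ``target`` should be joined onto the ``at`` side of
    ``source`` across a gap.  Paths are not modified here; the merge is
    deferred to :func:`write_fixed_paths`."""
    if source == target:
        raise ValueError("cannot connect a contig to itself")
    if at not in ("left", "right"):
        raise ValueError("at must be 'left' or 'right'")
    for name in (source, target):
        if not state.has_path(name):
            raise KeyError(f"no contig named {name!r}")
    for g in state.connections():
        if {g.source, g.target} == {source, target}:
            raise ValueError(f"duplicate connection {source}<->{target}")
    gap_id = f"connection:{source}:{target}"
    state.gaps.append(
        GapRecord(
            gap_id=gap_id, contig=source, step_index=-1,
            left_flank=None, right_flank=None,
            haplotype=state.path_by_name(source).assignment,
            status="CONNECTION", source=source, target=target, at=at, flip=flip,
        )
    )
    state.log(
        "connect_contigs",
        {"source": source, "target": target, "at": at, "flip": flip},
        gap_id=gap_id,
    )
    return state


def detect_broken_contigs(stats: pd.DataFrame) -> list[dict]:
    """Pairs of non-T2T contigs sharing chromosome and haplotype — the
    classic signature of one chromosome broken in two.  Each pair notes
    which telomere ends are missing."""
    cand = stats[
        (stats["t2t_class"] != "T2T_CONTIG")
        & (stats["chromosome"] != "UNASSIGNED")
    ]
    pairs = []
    for (chrom, hap), grp in cand.groupby(["chromosome", "haplotype"], sort=True):
        rows = grp.sort_values("contig").to_dict("records")
        for a, b in itertools.combinations(rows, 2):
            pairs.append(
                {
                    "chromosome": chrom,
                    "haplotype": hap,
                    "contig_a": a["contig"],
                    "contig_b": b["contig"],
                    "missing_ends_a": _missing_ends(a),
                    "missing_ends_b": _missing_ends(b),
                }
            )
    return pairs


def _missing_ends(row: dict) -> list[str]:
    out = []
    if not row.get("telo_p", False):
        out.append("p")
    if not row.get("telo_q", False):
        out.append("q")
    return out


# ---------------------------------------------------------------------------
# patch nodes

def build_patch_node(
    reads: Sequence[AnchoredRead],
    join: tuple[tuple[str, str], tuple[str, str]],
    prefix: str = "patch",
    serial: int = 1,
) -> PatchNode:
    """Assemble a bridging node from split-read evidence.

    The backbone is the single supporting read with the highest summed
    anchor MAPQ; the patch sequence is the unaligned interior between
    its two anchor alignments.  Abutting or overlapping anchors give a
    zero-length patch (edge-only join).
    """
    if not reads:
        raise ValueError("no supporting reads for patch")
    best = max(reads, key=lambda r: (r.anchor_a.mapq + r.anchor_b.mapq, r.name))
    left, right = sorted((best.anchor_a, best.anchor_b), key=lambda a: a.read_start)
    interior = best.sequence[left.read_end: right.read_start] if right.read_start > left.read_end else ""
    return PatchNode(
        id=f"{prefix}-{serial}",
        sequence=interior,
        joins=(join[0], join[1]),
        support=[r.name for r in reads],
    )


def register_patch_node(state: CurationState, patch: PatchNode) -> CurationState:
    """Insert a patch node (and its joining edges) into the graph."""
    if patch.id in state.graph:
        raise ValueError(f"patch id {patch.id!r} collides with an existing node")
    end_a, end_b = patch.joins
    step_a = _end_step(state, *end_a)
    step_b = _end_step(state, *end_b)
    if patch.sequence:
        state.graph.add_node(
            NodeRecord(patch.id, len(patch.sequence), sequence=patch.sequence)
        )
        state.graph.add_edge(
            EdgeRecord(step_a.node_id, step_a.orient, patch.id, "+")
        )
        state.graph.add_edge(
            EdgeRecord(patch.id, "+", step_b.node_id, step_b.orient)
        )
    else:
        state.graph.add_edge(
            EdgeRecord(step_a.node_id, step_a.orient, step_b.node_id, step_b.orient)
        )
    state.log(
        "register_patch_node",
        {
            "id": patch.id, "sequence": patch.sequence,
            "joins": [list(end_a), list(end_b)], "support": patch.support,
        },
    )
    return state


def _end_step(state: CurationState, name: str, end: str) -> PathStep:
    """Oriented node at a join end.

    ``name`` may be a contig path (its terminal node step is used) or a
    bare graph node (forward orientation assumed).
    """
    if state.has_path(name):
        nodes = state.path_by_name(name).node_steps()
        if not nodes:
            raise ValueError(f"contig {name} has no node steps")
        return nodes[-1] if end == "right" else nodes[0]
    if name in state.graph:
        return PathStep.node(name, "+")
    raise KeyError(f"join end {name!r} is neither a path nor a node")


# ---------------------------------------------------------------------------
# retention marks

def mark_keep_contigs(
    state: CurationState, contig_list: Sequence[str]
) -> tuple[CurationState, list[str]]:
    """Mark listed contigs keep_contig and everything else drop
    (reversible).  Returns warnings for connection endpoints that the
    keep list omits."""
    names = {p.name for p in state.paths}
    unknown = [c for c in contig_list if c not in names]
    if unknown:
        raise KeyError(f"unknown contig names: {', '.join(sorted(unknown))}")
    keep = set(contig_list)
    for p in state.paths:
        p.retain_flag = KEEP_CONTIG if p.name in keep else DROP
    warnings = []
    for g in state.connections():
        for endpoint in (g.source, g.target):
            if endpoint not in keep:
                warnings.append(
                    f"connection {g.gap_id} endpoint {endpoint} not in keep list"
                )
    state.log("mark_keep_contigs", {"contigs": sorted(keep)})
    return state, warnings


def mark_connection_endpoints(state: CurationState) -> CurationState:
    """Re-mark connection source/target paths so the writer merges them
    instead of dropping them."""
    for g in state.connections():
        for endpoint in (g.source, g.target):
            path = state.path_by_name(endpoint)
            if path.retain_flag == DROP:
                raise ValueError(
                    f"connection {g.gap_id} endpoint {endpoint} is marked drop; "
                    "resolve the conflict before writing"
                )
            if path.retain_flag is None:
                path.retain_flag = KEEP_CONTIG
    state.log("mark_connection_endpoints", {})
    return state


# ---------------------------------------------------------------------------
# unresolved-gap retention

def _oriented_digraph(state: CurationState) -> nx.DiGraph:
    g = nx.DiGraph()
    for nid in state.graph.nodes:
        g.add_node((nid, "+"))
        g.add_node((nid, "-"))
    for src, dst in state.graph.oriented_arcs():
        g.add_edge(src, dst)
    # connections contribute a synthetic traversal edge source-end -> target-end
    for conn in state.connections():
        src_path = state.path_by_name(conn.source)
        tgt_path = state.path_by_name(conn.target)
        tgt_steps = [s for s in tgt_path.node_steps()]
        if conn.flip:
            tgt_steps = [s.flipped() for s in reversed(tgt_steps)]
        src_steps = src_path.node_steps()
        if not src_steps or not tgt_steps:
            continue
        if conn.at == "right":
            a, b = src_steps[-1], tgt_steps[0]
        else:
            a, b = tgt_steps[-1], src_steps[0]
        g.add_edge((a.node_id, a.orient), (b.node_id, b.orient))
        g.add_edge((b.node_id, _flip(b.orient)), (a.node_id, _flip(a.orient)))
    return g


def _flip(o: str) -> str:
    return "-" if o == "+" else "+"


def nodes_in_unresolved_gaps(
    state: CurationState, mode: str = "intersection"
) -> set[str]:
    """Nodes lying between the flanks of any remaining OPEN gap.

    For flanks (L, R) the flagged set is descendants(L) ∩ ancestors(R)
    in the oriented-edge digraph (``mode='union'`` takes the union
    instead).  The result is unioned over gaps, recorded on the state,
    and excluded from path dropping so unused nodes keep attracting
    reads at consensus time.
    """
    g = _oriented_digraph(state)
    flagged: set[str] = set()
    for gap in state.open_gaps():
        if gap.left_flank is None or gap.right_flank is None:
            continue
        left = (gap.left_flank.node_id, gap.left_flank.orient)
        right = (gap.right_flank.node_id, gap.right_flank.orient)
        if left not in g or right not in g:
            continue
        desc = nx.descendants(g, left)
        anc = nx.ancestors(g, right)
        between = desc & anc if mode == "intersection" else desc | anc
        flagged |= {nid for nid, _ in between}
    flagged -= {
        f.node_id
        for gap in state.open_gaps()
        for f in (gap.left_flank, gap.right_flank)
        if f is not None
    }
    state.keep_nodes |= flagged
    state.log("nodes_in_unresolved_gaps", {"mode": mode, "nodes": sorted(flagged)})
    return flagged


# ---------------------------------------------------------------------------
# writer

def write_fixed_paths(
    state: CurationState,
    out_paths: str,
    out_gaf: Optional[str] = None,
    gap_len: int = DEFAULT_GAP_LEN,
) -> list[ContigPath]:
    """Emit the final path table (and its walk-notation twin).

    Filled gaps are already inline; connection pairs are merged here
    (target appended or prepended per ``at``, reverse-complemented when
    ``flip``, joined with a gap token).  Drop-marked paths vanish unless
    their nodes are in the unresolved-gap keep set, in which case each
    kept node is emitted as a minimal single-node path.
    """
    merged: dict[str, ContigPath] = {
        p.name: ContigPath(p.name, list(p.steps), p.assignment, p.retain_flag)
        for p in state.paths
    }
    order = [p.name for p in state.paths]

    conflicts = []
    for conn in state.connections():
        for endpoint in (conn.source, conn.target):
            if merged[endpoint].retain_flag == DROP:
                conflicts.append(f"{conn.gap_id}: endpoint {endpoint} marked drop")
    if conflicts:
        raise ValueError("unresolved conflicting marks: " + "; ".join(conflicts))

    for conn in state.connections():
        src = merged[conn.source]
        tgt = merged.pop(conn.target)
        order.remove(conn.target)
        tgt_steps = list(tgt.steps)
        if conn.flip:
            tgt_steps = [s.flipped() for s in reversed(tgt_steps)]
        if conn.at == "right":
            src.steps = src.steps + [PathStep.gap(gap_len)] + tgt_steps
        else:
            src.steps = tgt_steps + [PathStep.gap(gap_len)] + src.steps

    final: list[ContigPath] = []
    used_nodes: set[str] = set()
    for name in order:
        p = merged[name]
        if p.retain_flag == DROP:
            continue
        final.append(p)
        used_nodes |= set(p.node_ids())

    for nid in sorted(state.keep_nodes - used_nodes):
        final.append(ContigPath(f"unused_{nid}", [PathStep.node(nid, "+")], "NONE"))

    from .io import write_path_table

    write_path_table(final, out_paths)
    if out_gaf is not None:
        with open(out_gaf, "w") as fh:
            for p in final:
                fh.write(f"{p.name}\t{p.render_walk()}\t{p.assignment}\n")
    return final


# ---------------------------------------------------------------------------
# rDNA patching

def rdna_patch(
    state: CurationState,
    gap_id: str,
    morph_id: str,
    copies: int = 2,
    gap_len: int = DEFAULT_GAP_LEN,
) -> CurationState:
    """Replace a user-designated rDNA gap with [gap, morph x copies, gap].

    The conservative form keeps flanking gaps around the model rDNA
    units, preserving chromosome-specific unit information without
    asserting an exact traversal.
    """
    gap = state.gap_by_id(gap_id)
    if gap.status != "OPEN":
        raise ValueError(f"gap {gap_id} is {gap.status}, not OPEN")
    if morph_id not in state.graph:
        raise KeyError(f"rDNA morph node {morph_id!r} not registered in graph")
    if copies < 1:
        raise ValueError("copies must be >= 1")
    path = state.path_by_name(gap.contig)
    replacement = (
        [PathStep.gap(gap_len)]
        + [PathStep.node(morph_id, "+") for _ in range(copies)]
        + [PathStep.gap(gap_len)]
    )
    path.steps[gap.step_index: gap.step_index + 1] = replacement
    _shift_gap_indices(state, gap.contig, gap.step_index, len(replacement) - 1)
    gap.status = "FILLED"
    gap.fill_steps = None
    state.log(
        "rdna_patch",
        {"gap_id": gap_id, "morph": morph_id, "copies": copies, "gap_len": gap_len},
        gap_id=gap_id,
    )
    return state


# ---------------------------------------------------------------------------
# event sourcing

def replay_history(state: CurationState, history: Sequence) -> CurationState:
    """Re-apply a recorded edit history to a (fresh) initial state.

    Only mutating operations are dispatched; the state passed in is
    modified in place and returned.
    """
    for entry in history:
        op, p = entry.operation, entry.parameters
        if op == "find_gaps":
            register_gaps(state)
        elif op == "fill_gap":
            fill_gap(state, p["gap_id"], p["fill"], force=p.get("force", False))
        elif op == "delete_gap":
            delete_gap(state, p["gap_id"])
        elif op == "connect_contigs":
            connect_contigs(state, p["source"], p["target"], p["at"], p["flip"])
        elif op == "mark_keep_contigs":
            mark_keep_contigs(state, p["contigs"])
        elif op == "mark_connection_endpoints":
            mark_connection_endpoints(state)
        elif op == "nodes_in_unresolved_gaps":
            nodes_in_unresolved_gaps(state, mode=p.get("mode", "intersection"))
        elif op == "rdna_patch":
            rdna_patch(state, p["gap_id"], p["morph"], p["copies"], p["gap_len"])
        elif op == "register_patch_node":
            patch = PatchNode(
                p["id"], p["sequence"],
                (tuple(p["joins"][0]), tuple(p["joins"][1])), p["support"],
            )
            register_patch_node(state, patch)
        elif op == "read_bundle":
            pass  # initial load; the caller supplies the loaded state
        else:
            raise ValueError(f"cannot replay unknown operation {op!r}")
    return state
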