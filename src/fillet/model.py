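"""Core data model for assembly-graph curation.

The central object is :class:`CurationState`, which bundles the assembly
graph, the haplotype path table, the gap register, long-read graph
alignments, per-contig statistics and an append-only edit history into a
single entity that can be saved, restored and replayed.

Coordinates are 0-based, half-open everywhere in memory; any 1-based
presentation happens only at rendering time.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from typing import Callable, Iterable, Iterator, Optional

import pandas as pd

__all__ = [
    "NodeRecord",
    "EdgeRecord",
    "PathStep",
    "ContigPath",
    "GafRecord",
    "GapRecord",
    "HistoryEntry",
    "AssemblyGraph",
    "CurationState",
    "flip_orient",
    "default_clock",
]

DEFAULT_GAP_LEN = 1000

#: retention marks used on paths / nodes
KEEP_CONTIG = "keep_contig"
KEEP_UNRESOLVED = "keep_Nodes_in_unresolved_gaps"
DROP = "drop"


def flip_orient(orient: str) -> str:
    """Reverse an orientation sign ('+' <-> '-')."""
    if orient == "+":
        return "-"
    if orient == "-":
        return "+"
    raise ValueError(f"invalid orientation {orient!r}")


def default_clock() -> str:
    return datetime.now(timezone.utc).isoformat(timespec="seconds")


@dataclass
class NodeRecord:
    """A graph node: one homopolymer-compressed sequence segment.

    ``mat_markers``/``pat_markers`` hold haplotype-specific k-mer counts
    (trio markers) when phasing data exist; ``depth`` is reads-per-kilobase
    coverage from graph alignments.
    """

    id: str
    length_hpc: int
    sequence: Optional[str] = None
    depth: Optional[float] = None
    mat_markers: Optional[int] = None
    pat_markers: Optional[int] = None

    def __post_init__(self) -> None:
        if self.length_hpc < 0:
            raise ValueError(f"node {self.id}: negative length")
        if self.sequence is not None and len(self.sequence) != self.length_hpc:
            raise ValueError(
                f"node {self.id}: length_hpc {self.length_hpc} != sequence "
                f"length {len(self.sequence)}"
            )
        if self.depth is not None and self.depth < 0:
            raise ValueError(f"node {self.id}: negative depth")


@dataclass(frozen=True)
class EdgeRecord:
    """An oriented link between two nodes.

    An edge and its reverse-complement flip denote the same adjacency;
    :meth:`canonical` picks a stable representative of the pair.
    """

    from_id: str
    from_orient: str
    to_id: str
    to_orient: str
    overlap_bases: int = 0

    def flipped(self) -> "EdgeRecord":
        return EdgeRecord(
            self.to_id,
            flip_orient(self.to_orient),
            self.from_id,
            flip_orient(self.from_orient),
            self.overlap_bases,
        )

    def canonical(self) -> "EdgeRecord":
        other = self.flipped()
        a = (self.from_id, self.from_orient, self.to_id, self.to_orient)
        b = (other.from_id, other.from_orient, other.to_id, other.to_orient)
        return self if a <= b else other


@dataclass(frozen=True)
class PathStep:
    """One step of a contig path: an oriented node or a gap estimate."""

    kind: str  # "node" | "gap"
    node_id: Optional[str] = None
    orient: Optional[str] = None
    gap_len: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind == "node":
            if not self.node_id or self.orient not in ("+", "-"):
                raise ValueError("node step needs node_id and orient")
            if self.gap_len is not None:
                raise ValueError("node step must not carry gap_len")
        elif self.kind == "gap":
            if self.node_id is not None or self.orient is not None:
                raise ValueError("gap step must not carry node fields")
            if self.gap_len is not None and self.gap_len <= 0:
                raise ValueError("gap_len must be positive")
        else:
            raise ValueError(f"unknown step kind {self.kind!r}")

    @staticmethod
    def node(node_id: str, orient: str) -> "PathStep":
        return PathStep("node", node_id=node_id, orient=orient)

    @staticmethod
    def gap(gap_len: Optional[int] = None) -> "PathStep":
        return PathStep("gap", gap_len=gap_len)

    @property
    def is_gap(self) -> bool:
        return self.kind == "gap"

    def flipped(self) -> "PathStep":
        if self.is_gap:
            return self
        return PathStep.node(self.node_id, flip_orient(self.orient))

    def render(self) -> str:
        if self.is_gap:
            return f"[N{self.gap_len if self.gap_len else DEFAULT_GAP_LEN}N]"
        return f"{self.node_id}{self.orient}"


@dataclass
class ContigPath:
    """A named ordered walk through the graph, with gap placeholders."""

    name: str
    steps: list[PathStep]
    assignment: str = "NONE"
    retain_flag: Optional[str] = None

    def node_steps(self) -> list[PathStep]:
        return [s for s in self.steps if not s.is_gap]

    def node_ids(self) -> list[str]:
        return [s.node_id for s in self.steps if not s.is_gap]

    def gap_indices(self) -> list[int]:
        return [i for i, s in enumerate(self.steps) if s.is_gap]

    def render(self) -> str:
        return ",".join(s.render() for s in self.steps)

    def render_walk(self) -> str:
        """Render in GAF walk notation (``>``/``<`` prefixes)."""
        out = []
        for s in self.steps:
            if s.is_gap:
                out.append(s.render())
            else:
                out.append((">" if s.orient == "+" else "<") + s.node_id)
        return "".join(out)

    def validate(self) -> None:
        for a, b in itertools.pairwise(self.steps):
            if a.is_gap and b.is_gap:
                raise ValueError(f"path {self.name}: consecutive gap steps")


@dataclass
class GafRecord:
    """One long-read alignment to a walk in the graph."""

    read_name: str
    read_len: int
    read_start: int
    read_end: int
    strand: str
    walk: list[PathStep]  # node steps only
    path_len: int
    path_start: int
    path_end: int
    matches: int
    block_len: int
    mapq: int

    def check(self) -> None:
        if not (0 <= self.read_start <= self.read_end <= self.read_len):
            raise ValueError(f"{self.read_name}: bad read interval")
        if self.matches > self.block_len:
            raise ValueError(f"{self.read_name}: matches > block_len")
        if not self.walk:
            raise ValueError(f"{self.read_name}: empty walk")

    def is_valid(self) -> bool:
        try:
            self.check()
        except ValueError:
            return False
        return True


@dataclass
class GapRecord:
    """One gap: either an open/filled path gap or a contig connection."""

    gap_id: str
    contig: str
    step_index: int
    left_flank: Optional[PathStep]
    right_flank: Optional[PathStep]
    haplotype: str = "NONE"
    status: str = "OPEN"  # OPEN | FILLED | DELETED | CONNECTION
    fill_steps: Optional[list[PathStep]] = None
    original_gap: Optional[PathStep] = None
    terminal: bool = False
    # CONNECTION bookkeeping
    source: Optional[str] = None
    target: Optional[str] = None
    at: Optional[str] = None  # left | right
    flip: bool = False


@dataclass
class HistoryEntry:
    seq_no: int
    timestamp: str
    operation: str
    parameters: dict
    gap_id: Optional[str] = None


class AssemblyGraph:
    """Nodes plus the canonical edge set of a GFA v1 graph."""

    def __init__(self) -> None:
        self.nodes: dict[str, NodeRecord] = {}
        self._edges: dict[tuple, EdgeRecord] = {}

    # -- nodes ---------------------------------------------------------
    def add_node(self, node: NodeRecord) -> None:
        self.nodes[node.id] = node

    def __contains__(self, node_id: str) -> bool:
        return node_id in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    # -- edges ---------------------------------------------------------
    def add_edge(self, edge: EdgeRecord, validate: bool = True) -> None:
        if validate:
            for nid in (edge.from_id, edge.to_id):
                if nid not in self.nodes:
                    raise KeyError(f"edge references unknown segment {nid!r}")
        canon = edge.canonical()
        key = (canon.from_id, canon.from_orient, canon.to_id, canon.to_orient)
        self._edges[key] = canon

    @property
    def edges(self) -> list[EdgeRecord]:
        return list(self._edges.values())

    def n_edges(self) -> int:
        return len(self._edges)

    def oriented_arcs(self) -> Iterator[tuple[tuple[str, str], tuple[str, str]]]:
        """Yield directed arcs over oriented nodes, both traversal senses."""
        for e in self._edges.values():
            yield (e.from_id, e.from_orient), (e.to_id, e.to_orient)
            f = e.flipped()
            yield (f.from_id, f.from_orient), (f.to_id, f.to_orient)

    def copy(self) -> "AssemblyGraph":
        g = AssemblyGraph()
        g.nodes = {k: replace(v) for k, v in self.nodes.items()}
        g._edges = dict(self._edges)
        return g


EMPTY_STATS_COLUMNS = [
    "contig",
    "length",
    "telo_p",
    "telo_q",
    "gaps",
    "chromosome",
    "haplotype",
    "t2t_class",
]


def empty_stats() -> pd.DataFrame:
    return pd.DataFrame(columns=EMPTY_STATS_COLUMNS)


class CurationState:
    """Everything the curation session needs, in one saveable object.

    Mutating operations append to ``history``; the history is append-only
    and replaying it against the initial state reproduces the final state
    (see :func:`fillet.editing.replay_history`).
    """

    def __init__(self, clock: Callable[[], str] = default_clock) -> None:
        self.graph = AssemblyGraph()
        self.paths: list[ContigPath] = []
        self.gaps: list[GapRecord] = []
        self.gaf: list[GafRecord] = []
        self.stats: pd.DataFrame = empty_stats()
        self.history: list[HistoryEntry] = []
        self.scfmap: dict[str, str] = {}
        self.keep_nodes: set[str] = set()
        self.clock = clock

    # -- bookkeeping ---------------------------------------------------
    def log(self, operation: str, parameters: Optional[dict] = None,
            gap_id: Optional[str] = None) -> HistoryEntry:
        entry = HistoryEntry(
            seq_no=len(self.history) + 1,
            timestamp=self.clock(),
            operation=operation,
            parameters=dict(parameters or {}),
            gap_id=gap_id,
        )
        self.history.append(entry)
        return entry

    def path_by_name(self, name: str) -> ContigPath:
        for p in self.paths:
            if p.name == name:
                return p
        raise KeyError(f"no path named {name!r}")

    def has_path(self, name: str) -> bool:
        return any(p.name == name for p in self.paths)

    def gap_by_id(self, gap_id: str) -> GapRecord:
        for g in self.gaps:
            if g.gap_id == gap_id:
                return g
        raise KeyError(f"no gap with id {gap_id!r}")

    def open_gaps(self) -> list[GapRecord]:
        return [g for g in self.gaps if g.status == "OPEN"]

    def connections(self) -> list[GapRecord]:
        return [g for g in self.gaps if g.status == "CONNECTION"]
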