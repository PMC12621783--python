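"""Readers and writers for the assembly bundle formats.

Covers GFA v1 (S/L lines), the rukki/Verkko path table (TSV of name,
path, assignment), GAF graph alignments, PAF whole-genome alignments,
BED intervals, the scfmap contig/path name mapping, FASTA, and JSON
persistence of the whole :class:`~fillet.model.CurationState`.

All readers normalise to the in-memory model (0-based half-open
coordinates, ``+``/``-`` suffix orientation); writers render the
normalised form, so read-write-read is the identity.
"""

from __future__ import annotations

import json
import re
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    DEFAULT_GAP_LEN,
    AssemblyGraph,
    ContigPath,
    CurationState,
    EdgeRecord,
    GafRecord,
    GapRecord,
    HistoryEntry,
    NodeRecord,
    PathStep,
    empty_stats,
)

STATE_FORMAT = "fillet-state-1"

__all__ = [
    "parse_path_string",
    "render_path_steps",
    "read_gfa",
    "write_gfa",
    "gfa_nodes_to_fasta",
    "read_path_table",
    "write_path_table",
    "read_gaf",
    "write_gaf",
    "read_paf",
    "write_paf",
    "read_bed",
    "write_bed",
    "read_scfmap",
    "read_fasta",
    "write_fasta",
    "read_bundle",
    "save_state",
    "load_state",
]


# ---------------------------------------------------------------------------
# path strings

_GAP_RE = re.compile(r"\[(?:gap|N(\d+)N|N\.\.\.N)\]$")
_NODE_SUFFIX_RE = re.compile(r"^(.+?)([+-])$")
_WALK_TOKEN_RE = re.compile(r"([><])([^><,\[\]]+)")


def parse_path_string(text: str, default_gap_len: int = DEFAULT_GAP_LEN) -> list[PathStep]:
    """Parse a path cell into steps.

    Two orientation dialects are accepted: the suffix form
    (``utig4-1+,utig4-2-``) and the walk form (``>utig4-1<utig4-2``);
    gap tokens may be ``[gap]``, ``[N1000N]`` or ``[N...N]``.
    """
    steps: list[PathStep] = []
    for token in text.strip().split(","):
        token = token.strip()
        if not token:
            continue
        m = _GAP_RE.match(token)
        if m and token.startswith("["):
            k = int(m.group(1)) if m.group(1) else default_gap_len
            steps.append(PathStep.gap(k))
            continue
        if token[0] in "><":
            walk = _WALK_TOKEN_RE.findall(token)
            consumed = "".join(sign + name for sign, name in walk)
            if not walk or consumed != token:
                raise ValueError(f"unparseable path token {token!r}")
            for sign, name in walk:
                steps.append(PathStep.node(name, "+" if sign == ">" else "-"))
            continue
        m = _NODE_SUFFIX_RE.match(token)
        if m:
            steps.append(PathStep.node(m.group(1), m.group(2)))
            continue
        raise ValueError(f"unparseable path token {token!r}")
    return steps


def render_path_steps(steps: Sequence[PathStep]) -> str:
    """Render steps in the normalised suffix dialect."""
    return ",".join(s.render() for s in steps)


# ---------------------------------------------------------------------------
# GFA

def read_gfa(path: str | Path) -> AssemblyGraph:
    graph = AssemblyGraph()
    pending_edges: list[tuple[int, EdgeRecord]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            tag = fields[0]
            if tag == "S":
                if len(fields) < 3:
                    raise ValueError(f"{path}:{lineno}: malformed S line")
                name, seq = fields[1], fields[2]
                tags = _parse_tags(fields[3:])
                if seq == "*":
                    length = tags.get("LN")
                    if length is None:
                        raise ValueError(
                            f"{path}:{lineno}: S line without sequence needs LN tag"
                        )
                    graph.add_node(NodeRecord(name, int(length)))
                else:
                    graph.add_node(NodeRecord(name, len(seq), sequence=seq))
            elif tag == "L":
                if len(fields) < 6:
                    raise ValueError(f"{path}:{lineno}: malformed L line")
                overlap = _parse_overlap(fields[5], path, lineno)
                pending_edges.append(
                    (lineno, EdgeRecord(fields[1], fields[2], fields[3], fields[4], overlap))
                )
    for lineno, edge in pending_edges:
        for nid in (edge.from_id, edge.to_id):
            if nid not in graph:
                raise ValueError(
                    f"{path}:{lineno}: L line references unknown segment {nid!r}"
                )
        graph.add_edge(edge)
    return graph


def _parse_tags(fields: Iterable[str]) -> dict:
    tags = {}
    for f in fields:
        parts = f.split(":", 2)
        if len(parts) == 3:
            name, typ, value = parts
            tags[name] = int(value) if typ == "i" else value
    return tags


def _parse_overlap(field: str, path, lineno: int) -> int:
    if field == "*":
        return 0
    m = re.fullmatch(r"(\d+)M", field)
    if not m:
        raise ValueError(f"{path}:{lineno}: unsupported overlap CIGAR {field!r}")
    return int(m.group(1))


def write_gfa(graph: AssemblyGraph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(graph.nodes):
            node = graph.nodes[name]
            if node.sequence is not None:
                fh.write(f"S\t{name}\t{node.sequence}\n")
            else:
                fh.write(f"S\t{name}\t*\tLN:i:{node.length_hpc}\n")
        edges = sorted(
            graph.edges,
            key=lambda e: (e.from_id, e.from_orient, e.to_id, e.to_orient),
        )
        for e in edges:
            overlap = f"{e.overlap_bases}M" if e.overlap_bases else "0M"
            fh.write(
                f"L\t{e.from_id}\t{e.from_orient}\t{e.to_id}\t{e.to_orient}\t{overlap}\n"
            )


def gfa_nodes_to_fasta(graph: AssemblyGraph) -> tuple[list[SeqRecord], int]:
    """Export node sequences as FASTA records.

    Nodes without a stored sequence are skipped; the second return value
    counts the skips so they are never silently lost.
    """
    records, skipped = [], 0
    for name in sorted(graph.nodes):
        node = graph.nodes[name]
        if node.sequence is None:
            skipped += 1
            continue
        records.append(SeqRecord(Seq(node.sequence), id=name, description=""))
    return records, skipped


# ---------------------------------------------------------------------------
# path table

def read_path_table(path: str | Path) -> list[ContigPath]:
    paths: list[ContigPath] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[:2] == ["name", "path"]:
                continue
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(fields)}")
            try:
                steps = parse_path_string(fields[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            p = ContigPath(fields[0], steps, fields[2])
            p.validate()
            paths.append(p)
    names = [p.name for p in paths]
    if len(names) != len(set(names)):
        raise ValueError(f"{path}: duplicate path names")
    return paths


def write_path_table(paths: Sequence[ContigPath], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tpath\tassignment\n")
        for p in paths:
            fh.write(f"{p.name}\t{p.render()}\t{p.assignment}\n")


# ---------------------------------------------------------------------------
# GAF

def read_gaf(path: str | Path) -> tuple[list[GafRecord], int]:
    """Read a GAF file; invariant-violating records are dropped and counted."""
    records: list[GafRecord] = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(f"{path}:{lineno}: expected >=12 columns")
            walk = [s for s in parse_path_string(fields[5]) if not s.is_gap]
            rec = GafRecord(
                read_name=fields[0],
                read_len=int(fields[1]),
                read_start=int(fields[2]),
                read_end=int(fields[3]),
                strand=fields[4],
                walk=walk,
                path_len=int(fields[6]),
                path_start=int(fields[7]),
                path_end=int(fields[8]),
                matches=int(fields[9]),
                block_len=int(fields[10]),
                mapq=int(fields[11]),
            )
            if rec.is_valid():
                records.append(rec)
            else:
                dropped += 1
    return records, dropped


def write_gaf(records: Sequence[GafRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            walk = "".join(
                (">" if s.orient == "+" else "<") + s.node_id for s in r.walk
            )
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        r.read_name, r.read_len, r.read_start, r.read_end,
                        r.strand, walk, r.path_len, r.path_start, r.path_end,
                        r.matches, r.block_len, r.mapq,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# PAF (mashmap/minimap2 style whole-genome alignments)

def read_paf(path: str | Path) -> list["AlignmentBlock"]:
    from .qc import AlignmentBlock

    blocks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: expected >=12 columns")
            identity = None
            for tag in f[12:]:
                if tag.startswith("id:f:"):
                    identity = float(tag[5:])
            matches, block = int(f[9]), int(f[10])
            if identity is None:
                identity = 100.0 * matches / block if block else 0.0
            blocks.append(
                AlignmentBlock(
                    query=f[0], qlen=int(f[1]), qstart=int(f[2]), qend=int(f[3]),
                    strand=f[4], target=f[5], tlen=int(f[6]), tstart=int(f[7]),
                    tend=int(f[8]), identity_pct=identity,
                )
            )
    return blocks


def write_paf(blocks: Sequence["AlignmentBlock"], path: str | Path) -> None:
    with open(path, "w") as fh:
        for b in blocks:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        b.query, b.qlen, b.qstart, b.qend, b.strand,
                        b.target, b.tlen, b.tstart, b.tend,
                        b.block_len, b.block_len, 60,
                    )
                )
                + f"\tid:f:{b.identity_pct:g}\n"
            )


# ---------------------------------------------------------------------------
# BED / scfmap / FASTA

def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]), int(f[2])))
    return out


def write_bed(intervals: Iterable[tuple], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write("\t".join(str(x) for x in iv) + "\n")


def read_scfmap(path: str | Path) -> dict[str, str]:
    """Read the contig-name to path-name mapping (two-column text).

    Extra columns are tolerated but reported via a ValueError only when
    the first two are unusable.
    """
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            mapping[fields[0]] = fields[1]
    return mapping


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str] | Sequence[SeqRecord], path: str | Path) -> None:
    if isinstance(seqs, dict):
        records = [SeqRecord(Seq(s), id=n, description="") for n, s in seqs.items()]
    else:
        records = list(seqs)
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# bundle

def read_bundle(directory: str | Path, clock=None) -> CurationState:
    """Build a curation state from an assembly output directory.

    The directory must contain a GFA graph and a path TSV; a GAF, a
    consensus FASTA and a scfmap are picked up when present.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"not a directory: {directory}")

    gfa = _find_one(directory, ["*.gfa"], "assembly graph (.gfa)")
    tsv = _find_one(directory, ["*paths*.tsv", "*.paths.tsv", "*.tsv"], "path table (.tsv)")

    state = CurationState(**({"clock": clock} if clock else {}))
    state.graph = read_gfa(gfa)
    state.paths = read_path_table(tsv)

    gafs = sorted(directory.glob("*.gaf"))
    if gafs:
        state.gaf, _ = read_gaf(gafs[0])
    scfmaps = sorted(directory.glob("*.scfmap"))
    if scfmaps:
        state.scfmap = read_scfmap(scfmaps[0])
    state.log("read_bundle", {"directory": str(directory)})
    return state


def _find_one(directory: Path, patterns: list[str], what: str) -> Path:
    for pat in patterns:
        hits = sorted(directory.glob(pat))
        if hits:
            return hits[0]
    raise FileNotFoundError(f"{directory}: missing required {what}")


# ---------------------------------------------------------------------------
# state persistence

def save_state(state: CurationState, path: str | Path) -> None:
    doc = {
        "format": STATE_FORMAT,
        "nodes": [
            {
                "id": n.id, "length_hpc": n.length_hpc, "sequence": n.sequence,
                "depth": n.depth, "mat_markers": n.mat_markers,
                "pat_markers": n.pat_markers,
            }
            for n in state.graph.nodes.values()
        ],
        "edges": [asdict(e) for e in state.graph.edges],
        "paths": [
            {
                "name": p.name, "path": p.render(), "assignment": p.assignment,
                "retain_flag": p.retain_flag,
            }
            for p in state.paths
        ],
        "gaps": [_gap_to_doc(g) for g in state.gaps],
        "gaf": [
            {
                "read_name": r.read_name, "read_len": r.read_len,
                "read_start": r.read_start, "read_end": r.read_end,
                "strand": r.strand,
                "walk": render_path_steps(r.walk),
                "path_len": r.path_len, "path_start": r.path_start,
                "path_end": r.path_end, "matches": r.matches,
                "block_len": r.block_len, "mapq": r.mapq,
            }
            for r in state.gaf
        ],
        "stats": state.stats.to_dict(orient="list"),
        "scfmap": state.scfmap,
        "keep_nodes": sorted(state.keep_nodes),
        "history": [asdict(h) for h in state.history],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def _gap_to_doc(g: GapRecord) -> dict:
    return {
        "gap_id": g.gap_id, "contig": g.contig, "step_index": g.step_index,
        "left_flank": g.left_flank.render() if g.left_flank else None,
        "right_flank": g.right_flank.render() if g.right_flank else None,
        "haplotype": g.haplotype, "status": g.status,
        "fill_steps": render_path_steps(g.fill_steps) if g.fill_steps else None,
        "original_gap": g.original_gap.render() if g.original_gap else None,
        "terminal": g.terminal, "source": g.source, "target": g.target,
        "at": g.at, "flip": g.flip,
    }


def _gap_from_doc(d: dict) -> GapRecord:
    def step(text):
        return parse_path_string(text)[0] if text else None

    return GapRecord(
        gap_id=d["gap_id"], contig=d["contig"], step_index=d["step_index"],
        left_flank=step(d["left_flank"]), right_flank=step(d["right_flank"]),
        haplotype=d["haplotype"], status=d["status"],
        fill_steps=parse_path_string(d["fill_steps"]) if d["fill_steps"] else None,
        original_gap=step(d["original_gap"]), terminal=d["terminal"],
        source=d["source"], target=d["target"], at=d["at"], flip=d["flip"],
    )


def load_state(path: str | Path, clock=None) -> CurationState:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != STATE_FORMAT:
        raise ValueError(
            f"state format mismatch: file has {doc.get('format')!r}, "
            f"this build reads {STATE_FORMAT!r}"
        )
    state = CurationState(**({"clock": clock} if clock else {}))
    for nd in doc["nodes"]:
        state.graph.add_node(NodeRecord(**nd))
    for ed in doc["edges"]:
        state.graph.add_edge(EdgeRecord(**ed))
    for pd_ in doc["paths"]:
        p = ContigPath(pd_["name"], parse_path_string(pd_["path"]), pd_["assignment"])
        p.retain_flag = pd_["retain_flag"]
        state.paths.append(p)
    state.gaps = [_gap_from_doc(d) for d in doc["gaps"]]
    state.gaf = [
        GafRecord(
            read_name=r["read_name"], read_len=r["read_len"],
            read_start=r["read_start"], read_end=r["read_end"],
            strand=r["strand"],
            walk=[s for s in parse_path_string(r["walk"]) if not s.is_gap],
            path_len=r["path_len"], path_start=r["path_start"],
            path_end=r["path_end"], matches=r["matches"],
            block_len=r["block_len"], mapq=r["mapq"],
        )
        for r in doc["gaf"]
    ]
    stats = pd.DataFrame(doc["stats"])
    state.stats = stats if not stats.empty else empty_stats()
    state.scfmap = dict(doc["scfmap"])
    state.keep_nodes = set(doc["keep_nodes"])
    state.history = [HistoryEntry(**h) for h in doc["history"]]
    return state
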