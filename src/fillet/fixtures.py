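"""Synthetic, ground-truthed assembly fixtures.

Generates diploid assembly graphs (homozygous backbones, heterozygous
bubbles, repeat loops with per-haplotype copy numbers, deliberately
missing edges and orphan telomere nodes), matching path tables with gap
tokens, simulated long-read graph alignments, contig sequences with
planted telomere arrays and N runs, and whole-genome alignment tables —
everything needed to exercise the curation workflow without external
data, with the intended answer recorded alongside.

Everything is deterministic under the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .model import (
    AssemblyGraph,
    ContigPath,
    CurationState,
    EdgeRecord,
    GafRecord,
    NodeRecord,
    PathStep,
)
from .qc import AlignmentBlock

__all__ = [
    "PlannedGap",
    "FixtureTruth",
    "make_diploid_graph",
    "simulate_read_walks",
    "make_sequences",
    "make_alignment_table",
    "make_curation_scenario",
    "render_contig_sequences",
    "write_fixture_bundle",
]

TELO_MOTIF = "CCCTAA"
TELO_ARRAY_COPIES = 1200  # 7.2 kb of motif at planted telomere ends

# base composition of random sequence: GC fraction 0.42
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_P = np.array([0.29, 0.21, 0.21, 0.29])


@dataclass
class PlannedGap:
    """One deliberately planted gap and its intended resolution."""

    contig: str
    kind: str  # bubble | loop | missing_edge
    left: str  # rendered oriented flank, e.g. "chr1B0+"
    right: str
    fill: str  # rendered intended fill, flanks included ("" if via patch)
    n_reads: int  # planned spanning-read support
    repeat_node: Optional[str] = None
    copies: Optional[int] = None


@dataclass
class FixtureTruth:
    seed: int
    n_nodes: int = 0
    n_edges: int = 0
    n_paths: int = 0
    node_chrom: dict = field(default_factory=dict)
    node_len: dict = field(default_factory=dict)
    gaps: list = field(default_factory=list)
    true_paths: dict = field(default_factory=dict)  # contig -> rendered gapless path
    orphans: dict = field(default_factory=dict)  # orphan path -> main contig
    expected_class: dict = field(default_factory=dict)  # contig -> T2T class
    expected_multi_used: list = field(default_factory=list)
    features: dict = field(default_factory=dict)  # planted sequence features

    def gap_for(self, contig: str, kind: Optional[str] = None) -> PlannedGap:
        for g in self.gaps:
            if g.contig == contig and (kind is None or g.kind == kind):
                return g
        raise KeyError(f"no planned gap on {contig}")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n, p=_BASE_P).tobytes().decode()


def _node_len(rng: np.random.Generator, lo: int = 5_000, hi: int = 200_000) -> int:
    # log-uniform: small nodes common, occasional long ones
    return int(np.exp(rng.uniform(np.log(lo), np.log(hi))))


# ---------------------------------------------------------------------------
# graph generator

def make_diploid_graph(
    seed: int = 1,
    n_chrom: int = 1,
    bubbles_per_chrom: int = 2,
    loop_specs: Optional[dict] = None,
    missing_edge_specs: Optional[Sequence[tuple]] = None,
    gap_specs: Optional[Sequence[tuple]] = None,
    orphan_specs: Optional[Sequence[tuple]] = None,
    read_support: Optional[dict] = None,
    node_len_range: tuple[int, int] = (5_000, 200_000),
) -> tuple[AssemblyGraph, list[ContigPath], FixtureTruth]:
    """Build a diploid graph with two haplotype paths per chromosome.

    Layout per chromosome: a haplotype-specific telomere node at each
    end, homozygous backbone nodes shared by both haplotypes, and one
    heterozygous bubble between consecutive backbone nodes.  Optional
    features, all recorded in the returned truth:

    - ``loop_specs``: {chrom_index: (mat_copies, pat_copies)} — a shared
      repeat node with a self-loop between haplotype-specific flanks;
      both haplotype paths carry a gap there instead of the loop.
    - ``gap_specs``: [(chrom_index, hap, bubble_index)] — the bubble arm
      is replaced by a gap token in that haplotype's path.
    - ``missing_edge_specs``: [(chrom_index, hap, bubble_index)] — the
      bubble arm and its edges are absent from the graph entirely; the
      path carries a gap no graph walk can close (split-read territory).
    - ``orphan_specs``: [(chrom_index, hap)] — the 3' telomere node is
      disconnected and emitted as its own single-node path; the main
      path ends without a telomere.
    - ``read_support``: {(chrom_index, hap): n} spanning reads planned
      for that haplotype's planted gap (default 10, loops use it too).
    """
    rng = np.random.default_rng(seed)
    loop_specs = loop_specs or {}
    gap_specs = set(gap_specs or [])
    missing_edge_specs = set(missing_edge_specs or [])
    orphan_specs = set(orphan_specs or [])
    read_support = read_support or {}

    graph = AssemblyGraph()
    paths: list[ContigPath] = []
    truth = FixtureTruth(seed=seed)
    lo, hi = node_len_range

    def new_node(name: str, chrom: str, telo: Optional[str] = None) -> str:
        length = _node_len(rng, lo, hi)
        if telo:  # telomere nodes must hold the full array plus flank
            length = max(length, 3 * TELO_ARRAY_COPIES * len(TELO_MOTIF))
        seq = _random_seq(rng, length)
        if telo == "p":
            arr = TELO_MOTIF * TELO_ARRAY_COPIES
            seq = arr + seq[len(arr):]
        elif telo == "q":
            arr = "TTAGGG" * TELO_ARRAY_COPIES
            seq = seq[: len(seq) - len(arr)] + arr
        graph.add_node(NodeRecord(name, len(seq), sequence=seq))
        truth.node_chrom[name] = chrom
        truth.node_len[name] = len(seq)
        return name

    for c in range(1, n_chrom + 1):
        chrom = f"chr{c}"
        backbone = [new_node(f"{chrom}B{i}", chrom) for i in range(bubbles_per_chrom + 1)]
        telo5 = {h: new_node(f"{chrom}T5{h}", chrom, telo="p") for h in ("m", "p")}
        telo3 = {h: new_node(f"{chrom}T3{h}", chrom, telo="q") for h in ("m", "p")}
        arms: dict[tuple, Optional[str]] = {}
        for i in range(bubbles_per_chrom):
            for h in ("m", "p"):
                hap = "mat" if h == "m" else "pat"
                if (c, hap, i) in missing_edge_specs:
                    arms[(i, h)] = None
                    continue
                arms[(i, h)] = new_node(f"{chrom}A{i}{h}", chrom)

        loop = loop_specs.get(c)
        loop_nodes = {}
        if loop:
            loop_nodes = {
                "fm": new_node(f"{chrom}LFm", chrom),
                "fp": new_node(f"{chrom}LFp", chrom),
                "r": new_node(f"{chrom}R", chrom),
                "gm": new_node(f"{chrom}LGm", chrom),
                "gp": new_node(f"{chrom}LGp", chrom),
            }

        for h, hap, assign in (("m", "mat", "MATERNAL"), ("p", "pat", "PATERNAL")):
            contig = f"{chrom}_{hap}"
            arm_orient = "+" if h == "m" else "-"
            steps: list[PathStep] = [PathStep.node(telo5[h], "+")]
            true_steps: list[PathStep] = [PathStep.node(telo5[h], "+")]
            graph.add_edge(EdgeRecord(telo5[h], "+", backbone[0], "+"))
            steps.append(PathStep.node(backbone[0], "+"))
            true_steps.append(PathStep.node(backbone[0], "+"))
            for i in range(bubbles_per_chrom):
                arm = arms[(i, h)]
                left = PathStep.node(backbone[i], "+")
                right = PathStep.node(backbone[i + 1], "+")
                if arm is None:  # missing edge: no arm, no traversal
                    steps.append(PathStep.gap())
                    truth.gaps.append(
                        PlannedGap(contig, "missing_edge", left.render(),
                                   right.render(), "",
                                   read_support.get((c, hap), 10)))
                    true_steps.append(right)
                    steps.append(right)
                    continue
                arm_step = PathStep.node(arm, arm_orient)
                graph.add_edge(EdgeRecord(backbone[i], "+", arm, arm_orient))
                graph.add_edge(EdgeRecord(arm, arm_orient, backbone[i + 1], "+"))
                if (c, hap, i) in gap_specs:
                    steps.append(PathStep.gap())
                    truth.gaps.append(
                        PlannedGap(
                            contig, "bubble", left.render(), right.render(),
                            ",".join(s.render() for s in (left, arm_step, right)),
                            read_support.get((c, hap), 10)))
                else:
                    steps.append(arm_step)
                true_steps.append(arm_step)
                steps.append(right)
                true_steps.append(right)

            if loop:
                f, g, r = loop_nodes["f" + h], loop_nodes["g" + h], loop_nodes["r"]
                copies = loop[0 if h == "m" else 1]
                graph.add_edge(EdgeRecord(backbone[-1], "+", f, "+"))
                graph.add_edge(EdgeRecord(f, "+", r, "+"))
                graph.add_edge(EdgeRecord(r, "+", r, "+"))
                graph.add_edge(EdgeRecord(r, "+", g, "+"))
                fill = [PathStep.node(f, "+")] + \
                    [PathStep.node(r, "+")] * copies + [PathStep.node(g, "+")]
                steps += [PathStep.node(f, "+"), PathStep.gap(), PathStep.node(g, "+")]
                true_steps += fill
                truth.gaps.append(
                    PlannedGap(contig, "loop", f + "+", g + "+",
                               ",".join(s.render() for s in fill),
                               read_support.get((c, hap), 10),
                               repeat_node=r, copies=copies))
                last = g
            else:
                last = backbone[-1]

            if (c, hap) in orphan_specs:
                orphan_name = f"{contig}_orphan"
                paths.append(
                    ContigPath(orphan_name, [PathStep.node(telo3[h], "+")], assign)
                )
                truth.orphans[orphan_name] = contig
                truth.true_paths[orphan_name] = telo3[h] + "+"
                truth.expected_class[contig] = "T2T_SCAFFOLD"
            else:
                graph.add_edge(EdgeRecord(last, "+", telo3[h], "+"))
                steps.append(PathStep.node(telo3[h], "+"))
                true_steps.append(PathStep.node(telo3[h], "+"))
                truth.expected_class[contig] = "T2T_CONTIG"

            paths.append(ContigPath(contig, steps, assign))
            truth.true_paths[contig] = ",".join(s.render() for s in true_steps)

    truth.n_nodes = len(graph)
    truth.n_edges = graph.n_edges()
    truth.n_paths = len(paths)
    return graph, paths, truth


# ---------------------------------------------------------------------------
# read simulation

def simulate_read_walks(
    graph: AssemblyGraph,
    truth: FixtureTruth,
    n_reads_per_gap: Optional[int] = None,
    read_len_range: tuple[int, int] = (20_000, 60_000),
    mapq: int = 60,
    n_noise: int = 10,
    seed: int = 1,
) -> list[GafRecord]:
    """Simulate graph alignments of reads that follow the true paths
    across each planted gap, plus noise reads that never span flanks.

    Per gap, the planned support count from the truth is used unless
    ``n_reads_per_gap`` overrides it; each read's walk is reversed with
    probability 0.5.  Missing-edge gaps get no spanning reads (the graph
    cannot carry them); they are served by split alignments instead.
    """
    from .io import parse_path_string

    rng = np.random.default_rng(seed)
    records: list[GafRecord] = []
    serial = 0

    def emit(walk: list[PathStep], q: int) -> None:
        nonlocal serial
        serial += 1
        if rng.random() < 0.5:
            walk = [s.flipped() for s in reversed(walk)]
        plen = sum(truth.node_len.get(s.node_id, 10_000) for s in walk)
        rlen = int(rng.integers(*read_len_range))
        rlen = min(rlen, plen)
        records.append(
            GafRecord(
                read_name=f"sim{serial}", read_len=rlen, read_start=0,
                read_end=rlen, strand="+", walk=walk, path_len=plen,
                path_start=0, path_end=plen, matches=int(rlen * 0.95),
                block_len=rlen, mapq=q,
            )
        )

    for gap in truth.gaps:
        if gap.kind == "missing_edge" or not gap.fill:
            continue
        n = n_reads_per_gap if n_reads_per_gap is not None else gap.n_reads
        true_path = parse_path_string(truth.true_paths[gap.contig])
        left = parse_path_string(gap.left)[0]
        right = parse_path_string(gap.right)[0]
        li = true_path.index(left)
        ri = len(true_path) - 1 - true_path[::-1].index(right)
        lo = max(0, li - 1)
        hi = min(len(true_path), ri + 2)
        for _ in range(n):
            emit(true_path[lo:hi], mapq)

    node_ids = sorted(graph.nodes)
    flank_ids = {parse_path_string(g.left)[0].node_id for g in truth.gaps} | {
        parse_path_string(g.right)[0].node_id for g in truth.gaps
    }
    safe = [n for n in node_ids if n not in flank_ids] or node_ids
    for i in range(n_noise):
        nid = safe[int(rng.integers(len(safe)))]
        emit([PathStep.node(nid, "+")], 0 if i % 2 else mapq)
    return records


def simulate_split_alignments(
    truth: FixtureTruth,
    contig: str,
    n_reads: int = 4,
    interior_len: int = 4_000,
    anchor_len: int = 6_000,
    seed: int = 1,
):
    """Contig-space split alignments plus anchored read sequences for a
    planted missing-edge gap: each read anchors the right end of the
    left flank node and the left end of the right flank node."""
    from .editing import Anchor, AnchoredRead
    from .io import parse_path_string

    gap = truth.gap_for(contig, "missing_edge")
    rng = np.random.default_rng(seed)
    left = parse_path_string(gap.left)[0].node_id
    right = parse_path_string(gap.right)[0].node_id
    llen, rlen = truth.node_len[left], truth.node_len[right]
    interior_seq = _random_seq(rng, interior_len)

    gaf: list[GafRecord] = []
    reads: list[AnchoredRead] = []
    for i in range(n_reads):
        name = f"split{i + 1}"
        total = 2 * anchor_len + interior_len
        seq = (
            _random_seq(rng, anchor_len) + interior_seq + _random_seq(rng, anchor_len)
        )
        gaf.append(
            GafRecord(name, total, 0, anchor_len, "+",
                      [PathStep.node(left, "+")], llen,
                      llen - anchor_len, llen, anchor_len, anchor_len, 60)
        )
        gaf.append(
            GafRecord(name, total, anchor_len + interior_len, total, "+",
                      [PathStep.node(right, "+")], rlen,
                      0, anchor_len, anchor_len, anchor_len, 60)
        )
        reads.append(
            AnchoredRead(
                name, seq,
                Anchor(0, anchor_len, 60),
                Anchor(anchor_len + interior_len, total, 60),
            )
        )
    return gaf, reads


# ---------------------------------------------------------------------------
# sequence fixtures

def make_sequences(
    contig_lengths: dict[str, int],
    telomere_spec: Optional[dict] = None,
    internal_telomere_spec: Optional[dict] = None,
    gap_runs: Optional[dict] = None,
    seed: int = 1,
    telo_len: int = 7_200,
) -> tuple[dict[str, str], dict]:
    """Contig sequences with planted telomere arrays, internal arrays
    and N runs; the exact planted coordinates are returned as truth.

    ``telomere_spec``: contig -> iterable of 'p'/'q' ends to cap.
    ``internal_telomere_spec``: contig -> offset of an internal array
    (the tip before it stays non-telomeric).
    ``gap_runs``: contig -> list of (start, length) N runs.
    """
    rng = np.random.default_rng(seed)
    telomere_spec = telomere_spec or {}
    internal_telomere_spec = internal_telomere_spec or {}
    gap_runs = gap_runs or {}
    seqs: dict[str, str] = {}
    features: dict[str, dict] = {}

    for name, length in contig_lengths.items():
        seq = list(_random_seq(rng, length))
        feat: dict = {"telomeres": [], "internal": [], "gaps": []}
        ends = set(telomere_spec.get(name, ()))
        n_copies = telo_len // len(TELO_MOTIF)
        if "p" in ends:
            arr = TELO_MOTIF * n_copies
            seq[: len(arr)] = arr
            feat["telomeres"].append(("p", 0, len(arr)))
        if "q" in ends:
            arr = "TTAGGG" * n_copies
            seq[length - len(arr):] = arr
            feat["telomeres"].append(("q", length - len(arr), length))
        off = internal_telomere_spec.get(name)
        if off is not None:
            arr = TELO_MOTIF * n_copies
            if off < telo_len or off + len(arr) > length:
                raise ValueError(f"{name}: internal telomere overlaps an end")
            seq[off: off + len(arr)] = arr
            feat["internal"].append((off, off + len(arr)))
        for start, ln in gap_runs.get(name, ()):
            if start + ln > length:
                raise ValueError(f"{name}: gap run out of range")
            seq[start: start + ln] = "N" * ln
            feat["gaps"].append((start, start + ln))
        seqs[name] = "".join(seq)
        features[name] = feat
    return seqs, features


# ---------------------------------------------------------------------------
# alignment fixtures

def make_alignment_table(
    block_specs: Sequence[dict], seed: int = 1
) -> list[AlignmentBlock]:
    """Alignment blocks against a pseudo-reference from explicit specs:
    each spec gives query, target, len, identity, strand and optional
    qstart/tstart (defaults 0)."""
    blocks = []
    for spec in block_specs:
        qs = int(spec.get("qstart", 0))
        ts = int(spec.get("tstart", 0))
        ln = int(spec["len"])
        blocks.append(
            AlignmentBlock(
                query=spec["query"], target=spec["target"],
                qstart=qs, qend=qs + ln, tstart=ts, tend=ts + ln,
                strand=spec.get("strand", "+"),
                identity_pct=float(spec.get("identity", 99.5)),
                qlen=int(spec.get("qlen", qs + ln)),
                tlen=int(spec.get("tlen", ts + ln)),
            )
        )
    return blocks


# ---------------------------------------------------------------------------
# the full curation scenario

def make_curation_scenario(seed: int = 1, clock=None) -> tuple[CurationState, FixtureTruth, dict]:
    """A four-chromosome diploid fixture with six open gaps.

    chr1 carries a repeat loop (3 maternal / 7 paternal copies, 25 and 8
    spanning reads); chr2 a read-supported bubble gap (maternal) and an
    unsupported one resolvable only from the counterpart haplotype
    (paternal); chr3 a single-read bubble gap (maternal) and a
    missing-edge gap (paternal, split-read rescue); chr4's maternal q
    telomere node is an orphan path to be reconnected across a gap.

    Returns (state, truth, extras) where extras holds the split-read
    evidence for the missing-edge gap.
    """
    graph, paths, truth = make_diploid_graph(
        seed=seed,
        n_chrom=4,
        bubbles_per_chrom=2,
        loop_specs={1: (3, 7)},
        gap_specs=[(2, "mat", 0), (2, "pat", 0), (3, "mat", 1)],
        missing_edge_specs=[(3, "pat", 0)],
        orphan_specs=[(4, "mat")],
        read_support={
            (1, "mat"): 25, (1, "pat"): 8,
            (2, "mat"): 12, (2, "pat"): 0,
            (3, "mat"): 1, (3, "pat"): 4,
        },
        node_len_range=(5_000, 60_000),
    )
    state = CurationState(**({"clock": clock} if clock else {}))
    state.graph = graph
    state.paths = paths
    state.gaf = simulate_read_walks(graph, truth, seed=seed + 101)
    split_gaf, split_reads = simulate_split_alignments(
        truth, "chr3_pat", n_reads=4, seed=seed + 202
    )
    state.log("read_bundle", {"directory": "<synthetic>"})
    return state, truth, {"split_gaf": split_gaf, "split_reads": split_reads}


# ---------------------------------------------------------------------------
# helpers

def render_contig_sequences(
    graph: AssemblyGraph, paths: Sequence[ContigPath], gap_fill_n: Optional[int] = None
) -> dict[str, str]:
    """Concatenate node sequences along each path; gap steps become N
    runs of their estimated length (or ``gap_fill_n``)."""
    out = {}
    comp = str.maketrans("ACGTacgt", "TGCAtgca")
    for p in paths:
        parts = []
        for s in p.steps:
            if s.is_gap:
                parts.append("N" * (gap_fill_n or s.gap_len or 1000))
            else:
                seq = graph.nodes[s.node_id].sequence or ""
                parts.append(seq if s.orient == "+" else seq.translate(comp)[::-1])
        out[p.name] = "".join(parts)
    return out


def write_fixture_bundle(directory: str | Path, seed: int = 1) -> Path:
    """Write a complete synthetic bundle (GFA, path TSV, GAF, FASTA,
    PAF, truth JSON) for the curation scenario."""
    from . import io

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    state, truth, extras = make_curation_scenario(seed)
    io.write_gfa(state.graph, directory / "assembly.gfa")
    io.write_path_table(state.paths, directory / "assembly.paths.tsv")
    io.write_gaf(state.gaf, directory / "assembly.gaf")
    seqs = render_contig_sequences(state.graph, state.paths)
    io.write_fasta(seqs, directory / "assembly.fasta")
    blocks = make_alignment_table(
        [
            {"query": name, "target": name.rsplit("_", 1)[0],
             "len": max(1_000_000, len(seq)), "identity": 99.5}
            for name, seq in seqs.items()
        ],
        seed=seed,
    )
    io.write_paf(blocks, directory / "assembly.paf")
    doc = asdict(truth)
    doc["gaps"] = [asdict(g) for g in truth.gaps]
    with open(directory / "truth.json", "w") as fh:
        json.dump(doc, fh, indent=1)
    return directory
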