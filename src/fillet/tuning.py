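"""Contig-level finishing.

Internal-telomere discovery and trimming of artefactual tips, chromosome
label propagation over the graph for unplaced sequences, renaming,
flipping (reverse complement), karyotype-order sorting, and masking of
the chrY pseudoautosomal region.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx
from Bio.Seq import Seq

from . import intervals as iv
from .model import AssemblyGraph, ContigPath
from .qc import AlignmentBlock, TelomereAnnotation

__all__ = [
    "InternalTelomereHit",
    "NodeChromLabel",
    "find_internal_telomeres",
    "trim_contig",
    "find_multi_used_nodes",
    "propagate_chromosome_labels",
    "rename_contigs",
    "flip_contigs",
    "sort_contigs",
    "par_mask",
    "chromosome_sort_key",
]

UNASSIGNED = "UNASSIGNED"


@dataclass
class InternalTelomereHit:
    """A dense telomere array well inside a contig — the signature of an
    artefactual extension past the true chromosome end."""

    contig: str
    start: int
    end: int
    motif_prop: float
    dist_from_end: int


@dataclass
class NodeChromLabel:
    node: str
    chromosome: str
    multi_used: bool = False


# ---------------------------------------------------------------------------
# internal telomeres and trimming

def find_internal_telomeres(
    annotations: Sequence[TelomereAnnotation],
    contig_lengths: dict[str, int],
    min_prop: float = 0.5,
    min_dist: int = 15_000,
) -> list[InternalTelomereHit]:
    """Merged telomere blocks that sit at least ``min_dist`` from both
    contig boundaries with motif proportion above ``min_prop``."""
    out = []
    for a in annotations:
        length = contig_lengths[a.contig]
        dist = min(a.start, length - a.end)
        if a.motif_prop > min_prop and a.end > a.start and dist >= min_dist:
            out.append(InternalTelomereHit(a.contig, a.start, a.end, a.motif_prop, dist))
    return out


def trim_contig(
    seqs: dict[str, str],
    contig: str,
    keep_from: int,
    keep_to: int,
    out_path: Optional[str | Path] = None,
) -> dict[str, str]:
    """Keep only [keep_from, keep_to) of one contig; all other records
    pass through unchanged.  With ``out_path`` pointing at the source
    FASTA, the result is written alongside it with a ``_trimmed.fasta``
    suffix."""
    if contig not in seqs:
        raise KeyError(f"no contig {contig!r}")
    n = len(seqs[contig])
    if not (0 <= keep_from < keep_to <= n):
        raise ValueError(
            f"trim coordinates [{keep_from},{keep_to}) out of range for length {n}"
        )
    out = dict(seqs)
    out[contig] = seqs[contig][keep_from:keep_to]
    if out_path is not None:
        from .io import write_fasta

        target = _suffixed(out_path, "_trimmed")
        write_fasta(out, target)
    return out


def _suffixed(path: str | Path, suffix: str) -> Path:
    p = Path(path)
    stem = p.name[: -len(".fasta")] if p.name.endswith(".fasta") else p.stem
    return p.with_name(f"{stem}{suffix}.fasta")


# ---------------------------------------------------------------------------
# chromosome label propagation

def _canon_chrom(chrom: str) -> str:
    # chrY shares the PAR with chrX; treat them as one group so PAR
    # nodes are not flagged as multi-chromosome.
    return "chrX" if chrom == "chrY" else chrom


def find_multi_used_nodes(
    paths: Sequence[ContigPath], chromosomes: dict[str, str]
) -> list[NodeChromLabel]:
    """Label every node used by a chromosome-assigned path; a node is
    multi_used iff it occurs in paths of two or more distinct
    chromosomes (chrY counted as chrX).  Repeated use within one
    chromosome is fine."""
    node_chroms: dict[str, set[str]] = {}
    node_first: dict[str, str] = {}
    for p in paths:
        chrom = chromosomes.get(p.name, UNASSIGNED)
        if chrom == UNASSIGNED:
            continue
        for nid in p.node_ids():
            node_chroms.setdefault(nid, set()).add(_canon_chrom(chrom))
            node_first.setdefault(nid, chrom)
    return [
        NodeChromLabel(
            nid,
            node_first[nid] if len(groups) == 1 else UNASSIGNED,
            multi_used=len(groups) > 1,
        )
        for nid, groups in sorted(node_chroms.items())
    ]


def propagate_chromosome_labels(
    graph: AssemblyGraph, labels: Sequence[NodeChromLabel]
) -> dict[str, str]:
    """Spread chromosome labels to unplaced nodes over graph connectivity.

    Multi-used nodes are removed before clustering; each connected
    component inherits a label only when its labelled members agree on a
    single chromosome.
    """
    multi = {l.node for l in labels if l.multi_used}
    known = {l.node: l.chromosome for l in labels
             if not l.multi_used and l.chromosome != UNASSIGNED}
    g = nx.Graph()
    g.add_nodes_from(n for n in graph.nodes if n not in multi)
    for e in graph.edges:
        if e.from_id in multi or e.to_id in multi:
            continue
        g.add_edge(e.from_id, e.to_id)
    out: dict[str, str] = {}
    for comp in nx.connected_components(g):
        chroms = {known[n] for n in comp if n in known}
        label = chroms.pop() if len(chroms) == 1 else UNASSIGNED
        for n in comp:
            out[n] = label
    for n in multi:
        out[n] = UNASSIGNED
    return out


# ---------------------------------------------------------------------------
# rename / flip / sort

def rename_contigs(
    seqs: dict[str, str], name_map: dict[str, str]
) -> tuple[dict[str, str], list[str]]:
    """Replace headers per ``name_map``; sequences untouched.  Returns
    the renamed dict and the list of records left unmapped."""
    missing = [k for k in name_map if k not in seqs]
    if missing:
        raise KeyError(f"name_map keys absent from assembly: {', '.join(missing)}")
    targets = list(name_map.values())
    if len(targets) != len(set(targets)):
        raise ValueError("duplicate target names in name_map")
    out, unmapped = {}, []
    for name, seq in seqs.items():
        new = name_map.get(name)
        if new is None:
            unmapped.append(name)
            out[name] = seq
        else:
            out[new] = seq
    return out, unmapped


def flip_contigs(seqs: dict[str, str], contigs: Iterable[str]) -> dict[str, str]:
    """Reverse-complement the listed records (IUPAC-aware, case kept)."""
    contigs = list(contigs)
    for c in contigs:
        if c not in seqs:
            raise KeyError(f"no contig {c!r}")
    flip = set(contigs)
    return {
        name: str(Seq(seq).reverse_complement()) if name in flip else seq
        for name, seq in seqs.items()
    }


_CHR_RE = re.compile(r"^chr(\d+|[XYM])_?(.*)$", re.IGNORECASE)


def chromosome_sort_key(chrom: str) -> tuple:
    """Natural chromosome order: numeric ascending, then X, Y, M."""
    m = re.fullmatch(r"chr(\d+|[XYM])", chrom, re.IGNORECASE)
    if not m:
        return (2, 0, chrom)
    token = m.group(1).upper()
    if token.isdigit():
        return (0, int(token), "")
    return (1, "XYM".index(token), "")


def _split_name(name: str) -> Optional[tuple[str, str]]:
    if "_" not in name:
        return None
    chrom, hap = name.rsplit("_", 1)
    if re.fullmatch(r"chr(\d+|[XYM])", chrom, re.IGNORECASE):
        return chrom, hap
    return None


def sort_contigs(seqs: dict[str, str], sort_by: str = "hap") -> dict[str, str]:
    """Order records for the final assembly.

    ``hap``: group by haplotype, natural chromosome order within each;
    ``chr``: natural chromosome order, haplotypes adjacent.  Records not
    following the ``<chr>_<hap>`` convention sort last, original order
    preserved (stable).
    """
    if sort_by not in ("hap", "chr"):
        raise ValueError("sort_by must be 'hap' or 'chr'")
    names = list(seqs)
    orig = {n: i for i, n in enumerate(names)}

    def key(name: str):
        parts = _split_name(name)
        if parts is None:
            return (1, (), orig[name])
        chrom, hap = parts
        if sort_by == "hap":
            return (0, (hap, chromosome_sort_key(chrom)), orig[name])
        return (0, (chromosome_sort_key(chrom), hap), orig[name])

    return {n: seqs[n] for n in sorted(names, key=key)}


# ---------------------------------------------------------------------------
# PAR masking

def par_mask(
    blocks: Sequence[AlignmentBlock],
    seqs: dict[str, str],
    record: str,
    min_len: int = 10_000,
    min_identity: float = 95.0,
) -> tuple[dict[str, str], list[tuple[str, int, int]]]:
    """Mask pseudoautosomal intervals on ``record`` (normally chrY).

    Alignment blocks of at least ``min_len`` bases and ``min_identity``
    percent are retained, their target intervals unioned, and those
    bases replaced by N.  The masked FASTA dict and a BED of the masked
    intervals are returned.
    """
    if record not in seqs:
        raise KeyError(f"no record {record!r}")
    kept = [
        (b.tstart, b.tend)
        for b in blocks
        if b.target == record
        and (b.tend - b.tstart) >= min_len
        and b.identity_pct >= min_identity
    ]
    union = iv.merge(kept)
    seq = list(seqs[record])
    for s, e in union:
        seq[s:e] = "N" * (e - s)
    out = dict(seqs)
    out[record] = "".join(seq)
    return out, [(record, s, e) for s, e in union]
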