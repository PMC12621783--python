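"""Path editing: fills, deletes, connections, patches, retention and
the event-sourced history."""

import itertools
import random

import networkx as nx
import pandas as pd
import pytest

from fillet import editing, gaps as ga, io
from fillet.editing import Anchor, AnchoredRead
from fillet.model import (
    AssemblyGraph,
    ContigPath,
    CurationState,
    EdgeRecord,
    NodeRecord,
    PathStep,
)

from conftest import fixed_clock


def small_state(path_specs, edges=(), clock=None, extra_nodes=("X", "Y", "Z")):
    """State with auto-registered single-letter nodes."""
    state = CurationState(**({"clock": clock} if clock else {}))
    node_ids = set(extra_nodes)
    for _, text, _ in path_specs:
        for s in io.parse_path_string(text):
            if not s.is_gap:
                node_ids.add(s.node_id)
    for a, oa, b, ob in edges:
        node_ids |= {a, b}
    for nid in sorted(node_ids):
        state.graph.add_node(NodeRecord(nid, 1_000, sequence="A" * 1_000))
    for a, oa, b, ob in edges:
        state.graph.add_edge(EdgeRecord(a, oa, b, ob))
    for name, text, hap in path_specs:
        state.paths.append(ContigPath(name, io.parse_path_string(text), hap))
    return state


# ---------------------------------------------------------------------------
# fill

def test_fill_replaces_gap_step():
    state = small_state([("c", "A+,[gap],B-", "NONE")])
    editing.register_gaps(state)
    gid = state.gaps[0].gap_id
    editing.fill_gap(state, gid, "A+,X+,B-")
    assert state.path_by_name("c").render() == "A+,X+,B-"
    assert state.gap_by_id(gid).status == "FILLED"
    assert state.history[-1].operation == "fill_gap"


def test_fill_rejects_orientation_mismatch():
    state = small_state([("c", "A+,[gap],B-", "NONE")])
    editing.register_gaps(state)
    gid = state.gaps[0].gap_id
    with pytest.raises(ValueError, match="left boundary"):
        editing.fill_gap(state, gid, "A-,X+,B-")
    # but --force applies it anyway
    editing.fill_gap(state, gid, "A-,X+,B-", force=True)
    assert state.gap_by_id(gid).status == "FILLED"


def test_fill_already_filled_errors():
    state = small_state([("c", "A+,[gap],B+", "NONE")])
    editing.register_gaps(state)
    gid = state.gaps[0].gap_id
    editing.fill_gap(state, gid, "A+,B+")
    with pytest.raises(ValueError, match="FILLED"):
        editing.fill_gap(state, gid, "A+,B+")


def test_fill_unknown_node_errors():
    state = small_state([("c", "A+,[gap],B+", "NONE")])
    editing.register_gaps(state)
    with pytest.raises(KeyError, match="QQ"):
        editing.fill_gap(state, state.gaps[0].gap_id, "A+,QQ+,B+")


def test_fill_second_gap_index_shift():
    state = small_state([("c", "A+,[gap],B+,[gap],C+", "NONE")])
    editing.register_gaps(state)
    first, second = state.gaps
    editing.fill_gap(state, first.gap_id, "A+,X+,Y+,B+")
    editing.fill_gap(state, second.gap_id, "B+,Z+,C+")
    assert state.path_by_name("c").render() == "A+,X+,Y+,B+,Z+,C+"


# ---------------------------------------------------------------------------
# delete

def test_fill_then_delete_restores_rendering():
    state = small_state([("c", "A+,[N777N],B+,[gap],C+", "NONE")])
    before = state.path_by_name("c").render()
    editing.register_gaps(state)
    gid = state.gaps[0].gap_id
    editing.fill_gap(state, gid, "A+,X+,Y+,B+")
    assert state.path_by_name("c").render() != before
    editing.delete_gap(state, gid)
    assert state.path_by_name("c").render() == before
    assert state.gap_by_id(gid).status == "OPEN"


def test_delete_open_marks_deleted_and_twice_errors():
    state = small_state([("c", "A+,[gap],B+", "NONE")])
    editing.register_gaps(state)
    gid = state.gaps[0].gap_id
    editing.delete_gap(state, gid)
    assert state.gap_by_id(gid).status == "DELETED"
    with pytest.raises(ValueError):
        editing.delete_gap(state, gid)
    with pytest.raises(ValueError, match="DELETED"):
        editing.fill_gap(state, gid, "A+,B+")


# ---------------------------------------------------------------------------
# connections

def test_connect_records_without_touching_paths():
    state = small_state([("a", "A+,B+", "NONE"), ("b", "C+,D+", "NONE")])
    editing.connect_contigs(state, "a", "b", at="right")
    assert state.path_by_name("a").render() == "A+,B+"
    conn = state.connections()[0]
    assert (conn.source, conn.target, conn.at, conn.flip) == ("a", "b", "right", False)
    with pytest.raises(ValueError, match="duplicate"):
        editing.connect_contigs(state, "a", "b")
    with pytest.raises(KeyError):
        editing.connect_contigs(state, "a", "zz")
    with pytest.raises(ValueError):
        editing.connect_contigs(state, "a", "a")


def test_write_merges_connection_with_gap_token(tmp_path):
    state = small_state([("a", "A+,B+", "NONE"), ("b", "C+,D+", "NONE")])
    editing.connect_contigs(state, "a", "b", at="right")
    out = tmp_path / "paths.tsv"
    final = editing.write_fixed_paths(state, out)
    assert len(final) == 1
    assert final[0].render() == "A+,B+,[N1000N],C+,D+"


def test_write_flipped_connection(tmp_path):
    state = small_state([("a", "A+,B+", "NONE"), ("b", "C+,D-", "NONE")])
    editing.connect_contigs(state, "a", "b", at="right", flip=True)
    final = editing.write_fixed_paths(state, tmp_path / "p.tsv")
    assert final[0].render() == "A+,B+,[N1000N],D+,C-"


def test_write_connection_at_left(tmp_path):
    state = small_state([("a", "A+", "NONE"), ("b", "C+", "NONE")])
    editing.connect_contigs(state, "a", "b", at="left")
    final = editing.write_fixed_paths(state, tmp_path / "p.tsv")
    assert final[0].render() == "C+,[N1000N],A+"


# ---------------------------------------------------------------------------
# broken contigs

def test_detect_broken_contigs():
    stats = pd.DataFrame(
        [
            {"contig": "p1", "chromosome": "chr1", "haplotype": "pat",
             "t2t_class": "SCAFFOLD", "telo_p": True, "telo_q": False},
            {"contig": "p2", "chromosome": "chr1", "haplotype": "pat",
             "t2t_class": "SCAFFOLD", "telo_p": False, "telo_q": True},
            {"contig": "m1", "chromosome": "chr1", "haplotype": "mat",
             "t2t_class": "T2T_CONTIG", "telo_p": True, "telo_q": True},
        ]
    )
    pairs = editing.detect_broken_contigs(stats)
    assert len(pairs) == 1
    assert pairs[0]["contig_a"] == "p1" and pairs[0]["missing_ends_a"] == ["q"]
    assert pairs[0]["missing_ends_b"] == ["p"]


def test_detect_broken_all_t2t_empty():
    stats = pd.DataFrame(
        [{"contig": "c", "chromosome": "chr1", "haplotype": "mat",
          "t2t_class": "T2T_CONTIG", "telo_p": True, "telo_q": True}]
    )
    assert editing.detect_broken_contigs(stats) == []


def test_detect_broken_three_way_enumeration():
    rows = [
        {"contig": f"c{i}", "chromosome": "chr2", "haplotype": "mat",
         "t2t_class": "SCAFFOLD", "telo_p": False, "telo_q": False}
        for i in range(3)
    ]
    pairs = editing.detect_broken_contigs(pd.DataFrame(rows))
    assert len(pairs) == 3  # all pairwise candidates for review


# ---------------------------------------------------------------------------
# patch nodes

def test_patch_interior_arithmetic():
    read = AnchoredRead("r1", "A" * 6_000 + "C" * 4_000 + "G" * 6_000,
                        Anchor(0, 6_000, 60), Anchor(10_000, 16_000, 60))
    patch = editing.build_patch_node([read], (("cA", "right"), ("cB", "left")))
    assert patch.sequence == "C" * 4_000
    assert patch.support == ["r1"]


def test_patch_abutting_anchors_zero_length():
    read = AnchoredRead("r1", "A" * 12_000,
                        Anchor(0, 6_000, 60), Anchor(6_000, 12_000, 60))
    patch = editing.build_patch_node([read], (("cA", "right"), ("cB", "left")))
    assert patch.sequence == ""


def test_patch_picks_highest_mapq_sum():
    low = AnchoredRead("low", "T" * 12_000, Anchor(0, 5_000, 10), Anchor(7_000, 12_000, 10))
    high = AnchoredRead("high", "G" * 12_000, Anchor(0, 5_000, 60), Anchor(7_000, 12_000, 60))
    patch = editing.build_patch_node([low, high], (("cA", "right"), ("cB", "left")))
    assert patch.sequence == "G" * 2_000


def test_patch_no_reads_errors():
    with pytest.raises(ValueError):
        editing.build_patch_node([], (("cA", "right"), ("cB", "left")))


def test_register_patch_adds_node_and_edges():
    state = small_state([("cA", "A+,B+", "NONE"), ("cB", "C+,D+", "NONE")])
    patch = editing.PatchNode("patch-1", "ACGT" * 100, (("cA", "right"), ("cB", "left")), ["r"])
    editing.register_patch_node(state, patch)
    assert "patch-1" in state.graph
    arcs = set(state.graph.oriented_arcs())
    assert (("B", "+"), ("patch-1", "+")) in arcs
    assert (("patch-1", "+"), ("C", "+")) in arcs
    with pytest.raises(ValueError, match="collides"):
        editing.register_patch_node(state, patch)


# ---------------------------------------------------------------------------
# retention marks

def test_mark_keep_contigs_counts_and_errors():
    specs = [(f"p{i}", "A+", "NONE") for i in range(6)]
    state = small_state(specs)
    state, warnings = editing.mark_keep_contigs(state, ["p0", "p3"])
    dropped = [p for p in state.paths if p.retain_flag == "drop"]
    assert len(dropped) == 4 and warnings == []
    with pytest.raises(KeyError, match="zz"):
        editing.mark_keep_contigs(state, ["zz"])


def test_mark_keep_warns_on_dropped_connection_endpoint():
    state = small_state([("a", "A+", "NONE"), ("b", "B+", "NONE")])
    editing.connect_contigs(state, "a", "b")
    _, warnings = editing.mark_keep_contigs(state, ["a"])
    assert any("b" in w for w in warnings)
    with pytest.raises(ValueError, match="drop"):
        editing.mark_connection_endpoints(state)


def test_mark_connection_endpoints_annotates():
    state = small_state([("a", "A+", "NONE"), ("b", "B+", "NONE")])
    editing.connect_contigs(state, "a", "b")
    editing.mark_connection_endpoints(state)
    assert state.path_by_name("b").retain_flag == "keep_contig"


# ---------------------------------------------------------------------------
# unresolved gap retention

def test_keep_nodes_simple_chain():
    state = small_state(
        [("c", "A+,[gap],C+", "NONE")],
        edges=[("A", "+", "B", "+"), ("B", "+", "C", "+")],
    )
    editing.register_gaps(state)
    assert editing.nodes_in_unresolved_gaps(state) == {"B"}


def test_keep_nodes_excludes_unreachable():
    state = small_state(
        [("c", "A+,[gap],C+", "NONE")],
        edges=[("A", "+", "B", "+"), ("B", "+", "C", "+"), ("Z", "+", "C", "+")],
    )
    editing.register_gaps(state)
    # Z reaches C but is not reachable from A
    assert editing.nodes_in_unresolved_gaps(state) == {"B"}


def test_keep_nodes_both_bubble_arms():
    state = small_state(
        [("c", "A+,[gap],C+", "NONE")],
        edges=[("A", "+", "X", "+"), ("A", "+", "Y", "+"),
               ("X", "+", "C", "+"), ("Y", "+", "C", "+")],
    )
    editing.register_gaps(state)
    assert editing.nodes_in_unresolved_gaps(state) == {"X", "Y"}


def brute_force_between(arcs, nodes, left, right):
    """All-pairs reachability by DFS closure."""
    adj = {}
    for a, b in arcs:
        adj.setdefault(a, set()).add(b)

    def reach(src):
        seen, stack = set(), [src]
        while stack:
            cur = stack.pop()
            for nxt in adj.get(cur, ()):
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        return seen

    from_left = reach(left)
    into_right = {n for n in nodes if right in reach(n)}
    return from_left & into_right


def test_keep_nodes_matches_bruteforce_random_graphs():
    rng = random.Random(99)
    for trial in range(40):
        n = rng.randint(4, 50)
        ids = [f"n{i}" for i in range(n)]
        state = CurationState()
        for nid in ids:
            state.graph.add_node(NodeRecord(nid, 100))
        n_edges = rng.randint(n, 3 * n)
        for _ in range(n_edges):
            a, b = rng.sample(ids, 2)
            state.graph.add_edge(
                EdgeRecord(a, rng.choice("+-"), b, rng.choice("+-"))
            )
        left, right = rng.sample(ids, 2)
        state.paths = [
            ContigPath("c", [PathStep.node(left, "+"), PathStep.gap(),
                             PathStep.node(right, "+")], "NONE")
        ]
        editing.register_gaps(state)
        got = editing.nodes_in_unresolved_gaps(state)

        arcs = list(state.graph.oriented_arcs())
        oriented = [(nid, o) for nid in ids for o in "+-"]
        want = {
            nid for nid, _ in brute_force_between(
                arcs, oriented, (left, "+"), (right, "+"))
        } - {left, right}
        assert got == want, f"trial {trial}"


# ---------------------------------------------------------------------------
# writer details

def test_write_drops_and_unused_singletons(tmp_path):
    state = small_state(
        [("keepme", "A+,[gap],C+", "NONE"), ("dropme", "D+,E+", "NONE")],
        edges=[("A", "+", "B", "+"), ("B", "+", "C", "+")],
    )
    editing.register_gaps(state)
    editing.mark_keep_contigs(state, ["keepme"])
    editing.nodes_in_unresolved_gaps(state)
    out = tmp_path / "p.tsv"
    out_gaf = tmp_path / "p.gaf"
    final = editing.write_fixed_paths(state, out, out_gaf)
    names = [p.name for p in final]
    assert names == ["keepme", "unused_B"]
    assert out_gaf.read_text().splitlines()[0].split("\t")[1] == ">A[N1000N]>C"


def test_write_nothing_curated_identity_minus_drops(tmp_path):
    state = small_state([("a", "A+,B-", "NONE"), ("b", "C+", "NONE")])
    final = editing.write_fixed_paths(state, tmp_path / "p.tsv")
    assert [(p.name, p.render()) for p in final] == [("a", "A+,B-"), ("b", "C+")]


def test_write_gap_token_count_invariant(tmp_path, fresh_scenario):
    """Output gap tokens == OPEN gaps + CONNECTION records + 2 per rDNA
    patch, over retained paths."""
    state, truth, _ = fresh_scenario
    editing.register_gaps(state)
    open_before = len(state.open_gaps())
    # fill one gap, rDNA-patch another, connect the orphan
    g_loop = next(g for g in state.open_gaps() if g.contig == "chr2_mat")
    fill = [g_loop.left_flank, PathStep.node("chr2A0m", "+"), g_loop.right_flank]
    editing.fill_gap(state, g_loop.gap_id, fill)
    g_rdna = next(g for g in state.open_gaps() if g.contig == "chr3_mat")
    editing.rdna_patch(state, g_rdna.gap_id, "chr3A1m", copies=2)
    editing.connect_contigs(state, "chr4_mat", "chr4_mat_orphan", at="right")
    final = editing.write_fixed_paths(state, tmp_path / "p.tsv")
    tokens = sum(len(p.gap_indices()) for p in final)
    assert tokens == (open_before - 2) + 1 + 2


# ---------------------------------------------------------------------------
# rDNA patch

def test_rdna_patch_form():
    state = small_state([("c", "A+,[gap],B+", "NONE")])
    state.graph.add_node(NodeRecord("morph", 100, sequence="A" * 100))
    editing.register_gaps(state)
    gid = state.gaps[0].gap_id
    editing.rdna_patch(state, gid, "morph", copies=2)
    assert state.path_by_name("c").render() == "A+,[N1000N],morph+,morph+,[N1000N],B+"


def test_rdna_patch_single_copy_and_missing_morph():
    state = small_state([("c", "A+,[gap],B+", "NONE")])
    state.graph.add_node(NodeRecord("m", 10, sequence="A" * 10))
    editing.register_gaps(state)
    gid = state.gaps[0].gap_id
    with pytest.raises(KeyError):
        editing.rdna_patch(state, gid, "absent")
    editing.rdna_patch(state, gid, "m", copies=1)
    assert state.path_by_name("c").render() == "A+,[N1000N],m+,[N1000N],B+"


def test_rdna_patch_leaves_other_gaps_untouched():
    state = small_state([("c", "A+,[gap],B+,[gap],C+", "NONE")])
    state.graph.add_node(NodeRecord("m", 10, sequence="A" * 10))
    editing.register_gaps(state)
    first, second = state.gaps
    editing.rdna_patch(state, first.gap_id, "m", copies=2)
    assert state.gap_by_id(second.gap_id).status == "OPEN"
    assert state.path_by_name("c").steps[second.step_index].is_gap


# ---------------------------------------------------------------------------
# event sourcing

def snapshot(state, tmp_path, name):
    f = tmp_path / name
    io.save_state(state, f)
    return f.read_bytes()


def test_replay_reproduces_random_session(tmp_path):
    """A randomized editing session replayed from its history yields a
    byte-identical saved state."""
    rng = random.Random(7)
    spec = [
        ("c1", "A+,[gap],B+,[gap],C+", "MATERNAL"),
        ("c2", "A+,[gap],C+", "PATERNAL"),
        ("c3", "D+,E+", "NONE"),
        ("c4", "F+", "NONE"),
    ]
    edges = [("A", "+", "X", "+"), ("X", "+", "B", "+"),
             ("B", "+", "Y", "+"), ("Y", "+", "C", "+")]

    def build():
        return small_state(spec, edges, clock=fixed_clock())

    state = build()
    editing.register_gaps(state)
    fills = {"A+,[gap],B+": "A+,X+,B+", "B+,[gap],C+": "B+,Y+,C+",
             "A+,[gap],C+": "A+,X+,B+,Y+,C+"}
    for _ in range(50):
        action = rng.choice(["fill", "delete", "noop_keep"])
        open_gaps = [g for g in state.open_gaps()]
        filled = [g for g in state.gaps if g.status == "FILLED"]
        if action == "fill" and open_gaps:
            g = rng.choice(open_gaps)
            key = f"{g.left_flank.render()},[gap],{g.right_flank.render()}"
            editing.fill_gap(state, g.gap_id, fills[key])
        elif action == "delete" and filled:
            editing.delete_gap(state, rng.choice(filled).gap_id)
        else:
            editing.nodes_in_unresolved_gaps(state)
    if not state.connections():
        editing.connect_contigs(state, "c3", "c4", at="right")

    final_bytes = snapshot(state, tmp_path, "final.json")
    replayed = editing.replay_history(build(), state.history)
    assert snapshot(replayed, tmp_path, "replayed.json") == final_bytes


def test_every_mutation_logs_exactly_one_entry():
    state = small_state([("c", "A+,[gap],B+", "NONE"), ("d", "D+", "NONE")],
                        edges=[("A", "+", "B", "+")])
    n0 = len(state.history)
    editing.register_gaps(state)
    assert len(state.history) == n0 + 1
    editing.fill_gap(state, state.gaps[0].gap_id, "A+,B+")
    assert len(state.history) == n0 + 2
    editing.delete_gap(state, state.gaps[0].gap_id)
    assert len(state.history) == n0 + 3
    # history is append-only: seq numbers strictly increase
    seqs = [h.seq_no for h in state.history]
    assert seqs == sorted(set(seqs))
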