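"""Telomere scanning, T2T classification, contiguity, QV and
chromosome assignment."""

import itertools
import math
import random

import numpy as np
import pytest

from fillet import fixtures, qc
from fillet.qc import AlignmentBlock


MOTIF = qc.DEFAULT_MOTIF
RC = "TTAGGG"


def _random_nonmotif(rng, n):
    # alternating-ish random sequence with no CCCTAA/TTAGGG occurrences
    s = "".join(rng.choice("AC") for _ in range(n))
    assert MOTIF not in s and RC not in s
    return s


# ---------------------------------------------------------------------------
# single-pass scan

def test_pure_array_block():
    seq = MOTIF * (10_000 // 6 + 1)
    seq = seq[:10_002]  # whole copies only
    blocks = qc.scan_telomere_blocks(seq, search_limit=50_000)
    assert len(blocks) >= 1
    b = blocks[0]
    assert b.start == 0 and b.motif_prop == pytest.approx(1.0)


def test_random_sequence_no_blocks():
    rng = random.Random(0)
    seq = _random_nonmotif(rng, 30_000)
    assert qc.scan_telomere_blocks(seq) == []


def test_planted_array_against_bruteforce_oracle():
    """600 motif copies planted at 2,500 in 60 kb; block coordinates
    must match a brute-force occurrence scan."""
    rng = random.Random(1)
    prefix = _random_nonmotif(rng, 2_500)
    array = MOTIF * 600
    suffix = _random_nonmotif(rng, 60_000 - len(prefix) - len(array))
    seq = prefix + array + suffix

    # oracle: literal occurrence positions
    occ = [i for i in range(len(seq) - 5) if seq[i:i + 6] in (MOTIF, RC)]
    assert occ[0] == 2_500 and occ[-1] + 6 == 2_500 + 3_600

    blocks = qc.scan_telomere_blocks(seq, search_limit=50_000)
    assert len(blocks) == 1
    b = blocks[0]
    assert (b.start, b.end) == (2_500, 6_100)
    assert b.motif_prop >= 0.99


def test_scan_rejects_bad_motif():
    with pytest.raises(ValueError):
        qc.scan_telomere_blocks("ACGT" * 100, motif="CCNTAA")


def test_scan_strand_symmetry():
    """Scanning the reverse complement mirrors coordinates exactly."""
    rng = random.Random(2)
    seq = _random_nonmotif(rng, 1_000) + MOTIF * 500 + _random_nonmotif(rng, 40_000)
    comp = str.maketrans("ACGT", "TGCA")
    rc = seq.translate(comp)[::-1]
    fwd = qc.scan_telomere_blocks(seq, search_limit=len(seq))
    rev = qc.scan_telomere_blocks(rc, search_limit=len(rc))
    n = len(seq)
    mirrored = sorted((n - b.end, n - b.start) for b in rev)
    assert sorted((b.start, b.end) for b in fwd) == mirrored


# ---------------------------------------------------------------------------
# multipass

def test_multipass_terminal_telomere():
    rng = random.Random(3)
    seq = MOTIF * 1_300 + _random_nonmotif(rng, 100_000)
    blocks = qc.detect_telomeres_multipass(seq, contig="c")
    p_blocks = [b for b in blocks if b.side == "P_END"]
    assert len(p_blocks) == 1
    assert p_blocks[0].start == 0


def test_multipass_recovers_masked_tip():
    """A telomere array sitting behind a 3 kb non-telomeric tip is found
    once the tip is masked, and survives the interval union."""
    rng = random.Random(4)
    tip = _random_nonmotif(rng, 3_000)
    seq = tip + MOTIF * 1_000 + _random_nonmotif(rng, 80_000)
    blocks = qc.detect_telomeres_multipass(seq, contig="c")
    assert any(abs(b.start - 3_000) < 10 and b.side == "P_END" for b in blocks)


def test_multipass_internal_array_reported_end_not_telomeric():
    """Telomeric repeats ~18.8 kb inside with a non-telomeric tip: the
    array is reported as INTERNAL and the end carries no telomere."""
    rng = random.Random(5)
    seq, features = fixtures.make_sequences(
        {"chr11_mat": 200_000},
        internal_telomere_spec={"chr11_mat": 18_800},
        seed=11,
    )
    blocks = qc.detect_telomeres_multipass(seq["chr11_mat"], contig="chr11_mat")
    internal = [b for b in blocks if b.side == "INTERNAL"]
    assert len(internal) == 1
    want = features["chr11_mat"]["internal"][0]
    assert abs(internal[0].start - want[0]) < 10
    assert not any(b.side == "P_END" for b in blocks)


def test_multipass_union_idempotent():
    rng = random.Random(6)
    seq = MOTIF * 1_200 + _random_nonmotif(rng, 60_000) + RC * 1_200
    blocks = qc.detect_telomeres_multipass(seq, contig="c")
    again = qc.merge_telomere_annotations(blocks, len(seq))
    assert [(b.start, b.end, b.motif_prop) for b in again] == [
        (b.start, b.end, b.motif_prop) for b in blocks
    ]


# ---------------------------------------------------------------------------
# classification

@pytest.mark.parametrize(
    "p,q,gaps,expected",
    [
        (True, True, 0, "T2T_CONTIG"),
        (True, True, 1, "T2T_SCAFFOLD"),
        (True, True, 2, "T2T_SCAFFOLD"),
        (True, False, 0, "SCAFFOLD"),
        (False, True, 1, "SCAFFOLD"),
        (False, False, 0, "SCAFFOLD"),
    ],
)
def test_classify_t2t(p, q, gaps, expected):
    assert qc.classify_t2t(p, q, gaps) == expected


def test_gap_census():
    assert qc.gap_census({"c": "ACGT"}) == []
    assert qc.gap_census({"c": "AANNNAA"}) == [("c", 2, 5)]
    assert qc.gap_census({"c": "N" * 7}) == [("c", 0, 7)]
    assert qc.gap_census({"c": "ANAANNA"}, min_n=2) == [("c", 4, 6)]


# ---------------------------------------------------------------------------
# contiguity

def brute_force_n50(lengths):
    ordered = sorted(lengths, reverse=True)
    total = sum(ordered)
    for i in range(1, len(ordered) + 1):
        if sum(ordered[:i]) * 2 >= total:
            return ordered[i - 1], i, total
    raise AssertionError


@pytest.mark.parametrize(
    "lengths,n50,l50",
    [([100], 100, 1), ([50, 40, 30, 20, 10], 40, 2), ([10, 10, 10, 10], 10, 2)],
)
def test_contiguity_examples(lengths, n50, l50):
    assert qc.contiguity_stats(lengths) == (n50, l50, sum(lengths))


def test_contiguity_empty_errors():
    with pytest.raises(ValueError):
        qc.contiguity_stats([])


def test_contiguity_matches_bruteforce_random():
    rng = random.Random(42)
    for _ in range(200):
        lengths = [rng.randint(1, 10_000) for _ in range(rng.randint(1, 40))]
        assert qc.contiguity_stats(lengths) == brute_force_n50(lengths)


# ---------------------------------------------------------------------------
# QV

def test_qv_closed_form():
    total, err, k = 10**6, 10, 31
    res = qc.compute_qv(total, err, k)
    expected_e = 1 - (1 - err / total) ** (1 / k)
    assert res.per_base_error == pytest.approx(expected_e, abs=1e-15)
    assert res.qv == pytest.approx(-10 * math.log10(expected_e), abs=1e-9)


def test_qv_zero_error_cap():
    res = qc.compute_qv(12345, 0, 31)
    assert math.isinf(res.qv)
    assert res.render_qv(cap=99.0) == 99.0


def test_qv_all_error_boundary():
    res = qc.compute_qv(100, 100, 31)
    assert res.per_base_error == pytest.approx(1.0)
    assert res.qv == pytest.approx(0.0)


def test_qv_monotone_in_errors():
    prev = float("inf")
    for err in [0, 1, 10, 100, 1000, 10**6]:
        cur = qc.compute_qv(10**6, err, 31).qv
        assert cur <= prev
        prev = cur


def test_qv_invalid_inputs():
    with pytest.raises(ValueError):
        qc.compute_qv(0, 0, 31)
    with pytest.raises(ValueError):
        qc.compute_qv(10, 11, 31)


# ---------------------------------------------------------------------------
# chromosome assignment

def blk(query, target, length, identity=99.5, strand="+"):
    return fixtures.make_alignment_table(
        [{"query": query, "target": target, "len": length,
          "identity": identity, "strand": strand}]
    )[0]


def test_assign_basic_and_filters():
    out = qc.assign_chromosomes([blk("c1", "chr5", 2_000_000)])
    assert out[0].chromosome == "chr5" and out[0].orientation == "+"

    out = qc.assign_chromosomes([blk("c1", "chr5", 500_000)])
    assert out[0].chromosome == "UNASSIGNED"

    out = qc.assign_chromosomes([blk("c1", "chr5", 2_000_000, identity=98.0)])
    assert out[0].chromosome == "UNASSIGNED"


def test_assign_mixed_strand():
    blocks = [
        blk("c1", "chr2", 6_000_000, strand="+"),
        blk("c1", "chr2", 4_000_000, strand="-"),
    ]
    out = qc.assign_chromosomes(blocks)
    assert out[0].orientation == "MIXED"
    assert out[0].support_bases_fwd == 6_000_000
    assert out[0].support_bases_rev == 4_000_000


def test_assign_dominance_margin():
    blocks = [
        blk("c1", "chr2", 8_000_000, strand="-"),
        blk("c1", "chr2", 2_000_000, strand="+"),
    ]
    assert qc.assign_chromosomes(blocks)[0].orientation == "-"


def test_assign_permutation_invariant():
    blocks = [
        blk("c1", "chr1", 3_000_000),
        blk("c1", "chr2", 2_000_000),
        blk("c2", "chr2", 1_500_000, strand="-"),
    ]
    base = qc.assign_chromosomes(blocks)
    for perm in itertools.permutations(blocks):
        assert qc.assign_chromosomes(list(perm)) == base


# ---------------------------------------------------------------------------
# counterpart ranking

def test_rank_counterpart_group_sum():
    blocks = [
        blk("A", "B", 5_000), blk("A", "B", 7_000), blk("A", "C", 10_000),
        blk("A", "A", 99_000),  # self-alignment: excluded
        blk("Z", "B", 50_000),  # different query: excluded
    ]
    assert qc.rank_counterpart_nodes(blocks, "A") == [("B", 12_000), ("C", 10_000)]
    assert qc.rank_counterpart_nodes(blocks, "missing") == []


def test_rank_counterpart_tie_lexicographic():
    blocks = [blk("A", "C", 5_000), blk("A", "B", 5_000)]
    assert qc.rank_counterpart_nodes(blocks, "A") == [("B", 5_000), ("C", 5_000)]


# ---------------------------------------------------------------------------
# synteny subtraction

def test_non_syntenic_subtraction():
    genome = [("chr1_mat", 0, 1_000_000)]
    blocks = [
        fixtures.make_alignment_table(
            [{"query": "chr1_mat", "target": "chr1", "len": 200_000,
              "qstart": 200_000, "identity": 99.5}]
        )[0]
    ]
    out = qc.non_syntenic_regions(blocks, genome)
    assert out == [("chr1_mat", 0, 200_000), ("chr1_mat", 400_000, 1_000_000)]


def test_non_syntenic_chromosome_mismatch_ignored():
    genome = [("chr1_mat", 0, 500_000)]
    wrong = fixtures.make_alignment_table(
        [{"query": "chr1_mat", "target": "chr2", "len": 500_000, "identity": 99.5}]
    )
    assert qc.non_syntenic_regions(wrong, genome) == [("chr1_mat", 0, 500_000)]


def test_non_syntenic_full_cover_empty():
    genome = [("chr3_pat", 0, 300_000)]
    cover = fixtures.make_alignment_table(
        [{"query": "chr3_pat", "target": "chr3", "len": 300_000, "identity": 99.9}]
    )
    assert qc.non_syntenic_regions(cover, genome) == []
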