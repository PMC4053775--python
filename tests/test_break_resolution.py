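"""Break resolution: the difference rule, chimera subclasses, and the
false-location countermeasures (verification and fusion)."""

import numpy as np
import pytest

from kbreak import (
    GenomeLocation,
    Params,
    analyze_read,
    build_genome_index,
    build_support_index,
    check_concordance,
    classify_chimera,
    classify_gap,
    compute_location_profile,
    find_breaks,
    fuse_breaks,
    rule1_classify,
    select_flank_locations,
    verify_break,
)
from kbreak.events import FlankPair, classify_colinear
from kbreak.genome import pack_loc
from kbreak._kmers import revcomp

from conftest import clones, random_genome, substitute

K = 22


def _analyze(read, gidx, n=8, params=None):
    rc = clones(read, n)
    sidx = build_support_index(rc, gidx.k)
    return analyze_read("x0", read, gidx, sidx, params or Params())


# ---------------------------------------------------------------------------
# Rule 1
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("k", [10, 20, 22])
def test_rule1_is_a_partition(k):
    """For every (l, L) with 2 <= l, L <= 200 exactly one case holds."""
    for l in range(2, 201):
        for L in range(2, 201):
            kind, p = rule1_classify(l, L, k)
            cases = [
                l == L == k + 1,
                l == k and L > k,
                L == k and l > k,
            ]
            assert sum(cases) == (kind != "none")
            if kind == "deletion":
                assert p == L - k
            if kind == "insertion":
                assert p == l - k


@pytest.mark.parametrize(
    "l,L,expected",
    [
        (23, 23, ("substitution", 0)),
        (22, 122, ("deletion", 100)),
        (26, 22, ("insertion", 4)),
        (23, 24, ("none", 0)),
        (25, 25, ("none", 0)),
    ],
)
def test_rule1_examples(l, L, expected):
    assert rule1_classify(l, L, K) == expected


@pytest.mark.parametrize(
    "l,L,expected",
    [
        (21, 121, ("deletion", 100)),  # gap boundary slid by one
        (20, 27, ("deletion", 7)),
        (25, 21, ("insertion", 4)),  # insertion boundary slid by one
        (23, 1, ("insertion", 22)),  # maximal slide still advances by one
        (23, 0, ("none", 0)),  # standing still: inverted/overlap jump
        (22, -40, ("none", 0)),
        (24, 24, ("none", 0)),
    ],
)
def test_slid_generalization(l, L, expected):
    assert classify_colinear(l, L, K) == expected


def test_classify_gap_threshold():
    assert classify_gap(3, 15) == "deletion"
    assert classify_gap(15, 15) == "deletion"
    assert classify_gap(2500, 15) == "splice"
    assert classify_gap(150000, 15) == "splice"
    with pytest.raises(ValueError):
        classify_gap(0, 15)


# ---------------------------------------------------------------------------
# Concordance and chimera subclasses (unit level)
# ---------------------------------------------------------------------------


def _pair(chrom_b, strand_b, pos_b, chrom_a, strand_a, pos_a, l):
    b = GenomeLocation(chrom_b, strand_b, pos_b)
    a = GenomeLocation(chrom_a, strand_a, pos_a)
    return FlankPair(b, a, 0, 0, l, a.projected - b.projected, True, True)


def test_concordance():
    assert check_concordance(_pair("c", 1, 100, "c", 1, 123, 23), 23, 0)
    assert not check_concordance(_pair("c", 1, 100, "d", 1, 123, 23), 23, 0)
    assert not check_concordance(_pair("c", 1, 100, "c", -1, 123, 23), 23, 0)
    # deletion: L = l + p
    assert check_concordance(_pair("c", 1, 100, "c", 1, 129, 22), 22, 7)
    assert not check_concordance(_pair("c", 1, 100, "c", 1, 130, 22), 22, 7)


@pytest.mark.parametrize(
    "pair,expected",
    [
        (_pair("c1", 1, 100, "c2", 1, 500, K), 1),
        (_pair("c1", 1, 100, "c2", -1, 500, K), 2),
        (_pair("c1", 1, 100, "c1", -1, 500, K), 3),
        (_pair("c1", 1, 500, "c1", 1, 100, K), 4),  # inverted order
        (_pair("c1", 1, 500, "c1", 1, 510, K), 5),  # backward jump within l
        (_pair("c1", 1, 100, "c1", 1, 200, K), None),  # colinear forward
    ],
)
def test_chimera_subclasses(pair, expected):
    assert classify_chimera(pair) == expected


# ---------------------------------------------------------------------------
# Flank pair selection
# ---------------------------------------------------------------------------


def test_flank_pair_selection_prefers_concordant(toy_genome, toy_gidx):
    seq = toy_genome.chromosomes[0][1]
    read = substitute(seq[100:175], 40)
    lp = compute_location_profile("r", read, toy_gidx)
    (br,) = find_breaks(lp)
    pairs = select_flank_locations(br, lp, delta=2)
    assert len(pairs) == 1  # unique locations both sides
    best = pairs[0]
    assert best.colinear and best.coherent_b and best.coherent_a
    assert classify_colinear(br.l, best.L, K)[0] == "substitution"


def test_flank_pair_cross_product_ranking(toy_genome, toy_gidx):
    """With several locations per flank, all combinations are returned and
    a pair admitting a colinear interpretation ranks first."""
    seq = toy_genome.chromosomes[0][1]
    read = substitute(seq[100:175], 40)
    lp = compute_location_profile("r", read, toy_gidx)
    (br,) = find_breaks(lp)
    # graft decoy locations onto both flanks
    decoy_b = pack_loc(1, False, 50)
    decoy_a1, decoy_a2 = pack_loc(1, False, 200), pack_loc(1, True, 80)
    lp.locs[br.j_b] = lp.locs[br.j_b] + (decoy_b,)
    lp.locs[br.j_a] = lp.locs[br.j_a] + (decoy_a1, decoy_a2)
    lp._sets.clear()
    pairs = select_flank_locations(br, lp, delta=2)
    assert len(pairs) == 6
    kind, _ = classify_colinear(br.l, pairs[0].L, K)
    assert pairs[0].colinear and kind == "substitution"


# ---------------------------------------------------------------------------
# Verification and fusion against false locations
# ---------------------------------------------------------------------------


def _inject(lp, index, packed):
    lp.locs[index] = (packed,)
    lp.counts[index] = 1
    lp._sets.clear()


def test_verification_recovers_substitution_behind_fl(toy_genome, toy_gidx):
    """A false location at the end of a break shifts the flank; break
    verification discards it and the substitution is recovered."""
    seq = toy_genome.chromosomes[0][1]
    read = substitute(seq[100:175], 40)
    lp = compute_location_profile("r", read, toy_gidx)
    (clean,) = find_breaks(lp)
    # plant an FL at the gap edge, just before the true right flank
    _inject(lp, clean.j_a - 1, pack_loc(1, False, 123))
    (br,) = find_breaks(lp)
    assert br.j_a == clean.j_a - 1  # break ends early at the FL
    (vbr,) = verify_break([br], lp, delta=2)
    assert (vbr.j_b, vbr.j_a) == (clean.j_b, clean.j_a)
    assert clean.j_a - 1 in vbr.discarded


def test_verification_discards_fl_at_left_flank(toy_genome, toy_gidx):
    seq = toy_genome.chromosomes[0][1]
    read = substitute(seq[100:175], 40)
    lp = compute_location_profile("r", read, toy_gidx)
    (clean,) = find_breaks(lp)
    _inject(lp, clean.j_b + 1, pack_loc(0, True, 17))
    (br,) = find_breaks(lp)
    assert br.j_b == clean.j_b + 1
    (vbr,) = verify_break([br], lp, delta=2)
    assert vbr.j_b == clean.j_b
    assert clean.j_b + 1 in vbr.discarded


def test_verification_is_identity_on_clean_profiles(toy_genome, toy_gidx):
    seq = toy_genome.chromosomes[0][1]
    for read in (seq[100:175], substitute(seq[100:175], 40)):
        lp = compute_location_profile("r", read, toy_gidx)
        brs = find_breaks(lp)
        assert verify_break(brs, lp, delta=2) == brs
        assert fuse_breaks(brs, lp, g=2) == brs


def test_fusion_merges_mirage_breaks(toy_genome, toy_gidx):
    """An FL inside a deletion break splits it into two mirage breaks;
    fusion merges them so the deletion rule applies instead of a false
    chimera."""
    seq = toy_genome.chromosomes[0][1]
    read = seq[100:140] + seq[147:182]  # 7 nt deletion
    lp = compute_location_profile("r", read, toy_gidx)
    (clean,) = find_breaks(lp)
    mid = (clean.j_b + clean.j_a) // 2
    _inject(lp, mid, pack_loc(1, False, 222))
    brs = find_breaks(lp)
    assert len(brs) == 2
    fused = fuse_breaks(brs, lp, g=2)
    assert len(fused) == 1
    assert (fused[0].j_b, fused[0].j_a) == (clean.j_b, clean.j_a)
    assert mid in fused[0].discarded


def test_fusion_keeps_separate_events_apart(toy_genome, toy_gidx):
    """Two true substitutions k+2 apart leave a short but coherent matched
    run between their breaks; the run chains with the outer flanks and the
    breaks are not fused."""
    seq = toy_genome.chromosomes[0][1]
    read = substitute(substitute(seq[50:125], 30), 30 + K + 2)
    lp = compute_location_profile("r", read, toy_gidx)
    brs = find_breaks(lp)
    assert len(brs) == 2
    assert fuse_breaks(brs, lp, g=2) == brs


def test_end_to_end_fl_inside_deletion_still_calls_deletion(toy_genome, toy_gidx):
    seq = toy_genome.chromosomes[0][1]
    read = seq[100:140] + seq[147:182]
    ann = _analyze(read, toy_gidx)
    assert [e.kind for e in ann.events] == ["deletion"]


# ---------------------------------------------------------------------------
# Planted events: exact coordinates and reverse-complement invariance
# ---------------------------------------------------------------------------


def _norm_gap_oracle(seq, lo, hi):
    while lo > 0 and seq[lo - 1] == seq[hi]:
        lo, hi = lo - 1, hi - 1
    return lo, hi


def _norm_ins_oracle(seq, x, ins):
    while x > 0 and ins[-1] == seq[x - 1]:
        x, ins = x - 1, seq[x - 1] + ins[:-1]
    return x, ins


@pytest.mark.parametrize("seed", range(6))
def test_planted_events_recovered_at_exact_coordinates(seed):
    """On an FL-free random genome, substitutions, insertions and
    deletions are recovered with exactly the planted (canonicalized)
    coordinates and sizes, from the read and from its reverse
    complement."""
    rng = np.random.default_rng(1000 + seed)
    genome = random_genome(2000 + seed, [800])
    gidx = build_genome_index(genome, K)
    seq = genome.chromosomes[0][1]
    a = int(rng.integers(100, 300))

    # substitution at read position 40
    read = substitute(seq[a : a + 75], 40)
    for r in (read, revcomp(read)):
        (ev,) = _analyze(r, gidx).events
        assert (ev.kind, ev.chrom, ev.pos) == ("snv", "chr1", a + 40)

    # deletion of p in the middle
    p = int(rng.integers(1, 11))
    read = seq[a : a + 40] + seq[a + 40 + p : a + 75 + p]
    lo, hi = _norm_gap_oracle(seq, a + 40, a + 40 + p - 1)
    for r in (read, revcomp(read)):
        (ev,) = _analyze(r, gidx).events
        assert (ev.kind, ev.pos, ev.pos2, ev.p) == ("deletion", lo, hi, p)

    # insertion of random p bases
    ins = "".join("ACGT"[i] for i in rng.integers(0, 4, p))
    read = seq[a : a + 40] + ins + seq[a + 40 : a + 75 - p]
    x, canon = _norm_ins_oracle(seq, a + 40, ins)
    for r in (read, revcomp(read)):
        evs = _analyze(r, gidx).events
        if not evs:
            continue  # fully slid insertions can degenerate; none planted here
        (ev,) = evs
        assert (ev.kind, ev.pos, ev.p, ev.inserted) == ("insertion", x, p, canon)

    # splice-sized gap
    read = seq[a : a + 38] + seq[a + 238 : a + 275]
    lo, hi = _norm_gap_oracle(seq, a + 38, a + 237)
    for r in (read, revcomp(read)):
        (ev,) = _analyze(r, gidx).events
        assert (ev.kind, ev.pos, ev.pos2, ev.p) == ("splice", lo, hi, 200)


def test_chimera_keys_are_orientation_invariant(toy_genome, toy_gidx):
    s1 = toy_genome.chromosomes[0][1]
    s2 = toy_genome.chromosomes[1][1]
    read = s1[100:138] + revcomp(s2[50:88])
    anns = [_analyze(read, toy_gidx), _analyze(revcomp(read), toy_gidx)]
    keys = [[e.key for e in a.events] for a in anns]
    assert keys[0] == keys[1]
    (ev,) = anns[0].events
    assert ev.kind == "chimera" and ev.chimera_class == 2


def test_error_event_reports_break_end_position(toy_genome, toy_gidx):
    """A read-private substitution (support 1 inside the break) is an
    error whose reported position is the break end."""
    seq = toy_genome.chromosomes[0][1][:150]
    reads = [(f"c{i}", seq[o : o + 75]) for i, o in enumerate(range(0, 75, 5))]
    err = substitute(seq[0:75], 40)
    reads.append(("e", err))
    from kbreak import ReadCollection

    coll = ReadCollection(reads)
    sidx = build_support_index(coll, K)
    ann = analyze_read("e", err, toy_gidx, sidx, Params())
    (ev,) = ann.events
    assert (ev.kind, ev.read_pos, ev.pos) == ("error", 40, 40)
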