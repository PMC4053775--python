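"""Per-read orchestration and cross-read event aggregation."""

import numpy as np
import pytest

from kbreak import (
    Params,
    ReadCollection,
    ReferenceGenome,
    aggregate_events,
    analyze_collection,
    analyze_read,
    build_genome_index,
    build_support_index,
)
from kbreak._kmers import revcomp

from conftest import clones, random_genome, substitute

K = 22


@pytest.fixture(scope="module")
def genome():
    return random_genome(77, [2000])


@pytest.fixture(scope="module")
def gidx(genome):
    return build_genome_index(genome, K)


def test_exact_read_is_unique_and_clean(genome, gidx):
    seq = genome.chromosomes[0][1]
    read = seq[500:575]
    coll = clones(read, 4)
    ann = analyze_read("x0", read, gidx, build_support_index(coll, K), Params())
    assert ann.status == "unique"
    assert ann.events == [] and ann.labels == {"clean"}
    assert ann.primary == (0, "chr1", 1, 500)


def test_too_short_read(genome, gidx):
    coll = ReadCollection([("s", "ACGTACGTAC"), ("pad", genome.chromosomes[0][1][:40])])
    ann = analyze_read("s", "ACGTACGTAC", gidx, build_support_index(coll, K), Params())
    assert ann.status == "too_short"


def test_snv_read_at_coverage(genome, gidx):
    """Reads covering a shared substitution at staggered offsets: the one
    analyzed maps uniquely and yields one SNV at the exact position."""
    seq = genome.chromosomes[0][1]
    mut = seq[:600] + substitute(seq[600:601], 0) + seq[601:]
    coll = ReadCollection(
        [(f"c{i}", mut[560 + 3 * i : 635 + 3 * i]) for i in range(12)]
    )
    sidx = build_support_index(coll, K)
    ann = analyze_read("c5", coll.reads[5][1], gidx, sidx, Params())
    assert ann.status == "unique"
    assert [(e.kind, e.chrom, e.pos) for e in ann.events] == [("snv", "chr1", 600)]


def test_multi_junction_read_yields_two_splices(genome, gidx):
    """A read spanning three exons with a short (>= k) middle exon carries
    two splice junctions, both resolved from the same read."""
    seq = genome.chromosomes[0][1]
    # exons [100,130) [430,455) [855,880): middle exon 25 >= k
    tx = seq[100:130] + seq[430:455] + seq[855:880]
    assert len(tx) == 80
    read = tx[3:78]  # both junctions at least k from the read ends
    ann = analyze_read("x0", read, gidx, build_support_index(clones(read, 6), K), Params())
    kinds = sorted(e.kind for e in ann.events)
    assert kinds == ["splice", "splice"]
    spans = sorted((e.pos, e.pos2) for e in ann.events)
    assert spans[0][0] <= 130 and spans[1][1] >= 454


def test_repeat_read_is_multiple(gidx):
    two_copy = random_genome(5, [500])
    seq = two_copy.chromosomes[0][1]
    dup = ReferenceGenome([("chr1", seq + "T" * 40 + seq[100:300])])
    gdup = build_genome_index(dup, K)
    read = seq[150:225]  # inside the duplicated stretch
    ann = analyze_read("x0", read, gdup, build_support_index(clones(read, 3), K), Params())
    assert ann.status == "multiple"
    assert ann.n_chains == 2
    assert len(ann.secondary) == 1


def test_low_complexity_read_is_duplicated():
    g = ReferenceGenome([("chr1", "AT" * 800)])
    gidx2 = build_genome_index(g, K)
    read = "AT" * 40
    params = Params(duplication=100)
    ann = analyze_read("x0", read, gidx2, build_support_index(clones(read, 2), K), params)
    assert ann.status == "duplicated"


def test_each_break_yields_exactly_one_disposition(genome, gidx):
    seq = genome.chromosomes[0][1]
    read = substitute(substitute(seq[200:275], 25), 49)  # both interior
    ann = analyze_read("x0", read, gidx, build_support_index(clones(read, 6), K), Params())
    # two interior breaks -> two resolved substitution-shaped events
    assert len(ann.events) == 2
    assert sorted(e.read_pos for e in ann.events) == [25, 49]


def test_border_case_reads_defer_to_mid_read_coverage(genome, gidx):
    """The same junction planted at random offsets: end-of-read
    occurrences go to the undetermined pool, yet the junction is still
    recovered from the reads holding it mid-sequence."""
    rng = np.random.default_rng(0)
    seq = genome.chromosomes[0][1]
    tx = seq[300:400] + seq[900:1000]  # junction at tx position 100
    reads = []
    for i, o in enumerate(rng.integers(30, 120, 40)):
        reads.append((f"j{i}", tx[int(o) : int(o) + 75]))
    coll = ReadCollection(reads)
    anns = analyze_collection(gidx, coll, Params())
    cands = aggregate_events(anns)
    splices = [c for c in cands if c.kind == "splice"]
    assert len(splices) == 1
    assert splices[0].n_reads >= 5
    border = [a for a in anns if {"undetermined", "bio_undetermined"} & a.labels]
    assert border  # the junction-at-the-edge reads exist and are deferred
    # border reads are still uniquely located by their main block
    assert all(a.status == "unique" for a in border)


def test_aggregation_pools_strands_and_orderings(genome, gidx):
    seq = genome.chromosomes[0][1]
    mut = seq[:600] + substitute(seq[600:601], 0) + seq[601:]
    fwd = [(f"f{i}", mut[560 + 3 * i : 635 + 3 * i]) for i in range(5)]
    rev = [(f"r{i}", revcomp(s)) for i, (_, s) in enumerate(fwd)]
    coll = ReadCollection(fwd + rev)
    anns = analyze_collection(gidx, coll, Params())
    cands = [c for c in aggregate_events(anns) if c.kind == "snv"]
    assert len(cands) == 1
    assert cands[0].key == ("snv", "chr1", 600)
    assert cands[0].n_reads == len([a for a in anns if a.events])
    # order invariance of keys
    coll2 = ReadCollection(list(reversed(coll.reads)))
    cands2 = [c for c in aggregate_events(analyze_collection(gidx, coll2, Params())) if c.kind == "snv"]
    assert [c.key for c in cands2] == [c.key for c in cands]


def test_min_reads_filter(genome, gidx):
    """A read-private error yields a single-read candidate that the
    min-reads post-filter removes, while well-supported candidates stay."""
    seq = genome.chromosomes[0][1]
    reads = [(f"c{i}", seq[200 + 5 * i : 275 + 5 * i]) for i in range(8)]
    reads.append(("e", substitute(seq[200:275], 40)))
    anns = analyze_collection(gidx, ReadCollection(reads), Params())
    all_cands = aggregate_events(anns, min_reads=1)
    filtered = aggregate_events(anns, min_reads=2)
    assert any(c.kind == "error" and c.n_reads == 1 for c in all_cands)
    assert all(c.n_reads >= 2 for c in filtered)
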