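"""Ground-truth simulator: determinism, rates, and truth consistency."""

import numpy as np
import pytest

from kbreak import (
    Params,
    aggregate_events,
    analyze_collection,
    build_genome_index,
    build_transcripts,
    generate_reference,
    make_negative_control_junction_reads,
    mutate_genome,
    simulate_dataset,
    simulate_reads,
)
from kbreak.simulate import GenomeParams, MutationRates
from kbreak._kmers import revcomp

SMALL = GenomeParams(genome_size=120_000, n_chroms=2, n_genes=18)


def test_generate_reference_is_deterministic():
    g1, m1 = generate_reference(SMALL, seed=7)
    g2, m2 = generate_reference(SMALL, seed=7)
    assert g1.chromosomes == g2.chromosomes and m1 == m2
    g3, _ = generate_reference(SMALL, seed=8)
    assert g3.chromosomes != g1.chromosomes


def test_gene_models_respect_distribution_bounds():
    params = GenomeParams(genome_size=150_000, n_genes=20, exon_min=30)
    _, models = generate_reference(params, seed=3)
    assert len(models) == 20
    for mdl in models:
        assert all(e - s >= 30 for s, e in mdl.exons)
        for (s1, e1), (s2, e2) in zip(mdl.exons, mdl.exons[1:]):
            assert s2 - e1 >= params.intron_min


def test_zero_genes_gives_genome_only():
    genome, models = generate_reference(GenomeParams(genome_size=10_000, n_genes=0), 1)
    assert models == [] and genome.total_length == 10_000


def test_infeasible_gene_packing_errors():
    with pytest.raises(ValueError):
        generate_reference(GenomeParams(genome_size=20_000, n_genes=200), 1)


def test_zero_rates_are_identity():
    genome, models = generate_reference(SMALL, seed=5)
    mutated, lifted, ledger = mutate_genome(
        genome, models, MutationRates(snv_rate=0, indel_rate=0, n_fusions=0), seed=5
    )
    assert mutated.chromosomes == genome.chromosomes
    assert lifted == models
    assert ledger.variants == [] and ledger.fusions == []


def test_rate_validation():
    genome, models = generate_reference(SMALL, seed=5)
    with pytest.raises(ValueError):
        mutate_genome(genome, models, MutationRates(snv_rate=1.5), seed=1)


def test_substitution_count_within_binomial_bounds():
    genome, models = generate_reference(SMALL, seed=5)
    rate = 2e-3
    _, _, ledger = mutate_genome(
        genome, models, MutationRates(snv_rate=rate, indel_rate=0, n_fusions=0), seed=9
    )
    n = sum(1 for v in ledger.variants if v.kind == "snv")
    G = genome.total_length
    sd = (G * rate * (1 - rate)) ** 0.5
    assert abs(n - G * rate) < 4 * sd


def test_fusions_have_distinct_non_colinear_anchors():
    genome, models = generate_reference(SMALL, seed=5)
    _, _, ledger = mutate_genome(
        genome, models, MutationRates(n_fusions=5), seed=2
    )
    assert len(ledger.fusions) == 5
    anchors = {(f.chrom5, f.pos5, f.chrom3, f.pos3) for f in ledger.fusions}
    assert len(anchors) == 5
    assert all(f.cls in (1, 2, 3, 4, 5) for f in ledger.fusions)


@pytest.fixture(scope="module")
def small_dataset():
    return simulate_dataset(
        11, SMALL, MutationRates(n_fusions=2), read_length=75, coverage=8.0,
        error_rate=0.01,
    )


def test_dataset_is_reproducible(small_dataset):
    again = simulate_dataset(
        11, SMALL, MutationRates(n_fusions=2), read_length=75, coverage=8.0,
        error_rate=0.01,
    )
    assert again.reads.reads == small_dataset.reads.reads


def test_error_free_reads_are_transcript_substrings():
    ds = simulate_dataset(13, SMALL, MutationRates(n_fusions=0),
                          read_length=60, coverage=2.0, error_rate=0.0)
    tx_seqs = [t.seq for t in ds.transcripts]
    for rid, seq in list(ds.reads)[:200]:
        assert any(seq in t or revcomp(seq) in t for t in tx_seqs)
        assert ds.ledger.reads[rid].error_read_pos == []


def test_error_fraction_matches_closed_form(small_dataset):
    """With per-base error 1% and m=75, the fraction of reads carrying at
    least one error is 1 - 0.99^75 ~ 0.53."""
    n = len(small_dataset.reads)
    with_err = sum(1 for rt in small_dataset.ledger.reads.values() if rt.error_read_pos)
    expect = 1 - 0.99 ** 75
    sd = (n * expect * (1 - expect)) ** 0.5
    assert abs(with_err - n * expect) < 4 * sd


def test_truth_segments_reproduce_read_sequences(small_dataset):
    """Reads without errors or carried variants must be reconstructible
    from the reference genome via their truth segments."""
    ds = small_dataset
    checked = 0
    for rid, seq in ds.reads:
        rt = ds.ledger.reads[rid]
        if rt.error_read_pos or rt.events:
            continue
        if any(gs == 0 for _, _, _, gs, _ in rt.segments):
            continue
        rebuilt = [None] * len(seq)
        for r0, rl, chrom, gs, f0 in rt.segments:
            ref = ds.reference.sequence(chrom)
            for i in range(rl):
                b = ref[f0 + gs * i]
                rebuilt[r0 + i] = b if gs > 0 else revcomp(b)
        if None in rebuilt:
            continue
        assert "".join(rebuilt) == seq
        checked += 1
        if checked >= 100:
            break
    assert checked >= 50


def test_junction_spanning_reads_record_the_junction(small_dataset):
    ds = small_dataset
    spanning = [
        rid
        for rid, rt in ds.ledger.reads.items()
        if any(key[0] == "splice" for key, _ in rt.events)
    ]
    assert spanning
    rt = ds.ledger.reads[spanning[0]]
    key = next(k for k, _ in rt.events if k[0] == "splice")
    assert key in set(ds.ledger.junctions)
    assert len(rt.segments) >= 2


def test_transcript_shorter_than_read_is_skipped():
    genome, models = generate_reference(SMALL, seed=5)
    mutated, lifted, ledger = mutate_genome(genome, models, MutationRates(n_fusions=0), 5)
    txs = build_transcripts(genome, mutated, models, lifted, ledger)
    m = 100_000  # longer than every transcript
    with pytest.raises(ValueError):
        simulate_reads(txs, ledger, m, 0.0, seed=1, n_reads=10)


def test_negative_control_reads_are_centered_and_deterministic():
    genome, models = generate_reference(SMALL, seed=5)
    reads = make_negative_control_junction_reads(genome, models, 50, 76, seed=4)
    again = make_negative_control_junction_reads(genome, models, 50, 76, seed=4)
    assert reads.reads == again.reads
    assert len(reads) == 50
    assert all(len(s) == 76 for _, s in reads)
    # each half is a genuine exonic substring in transcription orientation
    exon_seqs = []
    for mdl in models:
        chrom = genome.sequence(mdl.chrom)
        for s, e in mdl.exons:
            ex = chrom[s:e] if mdl.strand > 0 else revcomp(chrom[s:e])
            exon_seqs.append(ex)
    for _, s in list(reads)[:10]:
        assert any(s[:38] == ex[-38:] for ex in exon_seqs if len(ex) >= 38)
        assert any(s[38:] == ex[:38] for ex in exon_seqs if len(ex) >= 38)


def test_zero_rate_dataset_maps_cleanly():
    """All mutation and error rates zero on a unique-k-mer genome, with
    uniform expression so support is everywhere informative: every read
    maps uniquely and nothing but the true splice junctions is called."""
    genome, models = generate_reference(
        GenomeParams(genome_size=80_000, n_chroms=1, n_genes=10), 21
    )
    mutated, lifted, ledger = mutate_genome(
        genome, models, MutationRates(snv_rate=0, indel_rate=0, n_fusions=0), 21
    )
    txs = build_transcripts(genome, mutated, models, lifted, ledger)
    eligible = [t for t in txs if len(t) >= 75]
    reads = simulate_reads(
        txs, ledger, 75, 0.0, seed=22, coverage=10.0,
        expression=np.ones(len(eligible)),
    )
    gidx = build_genome_index(genome, 22)
    anns = analyze_collection(gidx, reads, Params())
    assert all(a.status == "unique" for a in anns)
    cands = aggregate_events(anns)
    # no variant or chimera candidate may appear; a coverage dip at a
    # junction can occasionally read as a support drop (an "error" call),
    # but never as a false variant
    assert {c.kind for c in cands} <= {"splice", "error"}
    splice = [c for c in cands if c.kind == "splice"]
    truth = set(ledger.junctions)
    assert splice and all(c.key in truth for c in splice)
    assert sum(c.n_reads for c in cands if c.kind == "error") <= 0.01 * len(reads)
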