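"""Shared fixtures: toy genomes, indexes, and brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from kbreak import (
    Params,
    ReadCollection,
    ReferenceGenome,
    build_genome_index,
)
from kbreak._kmers import revcomp
from kbreak.simulate import _random_seq


def random_genome(seed: int, lengths: list[int]) -> ReferenceGenome:
    rng = np.random.default_rng(seed)
    return ReferenceGenome(
        [(f"chr{i + 1}", _random_seq(rng, n)) for i, n in enumerate(lengths)]
    )


def scan_locations(genome: ReferenceGenome, kmer: str) -> list[tuple[str, int, int]]:
    """Naive both-strand scan oracle for k-mer locations."""
    out = []
    k = len(kmer)
    for ci, (name, seq) in enumerate(genome.chromosomes):
        for p in range(len(seq) - k + 1):
            sub = seq[p : p + k]
            if "N" in sub:
                continue
            if sub == kmer:
                out.append((ci, name, 1, p))
            if revcomp(sub) == kmer:
                out.append((ci, name, -1, p))
    out.sort(key=lambda t: (t[0], t[2] < 0, t[3]))
    return [(name, strand, pos) for _, name, strand, pos in out]


def scan_support(reads: ReadCollection, kmer: str, canonical: bool) -> int:
    """Naive distinct-read support oracle."""
    n = 0
    rc = revcomp(kmer)
    for _, seq in reads:
        if kmer in seq or (canonical and rc in seq):
            n += 1
    return n


@pytest.fixture(scope="session")
def toy_genome() -> ReferenceGenome:
    return random_genome(42, [600, 300])


@pytest.fixture(scope="session")
def toy_gidx(toy_genome):
    return build_genome_index(toy_genome, k=22)


@pytest.fixture(scope="session")
def params() -> Params:
    return Params()


def clones(read: str, n: int, rid: str = "x") -> ReadCollection:
    """A collection holding ``n`` staggered-id copies of one read."""
    return ReadCollection([(f"{rid}{i}", read) for i in range(n)])


def covering_reads(seq: str, m: int, step: int = 1, rid: str = "c") -> ReadCollection:
    reads = [
        (f"{rid}{i}", seq[o : o + m])
        for i, o in enumerate(range(0, len(seq) - m + 1, step))
    ]
    return ReadCollection(reads)


def substitute(seq: str, pos: int) -> str:
    out = list(seq)
    out[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[pos]]
    return "".join(out)
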