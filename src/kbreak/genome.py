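"""Reference genome container and the exact-match k-mer location index.

The index answers, for any k-mer, the set of its exact matching locations
on both strands of the genome together with their total occurrence count.
Any sufficiently long k-mer is a near-unique witness of a genomic position,
so these per-k-mer location lists are the raw material from which per-read
location profiles are assembled.

Coordinate convention
---------------------
A :class:`GenomeLocation` carries a 0-based position ``pos`` and a strand in
{+1, -1}.  ``pos`` is always the forward-strand offset of the first base of
the k-mer *footprint* (for a reverse-strand hit this is where the last base
of the k-mer, read in match orientation, sits).  The *projected coordinate*
``c = strand * pos`` then advances by exactly +1 per read position for
colinear matches on either strand, which is what all downstream break
arithmetic relies on.

Internally a location is a packed integer ``(chrom_index << 36) |
(strand_bit << 35) | pos`` with strand_bit 0 for +1; sorting packed values
therefore gives the documented deterministic order (chromosome order, then
forward before reverse, then position).
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass

from Bio import SeqIO

from ._kmers import rolling_codes, encode

_STRAND_SHIFT = 35
_CHROM_SHIFT = 36
_POS_MASK = (1 << _STRAND_SHIFT) - 1

_INDEX_MAGIC = b"KBRKIDX1"


def pack_loc(chrom_idx: int, strand: int, pos: int) -> int:
    return (chrom_idx << _CHROM_SHIFT) | ((strand < 0) << _STRAND_SHIFT) | pos


@dataclass(frozen=True, order=True)
class GenomeLocation:
    """A strand-aware genomic position of a k-mer footprint."""

    chrom: str
    strand: int  # +1 or -1
    pos: int  # 0-based forward-strand offset of the footprint start

    @property
    def projected(self) -> int:
        """Strand-projected coordinate; +1 per read position when colinear."""
        return self.strand * self.pos


@dataclass
class ReferenceGenome:
    """An ordered multi-chromosome genome over the alphabet {A,C,G,T,N}."""

    chromosomes: list[tuple[str, str]]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, seq in self.chromosomes:
            if not seq:
                raise ValueError(f"chromosome {name!r} has an empty sequence")
            if set(seq) - set("ACGTN"):
                raise ValueError(f"chromosome {name!r} has symbols outside ACGTN")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    @property
    def total_length(self) -> int:
        return sum(len(s) for _, s in self.chromosomes)

    def sequence(self, chrom: str) -> str:
        for name, seq in self.chromosomes:
            if name == chrom:
                return seq
        raise KeyError(chrom)

    @classmethod
    def from_fasta(cls, path) -> "ReferenceGenome":
        """Load a (possibly line-wrapped, soft-masked) multi-FASTA file."""
        from .io import _open_maybe_gzip

        with _open_maybe_gzip(path) as handle:
            records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(handle, "fasta")]
        if not records:
            raise ValueError(f"no FASTA records found in {path}")
        return cls(records)

    def to_fasta(self, path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.chromosomes:
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


class GenomeIndex:
    """Exact k-mer → genomic locations map over both strands.

    Location lists are truncated at ``cap`` entries per k-mer but the true
    total occurrence count is always retained.  K-mers containing N are not
    indexed.  Only the query contract matters here; the compact full-text
    data structures used by production mappers are deliberately out of
    scope.
    """

    def __init__(self, genome: ReferenceGenome, k: int, cap: int = 255):
        if k < 1:
            raise ValueError("k must be >= 1")
        if cap < 1:
            raise ValueError("cap must be >= 1")
        if not genome.chromosomes:
            raise ValueError("empty genome")
        if all(len(seq) < k for _, seq in genome.chromosomes):
            raise ValueError(f"k={k} exceeds the length of every chromosome")
        self.genome = genome
        self.k = k
        self.cap = cap
        # value: packed int (single location) or list of packed ints (capped)
        self._map: dict[int, int | list[int]] = {}
        self._overflow: dict[int, int] = {}  # true totals for capped k-mers
        self._build()

    def _build(self) -> None:
        add = self._add
        k = self.k
        for ci, (_, seq) in enumerate(self.genome.chromosomes):
            if len(seq) < k:
                continue
            base = ci << _CHROM_SHIFT
            rev_bit = base | (1 << _STRAND_SHIFT)
            for p, fwd, rc in rolling_codes(seq, k):
                if fwd is None:
                    continue
                add(fwd, base | p)
                add(rc, rev_bit | p)

    def _add(self, key: int, packed: int) -> None:
        m = self._map
        cur = m.get(key)
        if cur is None:
            m[key] = packed
        elif isinstance(cur, int):
            m[key] = [cur, packed]
        elif len(cur) < self.cap:
            cur.append(packed)
        else:
            self._overflow[key] = self._overflow.get(key, self.cap) + 1

    # -- fast internal queries on codes ------------------------------------

    def locate_code(self, code: int) -> tuple[int, ...]:
        """Packed locations (sorted, capped) for an encoded k-mer."""
        cur = self._map.get(code)
        if cur is None:
            return ()
        if isinstance(cur, int):
            return (cur,)
        return tuple(sorted(cur))

    def count_code(self, code: int) -> int:
        cur = self._map.get(code)
        if cur is None:
            return 0
        if isinstance(cur, int):
            return 1
        return self._overflow.get(code, len(cur))

    # -- public string queries ---------------------------------------------

    def locate_kmer(self, kmer: str) -> list[GenomeLocation]:
        """All retained locations of ``kmer``, in deterministic order."""
        if len(kmer) != self.k:
            raise ValueError(f"k-mer length {len(kmer)} != k={self.k}")
        code = encode(kmer)
        if code is None:
            return []
        return [self.decode_loc(p) for p in self.locate_code(code)]

    def occurrence_count(self, kmer: str) -> int:
        """Exact total number of occurrences on both strands."""
        if len(kmer) != self.k:
            raise ValueError(f"k-mer length {len(kmer)} != k={self.k}")
        code = encode(kmer)
        if code is None:
            return 0
        return self.count_code(code)

    def decode_loc(self, packed: int) -> GenomeLocation:
        chrom = self.genome.names[packed >> _CHROM_SHIFT]
        strand = -1 if (packed >> _STRAND_SHIFT) & 1 else 1
        return GenomeLocation(chrom, strand, packed & _POS_MASK)

    # -- serialization ------------------------------------------------------

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            fh.write(_INDEX_MAGIC)
            pickle.dump(self, fh, protocol=pickle.HIGHEST_PROTOCOL)

    @classmethod
    def load(cls, path) -> "GenomeIndex":
        with open(path, "rb") as fh:
            magic = fh.read(len(_INDEX_MAGIC))
            if magic != _INDEX_MAGIC:
                raise ValueError(f"{path} is not a kbreak genome index")
            obj = pickle.load(fh)
        if not isinstance(obj, cls):
            raise ValueError(f"{path} does not contain a GenomeIndex")
        return obj


def build_genome_index(genome: ReferenceGenome, k: int, cap: int = 255) -> GenomeIndex:
    """Index every N-free k-mer of both strands of ``genome``."""
    return GenomeIndex(genome, k, cap)
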