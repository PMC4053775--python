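"""Read collection and the k-mer support index (the read-set layer).

The *support* of a k-mer is the number of distinct reads of the collection
that contain it; it is a proxy for local coverage that needs no mapping.
Sequencing is unstranded by default, so a k-mer and its reverse complement
share one counter ("canonical" mode); stranded libraries can count
orientations separately ("as-is" mode).  A k-mer repeated within one read
counts that read once.  Quality strings play no role anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._kmers import rolling_codes, encode, rc_code


@dataclass
class ReadCollection:
    """Ordered reads (id, sequence) over the alphabet {A,C,G,T,N}."""

    reads: list[tuple[str, str]]

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)

    @property
    def lengths(self) -> list[int]:
        return [len(s) for _, s in self.reads]


class SupportIndex:
    """Distinct-read counts per k-mer over a read collection."""

    def __init__(self, reads: ReadCollection, k: int, mode: str = "canonical"):
        if k < 1:
            raise ValueError("k must be >= 1")
        if mode not in ("canonical", "as-is"):
            raise ValueError(f"unknown mode {mode!r}")
        if not any(len(s) >= k for _, s in reads):
            raise ValueError(f"no read is at least k={k} long")
        self.k = k
        self.mode = mode
        self._counts: dict[int, int] = {}
        self._build(reads)

    def _build(self, reads: ReadCollection) -> None:
        counts = self._counts
        k = self.k
        canonical = self.mode == "canonical"
        for _, seq in reads:
            if len(seq) < k:
                continue
            seen = set()
            for _, fwd, rc in rolling_codes(seq, k):
                if fwd is None:
                    continue
                seen.add(min(fwd, rc) if canonical else fwd)
            for code in seen:
                counts[code] = counts.get(code, 0) + 1

    def support_code(self, fwd: int, rc: int) -> int:
        if self.mode == "canonical":
            return self._counts.get(min(fwd, rc), 0)
        return self._counts.get(fwd, 0)

    def support(self, kmer: str) -> int:
        """Number of distinct reads containing ``kmer`` (0 if never seen)."""
        if len(kmer) != self.k:
            raise ValueError(f"k-mer length {len(kmer)} != k={self.k}")
        code = encode(kmer)
        if code is None:
            return 0
        return self.support_code(code, rc_code(code, self.k))


def build_support_index(
    reads: ReadCollection, k: int, mode: str = "canonical"
) -> SupportIndex:
    """Count, for every k-mer of the collection, its distinct-read support."""
    return SupportIndex(reads, k, mode)
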