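"""Integer k-mer encoding shared by the genome and read-set indexes.

Bases are packed two bits each (A=0, C=1, G=2, T=3).  A rolling update
yields, for every k-mer start of a sequence, both the forward code and the
code of the reverse complement; positions whose k-mer contains a non-ACGT
symbol are reported as invalid and never indexed.
"""

from __future__ import annotations

from typing import Iterator

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    """Reverse complement of a sequence over {A,C,G,T,N}."""
    return "".join(_COMP[b] for b in reversed(seq))


def encode(kmer: str) -> int | None:
    """2-bit code of ``kmer``, or None if it contains a non-ACGT symbol."""
    code = 0
    for ch in kmer:
        v = _CODE.get(ch)
        if v is None:
            return None
        code = (code << 2) | v
    return code


def decode(code: int, k: int) -> str:
    out = []
    for shift in range(2 * (k - 1), -1, -2):
        out.append(_BASES[(code >> shift) & 3])
    return "".join(out)


def rc_code(code: int, k: int) -> int:
    """Code of the reverse complement of the k-mer encoded by ``code``."""
    out = 0
    for _ in range(k):
        out = (out << 2) | (3 - (code & 3))
        code >>= 2
    return out


def rolling_codes(seq: str, k: int) -> Iterator[tuple[int, int | None, int | None]]:
    """Yield ``(start, fwd_code, rc_code)`` for every k-mer start of ``seq``.

    Codes are None when the k-mer window contains a symbol outside ACGT.
    """
    mask = (1 << (2 * k)) - 1
    hi_shift = 2 * (k - 1)
    fwd = 0
    rc = 0
    last_bad = -1
    get = _CODE.get
    for i, ch in enumerate(seq):
        v = get(ch, -1)
        if v < 0:
            last_bad = i
            v = 0
        fwd = ((fwd << 2) | v) & mask
        rc = (rc >> 2) | ((3 - v) << hi_shift)
        p = i - k + 1
        if p >= 0:
            if last_bad < p:
                yield p, fwd, rc
            else:
                yield p, None, None
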