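"""Per-read k-mer profiles, break detection, and support classification.

For a read of length m analyzed with k-mers, both profiles have one entry
per k-mer start index i in [0, m-k]:

* the location profile holds the exact genomic locations of k-mer i (and
  their true count, even when the stored list was capped);
* the support profile holds the number of reads of the collection sharing
  k-mer i (at least 1, since the read itself is indexed).

A *break* is a maximal run of k-mer starts with zero usable locations: the
footprint of a difference between the read and the genome.  Whether the
support collapses inside the break (a read-private sequencing error) or
stays comparable to the rest of the read (a biological difference shared by
overlapping reads) is decided by a separation rule on the mean support
inside versus outside the break.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._kmers import rolling_codes
from .genome import GenomeIndex, _STRAND_SHIFT
from .params import Params
from .reads import SupportIndex

#: sentinel for a break flank that touches a read extremity
SENTINEL = -1


@dataclass
class LocationProfile:
    """Per-k-mer-start genomic locations of one read (packed ints)."""

    read_id: str
    m: int
    k: int
    locs: list[tuple[int, ...]]  # per index: sorted packed locations (capped)
    counts: list[int]  # per index: true total occurrence count
    chrom_names: list[str] = field(default_factory=list)
    _sets: dict[int, frozenset[int]] = field(default_factory=dict, repr=False)

    def __len__(self) -> int:
        return len(self.locs)

    def loc_set(self, i: int) -> frozenset[int]:
        s = self._sets.get(i)
        if s is None:
            s = frozenset(self.locs[i])
            self._sets[i] = s
        return s

    def has_successor(self, i: int, packed: int, offset: int) -> bool:
        """True if index ``i`` holds the location ``offset`` steps colinear
        from ``packed`` (projected coordinate advancing +1 per index)."""
        if (packed >> _STRAND_SHIFT) & 1:
            target = packed - offset
        else:
            target = packed + offset
        return target in self.loc_set(i)


@dataclass
class SupportProfile:
    """Per-k-mer-start distinct-read support of one read."""

    read_id: str
    s: list[int]

    def __len__(self) -> int:
        return len(self.s)


@dataclass
class Break:
    """A maximal run of location-less k-mer starts.

    ``j_b``/``j_a`` are the matched indices immediately flanking the gap,
    or SENTINEL / profile length when the gap touches a read extremity.
    ``l = j_a - j_b``.  ``discarded`` lists formerly-matched indices whose
    locations were dropped as false by verification or fusion.
    """

    j_b: int
    j_a: int
    n: int  # profile length, for border bookkeeping
    discarded: tuple[int, ...] = ()

    @property
    def border(self) -> bool:
        return self.j_b < 0 or self.j_a >= self.n

    @property
    def l(self) -> int:
        return self.j_a - self.j_b

    @property
    def gap(self) -> range:
        return range(self.j_b + 1, self.j_a)


@dataclass
class SupportVerdict:
    """Outcome of the inside/outside support comparison for one break."""

    verdict: str  # dropping | non_dropping | undetermined
    s_in: float
    s_out: float


def compute_location_profile(
    read_id: str, seq: str, gidx: GenomeIndex
) -> LocationProfile:
    """Locate every k-mer of the read on both genome strands.

    K-mers containing N (or any non-ACGT symbol) get zero locations and
    therefore contribute to breaks.
    """
    k = gidx.k
    m = len(seq)
    if m < k:
        raise ValueError(f"read {read_id!r} shorter than k={k}")
    locs: list[tuple[int, ...]] = []
    counts: list[int] = []
    locate = gidx.locate_code
    count = gidx.count_code
    for _, fwd, _ in rolling_codes(seq, k):
        if fwd is None:
            locs.append(())
            counts.append(0)
        else:
            locs.append(locate(fwd))
            counts.append(count(fwd))
    return LocationProfile(read_id, m, k, locs, counts, gidx.genome.names)


def compute_support_profile(
    read_id: str, seq: str, sidx: SupportIndex
) -> SupportProfile:
    """Support of every k-mer of a read that is part of the indexed set."""
    k = sidx.k
    if len(seq) < k:
        raise ValueError(f"read {read_id!r} shorter than k={k}")
    s: list[int] = []
    has_n = False
    for _, fwd, rc in rolling_codes(seq, k):
        if fwd is None:
            s.append(0)
            has_n = True
        else:
            s.append(sidx.support_code(fwd, rc))
    if not has_n and s and min(s) < 1:
        raise ValueError(
            f"read {read_id!r} has a zero-support k-mer: it is not part of "
            "the indexed collection"
        )
    return SupportProfile(read_id, s)


def find_breaks(profile: LocationProfile) -> list[Break]:
    """Maximal zero-location runs of the profile, left to right."""
    n = len(profile)
    counts = profile.counts
    breaks: list[Break] = []
    i = 0
    while i < n:
        if counts[i] == 0:
            j = i
            while j + 1 < n and counts[j + 1] == 0:
                j += 1
            breaks.append(Break(j_b=i - 1 if i > 0 else SENTINEL, j_a=j + 1, n=n))
            i = j + 1
        else:
            i += 1
    return breaks


def classify_support_over_break(
    sp: SupportProfile,
    br: Break,
    params: Params,
    outside: list[int] | None = None,
) -> SupportVerdict:
    """Compare mean support inside the break gap against the matched rest.

    ``outside`` defaults to every index not in the gap; the read analyzer
    passes the originally matched indices instead, so that locations later
    discarded as false still count on the outside.
    """
    gap = [i for i in br.gap if 0 <= i < len(sp.s)]
    inside = [sp.s[i] for i in gap]
    if outside is None:
        gapset = set(gap)
        out_vals = [v for i, v in enumerate(sp.s) if i not in gapset]
    else:
        gapset = set(gap)
        out_vals = [sp.s[i] for i in outside if i not in gapset]
    s_in = sum(inside) / len(inside) if inside else 0.0
    if not out_vals:
        return SupportVerdict("undetermined", s_in, 0.0)
    s_out = sum(out_vals) / len(out_vals)
    if s_out < params.tau_low:
        return SupportVerdict("undetermined", s_in, s_out)
    # the ratio rule is strict so that a variant riding at exactly half the
    # local coverage (a clean heterozygote) stays on the biological side
    if s_in <= params.sigma_abs or s_in < params.alpha * s_out:
        return SupportVerdict("dropping", s_in, s_out)
    return SupportVerdict("non_dropping", s_in, s_out)
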