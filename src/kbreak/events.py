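"""Turning breaks into typed events.

A break with matched flanks ``j_b < j_a`` (``l = j_a - j_b``) and flank
locations whose projected coordinates differ by ``L`` is interpreted by the
difference rule for colinear flanks:

* ``l = L = k + 1``  -> a single substitution at read ``j_a - 1``;
* ``l = k`` and ``L = k + p``  -> a p-nt genomic gap (deletion, or a splice
  junction when p exceeds the deletion/splice threshold);
* ``l = k + p`` and ``L = k``  -> a p-nt insertion.

When the sequence at a gap boundary happens to match the genome across the
junction, the flanking k-mers extend into the event and shrink the break
(``l < k`` for a gap, ``L < k`` for an insertion) while leaving the
difference ``L - l`` intact; the resolver recognizes these slid breaks and
reports the left-normalized placement, so the strict rule above is the
special case of an unambiguous junction.

Non-colinear flanks with break length at most k, locally coherent
neighbourhoods, and non-collapsing support are chimeric junctions, split
into five subclasses by chromosome, strand, and coordinate order.

False locations (random k-mer matches) corrupt this arithmetic in two
ways: an FL at a break end shifts a flank (fixed by break *verification*,
which discards flank locations incoherent with their neighbours), and an
FL inside a break splits it into two adjacent mirage breaks (fixed by
break *fusion*, which merges them and discards the intervening
locations).
"""

from __future__ import annotations

from dataclasses import dataclass

from ._kmers import revcomp
from .genome import GenomeIndex, GenomeLocation
from .params import Params
from .profiling import Break, LocationProfile, SENTINEL, SupportVerdict

_MAX_FLANK_LOCS = 16  # pairs examined per break are bounded for repeat-borne flanks


@dataclass
class FlankPair:
    """One combination of flank locations for a break."""

    loc_b: GenomeLocation
    loc_a: GenomeLocation
    packed_b: int
    packed_a: int
    l: int
    L: int  # c(loc_a) - c(loc_b), projected coordinates
    coherent_b: bool
    coherent_a: bool

    @property
    def colinear(self) -> bool:
        return self.loc_b.chrom == self.loc_a.chrom and self.loc_b.strand == self.loc_a.strand


@dataclass
class Event:
    """A typed difference between one read and the genome."""

    kind: str  # error | snv | insertion | deletion | splice | chimera
    read_id: str
    read_pos: int
    chrom: str
    strand: int
    pos: int  # forward-strand coordinate (first deleted base for gaps)
    p: int = 0
    chrom2: str | None = None
    strand2: int | None = None
    pos2: int | None = None  # last deleted base for gaps; 3' anchor for chimeras
    chimera_class: int | None = None
    inserted: str | None = None
    ref: str | None = None
    alt: str | None = None
    s_in: float = 0.0
    s_out: float = 0.0

    @property
    def key(self) -> tuple:
        """Canonical identity of the genomic event, stable across reads and
        read orientations."""
        if self.kind in ("snv", "error"):
            return (self.kind, self.chrom, self.pos)
        if self.kind == "insertion":
            return ("insertion", self.chrom, self.pos, self.p)
        if self.kind == "deletion":
            return ("deletion", self.chrom, self.pos, self.p)
        if self.kind == "splice":
            return ("splice", self.chrom, self.pos, self.pos2)
        return ("chimera",) + normalize_chimera_key(
            self.chrom, self.strand, self.pos, self.chrom2, self.strand2, self.pos2
        )


def normalize_chimera_key(
    chrom5: str, strand5: int, pos5: int, chrom3: str, strand3: int, pos3: int
) -> tuple:
    """Orientation-free identity of a chimeric junction.

    Read as 5'->3' the junction is (anchor5, anchor3); the reverse
    complement read sees (anchor3 flipped, anchor5 flipped).  The smaller
    tuple of the two is the canonical key.
    """
    a = ((chrom5, strand5, pos5), (chrom3, strand3, pos3))
    b = ((chrom3, -strand3, pos3), (chrom5, -strand5, pos5))
    return min(a, b)


# ---------------------------------------------------------------------------
# Rule 1 and its slid generalization
# ---------------------------------------------------------------------------


def rule1_classify(l: int, L: int, k: int) -> tuple[str, int]:
    """The difference rule for an unambiguous colinear break.

    Returns one of ``("substitution", 0)``, ``("deletion", p)``,
    ``("insertion", p)``, ``("none", 0)``; exactly one case holds for any
    (l, L) pair.
    """
    if l == k + 1 and L == k + 1:
        return ("substitution", 0)
    if l == k and L > k:
        return ("deletion", L - k)
    if L == k and l > k:
        return ("insertion", l - k)
    return ("none", 0)


def classify_colinear(l: int, L: int, k: int) -> tuple[str, int]:
    """Difference rule extended to junction-slid breaks.

    When the read sequence matches the genome across a gap or insertion
    boundary, flanking k-mers extend into the event: l (and L) shrink by
    the slide amount while ``L - l`` still equals the signed difference
    size.  A gap keeps ``l <= k`` and an insertion keeps ``L <= k``, so
    the shape remains recognizable.
    """
    kind, p = rule1_classify(l, L, k)
    if kind != "none":
        return kind, p
    d = L - l
    if d > 0 and l <= k:
        return ("deletion", d)
    if d < 0 and 1 <= L <= k:
        # L < 1 would mean the flanks stand still or run backward on the
        # genome: an inverted-order junction, not an insertion
        return ("insertion", -d)
    return ("none", 0)


def check_concordance(pair: FlankPair, l: int, p: int) -> bool:
    """Flanks on one chromosome and strand with L = l +/- the inferred
    difference (0 for a substitution, p for an indel), and coherent
    delta-neighbourhoods on both sides."""
    if not pair.colinear:
        return False
    if pair.L not in (l, l + p, l - p):
        return False
    return pair.coherent_b and pair.coherent_a


def classify_gap(p: int, d_max: int) -> str:
    """Split colinear gaps into short deletions and splice junctions by
    size alone; splice-site consensus sequences are never consulted."""
    if p < 1:
        raise ValueError("gap size must be >= 1")
    return "deletion" if p <= d_max else "splice"


def classify_chimera(pair: FlankPair) -> int | None:
    """Five-way subclass of a non-colinear junction, or None if the pair
    is plainly colinear (same chromosome/strand, forward order, no
    overlap).

    1: different chromosomes, same strand;  2: different chromosomes,
    strand change;  3: same chromosome, strand change;  4: same
    chromosome/strand, inverted order;  5: same chromosome/strand, short
    backward jump overlapping the break (repeat-inducing inversion).
    """
    b, a = pair.loc_b, pair.loc_a
    if b.chrom != a.chrom:
        return 1 if b.strand == a.strand else 2
    if b.strand != a.strand:
        return 3
    if pair.L <= 0:
        return 4
    if pair.L < pair.l:
        return 5
    return None


# ---------------------------------------------------------------------------
# Flank pairs and coherence
# ---------------------------------------------------------------------------


def _coherent_window(lp: LocationProfile, j: int, packed: int, step: int, delta: int) -> bool:
    """True when ``packed`` at index ``j`` chains with its neighbours in
    direction ``step`` over up to ``delta`` contiguous indices.  Unlocated
    neighbours or the profile edge truncate the window; at least one
    neighbour must be checkable — a location with no located neighbour on
    its away side cannot be affirmed coherent."""
    checked = 0
    for d in range(1, delta + 1):
        i = j + step * d
        if i < 0 or i >= len(lp) or not lp.locs[i]:
            break
        if not lp.has_successor(i, packed, step * d):
            return False
        checked += 1
    return checked > 0


def select_flank_locations(
    br: Break, lp: LocationProfile, delta: int
) -> list[FlankPair]:
    """All combinations of flank locations for an interior break, ranked.

    Ordering: pairs admitting a colinear interpretation first (smallest
    |L - l|), then remaining colinear pairs, then chimeric pairs; ties are
    broken by the deterministic location order.  Flank lists are truncated
    to a fixed number of locations for heavily repeated k-mers.
    """
    if br.j_b < 0 or br.j_a >= br.n:
        return []
    k = lp.k
    locs_b = lp.locs[br.j_b][:_MAX_FLANK_LOCS]
    locs_a = lp.locs[br.j_a][:_MAX_FLANK_LOCS]
    pairs: list[FlankPair] = []
    coh_b: dict[int, bool] = {}
    coh_a: dict[int, bool] = {}
    for pb in locs_b:
        if pb not in coh_b:
            coh_b[pb] = _coherent_window(lp, br.j_b, pb, -1, delta)
        for pa in locs_a:
            if pa not in coh_a:
                coh_a[pa] = _coherent_window(lp, br.j_a, pa, +1, delta)
            lb, la = _decode(lp, pb), _decode(lp, pa)
            pairs.append(
                FlankPair(
                    loc_b=lb,
                    loc_a=la,
                    packed_b=pb,
                    packed_a=pa,
                    l=br.l,
                    L=la.projected - lb.projected,
                    coherent_b=coh_b[pb],
                    coherent_a=coh_a[pa],
                )
            )

    def rank(pr: FlankPair) -> tuple:
        if pr.colinear:
            kind, _ = classify_colinear(pr.l, pr.L, k)
            grp = 0 if kind != "none" else 1
            dist = abs(pr.L - pr.l)
        else:
            grp, dist = 2, 0
        return (grp, dist, pr.packed_b, pr.packed_a)

    pairs.sort(key=rank)
    return pairs


def _decode(lp: LocationProfile, packed: int) -> GenomeLocation:
    from .genome import _STRAND_SHIFT, _CHROM_SHIFT, _POS_MASK

    chrom = lp.chrom_names[packed >> _CHROM_SHIFT]
    strand = -1 if (packed >> _STRAND_SHIFT) & 1 else 1
    return GenomeLocation(chrom, strand, packed & _POS_MASK)


# ---------------------------------------------------------------------------
# Break verification and fusion against false locations
# ---------------------------------------------------------------------------


def _flank_has_coherent_loc(lp: LocationProfile, j: int, step: int, delta: int) -> bool:
    """Does any location at index ``j`` chain colinearly with the nearest
    located index on its away side?  Skipping over unlocated indices
    catches a false location sitting at the end of a break, whose
    immediate neighbours are the gap itself.  If no located index exists
    within a read-scale horizon, the flank is trusted: a location is never
    discarded without contrary evidence."""
    horizon = lp.k + delta
    nxt = None
    for d in range(1, horizon + 1):
        i = j + step * d
        if i < 0 or i >= len(lp):
            break
        if lp.locs[i]:
            nxt = i
            break
    if nxt is None:
        return True
    off = nxt - j
    return any(lp.has_successor(nxt, packed, off) for packed in lp.locs[j])


def _resolvable(br: Break, lp: LocationProfile, delta: int, k: int) -> bool:
    pairs = select_flank_locations(br, lp, delta)
    for pr in pairs:
        if pr.colinear:
            kind, _ = classify_colinear(br.l, pr.L, k)
            if kind != "none" and pr.coherent_b and pr.coherent_a:
                return True
        if (
            br.l <= k
            and pr.coherent_b
            and pr.coherent_a
            and classify_chimera(pr) is not None
        ):
            return True
    return False


def verify_break(
    breaks: list[Break], lp: LocationProfile, delta: int
) -> list[Break]:
    """Discard flank locations that are incoherent with their neighbours
    when a break admits no colinear or chimeric interpretation, widening
    the break until a trustworthy flank is reached.

    Locations coherent with their neighbours are never discarded, so the
    procedure is the identity on profiles free of false locations.
    """
    k = lp.k
    out: list[Break] = []
    for br in breaks:
        if br.border or _resolvable(br, lp, delta, k):
            out.append(br)
            continue
        j_b, j_a = br.j_b, br.j_a
        discarded = list(br.discarded)
        for _ in range(32):  # safety bound; each step strictly widens
            cur = Break(j_b, j_a, br.n, tuple(discarded))
            if cur.border or _resolvable(cur, lp, delta, k):
                break
            trimmed = False
            if j_b >= 0 and lp.locs[j_b] and not _flank_has_coherent_loc(lp, j_b, -1, delta):
                discarded.append(j_b)
                j_b -= 1
                while j_b >= 0 and not lp.locs[j_b]:
                    j_b -= 1
                if j_b < 0:
                    j_b = SENTINEL
                trimmed = True
            elif j_a < br.n and lp.locs[j_a] and not _flank_has_coherent_loc(lp, j_a, +1, delta):
                discarded.append(j_a)
                j_a += 1
                while j_a < br.n and not lp.locs[j_a]:
                    j_a += 1
                trimmed = True
            if not trimmed:
                break
        out.append(Break(j_b, j_a, br.n, tuple(discarded)))
    return out


def fuse_breaks(breaks: list[Break], lp: LocationProfile, g: int) -> list[Break]:
    """Merge mirage breaks: two consecutive breaks separated by at most
    ``g`` matched indices whose locations are coherent with neither outer
    flank are one break; the intervening false locations are discarded."""
    if len(breaks) < 2:
        return list(breaks)
    breaks = list(breaks)
    changed = True
    while changed:
        changed = False
        for i in range(len(breaks) - 1):
            b1, b2 = breaks[i], breaks[i + 1]
            run = list(range(b1.j_a, b2.j_b + 1))
            if len(run) > g:
                continue
            if _run_coheres_with_outer(lp, run, b1.j_b, b2.j_a):
                continue
            merged = Break(
                b1.j_b,
                b2.j_a,
                b1.n,
                tuple(sorted(set(b1.discarded) | set(b2.discarded) | set(run))),
            )
            breaks[i : i + 2] = [merged]
            changed = True
            break
    return breaks


def _run_coheres_with_outer(
    lp: LocationProfile, run: list[int], left: int, right: int
) -> bool:
    """True if some intervening index chains with an outer flank location."""
    for i in run:
        if left >= 0 and lp.locs[left]:
            if any(lp.has_successor(i, pb, i - left) for pb in lp.locs[left]):
                return True
        if right < len(lp) and lp.locs[right]:
            if any(lp.has_successor(i, pa, i - right) for pa in lp.locs[right]):
                return True
    return False


# ---------------------------------------------------------------------------
# Break resolution: one disposition per break
# ---------------------------------------------------------------------------


def _fwd_of_read_pos(loc: GenomeLocation, j: int, t: int, k: int) -> int:
    """Forward-strand coordinate of read position ``t`` extrapolated from
    the location of k-mer ``j``."""
    if loc.strand > 0:
        return loc.pos + (t - j)
    return loc.pos + k - 1 - (t - j)


_COMP1 = {"A": "T", "C": "G", "G": "C", "T": "A"}


def canonical_chimera_anchors(
    genome,
    chrom5: str,
    strand5: int,
    pos5: int,
    chrom3: str,
    strand3: int,
    pos3: int,
    max_slide: int = 50,
) -> tuple[int, int]:
    """Canonical placement of a chimeric junction.

    When the bases flanking the junction are identical on both partners
    the junction point can slide; all equivalent placements are
    enumerated and the one minimizing the orientation-normalized key is
    kept, so the canonical anchors do not depend on which strand the
    junction was read from.
    """
    seq5 = genome.sequence(chrom5)
    seq3 = genome.sequence(chrom3)

    def base(seq: str, strand: int, p: int) -> str | None:
        if p < 0 or p >= len(seq):
            return None
        b = seq[p]
        if b not in _COMP1:
            return None
        return b if strand > 0 else _COMP1[b]

    placements = [(pos5, pos3)]
    p5, p3 = pos5, pos3
    for _ in range(max_slide):  # slide left: 5' base becomes the 3' start
        b = base(seq5, strand5, p5)
        if b is None or b != base(seq3, strand3, p3 - strand3):
            break
        p5, p3 = p5 - strand5, p3 - strand3
        placements.append((p5, p3))
    p5, p3 = pos5, pos3
    for _ in range(max_slide):  # slide right: 3' base becomes the 5' end
        b = base(seq3, strand3, p3)
        if b is None or b != base(seq5, strand5, p5 + strand5):
            break
        p5, p3 = p5 + strand5, p3 + strand3
        placements.append((p5, p3))
    return min(
        placements,
        key=lambda pp: normalize_chimera_key(
            chrom5, strand5, pp[0], chrom3, strand3, pp[1]
        ),
    )


def _normalize_gap(seq: str, lo: int, hi: int) -> tuple[int, int]:
    """Slide a genomic gap [lo, hi] to its leftmost equivalent placement."""
    while lo > 0 and seq[lo - 1] == seq[hi]:
        lo -= 1
        hi -= 1
    return lo, hi


def _normalize_insertion(seq: str, x: int, ins: str) -> tuple[int, str]:
    """Slide an insertion (before position x) to its leftmost placement."""
    while x > 0 and ins and ins[-1] == seq[x - 1]:
        ins = seq[x - 1] + ins[:-1]
        x -= 1
    return x, ins


def resolve_break(
    br: Break,
    lp: LocationProfile,
    verdict: SupportVerdict,
    gidx: GenomeIndex,
    params: Params,
    read_id: str,
    seq: str,
) -> tuple[str, Event | None]:
    """Assign one disposition to a break and build its event if resolved.

    Returns ``(disposition, event)`` where disposition is the event kind
    for resolved breaks and ``undetermined`` / ``bio_undetermined``
    otherwise (border cases, too-low or contradictory support, shapes not
    covered by any rule).
    """
    k = lp.k
    low = verdict.verdict == "undetermined"
    dropping = verdict.verdict == "dropping"
    fallback = "undetermined" if (low or dropping) else "bio_undetermined"
    if br.border:
        return (fallback, None)
    pairs = select_flank_locations(br, lp, params.delta)
    if not pairs:
        return (fallback, None)
    l = br.l
    j_a = br.j_a

    # colinear interpretations first
    for pair in pairs:
        if not pair.colinear or not (pair.coherent_b and pair.coherent_a):
            continue
        kind, p = classify_colinear(l, pair.L, k)
        if kind == "none":
            continue
        if low:
            return ("undetermined", None)
        genome_seq = gidx.genome.sequence(pair.loc_a.chrom)
        strand = pair.loc_a.strand
        if dropping:
            # read-private difference: a sequencing error at the break end
            read_pos = j_a - 1
            fwd = _fwd_of_read_pos(pair.loc_a, j_a, read_pos, k)
            alt = seq[read_pos] if strand > 0 else revcomp(seq[read_pos])
            ref = genome_seq[fwd] if 0 <= fwd < len(genome_seq) else None
            ev = Event(
                "error", read_id, read_pos, pair.loc_a.chrom, strand, fwd,
                p=p, ref=ref, alt=alt, s_in=verdict.s_in, s_out=verdict.s_out,
            )
            return ("error", ev)
        if kind == "substitution":
            read_pos = j_a - 1
            fwd = _fwd_of_read_pos(pair.loc_a, j_a, read_pos, k)
            alt = seq[read_pos] if strand > 0 else revcomp(seq[read_pos])
            ref = genome_seq[fwd] if 0 <= fwd < len(genome_seq) else None
            ev = Event(
                "snv", read_id, read_pos, pair.loc_a.chrom, strand, fwd,
                ref=ref, alt=alt, s_in=verdict.s_in, s_out=verdict.s_out,
            )
            return ("snv", ev)
        if kind == "insertion":
            ins_read = seq[j_a - p : j_a]
            if strand > 0:
                x, ins = pair.loc_a.pos, ins_read
            else:
                x, ins = pair.loc_a.pos + k, revcomp(ins_read)
            x, ins = _normalize_insertion(genome_seq, x, ins)
            ev = Event(
                "insertion", read_id, j_a - p, pair.loc_a.chrom, strand, x,
                p=p, inserted=ins, s_in=verdict.s_in, s_out=verdict.s_out,
            )
            return ("insertion", ev)
        # deletion-shaped gap: short deletion or splice junction
        if strand > 0:
            lo = pair.loc_b.pos + l
            hi = pair.loc_a.pos - 1
        else:
            lo = pair.loc_a.pos + k
            hi = pair.loc_b.pos + k - 1 - l
        lo, hi = _normalize_gap(genome_seq, lo, hi)
        gap_kind = classify_gap(p, params.d_max)
        if gap_kind == "splice" and params.max_splice is not None and p > params.max_splice:
            return ("bio_undetermined", None)
        ev = Event(
            gap_kind, read_id, j_a, pair.loc_a.chrom, strand, lo,
            p=p, pos2=hi, chrom2=pair.loc_a.chrom, strand2=strand,
            s_in=verdict.s_in, s_out=verdict.s_out,
        )
        return (gap_kind, ev)

    # chimeric interpretations: break length at most k, coherent flanks
    if l <= k:
        for pair in pairs:
            if not (pair.coherent_b and pair.coherent_a):
                continue
            cls = classify_chimera(pair)
            if cls is None:
                continue
            if verdict.verdict != "non_dropping":
                # a collapsing or too-low support profile cannot back a
                # chimeric junction
                return ("undetermined", None)
            pos5 = _fwd_of_read_pos(pair.loc_b, br.j_b, j_a - 1, k)
            pos3 = _fwd_of_read_pos(pair.loc_a, j_a, j_a, k)
            pos5, pos3 = canonical_chimera_anchors(
                gidx.genome, pair.loc_b.chrom, pair.loc_b.strand, pos5,
                pair.loc_a.chrom, pair.loc_a.strand, pos3,
            )
            ev = Event(
                "chimera", read_id, j_a, pair.loc_b.chrom, pair.loc_b.strand,
                pos5, chrom2=pair.loc_a.chrom, strand2=pair.loc_a.strand,
                pos2=pos3, chimera_class=cls,
                s_in=verdict.s_in, s_out=verdict.s_out,
            )
            return ("chimera", ev)

    return (fallback, None)
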