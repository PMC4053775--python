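"""Per-read orchestration: profiles -> breaks -> events -> category.

Each read is analyzed independently: compute both profiles, detect breaks,
fuse mirage breaks, verify flanks against false locations, then resolve
every break with its own support verdict.  The read's mapping status
(unique / multiple / none / duplicated / too_short) is decided from the
coherent location chains of its matched k-mer blocks, independently of
whether individual breaks could be resolved, so a read whose junction sits
too close to an extremity is still located by its main block.

Identical events found in different reads share a canonical key and are
aggregated into candidates with supporting read counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .events import Event, fuse_breaks, resolve_break, verify_break
from .genome import GenomeIndex, _POS_MASK
from .params import Params
from .profiling import (
    Break,
    LocationProfile,
    classify_support_over_break,
    compute_location_profile,
    compute_support_profile,
    find_breaks,
)
from .reads import ReadCollection, SupportIndex, build_support_index

_COLINEAR_KINDS = {"snv", "deletion", "splice", "insertion", "error"}


@dataclass
class Alignment:
    """Primary alignment of a read: leftmost forward position and CIGAR-like
    operations in read orientation (M/I/D/N plus terminal soft clips)."""

    chrom: str
    strand: int
    pos: int  # 0-based leftmost forward coordinate of the aligned span
    ops: list[tuple[str, int]]


@dataclass
class ReadAnnotation:
    """Analysis outcome for one read."""

    read_id: str
    m: int
    status: str  # unique | multiple | none | duplicated | too_short
    primary: tuple[int, str, int, int] | None = None  # (read offset, chrom, strand, fwd)
    n_chains: int = 0
    secondary: list[tuple[int, str, int, int]] = field(default_factory=list)
    events: list[Event] = field(default_factory=list)
    labels: set[str] = field(default_factory=set)
    alignment: Alignment | None = None


@dataclass
class EventCandidate:
    """An event aggregated across the reads that detected it."""

    key: tuple
    kind: str
    n_reads: int
    mean_support: float
    read_ids: list[str]
    event: Event  # representative


def _blocks(lp: LocationProfile, discarded: set[int]) -> list[tuple[int, int]]:
    """Maximal runs [s, e] of indices with usable locations."""
    out: list[tuple[int, int]] = []
    s = None
    for i in range(len(lp)):
        usable = lp.counts[i] > 0 and i not in discarded
        if usable and s is None:
            s = i
        elif not usable and s is not None:
            out.append((s, i - 1))
            s = None
    if s is not None:
        out.append((s, len(lp) - 1))
    return out


def _block_chains(lp: LocationProfile, s: int, e: int) -> list[int]:
    """Packed start locations whose colinear continuation spans [s, e]."""
    cands = list(lp.locs[s])
    for i in range(s + 1, e + 1):
        cands = [c for c in cands if lp.has_successor(i, c, i - s)]
        if not cands:
            break
    return cands


def _fwd_at(packed: int, strand: int, k: int, within_kmer: int = 0) -> int:
    pos = packed & _POS_MASK
    return pos + within_kmer if strand > 0 else pos + k - 1 - within_kmer


def _decode_primary(lp: LocationProfile, s: int, packed: int) -> tuple[int, str, int, int]:
    from .events import _decode

    loc = _decode(lp, packed)
    fwd = loc.pos if loc.strand > 0 else loc.pos + lp.k - 1
    return (s, loc.chrom, loc.strand, fwd)


def analyze_read(
    read_id: str,
    seq: str,
    gidx: GenomeIndex,
    sidx: SupportIndex,
    params: Params,
) -> ReadAnnotation:
    """Full single-read analysis against both indexes."""
    k = gidx.k
    if sidx.k != k:
        raise ValueError("genome and support indexes were built with different k")
    m = len(seq)
    if m < k:
        return ReadAnnotation(read_id, m, "too_short", labels={"too_short"})

    lp = compute_location_profile(read_id, seq, gidx)
    sp = compute_support_profile(read_id, seq, sidx)
    matched0 = [i for i, c in enumerate(lp.counts) if c > 0]

    breaks = find_breaks(lp)
    breaks = fuse_breaks(breaks, lp, params.fusion_gap)
    breaks = verify_break(breaks, lp, params.delta)
    discarded: set[int] = set()
    for br in breaks:
        discarded.update(br.discarded)

    ann = ReadAnnotation(read_id, m, "none")

    # ---- events ----------------------------------------------------------
    for br in breaks:
        verdict = classify_support_over_break(sp, br, params, outside=matched0)
        disposition, ev = resolve_break(br, lp, verdict, gidx, params, read_id, seq)
        ann.labels.add(disposition)
        if ev is not None:
            ann.events.append(ev)
    if not breaks:
        ann.labels.add("clean")

    # ---- mapping status --------------------------------------------------
    blocks = _blocks(lp, discarded)
    if not blocks:
        ann.status = "none"
        return ann
    if matched0 and all(lp.counts[i] > params.duplication for i in matched0):
        ann.status = "duplicated"
        return ann
    anchor = max(blocks, key=lambda se: (se[1] - se[0], -se[0]))
    chains = _block_chains(lp, *anchor)
    ann.n_chains = len(chains)
    if len(chains) == 1:
        ann.status = "unique"
        ann.primary = _decode_primary(lp, anchor[0], chains[0])
        ann.alignment = _build_alignment(lp, blocks, breaks, ann.events, anchor, chains[0])
    elif len(chains) > 1:
        ann.status = "multiple"
        ann.primary = _decode_primary(lp, anchor[0], chains[0])
        ann.secondary = [_decode_primary(lp, anchor[0], c) for c in chains[1:]]
    else:
        ann.status = "multiple"  # located but no single coherent chain
    return ann


def _event_L(kind: str, l: int, p: int) -> int | None:
    """Genomic offset L across a resolved colinear break of read offset l."""
    if kind in ("snv",) or (kind == "error" and p == 0):
        return l
    if kind in ("deletion", "splice"):
        return l + p
    if kind == "insertion":
        return l - p
    return None


def _build_alignment(
    lp: LocationProfile,
    blocks: list[tuple[int, int]],
    breaks: list[Break],
    events: list[Event],
    anchor: tuple[int, int],
    chain: int,
) -> Alignment | None:
    """Chain the anchor block outward across resolved colinear breaks.

    Blocks that cannot be connected (chimeric or unresolved breaks,
    inconsistent locations) are soft-clipped.  Returns operations in read
    orientation; the SAM writer flips them for reverse-strand records.
    """
    from .events import _decode

    k = lp.k
    m = lp.m
    idx = blocks.index(anchor)
    loc0 = _decode(lp, chain)
    strand = loc0.strand

    # walk right
    joins_right: list[tuple[Break, Event, int]] = []  # (break, event, next chain packed)
    cur_packed = chain
    cur_s, cur_e = anchor
    connected = [(cur_s, cur_e, chain)]
    for nb in range(idx + 1, len(blocks)):
        s1, e1 = blocks[nb]
        br = next((b for b in breaks if b.j_b == cur_e and b.j_a == s1), None)
        ev = _match_event(br, events) if br else None
        L = _event_L(ev.kind, br.l, ev.p) if (ev and br) else None
        if L is None:
            break
        delta_packed = (cur_e - cur_s) + L
        target = cur_packed + delta_packed if strand > 0 else cur_packed - delta_packed
        if target not in lp.loc_set(s1):
            break
        joins_right.append((br, ev, target))
        connected.append((s1, e1, target))
        cur_packed, cur_s, cur_e = target, s1, e1

    # walk left
    cur_packed = chain
    cur_s, cur_e = anchor
    joins_left: list[tuple[Break, Event, int]] = []
    for nb in range(idx - 1, -1, -1):
        s0, e0 = blocks[nb]
        br = next((b for b in breaks if b.j_b == e0 and b.j_a == cur_s), None)
        ev = _match_event(br, events) if br else None
        L = _event_L(ev.kind, br.l, ev.p) if (ev and br) else None
        if L is None:
            break
        delta_packed = (cur_s - s0 - br.l) + L  # c(cur_s) - c(s0)
        target = cur_packed - delta_packed if strand > 0 else cur_packed + delta_packed
        if target not in lp.loc_set(s0):
            break
        joins_left.append((br, ev, target))
        connected.insert(0, (s0, e0, target))
        cur_packed, cur_s, cur_e = target, s0, e0

    # assemble ops in read orientation
    first_s = connected[0][0]
    last_e = connected[-1][1]
    aligned_end = last_e + k - 1  # inclusive read position
    ops: list[tuple[str, int]] = []
    if first_s > 0:
        ops.append(("S", first_s))
    cur_read = first_s
    for (s, e, _), (br, ev, _) in zip(connected, joins_left[::-1] + joins_right):
        j_a = br.j_a
        if ev.kind in ("snv",) or (ev.kind == "error" and ev.p == 0):
            continue  # M runs straight through a substitution
        if ev.kind == "insertion":
            r_i = j_a - ev.p
            ops.append(("M", r_i - cur_read))
            ops.append(("I", ev.p))
            cur_read = j_a
        else:  # deletion or splice gap
            ops.append(("M", j_a - cur_read))
            ops.append(("N" if ev.kind == "splice" else "D", ev.p))
            cur_read = j_a
    ops.append(("M", aligned_end + 1 - cur_read))
    if aligned_end + 1 < m:
        ops.append(("S", m - aligned_end - 1))
    ops = [(op, n) for op, n in ops if n > 0]

    # leftmost forward coordinate of the aligned span
    if strand > 0:
        pos = connected[0][2] & _POS_MASK
    else:
        pos = connected[-1][2] & _POS_MASK
    return Alignment(loc0.chrom, strand, pos, ops)


def _match_event(br: Break | None, events: list[Event]) -> Event | None:
    """Find the colinear event resolved from a given break, if any."""
    if br is None:
        return None
    for ev in events:
        if ev.kind not in _COLINEAR_KINDS:
            continue
        # events record the read position at/just after the break end
        if br.j_b < ev.read_pos <= br.j_a:
            return ev
    return None


def aggregate_events(
    annotations: list[ReadAnnotation], min_reads: int = 1
) -> list[EventCandidate]:
    """Group identical events across reads by canonical key."""
    groups: dict[tuple, list[Event]] = {}
    readers: dict[tuple, set[str]] = {}
    for ann in annotations:
        for ev in ann.events:
            key = ev.key
            groups.setdefault(key, []).append(ev)
            readers.setdefault(key, set()).add(ev.read_id)
    out: list[EventCandidate] = []
    for key, evs in groups.items():
        ids = sorted(readers[key])
        out.append(
            EventCandidate(
                key=key,
                kind=evs[0].kind,
                n_reads=len(ids),
                mean_support=sum(e.s_in for e in evs) / len(evs),
                read_ids=ids[:5],
                event=evs[0],
            )
        )
    out.sort(key=lambda c: c.key)
    return [c for c in out if c.n_reads >= min_reads]


def analyze_collection(
    gidx: GenomeIndex,
    reads: ReadCollection,
    params: Params,
    sidx: SupportIndex | None = None,
) -> list[ReadAnnotation]:
    """Analyze every read of a collection against a genome index, building
    the support index over the same collection unless one is supplied."""
    if sidx is None:
        sidx = build_support_index(reads, gidx.k, params.support_mode)
    return [analyze_read(rid, seq, gidx, sidx, params) for rid, seq in reads]
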