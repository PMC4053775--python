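"""Ground-truth RNA-seq simulation.

The benchmarking protocol: alter a reference genome with random
substitutions and small indels, splice transcripts from gene models, fuse
a few transcript pairs into chimeric RNAs, draw reads along transcripts
under a heavy-tailed expression law, and inject per-base substitution
sequencing errors — recording, for every planted variant, junction and
fusion, and for every read, exact reference-coordinate ground truth.

All truth coordinates are in REFERENCE space (the genome the analyzer maps
against), left-normalized exactly like the analyzer's calls so that a
correct prediction matches its truth record key for key.

Coordinate liftover between the mutated and the reference genome is kept
as an explicit per-chromosome chain; indels are never planted across an
exon boundary, so gene models lift exactly.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np

from ._kmers import revcomp
from .events import (
    _normalize_gap,
    _normalize_insertion,
    canonical_chimera_anchors,
    normalize_chimera_key,
)
from .genome import ReferenceGenome
from .reads import ReadCollection

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


# ---------------------------------------------------------------------------
# Gene models and reference generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """A gene: ordered, non-overlapping exons on one chromosome strand.

    Exon coordinates are 0-based half-open and ascending regardless of
    strand; the mature transcript of a minus-strand gene is the reverse
    complement of the concatenated exons.
    """

    name: str
    chrom: str
    strand: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        prev_end = None
        for s, e in self.exons:
            if e - s < 1:
                raise ValueError(f"{self.name}: empty exon")
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"{self.name}: exons overlap or touch")
            prev_end = e

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class GenomeParams:
    """Shape of the synthetic reference: a small low-repeat genome densely
    populated with spliced genes, standing in for a human-scale setup at
    desk scale."""

    genome_size: int = 2_000_000
    n_chroms: int = 2
    n_genes: int = 300
    exon_mean: float = 150.0
    exon_sigma: float = 0.45
    exon_min: int = 40
    exon_max: int = 500
    intron_mean: float = 400.0
    intron_sigma: float = 0.8
    intron_min: int = 30
    intron_max: int = 5000
    exons_poisson: float = 3.5
    max_exons: int = 10


def generate_reference(
    params: GenomeParams, seed: int
) -> tuple[ReferenceGenome, list[GeneModel]]:
    """Random genome plus non-overlapping gene models, reproducible from
    the seed."""
    rng = np.random.default_rng(seed)
    chrom_len = params.genome_size // params.n_chroms
    chroms = [(f"chr{i + 1}", _random_seq(rng, chrom_len)) for i in range(params.n_chroms)]
    genome = ReferenceGenome(chroms)
    models: list[GeneModel] = []
    cursors = [0] * params.n_chroms
    for g in range(params.n_genes):
        n_ex = int(min(1 + rng.poisson(params.exons_poisson), params.max_exons))
        ex_lens = np.clip(
            np.round(rng.lognormal(np.log(params.exon_mean), params.exon_sigma, n_ex)),
            params.exon_min,
            params.exon_max,
        ).astype(int)
        in_lens = np.clip(
            np.round(rng.lognormal(np.log(params.intron_mean), params.intron_sigma, max(n_ex - 1, 0))),
            params.intron_min,
            params.intron_max,
        ).astype(int)
        span = int(ex_lens.sum() + in_lens.sum())
        gap = int(100 + rng.integers(0, 400))
        ci = None
        for cand in np.argsort(cursors):
            if cursors[cand] + gap + span <= chrom_len:
                ci = int(cand)
                break
        if ci is None:
            raise ValueError(
                f"gene {g} does not fit: genome too small for {params.n_genes} genes"
            )
        start = cursors[ci] + gap
        exons = []
        pos = start
        for i, el in enumerate(ex_lens):
            exons.append((pos, pos + int(el)))
            pos += int(el)
            if i < n_ex - 1:
                pos += int(in_lens[i])
        cursors[ci] = pos
        strand = 1 if rng.random() < 0.5 else -1
        models.append(GeneModel(f"g{g:04d}", f"chr{ci + 1}", strand, tuple(exons)))
    return genome, models


# ---------------------------------------------------------------------------
# Genome mutation and the truth ledger
# ---------------------------------------------------------------------------


@dataclass
class MutationRates:
    snv_rate: float = 1e-3
    indel_rate: float = 2e-4
    ins_fraction: float = 0.5
    indel_size_p: float = 0.35  # geometric; sizes clipped to indel_max
    indel_max: int = 10
    n_fusions: int = 0

    def validate(self) -> None:
        for r in (self.snv_rate, self.indel_rate, self.ins_fraction):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be within [0, 1]")


@dataclass
class Variant:
    kind: str  # snv | insertion | deletion
    chrom: str
    pos: int  # canonical (left-normalized) reference coordinate
    size: int = 0
    ref: str | None = None
    alt: str | None = None
    seq: str | None = None
    mut_pos: int = -1  # position (snv/boundary/first base) in mutated coords

    @property
    def key(self) -> tuple:
        if self.kind == "snv":
            return ("snv", self.chrom, self.pos)
        return (self.kind, self.chrom, self.pos, self.size)


@dataclass
class FusionTruth:
    name: str
    chrom5: str
    strand5: int
    pos5: int  # ref coordinate of the last 5' base
    chrom3: str
    strand3: int
    pos3: int  # ref coordinate of the first 3' base
    cls: int

    @property
    def key(self) -> tuple:
        return ("chimera",) + normalize_chimera_key(
            self.chrom5, self.strand5, self.pos5, self.chrom3, self.strand3, self.pos3
        )


@dataclass
class ReadTruth:
    """Where one simulated read comes from and what it carries.

    ``segments`` is a piecewise-linear map from read positions to forward
    reference coordinates: tuples ``(r_start, r_len, chrom, g_strand,
    fwd0)`` with fwd(r) = fwd0 + g_strand * (r - r_start).  ``events``
    lists (canonical key, flank) for every planted event the read covers,
    flank being the distance to the nearer read end.
    """

    segments: list[tuple[int, int, str, int, int]]
    events: list[tuple[tuple, int]] = field(default_factory=list)
    error_read_pos: list[int] = field(default_factory=list)
    error_refs: list[tuple[str, int]] = field(default_factory=list)

    def fwd_at(self, r: int) -> tuple[str, int, int] | None:
        """(chrom, strand, forward coordinate) at read position r."""
        for r0, rl, chrom, gs, f0 in self.segments:
            if r0 <= r < r0 + rl and gs != 0:
                return chrom, gs, f0 + gs * (r - r0)
        return None


@dataclass
class Chain:
    """mutated <-> reference coordinate map for one chromosome."""

    # copied segments: parallel arrays sorted by mut_start
    mut_starts: list[int]
    mut_ends: list[int]
    deltas: list[int]  # ref = mut + delta
    # inserted (mutated-only) regions: (mut_start, mut_end, ref_anchor)
    insertions: list[tuple[int, int, int]]

    def ref_to_mut(self, r: int) -> int:
        ref_starts = [ms + d for ms, d in zip(self.mut_starts, self.deltas)]
        i = bisect.bisect_right(ref_starts, r) - 1
        if i < 0:
            raise ValueError(f"reference position {r} precedes the first segment")
        return r - self.deltas[i]

    def mut_to_ref(self, m: int) -> int:
        i = bisect.bisect_right(self.mut_starts, m) - 1
        return m + self.deltas[max(i, 0)]


@dataclass
class TruthLedger:
    """Complete ground truth of one simulated dataset."""

    variants: list[Variant] = field(default_factory=list)
    junctions: list[tuple] = field(default_factory=list)  # canonical splice keys
    fusions: list[FusionTruth] = field(default_factory=list)
    reads: dict[str, ReadTruth] = field(default_factory=dict)
    chains: dict[str, Chain] = field(default_factory=dict)
    fusion_specs: list[tuple] = field(default_factory=list)  # (gene5, n_ex5, gene3, n_ex3, name)


def mutate_genome(
    genome: ReferenceGenome,
    models: list[GeneModel],
    rates: MutationRates,
    seed: int,
) -> tuple[ReferenceGenome, list[GeneModel], TruthLedger]:
    """Plant substitutions and small indels; derive the mutated genome,
    lift the gene models onto it, and pick fusion transcript pairs.

    Indels are rejected when their footprint comes within a few bases of
    an exon boundary (so models lift exactly and splice truth stays
    unambiguous) or of another indel.  Junction truth (canonical intron
    intervals of every model) is recorded here as well.
    """
    rates.validate()
    rng = np.random.default_rng(seed)
    ledger = TruthLedger()
    boundaries: dict[str, list[int]] = {name: [] for name, _ in genome.chromosomes}
    for mdl in models:
        for s, e in mdl.exons:
            boundaries[mdl.chrom].extend((s, e))
    for b in boundaries.values():
        b.sort()

    mut_chroms: list[tuple[str, str]] = []
    for name, seq in genome.chromosomes:
        L = len(seq)
        bset = boundaries[name]

        # --- indels (coordinate-changing) ---------------------------------
        cand = np.flatnonzero(rng.random(L) < rates.indel_rate)
        indels: list[tuple[int, str, int, str | None]] = []
        last_end = -(10**9)
        for x in cand:
            x = int(x)
            p = int(min(rng.geometric(rates.indel_size_p), rates.indel_max))
            kind = "insertion" if rng.random() < rates.ins_fraction else "deletion"
            lo, hi = x - 1, x + p + 1
            if lo < 1 or hi >= L - 1:
                continue
            if x < last_end + 2 * rates.indel_max + 4:
                continue
            i = bisect.bisect_left(bset, lo - 4)
            if i < len(bset) and bset[i] <= hi + 4:
                continue  # too close to an exon boundary
            S = _random_seq(rng, p) if kind == "insertion" else None
            indels.append((x, kind, p, S))
            last_end = hi
        indel_footprints = [(x - 2, x + p + 2) for x, _, p, _ in indels]

        # --- substitutions (no coordinate change, clear of indels) --------
        arr = np.frombuffer(seq.encode(), dtype="S1").copy()
        snv_pos = np.flatnonzero(rng.random(L) < rates.snv_rate)
        for x in snv_pos:
            x = int(x)
            ref_b = seq[x]
            if ref_b not in "ACGT":
                continue
            if any(lo <= x <= hi for lo, hi in indel_footprints):
                continue
            alt = "ACGT".replace(ref_b, "")[int(rng.integers(0, 3))]
            arr[x] = alt.encode()
            ledger.variants.append(Variant("snv", name, x, ref=ref_b, alt=alt))
        sub_seq = arr.tobytes().decode()

        # --- apply indels, building the chain -----------------------------
        parts: list[str] = []
        mut_starts, mut_ends, deltas = [], [], []
        ins_regions: list[tuple[int, int, int]] = []
        ref_cursor = 0
        mut_cursor = 0
        for x, kind, p, S in indels:
            parts.append(sub_seq[ref_cursor:x])
            mut_starts.append(mut_cursor)
            mut_ends.append(mut_cursor + (x - ref_cursor))
            deltas.append(ref_cursor - mut_cursor)
            mut_cursor += x - ref_cursor
            ref_cursor = x
            if kind == "insertion":
                cx, cs = _normalize_insertion(seq, x, S)
                ledger.variants.append(
                    Variant("insertion", name, cx, size=p, seq=cs, mut_pos=mut_cursor)
                )
                parts.append(S)
                ins_regions.append((mut_cursor, mut_cursor + p, x))
                mut_cursor += p
            else:
                clo, chi = _normalize_gap(seq, x, x + p - 1)
                ledger.variants.append(
                    Variant("deletion", name, clo, size=p, mut_pos=mut_cursor)
                )
                ref_cursor += p
        parts.append(sub_seq[ref_cursor:])
        mut_starts.append(mut_cursor)
        mut_ends.append(mut_cursor + (L - ref_cursor))
        deltas.append(ref_cursor - mut_cursor)
        mut_chroms.append((name, "".join(parts)))
        ledger.chains[name] = Chain(mut_starts, mut_ends, deltas, ins_regions)
        # snv mutated coordinates
        chain = ledger.chains[name]
        for v in ledger.variants:
            if v.chrom == name and v.kind == "snv":
                v.mut_pos = chain.ref_to_mut(v.pos)

    mutated = ReferenceGenome(mut_chroms)

    # --- lift gene models onto the mutated genome -------------------------
    lifted: list[GeneModel] = []
    for mdl in models:
        chain = ledger.chains[mdl.chrom]
        exons = tuple(
            (chain.ref_to_mut(s), chain.ref_to_mut(e - 1) + 1) for s, e in mdl.exons
        )
        lifted.append(GeneModel(mdl.name, mdl.chrom, mdl.strand, exons))

    # --- junction truth (reference coordinates, canonical) ----------------
    for mdl in models:
        seq = genome.sequence(mdl.chrom)
        for (s1, e1), (s2, e2) in zip(mdl.exons, mdl.exons[1:]):
            lo, hi = _normalize_gap(seq, e1, s2 - 1)
            ledger.junctions.append(("splice", mdl.chrom, lo, hi))

    # --- fusion pairs ------------------------------------------------------
    n_try = 0
    while len(ledger.fusion_specs) < rates.n_fusions and n_try < 200 * max(rates.n_fusions, 1):
        n_try += 1
        ia, ib = rng.integers(0, len(models), 2)
        if ia == ib:
            continue
        A, B = models[int(ia)], models[int(ib)]
        ca = int(rng.integers(1, len(A.exons) + 1))
        cb = int(rng.integers(1, len(B.exons) + 1))
        truth = _fusion_truth(genome, A, ca, B, cb, len(ledger.fusion_specs))
        if truth is None:
            continue
        part5 = _tx_part_length(A, ca, five_prime=True)
        part3 = _tx_part_length(B, cb, five_prime=False)
        if part5 < 50 or part3 < 50:
            continue
        ledger.fusions.append(truth)
        ledger.fusion_specs.append((A.name, ca, B.name, cb, truth.name))
    if len(ledger.fusion_specs) < rates.n_fusions:
        raise ValueError("could not place the requested number of fusions")
    return mutated, lifted, ledger


def _tx_part_length(mdl: GeneModel, n_ex: int, five_prime: bool) -> int:
    exons = list(mdl.exons) if mdl.strand > 0 else list(mdl.exons)[::-1]
    part = exons[:n_ex] if five_prime else exons[-n_ex:]
    return sum(e - s for s, e in part)


def _fusion_truth(
    genome: ReferenceGenome, A: GeneModel, ca: int, B: GeneModel, cb: int, idx: int
) -> FusionTruth | None:
    """Reference-coordinate anchors and subclass of a transcript fusion;
    None when the junction would be colinear (a plain long splice)."""
    ex_a = list(A.exons) if A.strand > 0 else list(A.exons)[::-1]
    ex_b = list(B.exons) if B.strand > 0 else list(B.exons)[::-1]
    s, e = ex_a[ca - 1]
    pos5 = e - 1 if A.strand > 0 else s
    s, e = ex_b[len(ex_b) - cb]
    pos3 = s if B.strand > 0 else e - 1
    cls = chimera_class_of_anchors(
        A.chrom, A.strand, pos5, B.chrom, B.strand, pos3
    )
    if cls is None:
        return None
    pos5, pos3 = canonical_chimera_anchors(
        genome, A.chrom, A.strand, pos5, B.chrom, B.strand, pos3
    )
    return FusionTruth(
        f"fusion{idx:02d}", A.chrom, A.strand, pos5, B.chrom, B.strand, pos3, cls
    )


def chimera_class_of_anchors(
    chrom5: str, strand5: int, pos5: int, chrom3: str, strand3: int, pos3: int, k: int = 22
) -> int | None:
    """Five-way chimera subclass from junction anchors (read orientation),
    mirroring the analyzer's enumeration for a clean break of length k."""
    if chrom5 != chrom3:
        return 1 if strand5 == strand3 else 2
    if strand5 != strand3:
        return 3
    L = strand3 * pos3 - strand5 * pos5 + k - 1
    if L <= 0:
        return 4
    if L < k:
        return 5
    return None


# ---------------------------------------------------------------------------
# Transcripts (mutated sequence + piecewise reference map)
# ---------------------------------------------------------------------------


@dataclass
class TxBlock:
    """Colinear run of transcript positions.  step is +1/-1 for copied
    genome, 0 for inserted (mutated-only) bases anchored at ref_start."""

    tx_start: int
    length: int
    chrom: str
    ref_start: int
    step: int

    def ref_at(self, tx: int) -> int:
        return self.ref_start + self.step * (tx - self.tx_start)


@dataclass
class Transcript:
    """A mature (spliced, mutated) transcript in 5'->3' orientation."""

    name: str
    seq: str
    blocks: list[TxBlock]
    # marks: ("point"|"boundary"|"span", tx, size, canonical key)
    marks: list[tuple[str, int, int, tuple]]
    exon_bounds: list[int]  # cumulative tx end of each exon, tx orientation

    def __len__(self) -> int:
        return len(self.seq)


def _chain_regions(chain: Chain) -> list[tuple[int, int, int, int]]:
    """Merged (mut_start, mut_end, step, ref_at_start) regions."""
    regions = [
        (ms, me, 1, ms + d)
        for ms, me, d in zip(chain.mut_starts, chain.mut_ends, chain.deltas)
    ]
    regions += [(ms, me, 0, anchor) for ms, me, anchor in chain.insertions]
    regions.sort()
    return regions


def build_transcripts(
    reference: ReferenceGenome,
    mutated: ReferenceGenome,
    models_ref: list[GeneModel],
    models_mut: list[GeneModel],
    ledger: TruthLedger,
) -> list[Transcript]:
    """Mature transcripts for every gene model plus the fused transcripts
    requested at mutation time."""
    by_name: dict[str, Transcript] = {}
    out: list[Transcript] = []
    for mref, mmut in zip(models_ref, models_mut):
        tx = _build_transcript(reference, mutated, mref, mmut, ledger)
        by_name[tx.name] = tx
        out.append(tx)
    for name5, ca, name3, cb, fname in ledger.fusion_specs:
        truth = next(f for f in ledger.fusions if f.name == fname)
        out.append(_build_fusion(by_name[name5], ca, by_name[name3], cb, truth))
    return out


def _build_transcript(
    reference: ReferenceGenome,
    mutated: ReferenceGenome,
    mref: GeneModel,
    mmut: GeneModel,
    ledger: TruthLedger,
) -> Transcript:
    chrom = mref.chrom
    chain = ledger.chains[chrom]
    regions = _chain_regions(chain)
    region_starts = [r[0] for r in regions]
    mut_seq = mutated.sequence(chrom)
    ref_seq = reference.sequence(chrom)
    chrom_variants = [v for v in ledger.variants if v.chrom == chrom]

    blocks: list[TxBlock] = []
    marks: list[tuple[str, int, int, tuple]] = []
    seq_parts: list[str] = []
    exon_bounds: list[int] = []
    tx = 0
    for (rs, re_), (ms, me) in zip(mref.exons, mmut.exons):
        seq_parts.append(mut_seq[ms:me])
        cursor = ms
        while cursor < me:
            i = bisect.bisect_right(region_starts, cursor) - 1
            r_ms, r_me, step, ref0 = regions[i]
            end = min(me, r_me)
            blocks.append(
                TxBlock(tx + (cursor - ms), end - cursor, chrom,
                        ref0 + step * (cursor - r_ms), step)
            )
            cursor = end
        for v in chrom_variants:
            if not (ms <= v.mut_pos < me if v.kind != "deletion" else ms < v.mut_pos < me):
                continue
            t = tx + (v.mut_pos - ms)
            if v.kind == "snv":
                marks.append(("point", t, 0, v.key))
            elif v.kind == "insertion":
                if v.mut_pos + v.size <= me:
                    marks.append(("span", t, v.size, v.key))
            else:
                marks.append(("boundary", t, v.size, v.key))
        tx += me - ms
        exon_bounds.append(tx)
        if len(exon_bounds) < len(mref.exons):
            nxt = mref.exons[len(exon_bounds)]
            lo, hi = _normalize_gap(ref_seq, re_, nxt[0] - 1)
            marks.append(("boundary", tx, hi - lo + 1, ("splice", chrom, lo, hi)))
    seq = "".join(seq_parts)
    if mref.strand < 0:
        seq, blocks, marks = _flip(seq, blocks, marks)
        lens = [e - s for s, e in mmut.exons][::-1]
        exon_bounds = list(np.cumsum(lens))
    marks.sort(key=lambda mk: mk[1])
    return Transcript(mref.name, seq, blocks, marks, exon_bounds)


def _flip(
    seq: str, blocks: list[TxBlock], marks: list[tuple[str, int, int, tuple]]
) -> tuple[str, list[TxBlock], list[tuple[str, int, int, tuple]]]:
    T = len(seq)
    new_blocks = [
        TxBlock(T - (b.tx_start + b.length), b.length, b.chrom,
                b.ref_start + b.step * (b.length - 1), -b.step)
        for b in reversed(blocks)
    ]
    new_marks = []
    for kind, t, size, key in marks:
        if kind == "point":
            new_marks.append((kind, T - 1 - t, size, key))
        elif kind == "boundary":
            new_marks.append((kind, T - t, size, key))
        else:  # span
            new_marks.append((kind, T - (t + size), size, key))
    return revcomp(seq), new_blocks, new_marks


def _slice_tx(
    tx: Transcript, lo: int, hi: int
) -> tuple[str, list[TxBlock], list[tuple[str, int, int, tuple]]]:
    """Re-based [lo, hi) slice of a transcript's sequence, blocks, marks."""
    blocks = []
    for b in tx.blocks:
        a, z = max(b.tx_start, lo), min(b.tx_start + b.length, hi)
        if a < z:
            blocks.append(
                TxBlock(a - lo, z - a, b.chrom, b.ref_at(a), b.step)
            )
    marks = []
    for kind, t, size, key in tx.marks:
        if kind == "boundary" and lo < t < hi:
            marks.append((kind, t - lo, size, key))
        elif kind == "point" and lo <= t < hi:
            marks.append((kind, t - lo, size, key))
        elif kind == "span" and lo <= t and t + size <= hi:
            marks.append((kind, t - lo, size, key))
    return tx.seq[lo:hi], blocks, marks


def _build_fusion(
    tx5: Transcript, ca: int, tx3: Transcript, cb: int, truth: FusionTruth
) -> Transcript:
    cut5 = tx5.exon_bounds[ca - 1]
    cut3 = tx3.exon_bounds[len(tx3.exon_bounds) - cb - 1] if cb < len(tx3.exon_bounds) else 0
    seq5, blocks5, marks5 = _slice_tx(tx5, 0, cut5)
    seq3, blocks3, marks3 = _slice_tx(tx3, cut3, len(tx3))
    off = len(seq5)
    blocks = blocks5 + [
        TxBlock(b.tx_start + off, b.length, b.chrom, b.ref_start, b.step)
        for b in blocks3
    ]
    marks = marks5 + [("boundary", off, 0, truth.key)] + [
        (kind, t + off, size, key) for kind, t, size, key in marks3
    ]
    bounds = [b for b in tx5.exon_bounds if b <= cut5]
    bounds += [off + (b - cut3) for b in tx3.exon_bounds if b > cut3]
    return Transcript(truth.name, seq5 + seq3, blocks, marks, bounds)


# ---------------------------------------------------------------------------
# Read sampling
# ---------------------------------------------------------------------------


def simulate_reads(
    transcripts: list[Transcript],
    ledger: TruthLedger,
    m: int,
    error_rate: float,
    seed: int,
    n_reads: int | None = None,
    coverage: float | None = None,
    expression: np.ndarray | None = None,
    stranded: bool = False,
) -> ReadCollection:
    """Sample reads uniformly along transcripts, weighted by a log-normal
    expression law, inject per-base substitution errors, and record per-
    read ground truth in the ledger.

    ``coverage`` is the target mean number of read bases per transcript
    base over the eligible (length >= m) transcriptome; transcripts
    shorter than the read length are skipped.
    """
    rng = np.random.default_rng(seed)
    eligible = [t for t in transcripts if len(t) >= m]
    if not eligible:
        raise ValueError("no transcript is as long as the read length")
    if expression is None:
        expression = rng.lognormal(mean=1.0, sigma=1.0, size=len(eligible))
    w = expression * np.array([len(t) - m + 1 for t in eligible], dtype=float)
    w = w / w.sum()
    if n_reads is None:
        if coverage is None:
            raise ValueError("give n_reads or coverage")
        n_reads = int(round(coverage * sum(len(t) for t in eligible) / m))
    counts = rng.multinomial(n_reads, w)
    reads: list[tuple[str, str]] = []
    rid = 0
    for t, c in zip(eligible, counts):
        if c == 0:
            continue
        offsets = rng.integers(0, len(t) - m + 1, c)
        strands = np.ones(c, dtype=int) if stranded else rng.choice([1, -1], c)
        for o, s in zip(offsets, strands):
            o, s = int(o), int(s)
            name = f"r{rid:07d}"
            rid += 1
            seq, truth = _make_read(t, o, m, s)
            seq, err_pos = _inject_errors(seq, error_rate, rng)
            for r in err_pos:
                truth.error_read_pos.append(r)
                hit = truth.fwd_at(r)
                if hit is not None:
                    truth.error_refs.append((hit[0], hit[2]))
            reads.append((name, seq))
            ledger.reads[name] = truth
    return ReadCollection(reads)


def _make_read(t: Transcript, o: int, m: int, s: int) -> tuple[str, ReadTruth]:
    seq = t.seq[o : o + m]
    if s < 0:
        seq = revcomp(seq)
    segments: list[tuple[int, int, str, int, int]] = []
    for b in t.blocks:
        a, z = max(b.tx_start, o), min(b.tx_start + b.length, o + m)
        if a >= z:
            continue
        if s > 0:
            r0 = a - o
            fwd0 = b.ref_at(a)
            gs = b.step
        else:
            r0 = o + m - z
            fwd0 = b.ref_at(z - 1)
            gs = -b.step
        segments.append((r0, z - a, b.chrom, gs, fwd0))
    segments.sort()
    truth = ReadTruth(segments)
    for kind, tpos, size, key in t.marks:
        if kind == "point" and o <= tpos < o + m:
            flank = min(tpos - o, o + m - 1 - tpos) + 1
        elif kind == "boundary" and o < tpos < o + m:
            flank = min(tpos - o, o + m - tpos)
        elif kind == "span" and o < tpos and tpos + size < o + m:
            flank = min(tpos - o, o + m - (tpos + size))
        else:
            continue
        truth.events.append((key, flank))
    return seq, truth


def _inject_errors(
    seq: str, error_rate: float, rng: np.random.Generator
) -> tuple[str, list[int]]:
    if error_rate <= 0:
        return seq, []
    pos = np.flatnonzero(rng.random(len(seq)) < error_rate)
    if len(pos) == 0:
        return seq, []
    out = list(seq)
    err = []
    for r in pos:
        r = int(r)
        if out[r] not in "ACGT":
            continue
        out[r] = "ACGT".replace(out[r], "")[int(rng.integers(0, 3))]
        err.append(r)
    return "".join(out), err


# ---------------------------------------------------------------------------
# Negative control and one-call dataset simulation
# ---------------------------------------------------------------------------


def make_negative_control_junction_reads(
    genome: ReferenceGenome,
    models: list[GeneModel],
    n: int,
    m: int,
    seed: int,
) -> ReadCollection:
    """Random exon-pair junction reads: each read joins the suffix of one
    exon to the prefix of an exon of a different gene, junction centered.
    By construction these junctions are non-colinear (or colinear only by
    chance) and each appears in exactly one read."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    h1 = m // 2
    h2 = m - h1
    pool = []  # (gene index, tx-oriented exon sequence)
    for gi, mdl in enumerate(models):
        seq = genome.sequence(mdl.chrom)
        for s, e in mdl.exons:
            ex = seq[s:e] if mdl.strand > 0 else revcomp(seq[s:e])
            pool.append((gi, ex))
    reads: list[tuple[str, str]] = []
    guard = 0
    while len(reads) < n:
        guard += 1
        if guard > 100 * n:
            raise ValueError("exon pool cannot supply enough junction reads")
        ia, ib = rng.integers(0, len(pool), 2)
        ga, ea = pool[int(ia)]
        gb, eb = pool[int(ib)]
        if ga == gb or len(ea) < h1 or len(eb) < h2:
            continue
        reads.append((f"nc{len(reads):06d}", ea[-h1:] + eb[:h2]))
    return ReadCollection(reads)


@dataclass
class SimulatedDataset:
    """Everything one benchmarking run needs."""

    reference: ReferenceGenome
    models: list[GeneModel]
    mutated: ReferenceGenome
    models_mut: list[GeneModel]
    transcripts: list[Transcript]
    reads: ReadCollection
    ledger: TruthLedger


def simulate_dataset(
    seed: int,
    genome_params: GenomeParams | None = None,
    rates: MutationRates | None = None,
    read_length: int = 75,
    coverage: float = 30.0,
    error_rate: float = 0.01,
    n_reads: int | None = None,
    stranded: bool = False,
) -> SimulatedDataset:
    """Full protocol: reference -> mutated genome -> transcripts -> reads."""
    genome_params = genome_params or GenomeParams()
    rates = rates or MutationRates()
    reference, models = generate_reference(genome_params, seed)
    mutated, models_mut, ledger = mutate_genome(reference, models, rates, seed + 1)
    transcripts = build_transcripts(reference, mutated, models, models_mut, ledger)
    reads = simulate_reads(
        transcripts, ledger, read_length, error_rate, seed + 2,
        n_reads=n_reads, coverage=None if n_reads else coverage, stranded=stranded,
    )
    return SimulatedDataset(reference, models, mutated, models_mut, transcripts, reads, ledger)
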