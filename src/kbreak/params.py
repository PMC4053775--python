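"""Tunable parameters of the read analyzer, with their defaults."""

from __future__ import annotations

from dataclasses import dataclass, asdict


@dataclass
class Params:
    """Analysis thresholds.

    k
        Seed length in nt.  22 keeps the chance of a random exact match of
        a k-mer to a human-scale genome around 1e-4; reads should be longer
        than 2k so that at least one k-mer can sit on each side of an
        interior event.
    cap
        Maximum number of locations retained per k-mer (true totals are
        always kept).
    duplication
        Occurrence count above which a k-mer is considered repeat-borne;
        reads made only of such k-mers are classified ``duplicated``.
    tau_low
        Mean outside-break support below which a read's support profile is
        ``undetermined`` (too little coverage to interpret).
    sigma_abs, alpha
        The support separation rule: a break is ``dropping`` (sequencing
        error) when the mean support inside the break is <= sigma_abs or
        <= alpha times the mean support outside; otherwise
        ``non_dropping`` (biological difference).
    delta
        Half-width of the coherence window: k-mers adjacent to a break
        flank must have successor-consecutive locations over delta
        neighbours for the flank to be trusted.
    fusion_gap
        Maximum number of matched k-mers between two breaks that break
        fusion may discard as false locations when merging mirage breaks.
    d_max
        Largest genomic gap (nt) still reported as a short deletion;
        anything larger is a splice junction.  No splice-site consensus is
        ever consulted.
    max_splice
        Optional upper bound on splice gap size; None leaves long-distance
        junctions unbounded.
    min_reads
        Post-filter on aggregated event candidates.
    stranded
        Library strandedness; unstranded libraries use canonical k-mer
        support counting.
    """

    k: int = 22
    cap: int = 255
    duplication: int = 1000
    tau_low: float = 2.0
    sigma_abs: float = 1.5
    alpha: float = 0.5
    delta: int = 2
    fusion_gap: int = 2
    d_max: int = 15
    max_splice: int | None = None
    min_reads: int = 1
    stranded: bool = False

    @property
    def support_mode(self) -> str:
        return "as-is" if self.stranded else "canonical"

    def to_dict(self) -> dict:
        return asdict(self)
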