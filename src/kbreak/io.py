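"""Formats and run plumbing: sequence input, SAM and event-table output.

FASTA and FASTQ (optionally gzipped) are auto-detected; quality strings
are discarded.  SAM output follows the standard: 1-based POS, reverse
strand records carry FLAG 16 with the reverse-complemented sequence, and
the CIGAR (M/I/D/N plus terminal soft clips) always accounts for the full
read length.  Event tables are versioned TSVs, one per category, plus an
aggregated candidate table.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import pysam
from Bio import SeqIO

from ._kmers import revcomp
from .classify import EventCandidate, ReadAnnotation
from .genome import ReferenceGenome
from .params import Params
from .reads import ReadCollection

TABLE_VERSION = "kbreak event table v1"

_CIGAR_CODE = {"M": 0, "I": 1, "D": 2, "N": 3, "S": 4}

EVENT_COLUMNS = [
    "read_id", "read_pos", "chrom", "strand", "pos", "chrom2", "strand2",
    "pos2", "p", "chimera_class", "s_in", "s_out",
]


def _open_maybe_gzip(path):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_sequences(path) -> ReadCollection:
    """Load reads from FASTA or FASTQ, plain or gzipped, auto-detected."""
    handle = _open_maybe_gzip(path)
    with handle:
        first = handle.read(1)
        while first and first.isspace():
            first = handle.read(1)
        if not first:
            raise ValueError(f"{path}: empty sequence file")
        if first == ">":
            fmt = "fasta"
        elif first == "@":
            fmt = "fastq"
        else:
            raise ValueError(f"{path}: neither FASTA nor FASTQ (starts with {first!r})")
        handle.seek(0)
        reads: list[tuple[str, str]] = []
        seen: dict[str, int] = {}
        n = 0
        try:
            for rec in SeqIO.parse(handle, fmt):
                n += 1
                rid = rec.id
                if rid in seen:
                    seen[rid] += 1
                    rid = f"{rid}.{seen[rec.id]}"
                else:
                    seen[rid] = 0
                reads.append((rid, str(rec.seq).upper()))
        except ValueError as exc:
            raise ValueError(f"{path}: malformed record #{n + 1}: {exc}") from exc
    if not reads:
        raise ValueError(f"{path}: no records")
    return ReadCollection(reads)


def write_reads_fastq(reads: ReadCollection, path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_sam(
    annotations: list[ReadAnnotation],
    genome: ReferenceGenome,
    reads: ReadCollection,
    path,
) -> None:
    """One primary record per input read; unique/multiple reads mapped with
    a length-conserving CIGAR, everything else unmapped."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": len(seq)} for name, seq in genome.chromosomes],
    }
    ref_ids = {name: i for i, (name, _) in enumerate(genome.chromosomes)}
    by_id = {a.read_id: a for a in annotations}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rid, seq in reads:
            ann = by_id.get(rid)
            a = pysam.AlignedSegment(out.header)
            a.query_name = rid
            if ann is None or ann.alignment is None:
                a.flag = 4
                a.query_sequence = seq
                out.write(a)
                continue
            aln = ann.alignment
            rev = aln.strand < 0
            a.flag = 16 if rev else 0
            a.reference_id = ref_ids[aln.chrom]
            a.reference_start = aln.pos
            a.mapping_quality = 60 if ann.status == "unique" else 0
            ops = aln.ops[::-1] if rev else aln.ops
            a.cigartuples = [(_CIGAR_CODE[op], n) for op, n in ops]
            a.query_sequence = revcomp(seq) if rev else seq
            a.set_tag("NH", max(ann.n_chains, 1))
            out.write(a)
            if ann.status == "multiple":
                for s_off, chrom, strand, fwd in ann.secondary[:10]:
                    b = pysam.AlignedSegment(out.header)
                    b.query_name = rid
                    b.flag = 256 | (16 if strand < 0 else 0)
                    b.reference_id = ref_ids[chrom]
                    # secondary records assert the anchor block match only
                    blk = _anchor_block_ops(ann, len(seq))
                    if blk is None:
                        continue
                    pre, mlen, post = blk
                    b.reference_start = fwd if strand > 0 else fwd - mlen + 1
                    ops2 = [("S", pre), ("M", mlen), ("S", post)]
                    ops2 = [(op, n) for op, n in ops2 if n > 0]
                    if strand < 0:
                        ops2 = ops2[::-1]
                    b.cigartuples = [(_CIGAR_CODE[op], n) for op, n in ops2]
                    b.query_sequence = revcomp(seq) if strand < 0 else seq
                    b.mapping_quality = 0
                    out.write(b)


def _anchor_block_ops(ann: ReadAnnotation, m: int) -> tuple[int, int, int] | None:
    """(left clip, matched length, right clip) of the primary anchor block."""
    if ann.primary is None or ann.alignment is None:
        return None
    pre = ann.primary[0]
    # the anchor block spans at least one k-mer; reconstruct its matched
    # length from the primary alignment's first M run at that offset
    mlen = 0
    off = 0
    for op, n in ann.alignment.ops:
        if op == "S":
            off += n
            continue
        if off >= pre and op == "M":
            mlen = n
            break
        if op in ("M", "I"):
            off += n
    if mlen == 0:
        return None
    post = m - pre - mlen
    if post < 0:
        return None
    return pre, mlen, post


def _event_row(ev) -> dict:
    return {
        "read_id": ev.read_id,
        "read_pos": ev.read_pos,
        "chrom": ev.chrom,
        "strand": ev.strand,
        "pos": ev.pos,
        "chrom2": ev.chrom2,
        "strand2": ev.strand2,
        "pos2": ev.pos2,
        "p": ev.p,
        "chimera_class": ev.chimera_class,
        "s_in": round(ev.s_in, 3),
        "s_out": round(ev.s_out, 3),
    }


def write_event_tables(
    candidates: list[EventCandidate],
    annotations: list[ReadAnnotation],
    outdir,
) -> None:
    """Per-category per-read TSVs plus the aggregated candidate TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    kinds = ["snv", "error", "insertion", "deletion", "splice", "chimera"]
    for kind in kinds:
        rows = [
            _event_row(ev)
            for ann in annotations
            for ev in ann.events
            if ev.kind == kind
        ]
        _write_tsv(pd.DataFrame(rows, columns=EVENT_COLUMNS), outdir / f"{kind}.tsv")
    for label in ("undetermined", "bio_undetermined"):
        rows = [
            {"read_id": ann.read_id, "status": ann.status}
            for ann in annotations
            if label in ann.labels
        ]
        _write_tsv(pd.DataFrame(rows, columns=["read_id", "status"]), outdir / f"{label}.tsv")
    agg = [
        {
            "kind": c.kind,
            "key": json.dumps(c.key),
            "chrom": c.event.chrom,
            "pos": c.event.pos,
            "pos2": c.event.pos2,
            "p": c.event.p,
            "chimera_class": c.event.chimera_class,
            "n_reads": c.n_reads,
            "mean_support": round(c.mean_support, 3),
            "example_reads": ",".join(c.read_ids),
        }
        for c in candidates
    ]
    cols = ["kind", "key", "chrom", "pos", "pos2", "p", "chimera_class",
            "n_reads", "mean_support", "example_reads"]
    _write_tsv(pd.DataFrame(agg, columns=cols), outdir / "candidates.tsv")


def write_read_table(annotations: list[ReadAnnotation], path) -> None:
    rows = []
    for ann in annotations:
        r = {"read_id": ann.read_id, "m": ann.m, "status": ann.status,
             "labels": ",".join(sorted(ann.labels))}
        if ann.primary is not None:
            r.update(
                anchor_offset=ann.primary[0], chrom=ann.primary[1],
                strand=ann.primary[2], fwd=ann.primary[3],
            )
        rows.append(r)
    cols = ["read_id", "m", "status", "labels", "anchor_offset", "chrom", "strand", "fwd"]
    _write_tsv(pd.DataFrame(rows, columns=cols), path)


def _write_tsv(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {TABLE_VERSION}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


@dataclass
class RunConfig:
    """Everything needed to reproduce an analysis run byte for byte."""

    genome: str
    reads: str
    outdir: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def make_run_config(genome, reads, outdir, params: Params, seed: int = 0) -> RunConfig:
    return RunConfig(str(genome), str(reads), str(outdir), params.to_dict(), seed)
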