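"""Desk-scale benchmarking protocol: simulate, analyze, score.

One call simulates a dataset under the standard study conditions (2 Mb
two-chromosome genome, 300 spliced genes, substitution rate 1e-3, indel
rate 2e-4, ten fused transcripts, ~30x transcriptome coverage, 1%
per-base sequencing error), analyzes the reads against the *reference*
genome with k = 22, and scores mapping and event predictions against the
ledger.  The negative control builds centered random exon-pair junction
reads over the same kind of genome and counts how many normal splice
candidates the analyzer reports (none are expected: each random junction
exists in a single read, so its support collapses).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .classify import aggregate_events, analyze_collection, ReadAnnotation, EventCandidate
from .evaluate import evaluate_events, evaluate_mapping
from .genome import GenomeIndex, ReferenceGenome, build_genome_index
from .params import Params
from .simulate import (
    GenomeParams,
    GeneModel,
    MutationRates,
    SimulatedDataset,
    generate_reference,
    make_negative_control_junction_reads,
    simulate_dataset,
)

#: read categories whose mapping quality the protocol tracks
MAPPING_EVENT_CATEGORIES = ["snv", "insertion", "deletion", "splice", "error"]


@dataclass
class BenchmarkResult:
    dataset: SimulatedDataset
    annotations: list[ReadAnnotation]
    candidates: list[EventCandidate]
    mapping: pd.DataFrame
    events: pd.DataFrame

    @property
    def splice_precision(self) -> float:
        return float(self.events.loc["splice", "precision"])

    @property
    def snv_precision(self) -> float:
        return float(self.events.loc["snv", "precision"])

    @property
    def indel_precision(self) -> float:
        return float(self.events.loc["indel", "precision"])

    def min_mapping(self, column: str) -> float:
        return float(self.mapping.loc[MAPPING_EVENT_CATEGORIES, column].min())


def default_rates() -> MutationRates:
    return MutationRates(snv_rate=1e-3, indel_rate=2e-4, n_fusions=10)


def run_benchmark(
    seed: int,
    read_length: int = 75,
    coverage: float = 30.0,
    error_rate: float = 0.01,
    params: Params | None = None,
    genome_params: GenomeParams | None = None,
    rates: MutationRates | None = None,
    gidx: GenomeIndex | None = None,
    dataset: SimulatedDataset | None = None,
    mapping_tolerance: int = 5,
    junction_tolerance: int = 3,
) -> BenchmarkResult:
    """Simulate (unless a dataset is supplied), analyze, and score."""
    params = params or Params()
    if dataset is None:
        dataset = simulate_dataset(
            seed,
            genome_params or GenomeParams(),
            rates or default_rates(),
            read_length=read_length,
            coverage=coverage,
            error_rate=error_rate,
        )
    if gidx is None:
        gidx = build_genome_index(dataset.reference, params.k, params.cap)
    annotations = analyze_collection(gidx, dataset.reads, params)
    candidates = aggregate_events(annotations, params.min_reads)
    mapping = evaluate_mapping(annotations, dataset.ledger, mapping_tolerance)
    events = evaluate_events(candidates, dataset.ledger, junction_tolerance)
    return BenchmarkResult(dataset, annotations, candidates, mapping, events)


def run_negative_control(
    seed: int,
    n: int = 10_000,
    m: int = 76,
    params: Params | None = None,
    genome: ReferenceGenome | None = None,
    models: list[GeneModel] | None = None,
    gidx: GenomeIndex | None = None,
) -> tuple[int, list[EventCandidate]]:
    """Analyze centered random exon-pair junction reads; returns the count
    of normal splice candidates (expected 0) and all candidates."""
    params = params or Params()
    if genome is None or models is None:
        genome, models = generate_reference(GenomeParams(), seed)
    reads = make_negative_control_junction_reads(genome, models, n, m, seed + 17)
    if gidx is None:
        gidx = build_genome_index(genome, params.k, params.cap)
    annotations = analyze_collection(gidx, reads, params)
    candidates = aggregate_events(annotations, params.min_reads)
    n_splice = sum(1 for c in candidates if c.kind == "splice")
    return n_splice, candidates
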