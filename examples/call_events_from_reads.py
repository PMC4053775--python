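"""Call events on hand-made reads over a toy genome.

Builds a random 5 kb genome, plants a substitution, a 7 nt deletion and
a splice-sized gap into small read stacks, and prints what the analyzer
infers for each read: its mapping status and the typed events with their
genomic coordinates.
"""

import numpy as np

from kbreak import (
    Params,
    ReadCollection,
    ReferenceGenome,
    analyze_collection,
    build_genome_index,
)
from kbreak.simulate import _random_seq

rng = np.random.default_rng(0)
genome = ReferenceGenome([("chr1", _random_seq(rng, 5000))])
gidx = build_genome_index(genome, k=22)
seq = genome.sequence("chr1")

snv_template = seq[:1040] + ("A" if seq[1040] != "A" else "C") + seq[1041:]
reads = []
# ten staggered reads sharing a substitution at chr1:1040
reads += [(f"snv{i}", snv_template[1000 + 4 * i : 1075 + 4 * i]) for i in range(10)]
# five reads over a 7 nt deletion at chr1:[2040, 2047)
reads += [(f"del{i}", seq[2000 + 2 * i : 2040] + seq[2047 : 2082 + 2 * i]) for i in range(5)]
# five reads spanning a 300 nt splice-like gap
reads += [(f"spl{i}", seq[3000 + 2 * i : 3040] + seq[3340 : 3375 + 2 * i]) for i in range(5)]
# one read with a private error (support stays 1 inside its break)
reads += [("err0", seq[1000:1030] + ("G" if seq[1030] != "G" else "T") + seq[1031:1075])]

annotations = analyze_collection(gidx, ReadCollection(reads), Params())
for ann in annotations:
    for ev in ann.events:
        span = f"{ev.pos}" if ev.pos2 is None else f"[{ev.pos}, {ev.pos2}]"
        print(f"{ann.read_id:6s} {ann.status:7s} -> {ev.kind:9s} {ev.chrom}:{span}"
              f"  support in/out = {ev.s_in:.1f}/{ev.s_out:.1f}")

# Each line is one resolved break: the same substitution is seen as an SNV
# by every read that covers it mid-sequence (shared support), the deletion
# and the gap give identical left-normalized genomic intervals from every
# read, and the read-private substitution is classified as an error.
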