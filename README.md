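# kbreak

Integrated k-mer profiling of RNA-seq reads: in a single pass per read,
`kbreak` maps the read on a reference genome **and** calls the event it
carries — sequencing error, SNV, short insertion or deletion, splice
junction, or chimeric (fusion-type) junction — using no annotation, no
quality values, and no splice-site consensus.

## Who this is for

Transcriptomics analyses usually chain a mapper, a coverage step, and
per-event inference tools, losing information at each hand-off — most
visibly, the mapping step cannot use coverage, so it cannot tell a
sequencing error from a variant. `kbreak` is for anyone who wants those
decisions made jointly, from two simple per-read profiles, with a
built-in ground-truth simulator to measure exactly how well that works.

## The method in brief

For a read of length m, every one of its m − k + 1 k-mers (default
k = 22) is looked up in two indexes:

* a **genome index** giving each k-mer's exact match locations on both
  strands (the location profile);
* a **read-set index** giving the number of distinct reads sharing each
  k-mer (the support profile) — local coverage without any mapping.

A difference between read and genome blanks the k-mers that overlap it,
leaving a *break* with matched flanks `j_b < j_a`. With `l = j_a − j_b`
and `L` the genomic offset between the flank locations:
`l = L = k + 1` is a substitution; `l = k, L = k + p` a p-nt genomic gap
(deletion if `p ≤ 15`, else a splice junction); `l = k + p, L = k` a
p-nt insertion; non-colinear flanks with `l ≤ k` are a chimeric
junction, in five subclasses. The support profile arbitrates biology
versus noise: support collapsing inside the break means a read-private
sequencing error, support comparable to the rest of the read means a
real variant or junction. Break *verification* and *fusion* procedures
defuse random false k-mer matches before any rule is applied, and reads
whose event sits within k of an extremity are deferred to reads covering
it mid-sequence. Details, parameters and limitations: see
[docs/methods.md](docs/methods.md).

## Worked example

`python examples/call_events_from_reads.py` builds a 5 kb toy genome and
small read stacks with a planted substitution, a 7 nt deletion, a 300 nt
gap, and one read-private error:

```
snv0   unique  -> snv       chr1:1040  support in/out = 8.0/6.5
...
del0   unique  -> deletion  chr1:[2040, 2046]  support in/out = 5.0/4.4
...
spl0   unique  -> splice    chr1:[3039, 3338]  support in/out = 5.0/4.6
...
err0   unique  -> error     chr1:1030  support in/out = 1.0/5.5
```

Every read maps uniquely; the shared substitution is called an SNV at
the exact genomic base (support inside the break ≈ outside), the
deletion and the gap give identical left-normalized genomic intervals
from every covering read (the splice interval starts at 3039, one base
left of the planted 3040, because the flanking base is identical — both
placements describe the same junction and all reads agree on the
canonical one), and the read-private substitution drops to support 1
inside its break and is classified as an error, at its exact position.

`python examples/simulate_and_evaluate.py` runs a reduced benchmarking
protocol (300 kb genome, 45 genes, ~20×, 1% error) and prints, among
other rows:

```
read mapping by category (tolerance 5 nt):
             tp  fp  fn  sensitivity  precision
snv         456   0  10       0.9785        1.0
splice     3270   0  29       0.9912        1.0
error      5208   0  36       0.9931        1.0
```

`python examples/negative_control.py` analyzes 2,000 centered random
exon-pair junction reads and prints
`normal splice candidates from 2000 random junction reads: 0` — each
artificial junction lives in one read only, its support collapses, and
no splice junction is ever called from it.

## Command line

```sh
kbreak index    --genome genome.fa -k 22 -o genome.idx
kbreak analyze  --index genome.idx --reads reads.fastq -o out/
kbreak simulate --seed 7 --genome-size 2000000 --genes 300 -o sim/
kbreak evaluate --truth sim/ --pred out/ --tolerance 3
```

`analyze` writes a SAM file (spliced alignments use N CIGAR operations;
every read appears exactly once as a primary record), one TSV per event
category, the undetermined/bio-undetermined read lists, and an
aggregated candidate table with supporting-read counts. Thresholds are
exposed as flags (`--support-low`, `--support-drop-abs`,
`--support-drop-ratio`, `--delta`, `--fusion-gap`, `--max-deletion`,
`--max-splice`, `--min-reads`, `--stranded`).

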