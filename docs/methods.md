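# Methods

## The model

`kbreak` analyzes an RNA-seq read collection against a reference genome
using nothing but exact k-mer matching and read-set k-mer counting — no
annotation, no quality values, no splice-site consensus, no pairing
information. Two facts carry the whole method:

* **P1 — a k-mer is a positional witness.** For a suitable k relative to
  the genome size, an exact k-mer match identifies a genomic position
  almost uniquely; random ("false") locations are rare but not absent.
* **P2 — support separates errors from biology.** Reads oversample the
  same molecules, so a biological difference (SNV, indel, junction) is
  shared by many overlapping reads, while a sequencing error is private
  to one read.

For each read of length m the analyzer computes two per-k-mer-start
profiles (m − k + 1 entries each): the **location profile** (exact
genomic matches of each k-mer on both strands, with their total count)
and the **support profile** (number of distinct reads containing each
k-mer, at least 1).

### Coordinate convention

Locations are 0-based. A reverse-strand hit stores the forward offset of
its footprint start, and the projected coordinate `c = strand · pos`
advances by exactly +1 per read position for colinear matches on either
strand. All break arithmetic happens on projected coordinates; reported
events are converted to forward coordinates, which makes every event key
invariant under reverse-complementing the read.

### Breaks and the difference rule

A maximal run of location-less k-mer starts is a *break* with matched
flanks `j_b < j_a`, `l = j_a − j_b`, and genomic flank offset
`L = c(loc_a) − c(loc_b)`. For a single difference at least k from the
read ends:

| shape | inference | position |
|---|---|---|
| `l = L = k + 1` | substitution | read `j_a − 1`, genome `c(loc_a) − 1` |
| `l = k`, `L = k + p` | p-nt genomic gap | genome `[c(loc_a) − p, c(loc_a) − 1]` |
| `l = k + p`, `L = k` | p-nt insertion | read `[j_a − p, j_a − 1]` |

Gaps are split by size alone: `p ≤ d_max` (default 15 nt) is a short
deletion, anything larger a splice junction, with no upper bound by
default (`--max-splice` exists). Substitution-shaped and indel-shaped
breaks whose support *drops* are sequencing errors; the reported error
position is the break end.

**Slid breaks.** When the read sequence happens to match the genome
across a junction boundary (one chance in four per base), flanking
k-mers extend into the event: `l` and `L` shrink by the slide while
`L − l` keeps the difference size. The resolver therefore accepts any
colinear pair with `L − l = p > 0` and `l ≤ k` as a p-nt gap, and
`l − L = p > 0` with `1 ≤ L ≤ k` as a p-nt insertion; the strict table
above is the unambiguous special case. All reported placements are
left-normalized (gaps slid to their leftmost equivalent position,
insertions left-aligned), so equivalent detections from different reads
collapse to one canonical key. The lower bound `L ≥ 1` matters: without
it an inverted-order junction on one chromosome (which stands still or
runs backward on the genome) would masquerade as an enormous insertion.

### Support separation

For each break the mean support inside the gap (`s_in`) is compared with
the mean support over all originally matched k-mer indices of the read
(`s_out`; locations later discarded as false still count as matched):

* `s_out < τ_low` (default 2): **undetermined** — coverage too low to
  interpret;
* `s_in ≤ σ_abs` (default 1.5) or `s_in < α·s_out` (default α = 0.5):
  **dropping** — a read-private difference, i.e. a sequencing error;
* otherwise **non_dropping** — a biological difference.

The ratio comparison is strict so that a variant riding at exactly half
the local coverage (a clean heterozygote) stays on the biological side.
The exact functional form of the separation rule is an open design
point; this thresholded ratio-plus-floor keeps the two regimes the
method relies on (errors ≈ support 1; variants tracking coverage) with
three interpretable knobs.

### Chimeric junctions

A break whose flanks are non-colinear, with length `l ≤ k` (allowing for
slides), strictly coherent δ-neighbourhoods on both flanks (default
δ = 2), and a non-dropping support verdict, is a chimeric junction, in
five subclasses: (1) different chromosomes, same strand; (2) different
chromosomes, strand change; (3) same chromosome, strand change; (4) same
chromosome and strand, inverted order (`L ≤ 0`); (5) same chromosome and
strand, short backward jump overlapping the break (`0 < L < l`).
Chimeric junction keys are slide-canonicalized like gaps, but in an
orientation-free way (all equivalent placements are enumerated and the
one minimizing the normalized key is kept). Colinear explanations are
always preferred: a read whose junction admits a forward colinear
interpretation is never called chimeric, which means an exact short
tandem repeat (formally identical to class 5) is reported as an
insertion — the more parsimonious call on sequence evidence alone.

### False locations: verification and fusion

A random k-mer match inside or at the edge of a break corrupts the
arithmetic. Two procedures, run after break detection and before
resolution, handle this:

* **Break fusion** merges two consecutive breaks separated by at most
  `g` matched indices (default 2) whose locations chain with neither
  outer flank — the mirage-break pattern left by an FL inside a true
  break — discarding the intervening locations.
* **Break verification** applies when a break admits neither a colinear
  nor a chimeric interpretation: a flank location that does not chain
  colinearly with the nearest located index on its away side is
  discarded and the break widened, repeating until a trustworthy flank
  is found. A location coherent with its neighbours is never discarded,
  so both procedures are the identity on FL-free profiles.

### Read classification

Mapping status is decided from the matched blocks independently of event
resolution: the longest block's coherent location chains give *unique*
(one chain), *multiple* (several), *none*, or *duplicated* (every
matched k-mer above the duplication count threshold, default 1000).
This is why a read whose junction sits within k of an extremity — a
*border case*, unresolvable in that read — is still mapped by its main
block; the event itself is deferred to reads covering it mid-sequence,
and the border read goes to the undetermined (dropping/low support) or
bio-undetermined (non-dropping) pool. Breaks are resolved independently
left to right, so one read may carry several events; two events closer
than k merge into a break no rule covers and the read lands in
bio-undetermined. Identical events across reads share a canonical key
and aggregate into candidates with supporting-read counts (`--min-reads`
post-filters them).

## Parameters

| parameter | default | meaning |
|---|---|---|
| k | 22 nt | seed length; reads must exceed 2k for interior events |
| cap | 255 | locations stored per k-mer (true totals always kept) |
| duplication | 1000 | occurrence count marking repeat-borne k-mers |
| τ_low | 2 | outside support below this → undetermined |
| σ_abs | 1.5 | inside support at/below this → dropping |
| α | 0.5 | dropping when `s_in < α·s_out` |
| δ | 2 | coherence window at break flanks |
| g | 2 | max matched indices bridged by break fusion |
| d_max | 15 nt | deletion/splice size boundary |
| min_reads | 1 | candidate post-filter |

k = 22 keeps the probability of a false location around 1e-4 at human
genome scale; on the 2 Mb benchmark genome FLs are far rarer still, and
the verification/fusion machinery is exercised mainly by the dedicated
toy tests.

## The simulator and what it does (not) emulate

The ground-truth generator follows the benchmarking protocol: a random
genome is altered with substitutions (default rate 1e-3) and 1–10 nt
indels (rate 2e-4, geometric sizes); spliced transcripts come from
non-overlapping gene models (about 4.5 exons/gene, exons ~40–500 nt,
introns ~30–5000 nt, both strands); a few transcript pairs are fused
into chimeric RNAs (5' exon prefix joined to a 3' exon suffix of another
gene, resampled until non-colinear); reads are drawn uniformly along
transcripts with log-normal(μ=1, σ=1) expression weights — a stand-in
for a realistic skewed expression distribution — from both strands, with
per-base substitution errors (default 1%). Coverage is specified as mean
read bases per transcript base over transcripts at least one read long.
All truth is recorded in reference coordinates and canonicalized with
the same normalization functions the analyzer uses, so a correct call
matches its truth record exactly.

Deliberate simplifications: indels are never planted across an exon
boundary (gene models then lift exactly through the mutation chain, and
splice truth stays unambiguous); the mutated genome is haploid, so all
variants are homozygous and support at a variant tracks full coverage —
heterozygous support levels are exercised at the unit level only;
sequencing errors are substitutions only; no library-preparation biases,
positional coverage biases, or quality strings; fusions are realized at
transcript level rather than by genomic rearrangement (read-level truth
is equivalent). Passing benchmarks therefore show that the profiling
arithmetic, the support separation, and the FL countermeasures work as
specified on reads with realistic error and coverage structure — not
that the thresholds are tuned for real library artifacts such as
template switching or PCR duplicates.

## Evaluation

Mapping: a read scores as correctly mapped when reported unique with the
right chromosome and strand and an anchor within 5 nt of its true origin
(the tolerance also absorbs junction-slide ambiguity by letting truth
segments extrapolate a few bases past their boundaries). Events: SNVs
and indels match planted variants exactly (position and size); splice
and chimeric junctions match within ±3 nt on both anchors, each truth
event at most once. Sensitivity and precision are per distinct event,
not per covering read. Strict sensitivity counts every planted event in
the denominator, including those in unexpressed or intronic sequence;
the `attainable` option restricts the denominator to events covered by
at least one read.

## Benchmark scale and numerical choices

The shipped benchmark runs a 2 Mb, two-chromosome genome with 300 genes
at ~30× coverage (about 97,000 reads of 75 nt, or the same base total as
200 nt reads), chosen so a full run takes about half a minute on one
core while leaving hundreds of junctions and dozens of transcribed
variants to score. Determinism: all randomness flows from explicit
seeds through `numpy.random.default_rng`; ties in location lists, pair
ranking, and aggregation order are broken by packed-integer and key
order, so reruns are byte-identical. Degenerate inputs: reads shorter
than k are classified `too_short`; k-mers containing N are never indexed
and count as unlocated in profiles; a read that is one single break is
undetermined.

## Known limitations

* Sensitivity for events near read extremities is structurally limited
  (border cases); the method relies on coverage to see the same event
  mid-read, so error-detection sensitivity is bounded by the interior
  fraction of the read.
* Two events within k nt are never resolved (bio-undetermined).
* Exact tandem duplications are reported as insertions, never as
  class-5 chimeras.
* The support rule compares against a read-wide outside mean; steep
  coverage gradients (transcript ends) can push a true junction's
  support under the dropping threshold and cost a call.
* Secondary SAM records for multiply-mapped reads assert the anchor
  block match only, not a full alternative alignment.
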