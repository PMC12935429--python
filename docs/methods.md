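# Methods

## Assay models

### LS-MPRA

The locus-specific MPRA assays a BAC-scale locus by random
fragmentation: each fragment instance is cloned upstream of a minimal
promoter driving a barcoded reporter, so transcription of the reporter
reads out the fragment's regulatory activity positionally. The package
models this chain as:

1. **Fragmentation.** Fragment start positions are uniform over the
   valid range and lengths uniform over a configured size band
   (defaults 200–500 bp), modelling enzymatic digestion followed by gel
   size selection. Strand is uniform and recorded, but coverage and
   enrichment are strand-agnostic — the assay reads out reporter
   transcription, not fragment orientation.
2. **Barcoding.** Each fragment instance receives a unique degenerate
   barcode. The default pattern is twelve `SW` repeats (24 nt matching
   `([GC][AT]){12}`), which bounds GC content at exactly 50 % and
   forbids homopolymers by construction; a `VHBD`-repeat alternative is
   available. Requests exceeding the pattern space fail with a capacity
   error.
3. **Expression.** Barcode transcript counts are one multinomial draw
   at the configured depth with fragment weight equal to the strength
   of the active region covering the largest share of the fragment
   (ties to the leftmost region; baseline weight 1 elsewhere). This is
   the minimal generative model under which active regions appear as
   enrichment peaks where overlapping fragments accumulate.
4. **Reads.** Association read 1 is `anchor5 + barcode + anchor3`
   padded to the read length; read 2 is the fragment's 5′ end. cDNA
   reads repeat the read-1 layout once per transcript. The anchors are
   fixed 20-nt vector arms defined in `mpralocus.io` and are part of
   this package's read-layout format. Sequencing error is an
   independent per-base substitution at one configurable rate
   (default 0); qualities are constant — no quality model is attempted.

**Quantification.** The association map keeps a barcode when it has at
least `min_support` mapped reads (default 1) and at least
`concordance_frac` (default 0.9) of them support one interval
(endpoints within ±`slop` = 5 bp); the consensus is the
support-weighted modal interval. These thresholds are package choices;
they are configurable and every dropped barcode carries its reason
(`unmapped` / `low-support` / `ambiguous`). The enrichment track is

    E(x) = log2((C(x) + p) / (A(x) + p)),

with `C` the cDNA signal and `A` the association coverage, both
counts-per-million scaled, and pseudocount `p` = 1 CPM-unit by default.
CPM log2-ratio at single-base resolution is this package's
normalization; signal-extraction scaling variants used by generic
coverage tools are deliberately out of scope. There is no automatic
peak caller — peaks in this assay are judged by inspection — but a
threshold + minimum-width interval extractor is shipped as plumbing,
off by default. Interval activity is the trapezoidal AUC with unit base
spacing.

**Fragment location.** The built-in locator is exact-20-mer seed plus
Hamming extension on both strands, requiring a unique best placement
with mismatch fraction ≤ 0.1. It is sufficient for desk-scale contigs
and deliberately not a general aligner; pre-computed alignments can be
substituted for real-genome work. When only the fragment's 5′ read is
available, the interval 3′ end comes from the mapped read span
(appropriate for merged/full-length reads) or a fixed expected length
from the size selection, configurable per run.

**Whitelists.** The decoding radius `d` defaults to
`floor((d_min − 1)/2)` of the canonical set's minimum pairwise
distance; any observed sequence within `d` of two or more canonicals is
discarded rather than assigned to the nearest — a conservative choice
that avoids systematic miscounting at the cost of a small read loss.
Variant maps are enumerated eagerly when the total Hamming-ball volume
is small and replaced by an equivalent distance scan at match time for
long barcodes at `d` ≥ 2 (identical contract, bounded memory).

**QC.** Restriction-site occurrences (AscI `GGCGCGCC` by default) are
flagged on the track: the association library is depleted where the
assembly enzyme cuts, which inflates the normalized ratio and can
masquerade as an enhancer peak.

### d-MPRA

The degenerate MPRA dissects one CRM with an error-prone-PCR library.
The generator mutates each clone position independently at a configured
per-nucleotide rate (default 0.001, the midpoint of the assay's
~0.02–0.2 % working range); the mutation type is drawn from a
(substitution, deletion, insertion) spectrum with default
(0.90, 0.08, 0.02) — the kit's true spectrum is unpublished, so this is
a documented, configurable choice with uniform substitution targets.
Plasmid counts are uniform-multinomial over clones; cDNA counts are
weighted by the product of per-site effect multipliers over each
clone's mutated positions (activator sites < 1, repressor sites > 1).

**Calling and filters.** Reads are globally aligned (unit
mismatch/gap costs, edlib backend) and deletion runs are
left-normalized so gap placement is deterministic. Reads failing to
span the contig end-to-end are excluded; reads containing insertions
are excluded (only substitutions and deletions are quantified);
deletions inside homopolymer runs (length ≥ 3 by default) are
uninterpretable because gap placement is degenerate there, so such
reads are excluded while substitutions inside runs are retained.

**Frequencies.** The denominator of
`f(i) = mutated-at-i / wild-type reads` is the global wild-type
(zero-call) read count. This makes `f` proportional to, but slightly
larger than, the per-site rate (by the factor `1/(1−r)^L` ≈ `e^{rL}`,
~1.35 at r = 0.001, L = 300); the inflation cancels in the
experimental/control ratio. A per-position denominator is implemented
as an alternative but is not the default. Monte-Carlo estimation draws
10 independent subsamples without replacement (multivariate
hypergeometric over clone counts) at a depth defaulting to the smaller
library's passing-read count, applied to both libraries, and reports
the position-wise mean and SD.

**Profile.** `raw = log2((f_exp + ε)/(f_ctrl + ε))` with
ε = 0.5 / (smaller wild-type count) by default — half a count on the
natural scale of the estimator; the baseline subtracts the median raw
value using the lower-middle convention for even counts (affects the
baseline by less than one sample value); smoothing is a centered
width-5 moving average with truncated (shrinking) windows at the array
ends — irrelevant after trimming but defined; the first 18 and last 14
positions are assembly-constrained and trimmed from the final profile,
so a 300-bp CRM yields 268 informative positions. Replicates are
aggregated position-wise (mean ± SD). A permutation null (shuffling the
corrected values across positions, re-smoothing, re-trimming) provides
a ±3 SD band for flagging positions incompatible with a no-effect
profile.

### Statistics

Cells are binarized as expressing a gene when its raw count exceeds
zero. Fisher's exact test uses the two-sided probability-mass
definition (scipy backend; an exhaustive hypergeometric enumeration
serves as the independent oracle in the test suite); the reported odds
ratio is the sample (unconditional) OR with the infinity convention for
zero cells, matching how such screens report plain ORs; no continuity
correction is applied. BH-FDR is the step-up procedure (statsmodels
backend, hand-applied formula as oracle); the conventional significance
default is q < 0.05. PFM rows are pseudocounted (10⁻⁶ per cell by
default) and renormalized before `IC(i) = 2 − H(i)` bits; bit scores
are `freq(b,i) × IC(i)` and sum to `IC(i)` by construction.

## What the generator does and does not emulate

The simulator reproduces the statistical structure the analysis relies
on: uniform fragment placement, unique barcoding, multinomial count
sampling at exact depths, independent per-base substitution sequencing
error, independent per-site mutagenesis with a type spectrum, and
multiplicative per-site expression effects. It does **not** model PCR
amplification bias, indel sequencing errors, quality-score structure,
GC-dependent coverage, chromatin context, or transfection efficiency.
Passing benchmarks therefore demonstrate that the analysis recovers
planted signal under the assay's idealized sampling model — they bound
algorithmic, not experimental, error. Real libraries with strong
amplification bias or coverage gaps will be noisier than these
conditions.

## Benchmark conditions

The seeded benchmark experiments (`mpralocus.benchmarks`, re-run by
`scripts/acceptance.py`) use: LS-MPRA — 10 kb reference, 5,000
fragments of 200–500 bp, one strength-8 region at 4,000–4,500,
cDNA depth 10⁵, 100 seeds; d-MPRA — 300-bp CRM, rate 0.001, 50,000
clones, an activator site (×0.1) at position 100 and a repressor site
(×10) at position 200 (both ≥ 25 bp inside the trimmed window), 10⁵
reads per library, 10 Monte-Carlo replicates, 100 seeds; null — the
same with no planted effects, scored against the ±3 SD permutation
band per position across seeds. The clone count (50,000 at depth 10⁵)
is a desk-scale stand-in for real library complexities (≥ 10⁷
transformants, where nearly every read is a distinct clone): it keeps
per-position mutation support well above granularity artifacts while
remaining fast. Benchmarks run the production statistics on exact
clone/count data; FASTQ serialization and alignment are exercised by
their own round-trip and consistency tests rather than re-run 10⁷
times inside the benchmark loop.

## Numerical and degenerate-input choices

- Coordinates are 0-based half-open everywhere, BED conventions in all
  files.
- Counts sum exactly to requested depths (multinomial draws, no
  rounding).
- Zero wild-type reads make wild-type normalization undefined and
  raise a degenerate-input error rather than returning infinities.
- Enrichment tracks are finite by construction (positive pseudocount
  required).
- Ambiguity is always a value, not an exception: unmapped/ambiguous
  barcodes, off-whitelist reads and unplaceable fragments are counted
  and reported, never silently dropped.
- The duplicated-CRM construct is treated as sequenced from its 3′
  copy; 5′/3′ copy concordance is not modelled.
- Tag-design interprets "GC balance" as GC fraction in [0.375, 0.625],
  "triplet repeats" as any homopolymer run ≥ 3, and
  "self-complementarity" as a tag equal to its own reverse complement;
  the randomized-greedy search is seeded and fails fast on requests
  beyond the Singleton bound.

## Known limitations

- The internal locator indexes one contig; it is not meant for
  mammalian-genome-scale references (import external alignments
  instead).
- Whitelist decoding is Hamming-only; indel (Levenshtein) barcode
  errors are not corrected.
- The unique-barcode enrichment mode is informative only below barcode
  saturation: once every barcode is detected in the cDNA library it is
  exactly flat by construction.
- Read merging of overlapping mates is not implemented; d-MPRA expects
  pre-merged or full-span reads.
- AUC replicate summaries report mean ± SEM only; cross-condition
  significance testing is intentionally left to dedicated statistics
  software.
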