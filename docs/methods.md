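# Methods

## The fingerprint transform

A genome is consumed as a chromosome-grouped, position-sorted stream of
biallelic autosomal SNVs (REF and the single ALT both one base in A/C/G/T;
zygosity is ignored — a site counts once whether heterozygous or
homozygous-alternate; non-SNV records are skipped without breaking the
consecutiveness of the SNVs flanking them). Every consecutive within-
chromosome pair contributes one count:

* **row** — the four-letter pair key (first SNV's ref+alt, then the
  second's): 12 × 12 = 144 rows, in fixed lexicographic order so that
  row-major serialization is identical across runs and implementations;
* **column** — the distance *d* = pos₂ − pos₁ − 1, the number of
  intervening reference bases. Pairs with *d* < *C* land in the 144 × *C*
  close matrix at column *d* (indexed from 0; *d* = 0, adjacent positions,
  is legal); all other pairs land in the 144 × *L* raw matrix at column
  *d* mod *L*.

Per-chromosome partial fingerprints sum element-wise to the whole-genome
fingerprint exactly, because pairs never span chromosomes.

**Distance convention.** Counting *intervening bases* (pos₂ − pos₁ − 1)
rather than the position difference is an offset choice; what matters for
mod-*L* comparability is that all compared fingerprints share one
convention, so it is recorded in the file header
(`##distance-convention=intervening-bases`).

## Parameters

| parameter | default | meaning |
|---|---|---|
| *L* | 20 | fingerprint length (columns). Small *L* → fast identity checks; large *L* (120–200) retains more signal for population structure. Minimum 2. |
| *C* | 20 | close cutoff (bases). Pair distances below *C* mostly encode how a pipeline represents multi-nucleotide variants, so they are segregated; at least 5 is advisable. *C* = 0 disables the close matrix. |
| identity threshold | 0.75 | lowest correlation expected between two versions of the same genome; used to call duplicates. |
| outlier FDR | 0.05 | Benjamini–Hochberg level for the relatedness screen. |

## Normalization

Two z-scoring passes over the raw matrix: (1) by distance — each of the
*L* columns is centered and scaled over its 144 rows; (2) by pair key —
each row of the result is centered and scaled over its *L* columns. The
order is essential: distance-first removes the strong column effects
(transition/transversion frequencies interact with the distance profile),
and the reverse order fails to flatten the structure. Numerical choices:

* standard deviations use the population form (divide by *n*), recorded in
  the file header (`##sd-convention=population`);
* a column or row with zero deviation (empty or constant — e.g. a tiny
  genome) is set to zeros after centering instead of dividing by zero, so
  degenerate inputs stay well defined; an all-constant raw matrix
  normalizes to the zero matrix;
* the close matrix is never normalized and never compared.

## Comparison

Real-valued fingerprints (normalized, population, adjusted — any mix, if
*L* matches) are serialized row-major and compared by Spearman correlation
with average ranks for ties. A zero-variance vector yields score 0 with a
warning flag rather than NaN, keeping cohort matrices total. The
all-against-all path ranks each vector once, row-standardizes the rank
matrix and takes one BLAS product — 2,504 genomes (3,133,756 pairs) take
seconds. Binary fingerprints are compared as (matching bits / 144)²; note
this score has a chance floor of ≈ 0.25 for unrelated bit vectors.

The binary fingerprint derives from an *L* = 2 raw matrix: bit = 1 iff the
odd-distance tally exceeds the even-distance tally; ties (including empty
rows) give 0, making the encoding deterministic.

## Population machinery

Population fingerprints are element-wise means of member normalized
fingerprints (same *L* and *C* required); member IDs are stored so
leave-one-out classification can recompute the mean exactly as
(*n*·mean − x)/(*n* − 1) without re-reading files. Classification ranks
populations by Spearman correlation, ties broken by name.

The relatedness screen takes all pairwise correlations of
population-adjusted fingerprints, computes robust z = 0.6745·(score −
median)/MAD (the constant makes MAD consistent for a normal distribution),
converts to one-sided upper-tail normal p-values, and applies
Benjamini–Hochberg. The MAD/FDR combination is applied globally over the
supplied pair universe (within-population pairs by default; any pair table
can be passed). A zero MAD aborts with an error: a degenerate score
distribution needs inspection, not an automated call.

## The synthetic-data generator

The simulator emulates exactly the features of real variant data that the
fingerprint statistics depend on:

* **shared pool** — loci with positions, SNV keys and allele frequencies
  (uniform on 0.05–0.95) common to a cohort; individuals draw genotypes
  Binomial(2, f) under Hardy–Weinberg, so two members of one population
  share variants in proportion to Σf². Populations are created by shifting
  locus frequencies on the logit scale with N(0, divergence) noise;
* **keys** — sampled with a 2:1 transition:transversion weight;
* **spacing** — a sequential walk: each inter-locus gap is
  *L*·G + r + 1 with G geometric (mean gap 1,000 bp) and r a remainder in
  0..*L*−1 whose distribution depends on the flanking key pair: with
  probability 0.5 (the spacing peak weight) r falls on a key-pair-specific
  *pair of adjacent columns* (fair coin between the two), otherwise
  uniform. This gives normalized fingerprints genuine mod-*L* structure —
  uniform spacing would leave only sampling noise — while keeping distance
  *parity* unbiased, as in real genomes, where inter-SNV distances carry no
  systematic odd/even signal; a single-column peak would make the 144-bit
  fingerprint unrealistically informative and robust;
* **pedigrees** — founders draw two Bernoulli(f) haplotypes; each child
  receives one recombined gamete per parent (Poisson crossovers, rate 1
  per chromosome per meiosis, uniform breakpoints — a uniform genetic map
  without hotspots, adequate for IBD-ordering behavior);
* **degradation** — dropout removes each variant i.i.d. with probability
  p; noise inserts, with probability p per consecutive pair that has free
  intervening positions, one spurious SNV at a uniform intervening
  position with a uniform key.

All simulators are bit-reproducible given (model, spec, seed).

**Pinned study conditions.** The defaults of `CohortModel.create` are the
conditions used for the robustness results: 22 autosomes, 200,000 loci
(≈137,000 observed variants per genome — a realistic desk-scale stand-in
for the few million SNVs of a real genome, keeping each fingerprint at
milliseconds), mean gap 1,000 bp, spacing peak weight 0.5, ts:tv 2:1.

**What passing tests do and do not show.** The generator reproduces the
*mechanisms* behind the method's claims — shared-pool correlation,
IBD-driven relatedness ordering (siblings above parent/child pairs, because
IBD2 sharing raises the chance of sharing carried variants),
population-adjustment decorrelation, graceful degradation — but not human
allele-frequency spectra, LD structure, mutation signatures, or the
spatial statistics of real genomes. Synthetic robustness levels are
therefore read as qualitative confirmations ("tolerates at least this much
degradation"), not as predictions of the exact breakdown points of any real
data set.

## Known limitations

* Sex chromosomes and non-autosomal contigs are excluded by design (shared
  X variants distort relatedness), and only SNVs are used; indels and
  structural variants are ignored.
* Sites that are multi-allelic in a record's ALT field are excluded even if
  biallelic within the selected sample; on jointly-called cohort VCFs this
  removes slightly more sites than per-sample calling would.
* Duplicate chrom/pos records keep the first occurrence (a zero-distance
  self-pair is meaningless); the count of dropped duplicates is reported.
* The binary fingerprint's squared-match score cannot fall below its
  ≈ 0.25 chance level, so at extreme degradation it is not comparable to a
  rank correlation that decays to 0.
* Population-adjusted correlations of members adjusted to their own
  finite population carry a small negative bias of order −1/(n−1).
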