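# genofp — genome fingerprints

`genofp` reduces a personal genome — any variant-level representation, VCF
or a plain chrom/pos/ref/alt table — to a small **genome fingerprint**: a
144 × *L* matrix summarizing the composition and spacing of consecutive
single-nucleotide variants. The reduction is a deterministic form of
locality-sensitive hashing: fingerprints of the same genome sequenced with
different technologies, processed by different pipelines, or mapped to
different reference versions remain highly correlated, while the original
variants cannot be reconstructed from the fingerprint. That makes
fingerprints suitable for fast duplicate detection, relatedness screening,
population assignment and cohort quality control — including on data too
sensitive to share directly.

It is intended for anyone who manages collections of personal genomes:
study designers deduplicating cohorts, biobanks screening for unexpected
relatives, and population geneticists who want a genome × feature matrix
for PCA/t-SNE without variant harmonization.

## The encoding

For each pair of consecutive biallelic autosomal SNVs on a chromosome:

1. each SNV gets a two-letter **key** (ref base + alt base; 12 possible),
   and the pair the four-letter concatenation (144 possible) — the matrix
   **row**;
2. the distance *d* between the SNVs (intervening reference bases) selects
   the **column**: pairs with *d* < *C* (default 20) go to a separate
   "close" matrix that mostly captures pipeline artifacts; all others are
   folded as *d* mod *L* (default *L* = 20) into the **raw** fingerprint.

The raw matrix is then z-scored twice — each distance column over its 144
rows, then each key row over its *L* columns (the order matters) — giving
the **normalized** fingerprint used for all comparisons. Two fingerprints
are compared by the Spearman correlation ρ of their row-serialized
matrices; comparisons of the same genome typically score above 0.75, and
lower values grade smoothly through sibling, parent/child, half-sibling and
unrelated pairs. A minimal 144-**bit** fingerprint (is each pair key's
distance more often odd or even?) supports the same tasks with lower
fidelity, scored as (matching bits / 144)².

Averaging normalized fingerprints over a cohort yields a **population
fingerprint**; subtracting it from a member gives a population-**adjusted**
fingerprint in which unrelated individuals decorrelate, so unexpectedly
related pairs stand out as robust-z outliers of the pairwise correlation
distribution (median/MAD, Benjamini–Hochberg at 5% FDR).

Raw fingerprints of genome slices (e.g. per-chromosome VCFs) combine by
simple element-wise summation into the whole-genome fingerprint.

## Worked example

The package ships a synthetic-cohort simulator, so the whole pipeline runs
without any downloads:

```bash
# simulate three genomes from one population (~2k variants each)
genofp sim-cohort -o demo --individuals 3 --loci 3000 --chroms 3 --seed 41

# fingerprint, compare a genome with itself and with another genome
genofp fingerprint demo/ind0.vcf -o demo/ind0.fp
genofp fingerprint demo/ind1.vcf -o demo/ind1.fp
genofp compare demo/ind0.fp demo/ind0.fp
genofp compare demo/ind0.fp demo/ind1.fp
```

prints

```
1
0.550812
```

— the self-comparison is exact (ρ = 1), while two distinct individuals from
the same simulated population score well below the 0.75 identity threshold
yet well above 0 (they share the population's variant pool; population
adjustment removes exactly this shared component). A robustness curve for
one genome:

```bash
genofp robustness demo/ind0.vcf --mode missing --level 0.1 --level 0.3 --seed 1
```

```
level	correlation
0.1	0.8553272928848152
0.3	0.5403818333383594
```

shows the self-correlation degrading as variants are dropped at random (a
3,000-locus toy genome is far noisier than a full-size one, which stays
above 0.75 beyond 30% dropout — see the reproduction script below). Subcommands `merge`, `binary`, `allpairs`, `pop-build`,
`pop-adjust`, `classify`, `outliers`, `sim-pedigree`, `degrade` and
`export-matrix` cover the rest of the workflow; every one is a thin wrapper
over the `genofp` library API (`compute_raw`, `normalize`, `binarize`,
`spearman_compare`, `build_population`, `find_related_outliers`,
`simulate_cohort`, ...).

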