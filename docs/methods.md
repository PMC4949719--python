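# Methods

## Overview of the procedure

`bsrad` analyses directional bisulfite-converted RAD libraries without a
reference genome. The stages, and the assumptions each one makes:

1. **Demultiplexing** (`bsrad.demux`). Barcodes (default 6 bp) are kept at
   pairwise Hamming distance ≥ 3, so a read is assigned iff exactly one
   barcode lies within one substitution of its prefix — single-error rescue
   can never be ambiguous. Quality control uses the sliding-window rule:
   a read is discarded when the mean Phred score in any window of 15% of
   the read length (rounded half-up, minimum 1 base, sliding one base at a
   time) drops below 10. No restriction-site check is applied, because the
   converted cut-site remnant is itself data. Reads shorter than
   barcode + 6 bp cannot carry the diagnostic remnant and are discarded.

2. **RAD locus assembly** (`bsrad.radloci`). Unconverted reads are piled
   into *stacks* of identical sequences with depth ≥ `min_stack_depth`
   (default 20; 100 is appropriate for deeply sequenced libraries).
   Sub-threshold (secondary) reads are never used for haplotype calls.
   Stacks of one individual merge into a locus by single linkage at ≤ 7
   mismatches; merged groups with more than `max_locus_stacks` alleles
   (2 for diploids, 4 for tetraploids) are dropped as putative repeats.
   Per-sample loci merge across individuals at ≤ 9 mismatches into catalog
   loci. The catalog is filtered to ≤ 10 polymorphic columns and
   heterozygosity ≤ 0.75 (fraction of carrying samples with ≥ 2 distinct
   alleles) to avoid pooled paralogs, and at most 2 alleles per sample per
   locus are retained (uniformly at random under the run seed). Catalog
   order is lexicographic by consensus — deterministic and identical for
   every sample, which is what makes positions comparable downstream.
   Consensus is per-column majority with ties resolved to the
   alphabetically smallest base.

3. **Pseudo-references** (`bsrad.refbuild`). Each individual gets two
   concatenated references (copies A/B): heterozygous loci contribute one
   allele to each copy (assignment random under the seed — phasing is
   irrelevant because RAD loci are far apart), homozygous alleles are
   duplicated, absent loci become N-runs so the coordinate frame never
   shifts. Loci are joined with a 2-base `NN` spacer so no trinucleotide
   context can span a junction; coordinates are 0-based internally,
   1-based only in exported report files.

4. **Three-letter alignment** (`bsalign`). RAD reads start at the cut
   site, so alignment is an ungapped comparison anchored at locus starts.
   Two hypotheses are scored per locus: complement-of-converted-bottom
   (CTOB; both sequences reduced G→A, making read-A-over-reference-G —
   the bisulfite signal — free by construction) and converted original
   top (OT; reduced C→T). The best placement wins if it has ≤ `max_mm`
   mismatches (1 for diploids, 3 for tetraploids, reflecting the
   possibility of reads from non-retained homeologous alleles) and is
   unique; any tie across loci or hypotheses within one reference copy is
   reported ambiguous and dropped. Each of the two reference copies is
   aligned **independently**: a read from a homozygous locus maps to both
   copies, giving the two report columns per individual that downstream
   stages expect. N never matches anything; base qualities are ignored
   (filtering already happened). Original-strand classes (OT/OB) are
   removed by the strand filter — in this directional protocol they are
   rare and low-coverage. A toy-scale windowed scanner
   (`bsalign.scan_windows`) applies the same scorer to an arbitrary
   supplied sequence; it is quadratic and not meant for genome-scale use.

5. **Methylation calling** (`bsrad.methcall`). For CTOB alignments,
   cytosines live on the '−' strand, i.e. at reference G positions: read
   G = methylated, read A = converted, anything else (sequencing error)
   counts for neither. The first 4 aligned bases (the P1 adapter overhang,
   whose cytosine is unmethylated by construction) are never scored.
   Context is derived from the reference copy's own sequence, never from
   reads; a cytosine whose 3′ neighbours leave the locus (or hit an N) is
   `unknown` and excluded. A record is written for every reference
   cytosine including uncovered ones, so "no cytosine in this genotype"
   (SNP) remains distinguishable from "no coverage". Apparent methylation
   pooled over CHH positions estimates the conversion failure rate in
   genomes where true CHH methylation is negligible.

6. **Differential methylation** (`bsrad.diffmeth`). Reports are
   outer-joined into coverage / level / context tables with one column per
   sample × copy. Rows are classified: *SNP-missing* if any column lacks
   the cytosine by genotype; else *context-swap* if reference contexts
   disagree across columns; else *SMP candidate*. Filters: per group at
   least `min_samples_per_group` (default 2; 1 for very small designs)
   samples with pooled coverage ≥ 25; one context at a time; swap and SNP
   rows excluded. A prefilter drops rows with mean level < 10% or
   population SD < 10% across samples. The per-sample observation for
   testing is the coverage-weighted pool of the sample's two copy columns
   — using both columns as separate observations would pseudo-replicate
   individuals (a `per_copy` switch exposes the alternative). Groups are
   compared per position with `scipy.stats.ks_2samp` (asymptotic
   p-values); p-values become Storey q-values with the fixed-λ estimator
   (λ = 0.5): π̂₀ = min(1, #{p>λ}/((1−λ)m)), q(i) the running tail minimum
   of π̂₀·m·p(i)/i. Technical replicates are scored reproducible at a
   position when their levels agree within 0.10 (both ≥ 25×).

## The simulator

`bsrad.simdata` generates complete experiments with ground truth. What it
emulates: SbfI geometry (CCTGCA/GG; every locus begins with the TGCAGG
remnant; the adapter overhang cytosine unmethylated, hence the TACAAA
diagnostic prefix on converted CTOB reads and TGTAGG on top-strand reads);
diploid or tetraploid genotypes with per-copy substitutions at `snp_rate`
per base (never inside the remnant — a cut-site mutation would remove the
locus from a real library); planted homozygous C→T SNPs and
context-changing SNPs in a configurable fraction of individuals; Beta-
distributed per-position methylation; per-read Bernoulli methylation,
conversion failure (default rate 0.99) and sequencing error (default
1e-3); Poisson coverage (default 50× bisulfite, 100× unconverted); a small
fraction of converted-top-strand reads (default 0.5%, within the ~0.1–1%
seen in real directional libraries).

Methylation model: each position draws a population level θ from a
context-specific Beta prior — defaults CpG (0.37, 0.13), CHG (0.036,
1.964), CHH (0.022, 1.978), giving means 0.74 / 0.018 / 0.011 as reported
for an alpine carnation-family diploid, with the strongly bimodal CpG
shape typical of plant methylomes; a prior of (0, b) means exactly zero,
which is how an animal-like CHH-free genome is simulated. Individuals
draw their own level p_i ~ Beta(θκ, (1−θ)κ) with concentration κ = 10
(inter-individual SD up to ≈0.15). This dispersion is a modelling choice:
no distribution across individuals is published, and without it the
10%-SD prefilter would remove essentially every null position (binomial
SD at 50× is at most 0.07), leaving the null calibration of the test
unobservable. Planted differential positions instead set every individual
exactly to its group mean, with the two means separated by exactly
`diff_delta` (direction random), so recovery can be scored unambiguously.

What the simulator does **not** emulate: PCR duplicates and shared
conversion outcomes among reads of one molecule (reads are independent),
fragment-length/size-selection effects, the second cut-side fragment,
paired-end reads, indels, allele dropout by polymorphic cut sites, and
batch/lane effects. Passing tests therefore demonstrate the correctness
of the bioinformatic logic under idealized sampling noise, not robustness
to every artefact of real libraries.

## Numerical and degenerate-input choices

* All randomness flows from one seed through per-stage
  `SeedSequence([seed, stage])` generators; sample iteration is sorted, so
  identical inputs and seed give byte-identical outputs.
* Single-linkage components are computed exactly (vectorized Hamming
  matrix + connected components); no heuristic clustering.
* The aligner short-circuits exact reduced-alphabet matches through hash
  lookups; this is exact, because 0 mismatches under a reduction is
  string equality of the reduced sequences — the vectorized scan handles
  everything else and an exhaustive scan is the test oracle.
* Zero-coverage positions have undefined level (missing, never 0/0 = 0);
  `conversion_efficiency` returns None when no CHH position has coverage;
  `reproducibility` returns (None, 0) when no position qualifies.
* `qvalues` follows the fixed-λ formula literally: a batch whose p-values
  all lie below λ yields π̂₀ = 0 and hence all-zero q-values — at realistic
  m the estimator is fine, but single-digit batches should use the
  documented λ semantics consciously.
* The asymptotic KS p-value is used (as in the cited implementation) even
  for 9-vs-9 groups. With n = 9 per group the statistic only takes values
  k/9, the achievable test sizes near 0.05 are 0.126 (D ≥ 5/9) and 0.0336
  (D ≥ 6/9), and ties (levels identically ≈0 or ≈1 across individuals)
  push the realized null rejection rate further below nominal. The test
  is therefore conservative at these sample sizes; q-value thresholds
  remain valid (conservative) FDR bounds.

## Parameters that matter

| parameter | default | meaning / why |
|---|---|---|
| `min_stack_depth` | 20 reads | identical-read depth to call a stack; 100 for deep libraries |
| `stack_merge_mm` | 7 bases | within-individual stack→locus merge radius |
| `catalog_merge_mm` | 9 bases | cross-individual locus merge radius |
| `max_snps` / `max_het` | 10 / 0.75 | paralog-pooling guards on catalog loci |
| `max_locus_stacks` | 2 (4 tetraploid) | alleles per locus before the group is dropped |
| `max_alleles` | 2 | alleles retained per sample per locus |
| `max_mm` | 1 (3 tetraploid) | alignment mismatch budget |
| `trim_head` | 4 bases | adapter-overhang bases never scored |
| `min_cov` | 25 reads | per-sample coverage to use a position |
| `min_samples_per_group` | 2 | samples at `min_cov` required per group |
| `min_mean` / `min_sd` | 0.10 / 0.10 | level prefilter before testing |
| `qvalue_lambda` | 0.5 | π₀ estimator tuning constant |
| `conversion_rate` (sim) | 0.99 | P(unmethylated C reads as T) |
| `mean_coverage` (sim) | 50× | bisulfite reads per locus per sample |

## Problem sizes used in the checks

The study-scale validation runs 450 loci × 94 bp, 9 vs 9 individuals,
50× bisulfite and 100× unconverted coverage, 50 planted CpG differences
of 0.8 — chosen so that, after coverage filtering, more than 2000 null
CpG positions support the null-calibration estimate while keeping a
single-CPU run in tens of seconds. SNP disambiguation uses 160 loci,
3 vs 3 individuals, 100 planted C→T and 50 context-changing SNPs with
background substitutions disabled so every planted site stays
deterministic. Replicate reproducibility redraws reads (same genotypes
and methylation truth, fresh noise stream) for 120 loci at 50×.

## Known limitations

* Ungapped, anchor-at-cut-site alignment only; indel alleles and shifted
  reads are unmappable by design (gapped alleles are also not assembled).
* Tetraploids are reduced to two retained alleles per locus; reads from
  the discarded homeologs are absorbed by the 3-mismatch budget or lost.
* Coverage pooled across the two report columns double-counts reads at
  homozygous loci (every read maps to both copies); the per-copy reports
  carry true read counts, which is what the accuracy evaluation uses.
* The KS test is conservative below ~10 individuals per group (see
  above); with 2 individuals per group it is descriptive only.
* DMR (region-level) calling, SMP frequency-spectrum tests and any
  annotation of significant loci are out of scope.
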