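# Methods

## Model overview

`paleomethyl` infers regional CpG methylation in ancient genomes from the
differential post-mortem deamination of methylated and unmethylated
cytosines. Two estimation steps share one probabilistic kernel
(`paleomethyl.model`):

1. **Deamination profile.** Chromosome-wide single-cytosine observations,
   balanced between CpG and non-CpG context, yield maximum-likelihood
   estimates of `D[M, v, k]`, the probability that a cytosine in
   methylation state `M` at distance `k` from fragment terminus `v` reads
   as T. The non-CpG observations identify the unmethylated rate directly
   (non-CpG cytosines are assumed to deaminate at the unmethylated CpG
   rate); CpG observations see the mixture `F_global·D1 + (1−F_global)·D0`,
   which identifies the methylated rate given the user's prior belief
   `F_global` about the genome-wide methylated fraction.
2. **Windowed methylation fraction.** Piles of read dinucleotides over the
   CpG sites of a window enter a likelihood in `f`, the fraction of
   methylated CpG copies, marginalized over a 7-state diploid dinucleotide
   genotype so true variants are explained by genotype rather than damage.

### Observation model

Every observation is canonicalized to the strand that carries the cytosine:
forward-mapped reads inform reference C positions, reverse-mapped reads
inform reference G positions with bases complemented, so deamination always
reads as C→T. Three error channels apply in sequence:

* **deamination** flips an emitted C to T with probability `D[M, v, k]`;
* **sequencing error** (ε from the Phred base quality) keeps the emitted
  base with probability 1−ε and moves to each other base with ε/3;
* **mapping error** (Q from MAPQ, capped at 0.99) replaces the whole
  observation with a uniform draw over the observed base space.

For step 1 the four bases collapse to {C, T, OTHER}; step 2 keeps the full
base pair, and a position the read does not cover (or that fails the
base-quality filter, or is N) is marginalized out.

### Genotype space and prior

The genotype alleles are {CG, TG, CA}: exactly the dinucleotides whose read
signal can mimic strand-specific deamination of a CpG (T at the first
position on forward reads; A at the second position, i.e. a complemented
C→T, on reverse reads). The prior draws two independent alleles with
probabilities CG: 1−3θ and θ each for TG, CA, and "anything else";
genotypes containing an "other" allele collapse into an aggregate state
that emits uniformly. θ (default 0.001, roughly a per-site heterozygosity)
lives entirely in this prior. Note the reference genotype dominates the
aggregate state only while `(1−3θ)² > 2θ−θ²`, i.e. θ ≲ 0.155; the supported
range is θ ∈ [0, 0.25].

A deliberate symmetry: the C of a CA allele (forward strand) and the
strand-complement C of a TG allele (reverse strand) are non-CpG cytosines
and deaminate at the unmethylated rate. This makes the likelihood exactly
strand-symmetric and matches what the simulator produces; only the CG
allele carries the per-read Bernoulli(f) methylation mixture.

Each read is treated as an independent molecule, so methylation is
marginalized per read, not per site; with the genome panel emulating many
cells this is the intended interpretation of `f` as a cell fraction.
The genotype, by contrast, is shared by all reads of a site — one
individual, one diploid genotype — which is why the per-site sum over G
sits inside the product over sites.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `F_global` | 0.75 | assumed genome-wide methylated CpG fraction (mammalian somatic tissue: 0.70–0.80); only used in step 1 |
| `K_max` | 20 | modelled terminal positions per read end; interior bases are clamped into the last bin, where damage has plateaued |
| `theta` | 0.001 | per-allele non-reference probability of the genotype prior; 0 disables variant marginalization |
| `min_baseq` / `min_mapq` / `min_length` | 13 / 25 / 30 | standard aDNA quality filters (Phred, Phred, bp); all user-overridable |
| `n_cpg` / `step` | 50 / `n_cpg` | window size and step in consecutive CpG sites; non-overlapping by default |

## Numerical choices

* Step-1 bins are optimized independently (the likelihood factorizes
  exactly over `(k, v)` since each observation falls in one bin) with
  L-BFGS-B on [1e−8, 1−1e−8]², start (0.01, 0.1); identical observation
  patterns are collapsed to weighted counts first. Standard errors come
  from the observed Fisher information via central finite differences
  (h = 1e−5). Empty bins get rate 0 with a zero count; bins whose reads all
  have near-certain mapping error are flagged flat and zeroed with a
  warning.
* Step 2 evaluates the window log-likelihood on a 101-point grid over
  [0, 1], refines the argmax with bounded scalar minimization
  (xatol 1e−6) — the grid guards against multimodality — and brackets the
  95% CI by root-finding on the profile-likelihood drop at the χ²₁ 0.95
  quantile (3.8415), clipped to [0, 1]. Per-site genotype sums are done in
  log space (log-sum-exp), so windows with tens of thousands of reads do
  not underflow. The production path is a vectorized compilation of the
  per-observation probabilities (affine in f per allele copy); tests pin it
  to the scalar reference kernel and to exhaustive latent-state
  enumeration.
* Degenerate windows return NaN with a reason flag: `no_data` (no
  observations) or `flat_likelihood` (grid range below 1e−9, e.g. mapping
  error saturated). Trailing partial windows are kept when they still hold
  at least max(5, n_cpg/5) sites and are flagged `partial`.
* Terminal position: distance to the nearer read end in original read
  orientation, ties assigned to 5′, clamped at `K_max − 1`. Fragment length
  is the aligned query length (collapsed aDNA reads).

## The simulator

`paleomethyl.simulate` generates the validation data. It emulates shotgun
sequencing of one ancient individual: a panel of `n_genomes` (default 100)
diploid genomes stands for the cell population; each CpG is flagged
methylated per genome by a Bernoulli draw at the level of a user
methylation map (both haplotype copies and both strands share the flag); a
single diploid genotype per site is shared by the whole panel, with
optional CG→TG/CA variants (het:hom odds 2:1 by default). Fragments draw
genome, haplotype and strand uniformly, lengths from a truncated lognormal
(log-mean log 70 bp, log-sd 0.25, truncated to 30–150 bp — a typical aDNA
length profile), and deaminate every cytosine of the sequenced strand at
`D[M, v, k]`, using haplotype context so CpG status is not truncated at
fragment edges. Sequencing errors follow the configured Phred quality;
reads are written to a coordinate-sorted indexed BAM at their true
positions (MAPQ 37), making validation hermetic; a FASTQ with adapter
read-through is available for users who want a real mapping step.

Three built-in damage presets span realistic chemistry: `ds_high` and
`ds_mid` mimic double-stranded libraries (5′ C→T decaying exponentially
from 0.29–0.44 and 0.145–0.23 terminal rates respectively, quiet 3′ ends —
the familiar 3′ G→A signal emerges from the opposite strand), `ss` mimics a
single-stranded library with elevated C→T at both termini. Methylated rates
sit above unmethylated at every position.

What the simulator does **not** emulate: microbial/contaminant admixture,
mapping artefacts (reads are placed at their true positions, so real-data
mapping bias and mismapping are exercised only through the Q channel of the
model), indels, base-composition-dependent error spectra, CpG depletion of
real genomes (the i.i.d. reference is CpG-rich, which *raises* the number
of sites per bp relative to real data), and nick/overhang chemistry beyond
what the supplied rate matrices encode. Passing recovery tests therefore
demonstrate correctness of the estimator under its own model assumptions
and realistic damage/coverage regimes, not robustness to mapping bias or
contamination.

## Validation design and problem sizes

The acceptance suite (`tests/test_acceptance.py`, recomputed by
`scripts/acceptance.py`) runs: exhaustive-enumeration agreement of the
window likelihood (500+ small piles, 1e−10); profile recovery at 5× over a
1 Mb chromosome for all three presets (MAE ≤ 0.02 over the first 11
terminal positions); a coverage titration at 5/10/20/40× with ~20 windows
of 50 CpGs per methylation level {0.1, 0.5, 0.9} (RMSD decreasing in
coverage, |bias| ≤ 0.02 at 40× with the true profile supplied); CI
calibration over ~200 windows at 20×, f = 0.75 (empirical coverage ≥ 0.90;
profile-likelihood intervals over-cover somewhat in this regime, ~0.98);
variant robustness with heterozygous variants at 10% of CpGs (full prior
within 0.03 of the variant-free bias and strictly better than a θ = 0
analysis of the same reads, which is biased upward by ~0.25); the
closed-form limit f̂ = (T fraction)/d when ε = Q = θ = 0 and D₀ = 0; and a
4-SE screen of the simulator's emitted damage spectrum at 1 Mb, 10×.
These sizes keep the whole suite under two minutes on one CPU while leaving
comfortable statistical margins.

## Known limitations

* Asymmetric (non-CpG) methylation contexts are out of scope; only
  symmetric CpGs are modelled.
* One pooled deamination profile per sample — no read-group stratification.
* Step 1 ignores the possibility of A/G SNPs under a cytosine; the
  optional polymorphic-site filter (`filter_polymorphic_sites`, drop sites
  with > 20% non-C/T observations) guards against this.
* Per-CpG (single-site) methylation calls and between-sample differential
  testing are not provided; the estimand is regional.
* The profile-likelihood CI is conservative at moderate coverage (see
  calibration above); it is an interval on f within the model, not a
  posterior.
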