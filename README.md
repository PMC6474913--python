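# paleomethyl

Maximum-likelihood mapping of regional CpG methylation from ancient-DNA
damage patterns.

## The problem

DNA methylation does not survive standard ancient-DNA (aDNA) library
preparation in a directly readable form, but it leaves a statistical
footprint: post-mortem hydrolytic deamination converts cytosine to uracil
(sequenced as T), and 5-methyl-cytosine deaminates directly to thymine at a
*faster* rate than unmethylated cytosine. The excess of C→T
mis-incorporations at CpG sites in an ancient genome therefore carries
information about the methylation state of the tissue the sample came from.
Naive counting of CpG→TpG mismatches confounds that signal with sequencing
errors, mapping errors, true CG→TG/CA variants, and the strong position
dependence of damage along a DNA fragment. `paleomethyl` is for
palaeo-epigeneticists who want regional methylation levels from ordinary
shotgun aDNA BAM files — on the same scale as modern whole-genome bisulphite
sequencing (WGBS) values, with confidence intervals.

## The model

A two-step maximum-likelihood procedure over a BAM plus the mapping
reference:

**Step 1 — position-specific deamination rates.** For read observations
X covering reference cytosines (canonicalized to the cytosine strand), with
per-observation base-quality error ε and mapping error Q,

  L(D | 𝔻) = ∏ⱼ ∏ᵢ p(X_{j,i,k,v} | D_{M,k,v}, Q_{j,i}, ε_{j,i}, F_global)

where D_{M,k,v} is the deamination probability at distance *k* from
terminus *v* (5′/3′) in methylation state *M* ∈ {0,1}, and F_global is the
assumed genome-wide methylated CpG fraction (default 0.75, typical of
mammalian somatic tissue). Observations inside CpG context see the mixture
F·D₁ + (1−F)·D₀; an equal-sized sample of non-CpG cytosines pins down D₀.
The likelihood factorizes over (k, v) bins; each bin is a bounded 2-D
optimization with standard errors from the observed information.

**Step 2 — windowed methylation fraction.** For the dinucleotide pile X
over each CpG site s in a window (default 50 consecutive CpGs),

  L(f | 𝔻) = ∏_S Σ_{G ∈ 0..6} p(G = g) · p(X | f, G = g, D, θ)

where f is the fraction of methylated CpG copies in the window and G ranges
over the diploid dinucleotide genotypes built from alleles {CG, TG, CA}
plus an aggregate "other" state, with prior allele probability θ (default
0.001) per non-reference allele. Marginalizing G keeps true CG→TG/CA
variants from masquerading as methylation. f̂ is found by grid search plus
bounded refinement and reported with a 95% profile-likelihood CI.

A methylation-aware aDNA read simulator (diploid genome panel representing
the cells of one individual, per-cell Bernoulli methylation flags,
methylation- and position-specific deamination, variant injection,
sequencing errors, optional adapter read-through) provides end-to-end
validation by parameter recovery; see `docs/methods.md`.

## Worked example

Simulate a 60 kb chromosome at 20× with 75% methylation and strong
double-stranded-library damage, then run both steps:

```bash
cat > sim.yaml <<'YAML'
reference: {length: 60000, seed: 4}
preset: ds_high
methylation_level: 0.75
coverage: 20
n_genomes: 100
seed: 9
YAML

paleomethyl simulate --config sim.yaml --out-prefix sim
paleomethyl deam   --bam sim.bam --ref sim.fa --chrom sim1 --out profile.tsv
paleomethyl methyl --bam sim.bam --ref sim.fa --profile profile.tsv \
                   --chrom sim1 --out methyl.tsv
```

`profile.tsv` begins:

```
# paleomethyl deamination profile K_max=20 F_global=0.75
terminus  position  rate_unmeth  rate_meth   se_unmeth    se_meth    n_obs_unmeth  n_obs_meth
5p        0         0.3172756    0.46980378  0.017457649  0.02522664 712           726
5p        1         0.22366868   0.34661192  0.015366393  0.02411609 739           694
```

The 5′-terminal unmethylated rate is estimated at 0.317 and the methylated
rate at 0.470 (the simulation truth is 0.29 and 0.442 — within about one
standard error at this small chromosome size), and both decay with distance
from the terminus as configured. `methyl.tsv` then holds one row per
50-CpG window:

```
chrom  start  end   n_cpg  n_obs  f_mle     ci_low    ci_high  loglik    flag
sim1   25     1291  50     948    1         0.690551  1        -162.867  ok
sim1   1346   2396  50     1014   0.774268  0.301885  1        -155.072  ok
```

Window estimates scatter around the true methylated fraction 0.75; the wide
CIs are honest — with a window of 50 CpGs at 20×, only the few read
positions near fragment termini carry strong damage signal. Uninformative
windows are reported as `NA` with a reason code instead of a number.

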