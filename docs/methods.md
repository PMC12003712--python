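# Methods

## Scope and model of the data

The package treats a two-cohort SNP-array CNV metabolomic-QTL study as a
chain of well-defined operations on four objects: a probe map, per-sample
LRR/BAF intensity matrices, per-probe copy-number dosages, and a metabolite
panel with covariates. All data are simulated; the generator is first-class,
tested code, and its ground truth (integer copy states, planted effect
sizes) is the calibration oracle for every downstream stage.

## Synthetic data generator

**Probe map.** Probe positions are cumulative exponential gaps (mean
3,000 bp, configurable) over a configurable number of chromosomes. GC
fraction is a moving average (window 25 probes) of white noise around 0.41,
clipped to [0.2, 0.8], so adjacent probes share GC context — spatial
coherence is required for a GC correction step to be identifiable.

**CNV truth.** CNV regions are declared as (chrom, start, end, copy state,
carrier frequency) with states in {0, 1, 3, 4}; carriers are Bernoulli draws
per sample, all other probes are copy-neutral (state 2). Overlapping regions
with conflicting states are a configuration error.

**Intensities.** LRR = state mean + GC term + wave + noise, with state
means (−3.5, −0.66, 0.0, 0.40, 0.68) for copies 0–4 — the conventional
Illumina-style levels, configurable. The GC term is `gc_coefficient ·
(gc − mean gc)` (default 0.5), shared across samples. The wave is a
per-chromosome sinusoid (default period 1 Mb, amplitude 0.05) scaled per
sample by a lognormal(0, 0.3) factor: real array waves vary in strength
between samples but do not vanish, and a strictly positive scale makes the
variance contribution of the wave deterministic in sign. LRR noise is
Gaussian, default sd 0.20 (comparable to the copy-neutral emission sd of
typical array platforms; no platform fit is claimed). BAF is drawn from the
allelic cluster of the true state — cluster means at k/state for k allele
copies, binomial(state, 0.5) weights, Gaussian jitter sd 0.03, clipped to
[0, 1]; homozygous deletions have no allelic signal and draw uniform BAF.

**Phenotypes.** Metabolites are a block-correlated Gaussian field:
`x = √r·z_block + √(1−r)·ε` with default blocks of 12 at within-block
correlation r = 0.6, emulating the strong within-class correlation of NMR
lipoprotein panels (the default panel size is 228). Planted effects add
`β · (copy_state − 2)` at declared (probe, metabolite) pairs. Sex is
simulated independently, has no phenotype effect by default, and enters the
covariates only.

**Seeding.** Every stream (map, truth, noise, wave, BAF, phenotypes, sex)
is a named `SeedSequence` child of the config seed, so a fixed seed gives
bitwise-reproducible panels and changing one knob (e.g. wave amplitude)
leaves all other draws untouched — paired comparisons between configurations
are exact. Two cohorts are two generator calls with distinct seeds.

**What the generator does not emulate:** batch/plate structure, probe
cross-hybridisation, platform-specific cluster asymmetries, missing calls,
X/Y chromosomes, haplotype phase, and LD between CNVs and flanking SNPs.
Tests passing here show the pipeline's operations are correct and calibrated
under the stated generative model, not that real-array artifacts beyond GC
and wave are handled.

## Normalisation

GC correction is a per-sample least-squares fit of LRR on GC fraction;
residuals keep the sample mean. Wave correction is a loess-style local
linear regression of LRR on position — tricube weights in a ±250 kb
neighbourhood (500 kb window default), degree 1 for stability at chromosome
ends, per sample and chromosome, trend subtracted and sample mean restored.
Windows with fewer than 5 probes fall back to the window mean with a logged
warning.

The trend is estimated on a winsorized copy of each sample's LRR (clipped to
median ± 0.5). Without this, a genuine homozygous-deletion block at LRR
−3.5 drags the local trend down and the subtraction pushes the block's
neighbourhood up by as much as +1, which a copy-number caller then reads as
confident duplication; winsorizing keeps CNV signal out of the wave
estimate while leaving the smooth artifact visible. GC correction runs
before wave correction so the positional trend being removed is not
GC-confounded.

Covariate PCs are computed from the corrected LRR matrix (column-centred,
full SVD). The conventional covariate set is 50 PCs plus a sex indicator; k
is capped at the rank bound with a warning for small simulations.

## Copy-number HMM

Five hidden states, the copy numbers 0–4. Emissions: Gaussian LRR per state
(default sds 1.0, 0.30, 0.20, 0.25, 0.28 — wide for the noisy
homozygous-deletion dropout) times a truncated-normal BAF mixture on [0, 1]
with components at the allelic ratios of the state and binomial(state, ½)
weights; state 0's BAF term is uniform. Missing BAF drops the BAF factor;
an all-missing chromosome yields uniform posteriors with a warning.

Transitions are distance-aware: `p_switch = clip(1 − exp(−ρ·d), pmin, pmax)`
with ρ = 2·10⁻⁶ per bp, pmin = 10⁻⁴, pmax = 0.2; leaving mass is distributed
over the other states proportional to the stationary prior
(0.001, 0.010, 0.978, 0.008, 0.003), so rows forget toward the prior at
large gaps. The chain is initialised at the stationary prior per chromosome.

Forward–backward uses scaled (normalised-alpha) recursions plus a per-probe
max-shift of the emission log-densities, so 10⁵-probe chromosomes cannot
underflow; the sequence log-likelihood is returned. Correctness is pinned by
a brute-force enumeration oracle on 3-probe chains (all 125 paths, 1e-10
agreement for posteriors, Viterbi path and path score, over 100 random
parameter draws).

The expected genotype (countAll) is the posterior-weighted sum of states,
exactly the mirror-model dosage: deletions, neutral and duplications in one
additive vector on [0, 4]. Deletion-only and duplication-only variants
restrict the expectation to states {0,1,2} / {2,3,4} and renormalise; a
probe with zero restricted mass is reported as 2.0 (no evidence either
way). The dosage-based allele frequency is the folded mean absolute
deviation `min(f, 1−f)` with `f = Σ|countAll − 2| / (2n)` — one declared
convention among several possible CNV-MAF definitions.

Viterbi segments are maximal runs of one non-neutral state; coordinates are
1-based inclusive probe spans in memory and 0-based half-open BED on disk.

## Association

The dosage is treated as a continuous outcome and fitted by ordinary least
squares, not ordinal regression: countAll is an expectation on [0, 4], and
the reverse-regression t-test is algebraically the forward test after
residualising covariates out of both sides (this equivalence is asserted in
the tests). Covariates (sex, LRR PCs) appear in every model and are never
selection candidates; collinear covariates are dropped with a warning.

Backward selection refits the full joint model each step and removes the
largest-p metabolite while that p exceeds `drop_alpha` (default 0.05); the
signature's joint p is the F-test of the selected metabolite block against
the covariate-only model, and an empty selection reports p = 1. When
n ≤ M + C + 2 the metabolites are pre-screened to the top min(M, n/10) by
univariate p before the joint fit.

The effective number of tests uses the sample variance (divisor M−1) of the
correlation-matrix eigenvalues; this convention makes the perfect-correlation
limit collapse exactly to M_eff = 1. Adjustment is Sidak exponentiation,
`1 − (1 − p)^{M_eff}`, computed via `expm1`/`log1p` so p = 1e-300 maps to
M_eff·p without cancellation. The global reporting filter marks records with
adjusted p ≤ 0.05.

Stratified validation labels samples deletion/neutral/duplication at
countAll 1.75 and 2.5 and runs two-sided Mann–Whitney U per contrast —
exact enumeration below 25 total samples when untied, normal approximation
with tie correction otherwise; a contrast with fewer than 2 samples in a
group is skipped with a status string rather than a p-value.

## Cross-cohort combination

Common probes are exact (chrom, position) matches — no liftover, no fuzzy
matching. Meta-analysis is fixed-effect inverse-variance (w = 1/se²) with
two-sided normal p and Cochran's Q reported for a future random-effects
extension; the estimator is a declared choice. Pooling stacks samples with
per-cohort covariates block-stacked (each cohort's PCs act only on its own
rows) plus cohort indicator columns, then runs the same univariate reverse
regression.

## Beacon annotation

GWAS rows join to probes purely by coordinate (|Δpos| ≤ window, default
window 0; a 4 bp window is available as an option) via per-chromosome binary
search — the rsid is carried through but never consulted, keeping the
matching variant-agnostic. Beacon flags are strictly binary, derive entirely
from the evidence tables passed in (no hidden state; flag totals equal
independent recounts), and follow a registered schema: metabolomic
signature, LRR signature, CNV presence per cohort, GWAS overlap.

## Orchestration and reproducibility

The pipeline derives per-stage seeds as `SeedSequence((master, stage_id))`,
so stages are independently re-runnable; the manifest stores SHA-256
checksums of every output, and two runs with the same config are
byte-identical. Association in the pipeline is restricted to polymorphic
probes (dosage MAF ≥ 0.01 by default) — monomorphic probes carry no testable
dosage contrast.

## Problem sizes

Default test and pipeline scales are chosen to exercise every code path at
desk scale: simulation-based checks use 40–60 samples × 300–600 probes for
HMM segmentation, n = 500–2000 for regression calibration and selection
recovery (1000 null replicates; 50 selection replicates), and the demo
pipeline 60 samples × 300 probes × 8 metabolites. The generator itself
handles the full 228-metabolite panel; nothing in the implementation is
specific to the small sizes.

## Known limitations

- The HMM is per-sample; no population haplotype sharing or CNV-SNP phasing,
  and no rare-variant or very-large-event specialisations.
- Autosomes only; no X/Y dosage model.
- The CNV allele-frequency and meta-analysis estimator conventions are
  declared package choices (alternatives are isolated in single functions).
- GC and wave are the only intensity artifacts modelled and removed; no
  batch/plate correction.
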