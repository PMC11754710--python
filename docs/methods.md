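# Methods

This document describes the statistical model, the numerical choices, and the
limitations of `rangecoal`. The README covers installation and a worked
example; this file is the reference for *what is computed and why*.

## 1. Problem setting

`rangecoal` infers the mode (dichotomous split vs. hybrid founding) and time
of origin of a focal population from reduced-representation SNP data
(RAD-seq-style), using:

1. a two-stage SNP filter producing a "complete" and a "reduced" dataset,
2. missing-data-aware folded two-dimensional site-frequency spectra (2D SFS),
3. a structured-coalescent simulator for three- and four-deme demographic
   models with divergence, admixture, size changes, and continuous migration,
4. composite-likelihood fitting with AIC model selection, and
5. parametric-bootstrap confidence intervals on divergence times, converted
   to years with a fixed mutation rate and generation time.

A synthetic-data generator with known ground truth exercises the entire
pipeline end to end.

## 2. Variant filtering

Input is a genotype matrix (diploid genotypes coded 0/1/2 alternate-allele
copies, −1 missing) with per-genotype read depth, per-sample deme and
sampling-site labels, and per-SNP locus labels.

**Complete dataset** (applied in this order; all thresholds inclusive):

1. Drop entire loci carrying more than 10 SNPs (paralog/repeat guard).
2. Per remaining locus, keep one SNP chosen uniformly at random (seeded)
   among SNPs that individually satisfy rules 3–5; if none qualifies the
   locus contributes nothing.
3. Missingness: fraction of missing genotypes ≤ 0.5.
4. Observed heterozygosity among called genotypes ≤ 0.5.
5. At least 2 carriers of the minor allele (ties between alleles use the
   smaller carrier count of the two).

When a SNP fails several rules, the recorded reason follows the priority
missingness > heterozygosity > singleton.

**Reduced dataset** (derived from the complete dataset):

1. Genotypes with depth < 6 are set missing.
2. Every sampling site must retain ≥ 2 called genotypes at the SNP.
3. SNPs that become monomorphic or exactly 50% alternate after masking are
   dropped.

VCF input is parsed with cyvcf2 (reading `FORMAT/DP` directly; cyvcf2's
`gt_depths` accessor returns −1 on minimal GT:DP records). A minimal VCFv4.2
writer is provided for round-tripping.

## 3. Folded 2D SFS with missing data

For each unordered deme pair, every SNP is downsampled so each sampling site
contributes **exactly 4 haploid alleles**, drawn uniformly without
replacement from the site's called alleles at that SNP (sites with fewer than
4 called alleles contribute nothing, and the SNP is skipped for a pair if any
of the pair's sites fails). The pair's haploid sample sizes are therefore
fixed at 4 × (number of sites per deme). Only allele counts matter for the
spectrum, so the 4-allele block is drawn as a hypergeometric variate; one
seeded realisation is shared by all pairs so pairwise spectra are mutually
consistent.

The joint spectrum is folded on the **pooled** minor allele across the pair:
cell (i, j) with 2(i+j) > n_a + n_b maps to (n_a − i, n_b − j); on the tie
diagonal 2(i+j) = n_a + n_b the lexicographically smaller member of each
complement pair is kept. The mask excludes the uninformative cells and all
cells that folding makes structurally unreachable:

- the monomorphic cell (0, 0),
- the singleton diagonal i + j = 1,
- cells with 2(i+j) > n_a + n_b and lexicographically larger tie cells.

Masking the structurally-zero cells matters numerically: the likelihood's
probability floor (below) would otherwise assign them positive expected
probability, stealing mass from reachable cells.

## 4. Coalescent engine

The engine simulates genealogies of the downsampled samples backwards in time
under a model described by: deme sizes (diploid N), merge events, admixture
events (a hybrid deme's lineages choose parent a with probability α), size
changes (including the two-event encoding of a post-founding bottleneck at
0.005 × present N for 50 generations), and piecewise-constant backwards
migration. Waiting times are competing exponentials over pairwise coalescence
(rate k(k−1)/(4N) per deme) and migration; events interrupt at their
scheduled times. Kernels are numba-compiled; batch simulations use a single
numba-local RNG seed per call.

**SNP-pattern law.** The expected pattern distribution of a polymorphic site
is xi ∝ E[branch length subtending the pattern], i.e. probabilities are
E[L_i] / E[L_tot] with genealogies size-biased by total branch length — not
the equal-weight average E[L_i / L_tot]. `expected_pair_sfs` therefore
accumulates every branch of every simulated genealogy weighted by its length
(low variance), and `sample_snp_patterns` draws genealogies with probability
proportional to total tree length from an oversampled pool (factor
`oversample`, default 2) before placing one uniform mutation per SNP. The
distinction is numerically material: for a single deme with n = 4 the folded
proportions are 8/11 and 3/11 under the correct law but ≈ 0.738/0.262 under
equal weighting. Both code paths are verified against the analytic folded
SFS and against msprime as an independent oracle (test-only dependency).

Sampled SNPs drawn from a finite genealogy pool have slightly more than
multinomial variance; tests that compare sampled counts to expectations use a
large `oversample`.

**Event-time ordering.** Parameter vectors are validated before simulation:
times must be non-negative, every non-root time must be *strictly* below
TDIV_ANC, explicit order constraints (e.g. TDIV_GAL < TDIV_ANC) are strict,
and no event may fall inside another deme's 50-generation post-founding
bottleneck window. Strictness is required, not cosmetic: with tied merge
times the root merge could execute first and strand lineages in an extinct
deme. Invalid vectors get log-likelihood −inf.

## 5. Model catalogue

Eleven named models (13 catalogue rows) cover the study design:

- 3-deme (Pgal, Pnig, Pspi): `3-dicho`, `3-dicho+mig`, `3-hybGAL`.
- 4-deme (Pgal, Pnig, PspE, PspW): `4-dicho`, `4-dicho+mig` (each with
  submodels `a`/`b` for the two divergence orders), `4-hybSPW`,
  `4-hybGALearly`, `4-hybGALearly+mig`, `4-hybGALlate`, `4-hybGAL+hybSPW`,
  `4-hybGALSPW`.

Background gene flow (Pnig↔Pspi in 3-deme; Pnig↔PspE and PspW↔PspE in
4-deme) is present in every model; `+mig` adds focal gene flow involving
Pgal. Hybrid models add a founding admixture (proportion α) followed by the
bottleneck. Default parameter ranges: population sizes 1e2–2e5 (log scale),
migration rates 1e-8–1e-2 (log), α 0.01–0.99, times 100–139,000 generations
(linear). `build_model(name, submodel, overrides=..., sample_sizes=...)`
returns a model; `overrides` fixes parameters, `sample_sizes` sets haploid
sample sizes per deme. Default haploid sizes are 4 × sampling sites of the
study design (3-deme: Pgal 12, Pnig 16, Pspi 32; 4-deme: Pgal 12, Pnig 16,
PspE 24, PspW 8).

## 6. Composite likelihood, optimiser, model selection

The log10 composite likelihood sums observed counts × log10 expected
probabilities over unmasked cells of all pairwise spectra, treating SNPs as
independent. Expected probabilities come from `n_sims` simulated genealogies,
floored at 1/(10 × n_sims) and renormalised so unseen cells stay finite.
`MaxObsLhood` is the entropy ceiling obtained by plugging the observed
proportions in as probabilities; `MaxEstLhood ≤ MaxObsLhood` always.

The optimiser is an ECM-flavoured coordinate search: starts are rejection
sampled from the ranges until they satisfy the event-order validation; each
cycle re-draws common random numbers, then proposes ± steps per coordinate
(multiplicative on log-scale parameters), accepting only improvements and
halving the step otherwise; `n_replicates` independent starts are run and the
best kept.

Model comparison uses AIC = 2k − 2 ln(10) × MaxEstLhood with k the number of
free parameters; ΔAIC ≥ 10 is treated as decisive. Three-deme and four-deme
fits are never comparable (their observed spectra differ) and comparing them
raises an error.

## 7. Calibration

Generations convert to years with a 3-year generation time. The TDIV_ANC
prior range derives from net nucleotide distances d via t = d / (2 μ) with
μ = 5.9e-9 substitutions/site/generation, each bound rounded **up** to the
nearest 1,000 generations (0.000494680 → 42,000; 0.00163939 → 139,000).

## 8. Synthetic data generator

`generate_dataset(SyntheticConfig)` simulates SNP patterns from any catalogue
model (via the engine's size-biased sampler), assigns them to loci and
sampling sites following the study layout, and adds realistic nuisance
structure: per-genotype depths from a negative binomial (mean 20, dispersion
5) so the depth rule genuinely fires, random genotype missingness, and
whole-site dropout blocks. Because the 2D SFS stage keeps 4 of each site's 8
called alleles, generation uses **doubled** haploid sample sizes so the
downstream spectra have the intended sizes. `pseudoreplicate_sfs` shortcuts
straight to observed spectra (used for recovery, selection, and bootstrap
experiments); `direct=True` skips the sampling noise and returns rounded
expectations.

What the generator does **not** emulate: linkage within loci (each retained
SNP is an independent genealogy), sequencing error/genotype miscalls, allele
dropout correlated with genotype, and reference bias.

## 9. Reduced problem sizes

Production-scale fits of this kind typically use ~1e7 simulations per
likelihood evaluation on a cluster. The test suite and `scripts/acceptance.py`
are designed for one CPU and minutes, using the package's ordinary public
knobs: smaller haploid
sample sizes via `sample_sizes`, nuisance parameters fixed at their
generating values via `overrides`, fewer simulations per evaluation, and
fewer optimiser cycles/replicates. These reduce Monte-Carlo precision, not
correctness; the acceptance experiments quantify the resulting error
directly (relative error of recovered times, ΔAIC margins, bootstrap
coverage).

## 10. Limitations

- Composite likelihood ignores linkage between SNPs, so AIC differences are
  heuristic rather than exact.
- The coordinate search is a local optimiser; multi-start mitigates but does
  not eliminate local optima. Use more replicates/cycles for production fits.
- Expected spectra are Monte-Carlo estimates; likelihood surfaces are noisy
  at small `n_sims`. Common random numbers per cycle keep comparisons fair
  within a cycle.
- The probability floor biases very small expected probabilities upwards;
  this is the standard trade-off for finite simulation budgets.
- Migration is piecewise constant between events; continuous change over
  time is not modelled.
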