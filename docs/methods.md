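# Methods

This note documents the statistical procedures implemented in
`indelassoc`, the choices made where the design was genuinely open, and
what the synthetic-data generators do and do not emulate.

## Data model

A cohort is one record per animal: genotype per biallelic indel locus
(II/ID/DD; insertion and deletion alleles), first-parity litter size
(positive integer, typically 1–3 in goats), and optional covariates that
the default models ignore. Missing data are handled **per locus**: an
animal untyped at one locus still contributes everywhere else. This is
essential because candidate-gene panels are often typed on different
subsets (here 501 animals at one locus, 1122 at another). Genotype tokens
are normalized case-insensitively through an alias table (`I/D`, `+/-`,
…) because lab sheets vary; `NA` is preserved as missing, never dropped.

Two totals for the same genotype group can legitimately disagree between
published tables (e.g. 919 vs 922 insertion homozygotes); the package
never reconciles such discrepancies silently — validation output surfaces
both, and the reproduction tolerances absorb the difference.

## Per-locus parameters

With insertion-allele frequency `p = (2 n_II + n_ID) / 2n` and `q = 1 − p`
(always from raw counts, never from rounded frequencies):

- homozygosity `Ho = p² + q²`, gene diversity `He = 1 − Ho`,
  effective allele number `Ne = 1/Ho`,
- Botstein polymorphism information content `PIC = He − 2 p² q²`
  (the biallelic case of `1 − Σp_i² − Σ_{i<j} 2 p_i² p_j²`).

`Ho + He = 1`, `Ne·Ho = 1` and `0 ≤ PIC ≤ He` (equality only at fixation)
hold by construction and are asserted as property tests.

### Hardy–Weinberg testing

The χ² goodness of fit compares observed counts with `(n p², 2npq, n q²)`.
The **default df is 1** (three classes minus one constraint minus one
estimated allele frequency), the field-standard convention. df = 2 is
exposed because some legacy software reports it, and near the 0.05
boundary the two conventions disagree — both bundled loci are exactly such
cases (statistics 4.86 and 5.34: p ≈ 0.027/0.021 at df 1 but 0.088/0.069
at df 2). Reports print both p-values whenever they straddle 0.05, rather
than guessing which convention a given source used. No continuity
correction is applied; for small homozygote classes (one locus here has
n_DD = 3, where the χ² approximation is dubious) the **exact conditional
test** is provided: conditioning on the observed allele counts, every
compatible heterozygote count is enumerated, each outcome's Levene
probability computed in log space, and outcomes no more probable than the
observed one are summed (two-sided, point-probability ordering, with a
1e-12 log-slack so exact ties are never excluded by rounding). Calibration
is verified empirically: over 2000 loci simulated under Hardy–Weinberg
proportions (n = 500, p = 0.2) the rejection rate at α = 0.05 stays ≤ 6%
(the test is conservative, as exact conditional tests are).

## Linkage disequilibrium

Haplotype frequencies for a locus pair are estimated from the 3×3 joint
genotype table by EM under random mating. Every cell except the double
heterozygote contributes fixed haplotype counts; the ID×ID cell is split
between coupling (AB/ab) and repulsion (Ab/aB) phase in proportion to the
current frequency products, and the M-step recounts expected haplotypes.
Because both phase assignments carry the same allele counts, the marginal
allele frequencies are invariant across iterations and equal the sample
frequencies — which reduces the likelihood to a one-dimensional profile in
p_AB and makes a fine grid sweep a practical exhaustive oracle (used in
tests, together with a coarse sweep of the full 3-simplex as a safety
net).

Numerical choices: initialization at linkage equilibrium (product of
marginal frequencies) plus **one seeded random restart** to guard the rare
boundary ridge, keeping the better likelihood; convergence when the
largest frequency change drops below 1e-10, capped at 1000 iterations —
far tighter than the 2-decimal reporting such studies use. The EM
log-likelihood is non-decreasing within a run (asserted on random tables).

From haplotype frequencies: `D = p_AB − p_A p_B`; `D′ = |D|/D_max` with
the usual sign-dependent `D_max`, and `D′ := 0` at `D = 0` (continuity,
avoiding 0/0); `r² = D²/(p_A p_a p_B p_b)`. LD is undefined (error, not
NaN) for monomorphic loci; the pairwise matrix routine converts that error
to a blank cell without aborting other pairs, and uses pairwise-complete
observations per pair. Parameter recovery is verified by simulation: mean
absolute D̂′ error < 0.05 at n = 5000 across D′ ∈ {0, 0.3, 0.6, 1.0}
(p_A = 0.2, p_B = 0.1, five seeds each).

## Association testing

Contingency tables cross litter-size class (binary: single vs ≥ 2 lambs;
or one row per observed litter size) against genotype columns II/ID/DD.
The test is chosen by the classical **expected-count switch rule**:
Pearson χ² (no continuity correction, df = (r−1)(c−1)) when every expected
cell is ≥ 5, otherwise the Freeman–Halton exact test. All-zero rows or
columns are dropped with a warning first; a table that degenerates to a
single row or column yields p = 1 with a degenerate flag.

The **Freeman–Halton test** enumerates every table with the observed
margins (rows and columns sorted so the largest margin in each direction
is the one determined by the others, which keeps the visited count near
its combinatorial minimum: ~800 tables for the bundled 2×3 panel, ~45 000
for the 3×3), computes each table's multivariate hypergeometric point
probability by log-factorial accumulation (stable at n > 1000), and sums
probabilities ≤ the observed one. A relative tie tolerance of 1e-7
prevents floating-point exclusion of exact ties — matching standard
statistical-package behaviour. An upper bound on the enumeration size is
checked first; configurations beyond 1e8 candidate tables raise a
capacity error instead of hanging (Monte-Carlo approximation is out of
scope). On 2×2 tables the procedure reduces exactly to the classical
two-sided Fisher test (verified against an independent implementation on
200 random tables).

The **cumulative-subset scan** draws one seeded permutation of the cohort
and re-runs the switch-rule test on nested prefixes grown in steps of 100
animals (plus a final all-animals stage). Nesting — rather than
independent subsets — means each stage accumulates the previous one, so a
stable association should stay significant as n grows while a
subset-driven artefact decays. The final stage reproduces the full-cohort
test exactly regardless of seed, and the scan is bit-reproducible from its
seed. Under a simulated null effect the final-stage rejection rate is
calibrated at ~5%.

**Genotype effects** use the reduced one-factor linear model. The full
model for litter size includes year, herd-year-season and parity terms,
but for first-parity records those covariates are constant or confounded
and drop out, so each genotype's least-squares mean is its arithmetic
mean, with SE = sample SD/√n (n−1 denominator). Pairwise comparisons use
the **pooled-variance Student t-test** (df = n₁+n₂−2) by default — Welch
is an option — with explicit degenerate handling (zero pooled variance:
t = 0, p = 1 for equal means). Genotype groups below `min_n = 5` are
excluded from testing and reported with their reason; the exclusion
applies to effect estimation only, not to contingency tables, which keep
rare-genotype columns (mirroring how such studies report both).

## Expression (2^−ΔΔCt)

Replicate Cts are averaged **on the Ct scale** per (sample, gene) before
differencing — standard ΔΔCt practice; with balanced replicates this
equals averaging the replicate-wise differences (asserted on fixtures).
ΔCt = Ct_target − Ct_reference; ΔΔCt subtracts the **mean ΔCt of a
designated calibrator group** (figures in such studies show group-relative
fold changes, and the calibrator choice is a required user input);
RQ = base^−ΔΔCt with base 2 by default (perfect doubling per cycle;
configurable, no Pfaffl efficiency correction). Samples missing a
reference Ct are dropped with a warning. Group summaries report mean
RQ ± SE and two-sided t-tests tiered at 0.05/0.01 (the one-star/two-star
figure convention); a default age→stage scheme pools testis samples from
0 days–4 weeks as mitotic and 6–8 weeks as meiotic.

## Synthetic data

The generators emulate exactly the structure the analysis assumes:

- genotypes i.i.d. under Hardy–Weinberg proportions at a given allele
  frequency, or exact genotype counts randomly assigned — defaults mirror
  the bundled panels (allele frequencies 0.908/0.092 and 0.205/0.795;
  explicit counts (919, 200, 3) and (29, 147, 325));
- locus pairs built from haplotype frequencies at a target D′ (2n
  haplotypes drawn i.i.d. and paired at random, genotypes emitted
  unphased), spanning equilibrium to complete linkage;
- litter size as a genotype-conditional categorical over classes {1,2,3}
  rather than a latent-threshold model — the analysis consumes only class
  counts and group means, so the categorical is sufficient and
  transparent. The shipped effect spec reproduces the observed
  heterozygote advantage of ≈ +0.16 lambs (class probabilities
  II (0.579, 0.409, 0.012), ID (0.420, 0.570, 0.010), DD (0.333, 0.667,
  0)); the null spec gives every genotype the same class probabilities;
- replicate Ct tables with between-sample ΔCt noise (tests use 0.25
  cycles, a low-noise qPCR setting under which a twofold change at
  n = 4 vs 3 is ≈ 2 within-group SDs on the RQ scale) and small
  replicate-level scatter (0.05 cycles).

One global integer seed drives a `SeedSequence` splitting scheme (one
child per locus, then one for phenotypes), so identical seeds give
byte-identical cohorts and adding a locus does not perturb the phenotype
stream.

What the generators do **not** emulate: pedigree and herd structure,
selection, genotyping error, multi-parity longitudinal phenotypes, and
qPCR amplification-efficiency variation. Passing tests therefore show the
estimators are correct under their stated assumptions, not that those
assumptions hold in any particular flock.

## Problem sizes used in the test suite

The suite runs the full bundled panels (n up to 1122; the 3×3 exact test
enumerates ~45 000 tables in well under a second), 2000 simulated loci
for exact-HWE calibration, 500 replicates for type-I and power checks,
and n = 5000 pairs for D′ recovery — sizes at which Monte-Carlo error is
comfortably below the asserted tolerances.

## Known limitations

- Only biallelic loci: the general multi-allelic Botstein sum is
  documented but not implemented.
- Pairwise LD only; no multi-locus phasing.
- The exact r×c test is full-enumeration only; tables beyond the
  enumeration budget need an external Monte-Carlo approach.
- The published table this package bundles reports one subset row whose
  printed exact p equals the one-sided tail rather than the two-sided
  value; the reproduction report flags it as a documented mismatch rather
  than matching it.
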