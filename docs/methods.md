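# Methods

This note documents the statistical models, algorithms and design
choices behind hevecore, in the spirit of a model-documentation page:
what is computed, under which assumptions, and what the synthetic-data
tests do and do not establish.

## Genotype coding and filtering

Genotypes are coded 0 (0/0), 1 (0/1 or 1/0), 2 (1/1) and 9 (missing).
Half calls such as `0/.` are coded 9: a single observed allele cannot
distinguish a homozygote from a heterozygote, and the conservative
choice biases no statistic. Only biallelic diploid SNPs are supported;
multi-allelic records raise a named error rather than being silently
split.

Three filters with deliberately different threshold semantics:

- `filter_samples(max_sample_missing=0.999)` — by default only samples
  with essentially no data are dropped (the assay-failure case); the
  threshold is exposed for stricter QC.
- `filter_variants(min_depth=20, max_locus_missing=0.10, min_af=0.05)`
  — the variant-calling filter. Depth masks *genotypes* (DP < 20 → 9)
  before locus-level screening; this genotype-masking reading of a
  per-sample depth requirement is a documented choice — the alternative
  (dropping whole loci on any under-covered sample) discards far more
  data. Locus thresholds are inclusive (≤ 10% missing, ≥ 5% MAF
  survive). MAF is computed over non-missing alleles; missing genotypes
  are never imputed into denominators.
- `select_panel_loci(min_maf=0.3, max_missing=0.5, min_spacing_bp=2e6)`
  — the assay-design screen uses *strict* inequalities, and physical
  spacing is enforced by a greedy left-to-right scan (keep a locus only
  if ≥ 2 Mb from the last kept locus on the chromosome). Greedy
  scanning is deterministic and order-independent given sorted
  positions; an exact maximum-cardinality spaced subset would differ
  only marginally at these densities.

Filters are idempotent, and every removal is logged with a reason in a
`FilterReport` whose counts must reconcile exactly.

## Diversity statistics

For a biallelic locus with alternate-allele frequency p (q = 1 − p),
estimated over called alleles only:

- He = 2pq — gene diversity, no small-sample correction;
- PIC = 1 − (p² + q²) − 2p²q² — Botstein's informativeness measure,
  maximal at 0.375 for p = 0.5;
- π = n_ref·n_alt / C(n, 2) with n called alleles — the mean pairwise
  allelic difference at the site (site-π as computed by VCFtools),
  which equals He·n/(n−1).

This specific combination (uncorrected He, pairwise-corrected π) is the
one consistent with the reference extrema the tests pin: at p = 0.5
with 195 fully called diploids, He = 0.5000 exactly while
π = 195·195/C(390,2) = 0.5013. Values are reported at 4 decimals;
internal computation is full precision.

Population summaries re-estimate frequencies within each group's
submatrix; group means over loci are unweighted, and the cross-group
"Mean" row is the unweighted mean of group values (not pooled over
samples). Retention rates are plain ratios, 100·core/original per
statistic; groups with fewer than two samples are flagged rather than
suppressed.

## Distances, trees and group assignment

The pairwise distance is 1 − IBS: at each locus called in both samples
a genotype pair shares (2 − |g_i − g_j|)/2 of its alleles by state, and
the distance is one minus the average over shared loci. It is
parameter-free, standard for SNP panels, and a pseudo-metric (symmetry
and zero diagonal are enforced; the triangle inequality is checked
empirically on fixtures, not asserted in general). A pair with zero
shared called loci is an error, not a guess.

Neighbor joining is the classical Saitou–Nei algorithm: join the pair
minimizing Q(i,j) = (r−2)d(i,j) − Σ_k d(i,k) − Σ_k d(j,k), with branch
lengths from the standard formulas and ties broken by the smallest
(row, column) index pair in the current node order. NJ is exact on
additive matrices, which the tests verify against brute-force
least-squares topology fitting (4 taxa) and path-distance recovery on
random additive 8-taxon matrices. Negative branch lengths (possible on
non-additive inputs) are preserved internally and clamped to zero only
at Newick export, with a log note. Newick serialization follows
scikit-bio's conventions (spaces encoded as underscores, special
characters quoted).

**Group assignment.** Groups are obtained by cutting k−1 internal
branches of the midpoint-rooted NJ tree. The cut branches are chosen
greedily to minimize a Ward-style within-group dispersion,
Σ_g (within-group cophenetic distance sum)/n_g, over the partitions
reachable by cutting one more branch. An earlier candidate rule — cut
the longest internal branches — proved unusable on weakly structured
panels: with ~100-SNP resolution the longest internal branches are
noise-driven terminal cherries, while the branch separating a
169-vs-26 split is short; the dispersion criterion recovers the
simulated split with ARI ≈ 1 at FST ≥ 0.15. Ties break by traversal
index, so assignment is deterministic. A tree with all-zero branch
lengths yields a single group with a `DegenerateTreeWarning`; k = n
returns singletons.

## PCA

Genotype columns are standardized as (g − 2p)/√(2p(1−p)) — the usual
variance standardization for SNP data — with missing entries set to 0
after centering (i.e., to the locus mean) and monomorphic loci dropped.
Coordinates are eigenvectors of the sample covariance scaled by √λ;
explained percentages are eigenvalue shares of the total variance.
Coordinates are defined up to sign, as tested.

## Admixture model and Evanno ΔK

The admixture model treats each individual's two allele draws at a
locus as independent Bernoulli with success probability
f_il = Σ_k q_ik p_lk, giving the log-likelihood
L = Σ g·log f + (2−g)·log(1−f) over called genotypes. Fitting is by EM
from a seeded random start (Q rows Dirichlet(1), P uniform on
(0.05, 0.95)); the updates are the standard frequency-model EM and
increase L monotonically (asserted per-iteration in tests). Frequencies
are clamped to [1e-9, 1−1e-9] for numerical safety. Defaults:
max_iter = 2000, tol = 1e-6 on the log-likelihood change — desk-scale
settings chosen so replicate runs at these panel sizes converge in
under a second each.

This deterministic-per-seed maximum-likelihood fit plays the role that
a Bayesian MCMC structure analysis plays in practice; the maximized
log-likelihood stands in for the per-run model-fit score. That is a
documented proxy: Evanno's ΔK only needs a replicate-wise fit score per
K, and the second-difference statistic
ΔK = |L″(K)| / sd(L(K)) behaves the same way (zero curvature ⇒ ΔK = 0;
the peak sits at the true K on two-subpopulation panels, 20/20 master
seeds in the acceptance tests at FST 0.1). Replicate standard
deviations use ddof = 1; a zero sd yields an undefined ΔK with a
warning rather than an infinity. Replicate seeds are spawned
deterministically from a master seed via `numpy.random.SeedSequence`.

Known limitation: whether the ΔK plateau of a full MCMC analysis on
real data would match this EM proxy cannot be established without real
genotypes; only the synthetic-recovery behaviour is claimed.

## Core collections

Per-group core sizes are max(1, round-half-up(ratio·size)) — a simple,
auditable allocation with a one-accession floor so minority groups stay
represented. (Published core-collection counts rarely pin down their
rounding rule; this one is stated so the arithmetic can be checked.)

Within a group, stepwise redundancy elimination repeatedly finds the
closest remaining pair and discards the member with the smaller mean
distance to everything else — the more redundant one — until the target
count remains. All ties break by sample order, so the procedure is
deterministic; on a 6-sample fixture it coincides with the exhaustive
max-min-distance subset. The ratio sweep (10–50% plus the 100%
baseline) recomputes diversity on each core with re-estimated
frequencies; `recommend_ratio` returns the smallest ratio at which
every group retains ≥ 95% (default) of He, PIC and π, falling back to
the best-retaining ratio with a warning. The 95% default is
deliberately conservative: stepwise cores typically *exceed* 100%
retention because redundancy elimination pushes frequencies toward
0.5.

## Fingerprints

Fingerprint codes concatenate the 0/1/2/9 digits of selected loci.
Selection is greedy because "maximally discriminating subset" is
set-cover-like: seed with the highest-PIC locus, then add whichever
locus most reduces the number of sample pairs still sharing identical
partial codes (ties: higher PIC, then panel order), stopping at full
resolution or the 20-locus cap. The unresolved-pair count is
non-increasing by construction. Collision auditing is strict by
default — a missing digit (9) is an ordinary character, so it neither
matches nor wildcards; a lenient mode treating 9 as a wildcard is
available for stricter identity claims. QR payloads are plain
`id|code` strings (the `|` is reserved); rendering to an image is an
optional extra, the payload being the portable artifact.

## Synthetic panels

The simulator emulates the statistical shape of a weakly structured
germplasm panel, not any particular collection:

- ancestral allele frequencies uniform on [maf_floor, 1 − maf_floor]
  (default floor 0.05, matching the frequency filter);
- subpopulation frequencies from the Balding–Nichols distribution
  Beta(p(1−F)/F, (1−p)(1−F)/F), a standard single-parameter two-level
  FST model (calibration verified against an independent Hudson FST
  estimator: ±0.05 at F = 0.2);
- genotypes Binomial(2, Σ_k q_ik p_lk); optional symmetric-Dirichlet
  admixture (α = 0 means unadmixed block membership);
- MCAR missingness plus optionally a fixed number of fully missing
  samples (the assay-failure case);
- one synthetic chromosome with sorted distinct positions (default
  200 Mb — enough span to exercise the 2 Mb spacing screen), random
  ref/alt bases, optional Poisson depths.

Defaults mirror the target study shape: subpopulations of 169 and 26,
99 loci, 3% missingness, FST 0.05. The true divergence of the real
material is unknown; FST is a free parameter, and the recovery tests
state the values they use (0.1–0.2).

What the simulator omits — linkage disequilibrium, selection,
multi-allelic sites, genotyping-error structure, non-random
missingness — bounds what passing tests show: they establish that the
estimators and selection procedures recover known truth under the
stated generative model, not that real panels meet that model's
assumptions.

## Problem sizes and determinism

Stochastic test batteries use 20 seeds per claim with median-based
assertions (median ARI, median RMSE, ≥ 18/20 ΔK hits); panel sizes are
the study shape (195 × 99) for structure recovery and smaller panels
for unit-level properties. Every random stage takes an explicit seed;
the pipeline derives per-stage seeds by hashing the stage name with the
master seed, so stages are individually reproducible and the full run
is byte-identical on re-execution (timings are logged outside the
manifest for that reason).
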