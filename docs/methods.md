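# Methods

## Genetic model

A cross population of `n` individuals is genotyped at co-dominant markers with
a known linkage map.  Putative QTLs are evaluated on a regular grid over the
map (default step 1 cM; every marker position is always on the grid).  For a
backcross, doubled-haploid (DH) or recombinant-inbred-line (RIL) population
each locus has two genotype classes, coded +1/−1 so that a fully informative
locus has unit variance; an F2 has three classes, with the additive indicator
+1/0/−1 for QQ/Qq/qq and a separate dominance indicator (1 for the
heterozygote).  The trait follows an exponential-family distribution whose
mean is linked to the additive (and, for F2, dominance) effects of all grid
loci jointly:

    g(mu_i) = mu0 + sum_j d_ij b_j   (+ dominance terms for F2).

Supported family/link pairs: normal/identity; Poisson with log, identity or
sqrt; binomial (including binomial counts with a `trials` column) with logit,
probit, cloglog or log.  Link and variance arithmetic is delegated to
statsmodels' family objects; means are clipped (binomial into
[1e-10, 1−1e-10], Poisson at ≥1e-10) and exponential-type linear predictors
capped at |eta| ≤ 30 so IRLS weights stay finite.

## Conditional genotype moments

Genotypes at non-marker loci are unobserved.  Each indicator is replaced by
its conditional expectation given the nearest informative flanking markers
(Haley–Knott regression), computed from a no-interference Markov model along
the chromosome with Haldane's map function r = (1 − exp(−2d))/2 (RILs use the
map-expanded r* = 2r/(1+2r); F2 genotypes are treated as two independent
gamete chains with heterozygote phase summed over).  The conditional variance
c_ij is retained.  Conditioning is deliberately *not* full multipoint: only
the nearest non-missing marker on each side is used, one side only at
chromosome ends, and the population prior when a chromosome is entirely
missing for an individual.  At observed markers d equals the coded genotype
and c = 0.

## Over-dispersion and the iteratively reweighted LASSO

Replacing x by d leaves residual genotype variance that inflates the
dispersion per individual, psi_i = 1 + sum_j b_j^2 c_ij ≥ 1.  The fit
alternates:

1. start with all effects zero (psi ≡ 1);
2. solve the L1-penalized GLM — an outer IRLS linearization
   (z = eta + (y−mu) g'(mu), w = 1/(V(mu) g'(mu)^2)) around a weighted-LASSO
   subproblem minimized by cyclic coordinate descent with soft-thresholding;
3. refresh psi from the current non-zero effects;
4. re-solve the penalized GLM on the design whose rows (intercept column
   included) are divided by sqrt(psi_i);
5. repeat 3–4 until the maximum coefficient change falls below 1e-4 (at most
   25 outer rounds; an oscillating trajectory returns its best iterate).

The *unweighted* variant stops after step 2.  The coordinate-descent kernel
is JIT-compiled and augmented with an exact active-set solve (fixed support
and signs reduce the problem to a linear system; a sign flip is handled by
stepping to the zero crossing and dropping that coordinate), which matters
because adjacent 1 cM grid columns are ~0.98 correlated and plain cyclic
descent converges very slowly on them.  Objective convention:
(1/2n) Σ w_i (z_i − X_i β)^2 + λ Σ|b_j| with weights normalized to mean one;
columns are *not* variance-standardized, so coefficients remain interpretable
as genetic effects on the link scale.

λ is chosen once at step 2 and reused (re-selection each round is a flag).
Three rules are available: K-fold cross-validation minimizing held-out
deviance (the reference rule), and two single-path information criteria that
cost one path fit instead of folds+1 — BIC (deviance + df·ln n) and AIC
(deviance + 2·df, the classical large-sample surrogate for leave-one-out CV
and hence for the CV-minimum).  The experiment runner uses BIC for the
pipeline's own selection; the coefficients reported for the unweighted
variant are read off the same path at the AIC λ, since that variant is
defined by CV-selected shrinkage and BIC visibly over-shrinks (on the binary
n=400 benchmark the Q2 window-summed raw coefficient averages ≈1.56 under
AIC, ≈1.38 under CV-min, ≈1.10 under BIC).

## Post-selection inference

Non-zero effects are pruned to at most one locus per marker interval (largest
|effect| wins, ties to the smaller position) and re-estimated by an
unpenalized GLM on the psi-standardized design, with psi refreshed between
IRLS rounds.  Dividing the linear predictor by sqrt(psi) acts as a
de-attenuation: it compensates the downward bias that Haley–Knott expectation
regressors induce under non-identity links.  The alternation contracts only
while sum_j b_j^2 mean(c_j) < 1; the refit guards every step (strict deviance
decrease, bounded coefficients) and, if the alternation diverges — which
happens for the very high-information Poisson benchmark — reports the
unadjusted (psi = 1) estimates with a warning.  The covariance of the
estimates is the inverse weighted information matrix times the dispersion
(1 for binomial/Poisson, Pearson estimate for normal); two-sided p-values use
the t distribution with n − p degrees of freedom.

**Genome profile.**  Significance is assessed on a per-locus −log10(p)
profile: each grid locus is tested in a GLM containing the fitted model's
other loci as cofactors, excluding cofactors within one matching window
(default 10 cM, one marker interval) of the tested locus so a QTL's own
neighbourhood cannot absorb it.  The cofactor model itself is consolidated
once: peaks of a first-pass profile (−log10 p ≥ 2, non-maximum suppression
within the window) replace the raw LASSO survivors; when that peak set is
implausibly large (> max(10, n/20), as for near-deterministic count traits) a
greedy forward BIC selection reduces it first.  QTL calls are profile peaks
at or above the genome-wide critical value; a call must be a local maximum of
the profile within the window (the shoulder of a strong QTL would otherwise
produce a ladder of calls one window apart) and calls are thinned to at most
one per window.  Call effects are taken from the joint refit model.

**Thresholds.**  The critical value is the empirical (1−level) quantile
(order statistic ⌈(1−level)·R⌉) of the genome-wide maximum profile −log10(p)
over R replicates of the null model (fresh simulations with all effects zero)
or of phenotype permutations of the observed data (rows permuted whole, so
marker linkage is preserved).  The default is R = 1000 at the 5% level, with
a `--replicates` override; the acceptance runs use R = 200.

**Heritability.**  For a called locus, h²_j = b̂_j² V_j / (Σ_l b̂_l² V_l + σ²)
with V_j = Var(d_j) + mean(c_j) and the latent-scale residual variance σ² per
family: π²/3 (logit), 1 (probit, the threshold model), π²/6 (cloglog), the
estimated dispersion (normal), and the delta-method variance of the linked
response at the mean fit for Poisson (1/mu-bar under log).

## Synthetic data

The simulator draws genotypes chromosome-by-chromosome as a first-order
Markov chain (fair first locus; switch probability = Haldane r of the
inter-locus distance; two independent gamete chains for F2; map-expanded r
for RIL) at the union of marker and QTL positions, then draws phenotypes from
the family distribution at mean g⁻¹(mu0 + Σ x b) using the *true* QTL
genotypes, which are stored but withheld from the mapper.  The benchmark
scenario is a backcross of six 100 cM chromosomes with 11 evenly spaced
markers each and ten QTLs at genome positions
(23, 56, 148, 193, 267, 332, 390, 478, 522, 574) cM with effects
(1.5, 2.0, 0.72, 1.1, −0.22, 0.70, −0.65, 1.25, 0.35, −0.80) and mu0 = 0.
Binary traits use the logit link, count traits the Poisson/log pair; the
coding is ±1.  Replicate r of a run with seed s uses the generator seeded
with the pair (s, r), so replicates are independent and reproducible.

What the generator does *not* emulate: genotyping error, segregation
distortion, epistasis, crossover interference, selective genotyping, or
covariates.  Passing tests therefore certify the estimator's behaviour under
the idealized cross model, not robustness to real-data artefacts.  One
consequence of the declared Poisson conditions (log link, mu0 = 0, ±1 coding,
effects up to 2) is worth noting: counts reach e^9 ≈ 8000, so a handful of
individuals carry most of the Fisher information, every locus near a QTL is
formally significant, and effect estimates for count traits are noticeably
attenuated relative to the binary case; the divergence guard and forward
consolidation above exist for exactly this regime.

## Numerical choices

- Coordinate descent: tolerance 1e-7 on the maximum coefficient change
  (2e-5 during path exploration), at most 1e5 sweeps; path of 25 λ values,
  geometric from λ_max down to 0.05·λ_max, truncated once >50 effects are
  active; warm starts along the path.
- IRLS: tolerance 1e-6 (1e-4 on paths), ≤50 iterations; step-halving with
  strict deviance decrease everywhere; information matrices receive a
  scale-aware ridge (1e-8 × mean diagonal) before solving; rank-deficient
  refits drop collinear columns by pivoted QR with a warning.
- Degenerate inputs: an all-constant working response yields a single λ = 0
  path with a warning; a CV fold with constant binomial response is re-drawn
  once; failed threshold replicates are dropped (error if >5% fail).
- Problem sizes in the shipped Monte-Carlo checks: 100 replicates for the
  n = 400 configurations, 200 for n = 200, thresholds from 150–200 null
  simulations — chosen so three-standard-error comparisons against the
  reference values are meaningful at desk scale.

## Known limitations

- Flanking-marker (not multipoint) conditioning; dense missingness degrades
  the regressors more than a hidden-Markov treatment would.
- The dispersion adjustment is reported unadjusted when its alternation
  diverges (near-deterministic traits).
- Ordinal/multinomial cumulative links, epistasis, QTL-by-environment and
  position confidence intervals are out of scope.
- Detection scoring uses a 10 cM matching radius (one marker interval);
  reported powers depend mildly on that operationalization.
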