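# Methods

This note documents the models, estimators, numerical choices and known
limitations of the package, and what the synthetic-data generators do and
do not emulate.

## Tree model and clade extraction

Trees are rooted, ultrametric and time-calibrated, with branch lengths in
Myr and ages measured backward from the present (tips at age 0).
Ultrametricity is enforced at parse time within a relative tolerance of
1e-6 of tree depth (configurable; disable for utility trees such as
non-ultrametric test scaffolds). Tip labels follow the `Genus_species`
convention; the genus is the substring before the first separator
(`_` by default, configurable).

Clades are defined against half-open time slices `(lo, lo+w]` with
`w = 2` Myr by default, from the present back to 20 Myr. A node is
selected for a slice when (i) its crown age lies in the slice, (ii) its
parent's age lies strictly above the slice's upper bound (the root counts
as having an infinitely old parent), and (iii) it subtends at least 4
tips. Condition (ii) formalises "most inclusive": within one slice no
selected node is an ancestor of another, so clades are pairwise disjoint.
Ages exactly on a boundary belong to the lower (younger) slice; the
boundary convention is arbitrary but fixed and tested.

### Sampling fraction and crown capture

The genus-level sampling fraction `f_g` is the number of congeners
sampled anywhere in the tree divided by the genus's described richness;
a clade's fraction is the tip-count-weighted mean of its genera's `f_g`,
and its total richness is estimated as `n = round(k/f)` (used only by the
method-of-moments estimator; the likelihoods consume `f` directly).
`f_g > 1` (more sampled than described — a data error) is clipped to 1
with a warning.

The crown-capture probability — the chance that the MRCA of the `k`
sampled species is the true crown node of an `n`-species clade — is
computed under a uniform prior on the root split (sizes `a, n−a` with
`a` uniform on `1..n−1`) and uniform sampling without replacement:

    P(n, k) = 1 − 2(n−k) / ((n−1)(k+1)).

This closed form is verified exactly (rational arithmetic) against a
complete enumeration of splits and subsets for all `n ≤ 12`. It is an
assumption: the uniform-split prior is the Yule-consistent choice, and
other priors would give different values. Default inclusion filters:
`f ≥ 0.3` and `P ≥ 0.7`, both configurable; filters are independent per
clade so their order is immaterial.

## Diversification estimation

### Method of moments

For a surviving crown clade of age `t` under constant rates with relative
extinction `eps = mu/lambda`, the expected present-day richness
conditional on the clade's survival is

    E[n] = 2 (x − eps)^2 / [(1 − eps)(x(1 + eps) − 2 eps)],  x = e^{rt}.

The estimator inverts `E[n] = n` for `r`; the package uses the closed
form of that inversion (which for `eps = 0` reduces to `ln(n/2)/t`) and
the tests confirm it against direct numerical root-finding on the
expectation to 1e-8. Headline analyses default to `eps = 0.5`, with 0 and
0.9 also reported. Speciation implied by the method-of-moments estimate
is `lambda = r/(1 − eps)`.

### Time-dependent birth–death likelihoods

Six nested models are fitted per clade: pure-birth and birth–death with
each rate either constant or exponential in time before present,
`lambda(tau) = lambda0 e^{alpha tau}`, `mu(tau) = mu0 e^{beta tau}`.
With `R(t) = ∫_0^t (lambda − mu)` and
`D(t) = 1/f + ∫_0^t lambda(s) e^{R(s)} ds`, the log-likelihood of the
branching times `t_1 (crown) > t_2 > …` under uniform sampling `f`,
conditioned on both crown lineages surviving and being sampled, is

    log L = −2 log(f D(t_1)) + Σ_{i≥2} [log lambda(t_i) + R(t_i)
                                        − log f − 2 log D(t_i)].

Labelled-topology constants are omitted; they cancel in all model
comparisons. Constant-rate models use the closed form of `D`;
exponential models integrate `lambda e^R` with 24-point Gauss–Legendre
panels between consecutive branching times (the integrand is smooth, and
the tests verify agreement with adaptive quadrature to far below
optimizer tolerance, and with the classical constant-rate closed form to
1e-9 in the nested limit).

Optimisation is bounded L-BFGS-B on `(log lambda0, alpha, log mu0, beta)`
with bounds `lambda0 ∈ [1e-4, 10]`, `mu0 ∈ [1e-6, 10]`,
`alpha, beta ∈ [−1, 1]` per Myr, three random restarts (configurable,
seeded) around a Yule-based heuristic start, plus warm starts from every
already-fitted nested submodel — the warm starts guarantee that a richer
model's maximised likelihood never falls below a nested one beyond
optimizer tolerance. Model selection is by plain AIC (AICc deliberately
not the default). "Speciation at present" is `lambda0` by the
time-before-present convention.

Conditioning on crown survival is an assumption the data source does not
pin down; it matches the default of the likelihood framework the model
family comes from.

## Trait evolution

Traits are analysed on the log scale (log10 by default for masses; the
base is recorded in outputs). Both models are Gaussian: the root state
and rate have closed-form profile ML estimates given the phylogenetic
covariance `C`, and `sigma2` uses the ML `n`-denominator (consistent with
AIC). Under the early-burst/ACDC model the instantaneous rate is
`sigma2_0 e^{a s}` with `s` time since the root; on an ultrametric tree
this rescales the covariance elementwise, `C_EB = (e^{aC} − 1)/a`, so the
fit is a 1-D bounded optimisation over `a ∈ [−10/depth, 0]` (an option
allows accelerating rates, `a > 0`). `a = 0` is compared explicitly so
the EB likelihood never falls below BM. The clade "trait rate" is the
selected model's `sigma2` (the root rate for EB); AIC ties break toward
BM.

## Correlation machinery

**Structured permutations.** Each posterior sample carries a partition of
branches into rate regimes. The observed statistic is the Spearman
correlation between per-tip rates (the rate of the regime containing the
tip's terminal branch) and the tip statistic; the null draws one uniform
permutation of the regime-to-rate assignment per sample, keeping shift
locations fixed — preserving both the multiset of rates and the
phylogenetic clustering of tips into regimes. The p-value is the
proportion of samples whose null correlation is strictly greater than the
observed one (a two-sided variant on absolute correlations is available).
Samples with a single regime are uninformative (the permutation is the
identity) and count toward the null, so an all-single-regime posterior
gives p = 1. Rates enter Spearman untransformed: the correlation is
rank-based, so the log transform applied elsewhere would not change it.
Binary tip statistics (e.g. annual vs. perennial) enter as 0/1 with
average ranks.

**PGLS.** Across-clade regressions use GLS with Brownian covariance from
the full tree pruned to one representative tip per clade
(lexicographically first member), Pagel's lambda fixed at 1. Inference
uses the t distribution with `n − 2` residual degrees of freedom — the
standard for a slope-plus-intercept model, and the choice under which the
confidence intervals are calibrated (checked by simulation); reports that
count `n − 1` are treating the regression differently and are not
reproduced.

**Phylogenetic ANOVA.** The observed one-way F statistic is compared with
F statistics of Brownian datasets simulated on the tree (rate estimated
from the data by ML; 1,000 simulations by default);
p is the proportion of simulated F ≥ observed. Constant data define
F = 0, p = 1.

**Type-I experiment.** Neutral single-rate Brownian traits are simulated
on the fixed tree and each is run through the permutation test; the
reported estimate is the fraction of datasets with p < 0.05 and its
binomial standard error.

## Synthetic data

The generators emulate the statistical features the analysis assumes:

- `simulate_bd_tree`: forward Gillespie crown simulation, extinct
  lineages pruned and unifurcations suppressed (reconstructed-tree
  convention), conditioned on survival by resimulation. Under the
  tip-count stop the simulation runs to just before the next event so
  terminal branches have positive length.
- `simulate_regimes`: shift points drawn without replacement with
  probability proportional to branch length among edges subtending at
  least 5 tips. The eligibility floor reflects what the emulated object
  is — a credible set of *detectable* rate shifts; a regime of one or two
  tips carries no signal and would not appear in one. Per-regime rates
  are drawn log-uniformly (speciation on [0.05, 0.5]/Myr, extinction as a
  uniform fraction [0, 0.8] of speciation, phenotypic rate on [0.05, 5]).
- `make_synthetic_posterior`: multiplicative lognormal rate jitter
  (log-sd 0.1 by default, giving a ~10% coefficient of variation across
  samples) and optional relocation of shifts within their subtrees.
- `make_taxonomy_and_subsample`: genera as contiguous tip blocks with
  Dirichlet-skewed sizes; tips retained independently with genus-specific
  probabilities, and the pre-pruning block sizes reported as described
  richness — emulating taxonomically non-random incomplete sampling.
- `generate_study_fixture`: a coherent small study (300-tip tree before
  subsampling, 4 regimes, 50-sample posterior) in which regime
  phenotypic rates equal `0.5 (lambda/mean lambda)^c` with coupling
  strength `c` — `c = 0` is an exact null for trait-rate/speciation
  association; larger `c` creates the association the pipeline is meant
  to detect.

What the generators do *not* emulate: measurement error in traits beyond
lognormal jitter, non-uniform (e.g. diversified) taxon sampling within
genera, diversity-dependent or environment-driven rate variation, and
posterior uncertainty in shift *locations* under the default settings.
Passing tests therefore demonstrate correctness and calibration of the
machinery under these idealised conditions, not robustness to every
property of real data.

## Problem sizes in the shipped tests

The test suite and calibration script run everything at desk scale,
chosen as the smallest sizes at which the statistical checks are stable:
~100–250-tip trees, 50-sample posteriors, 50–200 replicate datasets for
calibration/power/coverage experiments, and 20 replicate fixtures for
end-to-end checks. The corresponding empirical study scale (tens of
thousands of tips, thousands of posterior samples) changes runtimes, not
the code paths.

## Known limitations and honest failure modes

- **Size-coupled bias in clade rate regressions.** The log of the ML
  variance estimate carries a k-dependent bias
  (`E[log sigma2_hat] − log sigma2 = psi(nu/2) + log 2 − log k`,
  `nu = k − 1`), about −0.66 for k = 4 but only −0.22 for k = 10. Clade
  speciation estimates also increase with k within a time slice (richer
  clades diversify faster by construction). Regressing one on the other
  across clades therefore has a small *positive* expected slope even when
  traits evolve at one global rate: in the package's null fixtures the
  mean per-slice PGLS slope is ≈ +0.4–0.6, although slopes remain
  statistically indistinguishable from zero (mean |slope| below the mean
  slope SE; ~6% of null slices nominally significant). Any user of
  clade-based rate-on-rate regressions — with this package or otherwise —
  should compare observed slopes against this null rather than against
  zero.
- **Permutation-test power under rank-unstable posteriors.** When two
  regimes have nearly equal speciation rates, posterior jitter flips
  their rank order between samples and the per-sample observed
  correlation with any fixed tip statistic genuinely degrades. With the
  default 10% rate jitter the test's power against a perfect
  regime-level association is ≈ 0.86 over replicate fixtures (1.0 under
  a rank-stable posterior). This is a property of the inference target,
  not of the permutation machinery.
- The crown-capture formula and the likelihood conditioning are
  documented assumptions (see above), not established facts about any
  particular empirical dataset.
- No multiple-testing correction is applied anywhere; six permutation
  tests at the 0.05 level produce occasional nominal hits under the null.
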