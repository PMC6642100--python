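# Methods

## Models and Bayes factors

A *model* is a set of SNPs hypothesised to be causal for one disease; the
null model is the empty set.  For disease `d` with `n_d` cases and `n_0`
shared controls, a model `M` is scored by a logistic regression of
case/control status on the model's allele dosages (plus any covariates,
which appear in both the null and alternative fits), and its evidence is
the BIC / unit-information-prior approximate Bayes factor

    log BF_d(M) = (ll_M - ll_0) - (|M|/2) log(n_0 + n_d).

Logistic likelihoods are maximised by an internal Newton–Raphson solver
with step halving.  (Quasi-)separated fits — non-convergence or any
coefficient beyond 15 log-odds units — are refitted with a small ridge
penalty (`alpha = max(1e-4 n, 1)`) and flagged; this keeps model searches
total without letting separated models dominate.

The model prior is binomial on model size: with `p` SNPs in the region and
an expected number of causal variants `e`, each size-`k` model has prior
`pi^k (1-pi)^(p-k)` with `pi = e/p`, so the prior over all models of all
sizes sums to exactly 1 and all models of equal size are exchangeable.
Following standard practice for stochastic-search fine-mapping, searches
use an optimistic expectation (3) to aid mixing and final posteriors a
conservative one (2).  When a high-posterior subset of SNPs is analysed
(tag representatives, or an extracted group of interest), the *full*
region's SNP count still enters the prior.

Search proceeds either by exhaustive enumeration up to `max_k` (capped at
2e5 models) or by shotgun stochastic search: chains start from top marginal
SNPs, score the complete add/drop/swap neighbourhood of the current model,
and move to a neighbour sampled proportionally to `exp(logBF + logprior)`.
The posterior is normalised over every model scored by any chain, so on
small panels run to full coverage it coincides with the exhaustive
posterior (verified to 1e-6).  Pre-search tag compression collapses SNPs
at r² ≥ 0.99 onto greedy representatives; after search, models in the
smallest set reaching cumulative posterior 0.99 are re-expanded over each
tag's members and refitted.

## Joint analysis of multiple diseases

With diseases `1..D` sharing one control class, the natural joint model is
a multinomial logistic regression with one linear predictor per disease.
A *configuration* assigns one model per disease.  Exactly,

    ll_multinomial(theta) = sum_d ll_conditional,d(eta_d) + sum_i g(eta(x_i)),
    g(eta) = sum_d log(1+e^{eta_d}) - log(1 + sum_d e^{eta_d}),

where `ll_conditional,d` is the ordinary logistic likelihood of disease `d`
cases versus controls.  We approximate the multinomial log Bayes factor of
a configuration by the sum of per-disease logistic log BFs plus an offset
that reconciles the BIC penalties:

    offset = sum_d (|M_d|/2) (log(n_0+n_d) - log N),   N = n_0 + sum n_d.

The offset is zero when every model is null and zero when controls are not
shared (the joint BF is then an exact sum).  **Approximation domain:** the
residual error against a directly fitted multinomial has two parts, both
arising because the multinomial can use other diseases' cases as additional
quasi-controls when their predictors are null: a stochastic
score-difference term of order one log unit even for null data (the
binomial and multinomial score statistics are correlated at
`sqrt(I_bin/I_mult)`, e.g. 0.87 at equal class thirds), and a systematic
term growing with effect size (the log-likelihood-ratio scale factor is
`(N-n_d)(n_0+n_d)/(N n_0)`, 4/3 at equal thirds).  The offset is therefore
exact in expectation for null effects but the configuration *ranking*, not
the absolute joint BF, is the quantity the combination relies on; the
per-configuration error cancels to first order between configurations
sharing model sizes.

### Sharing prior

Configurations in which at least one pair of diseases shares a causal SNP
are upweighted by κ ≥ 1 (the `"any"` policy, default).  The main
alternative — κ per sharing *pair* — is available as `policy="pair"`; the
two coincide for two diseases.  The indicator policy was chosen as default
because (i) it matches the elicitation target (the chance that diseases
share *any* causal variant) and (ii) it admits exact closed-form
calibration: with `A = P(all models pairwise disjoint | kappa=1)`,
computable exactly by a dynamic programme over the binomial size prior
(each successive model must avoid the union of its predecessors), the prior
no-sharing mass at weight κ is `A / (A + kappa (1-A))`, so the κ hitting a
target `t` is `kappa = A(1-t) / (t(1-A))`.  The default target for `d`
diseases is `0.5^sqrt(d-1)`, the geometric-mean compromise between the
fully-dependent (0.5) and fully-independent (`0.5^(d-1)`) extremes.  On a
100-SNP region with two expected causal variants per disease the calibrated
κ for two diseases is 24.5, within the range used for colocalisation-style
priors once the per-pair sharing chance is of order 1%.

### Marginalisation without the cross-product

Per-disease marginal posteriors under the joint prior are computed from
per-disease aggregates only.  Writing `g_d(M) = exp(logBF_d + logprior_d +
c_d |M|)` with `c_d` the per-SNP offset coefficient, the marginal weight of
model `M` for disease `a` under the indicator policy is

    g_a(M) [ kappa * prod_{i != a} Z_i  -  (kappa-1) * D_a(M) ],

where `Z_i = sum g_i` and `D_a(M)` sums `prod g_i` over choices for the
other diseases that are pairwise disjoint and disjoint from `M`.  `D_a` is
evaluated by memoised recursion keyed on the SNPs still relevant
downstream; the configuration cross-product is never materialised.  A cost
cap aborts with advice to truncate (each posterior is truncated to the
smallest model set with cumulative pp ≥ 0.9999 before combination).  The
`"pair"` policy has no such decomposition and enumerates configurations
under the same cost cap.  Additional cohorts from distinct populations
(non-shared controls) contribute per-disease additive log BF terms before
marginalisation; models absent from an extra cohort's table contribute 0
with a logged warning.

Exactness of the decomposition is verified against explicit enumeration of
all configurations (two and three diseases) to 1e-10, and `kappa = 1` with
zero offset reproduces the independent per-disease posteriors exactly.

## SNP grouping and agreement classification

SNPs with marginal posterior inclusion probability above 0.001 are
clustered per disease by complete linkage on the dissimilarity
`1 + r^2 sign(r_model)` (≈0 for substitutable pairs, ≈2 for co-selected
pairs, ≈1 for unlinked pairs), where `r_model` is the posterior-weighted
Pearson correlation of the two SNPs' model-inclusion indicators.  The tree
is cut at the coarsest height at which every within-group pair has r² >
0.5, `r_model` < 0 and joint inclusion probability < 0.01 — the criteria
are re-checked explicitly after the cut, never assumed from the tree.
Overlapping groups from different diseases are merged when the merged group
still satisfies the criteria in every contributing disease; otherwise the
SNPs violating the most pairs (ties broken by id) are split off as
singletons.  Grouped model posteriors (GPP) sum the posterior over SNP
models realising a pattern of one SNP per group; models using two SNPs of
one group are reported as separate intra-group patterns, so total GPP mass
is conserved.  Stepwise results are classified against the top grouped
pattern as match / nested / split-signal (within 0.1 GPP of the top) /
discrepant.

## Expected Z-scores and joint-tag scans

For causal SNPs `c` with per-allele log odds ratios `gamma_c` and allele
frequencies `f_c`, the first-order expected single-SNP score-test statistic
at SNP `j` is

    E[Z_j] = sqrt(n0 n1/(n0+n1)) * sum_c rho_jc gamma_c sigma_c,
    sigma_c = sqrt(2 f_c (1-f_c))  (Hardy-Weinberg),

with `rho` the haplotype-panel allele correlation.  The profile is linear
in the effects, sign-equivariant, and scales with the balanced effective
sample size.  The approximation is first order in `gamma`; simulation
validation is performed in the weak-effect regime (odds ratios ≤ 1.15),
where the analytic value at causal variants lies within three standard
errors of the mean simulated score statistic (500 studies per setting); the
prediction at non-causal neighbours, including the joint-tag case, is
validated on the trio construction.  Sunbeam grids classify the
minimum-expected-p SNP over an odds-ratio grid for a trio (two causal, one
candidate tag), with a "none" region where no SNP reaches the two-sided
5e-8 threshold.  The panel-wide trio scan flags a third SNP as a potential
joint tag when `|E[Z_tag]| > max(|E[Z_1]|, |E[Z_2]|)` under equal effects —
a comparison from which the common effect magnitude cancels, so no odds
ratio need be chosen.

A feasibility fact worth recording: for binary haplotypes with equal MAFs,
`r_13 + r_23 - r_12 <= 1`, so a strict joint tag cannot exist in an
equal-MAF trio.  Joint-tag fixtures therefore use the structure seen in
real data: a common tag allele (MAF 0.4) carried together with either of
two disjoint rarer causal alleles (MAF 0.15; `r_causal,tag = 0.514`,
`r_causal,causal = -0.176`).

## Haplotype analysis

Phase over k ≤ 10 SNPs is resolved by EM over the 2^k haplotypes: the
E-step distributes each genotype over compatible ordered haplotype pairs
under Hardy–Weinberg (missing genotypes are marginalised), the M-step
re-estimates frequencies; the log-likelihood is non-decreasing and tracked.
Effects are estimated from 10 phase imputations drawn from the
per-individual posterior: each imputation is a logistic regression of
status on per-haplotype counts against the most frequent haplotype
(haplotypes under 1% frequency pooled into "other"), combined by Rubin's
rules (mean point estimate; variance = within + (1+1/m) between) with
Barnard–Rubin degrees of freedom for the 95% interval.  With unambiguous
phase all imputations coincide and the imputation count has no effect.

## Simulator

Panels are generated as independent LD blocks: each block draws one MAF
(shared by its SNPs — binary correlation is bounded by MAF mismatch, so
matched frequencies are needed to realise arbitrary within-block targets)
and thresholds an equicorrelated latent Gaussian whose latent correlation
is calibrated through the tetrachoric relation.  Genotypes are sums of two
mosaic haplotypes that copy random panel rows and switch template with a
per-interval probability, preserving MAF and (at low switch rates) local
LD; the construction is not faithful to a recombination map.  Three-SNP
panels with prescribed MAFs and pairwise correlations are solved exactly:
the 8 cell probabilities are linear in the one free triple moment, so
feasibility is an interval check and the midpoint is used; haplotype counts
are rounded by largest remainder.

Case/control ascertainment assigns pool candidates by comparing one
uniform draw `u1` against each disease's probability
`p_k = expit(log(prevalence) + sum_i beta_ik x_i)` (prevalence 0.1 by
default), with a second uniform breaking the tie when `u1` falls below
several `p_k`; each class keeps its first `N_k` assignments.  For more than
two diseases the tie-break is a uniform choice among tied diseases with
unfilled quotas.  Because the *same* `u1` is compared against every
disease, the case events are comonotone: a disease-specific SNP's realised
case/control odds ratio exceeds its nominal value when a competing disease
exists (e.g. nominal log 1.4 realises near 0.58 with one null competitor at
prevalence 0.1), while a SNP shared with equal effects realises its nominal
value.  This is a property of the assignment scheme, kept deliberately; the
single-disease design recovers nominal effects exactly.  Candidate
consumption is capped at 100 × the total target count, after which the
deficient class is reported.

## Problem sizes and what the tests show

Validation runs at desk scale: panels of 3–20 SNPs, 1000–5000 cases and
controls per class, 100 replicates for the selection-rate and
sharing-gain studies, 500 simulations per expected-Z setting, and a
12-SNP panel for exact search-equivalence.  The simulator emulates
block-structured LD and shared-control ascertainment but not
recombination-map detail, imputation uncertainty, genotyping error or
population stratification, so passing tests demonstrate correctness of the
statistical machinery under the stated generative model, not performance on
any particular real cohort.  Real-data covariates (country, principal
components) are consumed as given, never derived.

## Known limitations

* The joint Bayes factor offset reconciles BIC penalties only; against a
  directly fitted multinomial model the residual gap is ~1 log unit for
  null effects and grows with effect size (see above).  Marginal posterior
  *contrasts*, the quantity used downstream, are much less affected.
* The per-pair sharing policy cannot be calibrated in closed form and falls
  back to capped enumeration.
* Expected-Z theory is first order; with odds ratios above ~1.2 the
  analytic values drift from simulation even though winner classification
  remains stable.
* EM phasing is restricted to ≤ 10 SNPs by design; it is a credible-set
  tool, not a genome-scale phaser.
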