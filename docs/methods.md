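# Methods

## Study structure

The pipeline analyzes a factorial host-rearing experiment on field-collected
kudzu bugs: two collection months (August, September — analyzed separately
throughout, because the collections differ strongly in baseline survival and
fecundity), two photoperiods (16L:8D "long-day", 10L:14D "short-day"), and
three topical treatments (acetone carrier, 0.1% pyriproxyfen, 1.0%
pyriproxyfen), with four replicate 1-L containers of 20 females + 10 males
per cell. Females are followed daily for deaths and egg clutches over a
60-day horizon; September clutches are either held for host eclosion or
exposed to *Paratelenomus saccharalis* for emergence scoring (exposed
clutches have ≥ 15 eggs). The referent cell is short-day + acetone for the
survival model and long-day + acetone for the fecundity, viability and
yield analyses; the referent is carried explicitly on every sample object
and report rather than hard-coded, since the two conventions coexist.

## Models

**Survival.** Right-censored Weibull accelerated failure time:
log T = μ + **x**'β + σW, W ~ standard minimum Gumbel; equivalently T is
Weibull with shape 1/σ and scale exp(μ + **x**'β). Coefficients are
log-time shifts (days, log scale). The likelihood
Σ_events log f(t) + Σ_censored log S(t) is maximized by Newton iteration
with backtracking line search on (β, log σ), initialized from least squares
on log times (Gumbel variance identity σ² π²/6); once the gradient max-norm
falls below 1e−3 pure Newton steps finish the convergence to 1e−8 (near the
optimum the log likelihood itself can no longer resolve the improvement, so
line-search acceptance would stall). A Nelder–Mead restart plus Newton
polish is the fallback; non-convergence raises with the iteration trace.
The covariance is the inverse observed information; identically-zero design
columns are dropped and reported as aliased, other rank deficiencies raise.
Model-level inference is the likelihood-ratio χ² against the intercept-only
fit. Hazard ratios use the Weibull PH identity hr = exp(−β/σ), with CIs by
the delta method on g(β, log σ) = −β e^{−log σ}.

**Kaplan–Meier.** Product-limit estimator with Greenwood variance, ties
resolved deaths-before-censorings. The median is the earliest time with
S(t) ≤ 0.5 (undefined and flagged — not an error — if the curve never
reaches 0.5); its CI inverts the pointwise log(−log) band
(Brookmeyer–Crowley style), matching the default of standard survival
software, since no method was stated in the source analysis.

**Egg production.** Container totals over follow-up (the replicate is the
container, not the female) as NB2 with log link: E[y] = exp(**x**'β),
Var[y] = μ + μ²/θ. β by Fisher-scoring IRLS alternated with bounded 1-D
profile ML for θ on the log scale (bounds 1e−3 to 1e6; the upper bound is
effectively the Poisson limit); covariance from the observed information at
fixed θ̂ (the convention of standard NB GLM software). The additive
three-indicator model (pyr_1.0, pyr_0.1, short_day) is the default; no
photoperiod × chemical interaction, matching the reported model structure.
A treatment cell whose every replicate is zero makes the cell log-mean
diverge; this raises an explicit error recommending the hurdle model. The
hurdle fit factorizes exactly into a binomial logit on the zero/positive
indicator (ridge-penalized and flagged under separation, which the all-zero
cell produces by construction) and a zero-truncated NB on the positives
(L-BFGS-B with Nelder–Mead polish; covariance from a central-difference
Hessian); columns constant among positives are aliased out and reported.

Term F tests refit each term deletion at the full model's θ̂ and use
F = (deviance drop/df1)/φ̂ with φ̂ the full model's Pearson dispersion and
df2 = n − p. EMM cell means are exp of the linear predictor (for the
hurdle: π × truncated mean μ/(1 − p₀), with the log-scale SE by the delta
method over the block-diagonal joint covariance); intervals are t-based
with df = n − p — the design has only 4 replicates per cell, so asymptotic
normal intervals would be anticonservative.

**Viability.** Clutch-level successes with clutch size as binomial weight,
logit link, saturated cell-means coding (the five September cells with
eggs; short-day acetone has none). The weighted MLE on aggregated clutches
equals the egg-level Bernoulli MLE exactly (tested). Cells with zero
successes sit on the boundary: they are reported at 0 with a one-sided
rule-of-three interval (upper ≈ 3/n eggs), and enter Tukey contrasts via a
flagged refit that adds half a success and half a failure in the boundary
cell only — a finite stand-in for the divergent logit, analogous to what
EMM software reports there. Viability intervals use the normal reference
(the effective n is eggs, in the hundreds).

**Multiplicity.** All pairwise link-scale contrasts are adjusted with the
studentized-range distribution, p = P(Q_{k,df} ≥ √2 |t|) (reducing to the
ordinary t-test at k = 2), and rendered as a compact letter display by the
insert-and-absorb algorithm; letters are ordered by descending cell mean.
The letter display is provably consistent with the contrast matrix (pairs
share a letter iff adjusted p > α), and the adjusted p is floored at the
unadjusted p.

**Yield Monte-Carlo.** For each cell with both an egg and an emergence
estimate, a draw is eggs × p with eggs ~ logN(m_e, s_e) and
p ~ logit-N(m_p, s_p): normal sampling error on each model's own link
scale. The source analysis did not name the sampling distributions; this
choice ("the probability distribution produced by the modeled treatment
response") uses estimate-sampling rather than predictive distributions
because the point product of the estimates already reproduces the reported
mean yields to within coefficient rounding — a predictive version
(drawing NB replicate totals) is available through the generator if
replicate-level spread is wanted. The two factors are drawn independently:
they come from disjoint experiments. Draws are summarized by mean, 2.5/97.5%
quantiles, and percent increase vs the long-day acetone referent; the cell
lacking estimates (short-day acetone: no eggs, no exposures) is excluded
with an explicit reason. Separation letters come from a one-way gamma GLM
with log link on the draws (positive, right-skewed; the cell MLEs are the
sample means and the dispersion is Pearson/(N − k)) followed by the same
Tukey machinery. Default n_draws = 2000 per cell. The yield unit is
parasitoids per replicate of 20 host females.

## Calibration of the preset (and of the yield inputs)

The generator's preset equals the published model estimates: AFT
coefficients and log σ per collection; egg-model coefficients per
collection; per-cell eclosion/emergence probabilities with the published
per-cell egg totals, so that letter-display behavior is evaluated at the
experiment's real sample sizes. Two published-table quirks are handled
explicitly: the August long-day survival row prints coefficient +0.154
against Z = −1.61 (sign-inconsistent in the source; the coefficient is
carried as printed and Z is always recomputed as coef/SE), and the reported
"~51% reduction" under short days corresponds to the multiplier
exp(−0.666) = 0.514, i.e. a 48.6% reduction — the package reports the
multiplier and leaves the complement to the reader.

Two quantities are not printed anywhere and had to be chosen:

- **NB dispersion θ.** Backed out of the printed referent-cell SEs: with
  four replicates, var(cell log-mean) ≈ (1/θ + 1/μ)/4, giving θ ≈ 25 for
  September (SE 0.107 at μ ≈ 176) and θ ≈ 0.8 for the much noisier August
  replicates (SE 0.599 at μ ≈ 5). These defaults also make the September
  term tests as decisive as reported; θ remains a free parameter of
  `GeneratorParams` (neutral default 5).
- **Cell-mean SEs for the yield draws.** The egg coefficient table prints
  the referent-cell (intercept) SE and difference SEs. Every cell uses the
  intercept SE as its link-scale sampling SD: the design is balanced, so
  all cell means carry equal replication, and difference SEs would
  overstate single-cell uncertainty. Emergence cells use their own printed
  SEs, delta-transformed to the logit scale (s_logit = s_p / (p(1−p))).

Clutch structure is not modeled in the source analysis; container totals
are partitioned into clutches by iid truncated-Poisson sizes (mean 23 eggs,
the pooled eggs-per-clutch of the published viability table; ≥ 15 for
parasitoid-exposed clutches), last clutch taking the remainder. Clutch
structure only feeds the proportion models' weights. Male survival uses the
female parameters (males are flagged and excluded at analysis ingest;
the published models concern females). The censoring horizon defaults to
60 days, the span of the published survival curves.

## What the generator does and does not emulate

It reproduces the statistical structure the analysis assumes — Weibull
death times under the fitted AFT, NB(θ) container totals with a
deterministic zero cell (short-day acetone, zero-probability 1), binomial
clutch outcomes at the published per-cell rates and egg totals — with full
determinism under (design, params, seed). It does **not** emulate: daily
discretization of death recording (times are continuous), within-day
oviposition timing or per-day laying curves, diapause physiology or dose
kinetics, correlation between a container's survival and its egg total
(female-days are linked when a subjects table is supplied, but egg totals
are drawn marginally), over-clutch heterogeneity in viability
(success counts are exactly binomial, so real clutch-level overdispersion
is absent), or the dissected-but-unemerged parasitism category (excluded
from viability analysis in the source protocol and not generated).
Passing recovery tests therefore demonstrate correctness of the estimators
under the assumed models, not robustness to the real data's deviations
from them.

## Numerical choices and degenerate inputs

Convergence: AFT gradient max-norm < 1e−8 (trace-carrying error on
failure); NB IRLS/θ alternation to 1e−9 on log θ; logit IRLS step-norm
< 1e−12. Ties in KM: deaths first. Survival times are strictly positive;
all-censored groups yield a flagged undefined median. All-zero count
samples and all-boundary proportion samples raise. The studentized-range
tail probability comes from scipy; tests verify it against an independent
double-quadrature oracle to 1e−4. Seeds: a single master seed fans out to
per-collection, per-table (and per-stage) child seeds via
`numpy.random.SeedSequence`, so any stage reruns identically in isolation;
all child seeds stay below 2³¹.

Problem sizes used by the test suite: parameter recovery runs 100
generate-and-refit replicates at ~2000 females (survival), 500 replicate
fits of the 4-containers-per-cell design (counts), and ~10⁴ eggs per cell
(proportions); the null-calibration suite uses 1000 simulated LRTs and 400
simulated F tests. The full suite runs in about a minute on one core.

## Known limitations

- The hurdle count-part covariance comes from a finite-difference Hessian;
  for very small positive-count samples it can be rough (the MLE itself is
  verified against brute-force oracles).
- The gamma-GLM letters on 2000 draws per cell resolve mean differences
  well below 1%, so the equivalence (shared letter) of two treatments is
  extremely sensitive to their input means; with inputs taken from rounded
  published coefficients, the two long-day pyriproxyfen cells (whose
  reported means differ by only 0.5%) separate even though the original
  analysis found them equivalent. The means, intervals, ordering and every
  other letter relation are insensitive to this.
- August-preset fecundity is extremely overdispersed (θ ≈ 0.8); individual
  synthetic August datasets can produce wide, unstable EMM intervals, as
  the real August data apparently did.
- EMM df conventions differ by stage (t with n − p for counts, normal for
  egg-weighted proportions); both are documented choices, not estimates of
  the "true" df of the original software stack.
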