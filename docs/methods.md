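# Methods

## The quantity under study

Each observation is a *pattern*: one mother's (or one treatment group's)
daily or weekly metabolizable energy intake (MEI, MJ/day) from
parturition until after intake peaks, with the diet's metabolizable
energy density (MJ/kg dry matter) and the maternal body mass. Day 0 is
excluded everywhere; the *initial rate* is the first measurement at day
≥ 1, and all elevation measures are relative to it. Body mass at the
time of peak intake is the default allometric regressor, on the argument
that the tissues supporting lactation are maximal then; mass at
lactation onset is available as a sensitivity variant.

Six raw characteristics are extracted per pattern. Peak detection is the
global argmax of the analysable series with ties broken by the earliest
time (the peak is the first attainment, just before intake levels off);
an opt-in robust mode takes the argmax of a centered 3-point median
smooth instead, which suppresses single-measurement spikes. The default
stays deterministic and assumption-free. The cumulative elevation to
peak is a rectangle sum, (MEI − initial) × grid spacing: on daily data
this is literally the sum of the daily differences, and on weekly data
the weekly mean difference times seven. The grid spacing is the median
inter-measurement interval, so an isolated gap does not distort it. The
average rate includes both endpoints; whether the endpoints belong to
"between initial and peak" is ambiguous in ordinary usage, and the
inclusive convention is flagged here as a documented choice rather than
an inference.

## Growth-curve decomposition

The cumulative elevation series (re-zeroed at the initial-rate
measurement, in both time and level) is fitted with the generalized Von
Bertalanffy curve C(t) = A(1 − e^{−kt})^c by bounded nonlinear least
squares (`scipy.optimize.least_squares`, trf). Re-deriving the interior
maximum of C′: it exists iff c > 1 and sits at t\* = ln(c)/k — natural
logarithm; the decomposition identity

cumulative-to-peak = amplitude × time-to-peak × (1 − 1/c)/ln(c)

holds exactly only with the natural log, which fixes the base throughout.
The factor (1 − 1/c)/ln(c), the *shape*, decreases strictly from 1
(c → 1⁺) to 0 (c → ∞) and equals 0.5 when the rise is effectively
linear (the right-triangle area argument).

Numerical choices: initialisation A₀ = 1.05 × max observed cumulative,
c₀ = 2, k₀ = ln(c₀)/t_peak-guess with the raw time to peak as guess
(falling back to the largest observed increment); box constraints
A ∈ (0, 10 × max], k ∈ (0, 10] day⁻¹, c ∈ (1 + 10⁻⁶, 100], since c ≤ 1
has no interior peak and the decomposition is undefined there; two
alternative starts (c₀ = 1.5, 5) are tried only if the default start
fails. Degenerate series (constant zero, fewer than 3 points) raise a
no-fit error; optimizer failure is reported as `converged = False`, not
an exception.

Goodness of fit is RMSE/(max − min), for the cumulative series (primary)
and for the rate series (secondary; necessarily worse since the rate is
noisier). Abnormal fits are screened on r = (t\*_model −
t\*_raw)/t\*_raw using Tukey fences (Q1 − 1.5 IQR, Q3 + 1.5 IQR) over
the cohort of converged fits: the fence rule is a deterministic,
documented replacement for a partly visual screening step; cohorts
smaller than 4 skip the screening with a warning, and a zero-IQR cohort
flags nothing.

One consequence of re-zeroing at the first measurement deserves note:
when the true elevation is still rising steeply at day 1 (curvature
exponent c near 1), the deficit rate(day 1) × duration is removed from
the observed cumulative elevation, which biases the fitted curve toward
concave-down (larger shape) and can couple the fitted shape to the
fitted cumulative elevation. The same convention applies to real data;
tests of the shape-covariate regression therefore construct the
decomposition identity exactly rather than routing through trajectory
refits.

## Scaling regressions

The model is log10 y = intercept + b1·x + b2·x² + diet_coef·d + species
+ breed-in-species + residual, x = log10(mass in kg). Kilograms and
log10 are load-bearing: the local-exponent arithmetic b1 + b2·log10(M)
at 0.05 kg and 500 kg only reproduces with this parameterisation. Rows
with non-positive characteristics are dropped and logged.

*REML route* (no phylogeny): statsmodels MixedLM with a species random
intercept and a breed-within-species variance component; Wald intervals
and p-values; singular components reported near zero with a warning.

*Phylogenetic route*: a Bayesian animal model. The species covariance V
is the Brownian expectation (shared root-to-MRCA branch length) of the
supplied tree, scaled to unit height so σ²_phylo is comparable across
trees; multifurcations are accepted; pruning keeps unifurcations so the
pruned covariance is exactly the submatrix of the full one. Repeated
measures map onto the species effect through an incidence matrix, with
no per-species weighting. The Gibbs sampler alternates (i) a joint
multivariate-normal draw of all fixed and random effects from the
mixed-model equations and (ii) scaled inverse-chi-squared draws of the
three variances. Priors: improper flat on fixed effects (with a 10⁻¹⁰
relative ridge on their block purely for factorizability of
near-collinear designs) and inverse-gamma(0.001, 0.001) on each
variance — the customary weakly-informative default; both are
configurable, and variances can be pinned (degenerate priors), in which
case the posterior mean of the fixed effects provably equals GLS — the
sampler's validation oracle in the tests.

Reported: posterior means, 95 % equal-tailed credible intervals,
pMCMC = 2·min(Pr(>0), Pr(<0)) floored at 2/n_retained, the
phylogenetic signal λ = σ²_phylo/(σ²_phylo + σ²_breed + σ²_resid)
(posterior mean of the per-draw ratio — the phylogenetic-heritability
convention; whether a breed term belongs in the denominator is a
convention choice, documented here, not a derivation), and the marginal
r² var(Xβ)/(var(Xβ) + Σσ² + σ²_resid) averaged over draws. Chains
default to 60,000 iterations, 10,000 burn-in, thinning 25 (2,000
retained draws), which is ample for this model's dimension — the
split-R̂ of every fixed effect is computed and values above 1.1 are
surfaced as warnings; longer chains are a configuration setting.

Variants: species-averaged analysis (collapse to species means, identity
incidence — a Bayesian phylogenetic GLS; note that with one observation
per species the phylogenetic and residual variances are only weakly
separable, which is intrinsic to species-mean analyses), onset-mass
design, shape-as-covariate regression (the covariate is dropped with a
log entry if numerically constant), and ratio scalings with the
back-transformed prediction at covariate means reported as a fold
change.

## Synthetic data

The generator emulates the statistical structure of a compiled
comparative dataset, not any real database. Defaults: 24 species with
masses log-uniform on 0.01–600 kg (log-mass leverage is what the
regression needs); a Yule tree (unit splitting rate, held one extra
exponential waiting time after the last split so terminal branches are
positive, then scaled to unit height); species effects multivariate
normal with covariance σ²_phylo·V_λ, where λ_true damps off-diagonals
only — marginal variances are λ-invariant by construction; five
"well-studied" species contribute Poisson(5.6) patterns each (min 2, two
breeds) and the rest one, reproducing the heavy-tailed replication of
the compiled data (~47 patterns); peak-rate law defaulting to the
phylogeny-controlled reference estimates (intercept −0.233, b1 0.667,
b2 0.050, diet 0.024) with σ_phylo = 0.07, σ_breed = 0.02,
σ_resid = 0.04 (signal ratio ≈ 0.71, marginal r² ≈ 0.99, as observed
for rate characteristics); the initial rate is peak/1.9 with 0.02
log-SD scatter on the fold, making the initial-rate and amplitude laws
parallel to the peak-rate law; the time-to-peak law defaults to its
reference estimates (1.266, 0.078, 0.036, −0.001) with an independent
0.15 log-SD scatter; curvature c lognormal (median 2.5, log-SD 0.35,
truncated to (1.05, 60)), giving generating shapes of ~0.66 ± 0.11;
trajectories are the exact Von Bertalanffy elevation with k = ln(c)/T
and A = amplitude/(k(1−1/c)^{c−1}) so the drawn targets are exact before
noise; multiplicative lognormal observation noise with CV 0.05 (no
per-pattern measurement error is reported anywhere, so this is a
simulation knob, not an estimate); species of 20 kg and above are
recorded as weekly means tagged at the week midpoint (3.5, 10.5, …),
the rest daily; onset mass is peak mass times a 0.03 log-SD lognormal
factor; series extend to 1.4 × the time to peak so the maximum is
observable.

What passing tests on these data do *not* show about real data: the
generator has no digitisation error, no missing weeks, no within-series
autocorrelation, no diet changes during lactation, no correlation
between diet density and body mass, and its trajectories are exactly the
fitted family — so goodness-of-fit and parameter-recovery results are
upper bounds on what compiled literature data would give.

## Problem sizes and reproducibility

All randomness flows from explicit integer seeds (per-stage substream
seeds are derived by hashing the base seed with a stage tag, keeping
everything below 2³¹); a fixed seed makes a full pipeline run, including
every MCMC stream, byte-identical. The test suite runs its heaviest
check — 20 replicate recoveries at 24 species/~50 patterns with
60,000-iteration chains, plus a λ-ordering sweep — in a few minutes; the
million-iteration chains of historical software are reachable via
configuration but are not needed for convergence at this model size.

## Known limitations

- The visual component of historical abnormal-fit screening cannot be
  reproduced; the fence rule is the documented, deterministic stand-in.
- With c close to 1 the peak is ill-defined (time-to-peak → ∞ as the
  rate's maximum flattens), and fitted c near the lower bound makes the
  derived characteristics unstable; such fits are the ones the abnormal
  screen tends to catch.
- λ here is a variance ratio, not Pagel's branch-length transform;
  simulations with λ_true < 1 are deliberately mismatched to the
  analysis model (which assumes the full tree covariance), as in the
  original software convention, so λ recovery is ordinal rather than
  unbiased.
- The REML route treats the species effect as exchangeable; comparing it
  with the phylogenetic route is the intended use, not a substitute.
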