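# lactscale

Allometric analysis of how lactating mammal mothers raise their food
intake after giving birth.

Lactation is the most expensive thing most female mammals ever do, and
they pay for it mainly by eating more. `lactscale` implements a
comparative analysis of the *pattern* of maternal metabolizable energy
intake (MEI, MJ/day) elevation between parturition and its peak, across
species spanning five orders of magnitude in body mass: from the raw
time series to the allometric scaling laws, with phylogeny taken into
account. It is aimed at comparative physiologists and ecologists testing
metabolic-theory predictions about rates, durations and cumulative
energy budgets of lactation.

## What it computes

**Pattern characteristics.** From each intake time series (day 0, the
day of parturition, is never analysed): the initial rate (first
measurement after parturition), the peak rate and time to peak, the
average rate from initial to peak, the amplitude (peak − initial), and
the cumulative elevation to peak, a rectangle sum of (MEI − initial) on
the sampling grid.

**Growth-curve decomposition.** The cumulative elevation is fitted per
pattern with a generalized Von Bertalanffy curve

    C(t) = A (1 − e^{−kt})^c,

whose derivative (the extra intake) peaks at t\* = ln(c)/k when c > 1.
Evaluating the curve there gives model-based time to peak, amplitude
A·k·(1−1/c)^{c−1}, and cumulative elevation to peak A·(1−1/c)^c, linked
by the exact identity

    cumulative-to-peak = amplitude × time-to-peak × (1 − 1/c)/ln(c).

The last factor is the **shape** statistic: 0.5 for a perfectly linear
rise (a right-triangle area), above 0.5 for a decelerating
(concave-down) rise, below for an accelerating one. Non-converged fits
and fits whose model time to peak is a Tukey-fence outlier relative to
the raw one are excluded, with a logged reason.

**Scaling regressions.** Each characteristic y is modelled on the log10
scale as

    log10 y = intercept + b1·x + b2·x² + diet_coef·d + u_species + u_breed + e,

with x = log10(body mass, kg) and d the diet metabolizable-energy
density (MJ/kg DM) — i.e. a power law whose exponent depends on mass:
the local exponent at mass M is b = b1 + b2·log10(M). Two routes are
provided: a REML mixed model (species, breed-within-species), and a
Bayesian animal model sampled by an in-house Gibbs sampler in which the
species effects carry the Brownian-motion covariance of a supplied
phylogeny; the phylogenetic signal is reported as
λ = σ²_phylo/(σ²_phylo+σ²_breed+σ²_resid), along with 95 % credible
intervals, pMCMC values and the marginal r² of Nakagawa & Schielzeth.
Variant analyses: species-averaged (one point per species), mass at
lactation onset instead of at peak, the shape statistic as an extra
covariate, and ratio scalings such as peak/initial rate.

**Synthetic data.** A generator produces datasets with the structure the
analysis assumes — a Yule species tree, phylogenetically correlated
species effects with tunable signal λ, heavy-tailed replication across
species, curvilinear scaling with a diet effect, sigmoid trajectories,
daily sampling for small species and weekly means for large ones — so
the whole pipeline is testable end to end without any external data.

## Worked example

```sh
lactscale simulate --out demo --seed 1
# wrote 49 patterns to demo/dataset.csv
lactscale features --dataset demo/dataset.csv --out demo/chars.tsv
lactscale scale --features demo/chars.tsv --newick demo/tree.nwk \
    --characteristic peak_rate --seed 1
```

prints (60,000 iterations, 10,000 burn-in, thinning 25):

```
 intercept = -0.246  [-0.325, -0.167] **
        b1 =  0.675  [ 0.654,  0.696] **
        b2 =  0.037  [ 0.025,  0.050] **
 diet_coef =  0.028  [ 0.024,  0.033] **
    lambda =  0.281   marginal r2 = 0.994
```

The generator's defaults put the true peak-rate law at intercept −0.233,
b1 = 0.667, b2 = 0.050, diet coefficient 0.024: the credible intervals
recover b1 and the diet effect, the curvature b2 is estimated with the
expected width at 24 species, and the positive b2 means the scaling
exponent rises with body mass — about 0.63 for a 50-g mouse versus 0.77
for a 500-kg cow in this run (`ScalingFit.local_exponent`). The full
pipeline (`lactscale run-all --config cfg.yaml`) adds the growth-curve
stage, exclusions, variants and a Table-style TSV/JSON report.

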