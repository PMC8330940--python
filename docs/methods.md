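# Methods

## The estimation problem

A female gray whale's reproductive state is observable only indirectly: a
calf seen at her side the year after biopsy implies she was pregnant when
sampled; a calf in the sampling year implies lactation; a known age under 8
years (the species' mean age of sexual maturity) implies immaturity. Most
biopsied females have none of these anchors. Blubber progesterone separates
pregnant from non-pregnant females strongly but not perfectly, so the
package treats classification as a mixture problem: estimate the two
concentration clusters from all non-calf females at once, then read each
whale's pregnancy probability off the fitted model.

## Life-history rules

Age class: calf if sampled as a calf (≤ 8 m, accompanied by an adult
female); immature if known age < 8; adult if known age or length of sighting
history (LSH) ≥ 8 years; otherwise unknown. Known age exists only for whales
first documented as calves and takes precedence over LSH; a known age < 8
combined with LSH ≥ 8 is contradictory and rejected rather than resolved.
Reproductive state for adult females follows calf associations (next-year
calf → pregnant; same-year calf → lactating; neither → adult-unknown).
Season windows are pinned to calendar dates — summer Jun 15–Sep 21, fall
Sep 22–Nov 15, inclusive — the split between Sep 21/22 being fixed by the
published season labels of the repeated-samples records (9/20 is summer,
9/23 is fall). When an individual was biopsied more than once, the main
analysis keeps the biopsy with a determined class, else the earliest;
repeats are kept separately.

## Mixture model

Let x be blubber progesterone in ng/g and z = ln x. The model is

  z ~ λ_l N(μ_l, σ_l²) + λ_h N(μ_h, σ_h²),  λ_l + λ_h = 1,

with unconstrained variances: the back-transformed per-component
μ ± 1.96 σ coverage intervals reported by `summarize_fit` (0.6–6.4 and
4.8–59.6 ng/g on the packaged cohort) only make sense with separate σ_k.
Natural log is the working scale; the choice of base cancels in every
reported quantity (probabilities are density ratios, component geometric
means back-transform identically).

Fitting is by expectation–maximisation with closed-form M-steps. Defaults:
tolerance 1e-8 on the log-likelihood change, at most 1000 iterations, and a
best-of-three deterministic initialisation — median split, outer-quartile
moment match, and a 1-D 2-means threshold split — keeping the highest
log-likelihood. A single median-split start proved to land in poor local
optima on a few percent of simulated cohorts, biasing the high-component
mean; multiple deterministic starts remove that failure mode while keeping
refits bit-for-bit reproducible. For samples of n ≤ 30 the fitter
additionally seeds EM from every ordered split, which makes it match a
brute-force grid search on small instances (the unequal-variance mixture
likelihood is unbounded as σ → 0, so "optimum" always means the interior
solution that EM-type estimators and reference implementations target).
Degenerate collapses (σ → 0) trigger seeded perturbed restarts and
ultimately a hard error; non-convergence is flagged on the fit object and
probability evaluation refuses unconverged fits.

The pregnancy probability is the *mixing-weighted* posterior of the
high-mean component. The weighting matters: only the weighted form
reproduces the published 50% threshold and per-whale probabilities from the
published component parameters. The unweighted density ratio remains
available (`weighted=False`) for sensitivity analysis. The 50% threshold is
solved by bracketed root-finding on the log scale after verifying the curve
crosses the target exactly once on the search range. The overlap between
clusters is the area under the pointwise minimum of the two weighted
component densities, by adaptive quadrature split at the density crossings;
the published 4.5% anchor comes from an unstated definition, so the package
reports its own value (3.7% on the packaged cohort) without asserting
equality. Category thresholds are strict: p > 0.95 likely pregnant,
p < 0.05 likely non-pregnant, boundary values indeterminate.

## Bootstrap uncertainty

Each of B replicates draws n − 4 values with replacement from the full
62-value set and appends the four confirmed-pregnant concentrations,
preserving the sample size while guaranteeing the sparse high cluster is
never lost (drawing n and appending is supported but not default). The
mixture is refitted per replicate and the probability curve evaluated on a
200-point log-spaced grid plus every whale's concentration. A replicate is
retained when the fit converged, its curve is monotone increasing over the
observed range, and it reaches ≥ 0.99 at the highest observed
concentration. The end-point check alone (the simplest reading of
"approaches 1 at high progesterone") retains ~96% of replicates on the
packaged cohort; adding monotonicity retains ~87–88%, matching the
published ~90% retention, and is the default (`require_monotone=False`
restores the end-point rule; the strict limit criterion σ_h > σ_l, which
retains only ~45%, is exposed separately for comparison). The band is the
pointwise 2.5th/97.5th percentile (linear-interpolation definition) over
retained curves; per-whale intervals are the same percentiles at the
whale's concentration. With a fixed seed the whole procedure is
bit-for-bit reproducible. B = 10,000 runs in about half a minute on one
CPU; tests use B = 300–500 and the analysis driver defaults to B = 2,000,
which leaves percentile noise well below the width of the reported
intervals.

## Assay QC

Competitive EIA standard curves are fitted as 4PL,
y = d + (a − d)/(1 + (x/c)^b), by bounded least squares; binding at the
fitted EC50 is midway between asymptotes by construction. Parallelism uses
either the logit(binding)–log(dose) linearisation restricted to the 20–80%
binding window (pooled-variance t on the slope difference, df = n1+n2−4 —
the kit-validation convention) or the hill slopes of separate 4PL fits; the
published validation does not state the linearisation link, so logit–log,
the standard EIA choice, is pinned here. Accuracy is an OLS of recovered
vs added mass. Duplicate-well CV is SD/mean of the two readings; wells
above 10% are flagged for re-assay. Conversion to tissue concentration is
ng/g = pg/ml × extract volume (ml) × dilution factor / (mass g × 1000) —
the conventional rehydration/aliquot algebra, isolated in one function
because the source protocol does not spell it out.

## Synthetic data

The generator reproduces the structure the analysis assumes: non-calf
female log progesterone from the two-component mixture with defaults
pinned to the packaged-cohort refit (geometric means 2.0/16.9 ng/g,
σ 0.61/0.64, λ_h 0.31); confirmed-pregnant and known-non-pregnant classes
drawn from their own components; unknown-status whales from the λ-weighted
mixture; calves of both sexes at the low component times a 2.3× maternal
transfer multiplier; adult-male testosterone with a fall/summer log-mean
ratio of ~5.6 (0.7 vs 3.9 ng/g); multiplicative duplicate-well noise at a
5% CV. Class proportions default to the field cohort's (4 calves, 6
immature, 6 lactating, 4 pregnant, 26 adult-unknown, 20 unknown per 66
females). Sighting metadata is generated consistently with each class, so
the classification rules recover the generating classes exactly.

What the generator does not emulate: repeated sampling of individuals,
seasonal or gestational-stage trends in progesterone, assay plate effects
or inter-assay drift, and any covariance between hormone level and
sighting probability. Passing recovery tests therefore shows the estimator
is consistent under the model's own assumptions — not that field data meet
those assumptions.

## Numerical choices and limitations

Probabilities are computed in log space (no overflow at extreme
concentrations); the EM E-step uses the log-sum-exp trick. Percentiles use
the inclusive linear-interpolation definition. The fixture is
integrity-checked against a frozen SHA-256. CSV round-trips preserve
float64 exactly (%.17g on write, round-trip parsing on read).

Known limitations: the two-component assumption cannot represent
intermediate physiological states (early pregnancy, pseudopregnancy,
recent ovulation), which is why mid-range concentrations get wide
intervals rather than confident calls; the 8-year maturity cutoff is a
population mean applied as a hard threshold; per-whale intervals for the
four forced-in pregnant whales are conditional on forcing and slightly
optimistic; and absolute ng/g thresholds do not transfer across
laboratories or assay kits without calibration.
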