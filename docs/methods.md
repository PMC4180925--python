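# Methods

This note documents the models, conventions and numerical choices behind
`homecage`, in the order the pipeline applies them. It states no result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Coordinate stream and light schedule

The unit of analysis is one animal's centre-of-gravity trace, 15
samples/s over 3 days in a 30 × 30 cm cage, starting at the onset of the
first dark phase (7:00/19:00 lights on/off by default). Phase bins are
half-open: a transition instant belongs to the phase it begins, so
[0, 72 h) partitions into exactly six 12 h bins. Samples are NaN and
flagged undetected while the tracker has lost the animal (in or under
the shelter). On file input, missing rows between detected samples are
linearly interpolated up to 1 s; longer detected gaps are treated as a
corrupt file rather than silently bridged, since every downstream
duration would inherit the error. Gaps adjacent to undetected samples
are shelter occupancy and are kept undetected.

## Segmentation

Smoothing applies running medians with half-windows 3, 2, 1, 1 (window
2h+1) to x and y independently, in that order. Edges use shrinking
windows (the median of whatever part of the window is in range): this
keeps output length equal to input length without inventing phantom
motion at run boundaries. Detected runs shorter than the largest window
pass through unsmoothed with a warning.

An **arrest** is a maximal run of ≥ 3 samples that all lie within
ε = 0.1 cm of the run's medoid. The medoid is operationalized as the run
sample nearest the coordinate-wise median: the exact medoid is O(k²) and
a sleep arrest can span 10⁵ samples, while for the near-stationary
clouds this criterion is applied to the two coincide. Runs are found by
a deterministic left-to-right greedy (grow by doubling, then binary
search the last valid end); validity is not perfectly monotone in run
length, so maximality is approximate but reproducible. Complementary
intervals are **moves**; a move's distance is the summed displacement of
the smoothed coordinates between its own samples, so the two boundary
steps flanking a segment belong to neither neighbour. Velocity is
per-sample displacement × sample rate on smoothed coordinates; a move's
maximum velocity is the maximum over its samples.

A **shelter visit** opens when detection is lost while the last detected
position lies in the 2 cm entrance strip and closes at the first sample
of a run of ≥ 7 detected samples (0.5 s); shorter re-detections are
entry/exit flicker and do not close the visit. Detection lost elsewhere
is logged as a tracking dropout and excluded from visit logic. A record
that begins undetected opens a visit at t = 0. Zone occupancy
(Feeding, Spout, OnShelter) is closed point-in-polygon membership per
detected sample, merged into maximal intervals; each OnShelter interval
counts as one jump onto the shelter.

## Mouse-determined thresholds

Histograms use 0.5 log₂-unit bins with edges on multiples of 0.5 (a
`phase` argument exists to probe bin-alignment sensitivity; fitted
thresholds move by less than the fit tolerance under a half-bin shift).
Mixture fits minimize the sum of squared differences between bin counts
and a sum of Gaussian curves (amplitude parameterization), with bounded
nonlinear least squares (`scipy.optimize.least_squares`, trf). Component
means are box-constrained — moves: [−6, 1] and [1, 6] log₂ cm; shelter:
[0, 10], [9, 10], [10, 15] log₂ s — SDs in [0.05, max(span, 2)] log₂
units, amplitudes in [0, 10 × max count]. Five deterministic starts
place the means at fractions 0.1, 0.3, 0.5, 0.7, 0.9 of their boxes; the
lowest-cost successful fit wins. Curve intersections are located by sign
changes on a 512-point grid between the two means, refined by Brent's
method; with several roots the one nearest the midpoint of the means is
used. Because the least-squares amplitudes are the mixture densities
scaled by one common factor (n × bin width), the fitted intersection
estimates the analytic intersection of the generating weighted
densities — which is what the recovery suites check.

Percentiles use linear interpolation between order statistics (so
durations 1..10 s give a 90th percentile of 9.1 s). The short-visit
threshold is μ₁ + z₀.₉σ₁ with z₀.₉ = Φ⁻¹(0.9) = 1.2816. Preconditions:
≥ 50 moves, ≥ 50 visits, ≥ 10 arrests; animals failing a fit (optimizer
failure, no intersection, or a long threshold at or below the short one)
receive the cohort median for that threshold and carry a flag.
Classification tie-breaks: moves and arrests exactly at a threshold are
long (closed upper class); shelter visits are short strictly below the
short cutoff, long strictly above the long cutoff, intermediate
otherwise. The arrest percentile pools all three days; whether the
original analysis pooled or split by phase is not documented, so pooling
is the stated default.

## Parameters

An **activity bout** opens at a long move not already inside a bout and
closes at the first long arrest, the first shelter visit longer than the
short-visit threshold, or the end of the recording; the terminating
event is excluded from the bout. Brief (passing-through) visits, short
arrests and short moves do not interrupt a bout.

12 h binning assigns events by start time; cumulative durations are
clipped at bin edges, so the six bins conserve each measure's 3-day
total. The habituation index is day 3 over day 1 of the matched phase
(missing when day 1 is zero); the DarkLight index is dark/(dark+light)
on day 3 (missing when both are zero). Transition slopes are OLS slopes
of the per-10-min-bin fraction of time inside bouts, over the 2 h before
(anticipation) and after (response) each of day 3's two transitions,
excluding the 10-min bin adjacent to the transition; units are
proportion per hour. "Active" is operationalized as "inside an activity
bout", the pipeline's own activity construct; the 2 h window and 10-min
bins are configurable defaults chosen so anticipation windows never
overlap the opposite phase's response windows.

The **outside-sleeper exclusion** pools the light phases of days 2 and
3: flag = (shelter-time fraction < 0.60) AND (fraction of outside 5-min
bins with cumulative move distance < 2 cm exceeds 0.25). A 5-min bin
counts as outside when at least half of it is outside the shelter; move
distance is apportioned to bins by time overlap. Records not covering
days 2–3 are unevaluable. Both criteria are reported separately.

The **registry** is declarative (name, category, function of the
per-animal record) and ships with exactly 115 parameters: 14 singleton
measures (the four thresholds, peak long-move velocity, mean long-arrest
duration, total distance per 24 h, headline sheltering measures, zone
occupancy fractions, total jumps, total activity fraction), per-bin
frequencies for all seven segment classes (42), per-bin cumulative
durations for the four resting classes (24), per-bin bout count /
cumulative / mean duration (18), habituation indices for four measures ×
two phases (8), DarkLight indices for five measures (5), and the four
transition slopes (4). Each parameter carries one of six category tags.
The registry is the extension point for reconstituting any larger
published parameter set.

## Strain statistics

Per parameter, in order: log₁₀ transform iff all values are positive and
the adjusted Fisher–Pearson sample skewness is positive and decreases
under the transform; Winsorizing at mean ± 5 SD (ddof = 1) computed over
all animals pooled, not per strain, replacing values with the limit
itself (one-shot — limits are not recomputed, so repeated application
could tighten them slightly; the tests pin down the true properties:
only tail points change and the map is monotone); then ANOVA and
variance components on the processed values.

Heritability uses the inbred-panel estimator with the unequal-group
correction n₀ = (N − Σnᵢ²/N)/(a−1); V_B = max(0, (MS_B − MS_W)/n₀);
h² = ½V_B/(½V_B + V_W). The ½ reflects that the variance among fully
inbred lines is twice the additive genetic variance of a random-mating
population, making h² a narrow-sense estimate. Degenerate inputs:
all-identical values give h² = 0; strains with one animal contribute to
the between-strain term only, as in standard unbalanced ANOVA.
Calibration (acceptance suite): at the reference panel's group sizes the
mean estimate over 500 replicate cohorts lands within ±0.05 of
generating h² ∈ {0.2, 0.5, 0.7}; the estimator is slightly conservative
at high h² because the ratio is nonlinear in the variance components.

ANOVA significance uses α/(number of matrix columns). PCA z-scores
columns, eigendecomposes the correlation matrix of complete cases
(incomplete animals and constant columns dropped with counts logged) and
retains eigenvalues strictly above 1, with a 10⁻⁹ tolerance so an
exactly-unit eigenvalue (identity correlation) is never retained off
floating-point noise. Retained loadings are varimax-rotated (SVD
formulation; orthogonal, so communalities are preserved exactly);
|loading| ≥ 0.4 is flagged. Shared genetic variance is r² between the
two parameters' vectors of strain means; for independent parameters
across a strains its null expectation is 1/(a−1), which the tests verify
at a = 11. The category effect-size comparison treats parameters as
observations in a one-way ANOVA across the six categories
(df = (5, 109) for 115 parameters); zero within-category variance is
reported missing rather than as an infinite F.

## The synthetic cohort generator

Each animal is an alternating renewal process. Shelter-visit durations
are a 3-component log₂-normal mixture (defaults: means 3, 9.5, 12 log₂ s
≈ 8 s, 12 min, 68 min; SDs 0.8, 0.5, 0.6) with phase-dependent class
weights — dark (0.75, 0.20, 0.05), light (0.35, 0.20, 0.45) — so resting
visits concentrate in the light phase. Excursion durations are
log-normal with mean τ_sh·f/(1−f), where τ_sh is the expected shelter
visit under the current phase weights and f the target outside fraction,
so the long-run outside share matches f by renewal-reward. f is the
phase's activity level (defaults: dark 0.60, light 0.10) times a per-day
habituation multiplier (default 0.90) — so a day-3/day-1 activity index
tracks the multiplier squared — plus a linear anticipation ramp over the
last 2 h of a phase (fraction per hour). Excursions alternate moves
(bimodal log₂-normal distances: short ≈ 1 cm, long ≈ 8 cm, 35 % long;
velocities ~12 cm/s long, 2.5 cm/s short) and arrests (log₂-normal,
median ≈ 10 s). Long moves route occasionally to the feeding, spout or
on-shelter zones; "outside sleepers" are generated by converting most
light-phase rest into 30–90 min outside arrests.

Geometry is deliberately minimal: straight constant-velocity polylines
that reflect off the walls (exactly preserving drawn distances), with
isotropic jitter of 0.02 cm (clipped at 0.045 cm, well under ε) so
smoothing and the arrest criterion behave as on real data. The smallest
realized move displacement is 0.4 cm: a genuine turn or rear moves the
centre of gravity on this order, and displacements at or below ε are by
definition arrests, not moves. Durations are quantized to whole samples
and segments tile the 72 h record exactly; the first move after a
shelter visit lasts at least 8 samples so the exit debounce always
closes the visit.

Strain structure: selected profile fields (move-distance means, velocity,
arrest duration, activity fractions, habituation, anticipation,
jumping propensity) vary on a transformed scale (logit for proportions,
log for positive scale parameters). For a target h², a fraction
q = 2h²/(1+h²) of the field's latent variance is placed between strains
and 1−q within, which makes the inbred-panel estimator target h² in
expectation; a target of 0 collapses all strain-level values onto the
panel mean. A value-level generator (`simulate_strain_values`) applies
the same variance split directly to a phenotype and is the oracle for
estimator-calibration and null simulations, where hundreds of replicate
cohorts at n = 476 are needed. Seeding is hierarchical: one master seed,
per-animal substreams derived from (seed, strain index, animal index),
so any animal regenerates identically in isolation.

What the generator does **not** emulate: realistic path tortuosity and
posture, inter-individual differences in cage layout use, ultradian
rhythms, tracking noise and dropouts outside the shelter, and any
correlation structure between behavioral dimensions beyond what the
shared renewal construction induces. Passing recovery tests therefore
show that the pipeline inverts this generative family correctly — exact
segment boundaries, thresholds near analytic intersections, calibrated
h² — not that it is robust to every artefact of real video tracking.

Single-animal habituation and DarkLight indices are noisy because a 12 h
bin contains only a handful of hours-long shelter visits; recovery tests
compare means over several animals against generator arithmetic.

## Problem sizes

The test suite and acceptance script use: the full 476-animal reference
cohort at event level (the rendering path is exercised on shorter
records, 6–12 h, where boundary-recovery statistics are already in the
thousands); 100 seeds × 2000 events for mixture-threshold recovery; 500
replicate cohorts per heritability target; 1000 null cohorts for the
family-wise error rate. These sizes give Monte-Carlo standard errors
comfortably below the tolerances they are checked against.

## Known limitations

- The arrest criterion is one defensible operationalization of
  "complete inactivity or minute movements"; other smoothing-based
  segmenters would place boundaries a few samples differently.
- Mixture fits on 0.5-log₂ histograms have limited resolution when
  components are close (the shelter components 1 and 2 can trade mass);
  the multi-start least-squares is deterministic but not a likelihood
  method.
- Winsorizing and the transform decision are per-parameter marginal
  choices; no multivariate outlier handling.
- The PCA retention count on simulated cohorts depends on the generator's
  correlation structure and is not comparable to any particular
  empirical panel.
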