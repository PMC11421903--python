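# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `rumblesig`, in the order the pipeline runs them.

## Synthetic study generator

The generator emulates a two-population observational study of adult
female elephants with hierarchically nested social structure.

**Structure.** Each population holds `bond_groups_per_population` bond
groups of `core_groups_per_bond` core groups; callers are distributed
round-robin across core groups so group sizes are near-equal. Defaults
mirror the emulated study's scale: populations of 81 and 21 adult-female
callers with on average 12 calls each (negative-binomial overdispersion,
dispersion r = 4, with a floor of six calls so every caller can satisfy
the individual-experiment inclusion rule of three calls on each of two
dates). Ages are truncated-normal, mean 26, s.d. 12, minimum 10 years
(adults only). The matriarch of a core group is its oldest member, ties
broken by lexicographic id.

**Planted acoustic effects.** A call's second-harmonic (f1) mean is

```
f1 = context base + pop offset + bond offset + core offset
     + individual offset + age_slope · (age − mean age) + N(0, noise_sd)
```

Context base values are an evenly spaced ±2 Hz ladder around 30 Hz over
the nine behavioural contexts; each context also fixes a duration mean
(0.7–1.3 × the global mean) and a contour shape (flat/rise/fall/arch,
cycling), so behavioural context is a genuine confound that the
same-context pairing rule of the similarity analysis must remove. The
two population offsets are a fixed symmetric contrast (±sigma_pop/2),
making the between-population divergence exactly `sigma_pop_hz`; bond,
core and individual offsets are independent `N(0, sigma)` draws.
Defaults: sigma_pop 3 Hz, sigma_bond 0.5 Hz, sigma_core 1 Hz, sigma_ind
2 Hz, call-level noise 1.5 Hz, age slope −0.05 Hz/year. These place the
population signature well above, and the bond signature below, the
detection threshold at desk scale — matching the qualitative ordering
the experiments are meant to probe (population > individual > core >
bond).

**Waveforms.** A call is an additive harmonic stack on the fundamental
f0(t) = f1(t)/2 with amplitudes (0.45, 0.8, 1/3, 1/4, …): the second
harmonic dominates, as it does in rumbles, which also keeps tracing
well-posed when the fundamental falls inside the 14–80 Hz search band.
White Gaussian noise is added at the configured SNR (default 20 dB;
−inf yields pure noise), with a 50 ms raised-cosine fade at each end.
Contour shapes are defined with unit time-average so `f1_mean_hz` is
always the call's mean; `rise` spans ±1/3 of the mean by default
(e.g. 20→40 Hz around 30 Hz). Sample rate 2 kHz.

**Sightings.** Daily gathering events are nested and mutually exclusive:
a population masses together, else a bond group gathers, else a core
group stays cohesive, else individuals are solitary; conditional
probabilities are chosen so the marginal probability that a pair shares
a party equals exactly the configured tier rate (p_within_core ≥
p_cross_core_within_bond ≥ p_cross_bond; defaults 0.9 / 0.3 / 0.02).
Equal configured rates therefore give equal expected association indices
— the property the tier-inference null tests rely on. Individuals are
then detected independently (p_detect = 0.95), so 120 default survey
days keep everyone above the 20-sighting inclusion threshold.

**Relatedness.** Each dyad is decoupled from group structure with
probability `rel_decouple_frac` (default 0.5, emulating social units
that absorbed unrelated individuals); coupled within-core dyads centre
on 0.25, everything else on 0.0, s.d. 0.08, clipped to [−0.2, 0.6].

**What the generator does not emulate.** No vocal-tract acoustics
(formants, amplitude modulation, nonlinear phenomena), no recording-chain
differences beyond gain (which the features are invariant to by
construction), no demographic turnover, and sighting parties are
independent across days. Passing tests therefore show that the
*analysis machinery* behaves correctly under the planted statistical
structure — not that real rumbles carry signatures of any given size.

All randomness flows from one root seed through named substreams
(truth, group-offsets, calls, sightings, relatedness), so stages can be
regenerated independently and identical seeds give byte-identical
output.

## Acoustic features

STFT: 800-sample symmetric Hann window, 90% overlap, no padding (frame
count = floor((N − win)/hop) + 1), at the 2 kHz working rate. The
symmetric window makes time-reversal map exactly onto frame reversal
when the frames tile the signal, which the feature symmetry tests
exploit.

Mel scale: HTK convention, mel = 2595·log10(1 + f/700).

The 94-feature battery is 22 triangular mel bands over 8–500 Hz × four
temporal moments (mean, s.d., skew, excess kurtosis) of per-band energy
= 88, plus call duration, the skew of the call's energy distribution
over time, and the mean and s.d. over frames of the spectral centroid
(mel units) and spectral entropy. Energies are normalized by total call
energy before any statistic, so the vector is exactly invariant to
recording gain. Degenerate-moment convention: skew and excess kurtosis
are 0 whenever the s.d. is 0. An all-zero spectrogram raises a "silent
call" error.

The f1 contour is the ridge in the 14–80 Hz band that maximizes summed
spectral magnitude under a dynamic-programming jump cost (0.05 of the
call's maximum magnitude per frequency bin per frame). A frame is voiced
when the ridge magnitude exceeds 5× the median in-band magnitude of that
frame; calls with no voiced frame raise "untraceable call". The nine
contour statistics are mean, s.d., skew, excess kurtosis, 10th and 90th
percentiles (linear interpolation) of the voiced values, and the value
at the voiced frame nearest 25/50/75% of total call duration. At SNR ≥
10 dB the tracer's median error is within one frequency bin (2.5 Hz).

## Social-tier inference

Simple-ratio association index: x / (x + yA + yB), with x the sighting
rows containing both individuals and yA/yB the rows containing exactly
one; individuals seen fewer than 20 times are dropped before core-level
clustering (and only there). Ward linkage runs on the dissimilarity
1 − index. The cut height is found automatically: the cumulative number
of bifurcations is plotted against merge height, both axes normalized to
[0, 1], and the knot is the point of maximum perpendicular distance from
the chord joining the endpoints (tolerance 1e-9; a curve
indistinguishable from its chord has no knot). Cutting keeps merges at
height ≤ knot (inclusive, tolerance 1e-9), so the merge that forms the
bend is retained — the behaviour the two-block fixture requires. Bond
groups repeat the procedure on the sighting table restricted to
matriarchs, without the 20-sighting filter; each bond group is the union
of its matriarchs' core groups. Degenerate cases (one core group, or no
knot among matriarchs) collapse to a single bond group, by design.

## Classification experiments

Forest: 500 trees, 6 features tried per node, each tree trained on a 60%
subsample drawn *without* replacement, minimum node size 1, no depth
limit. Trees are sklearn `DecisionTreeClassifier`s; prediction is a hard
majority vote with ties broken by class order. Per-level designs:

* **population** — classes re-balanced each iteration by subsampling the
  larger population to the smaller's count; 20% of callers with ≥5 calls
  held out per population (max(1, round(0.2·n)) callers, round half up).
* **bond group** — only bond groups with ≥2 core groups of ≥5 calls; one
  qualifying core group held out per bond group.
* **core group** — only core groups with ≥2 callers of ≥5 calls; 20% of
  eligible callers held out per core group.
* **individual** — only callers with ≥3 calls on ≥2 dates; one
  qualifying date held out per caller, so every test caller also trains
  on other dates.

Each iteration reports accuracy, the majority-classifier baseline
(always guessing the training majority; training ties broken by a seeded
uniform draw) and the one-tailed exact binomial p-value P(X ≥ k) with
the *iteration's own* baseline as the null proportion. The experiment
summary is the median accuracy, median baseline and median p over
iterations, plus the mean ± s.d. test fraction. The full protocol uses
10,000 iterations; the desk-scale profile uses 150, where the medians
are already stable. Because test strata are unbalanced, the baseline is
generally not 1/n_classes and can sit above or below 0.5 in two-class
data.

The population-level logistic regression models population as a function
of the nine contour statistics and caller age (days), with
single-term-deletion likelihood-ratio χ² tests (analysis of deviance);
perfect separation is detected (all fitted probabilities at the labels)
and flagged rather than hidden.

## Proximity similarity and gamma mixed models

Proximity forests reuse the experiment hyperparameters with 8000 trees,
trained on all observations with no balancing or hold-out. The proximity
of calls i and j is the proportion of trees in which they share a
terminal node, each co-occurrence weighted by 1/(training observations
in that leaf); the adjustment is isolated in one function and can be
switched off (unadjusted proportion) by argument. An independent
brute-force tree traversal reproduces the module's output exactly in
tests.

Pair tables contain all unordered call pairs with the same behavioural
context and different callers (calls with uncertain context are dropped
first when the flag is present). Pair class is binary
(same/different population, or same/different group) or three-state
(same core / different cores within a bond / different bonds; reference
level = different bonds). Proximities get a +0.00001 offset so zeros
remain valid gamma responses; |age difference| is z-scored across the
emitted table.

The gamma GLMM has a log link, fixed effects for pair class and scaled
age difference (plus relatedness in the social-vs-genetic models), and a
scalar random intercept per caller dyad. Estimation is maximum
likelihood with a Laplace approximation: the per-dyad posterior mode is
found by a damped scalar Newton iteration vectorised across dyads (the
joint density is concave in the intercept, so this converges globally),
and L-BFGS-B optimises (β, log shape, log σ_u) with gradient tolerance
1e-6. Standard errors come from the observed information (numerical
Hessian of the Laplace log-likelihood); χ² tests from single-term
deletion. Pairwise contrasts among the three pair classes are reported
on the link scale with a Tukey-style family adjustment: each |z| is
referred to the maximum-absolute-component distribution of a trivariate
normal with the contrasts' estimated correlation (the contrast set is
rank-2, so eigenvalues are clipped before the quadrature). Collinearity
between group co-membership and relatedness is reported as a diagnostic
(their correlation and the design condition number).

Validation: with negligible dyad variance the fixed effects agree with a
statsmodels gamma GLM (whose β̂ does not depend on the shape parameter,
making it an exact oracle); at 4000 pairs / 200 dyads the planted
pair-class effect 0.4 and σ_u 0.5 are recovered with nominal CI
coverage; null effects are detected at ~5% as they should be.

## Problem sizes

Desk-scale defaults (CLI and acceptance script): 2 populations × 12
callers, 3 bond groups × 2 core groups per population, 8 calls/caller,
150 experiment iterations, 8000-tree proximity forests. Power and
recovery simulations use the sizes stated in their tests (e.g. 20
callers/population × 10 calls for the planted-offset power check; 200
dyads × 20 pairs for GLMM recovery). These sizes were chosen so each
check is decisively powered while remaining comfortable on a single CPU.

## Known limitations

* The 94-feature inventory is this package's documented default; it
  follows the stated design intent (energy distribution over time and
  frequency on the mel scale) rather than any specific published
  supplementary list, and is configurable.
* The knot finder automates what is elsewhere done by visual inspection;
  on curves with several comparable bends it returns the largest one and
  raises on exactly-linear curves. Tie handling among equal-height
  merges follows scipy's linkage ordering.
* The GLMM supports exactly one scalar random intercept — all this
  analysis needs — and is not a general mixed-model engine.
* Bond-group recovery depends on matriarch-level association built from
  far fewer rows than the core level; with weak bond cohesion it can
  merge or split a bond (mean adjusted Rand ≥ 0.9 rather than exactly 1
  in the recovery tests).
* Forest vote ties are broken by class order, and per-tree subsampling
  is without replacement; both choices are documented rather than
  tunable per experiment.
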