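# Methods

This note documents the models and procedures implemented in `imprintlab`,
the choices made where the design was genuinely open, and what the
synthetic-data tests do and do not establish about real data.

## The stimulus continuum and the choice rule

Stimuli form an ordered one-dimensional colour series (eight colours from
red to yellow, or from blue to green). Only the order and the symmetry of
distances are assumed; the perceptual spacing between neighbours is
unknown, so the axis is normalized to [0, 1] with equal spacing by default
and positions are user-settable when a discriminability scaling is
available. Display RGB values and approximate wavelengths are carried as
metadata only and never enter computation.

All models share one decision rule: an animal divides its approach between
two stimuli in proportion to the value it assigns to each,
`choice(i, j) = pref_i / (pref_i + pref_j)`. Using the same rule in the
biased and unbiased models isolates their disagreement to the preference
structure.

## Unbiased (universal-law) null model

If generalization depends only on perceptual distance, similarity decays
as `exp(−d/λ)` (exponential, the default) or `exp(−d²/2τ²)` (Gaussian).
The familiar stimulus is given value 1 and a comparison at distance `d`
value `similarity(d)`; the ratio rule then yields a raw familiar
preference `1/(1+similarity(d))`. Because the kernel scale is not
identified by the qualitative claims the null model supports, the raw
curve is affinely rescaled about the 50% chance anchor so its maximum
equals the strongest observed preference. The resulting prediction is
always 50% at zero distance, monotone non-decreasing in distance, and
identical for stimuli equidistant on either side of the familiar one —
the three properties the data are tested against. Only a 1-D grid-search
helper is provided for the scale; the null is a qualitative foil, not a
fitted model.

## Preference-update model of imprinting

A chick hatches with an initial preference curve over the continuum (its
predisposition) and imprinting updates it multiplicatively. With the
imprinted stimulus presented at every step,

    pref_i,t+1 = pref_i,t · (1 + α · w_i),   w_i = exp(−(x_i − x_imp)²/2σ²),

followed by renormalization of the curve to its maximum. Defaults are
α = 0.01, σ = 0.2 on the normalized axis, 400 steps, with read-out steps
t = 100 (standing for the short, 1-day exposure) and t = 300 (the long,
5-day exposure); these read-out equivalences are taken as fixed defaults,
not derived. The update-weight peak is fixed at 1 — any other height is
absorbed into α. Normalization to the maximum (rather than the sum) is
implemented as specified; preference ratios are invariant either way, and
the closed form

    pref_i,T / pref_j,T = (pref_i,0/pref_j,0) · ((1+αw_i)/(1+αw_j))^T

serves as an independent oracle in the tests (agreement to 1e−9 at
T = 400).

Initial curves come from predisposition double-choice tests: the ratio
rule inverts exactly (`pref_a/pref_b = c/(1−c)` for a mean choice `c`),
ratios are propagated through the measured-pair graph from an anchor fixed
at 1, and unmeasured stimuli are filled by piecewise-linear interpolation
of preference against position (constant beyond the ends) — the simplest
order-preserving fill through the measured anchors. Choices of exactly 0
or 1 are rejected (the ratio is undefined), as are pair graphs not
connected to the anchor.

Model predictions for a generalization test are the ratio choices of the
imprinted stimulus against each test stimulus, rescaled affinely about the
50% anchor so the largest deviation from chance maps to the maximum
observed preference; deviations below 50% (novelty preference) keep their
sign. The rescaling anchor (rehearsal vs. test maximum) is the caller's
choice of `max_observed`. Fit quality is the ordinary coefficient of
determination `R² = 1 − SS_res/SS_tot`, and `fit_readout` grid-searches
the read-out step, breaking ties toward the smallest step.

## Bayesian observer

The observer scores a colour by `P(target|colour)` from `P(colour|target)`,
`P(colour|not_target)` and a constant prior `P(target)` (default 0.5,
user-supplied). Likelihoods come from colour frequency tables built over a
binning of colour loci. The default binning is deliberately coarse —
dominant cone class, with an achromatic category when the largest relative
catch is below 0.35 (equal stimulation is 0.25) — because colour
prevalence in natural-spectra libraries is summarized categorically; a
cubic-cell grid binning over tetrahedral coordinates is available when a
finer partition is wanted. No claim is made about the exact frequencies of
any particular published database; the package ships only synthetic
libraries with known composition.

## Avian colorimetry

Quantum catches are trapezoidal integrals of reflectance × sensitivity ×
illuminant over 300–700 nm on a 1-nm grid (grid refinement changes smooth
integrands by <1e−6 relative); the illuminant defaults to 1 at every
wavelength. Catches are normalized to relative {vs s m l} values and
projected into the tetrahedral colour space by

    x = ((1 − 2s − m − u)/2)·√(3/2),  y = (−1 + 3m + u)/(2√2),  z = u − 1/4,

with u ≡ vs. Pure-cone stimulation lands on a vertex at distance 0.75 from
the origin (all vertices mutually equidistant); achromatic stimulation
lands at the origin. The receptor sensitivities shipped by
`synthetic_uvs_receptors` are synthetic stand-ins — smooth Gaussians
peaking near 370/445/508/565 nm — for exercising the machinery; analyses
of real spectra must supply measured sensitivity functions.

## Behavioural pipeline

Frames with tracking likelihood ≥ 0.9 (inclusive) are retained; dwell time
per retained frame is one frame interval, inferred per trial from the raw
timestamps so dropped frames do not stretch the dwell of survivors (no
gap interpolation). Zones are the areas within 20 cm of each monitor along
the 90-cm axis, boundary points inclusive to the monitor zone, the rest
center. The preference index is `100·t_fam/(t_fam+t_unf)`; a trial with no
choice-zone time is excluded (NaN). Rehearsal trials (familiar stimulus
alone) pass through the same formula against the blank-monitor zone.

Curves aggregate per-chick indices (mean, SEM = sd/√n), are tested against
chance with two-sided one-sample t-tests under Bonferroni–Holm correction
(α = 0.05), and summarized by the best of constant/linear/quadratic
least-squares fits against position, compared by AICc (AIC and adjusted R²
available). Exact fits are floored at a common tiny residual so ties
resolve toward the simpler polynomial.

## Synthetic data generator

Schedules reproduce the study designs exactly: imprinting days of
8 sessions × 10 trials (10 min stimulus + 2 min blank; one day short, five
long); test days of 8 sessions × (2 rehearsal + 8 test) trials with every
test stimulus exactly once per session in seeded order; predisposition
tests of 6 × 20-min double-choice trials (120 min of stimulus time), sides
counterbalanced 3/3 by alternation.

Behaviour is generated from a ground-truth preference curve through the
ratio choice rule. The familiar-side share of stimulus-zone time is
Beta-distributed with mean equal to the true choice probability and
concentration 10 by default — chosen once to give between-trial scatter
comparable to the published curves' standard errors — so the expected
preference index equals 100 × the choice probability; `concentration=inf`
gives the deterministic limit. A fixed fraction of trial time (default
0.10, as chicks spend over 90% of their time in the choice zones) is
assigned to the center zone, and rehearsal/imprinting trials use a
familiar-vs-blank choice probability of 0.72 (observed baselines sit at
68–73%). Frames realize zone times as reflected Gaussian random walks
inside each zone at 10 fps (an arbitrary webcam-scale default), with zone
frame counts equal to the rounded zone times so recovered dwell matches to
within one frame interval, and 2% of frames receive sub-threshold tracking
likelihood to exercise the filter.

Spectra libraries are smooth nonnegative curves on 300–700 nm: a seeded
fraction are long-wavelength reflectors (sigmoidal rise near 600 nm, the
shape characteristic of phaeomelanin), the rest carry one Gaussian bump
centred in 330–520 nm over a low broadband baseline. Under the synthetic
receptor set the red spectra classify as l-dominant and the rest do not,
so the seeded red fraction is recovered by the colorimetry chain.

What the generator does *not* emulate: circadian structure and sleep,
chick growth and motor development, occlusion or identity-switch tracking
failures, session-order effects, monitor-dependent colour shifts, and
sex differences. Passing the recovery tests therefore shows the pipeline
and models are self-consistent and correctly implemented at realistic
noise levels — not that the behavioural conclusions generalize to any
particular real dataset.

## Problem sizes and numerical choices

Default simulations are small enough to run in seconds: cohorts of 48
chicks (the study-scale per-experiment n), 400-step deterministic
dynamics, 10⁵-frame pipeline consistency checks, and spectra libraries of
a few hundred samples. Parameter-recovery checks at these sizes recover
pairwise choice probabilities within ±0.03 and the generalization read-out
step within ±20 of 300 (the read-out is weakly identified — the predicted
curve changes slowly near t = 300 — so observation noise beyond ~0.5
preference points widens recovery considerably; cohort-level SEMs are
well below that). Floating-point ties in the update dynamics are avoided
by renormalizing through division by the row maximum, which cancels
exactly in the ratio oracle up to accumulated rounding ≈1e−13.

## Known limitations

* The perceptual axis is ordinal; no receptor-noise (JND) scaling is
  provided, so kernel scales and σ are in normalized-axis units, not
  discriminability units.
* The Bayes module ships no measured target or environment tables; real
  conclusions require real spectra libraries and measured receptor
  sensitivities.
* The unbiased model's kernel scale is not identified by the qualitative
  properties it is used for; `fit_kernel_scale` is a convenience, not an
  inference procedure.
* Mixed-model ANOVA, Greenhouse–Geisser correction and independent-sample
  comparisons are deliberately out of scope; standard statistics packages
  handle them.
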