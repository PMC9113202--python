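# Methods

## Sequence encoding and the analysis window

A trial is scored as an ordered list of classified signal components over
the fixed alphabet `{rev, idle, leg_tap}`, each with onset and offset in
seconds.  Analyses use the **first 5 minutes of courtship**: the window is
anchored at the onset of the first signal component (not at trial start),
and an event is retained iff its onset lies in the half-open interval
`[t0, t0 + 300 s)`; offsets may overhang.  Anchoring at courtship start was
chosen because latency to the first component varies widely between males
(tens of seconds), and the quantity of interest is the display itself.
Ties in event order are broken deterministically by (onset, offset, label).
Leg-tap is a sequence symbol in its own right, mutually exclusive with idle
at the sequence level even though taps are produced coincident with idle
vibrations; the coincidence enters through the counting rules below, not
through composite symbols.

## Complexity metrics

**LZ76.**  The exhaustive-history parse of Lempel & Ziv (1976): scanning
left to right, the current word is extended while it can be reproduced by
copying from the prior text (a copy may start anywhere before the word and
run into it, but may not use the word's final character); each failure
closes a phrase, and the trailing word counts as one phrase.  The raw
count `c(n)` is normalized by the asymptotic incompressibility bound as
`c(n)·log_k(n)/n` with `k = 3`, so an incompressible sequence tends to 1
and a perfectly repetitive one to 0.  The normalization is a configurable
extension point behind `lz_normalized`.  The implementation scans with
C-level substring search; the test suite checks it against an independent
literal `O(n³)` parser on hundreds of random sequences.

**Shannon entropy.**  Plug-in entropy of the empirical component
proportions, with `0·log 0 ≡ 0`.  Base 2 (bits) by default; the base is a
config option since reported complexity values in this literature are
often unit-free.

**Markov entropy rate.**  Transition counts over adjacent pairs give a
row-stochastic matrix `p_ij` (rows with no observations contribute
nothing); the rate is `−Σ_i w_i Σ_j p_ij log₂ p_ij` with `w_i` the
empirical source frequencies (frequency of symbol *i* among the first
n − 1 positions).  Empirical weights are the default because they are
robust for short sequences with nearly absorbing rows; the stationary
distribution of the estimated chain is available as an alternative
weighting and agrees with the empirical choice on long stationary inputs.
Both entropies use plain plug-in estimators; their small-sample negative
bias (order `(cells − 1)/2n`) is documented rather than corrected, and it
matters when comparing halves of short sequences (see *Limitations*).

## Courtship rates and the half split

Courtship duration is the span from the first retained event's onset to
the last retained event's offset — a property of the display, not the
fixed 300 s window, so early-ending courtships are not diluted.  The
multi-modal rate divides the total component count by this duration with
each leg-tap counted twice (once as a vibratory, once as a visual
component, reflecting its mechanical coincidence with an idle); a
single-count rule is available by config.  The visual-only rate counts
events whose label is in the visual set, `{leg_tap}` by default with
`{idle, leg_tap}` selectable.

The plasticity analysis splits a display at the temporal midpoint
`t0 + span/2`; onsets strictly before the midpoint form the first half, an
onset exactly at the midpoint goes to the second.  A count-based split
(middle of the symbol sequence) is available by config.  Trials with fewer
than four windowed events, or an empty half, are excluded with a logged
reason.

## Inference

Each complexity metric enters its own single-predictor binary logistic
regression on the copulation outcome, fitted by IRLS (statsmodels
GLM/binomial) to gradient tolerance 1e-8.  The reported test is the Wald
χ² `(β̂₁/SE)²` with df = 1 — the test a single-predictor analysis of
deviance produces — with the likelihood-ratio statistic against the
intercept-only model emitted alongside for transparency.  With ~44 trials
and ~9 events, quasi-separation is plausible for a strong predictor;
`|β̂₁|·sd(x) > 15` (log-odds per predictor SD) triggers a warning and a
profile-likelihood CI, never a silent diverging Wald statistic.  A
constant predictor yields a flagged zero-information result.  Group
descriptives use Welch's unequal-variance t with Welch–Satterthwaite df
(scipy), oriented non-copulated minus copulated; half-wise comparisons use
a two-sided paired Wilcoxon signed-rank by default (paired t selectable),
with p = 1 when all differences vanish.  No multiple-testing correction is
applied across the five per-metric models, mirroring standard per-metric
reporting; tests are two-sided throughout.

## Synthetic displays and studies

The generator encodes the species' stereotyped grammar directly:
geometric rev-run lengths (support ≥ 1), bouts of exactly 1 or 2 non-rev
symbols (sizes {1: 0.7, 2: 0.3}), each bout symbol a leg-tap with
probability 0.3 else an idle, and **never** more than two consecutive
non-rev symbols — the field observation that longer bouts are very rare is
implemented as a hard constraint.  Geometric runs are the simplest
memoryless choice consistent with "many revs" and first-order analysis.
Defaults: mean rev run 15 (rev proportion ≈ 0.92, entropies in the
0.1–0.7 bit range typical of scored displays), 96 components per display
(per-trial lognormal, σ = 0.533, so counts spread roughly 40–250),
exponential event durations (means: rev 1.0 s, idle/leg-tap 1.5 s) and
gaps (mean 0.8 s), latency to first component exponential with mean 80 s.

A study draws per-male grammars (log-normal heterogeneity, σ = 0.6 on the
log mean run length), body masses (male 0.040 ± 0.008 g, female
0.052 ± 0.010 g, truncated positive), and a copulation outcome from
`logit p = β₀ + β₁·x` where `x` is the named metric (normalized LZ by
default) computed on the windowed events — the fitted model is therefore
correctly specified and the generator doubles as a
parameter-recovery/calibration harness.  `β₀ = −3.05` was set by solving
`E[logit⁻¹(β₀ + 4x)] = 9/44` over simulated trials at the default grammar,
so a default study produces about 9 copulations among 44 males.  Plastic
studies reduce copulating males' log mean run length by `δ` after the
component-count midpoint, bout composition unchanged; `δ ≈ 0.39` produces
a second-half entropy-rate shift of half its within-male SD (≈ 0.13 bits)
and is used in the power studies.

An i.i.d. generator with arbitrary component proportions supports
metric-behaviour studies with all temporal structure removed; it is a
reasoned stand-in for proportion-sweep simulations, and sweeps confirm
that all three metrics fall together as rev dominance grows.

## Problem sizes and numerical choices

Calibration checks run at: CI coverage, 100 replicate studies of 500
trials; null Wald calibration, 2000 studies of 44 trials (rejection rate
must lie in (0.03, 0.07) at α = 0.05, observed ≈ 0.037 — mildly
conservative, as expected for Wald tests at this event count); paired-test
size and power, 1000–1500 replicates at 35 pairs.  These sizes give Monte
Carlo standard errors well below the decision margins.  All generators are
bit-reproducible from (config, seed); analysis outputs embed a config hash
and regenerate byte-identically.

## Limitations

* **What the generator does not emulate.**  Real displays have
  non-exponential component durations, serial correlation in run lengths,
  female-feedback dependence, and acoustic structure within components;
  none are modelled.  Passing calibration tests therefore demonstrates the
  statistical machinery is sound under the assumed grammar, not that the
  grammar captures every property of scored field data.
* **Lockstep co-variation under run-length plasticity.**  Because the
  grammar is so stereotyped, a change in mean rev-run length moves
  component proportions and transition structure almost in lockstep:
  per-male second-half shifts in entropy and entropy rate correlate at
  ≈ 0.97, and at ~96 components per display the plug-in entropy-rate
  estimator's extra small-sample bias in the more complex half slightly
  exceeds its asymptotic advantage.  Dissociating proportion-based from
  transition-based complexity (entropy unchanged, entropy rate up) would
  require a plasticity mechanism that reorders components while holding
  proportions fixed — e.g. redistributing a fixed bout budget — which the
  current grammar config does not expose.
* Logistic Wald tests at n ≈ 44 with ~9 events are slightly conservative;
  the likelihood-ratio statistic is emitted alongside for users who prefer
  it.
* The exact normalization used for published complexity values varies
  between studies; `lz_normalized` documents its formula and keeps the
  normalization swappable so reproductions against a specific deposit can
  substitute the matching definition.
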