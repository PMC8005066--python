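# Methods

This note documents the models implemented in `armuse`, the parameters
that matter, what the synthetic-data generator does and does not emulate,
and the numerical and design decisions taken where the measurement
protocol leaves room.

## Accelerometry chain

**Filter.** Each axis is band-pass filtered at 0.25–2.5 Hz with a
4th-order Butterworth applied forward–backward (`scipy.signal.filtfilt`),
giving zero phase and a passband gain of ~0.999 at 1 Hz (squared
single-pass magnitude). The filter order and phase behaviour are
implementation choices — the protocol fixes only the pass band; zero
phase matters because epochs are aligned to a shared clock across wrists.
A constant (gravity) input maps to numerically zero; a 5 Hz tone is
attenuated by ~97%.

**Counts.** The manufacturer's count conversion is proprietary, so the
package uses an open, documented surrogate: per axis and 2-s epoch of
`n = 60` samples,

```
count = floor( Σ |a_i| / (n · 0.01664 g) )
```

i.e. the rectified mean acceleration in units of the published
0.01664 g-per-count calibration, floored to an integer (with a 1e-9
guard so an exactly calibrated mean lands on the integer). The surrogate
is monotone in amplitude, zero for zero signal, and yields 1 count for a
sustained rectified mean of exactly one calibration step. It is *not* a
bit-for-bit reproduction of the commercial algorithm and is not meant to
be; all downstream thresholds are interpreted in units of this surrogate.

**Classification.** The per-epoch resultant `√(x²+y²+z²)` of the three
axis counts is compared with a movement threshold of 2 counts,
*inclusive* (≥ 2 is movement), on the resultant only — no per-axis
thresholds. Exactly one moving wrist ⇒ unimanual (right = paretic side in
this cohort); both ⇒ bimanual; neither ⇒ no movement.

**Non-wear.** A maximal run of consecutive epochs with resultant < 2
lasting ≥ 3 h is non-wear, detected per wrist; analysis epochs require
both wrists worn. Off-wrist periods shorter than 3 h are
indistinguishable from genuine stillness under this rule and remain
"worn" — a known limitation of the rule itself, inherited deliberately.
Because a still epoch adjacent to a true off-wrist block extends the
sub-threshold run, the boundary of a detected non-wear interval is only
identifiable up to the nearest movement epoch on each side.

**Metrics and days.** TimeR/TimeL/TimeB are 2 s × the number of epochs in
each class; they satisfy `TimeR + TimeL + TimeB + no-movement time =
wearing time` identically. Days are local-calendar midnight-to-midnight;
day 1 is the day of the first valid epoch. Daily percentages divide by
that day's wearing time and are *missing* (never 0/0) on zero-wear days;
adherence divides wearing hours by a configurable waking-day length
(default 17 h, i.e. roughly 7 h of sleep). Trailing partial epochs are
dropped so counts stay integer-per-epoch. When the two wrists' start
times differ, both streams are trimmed to the later start rounded up to a
whole second; sub-sample residual offsets are tolerated.

## EMA processing

Scheduled prompts that the phone never delivered do not appear in the log
and are therefore excluded from the response-rate denominator
("provided" = logged scheduled prompts). "Answered" requires both a start
and a completion time; a started-but-abandoned prompt is malformed input
and lands in the rejects report. Duplicates are adjacent same-participant
records whose **start times** are < 1 min apart with identical close-ended
responses; the **first** record is kept (it is the original submission)
and removal chains through bursts. The close-ended mask defaults to items
1–16 (item 17 is free text) and is configurable, since item types are a
property of the questionnaire, not the pipeline. Self-triggered prompts
carry no notification time and never enter the scheduled denominator.

## Window synchronization

The pre window is the 10 min ending at the last epoch boundary at or
before the anchor — the response start for answered prompts, the
notification for unanswered ones (the bias question concerns behaviour
before the *opportunity* to respond). The post window starts at the first
boundary at or after completion. Windows are exactly 10 min of whole
epochs; a window touching any non-wear epoch, a recording edge, or the
gap between per-day recordings is excluded with a logged reason rather
than pro-rated — pro-rating would change the metric's denominator
silently. Adjacent prompts' windows may overlap; no exclusivity rule is
applied.

## Statistics

* **RM-ANOVA** (via `pingouin.rm_anova`): day (1..5) as the
  within-subject factor, complete cases only, all 10 pairwise day
  contrasts Bonferroni-corrected (the family is the 10 contrasts per
  outcome). No sphericity correction by default; Greenhouse–Geisser is
  available behind a flag. The F statistic is checked in the test suite
  against an independent textbook sums-of-squares decomposition to 1e-10.
* **Random-intercept models** (via `statsmodels.MixedLM`): outcome ~
  contrast indicator + (1 | participant), REML estimation, Wald tests.
  These tolerate unequal numbers of prompts per participant, which is why
  they, and not the ANOVA, are used at prompt level. Fits are sorted
  internally, so results are invariant to input row order. A constant
  outcome short-circuits to a zero effect rather than a degenerate fit.
* **Transform.** Outcomes are log-transformed as `log(x + 1)` when a
  Shapiro–Wilk test on the raw values rejects normality at α = 0.05; the
  offset (1 s or 1 percent point) is needed because window metrics can be
  exactly zero, and the applied transform is recorded in every result.

## Synthetic-data generator

The generator emulates a 30-participant, 5-day protocol: 6 scheduled
prompts per day in a 07:00–24:00 waking day, ≥ 2 h apart (sampled exactly
via the spacing-subtraction transform), two 5-min reminders, ~1%
undelivered prompts, a mean 4-min completion time, occasional duplicate
submissions, and self-triggered prompts driven by a spontaneous rate plus
a compensation mechanism (a missed scheduled prompt spawns a self-trigger
with probability 0.6) — the mechanism participants themselves described.
With the default answer probability (0.85 marginal, logit-normal
between-participant spread whose centre is solved numerically so the
marginal stays at 0.85), a 30-participant study yields a mean response
rate near 85%, ~5 self-triggers per participant, and a strong negative
rank correlation (≈ −0.7 to −0.8) between answered and self-triggered
counts.

**Signal tier.** Movement bouts are sinusoids (0.5–2 Hz, ~0.2 g peak,
random phase) on one axis plus white noise on all axes and 1 g gravity;
an off-wrist device records exactly constant gravity. Bout durations are
whole epochs, so ground-truth epoch labels are exact. Half-cosine 0.5-s
tapers at bout edges keep spectral leakage into neighbouring epochs below
the count deadband, and each day's off-wrist block is bracketed by short
bimanual bouts (sensors are handled when doffed/donned), which also pins
the non-wear run to the scripted block. Under these defaults the pipeline
recovers the scripted daily TimeR/TimeL/TimeB *exactly* for noise-free
signals and still exactly at the default 0.02 g noise, which sits well
below the ~0.05 g deadband of the count threshold. Activity shares
default to ~5.8% unimanual-paretic, 22.5% unimanual-left and 29% bimanual
of worn time, with one ~3.3-h off-wrist block per 17-h day (≈ 13.7 h
wearing, ≈ 80% adherence).

**Summary tier.** For Monte-Carlo studies of the validity statistics,
`simulate_daily_dataset` and `simulate_window_dataset` draw the daily
percentages and 10-min-window metrics directly from the participant-level
lognormal distributions the activity model implies (multiplicative
participant intercepts, day-to-day noise, a per-window latent
recent-movement state that doubles paretic TimeR). Rendering 30 Hz
signals for hundreds of replicates would add nothing to what these tests
measure. Injections: response bias raises the answer probability when the
pre-window movement state is on; immediate reactivity multiplies
post-window TimeR of answered prompts; accumulative reactivity multiplies
daily paretic activity by (1 + δ) per day (δ = 0.08 reproduces the order
of the drift the protocol is designed to detect). With all injections
neutral the generator is an exact null, and the test suite verifies that
all three tests then reject at the nominal 5% level over 500 seeded
replicates, that injected effects are detected in ≥ 80% of replicates on
the injected outcome only, and that 95% CIs cover the injected log-scale
effect at ≈ 95%.

**What the generator does not emulate:** realistic human kinematics
(gait, tremor, movement spectra), circadian structure of arm use,
item-level EMA content (responses are placeholders), and off-wrist
periods shorter than the detectable 3 h. Passing tests therefore
demonstrate the pipeline's arithmetic, rules and statistical calibration
— not classifier validity against real-world movement, which requires
real labelled recordings.

## Problem sizes in the test suite

Unit tests use minutes-long recordings; end-to-end pipeline tests use a
miniature protocol (2 participants, 1–2 days, 5-h waking days) so the
full raw-signal chain runs in seconds; Monte-Carlo checks use 500 (null
calibration) and 200 (effect recovery) summary-tier replicates at the
full 30 × 5 × 6 design; the acceptance script renders two participants at
the full 30 Hz, 17-h-day scale.

## Known limitations

* The count surrogate is calibrated to one published anchor point, not to
  the commercial algorithm's full transfer function; absolute counts are
  not interchangeable with device-branded counts, though the threshold
  semantics are preserved.
* The 3-h non-wear rule cannot see short removals and its boundaries are
  ambiguous next to genuine stillness (see above).
* Mixed-model p-values are asymptotic Wald; with very few participants
  (< ~10) they become unreliable, and the models refuse to fit with
  fewer than 2 participants per contrast level.
* The RM-ANOVA is complete-case; participants missing a day drop out of
  the day-effect analysis entirely (the mixed models are unaffected).
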