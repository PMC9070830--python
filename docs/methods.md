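# Methods

This note documents the models, conventions and numerical choices behind
`taprhythm`, and what the synthetic-data tests do and do not establish.

## Pacing-stimulus generation

A trial is a sequence of `n_tones = 48` tone onsets defined by 47 IOIs; the
first 4 tones are a visually counted ready cue that is never tapped or
scored. Times are real-valued milliseconds from the first ready-cue tone.

**Tempo-change condition.** The variable portion is a sampled triangle wave
between `ioi_min = 400` and `ioi_max = 600` ms around the base IOI of 500 ms,
organised as six tempo changes that alternate direction and both start and
end with a decrease. Because a pure alternation cannot start *and* end
downward, one decreasing change is split into a 500→400 half (placed first)
and a 600→500 half (placed last); between them sit five full ramps
(up/down/up/down/up). Counting the two halves as one change gives six.

- *Ramp discretization*: a ramp of length `k` beats contributes `k` IOIs
  linearly spaced from its start extreme (exclusive) to its end extreme
  (inclusive), so extremes are not duplicated at segment joins and each
  extreme value occurs exactly where a ramp ends.
- *Length assignment*: the six changes draw lengths from {4, 6, 8} beats with
  each allowed length used at least once and the remainder uniform,
  resampled until the lengths sum to the 36-IOI variable budget and the
  split change's length is even (its halves get `L/2` IOIs each). The
  multiset policy is configurable (`ramp_lengths_allowed`,
  `n_tempo_changes`).
- *Jitter budget*: initial isochronous pacing beats `n_i ~ Uniform{4..7}`
  and final beats `8 − n_i` (hence 1–4), so every trial offers the same
  number of tap opportunities.
- *Exact mean conservation*: with equal split halves the sum of the variable
  portion is exactly `500 × 36` (the +100/−100 ramp-sum residuals cancel),
  so the non-ready-cue mean equals the base IOI by construction up to float
  rounding. A micro-adjustment hook (`exact_mean`, on by default) absorbs
  any residual symmetrically into the final isochronous IOIs (≤ 1 ms each);
  with the default geometry it is a no-op at machine precision.

**Random condition.** The ramp-segment IOIs of a paired tempo-change
sequence are uniformly permuted in place; ready-cue and initial/final
isochronous IOIs keep their positions, preserving the IOI multiset and mean.

**Seeding.** All generation uses `numpy.random.default_rng` keyed by explicit
integer seed lists; cohort trials derive per-trial generators from
`(root_seed, participant, condition, repetition)`, so any single trial is
regenerable in isolation.

## Tap-beat alignment and asynchrony

"Score each tap against the closest beat" is ill-posed when taps double up,
so matching is a greedy global assignment: all (tap, beat) pairs with
`|tap − beat| ≤ window_fraction × local IOI` (default one half of the IOI
preceding the beat) are taken in order of increasing distance, ties toward
the earlier beat, each tap and beat consumed at most once. This makes
nearest-beat assignment a partition; leftover taps are recorded as
unmatched. The half-IOI window is a package decision recorded in output
metadata. Shifting taps and beats by a common constant leaves asynchronies
unchanged.

The first `k = 3` *matched* taps are removed from scoring (start-up
transient); applying the rule after matching means an early spurious tap
cannot consume the omission budget. Omitted and ready-cue beats are
"unscored", distinct from "missing" (no matched tap). Trials with fewer
than two scored asynchronies are flagged degenerate and dropped from
summaries with a logged warning. Per-trial summaries use the arithmetic mean
and the sample SD (n−1); per-participant condition summaries average
unweighted over trials, and conditions with no usable trial are reported as
absent, not zero.

## ITI series and the exclusion rule

The prediction/tracking ratio needs equal ITI and IOI counts over the scored
window. Interior runs of ≤ 3 consecutive missing taps are filled by placing
tap onsets at equal spacing between the flanking real taps (linear
interpolation; the filled ITIs sum exactly to the flanking tap-time
difference). Leading/trailing missing runs copy the adjacent matched beat's
asynchrony onto the beat onsets. Any missing run of ≥ 4 taps makes the
interpolation unreliable and excludes the trial, with the reason recorded;
an exhaustive sweep over all miss patterns confirms the rule fires exactly
at run length 4. The interpolation rule sits behind `build_iti_series` so an
alternative can be swapped in.

## Prediction/tracking ratio

`pearson_at_lag(x, y, lag)` correlates `x[n]` with `y[n − lag]` over the
overlap, requiring ≥ 3 pairs and non-constant windows; the lag-1 overlap
drops the unmatched endpoint pair (n−1 pairs from n-length series). The
per-trial result holds `r_lag0`, `r_lag1`, the scored-IOI lag-1
autocorrelation, and `ratio = r_lag0 / r_lag1`. Trials with `r_lag1 ≤ 0`
are marked invalid rather than producing negative or exploding ratios: the
ratio's interpretation presumes a positive tracking correlation. The ratio
is computed only for tempo-change trials — an isochronous IOI series is
constant and a shuffled one has no lag-1 structure to track; with random
ITIs the sign of `r_lag1` is a fair coin, so about half of such trials come
out invalid.

**Windowing of the theoretical limits.** For a zero-noise perfect predictor
(`ITI ≡ IOI`) the identity `ratio = 1 / autocorr₁(IOI)` holds exactly
against the scored-window autocorrelation, because `r_lag1` and the
autocorrelation then use identical pair sets. For a zero-noise pure tracker
the first scored ITI equals the IOI *preceding* the scored window, so
`r_lag0` equals the lag-1 autocorrelation computed with one interval of left
context (one more pair than the within-window value; the two differ by
~0.01 on 40-pair windows). Tests assert the exact identity against the
appropriately windowed value and the qualitative bounds (ratio > 1, < 1)
against either.

**Per-participant aggregation.** The per-trial ratio is a quotient of two
correlations and is heavy-tailed on the right (occasional small
denominators), so the default aggregate is the **median** of valid per-trial
ratios; the mean and the ratio-of-mean-correlations are selectable, and the
mode used is recorded in every output. Participants with no valid trial are
flagged unusable.

## Generative tapper

The simulator is this package's own synthetic stand-in for human
participants; no claim is made that its generative rule describes human
dynamics. Per pacing beat `n`:

```
e[n]  = w·IOI[n] + (1 − w)·IOI[n−1]
t[n]  = t[n−1] + e[n] − α·(asyn[n−1] + nma) + T[n] + M[n] − M[n−1]
```

with `asyn[n] = t[n] − beat[n]`, timekeeper noise `T ~ N(0, σ_tk²)`, motor
noise `M ~ N(0, σ_m²)` entering consecutive intervals with opposite signs
(the classical two-level timing decomposition, giving realistic negative
lag-1 ITI covariance). The prediction weight `w ∈ [0, 1]` interpolates
between a pure tracker (`w = 0`, ITIs echo the previous IOI) and a perfect
predictor (`w = 1`, oracle access to the upcoming IOI as an idealised
internal model) — this is precisely the continuum the ratio is meant to
measure. The phase-correction gain `α ∈ [0, 1]` pulls the next tap toward
an aim point `nma` ms *before* the beat, whose fixed point is asynchrony
`−nma` (anticipation bias; default 80 ms, matching the ~100 ms negative
mean asynchrony typical of non-musician tapping). `α = 0` is allowed —
without it the pure-tracker interval identity `ITI[n] = IOI[n−1]` would be
perturbed by the correction term — and trials start at the fixed point
unless `initial_asynchrony` is set. Each tap is independently deleted with
probability `p_miss` without affecting the internal dynamics; optional
`p_extra` inserts spurious taps to exercise the unmatched-tap path.

Defaults (`w` 0.5, `α` 0.4, `σ_tk` 10 ms, `σ_m` 5 ms, `p_miss` 0.02,
`nma` 80 ms) were chosen once as representative of adult non-musician
tapping at a 500 ms period: phase-correction estimates around 0.2–0.6,
total ITI SD of ~20–25 ms, and a few percent of unregistered presses.

**Cohort coupling.** A cohort draws `w ~ Uniform[w_low, w_high]` (default
[0.1, 0.9]) for 18 participants × 16 trials per condition (the 3 × 4 × 4
study layout). With constant IOIs the update above is `w`-independent, so a
cohort whose only individual difference is `w` would show *no* relation
between prediction tendency and isochronous tapping accuracy or precision.
The generator therefore couples skill to prediction weight:
`nma` and `σ_tk` are scaled by `1 + skill_coupling·(w_mid − w)` (default
coupling 1, preserving cohort means). This encodes, as the synthetic
cohort's defining condition, the empirically observed covariation of
prediction ability with synchronization accuracy/precision — it is what
makes the sign checks on the ratio–asynchrony correlations meaningful, and
it can be switched off (`skill_coupling = 0`).

**What passing tests show.** Recovery of `w` (Spearman ≈ 0.99 at the
default cohort), the correlation directions, and the
isochronous < tempo-change < random variability ordering demonstrate that
the *pipeline* measures what the generative model puts in, at realistic
noise levels. They cannot show that human data obey this generative rule;
real tappers exhibit drift, fatigue, tempo-dependent correction gains and
non-Gaussian errors that the simulator deliberately omits.

## Group statistics

One-way repeated-measures ANOVA removes the subject effect
(`SS_total = SS_condition + SS_subject + SS_error`);
`F = MS_condition / MS_error` with `(k−1, (n−1)(k−1))` degrees of freedom.
Greenhouse–Geisser epsilon is computed in trace form from the
double-centered condition covariance, `ε = tr(S_dc)² / ((k−1)·ΣS_dc²)`,
bounded in `(1/(k−1), 1]` and exactly 1 for k = 2. Mauchly's W uses an
orthonormal-contrast transform with the standard two-term chi-square series
approximation for its p-value. Following the conditional procedure, degrees
of freedom are ε-scaled only when Mauchly's test rejects at p < .05
(`always_correct` overrides). Effect size is generalized eta squared with
the observed within + subject variance in the denominator,
`η_G² = SS_cond / (SS_cond + SS_subj + SS_err)` — the variant appropriate
for a one-way fully-within design; the variant is fixed and labelled in
outputs. p-values are reported to machine precision. The implementation is
verified against an independent sums-of-squares/eigenvalue brute force
(1e-10) and against pingouin (1e-10).

Pearson tests report `r`, `r²`, `t = r·√((n−2)/(1−r²))`, `df = n − 2` and
the two-sided t-distribution p-value.

## Degenerate inputs and numerical conventions

- Correlations refuse constant windows and < 3 overlapping pairs; the ANOVA
  refuses incomplete matrices (no imputation) and < 3 subjects.
- A residual-free ANOVA (no error variance) reports F = 0 for a null effect
  rather than 0/0.
- Tap logs with non-monotonic times are rejected per trial with a logged
  reason; malformed values fail with the file line number. Every result
  table embeds a hash of the session configuration, and identical config +
  seed reproduce byte-identical tables.
- Exclusion accounting satisfies
  `n_input = n_scored + n_excluded + n_degenerate` in every report.

## Problem sizes

The validation suite uses 200 seeded stimulus generations, 50 zero-noise
trials per ratio limit, 1,000 random inputs per oracle-equivalence check,
an 18 × 48-trial cohort for recovery, an exhaustive 2¹⁰ miss-pattern sweep
for the exclusion rule, and a 12-participant cohort for the variability
ordering; the full suite runs in a few seconds on one CPU.

## Known limitations

- The interpolation rule for missed taps (equal spacing) is one defensible
  choice among several; results near the exclusion boundary depend on it.
- The half-IOI matching window can, under extreme drift (> half a local IOI),
  leave systematic runs of unmatched taps; the simulator's parameter ranges
  keep typical trajectories well inside the window.
- The prediction/tracking ratio is undefined for isochronous and random
  conditions by construction, and its per-trial distribution is heavy-tailed;
  single-trial ratios should not be interpreted in isolation.
- The cohort's skill coupling builds the ratio–asynchrony correlation
  directions into the synthetic data; those checks validate the pipeline's
  ability to detect the effect, not the effect's existence in humans.
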