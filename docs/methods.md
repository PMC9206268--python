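# Methods

## Setting

Quiet-stance posturography compares two views of standing balance recorded
simultaneously: the center of pressure (CoP) from a pressure platform,
which reflects fast ankle-level corrective activity, and the horizontal
displacement of a lumbar-worn tracker (LD), a proxy for center-of-mass /
hip-strategy motion. Each subject stands for 2 minutes per trial at a
100 Hz sampling rate under four conditions of increasing difficulty —
wide stance eyes open (W-EO), wide eyes closed (W-EC), narrow eyes open
(N-EO), narrow eyes closed (N-EC) — with two trials per condition. Subjects
are grouped as younger (< 55 y) or older (≥ 55 y).

## Signal conditioning

Each axis (medial–lateral ML, anterior–posterior AP) is low-pass filtered
with a zero-phase Butterworth filter, 5 Hz cutoff. "Fourth-order
zero-phase" is implemented as one forward and one backward pass of a
2nd-order design — the standard biomechanics reading: the composed filter
has exactly zero phase and a 4th-order magnitude roll-off,
|H(f)|² = 1/(1+(u/u_c)⁴) with bilinear-prewarped frequencies. A
forward–backward 4th-order design (8th-order magnitude) is selectable via
`preprocess.design`. The 5 Hz figure is used directly as the per-pass
design cutoff; no correction is applied for the double pass (the composed
−3 dB point sits slightly below 5 Hz). Edges are handled with reflective
(even) padding of 3× a generous impulse-response extent so start-up
transients cannot contaminate the path-length sums.

After filtering, each trial is referenced to its own mean position
("trial_mean" origin). The two systems' recorded origins are physically
incommensurable (plate frame vs foot-tracker frame), so the per-trial mean
is the only origin that makes the mean-distance measure comparable across
systems; this is also the convention of the standard CoP-measure
literature. Referencing to the recorded origin instead is available
(`preprocess.origin: file_origin`) for co-registered setups.

Trials with missing samples, non-monotone or irregular timestamps, or a
sampling rate off the declared one by more than 1% are rejected outright.
No resampling, interpolation, or artifact rejection is performed.

## The five sway measures

For demeaned series x[n] (ML) and y[n] (AP), n = 0..N−1, Δt = 1/fs,
T = (N−1)/fs:

- **distance-ML, distance-AP** — mean absolute deviation (1/N)Σ|x[n]|
  (mm): effectiveness of control.
- **velocity-ML, velocity-AP** — path length over time Σ|x[n+1]−x[n]|/T
  (mm/s): amount of regulatory activity.
- **AREA-CE** — 95% bivariate confidence-ellipse area
  2π·F(0.05; 2, N−2)·√(s_x²s_y² − s_xy²) (mm²), with unbiased sample
  (co)variances and the exact F quantile rather than the large-N constant
  3.00 (difference < 0.2% at N = 12,000).

T = (N−1)/fs because N points define N−1 path segments; at N = 12,000 the
N/fs alternative changes velocities by < 0.01%, but the choice is fixed for
bit-reproducibility. The two repeats of each condition are averaged
element-wise before any statistics.

All five measures are nonnegative, time-reversal invariant, translation
invariant after demeaning, and scale as c (distance, velocity) or c²
(area) under position scaling — these invariants are property-tested.

## Statistics

**Group comparisons.** Per (system, condition, parameter): Shapiro–Wilk
(Royston approximation, via scipy) on each group at α = 0.05; if either
group is non-normal the groups are compared with the Mann–Whitney U test,
otherwise with the independent t test (Welch by default on raw data;
pooled for summary-statistic inputs, the convention of demographic
tables). Medians and type-7 IQRs are always reported. No multiplicity
correction is applied across the 40 cells; the report records the count.

The Mann–Whitney p is exact — full enumeration of all C(n_a+n_b, n_a)
labelings of the pooled (possibly tied) ranks, two-sided as twice the
smaller tail capped at 1 — whenever the smaller group has ≤ 8
observations, and otherwise a normal approximation with tie correction and
a 0.5 continuity correction. The approximation tracks the exact tail within
0.02 once the smaller group has ≥ 5 observations; below that it is coarse
(worst case ≈ 0.09 at 2 vs 2), which is why the exact path covers that
regime.

**Discrimination.** The ROC treats OLDER as the positive class with the
orientation "higher value ⇒ older" fixed, not auto-flipped: a reversed
marker surfaces as AUC < 0.5 with a warning instead of being silently
rectified. AUC is the tie-aware pair-counting estimate (U-statistic
identity); its p-value against AUC = 0.5 uses the Mann–Whitney normal
approximation. The operating cutpoint maximizes Youden's J over midpoints
between consecutive distinct pooled values (±∞ included) under the rule
"value ≥ c → OLDER"; ties in J are broken toward higher sensitivity, then
the smaller cutpoint. Interpretation bands: [0.5,0.6) fail, [0.6,0.7)
poor, [0.7,0.8) fair, [0.8,0.9) good, [0.9,1.0] excellent.

**Agreement.** Per (age group, condition, parameter), the n×2 table of
(CoP, LD) averaged values is summarized by the single-measure two-way
mixed-effects consistency ICC — ICC(3,1) = (MS_R − MS_E)/(MS_R + MS_E) for
k = 2 — which ignores a fixed additive offset between systems. The 95% CI
uses the McGraw–Wong F-interval on (n−1, n−1) degrees of freedom, which
also yields the p-value for ICC = 0. Bands: < 0.5 poor, [0.5,0.75)
moderate, [0.75,0.9] good, (0.9,1] excellent (0.9 itself is "good").
Incomplete pairs are dropped listwise per cell.

**Power arithmetic.** Pooled Cohen's d = |Δmean|/√((s₁²+s₂²)/2);
`required_n_per_group` inverts the exact noncentral-t power of the equal-n
two-sample t test. At the reference velocity-ML summaries (11.4 ± 4.7 vs
18.0 ± 9.9 mm/s) d rounds to 0.85; the smallest n reaching 90% two-tailed
power at α = 0.05 is 30 with the unrounded d (0.8517) and 31 with d taken
as exactly 0.85 — the computation sits right at the power boundary.
G*Power-style shortcuts that report smaller n (e.g. 26) are not reproduced
by the exact noncentral-t inversion; the function documents rather than
imitates that discrepancy.

## Synthetic cohorts

The study's recordings are not publicly available, so a seeded generator
supplies cohorts with the second-order structure the analysis assumes.
Per subject, axis, condition and repeat:

- a **shared slow component**: Gaussian noise shaped by the same
  zero-phase Butterworth machinery at 0.3 Hz (reusing tested code; only
  second-order structure matters downstream), scaled by a per-axis base
  amplitude (ML 2.5 mm, AP 3.5 mm), a condition multiplier, an older-group
  amplitude multiplier (1.35), and a per-subject lognormal frailty
  (σ = 0.35) shared by both systems;
- **LD** = √0.9 × that latent + √0.1 × independent slow noise, plus a small
  band-limited (0.5–5 Hz) regulatory component (0.12 mm);
- **CoP** = the latent plus a 3× larger regulatory component — fast
  ankle-level corrections register at the plate, not the lumbar level.

Regulatory amplitude carries an older-group activity multiplier that is
larger in ML (2.2) than AP (1.5) and a per-subject, per-system lognormal
activity factor (σ = 0.30). Condition multipliers rise along the
difficulty ladder and rise faster in ML than AP
(ML 1.0/1.25/1.9/2.5, AP 1.0/1.3/1.45/1.8).

These defaults were set from the structure of the analysis, not fitted to
data: because AUC is invariant to any common monotone rescaling, only
group×feature interactions can shape the discrimination profile, so the
older-group effect on regulatory (velocity-dominating) content must exceed
the amplitude effect and be ML-dominant for velocity-ML to lead; and
because the slow frailty is shared across systems while the activity
factors are not, distance/area agree across systems (ICC ≈ 0.95+) while
velocities do not, most weakly in the older group where the
system-specific component is largest. The upper edge of the regulatory
band coincides with the 5 Hz analysis cutoff so the component survives
preprocessing. The resulting magnitudes (CoP velocities ~7–18 mm/s, LD
velocities ~3–8 mm/s, areas in the hundreds of mm²) sit in the range
conventional for quiet stance.

Reproducibility: every (subject, condition, repeat) cell draws from its own
counter-derived substream of the master seed, so cohorts regenerate
bit-for-bit, in whole or cell-by-cell; the batched cohort path (one filter
call per band across a subject's trials) is numerically identical to the
per-trial path and is tested as such. Demographics are drawn to the study's
ranges (ages 22–53 / 55–82, ~37% male, heights ~164 ± 7 cm).

**What the generator does not emulate:** real sway is non-Gaussian and
nonstationary, has 1/f-like low-frequency structure, intermittent
ballistic corrections, and fatigue/learning drift across trials; the
generator is a stationary Gaussian second-order emulation. Passing
end-to-end tests therefore demonstrates that the pipeline recovers
engineered group differences, discrimination rankings and agreement
dissociation of realistic magnitude — not that the published effect sizes
would be recovered from real recordings. Its agreement structure is also
cleaner than real data (distance ICCs near 1 rather than ~0.9).

## Problem sizes and numerical choices

- Default simulated study: 27/group, 2-minute trials at 100 Hz (12,000
  samples), as in the protocol; one full study runs in ~15 s.
- Null calibration: 1000 replicates at reduced size — 14 subjects/group,
  15-s trials at 50 Hz — chosen so the empirical type-I error of the full
  routed pipeline is measurable with SE ≈ 0.007 per cell in a few minutes.
  At this group size the comparison layer is near-nominal (overall
  rejection ≈ 0.049); much smaller groups push the Mann–Whitney
  approximation into its conservative regime.
- Degenerate inputs: constant parameter columns flag `degenerate` (p = 1)
  rather than erroring; covariance determinants that round negative clamp
  the ellipse area to 0; zero between-subject variance makes the ICC
  undefined (raised, not guessed).
- Tie-breaks are deterministic everywhere (Youden: J, then sensitivity,
  then smaller cutpoint) so reports are byte-reproducible.

## Known limitations

- Only the five time-domain measures are implemented; frequency-domain,
  hybrid and nonlinear stabilogram measures are out of scope.
- No covariate adjustment (height/weight) and no multiplicity correction,
  by design of the emulated analysis.
- The ROC cutpoints are in-sample Youden optima, not cross-validated, and
  the AUC p-value uses the U-statistic normal approximation rather than a
  DeLong variance.
- ICC is the consistency form; absolute-agreement ICC(2,1) and
  Bland–Altman limits are deliberate non-goals.
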