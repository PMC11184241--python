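# Methods

This note documents the models, conventions and defaults behind
`cyberface`: what each stage computes, the choices made where the design
was genuinely open, what the synthetic cohorts do and do not emulate, and
the package's known limitations.

## Timeline and units

All analysis happens on a 1-based clock of *analysis seconds* that starts
after a discarded lead-in (default 14 s — the time the experimenter spends
typing the participant's name and picking the condition). Segments are
1–59, 60–105 and 106–145 s; the ten aggregation intervals are 1–15, 16–30,
31–44, 45–59, 60–75, 76–90, 91–105, 106–120, 121–135 and 136–145 s. The
third interval deliberately spans 14 s and the last one 10 s; the grid
totals 145 s. Recordings vary in length (ball-toss timing is partly under
the participant's control), so a subject contributes to a second's
denominator only while on-record; intervals average over their observed
seconds.

Intensities are unitless scores in [0, 1]. AUCs are reported on a
standardized *frame* axis: the trapezium integral of the per-second series
(dx = 1 s) multiplied by a reference 30 frames/s, which makes subjects
recorded at 30 and 60 fps directly comparable and puts group means in the
tens-to-hundreds range. Segment AUCs integrate each segment's seconds
separately, so `total ≈ segment1 + segment2 + segment3` up to the two
bridging trapezoids (relative error well under 1% on smooth series). No
duration renormalization is applied: conditions did not differ in length
in the target design, and raw AUCs are the comparison unit.

## Per-second patterns

Second `s` averages the frames with `time ∈ [s−1, s)`; a trailing partial
second is dropped. The dominant emotion is the argmax over the seven
emotions (neutral never competes); ties — which essentially only occur in
degenerate all-zero seconds — break by the fixed canonical order
happiness, sadness, anger, surprise, fear, disgust, contempt, and both
tie and all-zero counts are reported as diagnostics. Group percentages
are per-second shares of on-record subjects; each fully observed second's
seven shares sum to 100 exactly.

The comparative-error screen for an exclusion-vs-inclusion percentage
difference uses the independent-proportions half-width
`ce = 100·z·sqrt(p1(1−p1)/n1 + p2(1−p2)/n2)` with z = 1.96. At n = 14 per
condition even a 24-point swing fails this bar (ce ≈ 28.5), which is the
sample-size caveat the screen exists to surface.

## Shuffled white-noise control

For every second independently a fresh uniform permutation of the seven
percentage values is drawn (Fisher–Yates via a seeded PCG64 generator).
This conserves each second's multiset — hence the 100-sum — while
destroying which-emotion-when structure; the shuffled pattern is a
white-noise synthetic control. Each emotion's original series is compared
with its shuffled series by Student's pooled-variance two-sample t across
seconds (the default; Welch and paired variants are available). Seconds
are treated as independent observations even though the original series
is autocorrelated — this matches the procedure being emulated and
inflates |t| for strongly structured series; the flat-pattern
false-rejection rate is nevertheless ≈ α because shuffling leaves the
per-second covariance between an emotion's original and shuffled value at
zero under uniform labels. One shuffle realization is the default
(`k = 1`); a multi-realization mode summarizes t over k shuffles for
stability. Comparisons require a gap-free pattern, so the pipeline
restricts to the leading run of seconds where every subject is on-record.

## Continuous calibration

Raw automated-coding streams can be corrected against a person's
idiosyncratic resting face: frame i's intensity becomes
`max(0, (l_a − l_m)/(1 − l_a))` with `l_m` the mean raw intensity over
frames 1..i−1, and the neutral channel becomes
`(N_a + 1 − l_max_m)/2` with `l_max_m` the running maximum of those
per-emotion means. The first frame has no history and uses
`l_m = l_max_m = 0` (raw value passes through). The correction can exceed
1 when a frame spikes far above its history; values are clamped to [0, 1]
with a logged count, and a raw intensity of exactly 1 is nudged to
1 − 1e−9 to avoid the singular denominator. Calibration is **off by
default** throughout the pipeline: vendor exports are already calibrated,
and these operations exist to emulate the documented behaviour of the
software on raw streams.

## Inference layer

* **Paired t** (NTS between conditions): classical, df = n − 1. All-zero
  differences return t = 0, p = 1; constant nonzero differences are a
  degenerate-input error rather than an infinite t.
* **Wilcoxon signed-rank**: zeros dropped, ties mid-ranked with the usual
  variance correction, and a *signed* normal-approximation
  Z = (W⁺ − n(n+1)/4)/σ (positive when the first argument tends to
  exceed the second; swapping arguments negates Z). No continuity
  correction, so printed Z→p pairs like Z = −0.596 → p = 0.551 reproduce
  exactly; agreement with the exact distribution is within ~0.08 in p for
  n in 10–15.
* **Two-way repeated-measures ANOVA** (condition × segment per emotion),
  fitted by pingouin on one value per cell. Per-emotion normalizing
  transforms default to arcsinh for anger, happiness, sadness and
  surprise, rank-based ordered-quantile (`Φ⁻¹((r−0.5)/n)`) for fear, and
  maximum-likelihood Yeo–Johnson for disgust; contempt is untransformed.
  Transforms are fitted on the analyzed vector itself (normalize-then-test
  workflow, no held-out split). Uncorrected p (integer df) is primary;
  the Greenhouse–Geisser p is reported alongside since sphericity is
  never guaranteed. Shapiro–Wilk on the transformed values is reported,
  not enforced. BH adjustment spans the full emotion × effect family
  (21 tests).
* **Extreme outliers**: points outside [Q1 − 3·IQR, Q3 + 3·IQR], with
  type-7 (linear-interpolation) quartiles — the bound depends on this
  convention, so it is fixed and documented. The ANOVA can be run with
  and without flagged subjects; exclusion drops whole subjects, never
  single cells, so the design stays balanced (no imputation).
* **Spearman matrices** between scales and between scales and AUCs, with
  Bonferroni (default) or BH correction; symmetric matrices correct each
  unordered pair once. Constant columns yield flagged NaNs.

## Synthetic cohorts

The generator emulates the *statistical structure* the analysis assumes,
not the raw videos or classifier noise:

* **Emotion streams.** Per emotion, a latent per-second AR(1) process
  `x_t = baseline + subject offset + effect(t) + a_t`, with
  `a_t = φ a_{t−1} + ε_t` (φ = 0.7, stationary SD 0.4), mapped through a
  logistic link; frames within a second add white latent noise
  (SD 0.3) around the second's value, so per-second means are stable and
  the frame rate (30 fps for all but the last two subjects, who record at
  60 fps) does not affect the per-second distribution. The neutral
  channel is 1 − max(emotions), clipped — plausible and excluded from
  analysis anyway. A Dirichlet construction was rejected because coded
  intensities do not sum to one.
* **Baselines** (latent logits, logistic values ~0.02–0.05) were
  calibrated once by Monte-Carlo so that the per-second argmax shares
  reproduce the published early-game inclusion profile: sadness ~30%,
  contempt ~23%, anger ~19%, happiness ~14%, surprise ~10%, fear ~3%,
  disgust ~2%.
* **Condition effects** are latent linear ramps whose magnitudes were
  fitted jointly to the published late-game segment shares: anger
  +0.31 over inclusion segment 3 and −0.31 over exclusion segment 3 (the
  condition × segment interaction: anger rises to ~27% of subjects late
  in inclusion and fades to ~9% late in exclusion), happiness +0.57 and
  surprise +0.31 late in exclusion (the late-exclusion rise). The
  separate `interaction_probe_spec` injects only the anger interaction at
  δ = 1.0 (2.5× the latent noise SD) as a positive control; the
  repeated-measures interaction test detects it in ≥ 90% of replicates.
* **Subject heterogeneity.** A per-subject, per-emotion latent offset
  (SD 0.15) shared across conditions; this value was chosen so the
  cross-condition Spearman correlation of total AUCs lands at ~0.65,
  inside the 0.6–0.7 band the published per-emotion correlations span.
  One consequence worth knowing: with 14 subjects the sadness-on-top
  ranking is reproduced in most but not all replicate cohorts (~80–90%),
  because the published 30%-vs-23% margin is itself not a many-σ
  separation at this sample size.
* **Recording durations** are drawn uniformly from 139–160 s total
  (125–146 s analyzed), so the 145-second grid is mostly covered with an
  honestly thinning tail, matching the reported session lengths.
* **Clinical scores** come from a Gaussian copula: target Spearman
  correlations (SCID-II/BIS-15/BEST/DERS-E/NTS, e.g. ρ(SCID-II, DERS-E)
  = 0.68) are converted to latent Pearson via `2·sin(πρ/6)`; the NTS
  latent splits into per-condition scores correlated 0.6 across
  conditions with means 78.50 (inclusion) and 110.57 (exclusion), SD 29.
  Marginals are truncated normals whose *post-truncation* mean is
  calibrated by a scalar root-solve to the published mean — without this
  the NTS exclusion mean would be biased down ~8 points by the 140
  ceiling. Subscales (BIS-15, BEST) load 0.8 on their parent's latent;
  their values are marginally correct but do not arithmetically sum to
  the parent total. Because every marginal map is strictly monotone, the
  latent Spearman structure is preserved exactly (rank-preserving
  copula); at n = 500 the realized correlations sit within ±0.1 of
  target.
* **Determinism.** Everything derives from one integer seed through
  named `SeedSequence` streams (PCG64), so cohorts are bit-reproducible
  across platforms.

What passing tests on synthetic cohorts do **not** show: robustness to
classifier artifacts (dropped faces, occlusion, lighting), non-Gaussian
subject heterogeneity, duration-condition confounds, or any claim about
real patients beyond the encoded structure.

## Numerical conventions

* Quartiles: type-7; tie-breaks: canonical emotion order; argmax on NaN
  columns yields flagged missing labels.
* Degenerate inputs are flagged, not silently dropped: zero-variance
  t-test series report t = 0, p = 1 with a flag; zero-sum AUC
  compositions yield NaN shares with a flag; an interval with no observed
  seconds is NaN.
* Written tables round at 1e−6; in-memory invariants (rows sum to 100,
  difference columns to 0) hold to machine precision.
* The pipeline fans a master seed out to named child seeds
  (SHA-256 of `"{seed}:{stage}"`, reduced mod 2³¹) so stages can be
  re-run in isolation; output trees are byte-identical across reruns of
  the same configuration.

## Problem sizes used by tests and the acceptance script

Monte-Carlo checks run at: 1,000 replicates for the shuffle-null
false-rejection rate and the shuffle conservation property, 200 for the
repeated-measures type-I rate, 100 for the interaction-detection and NTS
power rates, 50 for effect-direction recovery, n = 500 for copula
calibration, and 20 replicate cohorts for the dominant-ranking stability
rate. These sizes give binomial/standard errors comfortably inside the
asserted bands while keeping a full run in the low minutes on one core.

## Known limitations

* The comparative-error formula and the AUC standardization convention
  are reverse-engineered from printed values (both reproduce them to 2
  decimals); alternative readings of the standardization step differ by a
  constant factor and would not change any test decision, only the units.
* The shuffle-comparison t test inherits the independence-across-seconds
  assumption of the emulated procedure; its p-values for strongly
  autocorrelated series are anticonservative by construction.
* Published masked-AUC *inclusion* group means are internally
  inconsistent with their component means by ~0.23 (a rounding artifact
  in the source table); the package recomputes masked means from
  components and makes no attempt to reconcile that column.
* Subscale scores are marginally calibrated but not additive to their
  parent totals; analyses that need exact additivity should derive
  subscales differently.
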