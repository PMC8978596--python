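# Methods

`evprofiler` implements a desk-scale version of a biomarker-discovery
workflow for physiological resilience: extracellular vesicles (EVs) from
plasma are measured by imaging flow cytometry, each sample's per-event
feature export is reduced to one high-dimensional profile, regression trees
down-select the profile against a continuous resilience score, and the
surviving variables are evaluated with two-group statistics and ROC
diagnostics. This note records the model, the defaults and the design
decisions, in that order.

## Study design being modelled

Two groups of n = 10 subjects are drawn from the tertiles of the
Connor-Davidson Resilience Scale (CD-RISC, 0-100): *high* resilience
(score > 90) and *low* resilience (score <= 79). Each subject is sampled at
baseline (D0) and after 48 h of sleep and caloric restriction (D3, "peak
stress"). The analysis asks which features of the per-sample EV profile —
at baseline, or as D3 − D0 change scores — discriminate the groups.

## Per-sample profile construction

An event table has one row per detected object and one column per image
feature per spectral channel. Reduction proceeds as:

1. **Saturation filter.** Any object with a saturation count >= 1 in any of
   the three fluorescence channels (CD63, VAMP3, THSD1 — markers associated
   with exosomes, microvesicles and apoptotic bodies) is removed as likely
   debris or a fluorochrome aggregate.
2. **Derived feature.** Per channel, `PixelRange = RawMaxPixel − RawMinPixel`
   captures the within-object intensity range.
3. **Size stratification.** Objects are stratified by brightfield area:
   small < 0.031416 µm², medium in [0.031416, 0.785398] µm² (both boundaries
   inclusive), large > 0.785398 µm². The cutoffs are the circular areas of
   200 nm and 1000 nm diameter particles, the conventional diameters
   separating exosomes, microvesicles and apoptotic bodies.
4. **Summarisation.** For every active feature × channel × stratum (plus the
   unstratified *total*), the mean (AVG), median (MED) and sample standard
   deviation (SD, n−1 denominator) are computed. Strata with no events give
   missing AVG/MED; strata with fewer than two events give missing SD.
   Missingness is data, not an error.

Under the default manifest the active features number 8 (size) + 1 (shape)
+ 6 (texture) + 16 (signal strength) = 31, giving 31 × 3 channels × 4
strata = 372 variables per statistic and 1116 per sample, split 96/12/72/192
across the categories per statistic. The vendor's export schema is not
standardised, so the manifest is fully configurable: which features exist,
which are excluded (with a recorded reason, `redundant` or `irrelevant`),
how external headers map to canonical names (alias map), and the stratum
cutoffs. The default exclusion list (3 redundant, 5 irrelevant features) is
this package's reconstruction; only the per-category counts are fixed by
the design.

The antibody dimension is the fluorescence channel of measurement:
channel-specific features use that channel's columns, while brightfield and
side-scatter features are replicated across the antibody dimension. An
optional per-channel positivity gate (`positivity_thresholds`) restricts a
channel's summaries to events above an intensity threshold; the default is
no gate, because no threshold is part of the modelled design.

Change scores are elementwise D3 − D0 differences of two profiles, missing
wherever either input is missing.

## Regression trees (CART with least-squared-deviation splitting)

Trees are grown from scratch (no external tree library): at each node every
variable and every midpoint between consecutive distinct values is scored by
the reduction in within-node sum of squared deviations of the outcome
(CD-RISC score, or its change-score analogue); the best admissible split is
taken greedily. Stopping rules (defaults for the 20-subject design):
minimum 5 observations in a terminal node, minimum 10 before splitting,
maximum depth 3, and a minimum improvement of 1e-4 in normalized-risk units
(the common software default for this tree family). The tree's *risk* is
R = (1/N) Σ_terminal SSE(node); *normalized risk* divides by the population
variance (1/N denominator) of the outcome, so a root-only tree scores
exactly 1. Ties in improvement are broken toward the earlier variable in
manifest order, then the smaller threshold, which makes fitting independent
of row order. No pruning, surrogate splits or cross-validation — only the
three stopping rules plus the improvement floor.

## Two-level selection workflow

Per statistic (AVG, MED, SD): one tree per feature category (size, shape,
texture, signal strength) is fitted on that category's variables; the
splitter variables collected from the four category trees feed a final tree
for the statistic; the final trees' splitters, pooled across the three
statistics, form the candidate set. "Identified at the first level" is read
as *all* splitters of each category tree (config `level1_scope =
all_splitters`); the alternative reading — only each category tree's root
split — is available as `root_only`. Variables missing for any subject are
excluded listwise from an analysis, since the trees have no surrogate
splits.

## Group statistics

Shapiro-Wilk per group (α = 0.05) routes each candidate to a pooled-variance
Student t test (both groups consistent with normality) or to the
Mann-Whitney U test with the **exact** sampling distribution of U, computed
by dynamic programming over all C(n1+n2, n1) labelings (mid-ranks plus
exact permutation enumeration when ties are present and feasible, a
tie-corrected normal approximation otherwise — the method used is always
recorded). Two-sided p = min(1, 2·min(P(U<=u), P(U>=u))). Shapiro-Wilk and
the t tests are delegated to scipy as vetted infrastructure; the exact
distributions and everything downstream of them are authored here.

Significant parametric outcomes get Hedges' g: d = (m1−m2)/s_pooled with the
(n−1)-weighted pooled SD, g = d·J with J = 1 − 3/(4·df − 1), df = n1+n2−2,
and a normal-approximation 95% CI with SE² = (n1+n2)/(n1·n2) + g²/(2(n1+n2)).
On the design's stature summaries (181.13 ± 5.76 vs 174.05 ± 6.67, n = 10
per group) this prints g = 1.09 with CI (0.15, 2.03). Nonparametric
outcomes are summarised as median [IQR] with quartiles at the
weighted-average ((n+1)p) percentile position, the convention of the
statistics package the modelled workflow used. Welch's t is available via
`equal_var=False`; the pooled test is the default because the effect size
uses a pooled SD. No multiple-testing correction is applied by default, to
mirror the modelled workflow; the comparison stage is a plain function, so
a correction can be layered on its outputs.

Paired stress-effect tests (biomarkers, NTA concentration/size) route
Shapiro-Wilk on the differences to a paired t test or the exact Wilcoxon
signed-rank test (DP over the 2^m sign assignments, zeros dropped,
mid-ranks doubled to integers).

## ROC diagnostics

For each significant candidate: thresholds at midpoints between consecutive
distinct scores plus infinite sentinels; the orientation (">" or "<" calls
the positive class) is chosen so AUC >= 0.5 and reported as part of the
decision rule. AUC is the trapezoid integral, identical to the rank
statistic U/(n1·n2); its CI and two-sided p against AUC = 0.5 use the
Hanley-McNeil standard error. The operating point maximizes the Youden
index J = sens + spec − 1 (ties toward higher sensitivity, then the lower
cutoff); sensitivity and specificity get Wilson score CIs; LR+ =
sens/(1−spec), flagged infinite at perfect specificity. Wilson was chosen
because it reproduces the familiar lower bounds at n = 10 (e.g. 49.02% for
8/10, 59.58% for 9/10); graphical packages sometimes print hybrid upper
bounds that no single textbook interval reproduces, so the interval family
is recorded in the output metadata. A single distinct score value is a
degenerate curve: AUC 0.5 with a collapsed CI, flagged.

## Synthetic cohort generator

The generator emulates the *statistical structure* the analysis assumes,
not the instrument:

- **Scores.** CD-RISC draws from truncated normals: high ~ N(94.90, 3.04²)
  on (90, 100], low ~ N(70.00, 5.89²) on [0, 79] — the group summaries of
  the modelled cohort used as generator parameters. (Truncation shifts the
  realised means slightly; tests compare against the analytic truncated
  means.)
- **Events.** Per-sample event counts are Uniform{2000..10000} — unreported
  in the modelled study; chosen as desk-scale yet large enough for stable
  per-stratum SDs. Areas follow a three-component lognormal mixture
  (medians 0.015/0.15/1.5 µm², weights 0.50/0.35/0.15) roughly occupying
  the three strata. Intensities are lognormal (event-level log-SD 0.8) with
  a subject-level random effect (SD 0.4) shared across timepoints and a
  smaller visit effect (SD 0.1) — strictly positive, right-skewed, with
  realistic between-sample heterogeneity and within-subject coupling.
  Raw pixel maxima are built as minimum + positive range, so
  RawMax >= RawMin >= 0 holds by construction; aspect ratios live in (0, 1];
  a fraction p_sat = 0.02 of events gets a positive saturation count in one
  fluorescence channel.
- **Implanted effects (at D3 only — the modelled study found group
  differences in change scores, not at baseline).** Effect A multiplies the
  log-SD of THSD1 bright-detail intensity among large-stratum events
  (default 2.0 in the high group, 1.0 in the low group; the median is
  preserved, so the effect is a pure spread widening on the log scale —
  the lognormal mean rises with the spread, so some signal also reaches the
  AVG statistic, as it would in real intensity data). Effect B adds a shift
  to the minimum side-scatter pixel of medium-stratum events (default −0.4
  high, 0.0 low, clipped at zero). The neutral configuration
  (`EffectSpec.neutral()`) makes D0 and D3 exchangeable.
- **Panels.** Biomarker baselines are lognormals moment-matched to the
  group means/SDs of the modelled cohort (α-Klotho, BDNF, NPY, IGF-I,
  cortisol); peak-stress means scale by per-analyte declines (IGF-I −13.5%,
  α-Klotho −8.9%, NPY −17.2%, BDNF and cortisol flat), with the D3 SD
  scaled by the same factor (no D3 dispersions are reported to match) and
  within-subject correlation 0.8 on the latent log scale. The NTA panel
  (concentration, mean size) is moment-matched at both timepoints with no
  stress shift.

What the generator does **not** emulate: optics, spectral spillover and
compensation, instrument drift, inter-feature correlation structure beyond
the shared intensity scale (texture features are largely independent
draws), batch effects, and any real association between EV biology and
resilience. Passing tests therefore demonstrate that the pipeline recovers
effects of the implanted form at the implanted size under clean
distributional assumptions — not that such effects exist, or would be
recoverable, in real cohorts of this size.

## Calibration and what the test suite shows

- Fitted trees equal an independent naive exhaustive-search oracle in
  structure and risk on 1000 random small instances.
- The exact Mann-Whitney p equals full enumeration for every group split
  with n1+n2 <= 12, and AUC = U/(n1·n2) holds on every tested dataset.
- With identically distributed groups (n = 10+10) the routed comparison
  rejects at 5% within binomial error over 1000 seeds.
- With the default implanted effects, the change-score workflow selects the
  THSD1/large/SD target in >= 80% of 50 cohorts and its AUC median is
  >= 0.75 (in practice both are at or near 1.0 — the default effect is
  strong relative to desk-scale noise).
- **Post-selection inflation.** Comparisons on tree-selected variables are
  conditioned on the outcome, so their p-values reject more often than α
  under the null; this is a property of the select-then-test workflow
  itself. Nominal calibration is asserted for pre-declared variables; the
  null-cohort sweep additionally records candidate-set sizes and the
  (rare) chance selection of the designated target.

## Numerical choices and degenerate inputs

- Split-improvement near-ties use a 1e-9 relative tolerance before the
  deterministic tie-break, so prefix-sum and naive SSE arithmetic agree.
- A constant outcome, or a node no split can improve, terminates growth; a
  constant outcome makes normalized risk undefined (flagged `None`).
- Constant pooled comparison input is degenerate: p = 1, flagged, no test
  statistic.
- Shapiro-Wilk is undefined for n < 3 or constant samples; routing falls
  back to the nonparametric branch.
- Reports are byte-identical for identical inputs, config and seed: JSON is
  written with sorted keys and provenance carries the config digest and
  seed but no wall-clock timestamps.

## Problem sizes used in the shipped checks

The acceptance checks run 50 full cohorts at the default design (20
subjects × 2 timepoints × 2000–10000 events), 1000 null comparisons, 1000
tree-oracle instances and a 200-cohort reduced-size null sweep (5+5
subjects, 150–250 events) — sizes chosen so the whole suite completes in a
few minutes on one core while keeping Monte-Carlo error well inside the
asserted bands.

## Known limitations

- The feature list behind the 96/12/72/192 counts is a reconstruction; real
  exports will need an alias map and possibly a different active list.
- The exact Mann-Whitney path with ties falls back to enumeration only up
  to ~2·10⁵ labelings, then to a tie-corrected normal approximation
  (always flagged).
- Hedges' g CIs use the normal approximation; noncentral-t intervals would
  differ slightly at n = 10+10.
- The ROC stage evaluates one variable at a time; no multivariable
  classifier, cross-validation or paired-curve comparison is provided.
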