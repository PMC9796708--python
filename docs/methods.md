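# Methods

This note documents the models and numerical choices behind the package:
how movement networks are built and analyzed, what the synthetic cohort
generator does and does not emulate, and where the design was genuinely
open.

## From marker trajectories to networks

A trial is a short gait recording (default 120 frames/s) of 21 markers on
bone landmarks. Internally positions are meters, axis columns ordered
(ML, AP, V); readers permute file columns via an explicit `axis_map` and
convert from millimeters when the file declares them. Derivatives are
taken by repeated central first differences, `x'(t) ≈ (x(t+Δ) − x(t−Δ)) /
2Δ` — second-order accurate, exact on quadratics (acceleration) and cubics
(jerk) — losing one frame per end per application, so a 264-frame trial
yields 260 acceleration and 258 jerk frames. An optional zero-phase
low-pass filter (Butterworth order 2 run forward and backward, effective
4th order, default cutoff 10 Hz) can be applied to positions first. It is
recommended for measured optical data — a third derivative at 120 Hz is
noise-dominated without it — and unnecessary for the band-limited
synthetic data, so the pipeline default is off and file-based workflows
should set `filter_cutoff_hz`.

The kinectome of one (quantity, axis) pair is the 21 × 21 matrix of
Pearson correlations between the per-marker derivative series. Correlation
(normalized covariance) rather than raw covariance makes edge weights
bounded and scale-free, which the fingerprinting and degree analyses
presuppose. The 210 upper-triangle edges, in row-major order of the fixed
marker order, feed all downstream analyses.

## Analyses

**Group comparison.** Between-group tests use label-shuffling permutation
tests on the absolute difference of group means, with add-one Monte-Carlo
p-values, p = (#{null ≥ observed} + 1)/(n_perm + 1) (default n_perm =
10 000). Kinectome-level comparisons scalarize per subject as the mean
over the 210 edges; variability comparisons recompute the mean-over-edges
of each group's element-wise SD matrix at every label shuffle. Six
(quantity, axis) tests give a Bonferroni cutoff of 0.05/6 ≈ 0.0083; the 18
fingerprint-score comparisons give 0.05/18 ≈ 0.0028.

**Modularity.** Newman modularity Q is maximized by seeded Louvain runs
(networkx implementation) on non-negative adjacencies; correlations are
mapped through |r| by default (configurable to zeroing negatives), since
coupling strength, not sign, defines coordination here. Consensus
clustering re-runs Louvain (default 100 sub-seeded runs), zeroes
co-assignment entries below the chance level estimated from label-permuted
partitions, and re-clusters until the co-assignment matrix is binary
(error after 50 rounds; in practice 2–3 suffice). Group-level modules come
from consensus clustering of the allegiance matrix, which pools the
per-subject test-session partitions of both quantities per axis.

**Fingerprinting.** The identifiability matrix correlates test edge
vectors (rows) against retest vectors (columns). A subject is identified
when its diagonal entry strictly exceeds every off-diagonal entry of both
its row and its column — the strictest reading; ties count as failures.
I-others per subject averages its row and column off-diagonals so that
per-subject values support permutation comparisons. Scores are plain
correlation units; percentages only appear in reports.

**Edge selection.** Per-edge reliability is the one-way random-effects
ICC with subjects as clusters and the two sessions as observations
(the formula has no session effect, so no two-way model is fitted).
Zero-total-variance edges have undefined ICC, are recorded as missing, and
rank last; ties break stably by edge index. IR curves evaluate the
identification rate on the top-c ICC-ranked edges for c = 3…210; null
bands rebuild each count from uniformly random edge subsets (default 100
curves, mean and 95th/99th percentiles stored). "Edges of interest" are
the first c* edges where IR first exceeds the threshold (default 0.99).
Node occurrence pools the edge sets of the four informative parameters
(ML/AP × acceleration/jerk — the vertical axis is excluded as
uninformative), counts marker endpoints, and flags markers whose count
exceeds the 99th percentile of equally sized random-edge-subset draws.

**Clinical topology.** Weighted degree is the sum of absolute edge
weights per marker (bounded by 20). The prediction model is OLS of the
motor score on the flagged marker's degree plus age, education, and a
binary gender indicator, with variance inflation factors (warning above
10) and shuffled, seeded 5-fold cross-validation; both in-sample R² and
the R² of pooled out-of-fold predictions are reported, since either
convention is found in practice. The headline feature (marker, quantity,
axis) is whatever node-occurrence analysis flags — nothing is hard-coded
to T10.

## Synthetic cohorts

The generator produces the study conditions every test assumes: two ~2.2 s
trials per subject (two 1.1 s gait cycles at 120 frames/s), 21 markers,
and a subject table with group, age, sex, education, and motor score.

It is a harmonic-template model, not a biomechanical simulation. Each
marker's trajectory per axis is a unit-variance mixture
`√(1−s²)·[w_lat·L + w_priv·P]/‖·‖ + s·R` scaled by a plausible amplitude
(1.5–10 cm by segment and axis), plus posture offsets and a 1.2 m/s AP
walking ramp, where:

- `L` is a module-shared latent waveform: three harmonics of the gait
  frequency with per-module weight profiles and phases chosen so that
  within-module correlations are high (latent share 0.8) and cross-module
  correlations small. The planted modules per axis encode gait
  biomechanics: ML splits trunk+upper arms / head+forearms+pelvis /
  legs+feet; AP splits the passenger unit (head, trunk, pelvis) from the
  two antiphase contralateral arm–leg pairs; V splits arms and feet from
  the rest (which oscillates twice per cycle).
- `P` is a marker-private waveform with the same spectrum and fixed
  "anatomical" phases independent of the cohort seed.
- Subject identity enters as seeded phase offsets at module, marker, and
  harmonic level plus mixing-weight jitter, all shared by both trials; a
  relative scale σ maps to σ·π/4 radians of phase SD (default
  signature_scale 0.15 → 0.118 rad). Per-trial variation uses the same
  mapping (trial_noise_scale 0.05 → 0.039 rad) plus a global gait-phase
  shift per trial and additive noise *band-limited to the gait harmonics*:
  marker trajectories are smooth, and broadband white noise at any
  relevant amplitude would dominate the second and third derivatives,
  which no real pipeline (which filters first) would permit. Because both
  subject- and trial-level dispersion use the same mapping, test-retest
  contrast depends only on their ratio.
- `R` is the axial rigidity drive: an h³-weighted waveform whose phases
  are solved, per axis, to be orthogonal to all three module latents. The
  trunk anchor T10 always carries it (share 0.75 of its acceleration
  variance); in parkinsonian mode each distal marker (forearms, legs,
  feet) receives it at strength `γ_m = N(trunk_coupling, coupling_sd) +
  N(0, coupling_marker_sd)` clipped at 0 (defaults 0.3, 0.18, 0.12).
  Shares are specified in acceleration units and converted to position
  scale per receiver so a given coupling means the same for a wrist as for
  a heel despite their different harmonic content. Orthogonality makes
  trunk–limb edges first-order sensitive to the coupling while limb–limb
  edges move only at second order, which is what lets reliability-based
  edge selection recover T10 as the hub of the planted effect.

Parkinsonian mode additionally scales the left side's latent share by
(1 − asymmetry) (amplitude-only asymmetry would be invisible to
correlations), inflates subject-level phase dispersion along AP by
√2 (between_subject_ap_var_inflation 2), raises within-trial variability
by a dysregulation factor 1.5 (PD gait is more variable; this is also why
the diseased group needs more edges to reach the 99% identification
threshold than controls), and sets
`motor_score = 5 + 60·γ_subject + N(0, 3)` clipped at 0, giving scores in
a plausible motor-scale range (healthy ≈ 5, diseased ≈ 23 ± 12).
Demographics are nuisance draws (age 45–80, education 5–20 years, sex
~55/45) independent of the score.

**What passing tests do and do not show.** The generator reproduces the
*correlation structure* the analyses consume — planted communities,
stable subject signatures, a trunk-centred coupling gradient tied to the
score — so green tests demonstrate that the pipeline recovers known
structure of exactly this kind. Real optical data add broadband sensor
noise, soft-tissue artifact, non-stationary cycles, marker dropout, and
non-harmonic transients (heel strikes); none of these are emulated, so
performance figures on synthetic cohorts (e.g. IR = 100%) are upper
bounds, not forecasts for laboratory data.

## Numerical and design choices

- Seeds: every stochastic routine takes an explicit seed; the pipeline
  derives per-stage seeds from the master seed via CRC-hashed
  SeedSequences, so partial re-runs reproduce stage-for-stage.
- Simulated trials span an exact integer number of gait cycles, so
  harmonic cross-terms vanish in correlation sums and the global trial
  phase shift leaves kinectomes invariant, as it should.
- Kinectome symmetry tolerance 1e-9; matrices are symmetrized and clipped
  to [−1, 1] after `corrcoef` to absorb floating-point drift.
- Group analyses use the test session only (the retest is reserved for
  fingerprinting); averaging the two sessions is a config switch away in
  principle but not the default, since reusing the retest would leak the
  fingerprint data into group statistics.
- Degenerate inputs fail loudly: zero-variance series name the marker,
  all-zero adjacencies (m = 0) are rejected, constant inputs to Spearman
  raise, singular designs raise, subjects with ≠ 2 trials are listed.
- The C3D reader/writer covers the Intel floating-point variant with
  point data only (no analog channels), which is sufficient for marker
  exchange; other processor types are rejected with a clear error.
- Problem sizes in the test suite (cohorts of 10–23 subjects, 100-replicate
  parameter-recovery runs, 1000-replicate calibration at 199 permutations)
  were chosen so the full suite documents each property at comfortable
  statistical margins while remaining quick to run locally.

## Known limitations

- Gait events are assumed pre-segmented: trials must already be single
  (or double) gait cycles; no heel-strike detection is provided.
- Louvain + consensus is a local optimizer; Q values are certified against
  exhaustive search only on small graphs (≤ 8 nodes) in the tests.
- The one-way ICC treats sessions as exchangeable; systematic test/retest
  drift (a session effect) would require a two-way model.
- Fingerprint identifiability is evaluated within-group, as the analyses
  define it; cross-group identification is out of scope.
- The synthetic motor score is linear in the planted coupling by
  construction, so the prediction model's form is correct by design there;
  on real data the linearity is an assumption to check.
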