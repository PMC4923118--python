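# Methods

This note documents the models implemented in `salcomp`, the parameters
that matter, and the design choices made where the design was genuinely
open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinate conventions

All spatial quantities are degrees of visual angle; the origin is the
screen centre, x increases rightward. The default screen is 128 × 96 px at
0.1875°/px (24° × 18°), and a vertical band of ±2° around the midline
(`ScreenGeometry.central_exclusion_deg`) is excluded from all hemifield
statistics. Both lateralization indexes are signed **(R − L)/(R + L)** so
that positive values mean a rightward bias. The printed-formula convention
in the literature this design follows is internally inconsistent (the
letter order of the formula vs the stated reading of the sign); we fix the
semantics — positive = rightward — and keep the formula consistent with it,
since every downstream claim depends on the sign's meaning, not on letter
order.

## Saliency model

The saliency bank follows the classic biologically-inspired architecture —
per-channel feature maps, centre-surround contrast at multiple scales, a
max-based normalization that promotes maps with few isolated peaks, and an
unweighted average of the five channel conspicuity maps — with two
implementation choices worth noting:

* **Undecimated scale space.** Rather than a decimated image pyramid,
  centre and surround are Gaussian blurs applied at full analysis
  resolution (centre σ ∈ {0.3°, 0.6°}, surround = 4 × centre). At the
  modest default resolution a deep decimated pyramid degenerates (a
  40 × 30 map after four levels of a 128-px image leaves no room for the
  classic surround scales), and decimation on even grids breaks exact
  mirror equivariance. With symmetric kernels and reflected boundaries the
  whole bank commutes with horizontal flips to ~1e−15, so
  `sal_idx(flip(v)) = −sal_idx(v)` holds to the tested 1e−6.
* **Half-wave rectified on-centre responses**, `max(centre − surround, 0)`.
  This gives every isolated object a *compact* region of strictly positive
  saliency (support radius ≈ 1.8° for the default scales) surrounded by
  exact zeros, which is what makes "clusters = connected patches of
  saliency > 0" a meaningful object count on real-valued output. Values
  below 1e−6 of the global maximum are additionally clamped to zero before
  8-connected labelling.

Channels: intensity; double-opponent colour contrasts |R−G| and
|B−(R+G)/2|; orientation as rectified responses to zero-DC Gabor filters
at 0°/45°/90°/135° (a mirror-symmetric set — required for the flip
property); flicker |I_t − I_{t−1}|; motion as Reichardt-style shifted
correlations in four directions, |I_t · S_d(I_{t−1}) − I_{t−1} · S_d(I_t)|,
which are identically zero for a static scene (a plain shifted difference
is not — it responds to static edges). Flicker and motion are zero on the
first frame. The normalization operator rescales a map to peak 1 and
weights it by (1 − m̄)², m̄ being the mean of its non-global local maxima.

`Sal_idx` averages per-frame hemifield means over frames and is flagged
undefined (NaN) when both hemifields are zero, never silently 0.

## Gaze parsing and quality control

Fixation detection is dispersion-based (I-DT), scanning each maximal run
of valid samples left to right: a window is extended while both per-axis
ranges stay ≤ 1.5°, and emitted when its sampled duration reaches 100 ms.
Durations are counted as n_samples / rate with an *inclusive* threshold —
at 120 Hz, 12 samples qualify, 11 do not. Invalid (blink) samples break
candidates; no interpolation is attempted. Saccades per trial are
fixations − 1, clamped at 0, counting fixations that begin inside the
stimulus window.

Trial QC fails on (a) mean valid pre-stimulus position (200 ms window)
beyond ±2° on either axis, or no valid pre-stimulus sample, and (b)
fixation fraction < 50%, where the denominator counts *all*
stimulus-period samples, valid or not — so data loss counts against the
trial. QC is monotone: invalidating stimulus samples can only lower the
fraction. Subjects need ≥ 6 passing trials in every condition × side cell
(inclusive). `Gaze_idx` uses all valid stimulus-period samples outside the
central band, not only fixation members, and is flagged undefined when no
off-centre time was accumulated.

## Synthetic stimuli

Videos are 1.5 s at 25 fps, with per-video frame counts Bresenham-
alternated between 37 and 38 so that a 140-video set totals exactly 5250
frames. Events are moving Gaussian blobs (σ 0.3–0.6°, amplitude 0.45–0.68,
speed 1.5–3°/s with reflection at the hemifield box); background clutter
is Poisson-many static low-contrast patches (amplitude 0.16, σ 0.4°),
placed alternating between hemifields. Default clutter means are 6.3 (lat)
and 7.3 (multi), so the expected planted cluster counts are 7.3 and 9.3
including events. Objects are kept ≥ 4.5° apart (and off the event's whole
trajectory) so their saliency supports stay disjoint; packing occasionally
truncates the drawn patch count (measured bias ≈ −0.02 lat / −0.16 multi
clusters). Multi videos carry one event per hemifield with asymmetric
strength; the weight-based hemifield asymmetry (weight = amplitude × σ²)
defines the planted lateralization, and the layout is mirrored when size
jitter would contradict the requested side label.

The planted lateralization — not the pipeline-recovered `Sal_idx` — is
what the gaze generator couples to; recovery of the pipeline index is
validated separately (sign, flip antisymmetry, cluster counts). This keeps
the gaze model's coupling parameter interpretable.

## Synthetic gaze model

Viewing is a renewal process: gamma-distributed dwell times (shape 8,
mean 390 ms in lat / 325 ms in multi trials), zero saccade transit time.
At each renewal the gaze re-fixates the current target with probability
0.08 (merging into one longer fixation) or saccades to a new landing
point ≥ 1.8° away, drawn around a planted object in a hemifield chosen by
the condition policy:

* lat — event hemifield with probability `side_bias_lat` = 0.9, hence
  E[Gaze_idx] = ±0.8;
* multi — right hemifield with probability
  0.5 + `coupling_gamma` × Sal_idx (clamped), `coupling_gamma` = 0.30.

Samples carry 0.15° Gaussian jitter; blinks (150 ms invalid gaps) occur at
0.1/s; the pre-stimulus window (300 ms) fixates the centre with a 0.3° sd
offset. Dwell means, the refixation probability and the coupling gain are
calibrated against the printed behavioural summary statistics of the study
design this emulates (1.9 / 2.4 saccades per s; multi-cell correlations
≈ 0.3–0.45): a pure renewal process with the stated dwell means over-counts
fixations in a finite window, and the small refixation probability is the
behaviourally-motivated correction (observers do re-fixate). The
calibration was fixed from renewal-process simulations before the
corresponding tests were written, and is not revisited.

`expected_multi_correlation` provides the analytic counterpart used in
tests: E[gaze|sal] = 2p − 1 with variance (1 − (2p−1)²) · E[Σw²/(Σw)²],
the weight factor estimated by Monte-Carlo over the dwell structure alone
(independent of the trace/parsing pipeline), giving the expected Pearson r
after subject averaging.

## Cohorts, corruption and flip balancing

Default cohorts have 19 subjects × 140 videos over 2 runs, ITIs uniform on
[3, 7.4] s (mean 5.2). Every video is mirrored for half the subjects,
block-dealt within each condition × side cell so each subject also views
every cell half-mirrored — per-video *independent* random halves would
leave individual subjects' viewed cells unbalanced and break subject
selection. Flipped presentations are distinct aggregation units (video_id
+ "F"), so per-video gaze averaging never mixes orientations. A corruption
fraction (default 10%) plants QC failures (3° pre-stimulus offset, or 60%
stimulus-sample loss), and 3 designated non-compliant subjects get a 90%
rate, so default cohorts yield 16 usable subjects out of 19. Rendered
frames are produced on demand (`CohortData.render`); a materialized
140-video set would be ~0.8 GB.

## Design and decoding

Sub-group splitting (3 per run × condition cell) uses seeded randomized
restarts with pairwise-swap repair against two balance constraints, each
operationalized as max − min ≤ 1 per category (exact equality is
unattainable with 5–7 trials per sub-group): first/second half of run
(median onset split) and previous-trial condition. Unsatisfied residuals
after bounded search are returned as logged violations, never silently
dropped. Image-sets are (run, sub-group) pairs; folds train on 20 and test
on 4 volumes, each volume tested exactly once (24 pooled decisions).

The searchlight uses strict > 0.10 gray-matter thresholding, integer-
offset spheres (257 members at radius 4), truncated — not skipped — at
mask edges, and a deterministic linear SVM (C = 1, no feature scaling) as
the default classifier behind a pluggable fit/predict contract. Accuracy
maps store accuracy − 50 percentage points; group inference is a
voxel-wise one-sample t (uncorrected p), with zero-variance voxels flagged
NaN. Cluster-level family-wise correction is out of scope.

Synthetic beta volumes are Gaussian noise with a fixed (across subjects)
multivariate pattern added to multi-condition volumes inside an
informative region; amplitude 0 gives exact null data.

## Test problem sizes and what they show

The suite runs in about 6 minutes on one core by scaling simulations:
cluster-count calibration uses 30 seeded videos per condition (tolerance
±0.75 ≈ 1.6 × the Poisson sampling sd at that n, plus packing bias);
saccade-rate calibration 480 trials per condition (±0.15); the
linear-coupling correlation 200 cohorts of 30 videos (±0.03); decoding
null 50 seeds on a 12³ grid with a 216-voxel mask at radius 2 (radius-4
geometry is verified against the brute-force sphere oracle); the
coupling-recovery check 3 default cohorts against the analytic value
(±0.07). The fixation detector is checked against a brute-force window
oracle on 1000 random traces, cluster labelling against a hand-written
flood fill, and type-I error of the correlation cells against the nominal
5% ± 2% over 2000 null cells.

Passing these shows the pipeline is internally correct and recovers what
the generators plant. The generators emulate the *statistical* structure
of the target design — lateralized contrast, dwell statistics, coupling,
QC failure modes — not real scenes or real eyes: no semantic content, no
smooth pursuit, no velocity-based saccade dynamics, no measurement drift,
and beta volumes with white noise rather than spatially-correlated BOLD
residuals. Conclusions about real data therefore rest on the analysis
definitions, not on these simulations.

## Known limitations

* Saliency output is qualitative: no attempt is made to match any
  particular toolbox numerically; channel weights are uniform.
* The sub-group search is heuristic; for pathological schedules it
  reports residual imbalance instead of failing.
* `expected_multi_correlation` treats per-video noise as homoscedastic
  after subject averaging; adequate at the tested tolerances.
* Edge-sphere truncation and pooled (rather than per-fold-averaged)
  accuracy are fixed conventions; both alternatives exist in the field.
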