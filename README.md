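# salcomp

Analysis toolkit for free-viewing attention experiments that manipulate
**event competition**: does stimulus-driven salience guide overt spatial
orienting, and does it do so only when several events compete for attention?

The intended setting is a cohort of observers freely viewing short (1.5 s)
video clips that contain either a single lateralized distinctive event
(*lat* trials, weak competition) or distinctive events in both hemifields
(*multi* trials, strong competition), with eye tracking during viewing and,
optionally, condition-labelled fMRI beta images for multivariate decoding.

## What it computes

**Salience lateralization.** Each frame gets a multi-channel saliency map
(intensity, colour opponency, oriented contrast, flicker, motion; centre-
surround difference-of-Gaussians operators with max-based normalization).
Per video, hemifield means L and R (excluding a central band of ±2°) give

    Sal_idx = (R − L) / (R + L)  ∈ [−1, 1],   positive = rightward bias.

The time-summed saliency map is segmented into 8-connected clusters of
strictly positive salience (a count of distinctive scene locations), and
the percentage of fixations landing inside clusters is reported.

**Gaze lateralization.** Raw gaze traces are parsed into fixations with a
dispersion-threshold algorithm (I-DT: ≤1.5° × 1.5° for ≥100 ms); trials
pass QC when the pre-stimulus position is within ±2° of centre and ≥50% of
stimulus-period samples belong to fixations; subjects are retained with ≥6
passing trials per condition cell. Hemifield looking times give

    Gaze_idx = (Rtime − Ltime) / (Rtime + Ltime),

and saccades per trial are counted as fixations − 1.

**Statistics.** Pearson correlations between per-video `Sal_idx` and mean
`Gaze_idx`, separately per condition × side cell (so categorical side
effects cannot contribute); paired *t* on per-subject saccade rates; pooled
two-sample *t* on cluster counts and fixation-in-cluster percentages;
min–max 0–1 scaling of the indexes for use as parametric modulators.

**Searchlight decoding.** 24 beta images per subject (2 runs × 4
conditions × 3 pseudo-random sub-groups, balanced for previous-trial
condition and run half) are divided into 6 image-sets; a linear SVM
discriminates multi vs lat in a radius-4-voxel searchlight restricted to a
gray-matter mask (probability > 10%), leave-one-set-out over 6 folds,
producing accuracy−50% maps and a group-level one-sample *t* map.

**Synthetic data.** `salcomp.synthetic` generates everything the analysis
consumes — videos (moving Gaussian events over static clutter), renewal-
model gaze traces with planted salience coupling, full cohorts with
flip-balancing and QC corruption, and beta volumes with a planted
multivariate pattern — so the whole pipeline is testable end to end
against known ground truth.

## Worked example

```python
from salcomp import saliency
from salcomp.synthetic import generate_video, generate_cohort
from salcomp.pipeline import annotate_trials, behavioral_summary

video, truth = generate_video("multi", "right", seed=42)
sv = saliency.video_saliency(video.frames)
hemi = saliency.salience_lateralization_index(sv)
print(hemi.sal_idx, truth.true_lateralization, sv.n_clusters)
# sal_idx = +0.275   planted = +0.290    clusters = 10 (= planted objects)

cohort = generate_cohort(seed=1)                   # 19 subjects, 140 videos
annotated = annotate_trials(cohort.trials, cohort.traces)
summary = behavioral_summary(annotated)
```

which prints, for the default simulated cohort:

```
retained subjects: 16 of 19
Llat    n= 80  r=-0.02  p=0.877
Rlat    n= 80  r=+0.01  p=0.898
Lmulti  n= 60  r=+0.48  p=0.000
Rmulti  n= 60  r=+0.42  p=0.001
saccade rates: lat 1.95/s, multi 2.32/s; paired t(15) = 16.78, p = 4e-11
```

i.e. the salience–gaze coupling is recovered only in the high-competition
multi cells, gaze in lat trials is driven by the event side (Gaze_idx
≈ ±0.8) regardless of salience, and multi trials elicit more saccades —
the qualitative signature the toolkit is designed to measure.

A `salcomp` console script exposes the same stages
(`simulate`, `saliency`, `gaze`, `design`, `analyze`, `decode`); see
`salcomp --help`.

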