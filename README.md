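# saccdecode

Time-resolved EEG decoding of spatial frequency across the visual field,
during stable fixation and around saccades — built as a fully synthetic,
ground-truth-verifiable pipeline.

## The problem

A grating flashed at one location can be classified from EEG (high vs low
spatial frequency, 0.33 vs 1 c/dva) within ~80 ms when a classifier is
trained and tested at that location. Train at one location and test at
another, and the onset of above-chance decoding grows with the test
location's eccentricity from fixation — SF information spreads across the
visual field. When the observer is about to make a ~20 dva saccade, that
spread is predictively accelerated, and not only at the retinotopically
remapped location. Quantifying these onset latencies requires a pipeline of
saccade detection, trial exclusion, EEG preprocessing, time-resolved
multivariate classification, and Bayes-factor onset inference. No public
recording of this design exists, so this package pairs the pipeline with a
synthetic-session generator whose *embedded* discriminative latencies give
every stage an objective recovery target.

## What's in the box

| module (`saccdecode.`) | what it does |
| --- | --- |
| `config` | session design + screen geometry (8 locations, 2 fixation points, congruency pairs 1–5, 2–6, 3–7, 4–8, eccentricity bins) |
| `schedule` | trial scheduler: blocks, interleaving, catch flags, saccade-latency sampling (truncated normal 200 ± 60 ms on [100, 400] ms) |
| `gaze` | 1000 Hz gaze synthesis: fixational drift, microsaccades, 20.08 dva cued saccades, blinks, injectable violations |
| `eeg` | ground truth + EEG synthesis: location-specific (80 ms) and location-invariant (145/205/295 ms fixation, 140 ms saccade) class-signed topographies in mixed pink + broadband noise; continuous and direct-epoch routes |
| `eye_events` | median-based 5-sigma velocity saccade detector (15 ms minimum, 50 ms merge, 15 dva validity) and the trial-exclusion rules |
| `preprocess` | 256 Hz downsampling + mastoid reference, zero-phase 0.1–80 Hz band-pass + 50 Hz notch, ocular-component variance-ratio rejection, −200..+500 ms epochs with −100..0 ms baseline |
| `decoding` | per-timepoint shrinkage-LDA stacks, five-fold same-location CV, cross-location / congruency / latency-bin generalization, condition aggregation |
| `inference` | JZS Bayes factors (Cauchy r = 0.707 prior), BF > 3 onset rule (first 3 consecutive timepoints), leave-two-out jackknife CIs, paired contrasts |
| `cohort`, `studies`, `pipeline` | multi-subject simulation + decoding + inference drivers, verification studies, end-to-end `run_all` with manifest |

The numbered drivers under `analysis/` run the narrative end to end:
`01_simulate_session` → `02_detect_and_exclude` → `03_preprocess_epochs` →
`04_decode_and_infer` → `05_cohort_recovery`, writing tables under
`results/` (bulky gaze/EEG containers go to `scratch/`).

## Worked example

```bash
python analysis/04_decode_and_infer.py
```

simulates a 10-subject cohort (448 trials each at desk scale), decodes all
conditions and prints:

```
recovered decoding onsets (10 synthetic subjects):
     condition  onset_ms  ci_low_ms  ci_high_ms  embedded_ms  error_ms  n_absent
     congruent 152.34375  148.43750   152.34375        145.0   7.34375         0
       control 210.93750  210.93750   214.84375        205.0   5.93750         0
           far 296.87500  296.87500   300.78125        295.0   1.87500         0
   incongruent 152.34375   82.03125   156.25000        145.0   7.34375         0
latbin_100_200 152.34375  148.43750   152.34375          NaN       NaN         0
latbin_200_300 152.34375  152.34375   152.34375          NaN       NaN         0
latbin_300_400       NaN        NaN         NaN          NaN       NaN        28
           mid 210.93750  210.93750   210.93750        205.0   5.93750         0
          near 152.34375  152.34375   152.34375        145.0   7.34375         0
          same  82.03125   82.03125    89.84375         80.0   2.03125         0
fixation eccentricity ordering preserved: True
saccade vs control onset: 152.3 vs 210.9 ms (predictive acceleration: 58.6 ms)
```

Reading it: `same` decoding switches on one grid sample (3.9 ms) after the
embedded 80 ms latency; cross-location onsets reproduce the embedded
eccentricity gradient (near < mid < far); saccade-trial decoding at the
congruent *and* incongruent peripheral locations starts at ~152 ms — far
earlier than the same stimuli without a saccade (`control`, ~211 ms) and
indistinguishable across saccade-latency bins. The `ci_*` columns are
leave-two-out jackknife 95% intervals over C(10,2) = 45 subject subsets;
`n_absent` counts subsets with no detectable onset.

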