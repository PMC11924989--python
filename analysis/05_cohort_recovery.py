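#!/usr/bin/env python
"""Multi-cohort verification: onset recovery against embedded ground truth
and false-positive calibration of the onset rule under a null generator.

Runs several independent 10-subject cohorts (and zero-effect cohorts),
summarizing recovery error, the fixation eccentricity ordering, the
saccade-vs-control contrast, and the null false-onset rate.
"""

from pathlib import Path

from saccdecode.studies import null_study, recovery_study

SEED = 2028
N_COHORTS = 6
N_NULL = 12
ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main():
    RESULTS.mkdir(exist_ok=True)
    rec = recovery_study(n_cohorts=N_COHORTS, seed=SEED)
    rec["onsets"].to_csv(RESULTS / "recovery_onsets.csv", index=False,
                         float_format="%.2f")
    print(f"recovery over {N_COHORTS} cohorts x 10 subjects:")
    for cond, onset in sorted(rec["per_condition_onset_ms"].items()):
        print(f"  {cond:12s} median onset {onset:7.2f} ms")
    print(f"  pooled median |onset error| = {rec['median_abs_error_ms']:.2f} ms")
    print(f"  fixation ordering (same<near<mid<far): "
          f"{rec['ordering_fraction']:.0%} of cohorts")
    print(f"  saccade earlier than control: {rec['contrast_fraction']:.0%} of cohorts")

    nul = null_study(n_cohorts=N_NULL, seed=SEED + 1)
    print(f"null calibration: {nul['n_detected']}/{N_NULL} zero-effect cohorts "
          f"produced a (false) onset")
    print(f"wrote {RESULTS/'recovery_onsets.csv'}")


if __name__ == "__main__":
    main()
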