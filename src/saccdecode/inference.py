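"""JZS Bayes-factor inference, onset detection, and jackknife intervals.

Evidence at each timepoint is a one-sample JZS Bayes factor across subjects:
point null delta = 0 against a zero-centered Cauchy prior of scale
r = 0.707 on the standardized effect size (two-sided, so both above- and
below-chance decoding count as evidence).  BF10 > 3 is read as substantial
evidence for the alternative, BF10 < 1/3 for the null.  Decoding onset is
the first timepoint of the earliest run of three consecutive BF10 > 3
samples; its confidence interval comes from recomputing the onset over all
leave-two-out subject subsets (C(n, 2) subsets) and taking the 2.5th/97.5th
percentiles of the resulting onset distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import integrate

from .decoding import DecodeSeries

DEFAULT_PRIOR_SCALE = 0.707
SUBSTANTIAL_BF = 3.0


def bf_ttest(
    samples: np.ndarray, null_value: float = 0.0, r: float = DEFAULT_PRIOR_SCALE
) -> float:
    """One-sample JZS Bayes factor (BF10) against a point null.

    Computed by adaptive quadrature of the Zellner-Siow marginal likelihood:
    the prior on the standardized effect is Cauchy(0, r), equivalently the
    variance ratio g follows InverseGamma(1/2, r^2/2), and

        BF10 = int_0^inf (1 + N g)^{-1/2}
               (1 + t^2 / ((1 + N g) nu))^{-(nu+1)/2} pi(g) dg
               / (1 + t^2 / nu)^{-(nu+1)/2}

    with t the usual one-sample t statistic, N the sample size, nu = N - 1.
    """
    x = np.asarray(samples, float)
    if x.size < 2 or not np.isfinite(x).all():
        raise ValueError("need >= 2 finite samples")
    sd = x.std(ddof=1)
    if sd == 0.0:
        raise ValueError("zero-variance sample: Bayes factor undefined")
    n = x.size
    t = (x.mean() - null_value) / (sd / np.sqrt(n))
    return bf_from_t(t, n, r=r)


def bf_from_t(t: float, n: int, r: float = DEFAULT_PRIOR_SCALE) -> float:
    """BF10 from a t statistic and sample size (JZS, two-sided Cauchy prior)."""
    nu = n - 1

    def integrand(g):
        return (
            (1.0 + n * g) ** -0.5
            * (1.0 + t**2 / ((1.0 + n * g) * nu)) ** (-(nu + 1) / 2.0)
            * r
            / np.sqrt(2.0 * np.pi)
            * g**-1.5
            * np.exp(-(r**2) / (2.0 * g))
        )

    # split at g = 1 with h = 1/g on the tail: two finite, well-conditioned
    # pieces (the mass shifts to large g for extreme t, where the direct
    # (0, inf) quadrature becomes unreliable)
    head, _ = integrate.quad(integrand, 0.0, 1.0, limit=200)
    tail, _ = integrate.quad(lambda h: integrand(1.0 / h) / h**2, 0.0, 1.0, limit=200)
    alt = head + tail
    null = (1.0 + t**2 / nu) ** (-(nu + 1) / 2.0)
    return float(alt / null)


@dataclass
class BFSeries:
    """Per-timepoint Bayes factors across a subject cohort."""

    times: np.ndarray  # seconds
    bf10: np.ndarray
    n_subjects: int
    null_value: float

    @property
    def time_ms(self) -> np.ndarray:
        return self.times * 1000.0

    def evidence_class(self) -> np.ndarray:
        """'alt' (BF > 3), 'null' (BF < 1/3), or 'inconclusive'."""
        out = np.full(self.bf10.shape, "inconclusive", dtype=object)
        out[self.bf10 > SUBSTANTIAL_BF] = "alt"
        out[self.bf10 < 1.0 / SUBSTANTIAL_BF] = "null"
        return out


@dataclass
class OnsetEstimate:
    onset_ms: float | None
    ci_low_ms: float | None
    ci_high_ms: float | None
    n_permutations: int
    n_absent: int = 0


def _subject_matrix(series: list[DecodeSeries]) -> tuple[np.ndarray, np.ndarray]:
    t0 = series[0].times
    for s in series:
        if s.times.shape != t0.shape or not np.allclose(s.times, t0):
            raise ValueError("subject series must share one time grid")
    return t0, np.stack([s.accuracy for s in series])


def bf_timecourse(
    series: list[DecodeSeries], null_value: float = 0.5, r: float = DEFAULT_PRIOR_SCALE
) -> BFSeries:
    """Per-timepoint BF10 across subjects for one condition."""
    if len(series) < 2:
        raise ValueError("need at least 2 subjects")
    times, acc = _subject_matrix(series)
    bf = np.empty(acc.shape[1])
    for j in range(acc.shape[1]):
        if acc[:, j].std(ddof=1) == 0.0:
            # degenerate timepoint (identical accuracies across subjects):
            # no evidence either way; NaN is never counted as BF > 3
            bf[j] = np.nan
        else:
            bf[j] = bf_ttest(acc[:, j], null_value=null_value, r=r)
    return BFSeries(times=times, bf10=bf, n_subjects=len(series), null_value=null_value)


def detect_onset(
    bf: BFSeries,
    window_ms: tuple[float, float] = (0.0, 500.0),
    run_length: int = 3,
    threshold: float = SUBSTANTIAL_BF,
) -> float | None:
    """First timepoint (ms) of the earliest run of >= 3 consecutive BF > 3."""
    tms = bf.time_ms
    in_win = (tms >= window_ms[0]) & (tms <= window_ms[1])
    idx = np.flatnonzero(in_win)
    above = bf.bf10[idx] > threshold
    run = 0
    for k, a in enumerate(above):
        run = run + 1 if a else 0
        if run == run_length:
            return float(tms[idx[k - run_length + 1]])
    return None


def jackknife_onset_ci(
    series: list[DecodeSeries],
    null_value: float = 0.5,
    window_ms: tuple[float, float] = (0.0, 500.0),
    r: float = DEFAULT_PRIOR_SCALE,
) -> OnsetEstimate:
    """Leave-two-out jackknife confidence interval on the decoding onset.

    The BF time course and onset are recomputed for every C(n, 2) subject
    subset; the CI is the 2.5th-97.5th percentile span of the defined
    onsets (subsets with no detected onset are counted, not interpolated).
    The interval is widened, if needed, to contain the full-sample onset.
    """
    n = len(series)
    if n < 4:
        raise ValueError("jackknife needs at least 4 subjects")
    full = detect_onset(bf_timecourse(series, null_value, r=r), window_ms)
    onsets = []
    n_absent = 0
    for drop in combinations(range(n), 2):
        sub = [s for i, s in enumerate(series) if i not in drop]
        on = detect_onset(bf_timecourse(sub, null_value, r=r), window_ms)
        if on is None:
            n_absent += 1
        else:
            onsets.append(on)
    n_perm = comb(n, 2)
    if not onsets or full is None:
        return OnsetEstimate(full, None, None, n_perm, n_absent)
    lo, hi = np.percentile(onsets, [2.5, 97.5])
    return OnsetEstimate(
        onset_ms=full,
        ci_low_ms=float(min(lo, full)),
        ci_high_ms=float(max(hi, full)),
        n_permutations=n_perm,
        n_absent=n_absent,
    )


def difference_bf(
    series_a: list[DecodeSeries],
    series_b: list[DecodeSeries],
    r: float = DEFAULT_PRIOR_SCALE,
) -> BFSeries:
    """Paired condition contrast: per-timepoint BF on within-subject A - B
    differences against a null of 0."""
    ids_a = [s.subject_id for s in series_a]
    ids_b = [s.subject_id for s in series_b]
    if ids_a != ids_b:
        raise ValueError("series must be paired by subject (same ids, same order)")
    times, acc_a = _subject_matrix(series_a)
    tb, acc_b = _subject_matrix(series_b)
    if not np.allclose(times, tb):
        raise ValueError("paired series must share one time grid")
    diff = acc_a - acc_b
    bf = np.array([bf_ttest(diff[:, j], null_value=0.0, r=r) for j in range(diff.shape[1])])
    return BFSeries(times=times, bf10=bf, n_subjects=len(series_a), null_value=0.0)
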