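"""Time-resolved pairwise LDA decoding of spatial frequency.

One linear discriminant is fit per timepoint on the 64-channel amplitude
vector (a "classifier stack"), always trained on fixation trials of a single
location and evaluated strictly on the time diagonal (train time t -> test
time t).  The pooled covariance is regularized by analytic (Ledoit-Wolf)
shrinkage toward a scaled identity — with 64 dimensions and a few dozen
trials per class, plain pooled covariance is unusable.  Class balance is
enforced everywhere by seeded subsampling of the majority class.  Ties at
the decision boundary resolve to the "low" class.

Generalization schemes: same-location five-fold cross-validation;
cross-location testing labeled by eccentricity group (near/mid/far distance
of the test location from the current fixation point); congruent/incongruent
testing on saccade trials (retinotopic pairs 1-5, 2-6, 3-7, 4-8); and
saccade-latency binning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .config import Geometry
from .epochs import EpochSet

CLASS_ORDER = ("low", "high")  # index 0 / 1; ties predict "low"


# ---------------------------------------------------------------------------
# batched shrinkage LDA
# ---------------------------------------------------------------------------


def _ledoit_wolf_shrinkage(xc: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Per-timepoint Ledoit-Wolf shrinkage intensity toward nu * I.

    xc: class-centered data, (n, T, p); S: MLE covariance (T, p, p).
    Returns gamma (T,) in [0, 1].
    """
    n, T, p = xc.shape
    nu = np.trace(S, axis1=1, axis2=2) / p  # (T,)
    target = nu[:, None, None] * np.eye(p)
    d2 = np.sum((S - target) ** 2, axis=(1, 2))  # squared Frobenius distance
    # sum_i ||x_i x_i^T - S||_F^2 = sum_i (x_i.x_i)^2 - n ||S||_F^2
    sq = np.einsum("itp,itp->it", xc, xc)  # (n, T) squared norms
    b2 = (np.sum(sq**2, axis=0) - n * np.sum(S**2, axis=(1, 2))) / n**2
    with np.errstate(divide="ignore", invalid="ignore"):
        gamma = np.where(d2 > 0, np.minimum(b2 / d2, 1.0), 1.0)
    return np.clip(gamma, 0.0, 1.0)


def fit_lda_timecourse(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fit one shrinkage-LDA discriminant per timepoint.

    X: (n_trials, n_channels, n_times); y: (n_trials,) in {0, 1}.
    Returns (weights (T, p), bias (T,)); decision score = w.x + b, with
    score > 0 -> class 1 ("high").
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    Xt = X.transpose(0, 2, 1)  # (n, T, p)
    n, T, p = Xt.shape
    mu0 = Xt[y == 0].mean(axis=0)  # (T, p)
    mu1 = Xt[y == 1].mean(axis=0)
    xc = Xt.copy()
    xc[y == 0] -= mu0
    xc[y == 1] -= mu1
    xT = np.ascontiguousarray(xc.transpose(1, 0, 2))  # (T, n, p)
    S = (xT.transpose(0, 2, 1) @ xT) / n  # MLE pooled covariance, (T, p, p)
    gamma = _ledoit_wolf_shrinkage(xc, S)
    nu = np.trace(S, axis1=1, axis2=2) / p
    S_shrunk = (1.0 - gamma)[:, None, None] * S + (gamma * nu)[:, None, None] * np.eye(p)
    w = np.linalg.solve(S_shrunk, (mu1 - mu0)[..., None])[..., 0]  # (T, p)
    b = -np.einsum("tp,tp->t", w, 0.5 * (mu0 + mu1))
    return w, b


def predict_timecourse(w: np.ndarray, b: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Diagonal predictions: (n_trials, n_times) class indices in {0, 1}."""
    scores = np.einsum("ncT,Tc->nT", X, w) + b
    return (scores > 0).astype(int)  # ties (score == 0) fall to class 0, "low"


@dataclass
class ClassifierStack:
    """Per-timepoint linear discriminants trained at one location/side."""

    train_location: int
    fixation_side: str
    weights: np.ndarray  # (n_times, n_channels)
    bias: np.ndarray  # (n_times,)
    n_train_trials: int
    times: np.ndarray

    def __post_init__(self):
        if not np.isfinite(self.weights).all() or not np.isfinite(self.bias).all():
            raise ValueError("non-finite discriminant weights")


@dataclass
class DecodeSeries:
    """Per-timepoint fraction correct for one subject and condition."""

    subject_id: str
    condition: str
    times: np.ndarray
    accuracy: np.ndarray
    n_test_trials: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": self.subject_id,
                "condition": self.condition,
                "time_ms": np.round(self.times * 1000.0, 3),
                "accuracy": self.accuracy,
                "n_test": self.n_test_trials,
            }
        )


def _labels(meta: pd.DataFrame) -> np.ndarray:
    return (meta.sf_class.to_numpy() == "high").astype(int)


def _balance_classes(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Indices subsampling the majority class down to the minority count."""
    idx0, idx1 = np.flatnonzero(y == 0), np.flatnonzero(y == 1)
    m = min(idx0.size, idx1.size)
    keep = np.r_[rng.permutation(idx0)[:m], rng.permutation(idx1)[:m]]
    return np.sort(keep)


def _fixation_trials(epochs: EpochSet, location: int, side: str) -> EpochSet:
    meta = epochs.meta
    mask = (
        (meta.trial_type == "fixation")
        & (meta.location_id == location)
        & (meta.fixation_side == side)
    )
    return epochs.select(mask.to_numpy())


def train_stack(
    epochs: EpochSet, location: int, side: str, seed: int = 0
) -> ClassifierStack:
    """Train the per-timepoint discriminants on one location's fixation trials."""
    sub = _fixation_trials(epochs, location, side)
    y = _labels(sub.meta)
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError(
            f"need >= 2 trials per class at location {location} ({side}); "
            f"have {np.bincount(y, minlength=2)}"
        )
    keep = _balance_classes(y, np.random.default_rng(seed))
    w, b = fit_lda_timecourse(sub.data[keep], y[keep])
    return ClassifierStack(
        train_location=location,
        fixation_side=side,
        weights=w,
        bias=b,
        n_train_trials=keep.size,
        times=sub.times,
    )


def crossval_same(
    epochs: EpochSet, location: int, side: str, k: int = 5, seed: int = 0
) -> DecodeSeries:
    """Stratified k-fold, diagonal-tested, fold-averaged same-location series."""
    sub = _fixation_trials(epochs, location, side)
    y = _labels(sub.meta)
    rng = np.random.default_rng(seed)
    keep = _balance_classes(y, rng)
    X, y = sub.data[keep], y[keep]
    if min((y == 0).sum(), (y == 1).sum()) < k:
        raise ValueError(f"k={k} exceeds the minority class count at location {location}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(rng.integers(2**31)))
    accs = []
    for tr, te in skf.split(X[:, :, 0], y):
        w, b = fit_lda_timecourse(X[tr], y[tr])
        pred = predict_timecourse(w, b, X[te])
        accs.append((pred == y[te][:, None]).mean(axis=0))
    return DecodeSeries(
        subject_id=sub.subject_id,
        condition="same",
        times=sub.times,
        accuracy=np.mean(accs, axis=0),
        n_test_trials=len(y),
    )


def cross_test(
    stack: ClassifierStack, epochs: EpochSet, selector, condition: str
) -> DecodeSeries:
    """Evaluate a trained stack on the trials picked by `selector`.

    `selector` is a boolean mask over epochs.meta or a callable producing one.
    Evaluation is strictly diagonal.
    """
    mask = selector(epochs.meta) if callable(selector) else np.asarray(selector)
    if mask.dtype != bool:
        raise TypeError("selector must yield a boolean mask")
    if not mask.any():
        raise ValueError(f"selector for condition {condition!r} picked no trials")
    sub = epochs.select(mask)
    y = _labels(sub.meta)
    pred = predict_timecourse(stack.weights, stack.bias, sub.data)
    return DecodeSeries(
        subject_id=sub.subject_id,
        condition=condition,
        times=stack.times,
        accuracy=(pred == y[:, None]).mean(axis=0),
        n_test_trials=len(y),
    )


# ---------------------------------------------------------------------------
# condition mapping and aggregation
# ---------------------------------------------------------------------------


def map_condition(
    train_location: int,
    test_location: int,
    trial_type: str,
    geometry: Geometry,
    current_side: str | None = None,
    scheme: str = "congruency",
) -> str | None:
    """Label a (train location, test trial) pairing.

    Fixation/control tests: 'same' when train == test, otherwise the
    eccentricity group (near/mid/far) of the test location's distance from
    the current fixation point.  Peripheral saccade tests under the
    'congruency' scheme: 'congruent' for the retinotopic partner,
    'incongruent' for the same-eccentricity alternative, None otherwise;
    under the 'eccentricity' scheme they are binned like fixation tests.
    """
    if test_location not in geometry.locations:
        raise KeyError(f"unknown location id {test_location}")
    side = current_side or geometry.nearest_side(train_location)
    if trial_type in ("fixation", "control"):
        if test_location == train_location:
            return "same"
        return geometry.ecc_label(test_location, side)
    if trial_type == "saccade_peripheral":
        if scheme == "eccentricity":
            return geometry.ecc_label(test_location, side)
        if test_location == geometry.congruent_location(train_location):
            return "congruent"
        if test_location == geometry.incongruent_location(train_location):
            return "incongruent"
        return None
    return None


def aggregate(series: list[DecodeSeries], subject_id: str | None = None) -> list[DecodeSeries]:
    """Average series into one per condition: first over (train, test) pairs
    within a condition, then over fixation sides (the inputs here are the
    already pair-level series tagged with condition; order of the unweighted
    means does not depend on input ordering)."""
    if not series:
        return []
    t0 = series[0].times
    for s in series:
        if s.times.shape != t0.shape or not np.allclose(s.times, t0):
            raise ValueError("all series must share one time grid")
    out = []
    sid = subject_id or series[0].subject_id
    conditions = sorted({s.condition for s in series})
    for cond in conditions:
        group = [s for s in series if s.condition == cond]
        acc = np.mean([s.accuracy for s in group], axis=0)
        out.append(
            DecodeSeries(
                subject_id=sid,
                condition=cond,
                times=t0,
                accuracy=acc,
                n_test_trials=int(sum(s.n_test_trials for s in group)),
            )
        )
    return out


def bin_by_saccade_latency(
    stack: ClassifierStack,
    epochs: EpochSet,
    base_mask: np.ndarray,
    bin_edges_ms: np.ndarray | None = None,
) -> list[DecodeSeries]:
    """Evaluate a stack separately within saccade-latency bins.

    `base_mask` selects the saccade trials eligible for this stack (e.g. the
    congruent + incongruent locations); bins default to 100 ms widths over
    the 100-400 ms inclusion window.  Empty bins are dropped.
    """
    if bin_edges_ms is None:
        bin_edges_ms = np.arange(100.0, 400.0 + 1e-9, 100.0)
    lat = epochs.meta.stim_to_saccade_ms.to_numpy()
    out = []
    for lo, hi in zip(bin_edges_ms[:-1], bin_edges_ms[1:]):
        in_bin = base_mask & (lat >= lo) & (lat < hi)
        if not in_bin.any():
            continue
        out.append(
            cross_test(stack, epochs, in_bin, condition=f"latbin_{int(lo)}_{int(hi)}")
        )
    return out
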