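"""Session configuration and screen geometry.

The experiment this package emulates presents brief Gabor gratings at one of
eight screen locations while the observer fixates one of two horizontally
separated fixation points (20.08 dva apart) and, on cued trials, saccades
between them.  Four stimulus locations surround each fixation point at
5.05 dva.  The geometry object owns every spatial question the rest of the
pipeline asks: which cluster a location belongs to, how far it is from the
currently fixated point, which location is the retinotopically congruent
partner after a saccade, and which eccentricity group a test location falls
into.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

FIXATION_SEPARATION_DVA = 20.08
STIMULUS_RADIUS_DVA = 5.05


class ConfigurationError(ValueError):
    """Raised when a session configuration is internally inconsistent."""


class InfeasibilityError(ValueError):
    """Raised when a schedule cannot satisfy minimum per-cell trial counts."""


def _default_locations() -> dict[int, tuple[float, float]]:
    """Square of four locations around each fixation point.

    The right cluster is a pure translation of the left one, so location i
    and i + 4 occupy identical retinotopic positions relative to their own
    fixation point; that makes the congruency pairs 1-5, 2-6, 3-7, 4-8 exact.
    Within a cluster, locations 1/2 (and 5/6) sit on the far side from the
    screen centre and 3/4 (7/8) on the near side; 1/3 are upper, 2/4 lower.
    """
    o = STIMULUS_RADIUS_DVA / math.sqrt(2.0)
    fx = FIXATION_SEPARATION_DVA / 2.0
    left = {
        1: (-fx + o, o),
        2: (-fx + o, -o),
        3: (-fx - o, o),
        4: (-fx - o, -o),
    }
    right = {i + 4: (x + FIXATION_SEPARATION_DVA, y) for i, (x, y) in left.items()}
    return {**left, **right}


@dataclass(frozen=True)
class Geometry:
    """Stimulus locations, fixation points and the spatial predicates on them.

    Parameters
    ----------
    fixation_points : ((x, y), (x, y)) in dva; index 0 is the "left" point.
    locations : mapping of location id (1-8) to (x, y) in dva.
    ecc_cutpoints : (near/mid, mid/far) boundaries in dva on the distance of
        a test location from the *current* fixation point.
    """

    fixation_points: tuple[tuple[float, float], tuple[float, float]] = (
        (-FIXATION_SEPARATION_DVA / 2.0, 0.0),
        (FIXATION_SEPARATION_DVA / 2.0, 0.0),
    )
    locations: dict[int, tuple[float, float]] = field(default_factory=_default_locations)
    ecc_cutpoints: tuple[float, float] = (7.5, 20.0)

    def __post_init__(self):
        if len(self.locations) != 8:
            raise ConfigurationError("exactly 8 stimulus locations are required")
        for loc in self.locations:
            d = [self.distance(loc, side) for side in ("left", "right")]
            if sum(x <= 6.0 for x in d) != 1:
                raise ConfigurationError(
                    f"location {loc} must lie within 6 dva of exactly one fixation point"
                )

    # -- basic coordinates -------------------------------------------------
    def fixation_point(self, side: str) -> np.ndarray:
        return np.asarray(self.fixation_points[0 if side == "left" else 1], float)

    def position(self, loc: int) -> np.ndarray:
        try:
            return np.asarray(self.locations[int(loc)], float)
        except KeyError:
            raise KeyError(f"unknown location id {loc!r}") from None

    def distance(self, loc: int, side: str) -> float:
        """Distance of a stimulus location from the fixation point on `side`."""
        return float(np.linalg.norm(self.position(loc) - self.fixation_point(side)))

    def nearest_side(self, loc: int) -> str:
        return "left" if self.distance(loc, "left") <= self.distance(loc, "right") else "right"

    def cluster(self, side: str) -> list[int]:
        """Location ids whose nearest fixation point is on `side`."""
        return sorted(loc for loc in self.locations if self.nearest_side(loc) == side)

    @staticmethod
    def other_side(side: str) -> str:
        return "right" if side == "left" else "left"

    # -- condition mapping helpers ----------------------------------------
    def congruent_location(self, train_loc: int) -> int:
        """Opposite-cluster location with the same retinotopic offset.

        A classifier trained at `train_loc` (offset relative to its own
        fixation point) generalizes, after the eyes land on the other point,
        to the location with the matching offset there.
        """
        own_side = self.nearest_side(train_loc)
        offset = self.position(train_loc) - self.fixation_point(own_side)
        other = self.other_side(own_side)
        target = self.fixation_point(other) + offset
        candidates = self.cluster(other)
        dists = [float(np.linalg.norm(self.position(c) - target)) for c in candidates]
        return candidates[int(np.argmin(dists))]

    def incongruent_location(self, train_loc: int, tol: float = 1e-6) -> int:
        """The non-remapped opposite-cluster location at the congruent one's
        eccentricity (measured from the current fixation point)."""
        own_side = self.nearest_side(train_loc)
        cong = self.congruent_location(train_loc)
        d_cong = self.distance(cong, own_side)
        cands = [
            c
            for c in self.cluster(self.other_side(own_side))
            if c != cong and abs(self.distance(c, own_side) - d_cong) < max(tol, 1e-3 * d_cong)
        ]
        if len(cands) != 1:
            raise ConfigurationError(
                f"no unique incongruent partner for training location {train_loc}"
            )
        return cands[0]

    def ecc_label(self, test_loc: int, current_side: str) -> str:
        """Eccentricity group of a test location: near / mid / far."""
        d = self.distance(test_loc, current_side)
        lo, hi = self.ecc_cutpoints
        if d < lo:
            return "near"
        return "mid" if d < hi else "far"


@dataclass(frozen=True)
class SessionConfig:
    """Composition and timing of one recording session.

    Defaults reproduce the emulated design: 5 blocks of 480 trials
    (224 fixation + 224 saccade + 32 control), catch trials every 11-20
    trials, gratings at 0.33 or 1 c/dva shown for 100 ms, EEG synthesized at
    512 Hz and gaze at 1000 Hz.  Saccade-trial latencies between stimulus and
    saccade onset are drawn from a normal distribution (mean 200 ms,
    sd 60 ms) truncated to [100, 400] ms, emulating the online staircase that
    targeted ~200 ms.
    """

    n_blocks: int = 5
    trials_per_block: int = 480
    n_fixation_per_block: int = 224
    n_saccade_per_block: int = 224
    n_control_per_block: int = 32
    catch_interval: tuple[int, int] = (11, 20)
    geometry: Geometry = field(default_factory=Geometry)
    sf_classes: tuple[float, float] = (0.33, 1.0)  # (low, high) cycles/dva
    stimulus_duration_ms: float = 100.0
    eeg_rate_hz: float = 512.0
    gaze_rate_hz: float = 1000.0
    seed: int = 0
    # timing of events within a trial (seconds)
    trial_len_fixation_s: float = 2.2
    trial_len_saccade_s: float = 3.0
    stim_delay_range_s: tuple[float, float] = (0.4, 0.8)
    cue_delay_range_s: tuple[float, float] = (0.2, 0.6)
    cue_to_saccade_range_s: tuple[float, float] = (0.8, 1.2)
    stim_to_saccade_mean_ms: float = 200.0
    stim_to_saccade_sd_ms: float = 60.0
    stim_to_saccade_range_ms: tuple[float, float] = (100.0, 400.0)
    min_trials_per_cell: int = 0

    def __post_init__(self):
        counts = (
            self.n_fixation_per_block,
            self.n_saccade_per_block,
            self.n_control_per_block,
        )
        if any(c < 0 for c in counts) or sum(counts) != self.trials_per_block:
            raise ConfigurationError(
                "per-block trial-type counts must be nonnegative and sum to trials_per_block"
            )
        lo, hi = self.sf_classes
        if not (lo > 0 and hi > 0 and lo != hi):
            raise ConfigurationError("sf_classes must be two distinct positive values")
        if self.catch_interval[0] > self.catch_interval[1] or self.catch_interval[0] < 1:
            raise ConfigurationError("catch_interval must be a nonempty positive range")

    def with_(self, **kw) -> "SessionConfig":
        return replace(self, **kw)


def load_config(path) -> SessionConfig:
    """Build a SessionConfig from a flat YAML (or JSON) mapping.

    Recognized keys are the SessionConfig fields; `locations` may be given as
    a mapping of location id to [x, y] and `fixation_points` as two [x, y]
    pairs, which together build the geometry.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    geo_kw = {}
    if "locations" in raw:
        geo_kw["locations"] = {
            int(k): tuple(map(float, v)) for k, v in raw.pop("locations").items()
        }
    if "fixation_points" in raw:
        pts = raw.pop("fixation_points")
        geo_kw["fixation_points"] = (tuple(pts[0]), tuple(pts[1]))
    if "ecc_cutpoints" in raw:
        geo_kw["ecc_cutpoints"] = tuple(raw.pop("ecc_cutpoints"))
    if geo_kw:
        raw["geometry"] = Geometry(**geo_kw)
    for key in ("catch_interval", "sf_classes", "stim_delay_range_s",
                "cue_delay_range_s", "cue_to_saccade_range_s",
                "stim_to_saccade_range_ms"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return SessionConfig(**raw)


def desk_scale_config(seed: int = 0, **overrides) -> SessionConfig:
    """A reduced single-block session sized for desk-scale simulation.

    256 fixation + 96 saccade + 96 control trials keep every decoding cell
    populated (~16 trials per location x SF x side for training; the real
    design has ~85x more fixation trials than a desk run can afford) while a
    full multi-subject cohort stays cheap to synthesize and decode.
    """
    base = dict(
        n_blocks=1,
        trials_per_block=448,
        n_fixation_per_block=256,
        n_saccade_per_block=96,
        n_control_per_block=96,
        seed=seed,
    )
    base.update(overrides)
    return SessionConfig(**base)
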