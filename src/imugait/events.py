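"""Rule-based gait-event detection and per-sample phase labeling.

Three events per leg structure a gait cycle: heel strike (HS), toe off (TO)
and the instant of maximum hip flexion (HMax).  With both legs half a cycle
out of phase, the six events recur in a fixed chronology::

    L-HS -> R-TO -> R-HMax -> R-HS -> L-TO -> L-HMax -> (next L-HS)

Detection rules operate on single IMU channels:

* **HS** — falling zero crossing of the foot gyroscope Z channel: the foot's
  angular velocity decreases rapidly through zero as the heel contacts the
  ground.
* **TO** — negative trough of the same channel: maximum plantar-flexion
  rate, found by peak detection with a prominence threshold.
* **HMax** — falling zero crossing of the thigh gyroscope Z channel: the
  thigh angular velocity is zero at the hip-angle maximum, moving from
  flexion to extension.

The "gait phase" of a sample is the class of the most recent event; the
stretch between two consecutive events is labeled by its starting event,
giving a 6-class per-sample labeling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

#: The six event classes in cyclic chronological order.
EVENT_ORDER: tuple[str, ...] = ("L-HS", "R-TO", "R-HMax", "R-HS", "L-TO", "L-HMax")

_ORDER_POS = {label: i for i, label in enumerate(EVENT_ORDER)}

SIDES = ("L", "R")
EVENT_KINDS = ("HS", "TO", "HMax")


@dataclass(frozen=True)
class GaitEvent:
    """One gait event: sample index, side (L/R) and kind (HS/TO/HMax)."""

    sample_index: int
    side: str
    kind: str

    def __post_init__(self) -> None:
        if self.sample_index < 0:
            raise ValueError("sample_index must be non-negative")
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"kind must be one of {EVENT_KINDS}, got {self.kind!r}")

    @property
    def label(self) -> str:
        return f"{self.side}-{self.kind}"


@dataclass
class EventTimeline:
    """Chronologically ordered gait events with strictly increasing indices."""

    events: list[GaitEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: (e.sample_index, _ORDER_POS[e.label]))
        idx = self.indices
        if len(idx) > 1 and np.any(np.diff(idx) <= 0):
            raise ValueError("event sample indices must be strictly increasing (ties forbidden)")

    @property
    def indices(self) -> np.ndarray:
        return np.array([e.sample_index for e in self.events], dtype=int)

    @property
    def labels(self) -> list[str]:
        return [e.label for e in self.events]

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "sample_index": [e.sample_index for e in self.events],
                "side": [e.side for e in self.events],
                "event": [e.kind for e in self.events],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "EventTimeline":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(
            [
                GaitEvent(int(r.sample_index), str(r.side), str(r.event))
                for r in df.itertuples()
            ]
        )


def detect_hs(foot_gyro_z: np.ndarray, min_separation: int = 1) -> np.ndarray:
    """Falling zero crossings of the foot gyro Z channel (heel strikes).

    A crossing is a sample pair with ``x[k] > 0 >= x[k+1]``; the reported
    event index is ``k + 1`` (first non-positive sample).  Crossings closer
    than ``min_separation`` samples to the previously kept one are treated
    as noise chatter and discarded (first-kept rule).
    """
    x = np.asarray(foot_gyro_z, dtype=float)
    if x.size < 2:
        return np.array([], dtype=int)
    crossings = np.flatnonzero((x[:-1] > 0) & (x[1:] <= 0)) + 1
    return _debounce(crossings, min_separation)


def detect_hmax(thigh_gyro_z: np.ndarray, min_separation: int = 1) -> np.ndarray:
    """Falling zero crossings of the thigh gyro Z channel (hip-angle maxima).

    The thigh angular velocity is the derivative of the hip angle, so a
    falling zero crossing marks the hip's maximum flexion.  Same index and
    debouncing conventions as :func:`detect_hs`.
    """
    return detect_hs(thigh_gyro_z, min_separation)


def detect_to(
    foot_gyro_z: np.ndarray,
    min_separation: int = 1,
    min_prominence: float = 0.0,
) -> np.ndarray:
    """Negative troughs of the foot gyro Z channel (toe offs).

    TO is the maximum plantar-flexion rate, a signed extremum of the foot
    angular velocity — a trough under this package's sign convention.
    Troughs are located by peak detection on the negated channel with the
    given prominence threshold and minimum separation.
    """
    x = np.asarray(foot_gyro_z, dtype=float)
    if x.size < 3:
        return np.array([], dtype=int)
    peaks, _ = find_peaks(
        -x,
        prominence=min_prominence if min_prominence > 0 else None,
        distance=max(int(min_separation), 1),
    )
    return peaks.astype(int)


def estimate_noise_sigma(x: np.ndarray) -> float:
    """Robust high-frequency noise scale of a channel.

    Median absolute deviation of first differences, scaled to the standard
    deviation of Gaussian noise (the difference of two iid normals has
    standard deviation sigma * sqrt(2); MAD -> sigma via 1.4826).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        return 0.0
    d = np.diff(x)
    return 1.4826 * float(np.median(np.abs(d - np.median(d)))) / np.sqrt(2.0)


def _debounce(indices: np.ndarray, min_separation: int) -> np.ndarray:
    if len(indices) == 0 or min_separation <= 1:
        return indices.astype(int)
    kept = [int(indices[0])]
    for i in indices[1:]:
        if int(i) - kept[-1] >= min_separation:
            kept.append(int(i))
    return np.array(kept, dtype=int)


def _step(prev_label: str, next_label: str) -> int:
    """Cyclic advance from one event class to the next, in {0, ..., 5}."""
    return (_ORDER_POS[next_label] - _ORDER_POS[prev_label]) % len(EVENT_ORDER)


# Forward gaps of up to 4 classes are tolerated as missed detections; a
# repeated class (advance 0) or a one-step regression (advance 5) breaks
# the chronology.
_MAX_FORWARD_GAP = 4


def _valid_step(prev_label: str, next_label: str) -> bool:
    return 1 <= _step(prev_label, next_label) <= _MAX_FORWARD_GAP


@dataclass
class OrderViolation:
    position: int
    expected: str
    found: str


def validate_event_order(timeline: EventTimeline) -> list[OrderViolation]:
    """Check the six-event cyclic chronology of a timeline.

    Each consecutive pair must advance the cycle: the later event's class
    must lie 1-4 positions ahead of the earlier one's in the cyclic order.
    A repeated class or a step back by one class is reported as a violation
    carrying the position, the expected next class and the class found.
    Returns an empty list for a valid timeline.
    """
    violations: list[OrderViolation] = []
    labels = timeline.labels
    for pos in range(1, len(labels)):
        prev, cur = labels[pos - 1], labels[pos]
        if not _valid_step(prev, cur):
            expected = EVENT_ORDER[(_ORDER_POS[prev] + 1) % len(EVENT_ORDER)]
            violations.append(OrderViolation(pos, expected, cur))
    return violations


#: Score cost of a non-unit cyclic advance when merging detections.  Any
#: value in (1, 3) rejects single spurious insertions (which cost two
#: resyncs to gain one event) while still letting a single missed event be
#: bridged (one resync buys the whole remaining chain).
RESYNC_PENALTY = 2.5


@dataclass
class TimelineReport:
    """Outcome of merging per-channel detections into one timeline."""

    timeline: EventTimeline
    dropped: list[GaitEvent]
    warning: str | None = None


def build_timeline(per_side_events: dict[str, np.ndarray]) -> TimelineReport:
    """Merge per-channel event detections into one order-consistent timeline.

    Parameters
    ----------
    per_side_events
        Mapping from event label (``"L-HS"``, ``"R-TO"``, ...) to sorted
        sample indices detected for that class.

    The merged candidates are sorted by index and the best-scoring subset
    that respects the cyclic chronology is retained by dynamic programming
    over the six classes: every kept event scores 1, consecutive kept
    events must have strictly increasing indices and advance the cycle by
    1-4 classes, and any advance other than the unit step (a "resync"
    across missed detections) costs :data:`RESYNC_PENALTY`.  The penalty
    makes a lone spurious detection unprofitable — inserting it between
    two correctly ordered events always breaks the unit chain twice — while
    a genuine detector miss is bridged by a single paid resync.  Among
    equally scored subsets the earliest events win.  Dropped candidates are
    listed in the report.
    """
    candidates: list[GaitEvent] = []
    for label, idxs in per_side_events.items():
        if label not in _ORDER_POS:
            raise KeyError(f"unknown event label {label!r}; expected one of {EVENT_ORDER}")
        side, kind = label.split("-")
        for i in np.asarray(idxs, dtype=int):
            candidates.append(GaitEvent(int(i), side, kind))
    candidates.sort(key=lambda e: (e.sample_index, _ORDER_POS[e.label]))

    n = len(candidates)
    if n == 0:
        return TimelineReport(EventTimeline([]), [], warning="no candidate events")

    # Best-scoring valid subsequence: best[c] = (score, chain-end position)
    # of the best chain so far ending in class c.  Processing left to right
    # with per-class bests makes this O(n * 6).
    best_score = [-np.inf] * 6
    best_end = [-1] * 6
    prev = [-1] * n
    score = [1.0] * n
    for i, ev in enumerate(candidates):
        c = _ORDER_POS[ev.label]
        for pc in range(6):
            j = best_end[pc]
            if j < 0:
                continue
            d = _step(EVENT_ORDER[pc], ev.label)
            if not 1 <= d <= _MAX_FORWARD_GAP:
                continue
            if candidates[j].sample_index >= ev.sample_index:
                continue
            cand = best_score[pc] + 1.0 - (RESYNC_PENALTY if d > 1 else 0.0)
            if cand > score[i]:
                score[i] = cand
                prev[i] = j
        # ties keep the earlier chain end (leftmost retention)
        if score[i] > best_score[c]:
            best_score[c] = score[i]
            best_end[c] = i

    end = int(np.argmax(score))
    chain = []
    k = end
    while k != -1:
        chain.append(candidates[k])
        k = prev[k]
    chain.reverse()

    kept_ids = {id(e) for e in chain}
    dropped = [e for e in candidates if id(e) not in kept_ids]
    warning = None
    if not chain:
        warning = "all candidate events dropped"
    return TimelineReport(EventTimeline(chain), dropped, warning)


def label_phases(timeline: EventTimeline, n_samples: int) -> np.ndarray:
    """Per-sample gait-phase labels from an event timeline.

    Every sample from one event up to (excluding) the next carries the
    earlier event's class.  Samples before the first event are given the
    class cyclically preceding it; samples after the last event keep its
    class.  Returns an array of ``n_samples`` label strings.
    """
    if len(timeline) == 0:
        raise ValueError("cannot label phases from an empty timeline")
    last = timeline.events[-1].sample_index
    if n_samples <= last:
        raise ValueError(f"n_samples={n_samples} must exceed last event index {last}")
    labels = np.empty(n_samples, dtype=object)
    first = timeline.events[0]
    pre_class = EVENT_ORDER[(_ORDER_POS[first.label] - 1) % len(EVENT_ORDER)]
    labels[: first.sample_index] = pre_class
    for i, ev in enumerate(timeline.events):
        stop = (
            timeline.events[i + 1].sample_index
            if i + 1 < len(timeline.events)
            else n_samples
        )
        labels[ev.sample_index : stop] = ev.label
    return labels


def detect_events(
    stream,
    min_separation: int | None = None,
    min_prominence: float | None = None,
) -> TimelineReport:
    """Run all six detectors on an :class:`~imugait.streams.ImuStream`.

    ``min_separation`` defaults to a quarter of the estimated cycle period
    (refractory window between same-class events); ``min_prominence`` to
    three times the estimated channel noise sigma.
    """
    chans = {
        "L": (stream.channel("foot_l_gz"), stream.channel("thigh_l_gz")),
        "R": (stream.channel("foot_r_gz"), stream.channel("thigh_r_gz")),
    }
    per_side: dict[str, np.ndarray] = {}
    for side, (foot, thigh) in chans.items():
        sep = min_separation
        if sep is None:
            sep = _default_separation(foot, stream.sample_rate)
        prom = min_prominence
        if prom is None:
            prom = max(3.0 * estimate_noise_sigma(foot), 1e-6)
        per_side[f"{side}-HS"] = detect_hs(foot, sep)
        per_side[f"{side}-TO"] = detect_to(foot, sep, prom)
        per_side[f"{side}-HMax"] = detect_hmax(thigh, sep)
    return build_timeline(per_side)


def _default_separation(foot_gyro_z: np.ndarray, sample_rate: float) -> int:
    """Quarter of the dominant cycle period, estimated from the autocorrelation
    of the (mean-removed) channel; falls back to 0.25 s of samples."""
    x = np.asarray(foot_gyro_z, dtype=float)
    x = x - x.mean()
    n = len(x)
    if n < 8 or np.allclose(x, 0):
        return max(int(0.25 * sample_rate), 1)
    ac = np.correlate(x, x, mode="full")[n - 1 :]
    # first peak after the first zero crossing of the autocorrelation
    lo = int(np.argmax(ac < 0)) if np.any(ac < 0) else 1
    if lo >= n - 1:
        return max(int(0.25 * sample_rate), 1)
    lag = lo + int(np.argmax(ac[lo:]))
    return max(int(0.25 * lag), 1)
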