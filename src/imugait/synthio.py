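"""Synthetic two-leg IMU gait generation with embedded ground truth.

The generator emulates the signals a five-IMU lower-limb setup produces
during cyclic locomotion: both legs run the same periodic waveforms half a
cycle out of phase, and each cycle carries three events per leg — heel
strike (HS), toe off (TO) and the hip-flexion maximum (HMax) — at known
cycle fractions, so every stream ships with an exact event timeline.

The waveforms are not biomechanical simulations; they are shaped purely so
that the detection rules have the right structure to find:

* foot gyro Z — one steep falling zero crossing per cycle exactly at HS,
  one sharp negative trough exactly at TO, a single positive swing peak,
  and a slightly negative plateau during stance (no other falling
  crossings);
* thigh gyro Z — a sinusoid phased so its falling zero crossing lands at
  HMax (the angular velocity of the thigh vanishes at the hip-angle
  maximum);
* the remaining 26 channels — smooth periodic textures plus gravity on the
  vertical accelerometer axes.

Ten motion states (standing SD, level walking LW, stairs US/DS, slopes
USL/DSL, turning TL/TR, steering LS/RS) are distinguished by per-state
channel gains and offsets: turning and steering bias the waist yaw rate,
stairs and slopes bias the waist accelerometer axes, and standing scales
all dynamics to near zero.  Offsets are several times the sensor noise so
the states are learnable by construction.

The printed per-trial sample-count tables of the motivating study (10 road
conditions x 25 trials; 6 gait phases x 25 trials of level walking) are
packaged as CSV fixtures and exposed via :func:`load_count_fixture`.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .events import EVENT_ORDER, EventTimeline, GaitEvent
from .streams import CHANNELS, ImuStream

#: The ten motion states (road conditions / locomotion modes).
MOTION_STATES: tuple[str, ...] = (
    "SD", "LW", "US", "DS", "USL", "DSL", "TL", "TR", "LS", "RS",
)

_DEFAULT_FRACTIONS = {"HS": 0.0, "TO": 0.60, "HMax": 0.85}


@dataclass
class GaitCycleSpec:
    """Geometry, timing and noise of one synthetic gait cycle.

    ``event_fractions`` place each leg's own HS/TO/HMax within its own
    cycle (fractions in [0, 1)); ``inter_leg_offset`` shifts the right leg
    relative to the left.  The induced global order of the six events must
    match the canonical chronology L-HS, R-TO, R-HMax, R-HS, L-TO, L-HMax.
    """

    cycle_period: float = 1.0
    event_fractions: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_FRACTIONS)
    )
    inter_leg_offset: float = 0.5
    noise_sigma_gyro: float = 0.05
    noise_sigma_acc: float = 0.1
    sample_rate: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cycle_period <= 0:
            raise ValueError("cycle_period must be positive")
        if self.sample_rate * self.cycle_period < 50:
            raise ValueError(
                "sample_rate * cycle_period must be >= 50 "
                "(need enough samples per cycle to place 6 events)"
            )
        if set(self.event_fractions) != {"HS", "TO", "HMax"}:
            raise ValueError("event_fractions must have exactly the keys HS, TO, HMax")
        for k, v in self.event_fractions.items():
            if not 0 <= v < 1:
                raise ValueError(f"event fraction {k}={v} must lie in [0, 1)")
        order = [lbl for lbl, _ in sorted(self.global_fractions().items(),
                                          key=lambda kv: kv[1])]
        if tuple(order) != EVENT_ORDER:
            raise ValueError(
                "event_fractions + inter_leg_offset induce the global order "
                f"{' -> '.join(order)}; required: {' -> '.join(EVENT_ORDER)}"
            )

    def global_fractions(self) -> dict[str, float]:
        """Cycle fraction of each of the six events on the global time axis
        (left-leg cycle convention)."""
        out = {}
        for kind, frac in self.event_fractions.items():
            out[f"L-{kind}"] = frac % 1.0
            out[f"R-{kind}"] = (frac + self.inter_leg_offset) % 1.0
        return out


@dataclass
class StateSignature:
    """How one motion state reshapes the base walking waveforms.

    ``channel_gain`` multiplies the dynamic (zero-mean) part of each
    channel; ``channel_offset`` adds a constant bias.  Static components
    (gravity on the vertical accelerometer axes) are unaffected by gain.
    """

    state: str
    channel_gain: dict[str, float] = field(default_factory=dict)
    channel_offset: dict[str, float] = field(default_factory=dict)
    default_gain: float = 1.0

    def gain(self, channel: str) -> float:
        return self.channel_gain.get(channel, self.default_gain)

    def offset(self, channel: str) -> float:
        return self.channel_offset.get(channel, 0.0)


def default_signatures() -> dict[str, StateSignature]:
    """Default per-state signatures.

    Offsets are placed on channels a physical intuition would suggest —
    waist yaw rate for turning/steering, waist accelerometer axes for
    stairs and slopes — and sized at 8 sigma or more of the corresponding
    sensor noise so every pair of states is separable.  Standing scales all
    dynamics to 1% (sensor noise dominates).
    """
    sig = {
        "SD": StateSignature("SD", default_gain=0.01),
        "LW": StateSignature("LW", channel_offset={"waist_ax": 0.35, "waist_ay": 0.35}),
        "US": StateSignature("US", channel_gain={"thigh_l_gz": 1.3, "thigh_r_gz": 1.3},
                             channel_offset={"waist_ay": 0.8}),
        "DS": StateSignature("DS", channel_gain={"thigh_l_gz": 0.8, "thigh_r_gz": 0.8},
                             channel_offset={"waist_ay": -0.8}),
        "USL": StateSignature("USL", channel_gain={"foot_l_gz": 1.15, "foot_r_gz": 1.15},
                              channel_offset={"waist_ax": 0.8}),
        "DSL": StateSignature("DSL", channel_gain={"foot_l_gz": 0.9, "foot_r_gz": 0.9},
                              channel_offset={"waist_ax": -0.8}),
        "TL": StateSignature("TL", channel_offset={"waist_gz": 1.5}),
        "TR": StateSignature("TR", channel_offset={"waist_gz": -1.5}),
        "LS": StateSignature("LS", channel_offset={"waist_gz": 0.7}),
        "RS": StateSignature("RS", channel_offset={"waist_gz": -0.7}),
    }
    return sig


# ---------------------------------------------------------------------------
# waveform construction
# ---------------------------------------------------------------------------

_SWING_TROUGH = -3.5   # rad/s, TO spike depth
_SWING_PEAK = 6.0      # rad/s, mid-swing peak
_STANCE_LEVEL = -0.25  # rad/s, slightly negative stance plateau
# Small post-HS dip: keeps the signal falling steeply through the HS zero
# crossing (sharp localization under noise) while staying below the TO
# detector's prominence threshold so it is never mistaken for a trough.
_POST_HS_DIP = -0.45
_THIGH_AMP = 4.0       # rad/s, thigh gyro amplitude
_GRAVITY = 9.81        # m/s^2


def _cos_blend(u, u0, u1, v0, v1):
    """Half-cosine interpolation from (u0, v0) to (u1, v1), flat at both ends."""
    s = (u - u0) / (u1 - u0)
    return v0 + (v1 - v0) * 0.5 * (1.0 - np.cos(np.pi * s))


def _foot_gyro_z(u: np.ndarray, u_to: float) -> np.ndarray:
    """Foot gyro Z over one cycle (u in [0, 1), HS at u = 0).

    Piecewise: steep post-HS descent, recovery to a negative stance
    plateau, a sharp V-notch with its cusp exactly at ``u_to``, a smooth
    rise through a single rising zero crossing to the swing peak, then a
    quarter-cosine descent hitting zero exactly at the next HS (u = 1)
    with a steep slope.  The only falling zero crossing is at HS and the
    only prominent trough at TO.
    """
    if not 0.25 <= u_to <= 0.8:
        raise ValueError(f"TO fraction {u_to} outside the supported range [0.25, 0.8]")
    w = min(0.05, 0.4 * (1.0 - u_to))           # V-notch half-width
    u_dip = min(0.025, u_to / 8)                # post-HS dip extent
    u_rec = 3 * u_dip                           # end of recovery to plateau
    u_pk = u_to + w + 0.5 * (1.0 - u_to - w)    # swing peak location
    out = np.empty_like(u)

    m = u < u_dip
    out[m] = _POST_HS_DIP * u[m] / u_dip
    m = (u >= u_dip) & (u < u_rec)
    out[m] = _cos_blend(u[m], u_dip, u_rec, _POST_HS_DIP, _STANCE_LEVEL)
    m = (u >= u_rec) & (u < u_to - w)
    out[m] = _STANCE_LEVEL
    m = (u >= u_to - w) & (u < u_to)            # V-notch, linear flanks
    out[m] = _STANCE_LEVEL + (_SWING_TROUGH - _STANCE_LEVEL) * (u[m] - (u_to - w)) / w
    m = (u >= u_to) & (u < u_to + w)
    out[m] = _SWING_TROUGH + (_STANCE_LEVEL - _SWING_TROUGH) * (u[m] - u_to) / w
    m = (u >= u_to + w) & (u < u_pk)
    out[m] = _cos_blend(u[m], u_to + w, u_pk, _STANCE_LEVEL, _SWING_PEAK)
    m = u >= u_pk
    out[m] = _SWING_PEAK * np.cos(0.5 * np.pi * (u[m] - u_pk) / (1.0 - u_pk))
    return out


def _thigh_gyro_z(u: np.ndarray, u_hmax: float) -> np.ndarray:
    """Thigh gyro Z: sinusoid whose falling zero crossing lies at u_hmax."""
    return _THIGH_AMP * np.sin(2 * np.pi * (u_hmax - u))


def _leg_channels(u: np.ndarray, spec: GaitCycleSpec) -> dict[str, np.ndarray]:
    """Dynamic waveforms for one leg's foot and thigh IMUs (own-leg phase u)."""
    two_pi = 2 * np.pi
    return {
        "foot_gz": _foot_gyro_z(u, spec.event_fractions["TO"]),
        "foot_gx": 0.8 * np.sin(two_pi * u + 0.4),
        "foot_gy": 0.5 * np.sin(2 * two_pi * u + 1.0),
        "foot_ax": 1.5 * np.sin(two_pi * u + 2.0),
        "foot_ay": 1.0 * np.sin(2 * two_pi * u + 0.3),
        "foot_az": 1.2 * np.sin(two_pi * u + 1.3),
        "thigh_gz": _thigh_gyro_z(u, spec.event_fractions["HMax"]),
        "thigh_gx": 0.6 * np.sin(two_pi * u + 0.9),
        "thigh_gy": 0.4 * np.sin(2 * two_pi * u + 2.1),
        "thigh_ax": 1.1 * np.sin(two_pi * u + 0.7),
        "thigh_ay": 0.7 * np.sin(2 * two_pi * u + 1.6),
        "thigh_az": 0.9 * np.sin(two_pi * u + 2.8),
    }


def _waist_channels(u: np.ndarray) -> dict[str, np.ndarray]:
    """Dynamic waist IMU waveforms (left-leg phase convention)."""
    two_pi = 2 * np.pi
    return {
        "waist_gx": 0.25 * np.sin(two_pi * u + 0.2),
        "waist_gy": 0.30 * np.sin(2 * two_pi * u + 1.1),
        "waist_gz": 0.15 * np.sin(two_pi * u + 2.4),
        "waist_ax": 0.8 * np.sin(2 * two_pi * u + 0.5),
        "waist_ay": 0.6 * np.sin(2 * two_pi * u + 1.9),
        "waist_az": 0.9 * np.sin(2 * two_pi * u + 0.8),
    }


#: Constant (gravity) component per channel, unaffected by state gain.
_STATIC = {"waist_az": _GRAVITY, "thigh_l_az": _GRAVITY, "thigh_r_az": _GRAVITY,
           "foot_l_az": _GRAVITY, "foot_r_az": _GRAVITY}


def generate_cycle(
    spec: GaitCycleSpec,
    n_cycles: int,
    signature: StateSignature | None = None,
) -> tuple[ImuStream, EventTimeline]:
    """Generate ``n_cycles`` of two-leg gait plus the ground-truth timeline.

    The stream has exactly ``round(n_cycles * cycle_period * sample_rate)``
    samples.  Each leg's foot gyro Z crosses zero falling exactly at its HS
    truth indices and has its trough at its TO truth indices; the thigh
    gyro Z crosses zero falling at HMax.  The timeline holds ``6 *
    n_cycles`` events in the canonical chronology.  Output is a pure
    function of ``(spec, n_cycles, signature)`` — identical seeds give
    bit-identical streams.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if signature is None:
        signature = StateSignature("LW")
    rate, period = spec.sample_rate, spec.cycle_period
    n_samples = int(round(n_cycles * period * rate))
    t = np.arange(n_samples) / rate
    u_left = (t / period) % 1.0
    u_right = (t / period - spec.inter_leg_offset) % 1.0

    dynamics: dict[str, np.ndarray] = {}
    for side, u in (("l", u_left), ("r", u_right)):
        for name, wave in _leg_channels(u, spec).items():
            sensor, axis = name.split("_")
            dynamics[f"{sensor}_{side}_{axis}"] = wave
    dynamics.update(_waist_channels(u_left))

    rng = np.random.default_rng(spec.seed)
    data = np.empty((n_samples, len(CHANNELS)))
    for j, ch in enumerate(CHANNELS):
        sigma = spec.noise_sigma_gyro if ch.split("_")[-1].startswith("g") else spec.noise_sigma_acc
        col = (
            _STATIC.get(ch, 0.0)
            + signature.gain(ch) * dynamics[ch]
            + signature.offset(ch)
        )
        if sigma > 0:
            col = col + rng.normal(0.0, sigma, n_samples)
        data[:, j] = col

    events = []
    for label, gf in spec.global_fractions().items():
        side, kind = label.split("-")
        for c in range(n_cycles):
            idx = int(round((c + gf) * period * rate))
            if 0 <= idx < n_samples:
                events.append(GaitEvent(idx, side, kind))
    timeline = EventTimeline(events)
    return ImuStream(data, sample_rate=rate), timeline


# ---------------------------------------------------------------------------
# labeled datasets
# ---------------------------------------------------------------------------


@dataclass
class LabeledDataset:
    """Streams with per-sample state labels, event truth and subject ids."""

    streams: list[ImuStream]
    state_labels: list[np.ndarray]
    event_truth: list[EventTimeline]
    subject_ids: list[int]
    states: list[str]

    def __post_init__(self) -> None:
        n = len(self.streams)
        for lst in (self.state_labels, self.event_truth, self.subject_ids, self.states):
            if len(lst) != n:
                raise ValueError("all per-stream lists must have equal length")
        for s, lab, tl in zip(self.streams, self.state_labels, self.event_truth):
            if len(lab) != s.n_samples:
                raise ValueError("every stream needs exactly one state label per sample")
            if len(tl) and tl.events[-1].sample_index >= s.n_samples:
                raise ValueError("event truth indices must lie within stream bounds")

    def __len__(self) -> int:
        return len(self.streams)

    def sample_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Concatenate all streams into (X, y_state, subject) sample arrays."""
        X = np.vstack([s.data for s in self.streams])
        y = np.concatenate(self.state_labels)
        g = np.concatenate(
            [np.full(s.n_samples, sid) for s, sid in zip(self.streams, self.subject_ids)]
        )
        return X, y, g


def _stream_seed(base_seed: int, subject: int, state_index: int) -> int:
    """Counter scheme for per-stream seeds: reproducible for any subset."""
    return (int(base_seed) + 100_000 * int(subject) + 1_000 * int(state_index)) % (2**31)


def generate_dataset(
    states: list[str] | tuple[str, ...] = MOTION_STATES,
    n_subjects: int = 5,
    cycles_per_state: int = 10,
    seed: int = 0,
    spec: GaitCycleSpec | None = None,
    signatures: dict[str, StateSignature] | None = None,
) -> LabeledDataset:
    """One stream per (subject, state) with signatures, labels and truth.

    Subjects differ by a multiplicative jitter of up to +/-10% on the cycle
    period and on all channel gains, drawn from a per-subject RNG; each
    stream's noise realization uses a seed derived from ``seed`` by a fixed
    counter scheme (``seed + 100000*subject + 1000*state_index``), so any
    subset of subjects/states is reproducible in isolation.
    """
    unknown = [s for s in states if s not in MOTION_STATES]
    if unknown:
        raise ValueError(f"unknown states {unknown}; valid states: {list(MOTION_STATES)}")
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if spec is None:
        spec = GaitCycleSpec(seed=seed)
    if signatures is None:
        signatures = default_signatures()

    streams, labels, truths, subjects, state_names = [], [], [], [], []
    for subj in range(n_subjects):
        subj_rng = np.random.default_rng(_stream_seed(seed, subj, 999))
        period_jitter = 1.0 + subj_rng.uniform(-0.1, 0.1)
        gain_jitter = 1.0 + subj_rng.uniform(-0.1, 0.1)
        for s in states:
            si = MOTION_STATES.index(s)
            base = signatures[s]
            sig = StateSignature(
                state=s,
                channel_gain={c: g * gain_jitter for c, g in base.channel_gain.items()},
                channel_offset=dict(base.channel_offset),
                default_gain=base.default_gain * gain_jitter,
            )
            sspec = replace(
                spec,
                cycle_period=spec.cycle_period * period_jitter,
                seed=_stream_seed(seed, subj, si),
            )
            stream, truth = generate_cycle(sspec, cycles_per_state, sig)
            streams.append(stream)
            labels.append(np.full(stream.n_samples, s, dtype=object))
            truths.append(truth)
            subjects.append(subj)
            state_names.append(s)
    return LabeledDataset(streams, labels, truths, subjects, state_names)


# ---------------------------------------------------------------------------
# printed-table fixtures
# ---------------------------------------------------------------------------


@dataclass
class CountFixture:
    """A packaged per-trial sample-count grid (25 trials x N columns)."""

    table_id: str
    counts: pd.DataFrame

    @property
    def column_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())


_FIXTURE_FILES = {"table1": "table1.csv", "table2": "table2.csv"}


def load_count_fixture(table_id: str) -> CountFixture:
    """Load one of the packaged per-trial count grids.

    ``table1`` holds the 25 x 10 per-trial sample counts across the ten
    road conditions; ``table2`` the 25 x 7 level-walking gait-phase counts
    (first column: total LW samples per trial).  Cells reproduce the
    printed source grids exactly; all counts are positive integers.
    """
    if table_id not in _FIXTURE_FILES:
        raise KeyError(f"unknown table_id {table_id!r}; expected one of {sorted(_FIXTURE_FILES)}")
    ref = importlib.resources.files("imugait.data") / _FIXTURE_FILES[table_id]
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, index_col="trial")
    if (df.to_numpy() <= 0).any():
        raise ValueError(f"{table_id} fixture contains non-positive counts")
    return CountFixture(table_id, df)


def load_confusion_fixture(table_id: str) -> pd.DataFrame:
    """Load a packaged reference confusion matrix (``table4``: motion states,
    ``table6``: gait phases).  Rows are predicted classes, columns true
    classes; columns are normalized to sum to 1 at printed precision."""
    if table_id not in {"table4", "table6"}:
        raise KeyError(f"unknown table_id {table_id!r}; expected 'table4' or 'table6'")
    ref = importlib.resources.files("imugait.data") / f"{table_id}.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, index_col="pred")
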