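"""Multichannel IMU stream container and CSV round-tripping.

The sensor set is five body-worn IMUs — waist, left/right thigh, left/right
foot — each contributing a 3-axis gyroscope (rad/s) and a 3-axis
accelerometer (m/s^2), for 30 channels total sampled at a common rate
(200 Hz by default).  Channel names follow ``<sensor>_<axis>`` with axes
``gx, gy, gz`` (angular velocity) and ``ax, ay, az`` (specific force).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SENSORS: tuple[str, ...] = ("waist", "thigh_l", "thigh_r", "foot_l", "foot_r")
AXES: tuple[str, ...] = ("gx", "gy", "gz", "ax", "ay", "az")

#: Canonical 30-channel order used everywhere in the package.
CHANNELS: tuple[str, ...] = tuple(f"{s}_{a}" for s in SENSORS for a in AXES)

N_CHANNELS = len(CHANNELS)

GYRO_CHANNELS: tuple[str, ...] = tuple(
    c for c in CHANNELS if c.split("_")[-1].startswith("g")
)


@dataclass
class ImuStream:
    """A uniformly sampled 30-channel inertial record of one walking bout.

    Parameters
    ----------
    data
        Array of shape ``(n_samples, 30)`` in the canonical channel order.
    sample_rate
        Sampling frequency in Hz.
    channels
        Channel names; defaults to the canonical order.
    """

    data: np.ndarray
    sample_rate: float = 200.0
    channels: tuple[str, ...] = field(default=CHANNELS)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("ImuStream data must be 2-D (n_samples, n_channels)")
        if self.data.shape[1] != len(self.channels):
            raise ValueError(
                f"data has {self.data.shape[1]} columns but "
                f"{len(self.channels)} channel names were given"
            )
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    def channel(self, name: str) -> np.ndarray:
        """Return one channel by name as a 1-D view."""
        try:
            idx = self.channels.index(name)
        except ValueError:
            raise KeyError(
                f"unknown channel {name!r}; expected one of {list(self.channels)}"
            ) from None
        return self.data[:, idx]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.data, columns=list(self.channels))
        df.insert(0, "time_s", self.times)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ImuStream":
        if "time_s" not in df.columns:
            raise ValueError("stream frame must contain a 'time_s' column")
        missing = [c for c in CHANNELS if c not in df.columns]
        if missing:
            raise ValueError(f"stream frame is missing channels: {missing}")
        t = df["time_s"].to_numpy()
        if len(t) < 2:
            rate = 200.0
        else:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise ValueError("time_s must be strictly increasing")
            rate = 1.0 / float(np.median(dt))
        # reorder columns to canonical order regardless of file order
        return cls(df[list(CHANNELS)].to_numpy(dtype=float), sample_rate=rate)

    @classmethod
    def from_csv(cls, path) -> "ImuStream":
        return cls.from_frame(pd.read_csv(path))
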