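"""Core data containers for tremor accelerometry.

An :class:`AccelRecord` is one uniformly sampled hand-acceleration recording,
taken either with the hands resting on the lap (``rest``) or with the arms
extended anteriorly at shoulder level (``postural``), on one side (``R``/``L``).
The recording device is a biaxial micro-accelerometer, so a record carries one
or two acceleration axes in m/s².
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Analysis band of interest, Hz (inclusive at both edges).
BAND: tuple[float, float] = (0.9, 15.0)

CONDITIONS: tuple[str, ...] = ("rest", "postural")
SIDES: tuple[str, ...] = ("R", "L")
GROUPS: tuple[str, ...] = ("WELDER", "IPD", "ET")

#: Minimum record length in seconds for stable spectral summaries.
MIN_DURATION_S: float = 8.0


@dataclass(frozen=True)
class SignalSpec:
    """Acquisition settings for simulated recordings.

    The band of interest extends to 15 Hz; the default 128 Hz sampling gives
    more than 8x oversampling of the band top, and 16 s with 4-s Welch
    segments gives a 0.25 Hz spectral grid.
    """

    sampling_rate: float = 128.0
    duration: float = 16.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.sampling_rate) or self.sampling_rate < 64.0:
            raise ValueError(
                f"sampling_rate must be >= 64 Hz, got {self.sampling_rate}"
            )
        if not np.isfinite(self.duration) or self.duration < MIN_DURATION_S:
            raise ValueError(
                f"duration must be >= {MIN_DURATION_S} s, got {self.duration}"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.sampling_rate * self.duration))


@dataclass
class AccelRecord:
    """A uniformly sampled acceleration signal with condition/side labels.

    ``data`` has shape (n_samples, n_axes) with n_axes in {1, 2}, in m/s².
    """

    data: np.ndarray
    sampling_rate: float
    subject_id: str = ""
    condition: str = "rest"
    side: str = "R"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        if arr.ndim != 2 or arr.shape[1] not in (1, 2):
            raise ValueError(f"data must be (n, 1) or (n, 2), got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("data contains non-finite samples")
        if self.sampling_rate <= 0 or not np.isfinite(self.sampling_rate):
            raise ValueError(f"invalid sampling_rate {self.sampling_rate}")
        if arr.shape[0] / self.sampling_rate < MIN_DURATION_S:
            raise ValueError(
                f"record holds {arr.shape[0] / self.sampling_rate:.2f} s of data; "
                f"at least {MIN_DURATION_S} s are required"
            )
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")
        self.data = arr

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_axes(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate


class UndefinedMetricError(ValueError):
    """Raised when a spectral summary is undefined (e.g. zero band power)."""
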