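"""In-memory containers for bio-logger recordings.

A :class:`SensorRecording` mirrors what a tag writes: tri-axial acceleration
and angular velocity at 20 Hz, pressure natively at 1 Hz, and a per-timestep
behavior label (or UNLABELED).  A :class:`PreprocessedRecording` is what the
networks consume: a dense ``nb_desc x N`` channel matrix (pressure replaced by
its upsampled first difference), labels with no unlabeled samples left, and
the positions where unlabeled stretches were excised so that windowing never
spans a cut.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .behaviors import UNLABELED


@dataclass
class SensorRecording:
    """One individual's raw, time-aligned multi-sensor series."""

    individual_id: str
    acc: np.ndarray  # (N, 3) in g
    gyro: np.ndarray  # (N, 3) in deg/s
    pressure_1hz: np.ndarray  # (N // 20,) relative units, 1 Hz
    labels: np.ndarray  # (N,) int, Behavior code or UNLABELED
    sample_rate: float = 20.0

    def __post_init__(self) -> None:
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        self.pressure_1hz = np.asarray(self.pressure_1hz, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        n = len(self.labels)
        if self.acc.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise ValueError("acc/gyro must be (N, 3) matching labels length")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def n_samples(self) -> int:
        return len(self.labels)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate


@dataclass
class LabelTrack:
    """Behavior annotation as (start_s, end_s, code) intervals, 0.1 s precision.

    Intervals are half-open ``[start, end)``; a sample exactly on a shared
    boundary belongs to the later interval.
    """

    intervals: list[tuple[float, float, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ivs = sorted(self.intervals, key=lambda iv: iv[0])
        for start, end, _ in ivs:
            if not end > start:
                raise ValueError(f"interval ({start}, {end}) has non-positive length")
        for (s0, e0, _), (s1, _, _) in zip(ivs, ivs[1:]):
            if s1 < e0 - 1e-9:
                raise AnnotationError(
                    f"overlapping intervals: ({s0}, {e0}) and starting {s1}"
                )
        self.intervals = ivs


class AnnotationError(ValueError):
    """Raised for overlapping or otherwise inconsistent label intervals."""


@dataclass
class PreprocessedRecording:
    """Network-ready channels and labels with unlabeled stretches excised.

    ``cuts`` holds indices *into the kept array*: a cut at position c means
    samples c-1 and c were not contiguous in the raw recording.
    """

    individual_id: str
    X: np.ndarray  # (nb_desc, N) float
    y: np.ndarray  # (N,) int, no UNLABELED
    cuts: np.ndarray  # strictly increasing, each in (0, N)
    sample_rate: float = 20.0
    channel_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.X = np.ascontiguousarray(self.X, dtype=np.float32)
        self.y = np.asarray(self.y, dtype=np.int64)
        self.cuts = np.asarray(self.cuts, dtype=np.int64)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.y):
            raise ValueError("X must be (nb_desc, N) with N = len(y)")
        if np.any(self.y == UNLABELED):
            raise ValueError("preprocessed labels may not contain UNLABELED")
        if len(self.cuts) and (
            np.any(np.diff(self.cuts) <= 0)
            or self.cuts[0] <= 0
            or self.cuts[-1] >= len(self.y)
        ):
            raise ValueError("cuts must be strictly increasing interior positions")

    @property
    def n_samples(self) -> int:
        return len(self.y)

    @property
    def nb_desc(self) -> int:
        return self.X.shape[0]

    def segments(self) -> list[tuple[int, int]]:
        """Contiguous [start, end) index ranges between excision cuts."""
        bounds = [0, *self.cuts.tolist(), self.n_samples]
        return [(a, b) for a, b in zip(bounds, bounds[1:]) if b > a]
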