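"""Reading, writing and preprocessing of bio-logger recordings.

File dialect: one delimited text file per individual, one row per 20 Hz
timestep with columns ``time_s, ax, ay, az, gx, gy, gz, pressure, label``.
Pressure is natively 1 Hz, so the pressure cell is filled only on
integer-second rows and empty elsewhere; labels are behavior names with
``UNLABELED`` marking un-annotated samples.

Preprocessing follows the tag pipeline: the 1 Hz pressure series is
first-differenced and linearly upsampled to 20 Hz, behavior intervals are
mapped onto the 20 Hz grid, and unlabeled stretches (e.g. night sequences
with no video) are excised with their cut positions retained so windowing
never spans an excision.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .behaviors import CODE_TO_NAME, NAME_TO_CODE, UNLABELED
from .records import AnnotationError, LabelTrack, PreprocessedRecording, SensorRecording

COLUMNS = ["time_s", "ax", "ay", "az", "gx", "gy", "gz", "pressure", "label"]

CHANNEL_NAMES_7 = ("ax", "ay", "az", "gx", "gy", "gz", "pdiff")
CHANNEL_NAMES_6 = ("ax", "ay", "az", "gx", "gy", "gz")


class SchemaError(ValueError):
    """File structure does not match the expected dialect."""


class DataError(ValueError):
    """File parses but the data violate a precondition (with row numbers)."""


class EmptyRecordingError(ValueError):
    """No labeled samples remain after preprocessing."""


def write_recording(rec: SensorRecording, path: str | Path) -> Path:
    """Write one recording in the standard dialect (CSV)."""
    path = Path(path)
    n = rec.n_samples
    pressure = np.full(n, np.nan)
    idx = np.arange(len(rec.pressure_1hz)) * 20
    idx = idx[idx < n]
    pressure[idx] = rec.pressure_1hz[: len(idx)]
    df = pd.DataFrame({
        "time_s": np.arange(n) / rec.sample_rate,
        "ax": rec.acc[:, 0], "ay": rec.acc[:, 1], "az": rec.acc[:, 2],
        "gx": rec.gyro[:, 0], "gy": rec.gyro[:, 1], "gz": rec.gyro[:, 2],
        "pressure": pressure,
        "label": [CODE_TO_NAME[int(c)] for c in rec.labels],
    })
    # full repr precision so write -> read round-trips exactly
    df.to_csv(path, index=False)
    return path


def read_recording(path: str | Path, individual_id: str | None = None
                   ) -> SensorRecording:
    """Read a recording written in the standard dialect.

    Raises :class:`SchemaError` for missing columns or an empty file and
    :class:`DataError` (naming the offending row) for non-monotonic time or
    unknown labels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise SchemaError(f"{path}: no data rows")

    t = df["time_s"].to_numpy(float)
    bad = np.flatnonzero(np.diff(t) <= 0)
    if len(bad):
        raise DataError(
            f"{path}: non-monotonic time_s at data row {int(bad[0]) + 2} "
            f"(t={t[bad[0] + 1]!r} after t={t[bad[0]]!r})")

    unknown = [i for i, name in enumerate(df["label"]) if name not in NAME_TO_CODE]
    if unknown:
        raise DataError(f"{path}: unknown label at data row {unknown[0] + 2}")
    labels = np.array([NAME_TO_CODE[name] for name in df["label"]], dtype=np.int64)

    pressure = df["pressure"].to_numpy(float)
    p_idx = np.flatnonzero(~np.isnan(pressure))
    return SensorRecording(
        individual_id=individual_id or path.stem,
        acc=df[["ax", "ay", "az"]].to_numpy(float),
        gyro=df[["gx", "gy", "gz"]].to_numpy(float),
        pressure_1hz=pressure[p_idx],
        labels=labels,
    )


def pressure_to_diff_20hz(pressure_1hz: np.ndarray, rate: int = 20) -> np.ndarray:
    """First-difference the 1 Hz pressure, then upsample linearly to 20 Hz.

    Each difference ``d[i] = p[i+1] - p[i]`` is anchored at the end of its
    interval (second ``i+1``); the 20 Hz series interpolates linearly between
    anchors and holds the first/last difference constant over the boundary
    seconds, so the output has ``rate * len(pressure_1hz)`` samples and stays
    aligned with the other channels.
    """
    p = np.asarray(pressure_1hz, dtype=float)
    if p.ndim != 1 or len(p) < 2:
        raise ValueError("pressure series must be 1-D with at least 2 samples")
    d = np.diff(p)  # value at seconds 1 .. len(p)-1
    t_out = np.arange(rate * len(p)) / rate
    return np.interp(t_out, np.arange(1, len(p)), d)


def apply_labels(rec: SensorRecording, track: LabelTrack) -> SensorRecording:
    """Map annotation intervals onto the 20 Hz grid.

    Each sample takes the class of the half-open interval [start, end)
    containing its timestamp; samples in no interval become UNLABELED.
    Returns a new recording; the input is unchanged.
    """
    n = rec.n_samples
    t_end = n / rec.sample_rate
    for start, end, _ in track.intervals:
        if start < -1e-9 or end > t_end + 1e-9:
            raise AnnotationError(
                f"interval ({start}, {end}) outside recording span [0, {t_end})")
    labels = np.full(n, UNLABELED, dtype=np.int64)
    t = np.arange(n) / rec.sample_rate
    for start, end, code in track.intervals:
        labels[(t >= start - 1e-9) & (t < end - 1e-9)] = code
    out = SensorRecording(individual_id=rec.individual_id, acc=rec.acc.copy(),
                          gyro=rec.gyro.copy(), pressure_1hz=rec.pressure_1hz.copy(),
                          labels=labels, sample_rate=rec.sample_rate)
    return out


def channel_matrix(rec: SensorRecording, include_pressure: bool = True
                   ) -> np.ndarray:
    """Stack the network input channels as an (nb_desc, N) matrix."""
    parts = [rec.acc.T, rec.gyro.T]
    if include_pressure:
        pdiff = pressure_to_diff_20hz(rec.pressure_1hz)
        n = rec.n_samples
        if len(pdiff) < n:  # recording a fraction of a second longer
            pdiff = np.concatenate([pdiff, np.full(n - len(pdiff), pdiff[-1])])
        parts.append(pdiff[None, :n])
    return np.vstack(parts)


def drop_unlabeled(X: np.ndarray, labels: np.ndarray, individual_id: str = "",
                   sample_rate: float = 20.0,
                   channel_names: tuple[str, ...] = ()) -> PreprocessedRecording:
    """Excise contiguous UNLABELED runs, recording the cut positions.

    Cut positions index the *kept* array: a cut at c means kept samples c-1
    and c were not adjacent in the original series.
    """
    labels = np.asarray(labels)
    keep = labels != UNLABELED
    if not np.any(keep):
        raise EmptyRecordingError(f"{individual_id or 'recording'}: fully unlabeled")
    kept_idx = np.flatnonzero(keep)
    # a cut wherever consecutive kept samples were non-adjacent originally
    cuts = np.flatnonzero(np.diff(kept_idx) > 1) + 1
    return PreprocessedRecording(
        individual_id=individual_id, X=np.asarray(X)[:, keep], y=labels[keep],
        cuts=cuts, sample_rate=sample_rate, channel_names=channel_names)


def preprocess(rec: SensorRecording, include_pressure: bool = True
               ) -> PreprocessedRecording:
    """Full preprocessing: pressure diff+upsample, channel stack, gap excision."""
    X = channel_matrix(rec, include_pressure=include_pressure)
    names = CHANNEL_NAMES_7 if include_pressure else CHANNEL_NAMES_6
    return drop_unlabeled(X, rec.labels, individual_id=rec.individual_id,
                          sample_rate=rec.sample_rate, channel_names=names)
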