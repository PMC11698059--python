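"""Balanced training windows, overlapped test windows, and reassembly.

Training uses a class-balancing generator: it cycles round-robin over the
behavior classes and, for each turn, picks a uniformly random onset (run
start) of that class and places a fixed-length window uniformly at random
among the positions containing that onset.  Minority classes are thereby
over-represented relative to their share of recording time, which is what a
heavily imbalanced ethogram needs.

Evaluation slices each full recording into consecutive windows with a fixed
fractional overlap (default 10%); a final window is right-aligned to the end
so that every sample is covered, and per-window class probabilities are
reassembled into a full-length track by averaging over covering windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .records import PreprocessedRecording

logger = logging.getLogger(__name__)


class InfeasibleWindowError(ValueError):
    """No recording segment is long enough to host a window."""


class ReassemblyError(ValueError):
    """The window layout leaves samples uncovered."""


@dataclass
class WindowPlan:
    """Window sizing and per-epoch counts.

    ws                window size in samples (40 s at 20 Hz = 800)
    overlap_fraction  shared fraction of consecutive *test* windows
    n_train/n_val     windows generated per epoch / fixed validation windows
    """

    ws: int
    overlap_fraction: float = 0.1
    n_train: int = 6000
    n_val: int = 3000

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.ws < 1:
            raise ValueError("ws must be >= 1")

    @property
    def stride(self) -> int:
        return int(round(self.ws * (1.0 - self.overlap_fraction)))


@dataclass
class WindowBatch:
    """Fixed-length channel x time windows with per-timestep one-hot targets."""

    inputs: np.ndarray  # (n, nb_desc, ws) float32, raw sensor units
    targets: np.ndarray  # (n, ws, nb_classes) float32 one-hot
    provenance: list[tuple[str, int]] = field(default_factory=list)
    anchor_classes: np.ndarray | None = None  # balancing anchor per window

    def __len__(self) -> int:
        return self.inputs.shape[0]

    @property
    def ws(self) -> int:
        return self.inputs.shape[2]


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((len(labels), n_classes), dtype=np.float32)
    out[np.arange(len(labels)), labels] = 1.0
    return out


def _class_runs(rec: PreprocessedRecording) -> list[tuple[int, int, int, int, int]]:
    """(onset, run_end, class, seg_start, seg_end) for every label run."""
    runs = []
    for a, b in rec.segments():
        y = rec.y[a:b]
        starts = np.flatnonzero(np.diff(y) != 0) + 1
        starts = np.concatenate([[0], starts, [b - a]])
        for s, e in zip(starts, starts[1:]):
            runs.append((a + int(s), a + int(e), int(y[s]), a, b))
    return runs


def generate_balanced_windows(recordings: list[PreprocessedRecording],
                              plan: WindowPlan,
                              rng_seed: int | np.random.Generator,
                              n_windows: int | None = None,
                              n_classes: int | None = None) -> WindowBatch:
    """Emit exactly ``n_windows`` class-balanced training windows.

    Round-robin over classes present in the recordings; classes absent from
    every recording (or never placeable) are dropped with a logged warning
    and their quota redistributed over the remaining classes.
    """
    rng = np.random.default_rng(rng_seed)
    ws = plan.ws
    n_windows = plan.n_train if n_windows is None else n_windows

    runs_by_class: dict[int, list[tuple[int, int, int, int, int, int]]] = {}
    for ri, rec in enumerate(recordings):
        for onset, run_end, cls, seg_a, seg_b in _class_runs(rec):
            lo = max(seg_a, onset - ws + 1)
            hi = min(onset, seg_b - ws)  # inclusive upper start bound
            if hi >= lo:
                runs_by_class.setdefault(cls, []).append(
                    (ri, onset, run_end, seg_a, seg_b, lo))
    if not runs_by_class:
        raise InfeasibleWindowError(
            f"no recording segment is at least {ws} samples long")

    all_classes = sorted({int(c) for rec in recordings for c in np.unique(rec.y)})
    dropped = [c for c in all_classes if c not in runs_by_class]
    if dropped:
        logger.warning(
            "classes %s have no placeable windows; quota redistributed", dropped)
    classes = sorted(runs_by_class)
    if n_classes is None:
        n_classes = max(int(rec.y.max()) for rec in recordings) + 1

    inputs = np.empty((n_windows, recordings[0].nb_desc, ws), dtype=np.float32)
    targets = np.empty((n_windows, ws, n_classes), dtype=np.float32)
    provenance: list[tuple[str, int]] = []
    anchors = np.empty(n_windows, dtype=np.int64)

    for i in range(n_windows):
        cls = classes[i % len(classes)]
        ri, onset, _run_end, seg_a, seg_b, lo = runs_by_class[cls][
            int(rng.integers(len(runs_by_class[cls])))]
        hi = min(onset, seg_b - ws)
        start = int(rng.integers(lo, hi + 1))
        rec = recordings[ri]
        inputs[i] = rec.X[:, start:start + ws]
        targets[i] = one_hot(rec.y[start:start + ws], n_classes)
        provenance.append((rec.individual_id, start))
        anchors[i] = cls

    return WindowBatch(inputs=inputs, targets=targets, provenance=provenance,
                       anchor_classes=anchors)


def segment_test_windows(rec: PreprocessedRecording, ws: int,
                         overlap_fraction: float = 0.1,
                         n_classes: int | None = None
                         ) -> tuple[WindowBatch, np.ndarray]:
    """Consecutive overlapped windows covering every sample of a recording.

    Windows never span an excision cut; within each contiguous segment the
    stride is ``round(ws * (1 - overlap))`` and a final window is
    right-aligned to the segment end.  Returns the batch plus window starts.
    """
    stride = int(round(ws * (1.0 - overlap_fraction)))
    starts: list[int] = []
    for a, b in rec.segments():
        if b - a < ws:
            raise InfeasibleWindowError(
                f"{rec.individual_id}: segment [{a}, {b}) shorter than ws={ws}")
        seg_starts = list(range(a, b - ws + 1, stride))
        if seg_starts[-1] != b - ws:
            seg_starts.append(b - ws)
        starts.extend(seg_starts)
    starts_arr = np.array(starts, dtype=np.int64)

    if n_classes is None:
        n_classes = int(rec.y.max()) + 1
    inputs = np.empty((len(starts_arr), rec.nb_desc, ws), dtype=np.float32)
    targets = np.empty((len(starts_arr), ws, n_classes), dtype=np.float32)
    for i, s in enumerate(starts_arr):
        inputs[i] = rec.X[:, s:s + ws]
        targets[i] = one_hot(rec.y[s:s + ws], n_classes)
    batch = WindowBatch(inputs=inputs, targets=targets,
                        provenance=[(rec.individual_id, int(s)) for s in starts_arr])
    return batch, starts_arr


def reassemble_predictions(window_probs: np.ndarray, starts: np.ndarray,
                           total_length: int) -> np.ndarray:
    """Average per-window class probabilities into a full-length track.

    Every sample must be covered by at least one window; overlapping windows
    contribute the unweighted mean, which keeps each timestep's output a
    probability distribution.
    """
    n_win, ws, n_classes = window_probs.shape
    if len(starts) != n_win:
        raise ValueError("starts length must match number of windows")
    acc = np.zeros((total_length, n_classes), dtype=np.float64)
    count = np.zeros(total_length, dtype=np.int64)
    for probs, s in zip(window_probs, starts):
        acc[s:s + ws] += probs
        count[s:s + ws] += 1
    uncovered = np.flatnonzero(count == 0)
    if len(uncovered):
        raise ReassemblyError(
            f"coverage gap: sample {int(uncovered[0])} "
            f"({len(uncovered)} uncovered of {total_length})")
    return acc / count[:, None]
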