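"""Stimulus-locked segmentation and baseline correction.

Trials are cut with half-open sample windows
``[round(onset + a*fs), round(onset + b*fs))`` so that a 10 s window at
10 Hz is exactly 100 samples.  Segmentation keeps the instruction-phase
context (default -2..0 s) so that :func:`baseline_correct` can subtract
the per-trial, per-channel instruction mean before trimming to the task
window.  The same code path serves EEG and hemoglobin epochs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .errors import OutOfBoundsError, ShapeError

__all__ = ["EpochSet", "segment", "segment_array", "baseline_correct"]


@dataclass
class EpochSet:
    """Trials x channels x samples array aligned to stimulus onset."""

    data: np.ndarray
    fs: float
    t0: float                 # time of first sample relative to onset, s
    labels: np.ndarray        # per-trial class in {1, 2}
    channel_ids: list[str]
    modality: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.data.ndim != 3:
            raise ShapeError("data must be trials x channels x samples")
        if len(self.labels) != self.data.shape[0]:
            raise ShapeError("one label per trial required")
        if len(np.unique(self.labels)) > 2:
            raise ShapeError("labels must take at most 2 distinct values")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def replace(self, **kw) -> "EpochSet":
        return dataclasses.replace(self, **kw)


def segment_array(data, fs, markers, window=(0.0, 10.0), context=(-2.0, 10.0),
                  channel_ids=None, modality="") -> EpochSet:
    """Cut a channels x samples array into marker-locked epochs.

    ``context`` (which must contain ``window``) is the span actually
    extracted, so baseline samples remain available; trials are ordered by
    onset.  A marker whose context window leaves the recording raises
    :class:`OutOfBoundsError` naming the marker.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ShapeError("data must be channels x samples")
    a, b = context
    if not (a <= window[0] < window[1] <= b):
        raise ValueError(f"context {context} must contain window {window}")
    off_a, off_b = round(a * fs), round(b * fs)
    n = data.shape[1]

    ordered = sorted(markers, key=lambda m: m.onset)
    trials, labels = [], []
    for i, m in enumerate(ordered):
        start, stop = m.onset + off_a, m.onset + off_b
        if start < 0 or stop > n:
            raise OutOfBoundsError(
                f"marker {i} (onset sample {m.onset}) needs samples "
                f"[{start}, {stop}) outside the recording of length {n}"
            )
        trials.append(data[:, start:stop])
        labels.append(m.label)
    if channel_ids is None:
        channel_ids = [f"ch{c + 1}" for c in range(data.shape[0])]
    return EpochSet(
        data=np.stack(trials, axis=0) if trials else
        np.empty((0, data.shape[0], off_b - off_a)),
        fs=fs, t0=a, labels=np.asarray(labels, dtype=int),
        channel_ids=list(channel_ids), modality=modality,
    )


def segment(recording, window=(0.0, 10.0), context=(-2.0, 10.0)):
    """Segment a recording object into an :class:`EpochSet`.

    Accepts a raw recording (``.data``/``.fs``/``.markers``) and returns
    one epoch set; for a hemoglobin recording (``.hbo``/``.hbr``) returns
    an ``(hbo_epochs, hbr_epochs)`` pair.
    """
    if hasattr(recording, "hbo"):
        ids = [f"NIRS{p:02d}" for p in recording.pair_ids]
        return (
            segment_array(recording.hbo, recording.fs, recording.markers,
                          window, context, ids, "hbo"),
            segment_array(recording.hbr, recording.fs, recording.markers,
                          window, context, ids, "hbr"),
        )
    ids = [c.id for c in recording.channels]
    modality = recording.channels[0].modality if recording.channels else ""
    return segment_array(recording.data, recording.fs, recording.markers,
                         window, context, ids, modality)


def baseline_correct(epochs: EpochSet, baseline=(-2.0, 0.0),
                     task_window=(0.0, None)) -> EpochSet:
    """Subtract the per-trial, per-channel baseline mean; trim to the task.

    The baseline window (default the -2..0 s instruction phase) must lie
    within the retained context; afterwards epochs are trimmed to
    ``task_window`` (default 0 s to the end), so calling this twice raises
    because the baseline context is gone.
    """
    b0, b1 = baseline
    fs = epochs.fs
    i0 = round((b0 - epochs.t0) * fs)
    i1 = round((b1 - epochs.t0) * fs)
    if i0 < 0 or i1 > epochs.n_samples or i1 <= i0:
        raise ValueError(
            f"baseline window {baseline} s not contained in epochs starting "
            f"at t0={epochs.t0} s"
        )
    mean = epochs.data[:, :, i0:i1].mean(axis=2, keepdims=True)
    corrected = epochs.data - mean

    w0, w1 = task_window
    j0 = round((w0 - epochs.t0) * fs)
    j1 = epochs.n_samples if w1 is None else round((w1 - epochs.t0) * fs)
    if j0 < 0 or j1 > epochs.n_samples:
        raise ValueError(f"task window {task_window} outside epochs")
    return epochs.replace(data=corrected[:, :, j0:j1], t0=float(w0))
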