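"""Preprocessing pipeline: band-pass -> min-max normalize -> clip -> segment.

The stages mirror the standard acquisition arithmetic: recordings are
filtered to 0.5-40 Hz (zero phase), min-max normalized per channel into
[-1, 1], clipped into per-artifact epochs of F = T x fs frames (T = 11-s
task + 2-s relax on each side = 15 s), cut into non-overlapping 5-s
windows (640 samples at 128 Hz), and split 80:20 by holding out one
subject for testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .types import (
    EVALUATION_KINDS,
    RELAX,
    ArtifactKind,
    Epoch,
    Recording,
    Segment,
    SplitDataset,
)

__all__ = [
    "bandpass",
    "minmax_normalize",
    "NormParams",
    "inverse_normalize",
    "clip_epochs",
    "segment_epoch",
    "segment_recording",
    "split_by_subject",
    "preprocess_recording",
]


def bandpass(rec: Recording, low_hz: float = 0.5, high_hz: float = 40.0,
             order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass, applied per channel.

    Forward-backward filtering (filtfilt) preserves spike latencies; the
    default band keeps 0.5-40 Hz, attenuating 50/60 Hz line noise and
    baseline drift.
    """
    nyq = rec.fs / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"band edges must satisfy 0 < {low_hz} < {high_hz} < Nyquist {nyq}")
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=rec.fs,
                     output="sos")
    out = rec.copy()
    out.data = sps.sosfiltfilt(sos, rec.data, axis=1)
    return out


@dataclass
class NormParams:
    """Per-channel (min, max) of the min-max map, for inversion.

    ``constant`` flags channels with max == min, which are mapped to all
    zeros instead of dividing by zero.
    """

    mins: np.ndarray
    maxs: np.ndarray
    constant: np.ndarray  # bool per channel


def minmax_normalize(rec: Recording) -> tuple[Recording, NormParams]:
    """Map each channel by x -> 2 (x - min) / (max - min) - 1 into [-1, 1]."""
    if rec.n_samples < 2:
        raise ValueError("need at least 2 samples per channel to normalize")
    mins = rec.data.min(axis=1)
    maxs = rec.data.max(axis=1)
    constant = maxs - mins <= 0
    out = rec.copy()
    span = np.where(constant, 1.0, maxs - mins)
    out.data = 2.0 * (rec.data - mins[:, None]) / span[:, None] - 1.0
    out.data[constant] = 0.0
    return out, NormParams(mins=mins, maxs=maxs, constant=constant)


def inverse_normalize(rec: Recording, params: NormParams) -> Recording:
    """Undo :func:`minmax_normalize` (constant channels restored to min)."""
    out = rec.copy()
    span = np.where(params.constant, 0.0, params.maxs - params.mins)
    out.data = (rec.data + 1.0) / 2.0 * span[:, None] + params.mins[:, None]
    return out


def clip_epochs(rec: Recording, flank_s: float = 2.0, strict: bool = False,
                kinds: tuple[ArtifactKind, ...] | None = None) -> list[Epoch]:
    """Clip one epoch per artifact annotation: task + flanking relax.

    Each epoch spans ``flank_s`` seconds before the task onset through
    ``flank_s`` after its end (F = T x fs frames).  Epochs whose flank
    falls outside the recording are truncated and flagged, or skipped
    when ``strict`` is set.
    """
    if not rec.annotations:
        raise ValueError("recording has no annotations to clip epochs from")
    epochs: list[Epoch] = []
    for ann in rec.annotations:
        if ann.is_relax():
            continue
        kind = ArtifactKind(ann.label)
        if kinds is not None and kind not in kinds:
            continue
        if ann.duration_s <= 0:
            raise ValueError(f"annotation {ann.label!r} has zero duration")
        start = ann.onset_s - flank_s
        end = ann.end_s + flank_s
        truncated = start < 0 or end > rec.duration_s + 1e-9
        if truncated and strict:
            continue
        i0 = max(0, int(round(start * rec.fs)))
        i1 = min(rec.n_samples, int(round(end * rec.fs)))
        epochs.append(Epoch(
            data=rec.data[:, i0:i1].copy(),
            kind=kind,
            fs=rec.fs,
            subject_id=rec.subject_id,
            channel_names=list(rec.channel_names),
            truncated=truncated,
        ))
    return epochs


def segment_epoch(epoch: Epoch, window_s: float = 5.0) -> list[Segment]:
    """Cut an epoch into non-overlapping windows per channel.

    Yields floor(F / (window_s x fs)) segments per channel; a trailing
    remainder shorter than one window is dropped.  A window longer than
    the epoch yields an empty list.
    """
    win = int(round(window_s * epoch.fs))
    if win <= 0:
        raise ValueError("window must span at least one sample")
    n_win = epoch.F // win
    segments: list[Segment] = []
    for ci, ch in enumerate(epoch.channel_names):
        for w in range(n_win):
            segments.append(Segment(
                x=epoch.data[ci, w * win : (w + 1) * win].copy(),
                channel=ch,
                subject_id=epoch.subject_id,
                kind=epoch.kind,
                fs=epoch.fs,
            ))
    return segments


def segment_recording(rec: Recording, window_s: float = 5.0,
                      flank_s: float = 2.0, strict: bool = False,
                      kinds: tuple[ArtifactKind, ...] | None = EVALUATION_KINDS,
                      ) -> list[Segment]:
    """clip_epochs + segment_epoch over one recording.

    By default only the four evaluation artifact kinds enter the
    manifest; pass ``kinds=None`` to keep all nine.
    """
    segments: list[Segment] = []
    for ep in clip_epochs(rec, flank_s=flank_s, strict=strict, kinds=kinds):
        segments.extend(segment_epoch(ep, window_s=window_s))
    return segments


def split_by_subject(segments: list[Segment], held_out: str) -> SplitDataset:
    """Subject-held-out split: held-out subject -> test, the rest -> train."""
    subjects = {s.subject_id for s in segments}
    if len(subjects) < 2:
        raise ValueError("need at least 2 distinct subjects to split")
    if held_out not in subjects:
        raise ValueError(f"held-out subject {held_out!r} not in {sorted(subjects)}")
    train, test = [], []
    for s in segments:
        role = "test" if s.subject_id == held_out else "train"
        s2 = s.with_data(s.x)
        s2.role = role
        (test if role == "test" else train).append(s2)
    return SplitDataset(train=train, test=test, held_out_subject=held_out)


def preprocess_recording(rec: Recording, low_hz: float = 0.5,
                         high_hz: float = 40.0, window_s: float = 5.0,
                         kinds: tuple[ArtifactKind, ...] | None = EVALUATION_KINDS,
                         ) -> list[Segment]:
    """Full per-recording pipeline: filter, normalize, clip, segment."""
    filtered = bandpass(rec, low_hz=low_hz, high_hz=high_hz)
    normalized, _ = minmax_normalize(filtered)
    return segment_recording(normalized, window_s=window_s, kinds=kinds)
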