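"""Core domain containers shared by every stage of the pipeline.

A :class:`Recording` is a multichannel EEG time series with block
annotations; an :class:`Epoch` is the span clipped around one task block
(task plus flanking relax); a :class:`Segment` is the atomic 5-s,
single-channel training/evaluation window.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ArtifactKind",
    "EVALUATION_KINDS",
    "RELAX",
    "Annotation",
    "Recording",
    "Epoch",
    "Segment",
    "SplitDataset",
]

RELAX = "relax"


class ArtifactKind(str, enum.Enum):
    """The nine task labels recorded in the acquisition paradigm.

    Four of them (blink, eye movement, chewing, teeth clenching) are the
    modeled/evaluated kinds; the remaining five pass through clipping and
    segmentation but are excluded from the default train/test manifest.
    """

    EYE_BLINK = "eye_blink"
    EYE_MOVEMENT = "eye_movement"
    CHEWING = "chewing"
    CLENCH_TEETH = "clench_teeth"
    SWALLOWING = "swallowing"
    TONGUE_MOVEMENT = "tongue_movement"
    JAW_MOVEMENT = "jaw_movement"
    HEAD_MOVEMENT = "head_movement"
    SHOULDER_MOVEMENT = "shoulder_movement"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: The artifact kinds the denoiser is trained and evaluated on.
EVALUATION_KINDS = (
    ArtifactKind.EYE_BLINK,
    ArtifactKind.EYE_MOVEMENT,
    ArtifactKind.CHEWING,
    ArtifactKind.CLENCH_TEETH,
)


@dataclass(frozen=True)
class Annotation:
    """One block of the session paradigm: a task or a relax interval."""

    label: str  # ArtifactKind value or "relax"
    onset_s: float
    duration_s: float

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s

    def is_relax(self) -> bool:
        return self.label == RELAX


@dataclass
class Recording:
    """Multichannel EEG: ``data`` is channels x samples.

    Amplitudes are in microvolts before normalization and dimensionless
    in [-1, 1] afterwards.  ``annotations`` mark paradigm blocks; an
    artifact block's trailing relax may coincide with the next block's
    leading relax, otherwise blocks do not overlap.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    subject_id: str = "sub-00"
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples array")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but "
                f"{len(self.channel_names)} channel names"
            )
        if self.data.shape[0] == 0:
            raise ValueError("a Recording needs at least one channel")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        dur = self.duration_s
        for ann in self.annotations:
            if ann.onset_s < -1e-9 or ann.end_s > dur + 1e-9:
                raise ValueError(
                    f"annotation {ann.label!r} [{ann.onset_s}, {ann.end_s}] s "
                    f"lies outside the recording [0, {dur}] s"
                )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy(self) -> "Recording":
        return replace(
            self,
            data=self.data.copy(),
            channel_names=list(self.channel_names),
            annotations=list(self.annotations),
        )


@dataclass
class Epoch:
    """One artifact block clipped with its flanking relax periods.

    ``data`` is channels x F where F = T x fs frames (T = task length
    plus the two 2-s relax flanks; 15 s in the standard paradigm).
    ``truncated`` flags epochs whose flank hit a recording boundary.
    """

    data: np.ndarray
    kind: ArtifactKind
    fs: float
    subject_id: str
    channel_names: list[str]
    truncated: bool = False

    @property
    def T(self) -> float:
        """Epoch duration in seconds."""
        return self.data.shape[1] / self.fs

    @property
    def F(self) -> int:
        """Frame count (samples per channel)."""
        return self.data.shape[1]


@dataclass
class Segment:
    """A single-channel, fixed-length normalized window.

    This is the atomic unit fed to the wavelet cleaner (producing the
    reference target), to the generator (producing the denoised
    estimate), and to the metric suite.
    """

    x: np.ndarray
    channel: str
    subject_id: str
    kind: ArtifactKind
    role: str = "unassigned"  # train | test | unassigned
    fs: float = 128.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64).ravel()

    def __len__(self) -> int:
        return self.x.size

    def with_data(self, x: np.ndarray) -> "Segment":
        """Same metadata, new samples (used by cleaners/denoisers)."""
        return Segment(
            x=np.asarray(x, dtype=np.float64),
            channel=self.channel,
            subject_id=self.subject_id,
            kind=self.kind,
            role=self.role,
            fs=self.fs,
        )


@dataclass
class SplitDataset:
    """Subject-held-out train/test partition of a segment list."""

    train: list[Segment]
    test: list[Segment]
    held_out_subject: str

    def __post_init__(self) -> None:
        train_subjects = {s.subject_id for s in self.train}
        test_subjects = {s.subject_id for s in self.test}
        if train_subjects & test_subjects:
            raise ValueError(
                f"subjects {sorted(train_subjects & test_subjects)} appear "
                "in both train and test"
            )
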