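import numpy as np
import pytest

from eegdenoise.types import Annotation, ArtifactKind, Recording, Segment


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_recording(rng):
    """Seeded 4-channel, 20-s recording with nine annotations."""
    fs = 128.0
    data = rng.standard_normal((4, int(20 * fs))) * 10.0
    anns = [Annotation("relax", 0.0, 2.0)]
    t = 2.0
    for kind in list(ArtifactKind)[:4]:
        anns.append(Annotation(kind.value, t, 1.5))
        anns.append(Annotation("relax", t + 1.5, 1.0))
        t += 2.5
    return Recording(data=data, fs=fs,
                     channel_names=["Fp1", "Fp2", "C3", "C4"],
                     subject_id="sub-99", annotations=anns)


def make_segments(n, length=64, subjects=("sub-01",), channels=("Fp1",),
                  kinds=(ArtifactKind.EYE_BLINK,), seed=0):
    """Synthetic segment list cycling over the given metadata values."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        out.append(Segment(
            x=rng.uniform(-1, 1, size=length),
            channel=channels[i % len(channels)],
            subject_id=subjects[i % len(subjects)],
            kind=kinds[i % len(kinds)],
            fs=128.0,
        ))
    return out
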