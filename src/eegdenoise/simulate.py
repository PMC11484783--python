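"""Synthetic EEG sessions with ground-truth clean/artifact decomposition.

Real acquisition hardware is out of scope; this module emulates the
recording paradigm instead — alternating 2-s relax and 11-s task blocks
over a 117-s session, 32 channels at 128 Hz — so that every downstream
stage (preprocessing, wavelet cleaning, adversarial training, metrics)
can be exercised end to end with a known decomposition

    contaminated = clean background + injected artifact component.

Artifact morphologies follow their qualitative descriptions: eye blinks
are high sudden (biexponential) spikes, eye movements are smoothed square
waves, chewing is a rhythmic amplitude-modulated theta-range burst train,
and teeth clenching is high-amplitude 20-45 Hz noise bursts.  Amplitudes
are free parameters of the simulator (no published values exist); the
defaults are typical of scalp EEG where ocular artifacts reach several
times the background RMS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .types import RELAX, Annotation, ArtifactKind, Recording

__all__ = [
    "Paradigm",
    "ArtifactTemplate",
    "default_paradigm",
    "default_templates",
    "default_channel_names",
    "make_background",
    "inject_artifact",
    "make_session",
]

# 10-20-ish montage for 32 channels, frontal sites first.
_CHANNELS_32 = [
    "Fp1", "Fp2", "AF3", "AF4", "F7", "F3", "Fz", "F4",
    "F8", "FC5", "FC1", "FC2", "FC6", "T7", "C3", "Cz",
    "C4", "T8", "CP5", "CP1", "CP2", "CP6", "P7", "P3",
    "Pz", "P4", "P8", "PO3", "PO4", "O1", "Oz", "O2",
]

#: Paradigm order; the four evaluation kinds come first so each has full
#: 2-s relax flanks (the final block has no trailing relax).
_TASK_ORDER = [
    ArtifactKind.EYE_BLINK,
    ArtifactKind.EYE_MOVEMENT,
    ArtifactKind.CHEWING,
    ArtifactKind.CLENCH_TEETH,
    ArtifactKind.SWALLOWING,
    ArtifactKind.TONGUE_MOVEMENT,
    ArtifactKind.JAW_MOVEMENT,
    ArtifactKind.HEAD_MOVEMENT,
    ArtifactKind.SHOULDER_MOVEMENT,
]


@dataclass
class Paradigm:
    """Ordered session schedule of (activity, duration) blocks."""

    blocks: list[tuple[str, float]]  # (ArtifactKind value or "relax", seconds)
    fs: float = 128.0
    n_channels: int = 32

    @property
    def total_duration_s(self) -> float:
        return float(sum(d for _, d in self.blocks))

    def task_kinds(self) -> list[ArtifactKind]:
        return [ArtifactKind(lbl) for lbl, _ in self.blocks if lbl != RELAX]


def default_paradigm(fs: float = 128.0, n_channels: int = 32,
                     kinds: list[ArtifactKind] | None = None,
                     relax_s: float = 2.0, task_s: float = 11.0) -> Paradigm:
    """Nine (relax 2 s, task 11 s) pairs -> 117 s at 128 Hz = 14,976 samples."""
    kinds = list(kinds) if kinds is not None else list(_TASK_ORDER)
    blocks: list[tuple[str, float]] = []
    for kind in kinds:
        blocks.append((RELAX, relax_s))
        blocks.append((kind.value, task_s))
    return Paradigm(blocks=blocks, fs=fs, n_channels=n_channels)


def default_channel_names(n: int) -> list[str]:
    if n <= len(_CHANNELS_32):
        return _CHANNELS_32[:n]
    return _CHANNELS_32 + [f"EEG{i:03d}" for i in range(n - len(_CHANNELS_32))]


@dataclass
class ArtifactTemplate:
    """Morphology and scale of one injected artifact kind.

    ``amplitude_scale`` sets the artifact component RMS relative to the
    per-channel background RMS (so a scale of 5 means the artifact
    carries 5x the background's RMS amplitude on the most affected
    channel).  Morphology parameters are in seconds / Hz.
    """

    kind: ArtifactKind
    amplitude_scale: float = 5.0
    spike_width_s: float = 0.4     # blink biexponential width
    square_period_s: float = 2.0   # eye-movement square-wave period
    burst_band_hz: tuple[float, float] = (20.0, 45.0)  # clench noise band
    repetition_hz: float = 1.5     # chewing burst repetition
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.amplitude_scale >= 0:
            raise ValueError("amplitude_scale must be non-negative")
        for v in (self.spike_width_s, self.square_period_s, self.repetition_hz,
                  *self.burst_band_hz):
            if not v > 0:
                raise ValueError("morphology parameters must be positive")


def default_templates(seed: int | None = None) -> dict[ArtifactKind, ArtifactTemplate]:
    """One template per paradigm kind; non-ocular motion artifacts reuse
    the burst morphology with kind-specific bands/scales."""
    rng = np.random.SeedSequence(seed)
    seeds = rng.generate_state(len(_TASK_ORDER))
    t = {}
    t[ArtifactKind.EYE_BLINK] = ArtifactTemplate(
        ArtifactKind.EYE_BLINK, amplitude_scale=6.0, seed=int(seeds[0]))
    t[ArtifactKind.EYE_MOVEMENT] = ArtifactTemplate(
        ArtifactKind.EYE_MOVEMENT, amplitude_scale=4.0, seed=int(seeds[1]))
    t[ArtifactKind.CHEWING] = ArtifactTemplate(
        ArtifactKind.CHEWING, amplitude_scale=2.0, seed=int(seeds[2]))
    t[ArtifactKind.CLENCH_TEETH] = ArtifactTemplate(
        ArtifactKind.CLENCH_TEETH, amplitude_scale=3.0, seed=int(seeds[3]))
    for i, kind in enumerate(_TASK_ORDER[4:], start=4):
        t[kind] = ArtifactTemplate(kind, amplitude_scale=2.0,
                                   burst_band_hz=(10.0, 30.0),
                                   seed=int(seeds[i]))
    return t


# ---------------------------------------------------------------------------
# Background

def make_background(duration_s: float, fs: float, n_channels: int,
                    seed: int | None = None, *, slope: float = 1.0,
                    noise_floor: float = 1.0,
                    alpha_amplitude: float = 0.5, alpha_hz: float = 10.0,
                    rms_uv: float = 20.0,
                    channel_names: list[str] | None = None,
                    subject_id: str = "sub-00") -> Recording:
    """Clean-EEG surrogate: 1/f^slope noise, a white sensor floor, and an
    alpha tone.

    Parameters
    ----------
    slope
        Exponent of the power-law component's spectral decay, fitted
        recoverable from a periodogram regression over 1-40 Hz when the
        other components are disabled.
    noise_floor
        RMS of a white broadband component relative to the power-law
        component.  Consumer wearable recordings during motor tasks are
        dominated by such a flat sensor/EMG floor; 0 gives a pure
        power-law background.
    alpha_amplitude
        Alpha (8-13 Hz) oscillation amplitude relative to the noise RMS;
        set to 0 for a pure noise background.
    rms_uv
        Target per-channel RMS in microvolts.
    """
    if not duration_s > 0:
        raise ValueError("duration_s must be positive")
    if fs < 100:
        raise ValueError(
            "fs must be >= 100 Hz so the 30-50 Hz gamma band is representable")
    n = int(round(duration_s * fs))
    rng = np.random.default_rng(seed)
    # Shape white Gaussian noise in the frequency domain: PSD ~ f^-slope
    # means amplitude ~ f^(-slope/2).
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    nz = freqs > 0
    amp[nz] = freqs[nz] ** (-slope / 2.0)
    data = np.empty((n_channels, n))
    t = np.arange(n) / fs
    for ch in range(n_channels):
        spec = (rng.standard_normal(freqs.size)
                + 1j * rng.standard_normal(freqs.size)) * amp
        x = np.fft.irfft(spec, n=n)
        x /= np.sqrt(np.mean(x**2))
        if noise_floor > 0:
            w = rng.standard_normal(n)
            x = x + noise_floor * w / np.sqrt(np.mean(w**2))
        phase = rng.uniform(0, 2 * np.pi)
        x = x + alpha_amplitude * np.sqrt(2.0) * np.sin(
            2 * np.pi * alpha_hz * t + phase)
        x *= rms_uv / np.sqrt(np.mean(x**2))
        x -= x.mean()
        data[ch] = x
    names = channel_names or default_channel_names(n_channels)
    return Recording(data=data, fs=fs, channel_names=names,
                     subject_id=subject_id)


# ---------------------------------------------------------------------------
# Artifact morphologies (unit-RMS single-channel waveforms)

def _blink_waveform(n: int, fs: float, width_s: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Positive biexponential spike train, 0.5-1 Hz repetition.

    Rise/decay constants are width/3 and 2 width/3: blink deflections in
    frontal EEG are smooth lobes, not impulses.
    """
    out = np.zeros(n)
    tau_rise = width_s / 3.0
    tau_decay = 2.0 * width_s / 3.0
    kernel_t = np.arange(int(round(3 * width_s * fs))) / fs
    kernel = np.exp(-kernel_t / tau_decay) - np.exp(-kernel_t / tau_rise)
    kernel /= kernel.max()
    pos = 0.0
    while True:
        pos += rng.uniform(1.0, 2.0)  # 0.5-1 Hz repetition
        i = int(round(pos * fs))
        if i >= n:
            break
        end = min(n, i + kernel.size)
        out[i:end] += kernel[: end - i] * rng.uniform(0.8, 1.2)
    return out


def _square_waveform(n: int, fs: float, period_s: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Smoothed square wave (saccade-and-hold eye movement)."""
    t = np.arange(n) / fs
    phase = rng.uniform(0, 2 * np.pi)
    raw = sps.square(2 * np.pi * t / period_s + phase)
    # Smooth the edges with a ~60 ms Gaussian so transitions are saccade-like.
    win = sps.windows.gaussian(int(round(0.12 * fs)) | 1, std=0.02 * fs)
    win /= win.sum()
    return np.convolve(raw, win, mode="same")


def _chewing_waveform(n: int, fs: float, repetition_hz: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Amplitude-modulated 4-8 Hz bursts repeating at ~repetition_hz."""
    t = np.arange(n) / fs
    carrier_hz = rng.uniform(4.0, 8.0)
    carrier = np.sin(2 * np.pi * carrier_hz * t + rng.uniform(0, 2 * np.pi))
    env = 0.5 * (1 + np.cos(2 * np.pi * repetition_hz * t
                            + rng.uniform(0, 2 * np.pi)))
    return carrier * env**2


def _burst_noise_waveform(n: int, fs: float, band: tuple[float, float],
                          rng: np.random.Generator) -> np.ndarray:
    """Band-limited noise bursts (EMG-like, used for clench and motion)."""
    lo, hi = band
    hi = min(hi, 0.49 * fs)
    noise = rng.standard_normal(n)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, noise)
    # Burst envelope: on/off at ~2 Hz with smooth shoulders.
    t = np.arange(n) / fs
    env = 0.5 * (1 + np.cos(2 * np.pi * 2.0 * t + rng.uniform(0, 2 * np.pi)))
    return x * env


def _render_waveform(template: ArtifactTemplate, n: int, fs: float,
                     rng: np.random.Generator) -> np.ndarray:
    kind = template.kind
    if kind is ArtifactKind.EYE_BLINK:
        w = _blink_waveform(n, fs, template.spike_width_s, rng)
    elif kind is ArtifactKind.EYE_MOVEMENT:
        w = _square_waveform(n, fs, template.square_period_s, rng)
    elif kind is ArtifactKind.CHEWING:
        w = _chewing_waveform(n, fs, template.repetition_hz, rng)
    else:  # clench and the five motion kinds: band-limited bursts
        w = _burst_noise_waveform(n, fs, template.burst_band_hz, rng)
    rms = np.sqrt(np.mean(w**2))
    if rms > 0:
        w = w / rms
    return w


def _spatial_profile(n_channels: int) -> np.ndarray:
    """Frontal-weighted channel gains, 1.0 at the front tapering to 0.3."""
    return np.linspace(1.0, 0.3, n_channels)


def inject_artifact(rec: Recording, template: ArtifactTemplate,
                    onset_s: float, duration_s: float,
                    spatial_profile: np.ndarray | None = None,
                    seed: int | None = None,
                    ) -> tuple[Recording, np.ndarray]:
    """Add one artifact block to a copy of ``rec``.

    Returns ``(contaminated, component)`` where ``component`` is the
    injected channels x samples array (zero outside the block), so the
    ground-truth decomposition ``contaminated == rec.data + component``
    holds to machine precision.
    """
    i0 = int(round(onset_s * rec.fs))
    i1 = int(round((onset_s + duration_s) * rec.fs))
    if onset_s < 0 or i1 > rec.n_samples or duration_s <= 0:
        raise ValueError(
            f"artifact span [{onset_s}, {onset_s + duration_s}] s outside "
            f"recording of {rec.duration_s} s")
    rng = np.random.default_rng(template.seed if seed is None else seed)
    n = i1 - i0
    wave = _render_waveform(template, n, rec.fs, rng)
    # Taper 100 ms at both ends so block edges do not step.
    taper = sps.windows.tukey(n, alpha=min(1.0, 0.2 * rec.fs / max(n, 1)))
    wave = wave * taper
    profile = (np.asarray(spatial_profile, dtype=float)
               if spatial_profile is not None
               else _spatial_profile(rec.n_channels))
    if profile.size != rec.n_channels:
        raise ValueError("spatial profile length must equal channel count")
    bg_rms = np.sqrt(np.mean(rec.data**2, axis=1))
    component = np.zeros_like(rec.data)
    component[:, i0:i1] = (
        profile[:, None] * (template.amplitude_scale * bg_rms[:, None]) * wave
    )
    contaminated = rec.copy()
    contaminated.data = rec.data + component
    return contaminated, component


def make_session(paradigm: Paradigm,
                 templates: dict[ArtifactKind, ArtifactTemplate] | None = None,
                 seed: int | None = None, subject_id: str = "sub-00",
                 secondary_blink: ArtifactTemplate | None = None,
                 ) -> tuple[Recording, Recording]:
    """Simulate one session: returns (contaminated, clean) recordings.

    Both share the same background; every paradigm block is annotated on
    both.  Relax blocks are left untouched, task blocks receive their
    template's artifact.  ``secondary_blink``, when given, superimposes
    an additional blink train on every non-blink task block — subjects
    blink naturally throughout a real session — and is off by default so
    each block carries exactly one artifact kind.  Fully deterministic
    for a fixed ``seed``.
    """
    templates = templates if templates is not None else default_templates(seed)
    for kind in paradigm.task_kinds():
        if kind not in templates:
            raise ValueError(f"no artifact template for task kind {kind.value!r}")
    ss = np.random.SeedSequence(seed)
    bg_seed, *block_seeds = ss.generate_state(1 + len(paradigm.blocks))
    # separate stream for the optional secondary contamination, so the
    # primary session is unchanged by toggling it
    extra_seeds = np.random.SeedSequence(
        [0 if seed is None else seed, 1]).generate_state(len(paradigm.blocks))
    clean = make_background(paradigm.total_duration_s, paradigm.fs,
                            paradigm.n_channels, seed=int(bg_seed),
                            subject_id=subject_id)
    annotations = []
    t = 0.0
    contaminated = clean.copy()
    for (label, dur), bseed, sseed in zip(
            paradigm.blocks, block_seeds, extra_seeds):
        annotations.append(Annotation(label=label, onset_s=t, duration_s=dur))
        if label != RELAX:
            _, component = inject_artifact(
                clean, templates[ArtifactKind(label)], t, dur, seed=int(bseed))
            contaminated.data += component
            if (secondary_blink is not None
                    and label != ArtifactKind.EYE_BLINK.value):
                _, extra = inject_artifact(clean, secondary_blink, t, dur,
                                           seed=int(sseed))
                contaminated.data += extra
        t += dur
    clean.annotations = list(annotations)
    contaminated.annotations = list(annotations)
    return contaminated, clean
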