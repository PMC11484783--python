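"""Evaluation metrics: NMSE, RMSE, CC, per-band SNR, SAR, and tables.

Definitions (orgSig = original, recSig = reconstructed):

* ``MSE  = ||orgSig - recSig||^2 / N``, ``NMSE = MSE / ||orgSig||^2``
* ``RMSE = sqrt(MSE)``
* ``CC``  = Pearson correlation coefficient
* ``SNR_band = 10 log10(P_signal / P_noise)`` with P_signal the summed
  squared DFT magnitudes inside the band and P_noise the rest of the
  spectrum's power (DC excluded from both pools; rectangular window).
* ``SAR = 10 log10(sigma(A) / sigma(A - A'))`` — standard deviations,
  not variances.

Guarded infinities (zero noise power, perfect cleaning) are capped at
+/-300 dB and flagged, keeping tables finite and machine-comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import Segment

__all__ = ["Band", "DEFAULT_BANDS", "CAP_DB", "nmse", "rmse", "cc",
           "band_snr", "band_powers", "sar", "MetricsReport", "evaluate"]

CAP_DB = 300.0


@dataclass(frozen=True)
class Band:
    name: str
    lo_hz: float
    hi_hz: float

    def __post_init__(self) -> None:
        if not (0 < self.lo_hz < self.hi_hz):
            raise ValueError(f"invalid band ({self.lo_hz}, {self.hi_hz})")


DEFAULT_BANDS = (
    Band("Theta", 4.0, 8.0),
    Band("Alpha", 8.0, 13.0),
    Band("Beta", 13.0, 30.0),
    Band("Gamma", 30.0, 50.0),
)


def _as_vec(x) -> np.ndarray:
    return np.asarray(x, dtype=np.float64).ravel()


def nmse(org_sig, rec_sig, *, variance_normalized: bool = False) -> float:
    """MSE normalized by the original signal's squared norm.

    ``variance_normalized`` switches the denominator to N x var(orgSig)
    (the prose variant); the default divides by ||orgSig||^2.
    """
    a, b = _as_vec(org_sig), _as_vec(rec_sig)
    if a.size != b.size or a.size < 1:
        raise ValueError("inputs must be equal-length, non-empty vectors")
    if not np.any(a):
        raise ValueError("NMSE undefined for an all-zero original signal")
    mse = float(np.sum((a - b) ** 2)) / a.size
    denom = a.size * float(np.var(a)) if variance_normalized \
        else float(np.sum(a**2))
    if denom == 0:
        raise ValueError("NMSE normalization is zero")
    return mse / denom


def rmse(data, estimate) -> float:
    """Root mean squared elementwise difference (symmetric)."""
    a, b = _as_vec(data), _as_vec(estimate)
    if a.size != b.size or a.size < 1:
        raise ValueError("inputs must be equal-length, non-empty vectors")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def cc(sig, sig_prime) -> float:
    """Pearson correlation coefficient in [-1, 1]."""
    a, b = _as_vec(sig), _as_vec(sig_prime)
    if a.size != b.size or a.size < 2:
        raise ValueError("inputs must be equal-length vectors of length >= 2")
    sa, sb = np.std(a), np.std(b)
    if sa == 0 or sb == 0:
        raise ValueError("correlation undefined for a zero-variance input")
    r = float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))
    return float(np.clip(r, -1.0, 1.0))


def band_powers(x, fs: float, band: Band) -> tuple[float, float]:
    """(in-band, out-of-band) summed squared DFT magnitudes, DC excluded.

    The band is half-open (lo <= |f| < hi) so a disjoint band cover never
    double-counts a bin; both halves of the spectrum contribute, making
    in + out equal to the signal's total AC power (Parseval, up to the
    1/N convention).
    """
    v = _as_vec(x)
    if v.size < 2:
        raise ValueError("need at least 2 samples")
    if not (0 < band.lo_hz < band.hi_hz <= fs / 2):
        raise ValueError(
            f"band ({band.lo_hz}, {band.hi_hz}) outside (0, Nyquist {fs / 2}]")
    Y = np.fft.fft(v)
    p = np.abs(Y) ** 2
    freqs = np.abs(np.fft.fftfreq(v.size, d=1.0 / fs))
    in_band = (freqs >= band.lo_hz) & (freqs < band.hi_hz)
    ac = np.arange(v.size) != 0  # exclude the DC bin from both pools
    p_sig = float(p[in_band & ac].sum())
    p_noise = float(p[~in_band & ac].sum())
    return p_sig, p_noise


def band_snr(x, fs: float, band: Band) -> float:
    """10 log10(P_in / P_out) in dB, capped at +/-300 dB when degenerate."""
    p_sig, p_noise = band_powers(x, fs, band)
    total = p_sig + p_noise
    if total <= 0:
        return 0.0
    # spectral leakage at machine precision counts as an empty pool
    if p_noise <= 1e-15 * total:
        return CAP_DB
    if p_sig <= 1e-15 * total:
        return -CAP_DB
    return float(np.clip(10.0 * np.log10(p_sig / p_noise), -CAP_DB, CAP_DB))


def sar(a, a_prime) -> float:
    """10 log10(sigma(A) / sigma(A - A')) in dB, capped when A' == A."""
    A, Ap = _as_vec(a), _as_vec(a_prime)
    if A.size != Ap.size or A.size < 2:
        raise ValueError("inputs must be equal-length vectors of length >= 2")
    sA = float(np.std(A))
    if sA == 0:
        raise ValueError("SAR undefined for a constant artifacted signal")
    sR = float(np.std(A - Ap))
    if sR == 0:
        return CAP_DB
    return float(np.clip(10.0 * np.log10(sA / sR), -CAP_DB, CAP_DB))


@dataclass
class MetricsReport:
    """Per-electrode and mean comparison of wavelet vs model cleaning.

    ``per_electrode`` has one row per electrode and columns
    ``{metric}_{method}`` for metric in (nmse, rmse, cc, sar) and method
    in (wavelet, model); ``band_snr`` has one row per band and columns
    raw/wavelet/model.  ``flagged`` lists (electrode, metric) cells where
    a guard cap was applied.
    """

    per_electrode: pd.DataFrame
    band_snr: pd.DataFrame
    fs: float
    flagged: list[tuple[str, str]] = field(default_factory=list)

    @property
    def mean_row(self) -> pd.Series:
        return self.per_electrode.mean(axis=0)

    def electrode_table(self) -> pd.DataFrame:
        """Per-electrode rows plus an arithmetic 'Mean' row."""
        table = self.per_electrode.copy()
        table.loc["Mean"] = self.per_electrode.mean(axis=0)
        return table

    def to_csv(self, electrode_path, band_path) -> None:
        self.electrode_table().to_csv(electrode_path, float_format="%.6f")
        self.band_snr.to_csv(band_path, float_format="%.6f")

    def to_markdown(self) -> str:
        return (self.electrode_table().to_markdown(floatfmt=".4f")
                + "\n\n" + self.band_snr.to_markdown(floatfmt=".2f"))


def _mean_metric(fn, pairs) -> float:
    return float(np.mean([fn(a, b) for a, b in pairs]))


def evaluate(original: list[Segment], wavelet_cleaned: list[Segment],
             model_cleaned: list[Segment], fs: float | None = None,
             bands: tuple[Band, ...] = DEFAULT_BANDS) -> MetricsReport:
    """Score both cleaning methods against the original segments.

    Inputs are three index-aligned segment lists.  NMSE/RMSE/CC/SAR are
    computed per segment and averaged within electrode; band SNR is
    computed per segment on raw/wavelet/model signals and averaged over
    all segments of all electrodes (one value per band per method).
    """
    if not (len(original) == len(wavelet_cleaned) == len(model_cleaned)) \
            or not original:
        raise ValueError("the three segment lists must be non-empty and aligned")
    fs = fs if fs is not None else original[0].fs
    electrodes: dict[str, list[int]] = {}
    for i, seg in enumerate(original):
        electrodes.setdefault(seg.channel, []).append(i)

    rows = {}
    flagged: list[tuple[str, str]] = []
    for ch, idxs in electrodes.items():
        orig = [original[i].x for i in idxs]
        wav = [wavelet_cleaned[i].x for i in idxs]
        mod = [model_cleaned[i].x for i in idxs]
        row = {
            "nmse_wavelet": _mean_metric(nmse, zip(orig, wav)),
            "nmse_model": _mean_metric(nmse, zip(orig, mod)),
            "rmse_wavelet": _mean_metric(rmse, zip(orig, wav)),
            "rmse_model": _mean_metric(rmse, zip(orig, mod)),
            "cc_wavelet": _mean_metric(cc, zip(orig, wav)),
            "cc_model": _mean_metric(cc, zip(orig, mod)),
            "sar_wavelet": _mean_metric(sar, zip(orig, wav)),
            "sar_model": _mean_metric(sar, zip(orig, mod)),
        }
        for key in ("sar_wavelet", "sar_model"):
            if abs(row[key]) >= CAP_DB:
                flagged.append((ch, key))
        rows[ch] = row
    per_electrode = pd.DataFrame.from_dict(rows, orient="index")
    per_electrode.index.name = "electrode"

    snr_rows = {}
    for band in bands:
        snr_rows[band.name] = {
            "raw": float(np.mean([band_snr(s.x, fs, band) for s in original])),
            "wavelet": float(np.mean(
                [band_snr(s.x, fs, band) for s in wavelet_cleaned])),
            "model": float(np.mean(
                [band_snr(s.x, fs, band) for s in model_cleaned])),
        }
    band_df = pd.DataFrame.from_dict(snr_rows, orient="index")
    band_df.index.name = "band"
    return MetricsReport(per_electrode=per_electrode, band_snr=band_df,
                         fs=fs, flagged=flagged)
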