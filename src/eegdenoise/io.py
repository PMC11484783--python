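"""Reading and writing recordings and segment datasets.

Two recording formats are supported:

* **CSV** — one header row of channel names, one column per channel;
  lossless text round trip.  The sampling rate, subject id and block
  annotations live in a JSON sidecar ``<name>.meta.json``.
* **EDF** — plain European Data Format (16-bit), written by a minimal
  in-package writer and read back through :mod:`mne`; round trips are
  exact to the 16-bit quantization step of the per-channel physical
  range.  Annotations use the same JSON sidecar as CSV.

Segment datasets are stored as a directory holding a single ``.npy``
matrix (float32, one row per segment) plus a ``manifest.json`` listing
per-segment metadata (subject, channel, artifact kind, role) and the
shared sampling rate / window length.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np

from .types import Annotation, ArtifactKind, Recording, Segment

__all__ = [
    "read_recording",
    "write_recording",
    "save_segments",
    "load_segments",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def _write_sidecar(rec: Recording, path: Path) -> None:
    meta = {
        "fs": rec.fs,
        "subject_id": rec.subject_id,
        "channel_names": rec.channel_names,
        "n_samples": rec.n_samples,
        "annotations": [
            {"label": a.label, "onset_s": a.onset_s, "duration_s": a.duration_s}
            for a in rec.annotations
        ],
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def _read_sidecar(path: Path) -> dict | None:
    sp = _sidecar_path(path)
    if sp.exists():
        return json.loads(sp.read_text())
    return None


def _annotations_from_meta(meta: dict) -> list[Annotation]:
    return [
        Annotation(a["label"], float(a["onset_s"]), float(a["duration_s"]))
        for a in meta.get("annotations", [])
    ]


# ---------------------------------------------------------------------------
# CSV

def _write_csv(rec: Recording, path: Path) -> None:
    header = ",".join(rec.channel_names)
    np.savetxt(path, rec.data.T, delimiter=",", header=header, comments="",
               fmt="%.17g")
    _write_sidecar(rec, path)


def _read_csv(path: Path, fs: float | None) -> Recording:
    meta = _read_sidecar(path)
    if fs is None:
        if meta is None or "fs" not in meta:
            raise ValueError(
                f"no sampling rate for CSV recording {path}: provide fs or a "
                f"{_sidecar_path(path).name} sidecar")
        fs = float(meta["fs"])
    with open(path) as fh:
        header = fh.readline().strip()
    if not header:
        raise ValueError(f"{path}: empty CSV, no channel header")
    names = header.split(",")
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    if data.size == 0:
        raise ValueError(f"{path}: CSV has a header but no samples")
    return Recording(
        data=data.T,
        fs=fs,
        channel_names=names,
        subject_id=(meta or {}).get("subject_id", path.stem),
        annotations=_annotations_from_meta(meta) if meta else [],
    )


# ---------------------------------------------------------------------------
# EDF — minimal plain-EDF writer (16-bit); reading via mne.

def _edf_field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _write_edf(rec: Recording, path: Path) -> None:
    if abs(rec.fs - round(rec.fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    fs = int(round(rec.fs))
    ns = rec.n_channels
    n_records = math.ceil(rec.n_samples / fs)
    padded = np.zeros((ns, n_records * fs))
    padded[:, : rec.n_samples] = rec.data

    # Physical range from the data itself to minimize quantization error.
    phys_min = padded.min(axis=1)
    phys_max = padded.max(axis=1)
    flat = phys_max - phys_min <= 0
    phys_min[flat] -= 1.0
    phys_max[flat] += 1.0
    dig_min, dig_max = -32768, 32767

    header = b""
    header += _edf_field("0", 8)                      # version
    header += _edf_field(rec.subject_id, 80)          # patient id
    header += _edf_field("eegdenoise", 80)            # recording id
    header += _edf_field("01.01.00", 8)               # start date
    header += _edf_field("00.00.00", 8)               # start time
    header += _edf_field(str(256 * (ns + 1)), 8)      # header bytes
    header += _edf_field("", 44)                      # reserved
    header += _edf_field(str(n_records), 8)
    header += _edf_field("1", 8)                      # record duration (s)
    header += _edf_field(str(ns), 4)
    header += b"".join(_edf_field(n, 16) for n in rec.channel_names)
    header += b"".join(_edf_field("AgAgCl electrode", 80) for _ in range(ns))
    header += b"".join(_edf_field("uV", 8) for _ in range(ns))
    header += b"".join(_edf_field(f"{v:.6g}", 8) for v in phys_min)
    header += b"".join(_edf_field(f"{v:.6g}", 8) for v in phys_max)
    header += b"".join(_edf_field(str(dig_min), 8) for _ in range(ns))
    header += b"".join(_edf_field(str(dig_max), 8) for _ in range(ns))
    header += b"".join(_edf_field("", 80) for _ in range(ns))   # prefiltering
    header += b"".join(_edf_field(str(fs), 8) for _ in range(ns))
    header += b"".join(_edf_field("", 32) for _ in range(ns))   # reserved

    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.rint(
        (padded - phys_min[:, None]) * scale[:, None] + dig_min
    ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            fh.write(digital[:, r * fs : (r + 1) * fs].tobytes())
    _write_sidecar(rec, path)


def _read_edf(path: Path) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne scales uV channels to volts
    fs = float(raw.info["sfreq"])
    names = list(raw.ch_names)
    meta = _read_sidecar(path)
    if meta is not None:
        n = int(meta.get("n_samples", data.shape[1]))
        data = data[:, :n]  # drop final-record zero padding
        names = meta.get("channel_names", names)
    return Recording(
        data=data,
        fs=fs,
        channel_names=names,
        subject_id=(meta or {}).get("subject_id", path.stem),
        annotations=_annotations_from_meta(meta) if meta else [],
    )


# ---------------------------------------------------------------------------
# Public recording API

def write_recording(rec: Recording, path: str | Path,
                    format: str | None = None) -> None:
    """Write a recording as CSV or EDF (inferred from the suffix)."""
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        _write_csv(rec, path)
    elif fmt == "edf":
        _write_edf(rec, path)
    else:
        raise ValueError(f"unsupported recording format {fmt!r}")


def read_recording(path: str | Path, format: str | None = None,
                   fs: float | None = None) -> Recording:
    """Read a CSV or EDF recording written by :func:`write_recording`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        return _read_csv(path, fs)
    if fmt == "edf":
        return _read_edf(path)
    raise ValueError(f"unsupported recording format {fmt!r}")


# ---------------------------------------------------------------------------
# Segment container

def save_segments(segments: list[Segment], path: str | Path) -> None:
    """Store segments as ``<path>/segments.npy`` + ``manifest.json``.

    All segments must share one window length; arrays are stored float32.
    """
    path = Path(path)
    lengths = {len(s) for s in segments}
    if len(lengths) > 1:
        raise ValueError(f"mixed segment lengths {sorted(lengths)}")
    path.mkdir(parents=True, exist_ok=True)
    if segments:
        mat = np.stack([s.x for s in segments]).astype(np.float32)
    else:
        mat = np.zeros((0, 0), dtype=np.float32)
    np.save(path / "segments.npy", mat)
    manifest = {
        "n_segments": len(segments),
        "window_len": int(mat.shape[1]) if segments else 0,
        "fs": segments[0].fs if segments else None,
        "records": [
            {
                "subject_id": s.subject_id,
                "channel": s.channel,
                "kind": s.kind.value,
                "role": s.role,
            }
            for s in segments
        ],
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_segments(path: str | Path) -> list[Segment]:
    """Load a segment container written by :func:`save_segments`."""
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    mat = np.load(path / "segments.npy")
    if mat.shape[0] != manifest["n_segments"]:
        raise ValueError(
            f"{path}: manifest lists {manifest['n_segments']} segments but "
            f"array has {mat.shape[0]} rows")
    out = []
    for row, recm in zip(mat, manifest["records"]):
        out.append(Segment(
            x=row.astype(np.float64),
            channel=recm["channel"],
            subject_id=recm["subject_id"],
            kind=ArtifactKind(recm["kind"]),
            role=recm["role"],
            fs=manifest["fs"],
        ))
    return out
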