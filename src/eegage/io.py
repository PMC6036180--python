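"""Reading and writing EEG files (EDF and BrainVision).

Reading goes through :mod:`mne`, which implements both published format
specifications; samples are normalized to microvolts on ingestion.  Writing
is provided by two small format writers (16-bit EDF and an IEEE-float-32
BrainVision triplet) used by the simulator and by round-trip tests.
"""

from __future__ import annotations

import datetime as _dt
import os
from pathlib import Path

import numpy as np

from .recording import RawRecording

__all__ = ["read_recording", "write_edf", "write_brainvision"]

_V_TO_UV = 1e6


def read_recording(path: str | os.PathLike, format: str | None = None) -> RawRecording:
    """Read an EDF or BrainVision recording into a :class:`RawRecording`.

    ``format`` may be ``"edf"`` or ``"brainvision"``; when omitted it is
    inferred from the file suffix (``.edf`` vs ``.vhdr``).  Samples are
    converted to microvolts.  Non-finite samples are an error.
    """
    import mne

    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {"edf": "edf", ".edf": "edf", ".vhdr": "brainvision"}.get(
            suffix, None
        )
        if format is None:
            raise ValueError(f"cannot infer format from suffix {suffix!r}")
    try:
        if format == "edf":
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        elif format == "brainvision":
            raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
        else:
            raise ValueError(f"unknown format {format!r}")
    except (OSError, ValueError):
        raise
    except Exception as exc:  # mne raises various parse errors
        raise ValueError(f"could not parse {path}: {exc}") from exc

    data = raw.get_data() * _V_TO_UV
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path} contains non-finite samples")
    return RawRecording(data, float(raw.info["sfreq"]), list(raw.ch_names))


# ---------------------------------------------------------------------------
# EDF writer (EDF, 16-bit integer, 1-second data records)

def write_edf(path: str | os.PathLike, rec: RawRecording) -> Path:
    """Write a recording as a plain EDF file (16-bit, 1 s records).

    The recording is truncated to a whole number of seconds.  Physical
    minima/maxima are taken per channel from the data, so quantization error
    is (max-min)/65535 per channel.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1 s record per channel
    n_records = rec.n_samples // spr
    if n_records < 1:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    data = rec.data[:, : n_records * spr]
    nch = rec.n_channels

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin <= 0
    pmax = np.where(flat, pmin + 1.0, pmax)
    dmin, dmax = -32768, 32767
    gain = (dmax - dmin) / (pmax - pmin)
    digital = np.clip(
        np.rint((data - pmin[:, None]) * gain[:, None]) + dmin, dmin, dmax
    ).astype("<i2")

    def f(text: str, width: int) -> bytes:
        return text[:width].ljust(width).encode("ascii")

    now = _dt.datetime(2000, 1, 1)
    header = b"".join([
        f("0", 8),
        f("X X X X", 80),
        f("Synthetic EEG", 80),
        f(now.strftime("%d.%m.%y"), 8),
        f(now.strftime("%H.%M.%S"), 8),
        f(str(256 * (nch + 1)), 8),
        f("", 44),
        f(str(n_records), 8),
        f("1", 8),
        f(str(nch), 4),
    ])
    header += b"".join(f(lab, 16) for lab in rec.labels)
    header += b"".join(f("AgAgCl electrode", 80) for _ in range(nch))
    header += b"".join(f("uV", 8) for _ in range(nch))
    header += b"".join(f(f"{v:.6g}", 8) for v in pmin)
    header += b"".join(f(f"{v:.6g}", 8) for v in pmax)
    header += b"".join(f(str(dmin), 8) for _ in range(nch))
    header += b"".join(f(str(dmax), 8) for _ in range(nch))
    header += b"".join(f("", 80) for _ in range(nch))
    header += b"".join(f(str(spr), 8) for _ in range(nch))
    header += b"".join(f("", 32) for _ in range(nch))

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            fh.write(digital[:, r * spr : (r + 1) * spr].tobytes())
    return path


# ---------------------------------------------------------------------------
# BrainVision writer (.vhdr/.vmrk/.eeg, multiplexed IEEE float32)

_VHDR_TEMPLATE = """Brain Vision Data Exchange Header File Version 1.0
; Written by eegage

[Common Infos]
Codepage=UTF-8
DataFile={stem}.eeg
MarkerFile={stem}.vmrk
DataFormat=BINARY
DataOrientation=MULTIPLEXED
NumberOfChannels={nch}
SamplingInterval={interval}

[Binary Infos]
BinaryFormat=IEEE_FLOAT_32

[Channel Infos]
; Ch<n>=<name>,<reference>,<resolution in microvolts>,<unit>
{channels}
"""

_VMRK_TEMPLATE = """Brain Vision Data Exchange Marker File, Version 1.0

[Common Infos]
Codepage=UTF-8
DataFile={stem}.eeg

[Marker Infos]
Mk1=New Segment,,1,1,0,00000000000000000000
"""


def write_brainvision(vhdr_path: str | os.PathLike, rec: RawRecording) -> Path:
    """Write a recording as a BrainVision triplet next to ``vhdr_path``."""
    vhdr_path = Path(vhdr_path)
    stem = vhdr_path.stem
    base = vhdr_path.parent
    interval_us = 1e6 / rec.fs
    comma_escape = "\\1"  # BrainVision escapes literal commas in names
    channels = "\n".join(
        f"Ch{i + 1}={lab.replace(',', comma_escape)},,1,µV"
        for i, lab in enumerate(rec.labels)
    )
    vhdr_path.write_text(
        _VHDR_TEMPLATE.format(
            stem=stem, nch=rec.n_channels,
            interval=f"{interval_us:.10g}", channels=channels,
        ),
        encoding="utf-8",
    )
    (base / f"{stem}.vmrk").write_text(
        _VMRK_TEMPLATE.format(stem=stem), encoding="utf-8"
    )
    # multiplexed: sample-major, channel-minor
    interleaved = np.ascontiguousarray(rec.data.T, dtype="<f4")
    (base / f"{stem}.eeg").write_bytes(interleaved.tobytes())
    return vhdr_path
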