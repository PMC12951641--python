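"""Reading and writing recordings and tables.

Two interchangeable on-disk forms for a :class:`~wmcoupling.signal_core.Recording`:

* European Data Format (EDF): written by a minimal built-in 16-bit writer
  (one-second data records, per-channel physical scaling) and read back
  through mne's EDF reader. Classic EDF carries no annotations, so event
  markers travel in a companion ``<name>.events.tsv`` (label, time_s) file.
* Matrix + JSON sidecar: a raw float32 channel-major binary matrix next to a
  JSON file holding the sampling rate, channel names, sample count and
  annotations. Lossless to float32 precision.

Behavioral tables are plain TSV with columns participant_id, task, trial,
rt_s, correct (and set_size where applicable).
"""

from __future__ import annotations

import json
import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .signal_core import Recording

_EDF_DIGITAL_MIN = -32768
_EDF_DIGITAL_MAX = 32767


def _ascii_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(recording: Recording, path: str | Path) -> Path:
    """Write a recording as 16-bit EDF with one-second data records.

    The sampling rate must be an integer. The final partial record is
    zero-padded, so a reader may return up to ``fs - 1`` trailing padding
    samples. Annotations, which classic EDF cannot hold, are written to
    ``<name>.events.tsv`` beside the file.
    """
    path = Path(path)
    fs = recording.fs_hz
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    fs = int(round(fs))
    n_ch = recording.n_channels
    n_records = int(np.ceil(recording.n_samples / fs))
    padded = np.zeros((n_ch, n_records * fs))
    padded[:, : recording.n_samples] = recording.signal

    phys_min = padded.min(axis=1)
    phys_max = padded.max(axis=1)
    flat = phys_max - phys_min < 1e-12
    phys_min[flat] -= 1.0
    phys_max[flat] += 1.0

    header_bytes = 256 + 256 * n_ch
    with open(path, "wb") as fh:
        fh.write(_ascii_field("0", 8))
        fh.write(_ascii_field("X", 80))
        fh.write(_ascii_field("X", 80))
        fh.write(_ascii_field("01.01.00", 8))
        fh.write(_ascii_field("00.00.00", 8))
        fh.write(_ascii_field(header_bytes, 8))
        fh.write(_ascii_field("", 44))
        fh.write(_ascii_field(n_records, 8))
        fh.write(_ascii_field(1, 8))
        fh.write(_ascii_field(n_ch, 4))
        for name in recording.channel_names:
            fh.write(_ascii_field(name, 16))
        for _ in range(n_ch):
            fh.write(_ascii_field("", 80))  # transducer
        for _ in range(n_ch):
            fh.write(_ascii_field("uV", 8))
        for v in phys_min:
            fh.write(_ascii_field(f"{v:.8g}"[:8], 8))
        for v in phys_max:
            fh.write(_ascii_field(f"{v:.8g}"[:8], 8))
        for _ in range(n_ch):
            fh.write(_ascii_field(_EDF_DIGITAL_MIN, 8))
        for _ in range(n_ch):
            fh.write(_ascii_field(_EDF_DIGITAL_MAX, 8))
        for _ in range(n_ch):
            fh.write(_ascii_field("", 80))  # prefiltering
        for _ in range(n_ch):
            fh.write(_ascii_field(fs, 8))
        for _ in range(n_ch):
            fh.write(_ascii_field("", 32))
        # re-read the truncated physical extremes so scaling matches the header
        pmin = np.array([float(f"{v:.8g}"[:8]) for v in phys_min])
        pmax = np.array([float(f"{v:.8g}"[:8]) for v in phys_max])
        scale = (_EDF_DIGITAL_MAX - _EDF_DIGITAL_MIN) / (pmax - pmin)
        for r in range(n_records):
            block = padded[:, r * fs : (r + 1) * fs]
            digital = np.round(
                (block - pmin[:, None]) * scale[:, None] + _EDF_DIGITAL_MIN
            ).astype("<i2")
            fh.write(digital.tobytes())
    if recording.annotations:
        write_annotations_tsv(recording.annotations, path.with_suffix(".events.tsv"))
    return path


def read_edf(path: str | Path) -> Recording:
    """Read an EDF file through mne; units normalized to microvolts.

    Annotations are taken from a companion ``<name>.events.tsv`` if present.
    """
    from mne.io import read_raw_edf

    path = Path(path)
    raw = read_raw_edf(str(path), preload=True, verbose="error")
    signal_uv = raw.get_data() * 1e6  # mne returns Volts
    annotations: list[tuple[str, float]] = []
    events_path = path.with_suffix(".events.tsv")
    if events_path.exists():
        annotations = read_annotations_tsv(events_path)
    return Recording(
        signal=signal_uv,
        fs_hz=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        annotations=annotations,
    )


def write_sidecar(recording: Recording, base_path: str | Path) -> Path:
    """Write ``<base>.dat`` (float32 channel-major binary) + ``<base>.json``."""
    base = Path(base_path)
    dat = base.with_suffix(".dat")
    recording.signal.astype("<f4").tofile(dat)
    meta = {
        "fs_hz": recording.fs_hz,
        "channel_names": recording.channel_names,
        "n_samples": recording.n_samples,
        "dtype": "<f4",
        "units": "uV",
        "annotations": [
            {"label": lab, "time_s": t} for lab, t in recording.annotations
        ],
    }
    with open(base.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=1)
    return dat


def read_sidecar(base_path: str | Path) -> Recording:
    """Read the matrix + JSON sidecar form; errors name any missing key."""
    base = Path(base_path)
    with open(base.with_suffix(".json")) as fh:
        meta = json.load(fh)
    for key in ("fs_hz", "channel_names", "n_samples"):
        if key not in meta:
            raise KeyError(f"sidecar missing required key {key!r}")
    n_ch = len(meta["channel_names"])
    data = np.fromfile(base.with_suffix(".dat"), dtype=meta.get("dtype", "<f4"))
    expected = n_ch * meta["n_samples"]
    if data.size != expected:
        raise ValueError(
            f"matrix size {data.size} does not match sidecar "
            f"({n_ch} channels x {meta['n_samples']} samples)"
        )
    return Recording(
        signal=data.reshape(n_ch, meta["n_samples"]).astype(float),
        fs_hz=float(meta["fs_hz"]),
        channel_names=list(meta["channel_names"]),
        annotations=[(a["label"], float(a["time_s"])) for a in meta.get("annotations", [])],
    )


def read_recording(path: str | Path) -> Recording:
    """Dispatch on extension: ``.edf`` via mne, ``.json``/``.dat`` via sidecar."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return read_edf(path)
    if path.suffix.lower() in (".json", ".dat", ""):
        return read_sidecar(path)
    raise ValueError(f"unrecognized recording format: {path.suffix!r}")


def write_annotations_tsv(annotations: list[tuple[str, float]], path: str | Path) -> None:
    pd.DataFrame(annotations, columns=["label", "time_s"]).to_csv(
        path, sep="\t", index=False
    )


def read_annotations_tsv(path: str | Path) -> list[tuple[str, float]]:
    df = pd.read_csv(path, sep="\t")
    return [(str(r.label), float(r.time_s)) for r in df.itertuples()]


def write_behavior_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_behavior_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
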