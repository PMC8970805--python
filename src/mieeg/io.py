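"""Reading and writing labeled EEG trial sets.

Three on-disk dialects:

``npz``
    Single numpy archive with named arrays ``data`` (trials x channels x
    samples), ``labels``, ``fs``, ``channels``, ``duration``.  Lossless.
``csv``
    Long-format table ``trial,channel,sample_index,value`` plus a sidecar
    ``<stem>.labels.csv`` carrying per-trial labels and a commented metadata
    line (fs, duration, channel order).  Lossless up to text precision.
``edf``
    European Data Format, EDF+C: trials are concatenated, one data record per
    trial, with an annotations channel holding a ``left``/``right`` event at
    each trial onset.  Written by a minimal 16-bit writer in this module and
    read back through :mod:`mne`, so the round trip crosses an independent
    parser.  Lossy at the 16-bit quantization level.
"""

from __future__ import annotations

import datetime
import os
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ChannelMismatchError, FormatError, LabelError
from .synth import EEGTrialSet, LABEL_NAMES

_FORMATS = ("npz", "csv", "edf")


def _infer_format(path: Path, format: Optional[str]) -> str:
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt not in _FORMATS:
        raise FormatError(f"unknown trial-set format {fmt!r}; expected one of {_FORMATS}")
    return fmt


def write_trials(ts: EEGTrialSet, path, format: Optional[str] = None) -> Path:
    """Serialize a trial set; dialect inferred from the extension unless given."""
    path = Path(path)
    if ts.n_trials == 0:
        raise FormatError("refusing to write an empty trial set")
    fmt = _infer_format(path, format)
    if fmt == "npz":
        _write_npz(ts, path)
    elif fmt == "csv":
        _write_csv(ts, path)
    else:
        _write_edf(ts, path)
    return path


def read_trials(path, format: Optional[str] = None,
                trial_duration: Optional[float] = None) -> EEGTrialSet:
    """Load a trial set written by :func:`write_trials`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "npz":
        return _read_npz(path)
    if fmt == "csv":
        return _read_csv(path)
    return _read_edf(path, trial_duration=trial_duration)


# ---------------------------------------------------------------- npz

def _write_npz(ts: EEGTrialSet, path: Path) -> None:
    np.savez(
        path,
        data=ts.data,
        labels=np.asarray(ts.labels, dtype=np.int64),
        fs=np.asarray(ts.fs, dtype=float),
        channels=np.asarray(list(ts.channel_names)),
        duration=np.asarray(ts.trial_duration, dtype=float),
    )


def _read_npz(path: Path) -> EEGTrialSet:
    with np.load(path, allow_pickle=False) as z:
        if "labels" not in z:
            raise LabelError(f"{path} has no 'labels' array")
        data = z["data"]
        channels = [str(c) for c in z["channels"]]
        if data.shape[1] != len(channels):
            raise ChannelMismatchError(
                f"data has {data.shape[1]} channels but {len(channels)} names")
        return EEGTrialSet(
            data=data,
            labels=z["labels"].astype(np.int64),
            fs=float(z["fs"]),
            channel_names=channels,
            trial_duration=float(z["duration"]),
        )


# ---------------------------------------------------------------- csv

def _labels_path(path: Path) -> Path:
    return path.with_suffix(".labels.csv")


def _write_csv(ts: EEGTrialSet, path: Path) -> None:
    n_t, n_ch, n_s = ts.data.shape
    trial = np.repeat(np.arange(n_t), n_ch * n_s)
    channel = np.tile(np.repeat(np.asarray(ts.channel_names), n_s), n_t)
    sample = np.tile(np.arange(n_s), n_t * n_ch)
    df = pd.DataFrame({
        "trial": trial,
        "channel": channel,
        "sample_index": sample,
        "value": ts.data.ravel(),
    })
    df.to_csv(path, index=False)
    lp = _labels_path(path)
    with open(lp, "w") as fh:
        fh.write(f"# fs={ts.fs} duration={ts.trial_duration} "
                 f"channels={'|'.join(ts.channel_names)}\n")
        pd.DataFrame({
            "trial": np.arange(n_t),
            "label": [LABEL_NAMES[int(l)] for l in ts.labels],
        }).to_csv(fh, index=False)


def _read_csv(path: Path) -> EEGTrialSet:
    lp = _labels_path(path)
    if not lp.exists():
        raise LabelError(f"sidecar labels file {lp} not found")
    with open(lp) as fh:
        meta_line = fh.readline()
    if not meta_line.startswith("#"):
        raise LabelError(f"{lp} missing the metadata comment line")
    meta = dict(tok.split("=", 1) for tok in meta_line.lstrip("# ").split())
    fs = float(meta["fs"])
    duration = float(meta["duration"])
    channels = meta["channels"].split("|")

    lab_df = pd.read_csv(lp, comment="#")
    if "label" not in lab_df.columns:
        raise LabelError(f"{lp} has no 'label' column")
    try:
        labels = np.array([LABEL_NAMES.index(str(v)) for v in lab_df["label"]])
    except ValueError as exc:
        raise LabelError(f"unparsable label in {lp}: {exc}") from exc

    df = pd.read_csv(path)
    required = {"trial", "channel", "sample_index", "value"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path} missing columns {required - set(df.columns)}")
    n_t = int(df["trial"].max()) + 1
    n_s = int(df["sample_index"].max()) + 1
    seen = list(dict.fromkeys(df["channel"]))
    if set(seen) != set(channels):
        raise ChannelMismatchError(
            f"CSV channels {seen} do not match declared {channels}")
    data = np.empty((n_t, len(channels), n_s))
    df = df.sort_values(["trial", "sample_index"])
    for ci, ch in enumerate(channels):
        sub = df[df["channel"] == ch]
        if len(sub) != n_t * n_s:
            raise FormatError(f"channel {ch}: expected {n_t * n_s} rows, got {len(sub)}")
        data[:, ci, :] = sub["value"].to_numpy().reshape(n_t, n_s)
    return EEGTrialSet(data=data, labels=labels, fs=fs,
                       channel_names=channels, trial_duration=duration)


# ---------------------------------------------------------------- edf

_DIG_MIN, _DIG_MAX = -32768, 32767


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise FormatError(f"EDF header field too long: {text!r} > {width}")
    return b.ljust(width)


def _write_edf(ts: EEGTrialSet, path: Path) -> None:
    """Minimal EDF+C writer: one data record per trial, 16-bit samples,
    an EDF Annotations channel with a label event at each trial onset."""
    n_t, n_ch, n_s = ts.data.shape
    rec_dur = ts.trial_duration
    pmin = float(ts.data.min())
    pmax = float(ts.data.max())
    if pmax <= pmin:  # constant data: widen to a valid range
        pmax = pmin + 1.0
    scale = (_DIG_MAX - _DIG_MIN) / (pmax - pmin)

    ann_blobs = []
    for i in range(n_t):
        onset = i * rec_dur
        name = LABEL_NAMES[int(ts.labels[i])]
        tal = (f"+{onset:g}\x14\x14\x00"
               f"+{onset:g}\x15{rec_dur:g}\x14{name}\x14\x00")
        ann_blobs.append(tal.encode("ascii"))
    ann_bytes = max(len(b) for b in ann_blobs)
    ann_samples = (ann_bytes + 1) // 2 + 4  # int16 slots, small slack

    n_sig = n_ch + 1
    now = datetime.datetime(2000, 1, 1)
    header = b"".join([
        _pad("0", 8),
        _pad("X X X X", 80),
        _pad("Startdate 01-JAN-2000 X X X", 80),
        _pad(now.strftime("%d.%m.%y"), 8),
        _pad(now.strftime("%H.%M.%S"), 8),
        _pad(str(256 * (n_sig + 1)), 8),
        _pad("EDF+C", 44),
        _pad(str(n_t), 8),
        _pad(f"{rec_dur:g}", 8),
        _pad(str(n_sig), 4),
    ])
    labels = [f"EEG {name}" for name in ts.channel_names] + ["EDF Annotations"]
    fields = [
        (labels, 16),
        ([""] * n_sig, 80),                                   # transducer
        (["uV"] * n_ch + [""], 8),                            # physical dim
        ([f"{pmin:.8g}"[:8]] * n_ch + ["-1"], 8),             # physical min
        ([f"{pmax:.8g}"[:8]] * n_ch + ["1"], 8),              # physical max
        ([str(_DIG_MIN)] * n_sig, 8),                         # digital min
        ([str(_DIG_MAX)] * n_sig, 8),                         # digital max
        ([""] * n_sig, 80),                                   # prefiltering
        ([str(n_s)] * n_ch + [str(ann_samples)], 8),          # samples/record
        ([""] * n_sig, 32),                                   # reserved
    ]
    sig_header = b"".join(
        b"".join(_pad(v, width) for v in values) for values, width in fields)

    with open(path, "wb") as fh:
        fh.write(header + sig_header)
        for i in range(n_t):
            dig = np.round((ts.data[i] - pmin) * scale + _DIG_MIN)
            dig = np.clip(dig, _DIG_MIN, _DIG_MAX).astype("<i2")
            fh.write(dig.tobytes())
            blob = ann_blobs[i].ljust(2 * ann_samples, b"\x00")
            fh.write(blob)


def _read_edf(path: Path, trial_duration: Optional[float] = None) -> EEGTrialSet:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise FormatError("EDF reading requires the 'mne' package") from exc

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    data = raw.get_data(units="uV")  # channels x samples
    channels = [name.removeprefix("EEG ").strip() for name in raw.ch_names]

    onsets, labels, durations = [], [], []
    for onset, dur, desc in zip(raw.annotations.onset,
                                raw.annotations.duration,
                                raw.annotations.description):
        if desc in LABEL_NAMES:
            onsets.append(float(onset))
            durations.append(float(dur))
            labels.append(LABEL_NAMES.index(desc))
    if not labels:
        raise LabelError(f"{path} has no left/right trial annotations")
    dur = trial_duration or (durations[0] if durations[0] > 0
                             else onsets[1] - onsets[0] if len(onsets) > 1
                             else data.shape[1] / fs)
    n_s = int(round(fs * dur))
    trials = np.stack([
        data[:, int(round(o * fs)): int(round(o * fs)) + n_s] for o in onsets])
    return EEGTrialSet(data=trials, labels=np.array(labels), fs=fs,
                       channel_names=channels, trial_duration=dur)


__all__ = ["read_trials", "write_trials"]
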