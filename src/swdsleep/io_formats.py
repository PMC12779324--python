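"""Readers and writers for the formats the pipeline touches.

* EDF for signals.  Reading goes through :mod:`mne`; writing uses a
  minimal EDF writer (16-bit, one sampling rate across channels) since
  the wireless system's native format is out of scope and EDF is the
  interchange format polysomnography tools expect.  Channel roles are
  encoded in the channel label (names starting with ``EMG`` are EMG,
  everything else EEG).
* CSV for hypnograms (``epoch_index,start_s,label``) and event tables
  (``start_s,end_s,duration_s,onset_state,transition_flag``).
* JSON for per-animal summaries; YAML (with a schema version) for
  simulation configs.

Round trips are lossless up to the documented EDF 16-bit quantization.
"""

from __future__ import annotations

import datetime as dt
import json
import struct
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthdata import SimConfig, StateSpectrum
from .types import (
    EEG,
    EMG,
    Hypnogram,
    HYPNOGRAM_LABELS,
    Recording,
    ValidationError,
    validate_events,
)

# symmetric digital range so the physical<->digital map has zero offset
_EDF_DIG_MIN, _EDF_DIG_MAX = -32767, 32767


def _record_duration(fs: float, max_d: int = 60) -> tuple[int, int]:
    """Smallest whole-second record duration with an integral sample count."""
    for d in range(1, max_d + 1):
        n = fs * d
        if abs(n - round(n)) < 1e-6:
            return d, int(round(n))
    raise ValidationError(
        f"no whole-second EDF record duration <= {max_d} s fits fs = {fs} Hz"
    )


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def write_recording(recording: Recording, path) -> None:
    """Write a recording to EDF (16-bit; trailing partial record dropped)."""
    path = Path(path)
    fs = recording.fs
    rec_dur, spr = _record_duration(fs)
    n_records = recording.n_samples // spr
    n_ch = recording.signals.shape[0]
    hh, mm = recording.start_clock.split(":")
    start = dt.datetime(2000, 1, 1, int(hh), int(mm), 0)

    phys_min, phys_max, scaled = [], [], []
    for ch in range(n_ch):
        x = recording.signals[ch, : n_records * spr]
        amax = float(np.max(np.abs(x))) if x.size else 0.0
        amax = amax if amax > 0 else 1.0
        # scale by the 8-character ASCII value actually stored in the
        # header, so the round trip is exact to one quantization step
        amax = float(f"{amax * 1.001:.6g}"[:8])
        phys_min.append(-amax)
        phys_max.append(amax)
        dig = np.round(x / amax * _EDF_DIG_MAX).astype("<i2")
        scaled.append(dig.reshape(n_records, spr) if n_records else dig.reshape(0, spr))

    with open(path, "wb") as f:
        f.write(_pad("0", 8))
        f.write(_pad("X X X X", 80))
        f.write(_pad(f"Startdate 01-JAN-2000 X X swdsleep lights_off "
                     f"{recording.lights_off_clock}", 80))
        f.write(_pad(start.strftime("%d.%m.%y"), 8))
        f.write(_pad(start.strftime("%H.%M.%S"), 8))
        f.write(_pad(str(256 * (n_ch + 1)), 8))
        f.write(_pad("", 44))
        f.write(_pad(str(n_records), 8))
        f.write(_pad(str(rec_dur), 8))
        f.write(_pad(str(n_ch), 4))
        for name in recording.channel_names:
            f.write(_pad(name, 16))
        for _ in range(n_ch):
            f.write(_pad("", 80))  # transducer
        for _ in range(n_ch):
            f.write(_pad("uV", 8))
        for v in phys_min:
            f.write(_pad(f"{v:.6g}"[:8], 8))
        for v in phys_max:
            f.write(_pad(f"{v:.6g}"[:8], 8))
        for _ in range(n_ch):
            f.write(_pad(str(_EDF_DIG_MIN), 8))
        for _ in range(n_ch):
            f.write(_pad(str(_EDF_DIG_MAX), 8))
        for _ in range(n_ch):
            f.write(_pad("", 80))  # prefiltering
        for _ in range(n_ch):
            f.write(_pad(str(spr), 8))
        for _ in range(n_ch):
            f.write(_pad("", 32))
        for r in range(n_records):
            for ch in range(n_ch):
                f.write(scaled[ch][r].tobytes())


def infer_role(channel_name: str) -> str:
    return EMG if channel_name.upper().startswith("EMG") else EEG


def read_recording(path, lights_off_clock: str | None = None) -> Recording:
    """Read an EDF file into a :class:`Recording` (microvolts).

    Channel roles are inferred from names; the recording start clock
    comes from the EDF header.  ``lights_off_clock`` falls back to the
    value stamped in the recording-id field by :func:`write_recording`,
    else 19:00.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    names = list(raw.ch_names)
    data_uv = raw.get_data() * 1e6
    meas = raw.info["meas_date"]
    start_clock = f"{meas.hour:02d}:{meas.minute:02d}" if meas else "00:00"
    if lights_off_clock is None:
        lights_off_clock = "19:00"
        with open(path, "rb") as f:
            f.seek(88)
            rec_id = f.read(80).decode("ascii", errors="replace")
        if "lights_off" in rec_id:
            lights_off_clock = rec_id.split("lights_off")[1].strip().split()[0]
    return Recording(
        data_uv, fs, names, [infer_role(n) for n in names], start_clock, lights_off_clock
    )


# ---------------------------------------------------------------------------
# hypnogram / event CSV


def write_hypnogram(hypnogram: Hypnogram, path) -> None:
    df = pd.DataFrame(
        {
            "epoch_index": np.arange(hypnogram.n_epochs),
            "start_s": hypnogram.epoch_starts(),
            "label": hypnogram.labels,
        }
    )
    df.to_csv(path, index=False)


def read_hypnogram(path, epoch_len_s: float = 5.0) -> Hypnogram:
    """Read a hypnogram CSV; epoch length is inferred from the start grid
    when the file has at least two epochs."""
    df = pd.read_csv(path, dtype={"label": str})
    for col in ("epoch_index", "start_s", "label"):
        if col not in df.columns:
            raise ValidationError(f"hypnogram CSV missing column {col!r}")
    df = df.sort_values("epoch_index")
    if len(df) >= 2:
        steps = np.diff(df["start_s"].to_numpy())
        if np.ptp(steps) > 1e-6:
            raise ValidationError("hypnogram epoch grid is not uniform")
        epoch_len_s = float(steps[0])
    labels = df["label"].to_numpy(dtype="U8")
    bad = sorted(set(labels) - set(HYPNOGRAM_LABELS))
    if bad:
        raise ValidationError(f"unknown hypnogram labels in file: {bad}")
    return Hypnogram(labels, epoch_len_s)


def write_events(events: pd.DataFrame, path) -> None:
    validate_events(events)[list(
        ("start_s", "end_s", "duration_s", "onset_state", "transition_flag")
    )].to_csv(path, index=False)


def read_events(path) -> pd.DataFrame:
    """Read an event CSV; rows are sorted and invariants re-validated
    (overlapping events raise a :class:`ValidationError` naming rows)."""
    df = pd.read_csv(
        path,
        dtype={"onset_state": str},
    )
    if len(df) == 0:
        df = df.reindex(
            columns=["start_s", "end_s", "duration_s", "onset_state", "transition_flag"]
        )
        df["transition_flag"] = df["transition_flag"].astype(bool)
    else:
        df["transition_flag"] = df["transition_flag"].astype(bool)
    return validate_events(df)


# ---------------------------------------------------------------------------
# JSON summaries and YAML config

CONFIG_SCHEMA_VERSION = 1


def write_summary(summary, path) -> None:
    with open(path, "w") as f:
        json.dump(summary.to_dict() if hasattr(summary, "to_dict") else summary, f,
                  indent=2, allow_nan=True)


def _plain(obj):
    """Recursively convert numpy scalars/arrays so YAML can represent them."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _plain(obj.tolist())
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def write_config(config: SimConfig, path) -> None:
    d = _plain(asdict(config))
    d["state_spectra"] = {k: _plain(asdict(v)) if not isinstance(v, dict) else _plain(v)
                          for k, v in config.state_spectra.items()}
    with open(path, "w") as f:
        yaml.safe_dump({"schema_version": CONFIG_SCHEMA_VERSION, "simulation": d}, f,
                       sort_keys=False)


def read_config(path) -> SimConfig:
    with open(path) as f:
        doc = yaml.safe_load(f)
    if not isinstance(doc, dict) or "schema_version" not in doc:
        raise ValidationError("config file missing schema_version")
    if doc["schema_version"] != CONFIG_SCHEMA_VERSION:
        raise ValidationError(
            f"unsupported config schema version {doc['schema_version']}"
        )
    d = dict(doc["simulation"])
    d["state_spectra"] = {
        k: StateSpectrum(**v) for k, v in d.get("state_spectra", {}).items()
    }
    d["swd_duration_s"] = tuple(d["swd_duration_s"])
    d["swd_state_preference"] = tuple(d["swd_state_preference"])
    return SimConfig(**d)
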