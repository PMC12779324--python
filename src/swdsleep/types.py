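"""Core containers shared across the pipeline.

Conventions used everywhere in this package:

* times are seconds from recording start, as floats, on half-open
  intervals ``[start_s, end_s)``;
* epochs are indexed from 0 on a fixed grid of ``epoch_len_s`` seconds;
* signal amplitudes are microvolts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

WAKE = "WAKE"
NREM = "NREM"
REM = "REM"
SWD = "SWD"
UNSCORED = "UNSCORED"

#: the three vigilance states, in the order used for transition matrices
#: and confusion matrices
STATES = (WAKE, NREM, REM)

#: every label a hypnogram may carry
HYPNOGRAM_LABELS = (WAKE, NREM, REM, SWD, UNSCORED)

EEG = "EEG"
EMG = "EMG"

#: columns of an event table, in canonical order
EVENT_COLUMNS = ("start_s", "end_s", "duration_s", "onset_state", "transition_flag")


class RoleError(ValueError):
    """A recording lacks a channel role (e.g. EEG) required by an operation."""


class ValidationError(ValueError):
    """A container violates one of its documented invariants."""


@dataclass
class Recording:
    """Multichannel EEG/EMG time series in microvolts.

    Parameters
    ----------
    signals
        Array of shape ``(n_channels, n_samples)``, microvolts.
    fs
        Sampling rate in Hz.
    channel_names
        One name per channel.
    channel_roles
        One of ``"EEG"`` / ``"EMG"`` per channel.
    start_clock
        Wall-clock time ``"HH:MM"`` of the first sample, anchoring
        light--dark alignment.
    lights_off_clock
        Wall-clock time lights go off; the dark phase spans 12 h from
        this time (12:12 cycle).
    """

    signals: np.ndarray
    fs: float
    channel_names: list[str]
    channel_roles: list[str]
    start_clock: str = "07:00"
    lights_off_clock: str = "19:00"

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim == 1:
            self.signals = self.signals[None, :]
        if self.fs <= 0:
            raise ValidationError("sampling rate must be positive")
        n_ch = self.signals.shape[0]
        if len(self.channel_names) != n_ch or len(self.channel_roles) != n_ch:
            raise ValidationError("channel names/roles must match signal rows")
        bad = [r for r in self.channel_roles if r not in (EEG, EMG)]
        if bad:
            raise ValidationError(f"unknown channel roles: {bad}")

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, name: str) -> np.ndarray:
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}") from None
        return self.signals[idx]

    def channels_with_role(self, role: str) -> list[str]:
        return [n for n, r in zip(self.channel_names, self.channel_roles) if r == role]

    def first_eeg(self) -> str:
        eeg = self.channels_with_role(EEG)
        if not eeg:
            raise RoleError("recording has no EEG-tagged channel")
        return eeg[0]

    def first_emg(self) -> str:
        emg = self.channels_with_role(EMG)
        if not emg:
            raise RoleError("recording has no EMG-tagged channel")
        return emg[0]


@dataclass
class Hypnogram:
    """Per-epoch vigilance labels on a fixed epoch grid."""

    labels: np.ndarray
    epoch_len_s: float = 5.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype="U8")
        if self.epoch_len_s <= 0:
            raise ValidationError("epoch length must be positive")
        bad = set(np.unique(self.labels)) - set(HYPNOGRAM_LABELS)
        if bad:
            raise ValidationError(f"unknown hypnogram labels: {sorted(bad)}")

    @property
    def n_epochs(self) -> int:
        return len(self.labels)

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_len_s

    def epoch_starts(self) -> np.ndarray:
        return np.arange(self.n_epochs) * self.epoch_len_s

    def epoch_of(self, t_s: float) -> int:
        """Index of the epoch whose half-open interval contains ``t_s``."""
        idx = int(np.floor(t_s / self.epoch_len_s))
        if not 0 <= idx < self.n_epochs:
            raise ValidationError(f"time {t_s} s outside the hypnogram")
        return idx

    def copy(self) -> "Hypnogram":
        return Hypnogram(self.labels.copy(), self.epoch_len_s)


def events_frame(
    start_s,
    end_s,
    onset_state=None,
    transition_flag=None,
) -> pd.DataFrame:
    """Build a validated event table from parallel arrays."""
    start_s = np.asarray(start_s, dtype=float)
    end_s = np.asarray(end_s, dtype=float)
    n = len(start_s)
    if onset_state is None:
        onset_state = [UNSCORED] * n
    if transition_flag is None:
        transition_flag = [False] * n
    df = pd.DataFrame(
        {
            "start_s": start_s,
            "end_s": end_s,
            "duration_s": end_s - start_s,
            "onset_state": list(onset_state),
            "transition_flag": np.asarray(transition_flag, dtype=bool),
        }
    )
    return validate_events(df)


def empty_events() -> pd.DataFrame:
    return events_frame([], [])


def validate_events(events: pd.DataFrame, sort: bool = True) -> pd.DataFrame:
    """Validate (and optionally sort) an event table.

    Checks the invariants every event table must satisfy: positive
    durations, ``duration_s == end_s - start_s``, rows sorted by onset,
    and no overlapping events.  Raises :class:`ValidationError` naming
    the offending rows.
    """
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValidationError(f"event table missing columns: {missing}")
    events = events.reset_index(drop=True)
    bad = events.index[events["start_s"] >= events["end_s"]].tolist()
    if bad:
        raise ValidationError(f"events with start_s >= end_s at rows {bad}")
    dur_err = np.abs(
        events["duration_s"].to_numpy()
        - (events["end_s"].to_numpy() - events["start_s"].to_numpy())
    )
    bad = events.index[dur_err > 1e-9].tolist()
    if bad:
        raise ValidationError(f"duration_s inconsistent with start/end at rows {bad}")
    if sort:
        events = events.sort_values("start_s", kind="stable").reset_index(drop=True)
    starts = events["start_s"].to_numpy()
    ends = events["end_s"].to_numpy()
    if len(events) > 1:
        overlap = np.nonzero(starts[1:] < ends[:-1])[0]
        if overlap.size:
            rows = [(int(i), int(i) + 1) for i in overlap]
            raise ValidationError(f"overlapping events at row pairs {rows}")
    return events
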