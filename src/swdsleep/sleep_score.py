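"""Automated WAKE/NREM/REM scoring from EEG band powers and EMG tone.

A transparent percentile-threshold cascade, auto-calibrated per
recording so that absolute amplifier gain is irrelevant: high EMG tone
means wake; among quiet epochs, high delta power means NREM; a high
theta/delta ratio means REM.  A smoothing pass absorbs implausibly
short bouts and forbids direct wake-to-REM transitions, mirroring
rodent physiology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectral import BandScheme, _epoch_matrix, epoch_band_powers
from .types import (
    NREM,
    REM,
    STATES,
    UNSCORED,
    WAKE,
    Hypnogram,
    Recording,
    ValidationError,
)
from . import analytics_stats


@dataclass
class ScorerConfig:
    emg_wake_percentile: float = 60.0
    delta_nrem_percentile: float = 60.0
    theta_delta_rem_threshold: float = 1.5
    smoothing_min_bout_epochs: int = 2
    forbid_wake_to_rem: bool = True
    epoch_len_s: float = 5.0
    # a feature only participates in the cascade when its per-epoch
    # distribution is spread enough to carry state information (ratio of
    # its 85th to 15th percentile); guards single-state recordings
    feature_gap_ratio: float = 2.0
    # quiet, low-delta epochs: broadband (wake-like) spectra have a
    # markedly higher theta:delta ratio than slow-wave sleep
    theta_delta_broadband_threshold: float = 0.10

    def validate(self) -> None:
        for p in (self.emg_wake_percentile, self.delta_nrem_percentile):
            if not 0 < p < 100:
                raise ValidationError("percentiles must lie in (0, 100)")
        if self.theta_delta_rem_threshold <= 0:
            raise ValidationError("theta_delta_rem_threshold must be positive")
        if self.smoothing_min_bout_epochs < 1:
            raise ValidationError("smoothing_min_bout_epochs must be >= 1")


def extract_features(
    recording: Recording,
    channel_eeg: str | None = None,
    channel_emg: str | None = None,
    epoch_len_s: float = 5.0,
    scheme: BandScheme | None = None,
) -> pd.DataFrame:
    """Per-epoch features: delta/theta/total power, theta:delta ratio, EMG RMS.

    Epochs with (near-)zero EEG power are flagged ``degenerate`` and end
    up UNSCORED.
    """
    channel_eeg = channel_eeg or recording.first_eeg()
    channel_emg = channel_emg or recording.first_emg()
    bands = epoch_band_powers(recording, channel_eeg, epoch_len_s, scheme)
    emg = _epoch_matrix(recording.channel(channel_emg), recording.fs, epoch_len_s)
    emg_rms = np.sqrt(np.mean(emg**2, axis=1))
    total = bands.sum(axis=1).to_numpy()
    delta = bands["delta"].to_numpy()
    theta = bands["theta"].to_numpy()
    degenerate = (total <= 0) | (delta <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(degenerate, np.nan, theta / np.where(delta > 0, delta, np.nan))
    return pd.DataFrame(
        {
            "delta_power": delta,
            "theta_power": theta,
            "theta_delta_ratio": ratio,
            "emg_rms": emg_rms,
            "total_power": total,
            "degenerate": degenerate,
        }
    )


def classify_epochs(features: pd.DataFrame, config: ScorerConfig | None = None) -> np.ndarray:
    """Raw per-epoch labels from the percentile-threshold cascade.

    Thresholds are calibrated per recording: the EMG threshold is the
    ``emg_wake_percentile`` of per-epoch EMG RMS, the delta threshold the
    ``delta_nrem_percentile`` of per-epoch delta power (degenerate epochs
    excluded from both calibrations).
    """
    config = config or ScorerConfig()
    config.validate()
    if len(features) == 0:
        raise ValidationError("no epochs to classify")
    ok = ~features["degenerate"].to_numpy()
    if not ok.any():
        raise ValidationError("all epochs degenerate; cannot calibrate thresholds")
    emg = features["emg_rms"].to_numpy()
    delta = features["delta_power"].to_numpy()
    ratio = features["theta_delta_ratio"].to_numpy()

    def discriminates(x):
        lo, hi = np.percentile(x[ok], [15, 85])
        return lo > 0 and hi / lo >= config.feature_gap_ratio

    emg_thr = np.percentile(emg[ok], config.emg_wake_percentile)
    delta_thr = np.percentile(delta[ok], config.delta_nrem_percentile)
    labels = np.full(len(features), UNSCORED, dtype="U8")
    wake = ok & (emg >= emg_thr) if discriminates(emg) else np.zeros(len(ok), bool)
    nrem = (
        ok & ~wake & (delta >= delta_thr)
        if discriminates(delta)
        else np.zeros(len(ok), bool)
    )
    rem = ok & ~wake & ~nrem & (ratio >= config.theta_delta_rem_threshold)
    rest = ok & ~wake & ~nrem & ~rem
    labels[wake] = WAKE
    labels[nrem] = NREM
    labels[rem] = REM
    # quiet epochs with neither slow-wave dominance nor clear theta:
    # broadband spectra are wake, strongly delta-skewed ones NREM
    labels[rest] = np.where(
        ratio[rest] >= config.theta_delta_broadband_threshold, WAKE, NREM
    )
    return labels


def _absorb_short_bouts(labels: np.ndarray, min_epochs: int) -> np.ndarray:
    out = labels.copy()
    bouts = analytics_stats.segment_bouts(Hypnogram(out, 1.0))
    # bouts touching either record boundary are kept: their true extent
    # beyond the recording is unknown
    for _, b in bouts.iterrows():
        if b["start_epoch"] == 0 or b["end_epoch"] == len(out):
            continue
        if b["end_epoch"] - b["start_epoch"] < min_epochs:
            out[b["start_epoch"] : b["end_epoch"]] = out[b["start_epoch"] - 1]
    return out


def _forbid_wake_to_rem(labels: np.ndarray) -> np.ndarray:
    out = labels.copy()
    bouts = analytics_stats.segment_bouts(Hypnogram(out, 1.0))
    prev_state = None
    for _, b in bouts.iterrows():
        if b["state"] == REM and prev_state == WAKE:
            out[b["start_epoch"] : b["end_epoch"]] = NREM
        prev_state = b["state"]
    return out


def smooth_hypnogram(raw_labels: np.ndarray, config: ScorerConfig | None = None) -> Hypnogram:
    """Absorb short bouts and forbid wake-to-REM transitions.

    Iterated to a fixed point, so applying the smoother twice changes
    nothing.  Short bouts are absorbed into the preceding state (the
    following state at the start of the record).
    """
    config = config or ScorerConfig()
    labels = np.asarray(raw_labels, dtype="U8").copy()
    for _ in range(len(labels) + 1):
        new = _absorb_short_bouts(labels, config.smoothing_min_bout_epochs)
        if config.forbid_wake_to_rem:
            new = _forbid_wake_to_rem(new)
        if np.array_equal(new, labels):
            break
        labels = new
    return Hypnogram(labels, config.epoch_len_s)


def score_sleep(
    recording: Recording,
    config: ScorerConfig | None = None,
    channel_eeg: str | None = None,
    channel_emg: str | None = None,
    scheme: BandScheme | None = None,
) -> Hypnogram:
    """Full scoring pipeline: features -> cascade -> smoothing."""
    config = config or ScorerConfig()
    features = extract_features(
        recording, channel_eeg, channel_emg, config.epoch_len_s, scheme
    )
    raw = classify_epochs(features, config)
    return smooth_hypnogram(raw, config)


def confusion_matrix(reference: Hypnogram, automated: Hypnogram) -> pd.DataFrame:
    """3x3 epoch counts, rows = reference, columns = automated.

    Only epochs where both hypnograms carry one of the three vigilance
    states are tallied; SWD/UNSCORED epochs are excluded.
    """
    if reference.n_epochs != automated.n_epochs or not np.isclose(
        reference.epoch_len_s, automated.epoch_len_s
    ):
        raise ValidationError("hypnograms must share the same epoch grid")
    order = (REM, NREM, WAKE)
    mat = pd.DataFrame(0, index=order, columns=order, dtype=int)
    both = np.isin(reference.labels, order) & np.isin(automated.labels, order)
    for r in order:
        for a in order:
            mat.loc[r, a] = int(
                np.sum(both & (reference.labels == r) & (automated.labels == a))
            )
    return mat


def validate_against(
    automated: Hypnogram, reference: Hypnogram
) -> tuple[pd.DataFrame, dict[str, float], float, float]:
    """Agreement of an automated hypnogram with a reference.

    Returns the confusion matrix, per-state agreement percentages
    (diagonal over reference row total), global agreement percent
    (trace over total), and Cohen's kappa.
    """
    mat = confusion_matrix(reference, automated)
    per_state = {}
    for s in mat.index:
        row_total = mat.loc[s].sum()
        per_state[s] = 100.0 * mat.loc[s, s] / row_total if row_total else float("nan")
    total = mat.to_numpy().sum()
    if total == 0:
        raise ValidationError("no co-scored epochs to compare")
    global_pct = 100.0 * np.trace(mat.to_numpy()) / total
    kappa = analytics_stats.cohens_kappa(mat.to_numpy())
    return mat, per_state, float(global_pct), float(kappa)
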