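"""Spike-and-wave discharge detection by harmonic spectral peaks.

An epoch is flagged as seizure activity when its power spectrum shows a
prominent local maximum with fundamental in the 5-10 Hz band *and* a
local maximum at twice that fundamental, and the epoch's amplitude
exceeds a threshold relative to the recording's median epoch RMS.
Flagged epochs are then merged into events.

Detection runs on a 1-s grid, finer than the 5-s sleep-scoring epoch,
so event boundaries are resolved to about a second.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from scipy.signal import find_peaks

from .spectral import PsdEstimate, _epoch_matrix, welch_psd
from .types import Recording, ValidationError, empty_events, events_frame


@dataclass
class DetectorConfig:
    fundamental_lo_hz: float = 5.0
    fundamental_hi_hz: float = 10.0
    harmonic_tolerance_hz: float = 1.0
    peak_prominence_ratio: float = 3.0  # peak >= ratio x local spectral baseline
    amplitude_gain_threshold: float = 2.0  # epoch RMS >= thr x median epoch RMS
    min_event_s: float = 1.0
    merge_gap_s: float = 1.0  # one detection epoch
    detection_epoch_s: float = 1.0
    baseline_smooth_hz: float = 8.0  # width of the median-filter baseline
    harmonic_prominence_ratio: float = 1.5  # harmonic peak vs local baseline
    psd_smooth_bins: int = 3  # Daniell smoothing of the epoch periodogram

    def validate(self, fs: float) -> None:
        if not 0 < self.fundamental_lo_hz < self.fundamental_hi_hz < fs / 2:
            raise ValidationError("fundamental band must satisfy 0 < lo < hi < fs/2")
        for name in (
            "harmonic_tolerance_hz",
            "peak_prominence_ratio",
            "amplitude_gain_threshold",
            "min_event_s",
            "detection_epoch_s",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


def _spectral_baseline(power: np.ndarray, df_hz: float, width_hz: float) -> np.ndarray:
    """Median-smoothed PSD baseline, robust to the 1/f slope and to peaks."""
    size = max(3, int(round(width_hz / df_hz)) | 1)
    return median_filter(power, size=size, mode="nearest")


def epoch_swd_score(
    psd: PsdEstimate,
    epoch_rms: float,
    config: DetectorConfig,
    reference_rms: float,
) -> tuple[bool, float | None]:
    """Score one detection epoch.

    Returns ``(flag, f0)``: flag is True iff (i) the PSD has a local
    maximum f0 inside the fundamental band whose height is at least
    ``peak_prominence_ratio`` times the local median baseline, (ii) a
    local maximum exists at ``2*f0`` within the harmonic tolerance, and
    (iii) ``epoch_rms >= amplitude_gain_threshold * reference_rms``.
    """
    df = psd.resolution_hz
    if df > config.harmonic_tolerance_hz:
        raise ValidationError(
            f"PSD resolution {df:.2f} Hz coarser than the harmonic tolerance"
        )
    if epoch_rms < config.amplitude_gain_threshold * reference_rms:
        return False, None
    power = psd.power
    if config.psd_smooth_bins > 1:
        # light Daniell smoothing tames single-segment periodogram noise
        kernel = np.ones(config.psd_smooth_bins) / config.psd_smooth_bins
        power = np.convolve(power, kernel, mode="same")
    baseline = _spectral_baseline(power, df, config.baseline_smooth_hz)
    peaks, _ = find_peaks(power)
    if peaks.size == 0:
        return False, None
    f_peaks = psd.freqs[peaks]
    in_band = (f_peaks >= config.fundamental_lo_hz) & (f_peaks <= config.fundamental_hi_hz)
    ratios = power[peaks] / np.maximum(baseline[peaks], 1e-300)
    candidates = peaks[in_band & (ratios >= config.peak_prominence_ratio)]
    if candidates.size == 0:
        return False, None
    # strongest prominent fundamental first; the first-harmonic local
    # maximum must itself stand clear of the baseline
    for idx in candidates[np.argsort(power[candidates])[::-1]]:
        f0 = float(psd.freqs[idx])
        harmonic = (np.abs(f_peaks - 2 * f0) <= config.harmonic_tolerance_hz) & (
            ratios >= config.harmonic_prominence_ratio
        )
        if harmonic.any():
            return True, f0
    return False, None


def score_epochs(
    recording: Recording,
    config: DetectorConfig | None = None,
    channel: str | None = None,
) -> pd.DataFrame:
    """Per-epoch flags and fundamentals over the whole recording."""
    config = config or DetectorConfig()
    config.validate(recording.fs)
    channel = channel or recording.first_eeg()
    x = recording.channel(channel)
    mat = _epoch_matrix(x, recording.fs, config.detection_epoch_s)
    n_epochs = mat.shape[0]
    if n_epochs == 0:
        return pd.DataFrame({"flag": [], "f0_hz": [], "rms": []})
    # one-shot PSD of all epochs: single Hann segment per detection epoch,
    # zero-padded x2 so the frequency grid is finer than the harmonic tolerance
    nperseg = int(round(config.detection_epoch_s * recording.fs))
    psd_all = welch_psd(mat, recording.fs, window_s=config.detection_epoch_s,
                        overlap_fraction=0.0, nfft=2 * nperseg)
    rms = np.sqrt(np.mean(mat**2, axis=1))
    reference = float(np.median(rms))
    flags = np.zeros(n_epochs, dtype=bool)
    f0s = np.full(n_epochs, np.nan)
    loud = rms >= config.amplitude_gain_threshold * reference
    for i in np.nonzero(loud)[0]:
        epoch_psd = PsdEstimate(psd_all.freqs, psd_all.power[i], 1,
                                config.detection_epoch_s)
        flags[i], f0 = epoch_swd_score(epoch_psd, rms[i], config, reference)
        if f0 is not None:
            f0s[i] = f0
    return pd.DataFrame({"flag": flags, "f0_hz": f0s, "rms": rms})


def merge_flags_to_events(
    flags: np.ndarray | pd.DataFrame,
    config: DetectorConfig | None = None,
) -> pd.DataFrame:
    """Merge flagged detection epochs into a sorted event table.

    Runs of flagged epochs separated by gaps of at most ``merge_gap_s``
    are bridged into one event; events shorter than ``min_event_s`` are
    discarded.
    """
    config = config or DetectorConfig()
    if isinstance(flags, pd.DataFrame):
        flag_arr = flags["flag"].to_numpy(dtype=bool)
    else:
        flag_arr = np.asarray(flags, dtype=bool)
    ep = config.detection_epoch_s
    gap_epochs = int(np.floor(config.merge_gap_s / ep + 1e-9))
    idx = np.nonzero(flag_arr)[0]
    if idx.size == 0:
        return empty_events()
    runs: list[list[int]] = [[int(idx[0]), int(idx[0])]]
    for i in idx[1:]:
        if i - runs[-1][1] - 1 <= gap_epochs:
            runs[-1][1] = int(i)
        else:
            runs.append([int(i), int(i)])
    starts, ends = [], []
    for a, b in runs:
        s, e = a * ep, (b + 1) * ep
        if e - s >= config.min_event_s - 1e-9:
            starts.append(s)
            ends.append(e)
    return events_frame(starts, ends)


def detect_swds(
    recording: Recording,
    config: DetectorConfig | None = None,
    channel: str | None = None,
) -> pd.DataFrame:
    """Full detection pipeline: per-epoch scoring then event merging."""
    config = config or DetectorConfig()
    if recording.n_samples == 0:
        return empty_events()
    scored = score_epochs(recording, config, channel)
    return merge_flags_to_events(scored, config)


def event_summary(events: pd.DataFrame) -> tuple[int, float, float]:
    """``(count, mean_duration_s, total_duration_s)``; mean is NaN when empty."""
    count = len(events)
    total = float(events["duration_s"].sum()) if count else 0.0
    mean = total / count if count else float("nan")
    return count, mean, total


def match_events(
    detected: pd.DataFrame,
    truth: pd.DataFrame,
    min_overlap_fraction: float = 0.5,
) -> tuple[int, int, int]:
    """Match detections to ground truth by maximal overlap.

    A truth event is recovered when some detection overlaps at least
    ``min_overlap_fraction`` of its duration; each detection is assigned
    to at most one truth event (maximal-overlap assignment).  Returns
    ``(n_matched, n_detected, n_truth)`` from which recall and precision
    follow.
    """
    if len(detected) == 0 or len(truth) == 0:
        return 0, len(detected), len(truth)
    d_start = detected["start_s"].to_numpy()
    d_end = detected["end_s"].to_numpy()
    overlap_best = np.full(len(truth), 0.0)
    assigned = np.full(len(detected), -1)
    for ti, (ts, te, td) in enumerate(
        zip(truth["start_s"], truth["end_s"], truth["duration_s"])
    ):
        ov = np.minimum(d_end, te) - np.maximum(d_start, ts)
        ov = np.where(assigned >= 0, -np.inf, ov)
        di = int(np.argmax(ov))
        if ov[di] >= min_overlap_fraction * td:
            assigned[di] = ti
            overlap_best[ti] = ov[di]
    n_matched = int((assigned >= 0).sum())
    return n_matched, len(detected), len(truth)
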