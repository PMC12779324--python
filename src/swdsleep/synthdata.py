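"""Synthetic rodent EEG/EMG with known hypnogram and spike-wave events.

The generator emulates the statistical structure the downstream analysis
assumes: an epoch-stepped Markov chain over WAKE/NREM/REM with a dark-phase
wake bias, state-conditioned EEG spectra (delta-dominant NREM, theta-dominant
REM, broadband wake) on a 1/f background, EMG tone with REM atonia, and
injectable periodic spike-wave events with a 5-10 Hz fundamental whose sharp
spike component guarantees harmonic spectral peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import clock
from .types import (
    EEG,
    EMG,
    NREM,
    REM,
    STATES,
    WAKE,
    Hypnogram,
    Recording,
    ValidationError,
    empty_events,
    events_frame,
)


class ConfigurationError(ValueError):
    """A simulation config violates one of its invariants."""


class PlacementError(RuntimeError):
    """Event placement failed after bounded retries (rate too high)."""


@dataclass
class StateSpectrum:
    """EEG/EMG signature of one vigilance state.

    The per-state EEG power spectrum is ``f**-slope`` plus an optional
    Gaussian band boost; ``boost_gain`` is the ratio of boost power to
    background power.  ``emg_jitter`` is the lognormal sigma of per-epoch
    EMG RMS variability.
    """

    slope: float
    boost_hz: float | None
    boost_gain: float
    boost_width_hz: float
    eeg_rms_uv: float
    emg_rms_uv: float
    emg_jitter: float = 0.15


def default_state_spectra() -> dict[str, StateSpectrum]:
    # wake: broadband 1/f, high muscle tone; NREM: high-amplitude slow
    # activity (delta boost); REM: theta-dominant low-amplitude EEG with
    # muscle atonia.
    return {
        WAKE: StateSpectrum(1.0, None, 0.0, 1.5, 60.0, 30.0),
        NREM: StateSpectrum(2.0, 2.5, 3.0, 1.2, 85.0, 10.0),
        REM: StateSpectrum(1.0, 7.0, 2.5, 1.5, 60.0, 4.0),
    }


def default_transition_matrix() -> np.ndarray:
    # Stationary distribution (0.40, 0.50, 0.10) over (WAKE, NREM, REM)
    # with 5-s epochs: mean bouts ~111 s wake, ~100 s NREM, ~50 s REM.
    return np.array(
        [
            [0.955, 0.045, 0.000],
            [0.030, 0.950, 0.020],
            [0.030, 0.070, 0.900],
        ]
    )


@dataclass
class SimConfig:
    """Everything that defines one simulated recording."""

    duration_s: float = 24 * 3600.0
    epoch_len_s: float = 5.0
    fs: float = 250.4
    state_transition_matrix: np.ndarray = field(default_factory=default_transition_matrix)
    dark_phase_wake_bias: float = 1.02
    state_spectra: dict[str, StateSpectrum] = field(default_factory=default_state_spectra)
    swd_rate_per_h: float = 10.0
    swd_duration_s: tuple[float, float] = (4.0, 1.5)  # mean, sd
    swd_min_duration_s: float = 1.5
    swd_f0_hz: float = 7.0
    swd_amplitude_gain: float = 5.0
    swd_state_preference: tuple[float, float, float] = (0.948, 0.044, 0.005)
    initial_state: str = WAKE
    start_clock: str = "07:00"
    lights_off_clock: str = "19:00"
    crossfade_s: float = 0.25
    highest_band_edge_hz: float = 48.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.state_transition_matrix = np.asarray(self.state_transition_matrix, float)
        # normalize the onset-state preference (defaults come from observed
        # percentages 94.8/4.4/0.5 that round to 99.7)
        pref = np.asarray(self.swd_state_preference, float)
        if pref.min() < 0:
            raise ConfigurationError("swd_state_preference entries must be >= 0")
        self.swd_state_preference = tuple(pref / pref.sum())
        self.validate()

    def validate(self) -> None:
        P = self.state_transition_matrix
        if P.shape != (3, 3) or (P < 0).any() or np.abs(P.sum(axis=1) - 1).max() > 1e-9:
            raise ConfigurationError(
                "state_transition_matrix must be 3x3 row-stochastic with "
                "non-negative entries"
            )
        if not 5.0 <= self.swd_f0_hz <= 10.0:
            raise ConfigurationError("swd_f0_hz must lie in [5, 10] Hz")
        if self.fs <= 2 * self.highest_band_edge_hz:
            raise ConfigurationError(
                "fs must exceed twice the highest analysis band edge"
            )
        if abs(sum(self.swd_state_preference) - 1) > 1e-9:
            raise ConfigurationError("swd_state_preference must sum to 1")
        if self.duration_s < 0 or self.epoch_len_s <= 0:
            raise ConfigurationError("invalid duration or epoch length")
        if self.initial_state not in STATES:
            raise ConfigurationError(f"unknown initial state {self.initial_state!r}")

    @property
    def n_epochs(self) -> int:
        return int(np.floor(self.duration_s / self.epoch_len_s))

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one named randomness stream."""
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stream]))


_HYPNO_STREAM, _SIGNAL_STREAM, _EVENT_STREAM = 11, 23, 37


def _effective_matrix(config: SimConfig, dark: bool) -> np.ndarray:
    """Transition matrix with WAKE->REM forbidden and the dark-phase bias."""
    P = config.state_transition_matrix.copy()
    # REM is entered only from NREM: move any WAKE->REM mass to WAKE->NREM
    P[0, 1] += P[0, 2]
    P[0, 2] = 0.0
    if dark and config.dark_phase_wake_bias != 1.0:
        ww = min(P[0, 0] * config.dark_phase_wake_bias, 1.0)
        rest = P[0, 1] + P[0, 2]
        scale = (1.0 - ww) / rest if rest > 0 else 0.0
        P[0] = [ww, P[0, 1] * scale, P[0, 2] * scale]
    return P


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Left eigenvector of a row-stochastic matrix for eigenvalue 1."""
    w, v = np.linalg.eig(np.asarray(P, float).T)
    i = int(np.argmin(np.abs(w - 1)))
    s = np.real(v[:, i])
    return s / s.sum()


def generate_hypnogram(config: SimConfig) -> Hypnogram:
    """Sample the per-epoch Markov chain over WAKE/NREM/REM.

    One transition per epoch; the dark-phase variant of the matrix is
    used for epochs whose start time falls in the 12-h dark phase.
    Deterministic given ``config.seed``.
    """
    config.validate()
    n = config.n_epochs
    rng = config.rng(_HYPNO_STREAM)
    cum = {
        False: np.cumsum(_effective_matrix(config, False), axis=1),
        True: np.cumsum(_effective_matrix(config, True), axis=1),
    }
    starts = np.arange(n) * config.epoch_len_s
    dark = clock.is_dark(config.start_clock, starts, config.lights_off_clock)
    u = rng.random(n)
    labels = np.empty(n, dtype="U8")
    state = STATES.index(config.initial_state)
    for i in range(n):
        labels[i] = STATES[state]
        state = int(np.searchsorted(cum[bool(dark[i])][state], u[i], side="right"))
        state = min(state, 2)
    return Hypnogram(labels, config.epoch_len_s)


def _psd_shape(freqs: np.ndarray, spec: StateSpectrum) -> np.ndarray:
    """Unnormalized PSD shape for one state (zero at DC)."""
    f = np.maximum(freqs, 0.5)
    base = f ** (-spec.slope)
    base /= np.trapezoid(base[1:], freqs[1:]) if len(freqs) > 2 else 1.0
    shape = base.copy()
    if spec.boost_hz is not None and spec.boost_gain > 0:
        bump = np.exp(-((freqs - spec.boost_hz) ** 2) / (2 * spec.boost_width_hz**2))
        area = np.trapezoid(bump[1:], freqs[1:])
        if area > 0:
            shape = base + spec.boost_gain * bump / area
    shape[freqs == 0] = 0.0
    return shape


def _colored_noise(n: int, fs: float, spec: StateSpectrum, rng) -> np.ndarray:
    """Gaussian noise with the state's PSD shape, scaled to its RMS."""
    if n == 0:
        return np.zeros(0)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    amp = np.sqrt(_psd_shape(freqs, spec))
    z = rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))
    x = np.fft.irfft(z * amp, n=n)
    sd = x.std()
    return x * (spec.eeg_rms_uv / sd) if sd > 0 else x


def synthesize_signals(hypnogram: Hypnogram, config: SimConfig) -> Recording:
    """Render EEG + EMG for a hypnogram.

    EEG is synthesized per state bout (stationary within a bout) with a
    raised-cosine crossfade at bout boundaries to avoid spectral splatter;
    EMG is white noise whose per-epoch RMS is the state level with
    lognormal jitter.
    """
    config.validate()
    n_epochs = hypnogram.n_epochs
    spe = config.epoch_len_s * config.fs  # samples per epoch (may be non-integer)
    n_samples = int(round(n_epochs * spe))
    eeg = np.zeros(n_samples)
    emg = np.zeros(n_samples)
    if n_samples == 0:
        return Recording(
            np.zeros((2, 0)), config.fs, ["EEG1", "EMG1"], [EEG, EMG],
            config.start_clock, config.lights_off_clock,
        )
    rng = config.rng(_SIGNAL_STREAM)
    cf = int(round(config.crossfade_s * config.fs))
    ramp = np.sin(0.5 * np.pi * np.linspace(0, 1, cf)) ** 2 if cf else np.zeros(0)

    labels = hypnogram.labels
    change = np.nonzero(labels[1:] != labels[:-1])[0] + 1
    bout_edges = np.concatenate(([0], change, [n_epochs]))
    for b0, b1 in zip(bout_edges[:-1], bout_edges[1:]):
        s0, s1 = int(round(b0 * spe)), int(round(b1 * spe))
        spec = config.state_spectra[labels[b0]]
        lead = min(cf, s0)  # extend into the previous bout for the crossfade
        y = _colored_noise(s1 - s0 + lead, config.fs, spec, rng)
        if lead:
            eeg[s0 - lead : s0] = eeg[s0 - lead : s0] * (1 - ramp[-lead:]) + y[:lead] * ramp[-lead:]
        eeg[s0:s1] = y[lead:]
    for i in range(n_epochs):
        s0, s1 = int(round(i * spe)), int(round((i + 1) * spe))
        spec = config.state_spectra[labels[i]]
        level = spec.emg_rms_uv * np.exp(spec.emg_jitter * rng.standard_normal())
        emg[s0:s1] = rng.standard_normal(s1 - s0) * level
    return Recording(
        np.vstack([eeg, emg]), config.fs, ["EEG1", "EMG1"], [EEG, EMG],
        config.start_clock, config.lights_off_clock,
    )


def swd_waveform(duration_s: float, fs: float, f0_hz: float) -> np.ndarray:
    """Periodic spike-and-slow-wave template, unit RMS, tapered edges.

    Each cycle is a narrow Gaussian spike riding on a slow wave at the
    fundamental; the spike's sharpness puts substantial power at the
    harmonics of ``f0_hz``, which is what the spectral detector keys on.
    """
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    phase = (t * f0_hz) % 1.0
    spike = np.exp(-((phase - 0.3) ** 2) / (2 * 0.04**2))
    slow = -0.55 * np.cos(2 * np.pi * (phase - 0.3))
    w = spike + slow
    taper_n = min(int(round(0.15 * fs)), n // 2)
    if taper_n:
        ramp = np.sin(0.5 * np.pi * np.linspace(0, 1, taper_n)) ** 2
        w[:taper_n] *= ramp
        w[-taper_n:] *= ramp[::-1]
    r = np.sqrt(np.mean(w**2))
    return w / r if r > 0 else w


def _place_events(
    hypnogram: Hypnogram,
    config: SimConfig,
    rng: np.random.Generator,
    n_events: int,
    min_gap_s: float = 5.0,
    max_retries: int = 2000,
) -> pd.DataFrame:
    """Draw non-overlapping ground-truth events honoring the state preference."""
    if n_events == 0:
        return empty_events()
    total_s = hypnogram.duration_s
    epoch_len = hypnogram.epoch_len_s
    mean_d, sd_d = config.swd_duration_s
    state_epochs = {s: np.nonzero(hypnogram.labels == s)[0] for s in STATES}
    placed: list[tuple[float, float, str]] = []
    for _ in range(n_events):
        ok = False
        for _try in range(max_retries):
            dur = max(config.swd_min_duration_s, rng.normal(mean_d, sd_d))
            state = STATES[rng.choice(3, p=np.asarray(config.swd_state_preference))]
            pool = state_epochs[state]
            if pool.size == 0:
                pool = np.arange(hypnogram.n_epochs)
            epoch = int(pool[rng.integers(pool.size)])
            start = epoch * epoch_len + rng.uniform(0, epoch_len)
            end = start + dur
            if end > total_s:
                continue
            if any(start < e + min_gap_s and end > s - min_gap_s for s, e, _ in placed):
                continue
            placed.append((start, end, hypnogram.labels[epoch]))
            ok = True
            break
        if not ok:
            raise PlacementError(
                f"could not place {n_events} non-overlapping events "
                f"(placed {len(placed)}); reduce swd_rate_per_h"
            )
    placed.sort()
    return events_frame(
        [p[0] for p in placed], [p[1] for p in placed], onset_state=[p[2] for p in placed]
    )


def inject_swd_events(
    recording: Recording,
    hypnogram: Hypnogram,
    config: SimConfig,
    n_events: int | None = None,
) -> tuple[Recording, pd.DataFrame]:
    """Superimpose spike-wave events on every EEG channel.

    The number of events is Poisson with mean ``swd_rate_per_h x hours``
    unless ``n_events`` requests an exact count.  Each event's amplitude
    is ``swd_amplitude_gain`` times the local pre-injection background
    RMS.  Returns the modified recording and the ground-truth table.
    """
    config.validate()
    rng = config.rng(_EVENT_STREAM)
    hours = recording.duration_s / 3600.0
    if n_events is None:
        n_events = int(rng.poisson(config.swd_rate_per_h * hours))
    if n_events == 0:
        return recording, empty_events()
    events = _place_events(hypnogram, config, rng, n_events)
    signals = recording.signals.copy()
    eeg_rows = [i for i, r in enumerate(recording.channel_roles) if r == EEG]
    if not eeg_rows:
        raise ValidationError("recording has no EEG channel to inject into")
    for start, end in zip(events["start_s"], events["end_s"]):
        i0 = int(round(start * recording.fs))
        i1 = min(int(round(end * recording.fs)), recording.n_samples)
        w = swd_waveform((i1 - i0) / recording.fs, recording.fs, config.swd_f0_hz)[: i1 - i0]
        for row in eeg_rows:
            local_rms = np.sqrt(np.mean(signals[row, i0:i1] ** 2))
            signals[row, i0:i1] += config.swd_amplitude_gain * local_rms * w
    out = Recording(
        signals, recording.fs, list(recording.channel_names),
        list(recording.channel_roles), recording.start_clock, recording.lights_off_clock,
    )
    return out, events


@dataclass
class GroupEffect:
    """Multiplicative effects distinguishing a cohort group from baseline.

    ``rem_dwell`` scales the REM self-transition probability (shorter REM
    bouts, hence less REM time, when < 1); ``swd_rate`` scales the event
    rate.
    """

    rem_dwell: float = 1.0
    swd_rate: float = 1.0


@dataclass
class CohortAnimal:
    group: str
    index: int
    seed: int
    recording: Recording | None
    hypnogram: Hypnogram
    events: pd.DataFrame


def _apply_effect(config: SimConfig, effect: GroupEffect, seed: int) -> SimConfig:
    P = config.state_transition_matrix.copy()
    rr = P[2, 2] * effect.rem_dwell
    exits = P[2, 0] + P[2, 1]
    scale = (1.0 - rr) / exits if exits > 0 else 0.0
    P[2] = [P[2, 0] * scale, P[2, 1] * scale, rr]
    return replace(
        config,
        state_transition_matrix=P,
        swd_rate_per_h=config.swd_rate_per_h * effect.swd_rate,
        seed=seed,
    )


def simulate_animal(config: SimConfig, synthesize: bool = True) -> CohortAnimal:
    """One full simulated animal-day: hypnogram, (optionally) signals, events."""
    hyp = generate_hypnogram(config)
    if synthesize:
        rec = synthesize_signals(hyp, config)
        rec, events = inject_swd_events(rec, hyp, config)
    else:
        rec = None
        rng = config.rng(_EVENT_STREAM)
        n = int(rng.poisson(config.swd_rate_per_h * config.duration_s / 3600.0))
        events = _place_events(hyp, config, rng, n)
    return CohortAnimal("", 0, config.seed, rec, hyp, events)


def make_cohort(
    group_specs: list[tuple[str, int, GroupEffect]],
    seed: int,
    base_config: SimConfig | None = None,
    synthesize: bool = True,
) -> list[CohortAnimal]:
    """Simulate a multi-group cohort with per-animal derived seeds.

    Each animal's seed is mixed deterministically from ``(seed, group
    index, animal index)``, so adding animals or groups never reshuffles
    the data of existing ones.  With ``synthesize=False`` only ground
    truth (hypnogram + event table) is produced, which is what cohort-
    level power analyses need and orders of magnitude cheaper.
    """
    if not group_specs:
        raise ConfigurationError("group_specs must not be empty")
    base = base_config or SimConfig()
    animals = []
    for gi, (label, n, effect) in enumerate(group_specs):
        if n < 1:
            raise ConfigurationError(f"group {label!r} must have n >= 1")
        for ai in range(n):
            aseed = int(
                np.random.SeedSequence([int(seed), gi, ai]).generate_state(1)[0]
                % (2**31)
            )
            cfg = _apply_effect(base, effect, aseed)
            animal = simulate_animal(cfg, synthesize=synthesize)
            animal.group, animal.index = label, ai
            animals.append(animal)
    return animals
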