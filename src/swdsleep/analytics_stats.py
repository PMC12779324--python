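"""Bout/transition analytics and the self-contained statistics.

Covers bout segmentation, state totals with seizure-time masking,
hourly and light--dark aggregation, onset-state assignment with
wake->NREM transition flagging, percent-of-baseline normalization, and
the statistical tests the pipeline needs end-to-end: Fisher's exact
test, Cohen's kappa, Pearson correlation, and two-sample comparisons
(Welch's t, Wilcoxon rank-sum).  Heavier model fitting (mixed models,
ANOVA) is deliberately left to external software; the per-animal
summary tables exported here are its input.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from . import clock
from .types import (
    NREM,
    REM,
    STATES,
    SWD,
    UNSCORED,
    WAKE,
    Hypnogram,
    ValidationError,
    validate_events,
)

# ---------------------------------------------------------------------------
# bouts and state totals


def segment_bouts(hypnogram: Hypnogram) -> pd.DataFrame:
    """Maximal runs of identical labels; bouts tile the hypnogram exactly.

    Columns: state, start_epoch, end_epoch (half-open), duration_s.
    """
    labels = hypnogram.labels
    if len(labels) == 0:
        return pd.DataFrame(columns=["state", "start_epoch", "end_epoch", "duration_s"])
    change = np.nonzero(labels[1:] != labels[:-1])[0] + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(labels)]))
    return pd.DataFrame(
        {
            "state": labels[starts],
            "start_epoch": starts,
            "end_epoch": ends,
            "duration_s": (ends - starts) * hypnogram.epoch_len_s,
        }
    )


def mask_swd_epochs(hypnogram: Hypnogram, events: pd.DataFrame) -> Hypnogram:
    """Relabel every epoch overlapping a seizure event to SWD.

    Seizure time is excluded from the vigilance-state totals (an epoch
    partly covered by an event counts as SWD in full); masking is
    state-agnostic.
    """
    events = validate_events(events)
    out = hypnogram.copy()
    ep = hypnogram.epoch_len_s
    for start, end in zip(events["start_s"], events["end_s"]):
        i0 = int(np.floor(start / ep))
        i1 = int(np.ceil(end / ep))
        out.labels[max(i0, 0) : min(i1, out.n_epochs)] = SWD
    return out


@dataclass
class StateBlock:
    """Totals for one vigilance state over one time window."""

    total_min: float = 0.0
    n_bouts: int = 0
    mean_bout_s: float | None = None


@dataclass
class AnimalSummary:
    """Per-animal metrics feeding the group-level figures and exports."""

    duration_min: float = 0.0
    swd_count: int = 0
    swd_mean_s: float | None = None
    swd_total_s: float = 0.0
    states_24h: dict = field(default_factory=dict)
    states_light: dict = field(default_factory=dict)
    states_dark: dict = field(default_factory=dict)
    hourly_state_min: dict = field(default_factory=dict)  # state -> 24-vector
    hourly_swd_counts: list = field(default_factory=list)
    swd_masked_min: float = 0.0
    unscored_min: float = 0.0
    phase_coverage: dict = field(default_factory=dict)  # phase -> fraction of 12 h
    onset_state_pct: dict = field(default_factory=dict)
    transition_swd_proportion: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def _window_block(labels, epoch_len_s, window_mask) -> dict:
    """Per-state totals / bout stats within a boolean epoch window."""
    block = {}
    sub = Hypnogram(np.where(window_mask, labels, "UNSCORED"), epoch_len_s)
    bouts = segment_bouts(sub)
    for s in STATES:
        n_ep = int(np.sum(window_mask & (labels == s)))
        sb = bouts[bouts["state"] == s]
        mean_bout = float(sb["duration_s"].mean()) if len(sb) else None
        block[s] = StateBlock(
            total_min=n_ep * epoch_len_s / 60.0,
            n_bouts=int(len(sb)),
            mean_bout_s=mean_bout,
        )
    return block


def state_totals(
    hypnogram: Hypnogram,
    events: pd.DataFrame,
    start_clock: str = "07:00",
    lights_off_clock: str = "19:00",
) -> AnimalSummary:
    """State/bout totals over 24 h, per 12-h phase, and per hour of day.

    Epochs overlapping seizure events are masked to SWD before any
    totals are taken, so seizure time never inflates wake (or any other
    state) minutes.  Recordings shorter than an aggregation window get
    explicit per-phase coverage fractions rather than silently partial
    numbers.
    """
    events = validate_events(events)
    masked = mask_swd_epochs(hypnogram, events)
    labels = masked.labels
    ep = hypnogram.epoch_len_s
    n = hypnogram.n_epochs
    starts = hypnogram.epoch_starts()
    dark = clock.is_dark(start_clock, starts, lights_off_clock)
    hours = clock.hour_of_day(start_clock, starts)

    summary = AnimalSummary(duration_min=n * ep / 60.0)
    summary.swd_count, summary.swd_mean_s, summary.swd_total_s = _event_summary(events)
    summary.states_24h = {s: asdict(b) for s, b in _window_block(labels, ep, np.ones(n, bool)).items()}
    summary.states_light = {s: asdict(b) for s, b in _window_block(labels, ep, ~dark).items()}
    summary.states_dark = {s: asdict(b) for s, b in _window_block(labels, ep, dark).items()}
    summary.hourly_state_min = {
        s: [float(np.sum((hours == h) & (labels == s)) * ep / 60.0) for h in range(24)]
        for s in STATES
    }
    summary.hourly_swd_counts = [int(c) for c in hourly_counts(events, start_clock)]
    summary.swd_masked_min = float(np.sum(labels == SWD) * ep / 60.0)
    summary.unscored_min = float(np.sum(labels == UNSCORED) * ep / 60.0)
    summary.phase_coverage = {
        "light": float(np.sum(~dark) * ep / clock.DARK_LEN_S),
        "dark": float(np.sum(dark) * ep / clock.DARK_LEN_S),
    }
    return summary


def _event_summary(events: pd.DataFrame) -> tuple[int, float | None, float]:
    count = len(events)
    total = float(events["duration_s"].sum()) if count else 0.0
    return count, (total / count if count else None), total


# ---------------------------------------------------------------------------
# event-state assignment and aggregation


def assign_event_states(
    events: pd.DataFrame,
    hypnogram: Hypnogram,
    transition_window_s: float = 30.0,
) -> pd.DataFrame:
    """Annotate events with onset state and wake->NREM transition flag.

    The hypnogram here must be the pre-masking one (original sleep
    labels).  ``transition_flag`` is set when the onset state is NREM,
    the enclosing NREM bout begins within ``transition_window_s`` of the
    end of a WAKE bout, and the event starts within the same window of
    that bout's start.
    """
    events = validate_events(events)
    bouts = segment_bouts(hypnogram)
    ep = hypnogram.epoch_len_s
    onset_states, flags = [], []
    for start in events["start_s"]:
        epoch = hypnogram.epoch_of(start)  # raises if beyond the hypnogram
        onset_states.append(hypnogram.labels[epoch])
        flags.append(False)
        if hypnogram.labels[epoch] != NREM:
            continue
        b = bouts[(bouts["start_epoch"] <= epoch) & (epoch < bouts["end_epoch"])].iloc[0]
        bout_start_s = b["start_epoch"] * ep
        wake_before = bouts[
            (bouts["state"] == WAKE) & (bouts["end_epoch"] <= b["start_epoch"])
        ]
        if len(wake_before) == 0:
            continue
        wake_end_s = wake_before["end_epoch"].iloc[-1] * ep
        if (
            bout_start_s - wake_end_s <= transition_window_s
            and start - bout_start_s <= transition_window_s
        ):
            flags[-1] = True
    out = events.copy()
    out["onset_state"] = onset_states
    out["transition_flag"] = np.asarray(flags, dtype=bool)
    return out


def state_event_proportions(events: pd.DataFrame) -> dict[str, float]:
    """Percentage of events starting in each of WAKE/NREM/REM."""
    if len(events) == 0:
        raise ValidationError("cannot compute onset-state proportions of no events")
    counts = {s: int(np.sum(events["onset_state"] == s)) for s in STATES}
    denom = sum(counts.values())
    if denom == 0:
        raise ValidationError("no events with a scored onset state")
    return {s: 100.0 * c / denom for s, c in counts.items()}


def hourly_counts(events: pd.DataFrame, start_clock: str = "07:00") -> np.ndarray:
    """24-vector of event counts by hour of day of onset (half-open bins)."""
    events = validate_events(events)
    out = np.zeros(24, dtype=int)
    if len(events):
        hours = clock.hour_of_day(start_clock, events["start_s"].to_numpy())
        np.add.at(out, hours, 1)
    return out


def phase_split(
    hourly: np.ndarray, lights_off_clock: str = "19:00"
) -> tuple[float, float]:
    """Split a 24-vector (indexed by hour of day) into (light, dark) sums."""
    hourly = np.asarray(hourly)
    if hourly.shape != (24,):
        raise ValidationError("phase_split expects a 24-vector indexed by hour of day")
    dark_hours = clock.is_dark("00:00", np.arange(24) * 3600.0, lights_off_clock)
    return float(hourly[~dark_hours].sum()), float(hourly[dark_hours].sum())


def percent_of_baseline(value_treatment: float, value_baseline: float) -> float:
    """Treatment metric as percent of its time-matched baseline."""
    if value_baseline <= 0:
        raise ValidationError("baseline must be positive for percent-of-baseline")
    return 100.0 * value_treatment / value_baseline


def window_events(events: pd.DataFrame, start_s: float, end_s: float) -> pd.DataFrame:
    """Events whose onset falls in ``[start_s, end_s)`` (drug-window extraction)."""
    events = validate_events(events)
    m = (events["start_s"] >= start_s) & (events["start_s"] < end_s)
    return events[m].reset_index(drop=True)


# ---------------------------------------------------------------------------
# statistics


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 contingency table.

    Uses the minimum-likelihood convention: the sum of the probabilities
    of all tables with the observed margins whose hypergeometric
    probability does not exceed the observed table's.
    """
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValidationError("expected a non-negative 2x2 table")
    if table.sum() == 0:
        raise ValidationError("all-zero contingency table")
    _, p = sstats.fisher_exact(table, alternative="two-sided")
    return float(p)


def cohens_kappa(confusion) -> float:
    """Chance-corrected agreement from a square confusion matrix.

    kappa = (p_o - p_e) / (1 - p_e) with p_o the observed agreement
    (trace over total) and p_e the chance agreement from the marginals.
    """
    mat = np.asarray(confusion, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValidationError("confusion matrix must be square")
    total = mat.sum()
    if total <= 0:
        raise ValidationError("empty confusion matrix")
    p_o = np.trace(mat) / total
    p_e = float(np.sum(mat.sum(axis=0) * mat.sum(axis=1))) / total**2
    if np.isclose(p_e, 1.0):
        raise ValidationError("chance agreement is 1; kappa undefined")
    return float((p_o - p_e) / (1 - p_e))


def pearson_r(x, y) -> tuple[float, float, int, float]:
    """Pearson correlation with its t statistic: ``(r, t, df, p)``.

    t = r sqrt(df) / sqrt(1 - r^2) with df = n - 2; p two-sided from the
    t distribution.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("pearson_r needs equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("pearson_r undefined for constant input")
    r = float(sstats.pearsonr(x, y).statistic)
    df = len(x) - 2
    if abs(r) >= 1.0:
        return r, float(np.inf) * np.sign(r), df, 0.0
    t = r * np.sqrt(df) / np.sqrt(1 - r**2)
    p = 2 * sstats.t.sf(abs(t), df)
    return r, float(t), df, float(p)


def two_sample_test(group_a, group_b, method: str = "welch_t") -> tuple[float, float]:
    """Two-sample comparison: Welch's t or Wilcoxon rank-sum.

    ``welch_t`` uses the Satterthwaite degrees of freedom.  ``rank_sum``
    reports the Wilcoxon rank-sum statistic W (midranks for ties) with
    an exact p for combined n <= 20 and the normal approximation
    otherwise; p is two-sided.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs n >= 2")
    if method == "welch_t":
        res = sstats.ttest_ind(a, b, equal_var=False)
        return float(res.statistic), float(res.pvalue)
    if method == "rank_sum":
        exact = len(a) + len(b) <= 20 and len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
        res = sstats.mannwhitneyu(
            a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
        )
        w = float(res.statistic) + len(a) * (len(a) + 1) / 2.0
        return w, float(res.pvalue)
    raise ValidationError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# cohort-level reporting


def summarize_animal(
    hypnogram: Hypnogram,
    events: pd.DataFrame,
    start_clock: str = "07:00",
    lights_off_clock: str = "19:00",
    transition_window_s: float = 30.0,
) -> AnimalSummary:
    """Full per-animal summary: state block + onset-state annotations."""
    annotated = assign_event_states(events, hypnogram, transition_window_s)
    summary = state_totals(hypnogram, annotated, start_clock, lights_off_clock)
    if len(annotated):
        summary.onset_state_pct = state_event_proportions(annotated)
        nrem_onsets = annotated[annotated["onset_state"] == NREM]
        if len(nrem_onsets):
            summary.transition_swd_proportion = float(
                nrem_onsets["transition_flag"].mean()
            )
    return summary


def cohort_table(animals) -> pd.DataFrame:
    """Tidy per-animal table (one row per animal) for external statistics."""
    rows = []
    for a in animals:
        s = summarize_animal(a.hypnogram, a.events)
        rows.append(
            {
                "group": a.group,
                "animal": a.index,
                "swd_count": s.swd_count,
                "swd_total_s": s.swd_total_s,
                "swd_mean_s": s.swd_mean_s,
                **{
                    f"{st.lower()}_min": s.states_24h[st]["total_min"]
                    for st in STATES
                },
                **{
                    f"{st.lower()}_bouts": s.states_24h[st]["n_bouts"]
                    for st in STATES
                },
            }
        )
    return pd.DataFrame(rows)


def compare_groups(
    table: pd.DataFrame,
    metrics=("rem_min", "swd_count"),
    method: str = "welch_t",
) -> pd.DataFrame:
    """Two-group comparison of per-animal metrics from a cohort table."""
    groups = list(dict.fromkeys(table["group"]))
    if len(groups) != 2:
        raise ValidationError("compare_groups expects exactly two groups")
    a = table[table["group"] == groups[0]]
    b = table[table["group"] == groups[1]]
    rows = []
    for m in metrics:
        stat, p = two_sample_test(a[m], b[m], method=method)
        rows.append(
            {
                "metric": m,
                "group_a": groups[0],
                "group_b": groups[1],
                "mean_a": float(a[m].mean()),
                "mean_b": float(b[m].mean()),
                "statistic": stat,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)
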