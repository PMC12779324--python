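"""Wall-clock helpers for light--dark (12:12) alignment."""

from __future__ import annotations

import numpy as np

DAY_S = 24 * 3600
DARK_LEN_S = 12 * 3600


def parse_clock(clock: str) -> float:
    """``"HH:MM"`` -> seconds since midnight."""
    hh, mm = clock.split(":")
    h, m = int(hh), int(mm)
    if not (0 <= h < 24 and 0 <= m < 60):
        raise ValueError(f"invalid clock time {clock!r}")
    return h * 3600.0 + m * 60.0


def clock_of(start_clock: str, t_s) -> np.ndarray:
    """Seconds since midnight of recording-relative time(s) ``t_s``."""
    return (parse_clock(start_clock) + np.asarray(t_s, dtype=float)) % DAY_S


def is_dark(start_clock: str, t_s, lights_off_clock: str = "19:00") -> np.ndarray:
    """True where a recording-relative time falls in the 12-h dark phase."""
    rel = (clock_of(start_clock, t_s) - parse_clock(lights_off_clock)) % DAY_S
    return rel < DARK_LEN_S


def hour_of_day(start_clock: str, t_s) -> np.ndarray:
    """Integer hour-of-day (0-23) containing each recording-relative time."""
    return (clock_of(start_clock, t_s) // 3600).astype(int)
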