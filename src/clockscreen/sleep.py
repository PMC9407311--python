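"""Sleep scoring and quantification for DAM beam-break series.

Fly sleep is defined behaviorally as any period of at least 5 consecutive
minutes without beam breaks.  A minute is scored asleep iff it lies inside
a maximal run of >=5 zero-count minutes; missing minutes (NaN counts) are
conservatively treated as activity, i.e. they terminate inactivity runs
and are never themselves sleep.  Runs truncated by the start or end of the
selected segment count if their observed length reaches 5 min.

Daily sleep is summarized two ways:

* half-hour profiles (48 ZT bins, mean +/- SEM across flies of per-fly
  day-averaged sleep minutes per bin), and
* the four canonical 6-h windows — morning ZT21-3, siesta ZT3-9, evening
  ZT9-15 and night ZT15-21 — as per-day sums averaged across the analysis
  days, so that one fly contributes one value per window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from clockscreen.dam_io import FlySeries, MINUTES_PER_DAY

MIN_SLEEP_RUN = 5

WINDOW_NAMES = ("morning", "siesta", "evening", "night")

#: half-open ZT minute intervals; morning wraps midnight-ZT
WINDOW_BOUNDS = {
    "morning": ((1260, 1440), (0, 180)),   # ZT21-24 + ZT0-3
    "siesta": ((180, 540),),               # ZT3-9
    "evening": ((540, 900),),              # ZT9-15
    "night": ((900, 1260),),               # ZT15-21
}


@dataclass
class SleepSeries:
    """Per-minute sleep state aligned to one fly's count series."""

    fly_id: str
    genotype: str
    asleep: np.ndarray                    # bool, same length as counts
    n_days: int

    @property
    def total_sleep_minutes(self) -> int:
        return int(self.asleep.sum())

    def days(self) -> np.ndarray:
        return self.asleep.reshape(self.n_days, MINUTES_PER_DAY)


@dataclass
class SleepBout:
    onset_minute: int                     # index into the series
    duration: int                         # minutes, >= 5

    @property
    def onset_zt_minute(self) -> int:
        return self.onset_minute % MINUTES_PER_DAY


@dataclass
class SleepProfile:
    """Genotype-average sleep in 48 half-hour ZT bins."""

    genotype: str
    n_flies: int
    bin_mean: np.ndarray                  # (48,), minutes asleep per bin, in [0, 30]
    bin_sem: np.ndarray                   # (48,), SEM across flies


@dataclass
class WindowSleep:
    """Per-fly sleep minutes in the four 6-h windows (day-averaged)."""

    fly_id: str
    genotype: str
    morning: float
    siesta: float
    evening: float
    night: float

    @property
    def total(self) -> float:
        return self.morning + self.siesta + self.evening + self.night


def _zero_runs(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Start indices and lengths of maximal runs of exact-zero counts.

    NaN (missing) minutes compare unequal to zero and therefore break runs.
    """
    zero = np.zeros(len(counts) + 2, dtype=bool)
    zero[1:-1] = counts == 0
    d = np.diff(zero.astype(np.int8))
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    return starts, ends - starts


def score_sleep(fs: FlySeries) -> SleepSeries:
    """Score per-minute sleep by the 5-min inactivity rule."""
    starts, lengths = _zero_runs(fs.counts)
    asleep = np.zeros(len(fs.counts), dtype=bool)
    for s, ln in zip(starts, lengths):
        if ln >= MIN_SLEEP_RUN:
            asleep[s:s + ln] = True
    return SleepSeries(fly_id=fs.fly_id, genotype=fs.genotype,
                       asleep=asleep, n_days=fs.n_days)


def sleep_bouts(ss: SleepSeries) -> list[SleepBout]:
    """Maximal sleep runs as bouts; durations sum to total sleep minutes."""
    starts, lengths = _zero_runs(np.where(ss.asleep, 0.0, 1.0))
    return [SleepBout(int(s), int(ln)) for s, ln in zip(starts, lengths)]


def _fly_bin_means(ss: SleepSeries, bin_minutes: int = 30) -> np.ndarray:
    """One fly's day-averaged sleep minutes per ZT bin."""
    per_day = ss.days().reshape(ss.n_days, MINUTES_PER_DAY // bin_minutes, bin_minutes)
    return per_day.sum(axis=2).mean(axis=0)


def sleep_profile(flies: Sequence[SleepSeries], genotype: str | None = None,
                  bin_minutes: int = 30) -> SleepProfile:
    """Average sleep profile across flies in half-hour ZT bins.

    The mean is taken across flies of each fly's day-averaged bin values;
    the SEM is across flies.  Requires >=2 flies for a finite SEM.
    """
    flies = [f for f in flies if genotype is None or f.genotype == genotype]
    if not flies:
        raise ValueError("no flies for sleep profile")
    per_fly = np.stack([_fly_bin_means(f, bin_minutes) for f in flies])
    n = len(flies)
    sem = (per_fly.std(axis=0, ddof=1) / np.sqrt(n)) if n > 1 else np.full(per_fly.shape[1], np.nan)
    return SleepProfile(genotype=genotype or flies[0].genotype, n_flies=n,
                        bin_mean=per_fly.mean(axis=0), bin_sem=sem)


def window_sleep(ss: SleepSeries) -> WindowSleep:
    """Sleep minutes per 6-h window, summed within each day then averaged
    across the analysis days.  The four windows partition the ZT day, so
    their sum equals total daily sleep."""
    days = ss.days()
    vals = {}
    for name in WINDOW_NAMES:
        per_day = np.zeros(ss.n_days)
        for lo, hi in WINDOW_BOUNDS[name]:
            per_day += days[:, lo:hi].sum(axis=1)
        vals[name] = float(per_day.mean())
    return WindowSleep(fly_id=ss.fly_id, genotype=ss.genotype, **vals)


def window_sleep_table(flies: Iterable[SleepSeries]) -> pd.DataFrame:
    """Per-fly window-sleep table (columns: fly_id, genotype, the four
    windows, total), the input to the screen statistics."""
    rows = []
    for ss in flies:
        w = window_sleep(ss)
        rows.append({"fly_id": w.fly_id, "genotype": w.genotype,
                     "morning": w.morning, "siesta": w.siesta,
                     "evening": w.evening, "night": w.night, "total": w.total})
    return pd.DataFrame(rows)
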