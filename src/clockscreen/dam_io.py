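"""Reading, aligning and cleaning Drosophila Activity Monitor (DAM) data.

Trikinetics DAM monitors report, once per minute, the number of infrared
beam interruptions for each of 32 flies housed in glass tubes.  This module
parses the tab-separated monitor text dialect (42 columns: record index,
date, time, a status field, five auxiliary fields, a light flag, then the
32 channel counts), repairs timestamp gaps with an explicit missing-data
marker (NaN, never zero), aligns recordings to Zeitgeber time (ZT0 =
lights-on), selects the analysis days for LD sleep or DD rhythmicity work,
and removes flies that died during the recording.

Counts are kept as float arrays so that missing minutes can be NaN; real
counts are non-negative integers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

N_CHANNELS = 32
MINUTES_PER_DAY = 1440

#: a fly-day with more than this fraction of missing minutes is dropped
MAX_MISSING_FRACTION = 0.05

_DATE_FMT = "%d %b %y"
_TIME_FMT = "%H:%M:%S"


@dataclass
class MonitorRecording:
    """One DAM monitor's gap-repaired minute-resolution recording."""

    monitor_id: str
    timestamps: pd.DatetimeIndex          # strictly increasing, 1-min spacing
    light_flag: np.ndarray                # int8; -1 where the minute is missing
    counts: np.ndarray                    # float (n, 32); NaN = missing minute
    n_malformed: int = 0

    def __post_init__(self) -> None:
        if self.counts.ndim != 2 or self.counts.shape[1] != N_CHANNELS:
            raise ValueError(f"expected {N_CHANNELS} channels, got {self.counts.shape}")
        if len(self.timestamps) != len(self.counts):
            raise ValueError("timestamps and counts length mismatch")

    @property
    def n_minutes(self) -> int:
        return len(self.timestamps)


@dataclass
class ExperimentDesign:
    """Channel-to-genotype map plus the lighting schedule of the experiment.

    Parameters
    ----------
    channel_map
        ``{(monitor_id, channel_1_to_32): genotype}``; channels absent from
        the map are not analyzed.
    lights_on
        Clock time of lights-on defining ZT0, as ``"HH:MM"``.
    ld_days, dd_days
        Number of LD 12:12 days recorded, then days in constant darkness.
    """

    channel_map: Mapping[tuple[str, int], str]
    lights_on: str = "08:00"
    ld_days: int = 0
    dd_days: int = 0

    @property
    def lights_on_minute(self) -> int:
        hh, mm = self.lights_on.split(":")
        return int(hh) * 60 + int(mm)

    @classmethod
    def from_csv(cls, path, lights_on: str, ld_days: int, dd_days: int) -> "ExperimentDesign":
        """Load a design table (columns: monitor, channel, genotype)."""
        tab = pd.read_csv(path)
        cmap = {
            (str(r.monitor), int(r.channel)): str(r.genotype)
            for r in tab.itertuples(index=False)
        }
        return cls(cmap, lights_on=lights_on, ld_days=ld_days, dd_days=dd_days)


@dataclass
class FlySeries:
    """One fly's minute-resolution beam-break counts in Zeitgeber time.

    The series always covers whole ZT days (length = ``n_days * 1440``),
    starting at ZT0.  ``day_seg`` labels each retained day ``"LD"`` or
    ``"DD"``; ``day_ids`` keeps the original day index so that dropped
    days remain visible.
    """

    fly_id: str
    genotype: str
    counts: np.ndarray                    # float, NaN = missing minute
    day_seg: list[str] = field(default_factory=list)
    day_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.counts) != self.n_days * MINUTES_PER_DAY:
            raise ValueError("FlySeries length must be a whole number of days")

    @property
    def n_days(self) -> int:
        return len(self.day_seg)

    @property
    def zt_minutes(self) -> np.ndarray:
        """Minute-of-day in Zeitgeber time, cyclic with period 1440."""
        return np.arange(len(self.counts)) % MINUTES_PER_DAY

    def days(self) -> np.ndarray:
        """Counts reshaped to (n_days, 1440)."""
        return self.counts.reshape(self.n_days, MINUTES_PER_DAY)


def write_monitor_file(path, timestamps: pd.DatetimeIndex, light_flag: np.ndarray,
                       counts: np.ndarray) -> None:
    """Write a 42-column DAM monitor text file.

    Minutes whose counts are all-NaN are omitted from the file (a recording
    gap), which is how real monitors represent dropped minutes.
    """
    counts = np.asarray(counts, dtype=float)
    keep = ~np.all(np.isnan(counts), axis=1)
    ts = timestamps[keep]
    cc = counts[keep].astype(np.int64)
    lf = np.asarray(light_flag)[keep].astype(np.int64)
    n = len(ts)
    df = pd.DataFrame({
        0: np.arange(1, n + 1),
        1: ts.strftime(_DATE_FMT),
        2: ts.strftime(_TIME_FMT),
        3: np.ones(n, dtype=np.int64),
    })
    for j in range(4, 9):                 # five auxiliary fields
        df[j] = 0
    df[9] = lf
    for ch in range(N_CHANNELS):
        df[10 + ch] = cc[:, ch]
    df.to_csv(path, sep="\t", header=False, index=False)


def parse_monitor_file(path, monitor_id: str | None = None) -> MonitorRecording:
    """Parse one DAM monitor text file into a gap-repaired recording.

    Malformed lines (unparseable timestamp or non-numeric counts) are
    skipped and counted; missing minutes are inserted as NaN rows.  A file
    with fewer than 42 tab-separated columns on every line raises
    ``ValueError``.
    """
    if monitor_id is None:
        monitor_id = str(path).rsplit("/", 1)[-1].rsplit(".", 1)[0]
    try:
        raw = pd.read_csv(path, sep="\t", header=None, dtype=str,
                          engine="c", on_bad_lines="skip",
                          skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty monitor file")
    if raw.shape[1] < 10 + N_CHANNELS:
        raise ValueError(
            f"{path}: DAM format error, every line has fewer than "
            f"{10 + N_CHANNELS} columns")
    n_raw = len(raw)

    ts = pd.to_datetime(raw[1].str.strip() + " " + raw[2].str.strip(),
                        format=_DATE_FMT + " " + _TIME_FMT, errors="coerce")
    light = pd.to_numeric(raw[9], errors="coerce")
    cnt = raw.iloc[:, 10:10 + N_CHANNELS].apply(pd.to_numeric, errors="coerce")
    ok = ts.notna() & light.notna() & cnt.notna().all(axis=1) & (cnt >= 0).all(axis=1)
    n_malformed = int(n_raw - ok.sum())
    if n_malformed:
        logger.info("%s: skipped %d malformed line(s)", monitor_id, n_malformed)
    if not ok.any():
        raise ValueError(f"{path}: no parseable DAM lines")

    ts = ts[ok]
    frame = pd.DataFrame(cnt[ok].to_numpy(dtype=float), index=ts)
    frame["__light"] = light[ok].to_numpy(dtype=float)
    frame = frame[~frame.index.duplicated(keep="first")].sort_index()

    # gap repair: reindex onto the full 1-min grid; inserted rows are NaN
    full = pd.date_range(frame.index[0], frame.index[-1], freq="min")
    n_gap = len(full) - len(frame)
    if n_gap:
        logger.info("%s: inserted %d missing minute(s)", monitor_id, n_gap)
    frame = frame.reindex(full)

    lf = frame.pop("__light").to_numpy()
    light_flag = np.where(np.isnan(lf), -1, lf).astype(np.int8)
    return MonitorRecording(monitor_id=monitor_id, timestamps=full,
                            light_flag=light_flag,
                            counts=frame.to_numpy(dtype=float),
                            n_malformed=n_malformed)


def _check_light_flag(rec: MonitorRecording, zt: np.ndarray) -> None:
    """Warn when recorded light transitions disagree with the declared
    lights-on time by more than 60 min; the declared time always wins."""
    lf = rec.light_flag
    valid = lf >= 0
    rises = np.nonzero((lf[1:] == 1) & (lf[:-1] == 0) & valid[1:] & valid[:-1])[0] + 1
    if len(rises) == 0:
        return
    dev = zt[rises] % MINUTES_PER_DAY
    dev = np.minimum(dev, MINUTES_PER_DAY - dev)        # circular distance to ZT0
    med = float(np.median(dev))
    if med > 60:
        logger.warning(
            "%s: recorded lights-on transitions deviate from the declared "
            "lights-on time by %.0f min (median); using the declared time",
            rec.monitor_id, med)


def align_to_zeitgeber(rec: MonitorRecording, design: ExperimentDesign) -> list[FlySeries]:
    """Split a recording into per-fly series aligned to Zeitgeber time.

    ZT minute 0 is placed at the declared lights-on clock time; leading and
    trailing partial days are dropped so only whole ZT days remain.  Days
    with more than 5% missing minutes are dropped (missingness in a DAM
    file affects all 32 channels alike).  Only channels present in the
    design's channel map are returned.
    """
    minute_of_day = (rec.timestamps.hour * 60 + rec.timestamps.minute).to_numpy()
    zt = (minute_of_day - design.lights_on_minute) % MINUTES_PER_DAY

    starts = np.nonzero(zt == 0)[0]
    if len(starts) == 0:
        raise ValueError(f"{rec.monitor_id}: no whole ZT day in recording")
    start = int(starts[0])
    n_days = (rec.n_minutes - start) // MINUTES_PER_DAY
    if n_days < 1:
        raise ValueError(f"{rec.monitor_id}: no whole ZT day in recording")
    if start:
        logger.info("%s: dropped %d leading minutes (partial day)", rec.monitor_id, start)

    _check_light_flag(rec, zt)

    stop = start + n_days * MINUTES_PER_DAY
    counts = rec.counts[start:stop]
    missing = np.isnan(counts[:, 0]).reshape(n_days, MINUTES_PER_DAY)
    day_ok = missing.mean(axis=1) <= MAX_MISSING_FRACTION
    if not day_ok.all():
        logger.warning("%s: dropped %d day(s) with >%.0f%% missing minutes",
                       rec.monitor_id, int((~day_ok).sum()), 100 * MAX_MISSING_FRACTION)

    day_ids = [d for d in range(n_days) if day_ok[d]]
    day_seg = ["LD" if d < design.ld_days else "DD" for d in day_ids]
    keep_mask = np.repeat(day_ok, MINUTES_PER_DAY)

    out: list[FlySeries] = []
    for ch in range(N_CHANNELS):
        genotype = design.channel_map.get((rec.monitor_id, ch + 1))
        if genotype is None:
            continue
        out.append(FlySeries(
            fly_id=f"{rec.monitor_id}:c{ch + 1:02d}",
            genotype=genotype,
            counts=counts[keep_mask, ch].copy(),
            day_seg=list(day_seg),
            day_ids=list(day_ids),
        ))
    return out


def select_days(fs: FlySeries, which: str) -> FlySeries:
    """Select the analysis days of a series.

    ``"ld_sleep"``
        The last 4 complete LD days (the earlier LD days serve as
        entrainment).
    ``"dd_rhythm"``
        DD days 2 through 7; the first DD day is discarded as a transient
        after the lights-out transition.
    """
    if which == "ld_sleep":
        pos = [k for k, s in enumerate(fs.day_seg) if s == "LD"]
        if len(pos) < 4:
            raise ValueError(f"{fs.fly_id}: need >=4 LD days, have {len(pos)}")
        pos = pos[-4:]
    elif which == "dd_rhythm":
        pos = [k for k, s in enumerate(fs.day_seg) if s == "DD"]
        if len(pos) < 7:
            raise ValueError(f"{fs.fly_id}: need >=7 DD days, have {len(pos)}")
        pos = pos[1:7]
    else:
        raise ValueError(f"unknown day selector {which!r}")

    idx = np.concatenate([np.arange(p * MINUTES_PER_DAY, (p + 1) * MINUTES_PER_DAY)
                          for p in pos])
    return replace(fs, counts=fs.counts[idx],
                   day_seg=[fs.day_seg[p] for p in pos],
                   day_ids=[fs.day_ids[p] for p in pos])


def filter_dead_flies(series: Iterable[FlySeries]) -> tuple[list[FlySeries], list[FlySeries]]:
    """Remove flies with zero beam breaks over the final 24 h.

    Returns ``(kept, removed)``; removals are logged with the fly id.
    The operation is idempotent.
    """
    kept: list[FlySeries] = []
    removed: list[FlySeries] = []
    for fs in series:
        last_day = fs.counts[-MINUTES_PER_DAY:]
        if np.nansum(last_day) == 0:
            logger.info("removed dead fly %s (no activity in final 24 h)", fs.fly_id)
            removed.append(fs)
        else:
            kept.append(fs)
    return kept, removed


def bin_series(fs: FlySeries | np.ndarray, bin_minutes: int) -> np.ndarray:
    """Sum counts into non-overlapping bins of ``bin_minutes``.

    ``bin_minutes`` must divide 1440 so bins never straddle ZT days.
    Missing minutes contribute nothing to their bin.
    """
    if MINUTES_PER_DAY % bin_minutes:
        raise ValueError(f"bin size {bin_minutes} does not divide 1440")
    x = fs.counts if isinstance(fs, FlySeries) else np.asarray(fs, dtype=float)
    if len(x) % bin_minutes:
        raise ValueError("series length is not a multiple of the bin size")
    return np.nansum(x.reshape(-1, bin_minutes), axis=1)


def ingest_experiment(monitor_paths: Sequence, design: ExperimentDesign) -> list[FlySeries]:
    """Parse and ZT-align a set of monitor files into one fly list."""
    out: list[FlySeries] = []
    for p in monitor_paths:
        out.extend(align_to_zeitgeber(parse_monitor_file(p), design))
    return out
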