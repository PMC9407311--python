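"""DAM monitor parsing, Zeitgeber alignment, day selection and cleaning."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from clockscreen.dam_io import (
    ExperimentDesign,
    FlySeries,
    MINUTES_PER_DAY,
    N_CHANNELS,
    align_to_zeitgeber,
    bin_series,
    filter_dead_flies,
    parse_monitor_file,
    select_days,
    write_monitor_file,
)
from clockscreen.synth import ScreenScenario, simulate_experiment


def _dam_row(idx, when, light, counts):
    return "\t".join(map(str, [idx, when.strftime("%d %b %y"),
                               when.strftime("%H:%M:%S"), 1, 0, 0, 0, 0, 0,
                               light, *counts]))


def _write_dam(path, rows):
    path.write_text("\n".join(rows) + "\n")


def _minutes(start, n):
    return [start + dt.timedelta(minutes=k) for k in range(n)]


def test_parse_echoes_channel_counts(tmp_path):
    t0 = dt.datetime(2024, 1, 1, 8, 0)
    vals = [0, 2, 5]
    rows = [_dam_row(i + 1, w, 1, [vals[i]] + [0] * 31)
            for i, w in enumerate(_minutes(t0, 3))]
    p = tmp_path / "M1.txt"
    _write_dam(p, rows)
    rec = parse_monitor_file(p)
    assert rec.n_minutes == 3
    assert rec.counts[:, 0].tolist() == vals
    assert rec.n_malformed == 0


def test_gap_is_repaired_with_missing_marker_not_zero(tmp_path):
    t0 = dt.datetime(2024, 1, 1, 8, 0)
    times = [t0, t0 + dt.timedelta(minutes=1), t0 + dt.timedelta(minutes=4)]
    rows = [_dam_row(i + 1, w, 1, [3] * 32) for i, w in enumerate(times)]
    p = tmp_path / "M1.txt"
    _write_dam(p, rows)
    rec = parse_monitor_file(p)
    assert rec.n_minutes == 5
    assert np.isnan(rec.counts[2:4]).all()
    assert (rec.counts[[0, 1, 4]] == 3).all()
    assert (rec.light_flag[2:4] == -1).all()


def test_malformed_lines_are_skipped_and_counted(tmp_path):
    t0 = dt.datetime(2024, 1, 1, 8, 0)
    rows = [_dam_row(i + 1, w, 1, [1] * 32) for i, w in enumerate(_minutes(t0, 3))]
    rows.insert(1, rows[0].replace("08:00:00", "garbage"))
    p = tmp_path / "M1.txt"
    _write_dam(p, rows)
    rec = parse_monitor_file(p)
    assert rec.n_malformed == 1
    assert rec.n_minutes == 3


def test_file_with_too_few_columns_is_a_format_error(tmp_path):
    p = tmp_path / "M1.txt"
    p.write_text("1\t01 Jan 24\t08:00:00\t1\n2\t01 Jan 24\t08:01:00\t1\n")
    with pytest.raises(ValueError, match="format"):
        parse_monitor_file(p)


def test_write_parse_roundtrip_is_count_identical(tmp_path, rng):
    n = 2 * MINUTES_PER_DAY
    counts = rng.poisson(1.5, size=(n, N_CHANNELS)).astype(float)
    counts[500:510] = np.nan                       # a 10-min recording gap
    ts = pd.date_range("2024-01-01 08:00", periods=n, freq="min")
    light = (np.arange(n) % MINUTES_PER_DAY < 720).astype(int)
    p = tmp_path / "M1.txt"
    write_monitor_file(p, ts, light, counts)
    rec = parse_monitor_file(p)
    assert rec.n_minutes == n
    np.testing.assert_array_equal(rec.counts, counts)
    assert (rec.light_flag[500:510] == -1).all()


def _recording(tmp_path, start, n, lights_on_minute=480, counts_fn=None):
    ts = pd.date_range(start, periods=n, freq="min")
    mod = (ts.hour * 60 + ts.minute - lights_on_minute) % MINUTES_PER_DAY
    light = (mod < 720).astype(int)
    counts = np.ones((n, N_CHANNELS)) if counts_fn is None else counts_fn(n)
    p = tmp_path / "M1.txt"
    write_monitor_file(p, ts, light, counts)
    return parse_monitor_file(p)


DESIGN = ExperimentDesign({("M1", c): "wt" for c in range(1, N_CHANNELS + 1)},
                          lights_on="08:00", ld_days=2, dd_days=0)


def test_alignment_starts_at_lights_on(tmp_path):
    rec = _recording(tmp_path, "2024-01-01 08:00", 2 * MINUTES_PER_DAY)
    flies = align_to_zeitgeber(rec, DESIGN)
    assert len(flies) == N_CHANNELS
    assert flies[0].n_days == 2
    assert flies[0].zt_minutes[0] == 0


def test_partial_leading_day_is_dropped(tmp_path):
    rec = _recording(tmp_path, "2024-01-01 06:00", 2 * MINUTES_PER_DAY + 120)
    flies = align_to_zeitgeber(rec, DESIGN)
    assert flies[0].n_days == 2
    assert len(flies[0].counts) == 2 * MINUTES_PER_DAY


def test_shifted_light_flag_warns_but_declared_time_wins(tmp_path, caplog):
    # recorded flags rise at 10:00, 120 min after the declared lights-on
    rec = _recording(tmp_path, "2024-01-01 08:00", 2 * MINUTES_PER_DAY,
                     lights_on_minute=600)
    with caplog.at_level("WARNING", logger="clockscreen.dam_io"):
        flies = align_to_zeitgeber(rec, DESIGN)
    assert any("declared" in r.message for r in caplog.records)
    assert flies[0].zt_minutes[0] == 0     # ZT0 still at the declared 08:00


def test_alignment_conserves_counts_for_whole_days(tmp_path, rng):
    rec = _recording(tmp_path, "2024-01-01 08:00", 2 * MINUTES_PER_DAY,
                     counts_fn=lambda n: rng.poisson(2.0, (n, N_CHANNELS)).astype(float))
    flies = align_to_zeitgeber(rec, DESIGN)
    total = sum(np.nansum(f.counts) for f in flies)
    assert total == np.nansum(rec.counts)


def _labelled_series(ld, dd):
    n = (ld + dd) * MINUTES_PER_DAY
    counts = np.repeat(np.arange(ld + dd, dtype=float) + 1.0, MINUTES_PER_DAY)
    return FlySeries("f", "wt", counts, ["LD"] * ld + ["DD"] * dd,
                     list(range(ld + dd)))


def test_ld_sleep_selector_keeps_last_four_ld_days():
    fs = select_days(_labelled_series(7, 7), "ld_sleep")
    assert fs.n_days == 4 and len(fs.counts) == 5760
    assert fs.day_ids == [3, 4, 5, 6]


def test_dd_rhythm_selector_keeps_dd_days_two_through_seven():
    fs = select_days(_labelled_series(7, 7), "dd_rhythm")
    assert fs.day_ids == [8, 9, 10, 11, 12, 13]
    assert all(s == "DD" for s in fs.day_seg)


def test_too_few_days_raises():
    with pytest.raises(ValueError):
        select_days(_labelled_series(3, 0), "ld_sleep")
    with pytest.raises(ValueError):
        select_days(_labelled_series(7, 3), "dd_rhythm")


def test_dead_fly_rule_boundary():
    dead = _labelled_series(2, 0)
    dead.counts[-MINUTES_PER_DAY:] = 0.0
    barely = _labelled_series(2, 0)
    barely.counts[-MINUTES_PER_DAY:] = 0.0
    barely.counts[-10] = 1.0
    kept, removed = filter_dead_flies([dead, barely])
    assert [f.fly_id for f in removed] == ["f"] and len(kept) == 1
    # idempotent
    kept2, removed2 = filter_dead_flies(kept)
    assert kept2 == kept and not removed2


def test_programmed_deaths_are_detected(tmp_path):
    scen = ScreenScenario({"wt": (8, "control")}, seed=5)
    deaths = {"Monitor1:c02": 600, "Monitor1:c05": 0, "Monitor1:c07": 1200}
    paths, design, truth = simulate_experiment(scen, tmp_path, days_ld=2,
                                               deaths=deaths)
    flies = align_to_zeitgeber(parse_monitor_file(paths[0]), design)
    kept, removed = filter_dead_flies(flies)
    assert sorted(f.fly_id for f in removed) == sorted(deaths)


def test_bin_series_sums_and_identity():
    fs = make_ones(60)
    assert bin_series(fs, 30)[:2].tolist() == [30.0, 30.0]
    np.testing.assert_array_equal(bin_series(fs, 1), fs.counts)


def make_ones(n_first):
    counts = np.zeros(MINUTES_PER_DAY)
    counts[:n_first] = 1.0
    return FlySeries("f", "wt", counts, ["LD"], [0])


def test_bin_series_conserves_total(rng):
    counts = rng.poisson(2.0, MINUTES_PER_DAY).astype(float)
    fs = FlySeries("f", "wt", counts, ["LD"], [0])
    assert bin_series(fs, 30).sum() == counts.sum()
    with pytest.raises(ValueError):
        bin_series(fs, 7)
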