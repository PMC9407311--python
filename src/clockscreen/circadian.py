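"""Chi-square periodogram rhythmicity testing and period estimation.

The chi-square periodogram folds an equally spaced activity series at each
candidate period P into an R x B array (B phase columns per cycle, R
complete cycles) and measures how much of the total variance is explained
by the phase-column means:

    Qp = R * N * sum_b (M_b - Mbar)^2 / sum_i (x_i - Mbar)^2,   N = R * B

where M_b are the column means and Mbar is the grand mean of the folded
N points.  Under independent noise Qp is asymptotically chi-square with
B - 1 degrees of freedom (exactly, Qp/N follows a Beta((B-1)/2, (N-B)/2)
law, which converges to chi2_{B-1} as the number of cycles grows); the
significance line is the pointwise 0.95 chi-square quantile per period.
A fly is called rhythmic when Qp exceeds the line anywhere, and its
free-running period is the candidate maximizing Qp - sig_line.

Defaults follow common DD practice: activity counts in 30-min bins, DD
days 2-7, candidate periods 16-32 h in 0.5-h steps (each an integer
number of 30-min phase bins).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from clockscreen.dam_io import FlySeries, bin_series

DEFAULT_BIN_MINUTES = 30
DEFAULT_PERIODS = np.arange(16.0, 32.0 + 1e-9, 0.5)
ALPHA = 0.05


@dataclass
class Periodogram:
    """Qp statistic and chi-square significance line per candidate period."""

    fly_id: str
    periods: np.ndarray                   # hours, strictly increasing
    qp: np.ndarray
    df: np.ndarray                        # B - 1 per period
    sig_line: np.ndarray                  # chi2 0.95 quantile per period
    bin_minutes: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"period_h": self.periods, "Qp": self.qp,
                             "df": self.df, "sig_line": self.sig_line})


@dataclass
class RhythmCall:
    fly_id: str
    rhythmic: bool
    period_hours: float | None            # None when arrhythmic
    power: float                          # max(Qp - sig_line); > 0 iff rhythmic


def chi2_periodogram(series: FlySeries | np.ndarray,
                     periods: Sequence[float] | None = None,
                     bin_minutes: int = DEFAULT_BIN_MINUTES,
                     alpha: float = ALPHA,
                     fly_id: str = "") -> Periodogram:
    """Compute the chi-square periodogram of a (DD) activity series.

    ``series`` is either a FlySeries of minute counts (binned internally)
    or an already-binned 1-D array.  Every candidate period must be an
    integer multiple of the bin size, and the series must hold at least
    two full cycles of the longest candidate period.
    """
    if isinstance(series, FlySeries):
        fly_id = fly_id or series.fly_id
        x = bin_series(series, bin_minutes)
    else:
        x = np.asarray(series, dtype=float)
    periods = np.asarray(DEFAULT_PERIODS if periods is None else periods, dtype=float)
    if np.any(np.diff(periods) <= 0):
        raise ValueError("candidate periods must be strictly increasing")

    n_total = len(x)
    if np.nanvar(x) == 0:
        raise ValueError("constant series: periodogram undefined")
    qp = np.empty(len(periods))
    df = np.empty(len(periods), dtype=int)
    for k, p in enumerate(periods):
        b_exact = p * 60.0 / bin_minutes
        b = int(round(b_exact))
        if abs(b_exact - b) > 1e-9 or b < 2:
            raise ValueError(f"period {p} h is not an integer number of "
                             f"{bin_minutes}-min bins")
        r = n_total // b
        if r < 2:
            raise ValueError(f"fewer than 2 full cycles at period {p} h")
        n = r * b
        folded = x[:n].reshape(r, b)
        mbar = folded.mean()
        col_means = folded.mean(axis=0)
        sst = ((folded - mbar) ** 2).sum()
        if sst == 0:
            raise ValueError("constant series: periodogram undefined")
        qp[k] = r * n * ((col_means - mbar) ** 2).sum() / sst
        df[k] = b - 1
    sig = stats.chi2.ppf(1 - alpha, df)
    return Periodogram(fly_id=fly_id, periods=periods, qp=qp, df=df,
                       sig_line=sig, bin_minutes=bin_minutes)


def estimate_period(pg: Periodogram) -> RhythmCall:
    """Call rhythmicity and the free-running period from a periodogram.

    Rhythmic iff max(Qp - sig_line) > 0; the period is the argmax of
    Qp - sig_line, ties broken toward the candidate closest to 24 h and,
    on an exact tie, toward the shorter period.
    """
    excess = pg.qp - pg.sig_line
    best = np.max(excess)
    # lexicographic tie-break: excess desc, |P - 24| asc, P asc
    cand = np.nonzero(excess == best)[0]
    order = sorted(cand, key=lambda i: (abs(pg.periods[i] - 24.0), pg.periods[i]))
    i = order[0]
    rhythmic = bool(best > 0)
    return RhythmCall(fly_id=pg.fly_id, rhythmic=rhythmic,
                      period_hours=float(pg.periods[i]) if rhythmic else None,
                      power=float(best))


def group_rhythmicity(calls: Sequence[RhythmCall], genotype: str = "") -> dict:
    """Summarize rhythmicity for one genotype.

    Returns percent rhythmic and the mean +/- SEM free-running period among
    rhythmic flies (NaN when none are rhythmic).  Cross-genotype period
    comparisons are done with screen_stats.oneway_anova / tukey_hsd on the
    per-fly periods returned here.
    """
    if not calls:
        raise ValueError("no rhythm calls")
    periods = np.array([c.period_hours for c in calls if c.rhythmic], dtype=float)
    n_r = len(periods)
    return {
        "genotype": genotype,
        "n": len(calls),
        "n_rhythmic": n_r,
        "percent_rhythmic": 100.0 * n_r / len(calls),
        "mean_period_h": float(periods.mean()) if n_r else float("nan"),
        "sem_period_h": (float(periods.std(ddof=1) / np.sqrt(n_r)) if n_r > 1
                         else (0.0 if n_r == 1 else float("nan"))),
        "periods": periods,
    }
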