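"""Matplotlib figures for sleep profiles, periodograms and screen scatter.

All functions draw onto a provided Axes (or create one) and return it, so
they compose with any figure layout.  Use a non-interactive backend
(``matplotlib.use("Agg")``) in scripts.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd


def plot_sleep_profile(profiles, ax=None):
    """Half-hour sleep profiles with SEM ribbons, one line per genotype."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    if not isinstance(profiles, (list, tuple)):
        profiles = [profiles]
    zt = np.arange(48) * 0.5 + 0.25
    for prof in profiles:
        line, = ax.plot(zt, prof.bin_mean, label=f"{prof.genotype} (n={prof.n_flies})")
        if np.isfinite(prof.bin_sem).all():
            ax.fill_between(zt, prof.bin_mean - prof.bin_sem,
                            prof.bin_mean + prof.bin_sem,
                            alpha=0.25, color=line.get_color(), lw=0)
    ax.axvspan(12, 24, color="0.85", zorder=0)        # lights off
    ax.set_xlim(0, 24)
    ax.set_ylim(0, 30)
    ax.set_xlabel("Zeitgeber time (h)")
    ax.set_ylabel("sleep (min / 30 min)")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_periodogram(pg, ax=None):
    """Qp with the chi-square 0.95 significance line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    ax.plot(pg.periods, pg.qp, label="Qp")
    ax.plot(pg.periods, pg.sig_line, "--", color="0.4", label="chi2 0.95")
    ax.set_xlabel("period (h)")
    ax.set_ylabel("Qp")
    ax.legend(frameon=False, fontsize=8)
    if pg.fly_id:
        ax.set_title(pg.fly_id, fontsize=9)
    return ax


def plot_screen_scatter(table: pd.DataFrame, hits=None, metric: str = "siesta",
                        control: str | None = None, ax=None, seed: int = 0):
    """Per-fly scatter of a window metric by genotype with significance
    stars (* p<0.05, ** p<0.01) versus the control."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3))
    genotypes = list(dict.fromkeys(table["genotype"]))
    rng = np.random.default_rng(seed)
    pmap = {}
    if hits is not None:
        for h in hits:
            pmap[h.genotype] = min(h.p_vs_controls.values())
    top = table[metric].max()
    for x, g in enumerate(genotypes):
        vals = table.loc[table["genotype"] == g, metric]
        ax.scatter(x + rng.uniform(-0.2, 0.2, len(vals)), vals, s=6, alpha=0.6)
        ax.hlines(vals.median(), x - 0.3, x + 0.3, color="k", lw=1.2)
        p = pmap.get(g)
        if p is not None and p < 0.05:
            ax.text(x, top * 1.03, "**" if p < 0.01 else "*", ha="center", fontsize=10)
    ax.set_xticks(range(len(genotypes)))
    ax.set_xticklabels(genotypes, rotation=90, fontsize=7)
    ax.set_ylabel(f"{metric} sleep (min)")
    if control:
        ax.axhline(table.loc[table["genotype"] == control, metric].median(),
                   color="0.7", ls=":", zorder=0)
    return ax
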