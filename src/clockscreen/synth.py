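"""Synthetic DAM recordings and amplicon read sets with known ground truth.

Activity model
--------------
A fly is simulated as a two-state (sleep/wake) alternating renewal
process.  Sleep bouts last 10 + Geometric(mean 20) minutes, so every
programmed sleep bout is at least 10 min and the 5-min scoring rule
recovers programmed sleep losslessly.  Wake bouts are geometric with a
per-window mean of sleep_mean * (1 - f_w) / f_w, which pins the long-run
sleep occupancy of window w at f_w.  Wake minutes carry zero-truncated
Poisson(lambda=2) beam-break counts (always >= 1, so sleep is identifiable
from zero runs alone); sleep minutes carry 0.  At every 6-h window
boundary the ongoing bout is truncated and the state redrawn
Bernoulli(f_new), keeping per-window occupancy unbiased.  In constant
darkness the window template advances by (24 - tau) h per day, i.e. the
template phase runs at 24/tau phase-minutes per real minute.

The "control" preset (f = 0.35, 0.92, 0.25, 0.90 for morning, siesta,
evening, night) gives an expected siesta of ~0.92 * 360 = 331 min (~5.5 h)
of high night/siesta sleep with low morning/evening sleep; "mutantA"
lowers only the siesta occupancy to 0.837, a ~30-min siesta reduction
typical of a receptor mutant.

Read model
----------
Each simulated amplicon read is a same-pair product i (uniform over
pairs), or with probability p_cross a cross-pair fused product (uniform
over i < j).  Same-pair reads carry a small indel at cut i with the
per-guide probability: 80% deletions of Geometric(mean 4) size clipped to
1-15 bp spanning the cut, 20% single-base insertions at the cut.
Uniform substitution errors are applied per base everywhere.  Truth
labels are emitted per read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from clockscreen.amplicon import AmpliconReference, Guide, PrimerPair, revcomp
from clockscreen.dam_io import (
    ExperimentDesign,
    FlySeries,
    MINUTES_PER_DAY,
    N_CHANNELS,
    write_monitor_file,
)

SLEEP_BOUT_MIN = 10
SLEEP_BOUT_GEOM_MEAN = 20.0
SLEEP_BOUT_MEAN = SLEEP_BOUT_MIN + SLEEP_BOUT_GEOM_MEAN
WAKE_COUNT_LAMBDA = 2.0

#: ZT window boundaries (minutes); window w spans [edge_w, edge_{w+1})
_EDGES = np.array([0, 180, 540, 900, 1260, 1440])
#: occupancy index per edge interval: ZT0-3 morning, 3-9 siesta, 9-15
#: evening, 15-21 night, 21-24 morning again
_WINDOW_OF_EDGE = np.array([0, 1, 2, 3, 0])


@dataclass(frozen=True)
class ActivityPreset:
    """Generative sleep parameters for one genotype."""

    name: str
    f_windows: tuple[float, float, float, float]   # morning, siesta, evening, night
    tau_hours: float = 24.0

    def occupancy_at_phase(self, phase: float) -> float:
        k = np.searchsorted(_EDGES, phase, side="right") - 1
        return self.f_windows[_WINDOW_OF_EDGE[k]]


PRESETS = {
    "control": ActivityPreset("control", (0.35, 0.92, 0.25, 0.90)),
    "mutantA": ActivityPreset("mutantA", (0.35, 0.837, 0.25, 0.90)),
}


@dataclass
class ScreenScenario:
    """Genotype composition of a simulated screen.

    ``genotypes`` maps genotype name -> (n flies, preset name).
    """

    genotypes: dict[str, tuple[int, str]]
    seed: int = 0

    @classmethod
    def screen_default(cls, seed: int = 0) -> "ScreenScenario":
        """One Cas9-control genotype (n=150) plus 21 guide genotypes
        (n=32 each), of which g03, g08, g14 and g20 carry the ~30-min
        siesta-reducing preset."""
        effects = {"g03", "g08", "g14", "g20"}
        geno = {"control": (150, "control")}
        for k in range(1, 22):
            name = f"g{k:02d}"
            geno[name] = (32, "mutantA" if name in effects else "control")
        return cls(genotypes=geno, seed=seed)

    @property
    def true_effects(self) -> list[str]:
        return [g for g, (_, p) in self.genotypes.items() if p != "control"]


def _zt_poisson(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    """Zero-truncated Poisson draws (every value >= 1)."""
    x = rng.poisson(lam, size)
    bad = x == 0
    while bad.any():
        x[bad] = rng.poisson(lam, int(bad.sum()))
        bad = x == 0
    return x


def simulate_fly_activity(preset: ActivityPreset | str, days_ld: int, days_dd: int,
                          seed: int | np.random.Generator = 0,
                          fly_id: str = "fly", genotype: str | None = None) -> FlySeries:
    """Simulate one fly's minute-resolution beam-break series.

    The series starts at ZT0 of LD day 1 and is seed-reproducible.
    """
    if isinstance(preset, str):
        preset = PRESETS[preset]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    total = (days_ld + days_dd) * MINUTES_PER_DAY
    ld_end = days_ld * MINUTES_PER_DAY
    counts = np.zeros(total, dtype=float)
    rate_dd = 24.0 / preset.tau_hours      # phase-minutes per real minute in DD

    t = 0
    while t < total:
        in_dd = t >= ld_end
        rate = rate_dd if in_dd else 1.0
        phase = ((t - ld_end) * rate_dd) % MINUTES_PER_DAY if in_dd else t % MINUTES_PER_DAY
        f = preset.occupancy_at_phase(phase)
        # real minutes until the template crosses the next window boundary
        next_edge = _EDGES[np.searchsorted(_EDGES, phase, side="right")]
        seg_end = t + max(1, math.ceil((next_edge - phase) / rate))
        if not in_dd:
            seg_end = min(seg_end, ld_end)
        seg_end = min(seg_end, total)

        asleep = rng.random() < f
        while t < seg_end:
            if asleep:
                dur = SLEEP_BOUT_MIN + int(rng.geometric(1.0 / SLEEP_BOUT_GEOM_MEAN))
                t += min(dur, seg_end - t)      # counts stay 0
            else:
                if f >= 1.0:
                    dur = seg_end - t
                elif f <= 0.0:
                    dur = seg_end - t
                    counts[t:seg_end] = _zt_poisson(rng, WAKE_COUNT_LAMBDA, seg_end - t)
                    t = seg_end
                    break
                else:
                    mean_wake = SLEEP_BOUT_MEAN * (1.0 - f) / f
                    p = min(1.0, 1.0 / max(mean_wake, 1.0))
                    dur = int(rng.geometric(p))
                dur = min(dur, seg_end - t)
                if f < 1.0:
                    counts[t:t + dur] = _zt_poisson(rng, WAKE_COUNT_LAMBDA, dur)
                t += dur
            asleep = not asleep

    day_seg = ["LD"] * days_ld + ["DD"] * days_dd
    return FlySeries(fly_id=fly_id, genotype=genotype or preset.name,
                     counts=counts, day_seg=day_seg,
                     day_ids=list(range(days_ld + days_dd)))


def simulate_experiment(scenario: ScreenScenario, out_dir,
                        days_ld: int = 5, days_dd: int = 0,
                        lights_on: str = "08:00",
                        start_date: str = "2024-01-01",
                        deaths: dict[str, int] | None = None,
                        ) -> tuple[list[Path], ExperimentDesign, pd.DataFrame]:
    """Write Trikinetics-format monitor files plus a design and truth table.

    Flies are packed 32 per monitor in scenario order.  ``deaths`` maps a
    fly id to the minute after which all of its counts are forced to zero
    (a programmed death).  Returns (monitor paths, design, truth table).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(scenario.seed)
    deaths = deaths or {}

    flies = []                            # (fly_id, genotype, preset_name)
    for geno, (n, preset_name) in scenario.genotypes.items():
        for k in range(n):
            flies.append((geno, preset_name, k))

    total = (days_ld + days_dd) * MINUTES_PER_DAY
    timestamps = pd.date_range(f"{start_date} {lights_on}", periods=total, freq="min")
    zt = np.arange(total) % MINUTES_PER_DAY
    is_ld_day = (np.arange(total) // MINUTES_PER_DAY) < days_ld
    light = ((zt < 720) & is_ld_day).astype(np.int8)

    n_monitors = math.ceil(len(flies) / N_CHANNELS)
    monitor_paths: list[Path] = []
    channel_map: dict[tuple[str, int], str] = {}
    truth_rows = []
    for m in range(n_monitors):
        monitor_id = f"Monitor{m + 1}"
        counts = np.zeros((total, N_CHANNELS), dtype=float)
        for ch in range(N_CHANNELS):
            fly_no = m * N_CHANNELS + ch
            if fly_no >= len(flies):
                break
            geno, preset_name, k = flies[fly_no]
            fly_id = f"{monitor_id}:c{ch + 1:02d}"
            fs = simulate_fly_activity(PRESETS[preset_name], days_ld, days_dd,
                                       seed=rng, fly_id=fly_id, genotype=geno)
            col = fs.counts
            if fly_id in deaths:
                col = col.copy()
                col[deaths[fly_id]:] = 0.0
            counts[:, ch] = col
            channel_map[(monitor_id, ch + 1)] = geno
            truth_rows.append({"fly_id": fly_id, "genotype": geno,
                               "preset": preset_name,
                               "is_effect": preset_name != "control",
                               "dead": fly_id in deaths})
        path = out_dir / f"{monitor_id}.txt"
        write_monitor_file(path, timestamps, light, counts)
        monitor_paths.append(path)

    design = ExperimentDesign(channel_map, lights_on=lights_on,
                              ld_days=days_ld, dd_days=days_dd)
    pd.DataFrame([{"monitor": m, "channel": c, "genotype": g}
                  for (m, c), g in channel_map.items()]
                 ).to_csv(out_dir / "design.csv", index=False)
    truth = pd.DataFrame(truth_rows)
    truth.to_csv(out_dir / "truth.csv", index=False)
    return monitor_paths, design, truth


# ---------------------------------------------------------------------------
# amplicon read simulation

@dataclass
class ReadSimConfig:
    """Parameters of a simulated amplicon sequencing run."""

    ref: AmpliconReference
    p_indel: list[float]                  # per-guide small-indel probability
    p_cross: float = 0.0                  # cross-pair large-deletion probability
    sub_rate: float = 0.001               # substitution error per base
    n_reads: int = 10000
    p_insertion: float = 0.2              # insertions among small edits
    del_geom_mean: float = 4.0            # deletion size law, clipped to 1-15
    del_max: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.p_indel) != self.ref.n_sites:
            raise ValueError("p_indel needs one probability per guide")
        for p in (*self.p_indel, self.p_cross, self.sub_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_reads < 1:
            raise ValueError("read count must be >= 1")

    @classmethod
    def from_yaml(cls, path, ref: AmpliconReference) -> "ReadSimConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        return cls(ref=ref, **cfg)


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _substitute(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(len(arr)) < rate)[0]
    for p in hit:
        choices = _BASES[_BASES != arr[p]]
        arr[p] = rng.choice(choices)
    return arr.tobytes().decode()


def simulate_amplicon_reads(cfg: ReadSimConfig, out_fastq=None, truth_csv=None,
                            ) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Draw reads per the read model; returns (reads, truth table) and
    optionally writes a FASTQ plus a per-read truth CSV."""
    rng = np.random.default_rng(cfg.seed)
    ref = cfg.ref
    n_pairs = ref.n_sites
    cross_combos = [(i, j) for i in range(1, n_pairs + 1)
                    for j in range(i + 1, n_pairs + 1)]

    reads: list[tuple[str, str]] = []
    rows = []
    for k in range(cfg.n_reads):
        rid = f"read{k:06d}"
        if cross_combos and rng.random() < cfg.p_cross:
            i, j = cross_combos[rng.integers(len(cross_combos))]
            seq, span = ref.fused_amplicon(i, j)
            truth_cat, indel = "large_deletion", -span
            product = f"cross_{i}_{j}"
        else:
            i = int(rng.integers(n_pairs)) + 1
            product = f"same_{i}"
            pair, cut = ref.pairs[i - 1], ref.guides[i - 1].cut
            seq = ref.amplicon(i)
            local_cut = cut - pair.start
            if rng.random() < cfg.p_indel[i - 1]:
                if rng.random() < cfg.p_insertion:
                    ins = chr(_BASES[rng.integers(4)])
                    seq = seq[:local_cut] + ins + seq[local_cut:]
                    truth_cat, indel = "small_indel", 1
                else:
                    size = int(np.clip(rng.geometric(1.0 / cfg.del_geom_mean),
                                       1, cfg.del_max))
                    start = max(0, local_cut - size // 2)
                    seq = seq[:start] + seq[start + size:]
                    truth_cat, indel = "small_indel", -size
            else:
                truth_cat, indel = "unmodified", 0
        seq = _substitute(seq, cfg.sub_rate, rng)
        reads.append((rid, seq))
        rows.append({"read_id": rid, "product": product,
                     "category": truth_cat, "indel_len": indel})
    truth = pd.DataFrame(rows)

    if out_fastq is not None:
        records = [SeqRecord(Seq(s), id=rid, description="",
                             letter_annotations={"phred_quality": [40] * len(s)})
                   for rid, s in reads]
        SeqIO.write(records, str(out_fastq), "fastq")
    if truth_csv is not None:
        truth.to_csv(truth_csv, index=False)
    return reads, truth


# ---------------------------------------------------------------------------
# synthetic references

def make_synthetic_reference(n_guides: int = 3, amplicon_len: int = 250,
                             guide_spacing: int = 1500, margin: int = 200,
                             seed: int = 0, gene: str = "synthgene",
                             ) -> AmpliconReference:
    """Construct a random reference with planted protospacers (NGG PAMs)
    and flanking primer pairs.

    Guide cut sites are ``guide_spacing`` bp apart, so cross-pair products
    of non-adjacent guides delete a multi-kb span.  Primers and
    protospacers are checked for uniqueness; the sequence is redrawn if a
    collision occurs (vanishingly rare at these lengths).
    """
    rng = np.random.default_rng(seed)
    length = margin * 2 + guide_spacing * (n_guides - 1) + amplicon_len
    for attempt in range(20):
        arr = _BASES[rng.integers(4, size=length)]
        seq = bytearray(arr.tobytes())
        guides, pairs = [], []
        ok = True
        for g in range(n_guides):
            cut = margin + amplicon_len // 2 + g * guide_spacing
            s = cut - 17                   # forward protospacer start
            seq[s + 21:s + 23] = b"GG"     # plant the NGG PAM
        ref_seq = seq.decode()
        for g in range(n_guides):
            cut = margin + amplicon_len // 2 + g * guide_spacing
            s = cut - 17
            proto = ref_seq[s:s + 20]
            a_start = cut - amplicon_len // 2
            a_end = a_start + amplicon_len
            fwd = ref_seq[a_start:a_start + 20]
            rev = revcomp(ref_seq[a_end - 20:a_end])
            for sub in (proto, fwd):
                if _count_both_strands(ref_seq, sub) != 1:
                    ok = False
            if _count_both_strands(ref_seq, revcomp(rev)) != 1:
                ok = False
            guides.append(Guide(protospacer=proto, strand="+", start=s, cut=cut))
            pairs.append(PrimerPair(index=g + 1, forward=fwd, reverse=rev,
                                    start=a_start, end=a_end))
        if ok:
            return AmpliconReference(gene=gene, seq=ref_seq, guides=guides, pairs=pairs)
    raise RuntimeError("could not build a collision-free synthetic reference")


def _count_both_strands(seq: str, sub: str) -> int:
    n = seq.count(sub)
    rc = revcomp(sub)
    n += seq.count(rc) if rc != sub else 0
    return n


def write_reference_files(ref: AmpliconReference, out_dir) -> dict[str, Path]:
    """Emit reference FASTA plus guides/primers TSVs (the build_reference
    input formats)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta = out_dir / f"{ref.gene}.fa"
    SeqIO.write([SeqRecord(Seq(ref.seq), id=ref.gene, description="synthetic")],
                str(fasta), "fasta")
    guides = out_dir / f"{ref.gene}_guides.tsv"
    pd.DataFrame([{"gene": ref.gene, "protospacer": g.protospacer,
                   "strand": g.strand} for g in ref.guides]
                 ).to_csv(guides, sep="\t", index=False)
    primers = out_dir / f"{ref.gene}_primers.tsv"
    pd.DataFrame([{"gene": ref.gene, "index": p.index, "forward": p.forward,
                   "reverse": p.reverse} for p in ref.pairs]
                 ).to_csv(primers, sep="\t", index=False)
    return {"fasta": fasta, "guides": guides, "primers": primers}
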