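# Methods

## Sleep scoring and windows

Sleep is scored by the standard fly criterion: a minute is asleep iff it
belongs to a maximal run of ≥5 consecutive minutes with zero beam breaks.
Two edge rules are ours, stated here because the criterion itself does not
fix them: (i) runs truncated by the boundary of the selected segment count
if their *observed* length reaches 5 min (no look-back across the
boundary); (ii) missing minutes terminate inactivity runs and are never
sleep — the conservative reading of a recording gap. A fly-day with >5%
missing minutes is dropped at alignment time; since missingness in a DAM
file affects all 32 channels alike, the day is dropped monitor-wide.

LD analyses use the last 4 complete LD days, leaving the earlier days for
entrainment; the recording design therefore needs ≥5 LD days. Window
totals (morning ZT21–3, siesta ZT3–9, evening ZT9–15, night ZT15–21) are
per-day sums averaged across the 4 analysis days, so one fly contributes
one value per window and the four windows always add up to total daily
sleep. Averaging (rather than summing) across days keeps the units
comparable to single-day scatter plots. Flies with zero counts over the
final 24 h of the selected segment are removed as dead; the rule is
deliberately minimal and logged per fly.

## Chi-square periodogram

For candidate period P the binned series is folded into R complete cycles
of B = P/bin phase columns and

    Qp = R · N · Σ_b (M_b − M̄)² / Σ_i (x_i − M̄)²,    N = R·B.

Rather than trusting the transcription of the statistic, its null behavior
is derived and then simulated: under i.i.d. noise Qp = N·SSB/SST, so
Qp/N ~ Beta((B−1)/2, (N−B)/2) exactly (for normal errors), which converges
to χ²(B−1) as the cycle count grows. At 6 cycles of a 24-h fold the exact
pointwise size of the χ²₀.₉₅ test is ≈0.037 — slightly conservative; at 20
cycles it is ≈0.046. The null-calibration test simulates 1,000 white-noise
series of 20 cycles, where the asymptotic reference is the claim under
test; the distributional (Kolmogorov) check uses the same regime.

Defaults: activity counts (not sleep state) in 30-min bins; DD days 2–7
(day 1 discarded as a transient after lights-out); candidate periods
16–32 h in 0.5-h steps so every period is an integer number of bins;
pointwise α = 0.05 per period with no cross-period multiplicity
correction (the field convention; the periodogram is used as a per-fly
detector, not a hypothesis family). Rhythmic ⇔ max(Qp − sig) > 0; period
= argmax, ties broken toward 24 h, then toward the shorter period.
Constant series and series with fewer than 2 cycles of the longest
candidate are rejected as degenerate rather than scored.

## Screen statistics

One-way fixed-effects ANOVA followed by all-pairs Tukey HSD; unequal
group sizes use the Tukey–Kramer standard error
sqrt(MSW/2·(1/n_a + 1/n_b)), with adjusted p from the studentized-range
distribution (k groups, ANOVA within-group df). Both are implemented
directly (the hand-checkable q and F values are part of the test suite)
and verified against scipy's `f_oneway` and `tukey_hsd` to 1e-8 on random
data. `call_screen_hits` computes the Tukey statistics only for
experimental-vs-control pairs — numerically identical to the full table
for those pairs, and much faster for 22-genotype screens. A hit must be
significant versus *every* listed control and lie on the required side of
each control mean; screen mode passes one control, focused mode two
(driver-only and guide-only). No normality checks or nonparametric
fallback are applied: the procedure mirrors the plain ANOVA/Tukey used in
this kind of screen. Medians are reported alongside means because screen
summaries are customarily quoted as medians.

## Amplicon read classification

The 3-guide design implies two product classes: same-pair amplicons
(PCR1–3) carrying small indels at one cut site, and cross-pair fusion
products (PCR4–6) created when two guides cut simultaneously and the
intervening fragment is lost. Primer matching (≤2 mismatches at each read
end, both orientations tried, ties to the lower pair index) is therefore
the primary large-deletion evidence: any F_i…R_j read with i<j is a
large_deletion and its deleted span is the distance between the two cut
sites. Same-pair reads are globally aligned to their amplicon with affine
gap scoring (match +5, mismatch −4, gap open −10, extend −1; a length-L
gap costs 10+L), which favors the contiguous deletions typical of NHEJ
over scattered mismatches. Classification rules: deletion ≥50 bp →
large_deletion; indel overlapping the ±3 bp window around the predicted
cut (3 bp 5′ of the PAM; between protospacer bases 17/18) → small_indel;
mismatches only → substitution_only, excluded from % modified; indels
outside the window → unmodified (treated as PCR/sequencing artifacts).
The ±3 bp window tolerates cut-site micro-ambiguity and gap-placement
ambiguity in short repeats while excluding distal artifacts.

Per-guide % modified uses reads *covering* the site (same-pair i plus
cross-pair products whose junction involves cut i) as the denominator;
the gene-level large-deletion percentage uses all assigned reads. Reads
are single-end (merged or long-amplicon); paired-end merging, UMIs and
HDR/base-editing modes are out of scope.

## Synthetic data

The activity generator is a two-state alternating renewal process whose
only calibrated quantity is the per-window sleep occupancy f_w. Sleep
bouts last 10 + Geometric(mean 20) min: the 10-min floor guarantees the
5-min rule recovers programmed sleep losslessly, decoupling generator
calibration from scoring-rule erosion and making expectations analytic
(E[window sleep] = f_w·360 min). Wake bouts are geometric with mean
30·(1−f_w)/f_w, pinning the long-run occupancy at f_w; wake minutes carry
zero-truncated Poisson(λ=2) counts so sleep is identifiable from zero
runs alone. At each window boundary the ongoing bout is truncated and the
state redrawn Bernoulli(f_new), which keeps per-window occupancy unbiased
at the cost of a few minutes/day of boundary erosion. In DD the window
template advances by (24−τ) h per day (phase rate 24/τ), giving a true
behavioral period of τ hours.

Presets: "control" f = (0.35, 0.92, 0.25, 0.90) for (morning, siesta,
evening, night) — expected siesta ≈ 331 min ≈ 5.5 h; "mutantA" is
identical except siesta f = 0.837, a ~30-min reduction typical of a
receptor mutant. The default screen scenario is 1 control genotype
(n=150) plus 21 guide genotypes (n=32), with g03/g08/g14/g20 carrying
"mutantA". Between-fly variance is an assumption (the renewal process
plus count noise, no programmed fly-level heterogeneity), so screen power
is verified by construction — the ~30-min effect is ≳7 within-genotype
SDs of the 4-day-averaged siesta — not matched to any particular
empirical variance. Consequently a passing screen demonstrates the
statistics and plumbing, not field-realistic power.

The read simulator draws each read from one product (uniform same-pair;
cross-pair with probability p_cross, uniform over i<j), applies a small
indel at the cut with the per-guide probability (80% deletions of
Geometric(mean 4) size clipped to 1–15 bp spanning the cut, 20% 1-bp
insertions), then uniform substitution errors. It does not model quality
decay, indel sequencing errors, chimeric PCR other than the programmed
fusions, or microhomology-biased NHEJ spectra — so classifier accuracy on
it bounds performance only for substitution-dominated platforms (MiSeq
class), which is the intended assay.

All generators are driven by a single numpy Generator per call and are
byte-for-byte reproducible for a given seed.

## Problem sizes

Test and acceptance runs are sized for one CPU: sleep-oracle equivalence
on 1,000 day-length traces; periodogram null calibration on 1,000
replicates of 20 cycles; screen FWER on 200 null 22-genotype screens;
period recovery with 5 flies per τ; screen recovery with 5 (tests) or 20
(acceptance script) replicate screens of 822 flies × 5 LD days with a
full monitor-file round trip; classifier validation on 50,000 reads at
the 0.7% operating point and 20,000 reads for the false-positive bound.

## Known limitations

- No multi-beam or video tracking input; the DAM status field is ignored
  beyond line-level validation.
- Rhythmicity uses one statistic (chi-square periodogram); Lomb–Scargle
  and autocorrelation cross-checks, and phase markers (activity onset),
  are out of scope.
- The hit-calling FWER guarantee is inherited from Tukey's procedure and
  holds per screen metric; screening several windows would need an extra
  correction layer.
- The amplicon classifier quantifies editing per read; it does not
  reconstruct allele spectra or distinguish clonal from independent
  editing events in pooled cells.
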