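"""Classify simulated amplicon-sequencing reads from a 3-guide design.

Builds a synthetic multi-kb reference with three planted guides and
primer pairs, simulates 6,000 reads with unequal per-guide editing rates
plus 4% cross-pair large-deletion reads and 0.1% substitution error, and
summarizes per-guide percent modified and the gene-level large-deletion
fraction.
"""

from clockscreen import (
    ReadSimConfig,
    classify_reads,
    make_synthetic_reference,
    simulate_amplicon_reads,
    summarize_editing,
)

ref = make_synthetic_reference(n_guides=3, seed=5)
cfg = ReadSimConfig(ref=ref, p_indel=[0.007, 0.10, 0.50], p_cross=0.04,
                    sub_rate=0.001, n_reads=6000, seed=2)
reads, truth = simulate_amplicon_reads(cfg)

calls = classify_reads(reads, ref)
summary = summarize_editing(calls, ref)

print(summary.per_guide.round(2).to_string(index=False))
print(f"\nlarge-deletion reads: {summary.pct_large_deletion:.1f}% of "
      f"{summary.n_assigned} assigned")
print("category counts:", summary.category_counts)
# Per-guide "pct_modified" recovers the programmed editing rates (plus the
# shared cross-pair deletions); guide efficiencies spanning 0.7%-50% and a
# 2-6% large-deletion fraction mirror a typical 3-guide mutagenesis assay.
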