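"""Amplicon reference building, read assignment, alignment, classification."""

import numpy as np
import pandas as pd
import pytest

from clockscreen.amplicon import (
    LARGE_DELETION_MIN,
    align_read,
    assign_primer_pair,
    build_reference,
    calls_table,
    classify_read,
    classify_reads,
    locate_guide,
    revcomp,
    summarize_editing,
    _alignment_indels,
)
from clockscreen.synth import (
    ReadSimConfig,
    make_synthetic_reference,
    simulate_amplicon_reads,
    write_reference_files,
)


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(4, size=n))


# ---------------------------------------------------------------------------
# reference construction

def test_synthetic_reference_cut_sites_are_where_planted(ref3):
    for g, p in zip(ref3.guides, ref3.pairs):
        assert p.start <= g.cut < p.end
        # forward guide: cut 3 bp 5' of the NGG PAM
        assert ref3.seq[g.start + 21:g.start + 23] == "GG"
        assert g.cut == g.start + 17


def test_build_reference_roundtrip(tmp_path, ref3):
    files = write_reference_files(ref3, tmp_path)
    rebuilt = build_reference(files["fasta"], files["guides"], files["primers"])
    assert rebuilt.seq == ref3.seq
    assert [g.cut for g in rebuilt.guides] == [g.cut for g in ref3.guides]
    assert [(p.start, p.end) for p in rebuilt.pairs] == \
        [(p.start, p.end) for p in ref3.pairs]


def test_reverse_strand_protospacer_cut_site_by_manual_count(rng):
    proto = "ACGTACGTTTGCAGGTCAAT"          # 20 nt, arbitrary
    left = _random_seq(rng, 100)
    right = _random_seq(rng, 100)
    s = len(left) + 3                        # match start of revcomp(proto)
    seq = left + "CCA" + revcomp(proto) + right
    g = locate_guide(seq, proto)
    assert g.strand == "-" and g.start == s
    # cut falls between protospacer bases 17/18, i.e. 3 bp from the PAM:
    # forward coordinates s+2 | s+3
    assert g.cut == s + 3


def test_absent_or_duplicated_guide_raises(rng):
    seq = _random_seq(rng, 300)
    with pytest.raises(ValueError, match="not found"):
        locate_guide(seq, "A" * 20)
    proto = seq[50:70]
    dup = seq + seq[40:80]
    with pytest.raises(ValueError, match="times"):
        locate_guide(dup, proto)


# ---------------------------------------------------------------------------
# primer-pair assignment

def test_exact_amplicon_assigns_same_pair(ref3):
    asg = assign_primer_pair(ref3.amplicon(2), ref3)
    assert asg.kind == "same" and (asg.i, asg.j) == (2, 2)


def test_fused_product_assigns_cross_pair(ref3):
    fused, span = ref3.fused_amplicon(1, 3)
    asg = assign_primer_pair(fused, ref3)
    assert asg.kind == "cross" and (asg.i, asg.j) == (1, 3)
    assert span == ref3.guides[2].cut - ref3.guides[0].cut


def test_unmatched_read_is_unassigned(ref3, rng):
    asg = assign_primer_pair(_random_seq(rng, 250), ref3)
    assert asg.kind == "unassigned"


def test_assignment_is_orientation_invariant(ref3):
    read = ref3.amplicon(1)
    fwd = assign_primer_pair(read, ref3)
    rev = assign_primer_pair(revcomp(read), ref3)
    assert (fwd.kind, fwd.i, fwd.j) == (rev.kind, rev.i, rev.j)
    assert rev.oriented_read == read


def test_primer_mismatch_tolerance_boundary(ref3):
    read = list(ref3.amplicon(1))
    read[0] = "A" if read[0] != "A" else "C"
    read[1] = "A" if read[1] != "A" else "C"
    asg = assign_primer_pair("".join(read), ref3)
    assert asg.kind == "same" and asg.mismatches == 2   # <=2 mismatches allowed
    read[2] = "A" if read[2] != "A" else "C"
    assert assign_primer_pair("".join(read), ref3).kind == "unassigned"


# ---------------------------------------------------------------------------
# alignment

def test_identical_read_aligns_gapless(ref3):
    seg = ref3.amplicon(1)
    assert _alignment_indels(align_read(seg, seg), 0) == []


def test_planted_deletion_recovered_at_position(ref3):
    seg = ref3.amplicon(1)
    pos = 100
    read = seg[:pos] + seg[pos + 4:]
    indels = _alignment_indels(align_read(read, seg), 0)
    assert len(indels) == 1
    p, ln = indels[0]
    assert ln == -4 and abs(p - pos) <= 2    # placement ambiguity in repeats


def test_substitutions_do_not_open_gaps(ref3, rng):
    seg = ref3.amplicon(2)
    read = list(seg)
    for p in rng.choice(len(seg), size=max(1, len(seg) // 50), replace=False):
        read[p] = "ACGT"[(("ACGT".index(read[p])) + 1) % 4]
    indels = _alignment_indels(align_read("".join(read), seg), 0)
    assert indels == []


# ---------------------------------------------------------------------------
# classification

def test_exact_read_is_unmodified(ref3):
    call = classify_read(ref3.amplicon(1), ref3, "r0")
    assert call.category == "unmodified" and call.kind == "same"


def test_three_bp_deletion_at_cut_is_small_indel(ref3):
    cut = ref3.guides[1].cut - ref3.pairs[1].start
    seg = ref3.amplicon(2)
    read = seg[:cut - 1] + seg[cut + 2:]
    call = classify_read(read, ref3, "r1")
    assert call.category == "small_indel" and call.indel_len == -3


def test_cross_pair_read_is_large_deletion_spanning_kilobases(ref3):
    fused, span = ref3.fused_amplicon(1, 3)
    call = classify_read(fused, ref3, "r2")
    assert call.category == "large_deletion"
    assert call.deletion_span == span and span > 2000


def test_same_pair_deletion_over_50bp_is_large_deletion(ref3):
    cut = ref3.guides[0].cut - ref3.pairs[0].start
    seg = ref3.amplicon(1)
    read = seg[:cut - 30] + seg[cut + 30:]   # 60-bp deletion around the cut
    call = classify_read(read, ref3, "r3")
    assert call.category == "large_deletion"
    assert call.deletion_span >= LARGE_DELETION_MIN


def test_distal_indel_outside_window_is_not_an_edit(ref3):
    seg = ref3.amplicon(1)
    cut = ref3.guides[0].cut - ref3.pairs[0].start
    pos = cut - 40
    read = seg[:pos] + seg[pos + 2:]         # 2-bp deletion 40 bp from the cut
    call = classify_read(read, ref3, "r4")
    assert call.category == "unmodified"


def test_substitution_only_read_never_counts_as_edited(ref3):
    seg = ref3.amplicon(3)
    cut = ref3.guides[2].cut - ref3.pairs[2].start
    read = list(seg)
    read[cut] = "ACGT"[("ACGT".index(read[cut]) + 1) % 4]   # SNV at the cut
    call = classify_read("".join(read), ref3, "r5")
    assert call.category == "substitution_only"


def test_classification_is_orientation_invariant(ref3):
    cfg = ReadSimConfig(ref=ref3, p_indel=[0.3, 0.3, 0.3], p_cross=0.05,
                        sub_rate=0.002, n_reads=150, seed=4)
    reads, _ = simulate_amplicon_reads(cfg)
    fwd = [c.category for c in classify_reads(reads, ref3)]
    rev = [c.category for c in classify_reads([(r, revcomp(s)) for r, s in reads], ref3)]
    assert fwd == rev


# ---------------------------------------------------------------------------
# summaries

def test_all_unmodified_reads_give_zero_percent(ref3):
    reads = [(f"r{i}", ref3.amplicon(1 + i % 3)) for i in range(30)]
    summ = summarize_editing(classify_reads(reads, ref3), ref3)
    assert (summ.per_guide["pct_modified"] == 0).all()
    assert summ.pct_large_deletion == 0.0


def test_category_counts_partition_assigned_reads(ref3):
    cfg = ReadSimConfig(ref=ref3, p_indel=[0.2, 0.1, 0.05], p_cross=0.04,
                        sub_rate=0.005, n_reads=400, seed=11)
    reads, _ = simulate_amplicon_reads(cfg)
    calls = classify_reads(reads, ref3)
    summ = summarize_editing(calls, ref3)
    n_assigned = sum(c.category != "unassigned" for c in calls)
    assert summ.n_assigned == n_assigned
    assert sum(summ.category_counts.values()) == n_assigned


def test_programmed_editing_rates_recovered_within_3_se(ref1):
    for p_true in (0.1, 0.5):
        cfg = ReadSimConfig(ref=ref1, p_indel=[p_true], p_cross=0.0,
                            sub_rate=0.001, n_reads=4000, seed=21)
        reads, _ = simulate_amplicon_reads(cfg)
        summ = summarize_editing(classify_reads(reads, ref1), ref1)
        est = summ.per_guide["pct_modified"].iloc[0] / 100.0
        se = np.sqrt(p_true * (1 - p_true) / cfg.n_reads)
        assert abs(est - p_true) <= 3 * se


def test_zero_edit_false_positive_rate_below_point_one_percent(ref3):
    cfg = ReadSimConfig(ref=ref3, p_indel=[0.0, 0.0, 0.0], p_cross=0.0,
                        sub_rate=0.01, n_reads=3000, seed=31)   # 1% error
    reads, _ = simulate_amplicon_reads(cfg)
    summ = summarize_editing(classify_reads(reads, ref3), ref3)
    assert (summ.per_guide["pct_modified"] < 0.1).all()


def test_large_deletion_percentage_in_described_band(ref3):
    cfg = ReadSimConfig(ref=ref3, p_indel=[0.02, 0.02, 0.02], p_cross=0.04,
                        sub_rate=0.001, n_reads=4000, seed=41)
    reads, _ = simulate_amplicon_reads(cfg)
    summ = summarize_editing(classify_reads(reads, ref3), ref3)
    assert 2.0 <= summ.pct_large_deletion <= 6.0


def test_fastq_roundtrip_classification(tmp_path, ref1):
    cfg = ReadSimConfig(ref=ref1, p_indel=[0.2], sub_rate=0.001,
                        n_reads=60, seed=51)
    fq = tmp_path / "reads.fastq"
    _, truth = simulate_amplicon_reads(cfg, out_fastq=fq,
                                       truth_csv=tmp_path / "truth.csv")
    calls = classify_reads(str(fq), ref1)
    tab = calls_table(calls).merge(truth, on="read_id", suffixes=("_call", "_true"))
    assert len(tab) == 60
    mapped = tab["category_call"].replace({"substitution_only": "unmodified"})
    assert (mapped == tab["category_true"]).mean() >= 0.99
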