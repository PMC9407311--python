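"""Read-level classification of CRISPR editing from targeted amplicon
sequencing with a 3-guide / 3-primer-pair design.

Each gene is targeted by three guides; three primer pairs (F_i, R_i)
amplify 230-270 bp regions centered on the predicted SpCas9 cut sites
(3 bp 5' of each NGG PAM).  When a single guide cuts, error-prone repair
leaves a small indel near its cut site inside the same-pair amplicon
(products PCR1-3).  When two guides cut simultaneously, the intervening
genomic segment is lost and a chimeric product amplifies from F_i to R_j
(i < j; products PCR4-6), so cross-primer-pair reads are direct evidence
of a large deletion.

Reads are assigned to a product by matching the 5' end against the
forward primers and the 3' end against the reverse primers (<=2
mismatches each, either read orientation), globally aligned to the
assigned reference segment with affine gap scoring that favors the
contiguous deletions typical of NHEJ, and classified as unmodified,
small_indel (an indel overlapping a +/-3 bp window around the cut site),
large_deletion (cross-pair product, or a same-pair deletion >= 50 bp),
or substitution_only (mismatches but no gap; these are sequencing/PCR
errors and never count as editing).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner

logger = logging.getLogger(__name__)

QUANT_WINDOW = 3          # +/- bp around the cut site counted as on-target
LARGE_DELETION_MIN = 50   # bp; same-pair deletions at least this long
PRIMER_MAX_MISMATCH = 2
AMPLICON_RANGE = (230, 270)
MIN_ALIGN_IDENTITY = 0.6  # score floor, as fraction of the perfect-match score

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _make_aligner() -> PairwiseAligner:
    # NHEJ-friendly affine scoring: a length-L gap costs 10 + L
    a = PairwiseAligner()
    a.mode = "global"
    a.match_score = 5
    a.mismatch_score = -4
    a.open_gap_score = -11
    a.extend_gap_score = -1
    return a


_ALIGNER = _make_aligner()


@dataclass
class Guide:
    """One protospacer mapped onto the reference.

    ``cut`` is the forward-strand coordinate of the first base 3' of the
    blunt SpCas9 cut (between protospacer positions 17 and 18, i.e. 3 bp
    5' of the PAM).
    """

    protospacer: str
    strand: str                           # '+' or '-'
    start: int                            # match start on the forward strand
    cut: int


@dataclass
class PrimerPair:
    index: int                            # 1-based pair number
    forward: str
    reverse: str                          # as sequenced (revcomp of reference)
    start: int                            # amplicon start on the reference
    end: int                              # amplicon end (exclusive)


@dataclass
class AmpliconReference:
    """Reference sequence with guide cut sites and primer pairs for one gene."""

    gene: str
    seq: str
    guides: list[Guide]
    pairs: list[PrimerPair]

    def __post_init__(self) -> None:
        if len(self.guides) != len(self.pairs):
            raise ValueError("need one primer pair per guide")
        for g, p in zip(self.guides, self.pairs):
            if not (p.start <= g.cut < p.end):
                raise ValueError(
                    f"{self.gene}: cut site {g.cut} outside amplicon "
                    f"{p.index} [{p.start}, {p.end})")
            ln = p.end - p.start
            if not (AMPLICON_RANGE[0] <= ln <= AMPLICON_RANGE[1]):
                logger.warning("%s: amplicon %d length %d bp outside the "
                               "%d-%d bp design range", self.gene, p.index,
                               ln, *AMPLICON_RANGE)

    @property
    def n_sites(self) -> int:
        return len(self.guides)

    def amplicon(self, i: int) -> str:
        """Expected same-pair product i (1-based)."""
        p = self.pairs[i - 1]
        return self.seq[p.start:p.end]

    def fused_amplicon(self, i: int, j: int) -> tuple[str, int]:
        """Expected cross-pair product (i < j): left of cut i joined to
        right of cut j.  Returns (sequence, deleted span in bp)."""
        if not i < j:
            raise ValueError("cross-pair product requires i < j")
        pi, pj = self.pairs[i - 1], self.pairs[j - 1]
        ci, cj = self.guides[i - 1].cut, self.guides[j - 1].cut
        return self.seq[pi.start:ci] + self.seq[cj:pj.end], cj - ci


@dataclass
class ProductAssignment:
    kind: str                             # 'same' | 'cross' | 'unassigned'
    i: int | None = None                  # forward-primer pair (1-based)
    j: int | None = None                  # reverse-primer pair (1-based)
    oriented_read: str = ""               # read in amplicon orientation
    mismatches: int = 0


@dataclass
class ReadCall:
    """Classification of a single read."""

    read_id: str
    kind: str                             # product assignment kind
    pair_i: int | None
    pair_j: int | None
    category: str                         # unmodified | small_indel | large_deletion
                                          # | substitution_only | unassigned
    indel_len: int = 0                    # signed: +insertion / -deletion
    indel_pos: int | None = None          # reference coordinate
    deletion_span: int = 0                # bp lost between cuts (cross-pair)


@dataclass
class EditingSummary:
    gene: str
    per_guide: pd.DataFrame               # site, covering, small_indel, large_del, pct_modified
    n_assigned: int
    n_large_deletion: int
    pct_large_deletion: float
    category_counts: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# reference construction

def _find_unique(seq: str, sub: str, what: str) -> tuple[int, str]:
    """Locate ``sub`` exactly once in ``seq`` on either strand.

    Returns (forward-strand start, strand).
    """
    hits = [(p, "+") for p in _find_all(seq, sub)]
    hits += [(p, "-") for p in _find_all(seq, revcomp(sub))]
    if not hits:
        raise ValueError(f"{what} not found in reference")
    if len(hits) > 1:
        raise ValueError(f"{what} found {len(hits)} times in reference")
    return hits[0]


def _find_all(seq: str, sub: str) -> list[int]:
    out, p = [], seq.find(sub)
    while p != -1:
        out.append(p)
        p = seq.find(sub, p + 1)
    return out


def locate_guide(seq: str, protospacer: str) -> Guide:
    """Map a 20-nt protospacer onto the reference and compute its cut site.

    Forward match at s: PAM at s+20..s+22, cut between s+16 and s+17, so
    cut = s + 17.  Reverse match at s (reference carries the protospacer's
    reverse complement): PAM at s-3..s-1 on the forward strand, cut
    between s+2 and s+3, so cut = s + 3.
    """
    start, strand = _find_unique(seq, protospacer, f"protospacer {protospacer}")
    if strand == "+":
        cut = start + 17
        pam = seq[start + 20:start + 23]
        pam_ok = pam[1:3] == "GG"
    else:
        cut = start + 3
        pam = seq[max(0, start - 3):start]
        pam_ok = pam[:2] == "CC"
    if not pam_ok:
        logger.warning("protospacer %s: no NGG PAM adjacent to the match", protospacer)
    return Guide(protospacer=protospacer.upper(), strand=strand, start=start, cut=cut)


def build_reference(ref_fasta, guides_tsv, primers_tsv, gene: str | None = None) -> AmpliconReference:
    """Assemble an AmpliconReference from a FASTA reference, a guides TSV
    (columns: gene, protospacer[, strand]) and a primers TSV (columns:
    gene, index, forward, reverse).

    Primers and protospacers must occur exactly once in the reference
    (forward or reverse complement); amplicon spans outside 230-270 bp
    produce a warning, not an error.
    """
    records = list(SeqIO.parse(str(ref_fasta), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {ref_fasta}")
    rec = records[0]
    seq = str(rec.seq).upper()
    gene = gene or rec.id

    gtab = pd.read_csv(guides_tsv, sep="\t")
    ptab = pd.read_csv(primers_tsv, sep="\t")
    gtab = gtab[gtab["gene"] == gene] if "gene" in gtab else gtab
    ptab = ptab[ptab["gene"] == gene] if "gene" in ptab else ptab

    guides = [locate_guide(seq, str(p).upper()) for p in gtab["protospacer"]]
    pairs = []
    for row in ptab.sort_values("index").itertuples(index=False):
        fwd, rev = str(row.forward).upper(), str(row.reverse).upper()
        fstart, fstrand = _find_unique(seq, fwd, f"forward primer {row.index}")
        if fstrand != "+":
            raise ValueError(f"forward primer {row.index} matches the reverse strand")
        rstart, rstrand = _find_unique(seq, rev, f"reverse primer {row.index}")
        if rstrand != "-":
            raise ValueError(f"reverse primer {row.index} matches the forward strand")
        pairs.append(PrimerPair(index=int(row.index), forward=fwd, reverse=rev,
                                start=fstart, end=rstart + len(rev)))
    guides.sort(key=lambda g: g.cut)
    pairs.sort(key=lambda p: p.start)
    for k, p in enumerate(pairs, start=1):
        p.index = k
    return AmpliconReference(gene=gene, seq=seq, guides=guides, pairs=pairs)


# ---------------------------------------------------------------------------
# read assignment and alignment

def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _match_end(read: str, primers: list[str], at_start: bool) -> tuple[int | None, int]:
    """Best primer matching the read's 5' prefix (or 3' suffix against the
    reverse primer's complement).  Ties go to the lowest pair index."""
    best, best_mm = None, PRIMER_MAX_MISMATCH + 1
    for idx, primer in enumerate(primers, start=1):
        if len(read) < len(primer):
            continue
        probe = read[:len(primer)] if at_start else read[-len(primer):]
        target = primer if at_start else revcomp(primer)
        mm = _mismatches(probe, target)
        if mm < best_mm:
            best, best_mm = idx, mm
    return best, best_mm


def assign_primer_pair(read: str, ref: AmpliconReference) -> ProductAssignment:
    """Assign a read to a same-pair or cross-pair product by its primers.

    Both read orientations are tried; the orientation with fewer total
    primer mismatches wins, so classification is orientation invariant.
    A forward primer i and reverse primer j with i == j give a same-pair
    product, i < j a cross-pair (large-deletion candidate); anything else
    is unassigned.
    """
    read = read.upper()
    fwd_primers = [p.forward for p in ref.pairs]
    rev_primers = [p.reverse for p in ref.pairs]
    best: ProductAssignment | None = None
    for oriented in (read, revcomp(read)):
        fi, fmm = _match_end(oriented, fwd_primers, at_start=True)
        rj, rmm = _match_end(oriented, rev_primers, at_start=False)
        if fi is None or rj is None or fmm > PRIMER_MAX_MISMATCH or rmm > PRIMER_MAX_MISMATCH:
            continue
        if fi > rj:
            continue                      # inverted product: not a screen read
        cand = ProductAssignment(kind="same" if fi == rj else "cross",
                                 i=fi, j=rj, oriented_read=oriented,
                                 mismatches=fmm + rmm)
        if best is None or cand.mismatches < best.mismatches:
            best = cand
    return best if best is not None else ProductAssignment(kind="unassigned",
                                                           oriented_read=read)


def align_read(read: str, ref_segment: str):
    """Global affine-gap alignment of an oriented read to its reference
    segment (match +5, mismatch -4, length-L gap costs 10 + L)."""
    return _ALIGNER.align(ref_segment, read)[0]


def _alignment_indels(aln, offset: int) -> list[tuple[int, int]]:
    """Signed indels from an alignment as (reference_position, length):
    negative length = deletion in the read, positive = insertion.  The
    reference position is shifted by ``offset`` into global coordinates.
    Terminal gaps are included, so truncated reads surface as deletions."""
    tc, qc = aln.coordinates
    indels = []
    for k in range(1, len(tc)):
        dt = int(tc[k] - tc[k - 1])
        dq = int(qc[k] - qc[k - 1])
        if dt > 0 and dq == 0:            # read skips reference bases
            indels.append((offset + int(tc[k - 1]), -dt))
        elif dq > 0 and dt == 0:          # read carries extra bases
            indels.append((offset + int(tc[k - 1]), dq))
    return indels


def _overlaps_window(pos: int, length: int, cut: int, window: int = QUANT_WINDOW) -> bool:
    if length < 0:                        # deletion covering [pos, pos - length)
        return pos <= cut + window and pos - length >= cut - window
    return cut - window <= pos <= cut + window


def classify_read(read, ref: AmpliconReference, read_id: str = "") -> ReadCall:
    """Assign, align and classify one read (str or Bio SeqRecord)."""
    if not isinstance(read, str):
        read_id = read_id or read.id
        read = str(read.seq)
    asg = assign_primer_pair(read, ref)
    if asg.kind == "unassigned":
        return ReadCall(read_id=read_id, kind="unassigned", pair_i=None,
                        pair_j=None, category="unassigned")
    if asg.kind == "cross":
        _, span = ref.fused_amplicon(asg.i, asg.j)
        return ReadCall(read_id=read_id, kind="cross", pair_i=asg.i, pair_j=asg.j,
                        category="large_deletion",
                        indel_len=-span,
                        indel_pos=ref.guides[asg.i - 1].cut,
                        deletion_span=span)

    pair = ref.pairs[asg.i - 1]
    cut = ref.guides[asg.i - 1].cut
    segment = ref.amplicon(asg.i)
    if asg.oriented_read == segment:      # fast path: exact product
        return ReadCall(read_id=read_id, kind="same", pair_i=asg.i, pair_j=asg.i,
                        category="unmodified")
    aln = align_read(asg.oriented_read, segment)
    if aln.score < MIN_ALIGN_IDENTITY * 5 * len(segment):
        return ReadCall(read_id=read_id, kind="unassigned", pair_i=None,
                        pair_j=None, category="unassigned")
    indels = _alignment_indels(aln, offset=pair.start)

    if not indels:
        cat = "substitution_only"
        return ReadCall(read_id=read_id, kind="same", pair_i=asg.i, pair_j=asg.i,
                        category=cat)
    # largest deletion decides large_deletion; else on-target indels
    biggest_del = min((ln for _, ln in indels if ln < 0), default=0)
    if biggest_del <= -LARGE_DELETION_MIN:
        pos = next(p for p, ln in indels if ln == biggest_del)
        return ReadCall(read_id=read_id, kind="same", pair_i=asg.i, pair_j=asg.i,
                        category="large_deletion", indel_len=biggest_del,
                        indel_pos=pos, deletion_span=-biggest_del)
    on_target = [(p, ln) for p, ln in indels if _overlaps_window(p, ln, cut)]
    if on_target:
        # report the largest on-target event
        pos, ln = max(on_target, key=lambda t: abs(t[1]))
        return ReadCall(read_id=read_id, kind="same", pair_i=asg.i, pair_j=asg.i,
                        category="small_indel", indel_len=ln, indel_pos=pos)
    # distal indels only: treated as PCR/sequencing artifacts, not edits
    return ReadCall(read_id=read_id, kind="same", pair_i=asg.i, pair_j=asg.i,
                    category="unmodified")


def classify_reads(reads, ref: AmpliconReference) -> list[ReadCall]:
    """Classify an iterable of reads (SeqRecords, (id, seq) pairs, a FASTQ
    path, or plain strings)."""
    if isinstance(reads, (str,)) or hasattr(reads, "read"):
        reads = SeqIO.parse(str(reads), "fastq")
    out = []
    for k, r in enumerate(reads):
        if isinstance(r, tuple):
            rid, seq = r
        elif isinstance(r, str):
            rid, seq = f"read{k}", r
        else:
            rid, seq = r.id, str(r.seq)
        out.append(classify_read(seq, ref, read_id=rid))
    return out


def calls_table(calls: Sequence[ReadCall]) -> pd.DataFrame:
    return pd.DataFrame([{
        "read_id": c.read_id, "kind": c.kind, "pair_i": c.pair_i,
        "pair_j": c.pair_j, "category": c.category, "indel_len": c.indel_len,
        "indel_pos": c.indel_pos, "deletion_span": c.deletion_span,
    } for c in calls])


def summarize_editing(calls: Sequence[ReadCall], ref: AmpliconReference) -> EditingSummary:
    """Per-guide percent modified and the gene-level large-deletion rate.

    A read *covers* site i when it is the same-pair product i or a
    cross-pair product whose junction involves cut i.  Percent modified at
    site i = (small indels at i + large deletions involving i) / covering
    reads.  The gene-level large-deletion percentage uses all assigned
    reads as the denominator.
    """
    assigned = [c for c in calls if c.category != "unassigned"]
    if not assigned:
        raise ValueError("no assigned reads to summarize")
    rows = []
    for i in range(1, ref.n_sites + 1):
        same = [c for c in assigned if c.kind == "same" and c.pair_i == i]
        cross = [c for c in assigned if c.kind == "cross" and i in (c.pair_i, c.pair_j)]
        covering = len(same) + len(cross)
        n_small = sum(c.category == "small_indel" for c in same)
        n_large = sum(c.category == "large_deletion" for c in same) + len(cross)
        pct = 100.0 * (n_small + n_large) / covering if covering else float("nan")
        rows.append({"site": i, "covering": covering, "small_indel": n_small,
                     "large_deletion": n_large, "pct_modified": pct})
    n_large_total = sum(c.category == "large_deletion" for c in assigned)
    cats = pd.Series([c.category for c in assigned]).value_counts().to_dict()
    return EditingSummary(
        gene=ref.gene,
        per_guide=pd.DataFrame(rows),
        n_assigned=len(assigned),
        n_large_deletion=n_large_total,
        pct_large_deletion=100.0 * n_large_total / len(assigned),
        category_counts=cats,
    )
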