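"""Detection of nearly identical neighboring exons — a tandem-duplication
assembly-error signature — and of falsely fused ("chimeric") gene models.

Collapsed-haplotype and polymerase-slippage errors in long-read assemblies
show up as short (~1 kb) sequences repeated twice in tandem.  When such a
repeat overlaps annotated exons, the annotation acquires two nearly identical
exons a few kb apart.  The scan implemented here looks for exactly that
signature: non-overlapping exon pairs on the same contig within ``max_gap``
bp of each other whose sequences (i) share a highly significant local
alignment covering most of the shorter exon and (ii) have a near-perfect
length-normalized global-alignment score.

The normalized score is the raw Needleman–Wunsch score under the NUC.4.4
substitution matrix divided by the number of alignment columns (gaps
included).  It equals 5 for identical unambiguous sequences and decreases
toward the mismatch penalty as the sequences diverge; pairs scoring above
4.8 (roughly >97% identity) are flagged as candidate assembly errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices
from scipy.optimize import brentq

__all__ = [
    "ExonRecord",
    "ExonPairScore",
    "ChimerCall",
    "neighboring_pairs",
    "local_similarity_filter",
    "nw_normalized_score",
    "scan_assembly",
    "detect_false_chimers",
    "karlin_altschul_evalue",
]

_NUC44 = substitution_matrices.load("NUC.4.4")

#: Affine gap convention: a run of L gap columns costs GAP_OPEN + L * GAP_EXTEND.
GAP_OPEN = 10.0
GAP_EXTEND = 1.0


@dataclass(frozen=True)
class ExonRecord:
    """An annotated exon interval with its sequence.

    Coordinates are 0-based half-open; ``sequence`` is the plus-strand
    projection of the interval (exons are compared as annotated).
    """

    exon_id: str
    contig: str
    start: int
    end: int
    strand: str = "+"
    transcript_id: str = ""
    gene_id: str = ""
    sequence: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid exon interval [{self.start}, {self.end})")
        if self.sequence and len(self.sequence) != self.end - self.start:
            raise ValueError(
                f"exon {self.exon_id}: sequence length {len(self.sequence)} "
                f"!= interval length {self.end - self.start}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ExonPairScore:
    """A scored candidate duplicate exon pair."""

    exon_a: str
    exon_b: str
    gap: int
    coverage_frac: float
    local_significance: float
    norm_score: float
    flagged: bool = False


def _global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _NUC44
    # Biopython charges open_gap_score for the first gap column; our
    # convention (10 + L) therefore maps to open=-11, extend=-1.
    aligner.open_gap_score = -(GAP_OPEN + GAP_EXTEND)
    aligner.extend_gap_score = -GAP_EXTEND
    return aligner


def _local_aligner() -> Align.PairwiseAligner:
    # Ungapped Smith-Waterman: Karlin-Altschul significance theory is exact
    # for ungapped local scores, so the e-value gate is computed on them.
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _NUC44
    aligner.open_gap_score = -1e6
    aligner.extend_gap_score = -1e6
    return aligner


_VALID_CHARS = set(str(_NUC44.alphabet))


def _check_sequence(seq: str, label: str) -> str:
    if not seq:
        raise ValueError(f"{label}: empty sequence")
    seq = seq.upper()
    bad = set(seq) - _VALID_CHARS
    if bad:
        raise ValueError(f"{label}: characters outside the NUC.4.4 alphabet: {sorted(bad)}")
    return seq


def nw_normalized_score(seq_a: str, seq_b: str) -> float:
    """Length-normalized global-alignment score of two nucleotide sequences.

    The optimal Needleman–Wunsch score under NUC.4.4 with affine gaps
    (open 10, extend 1, subtracted) divided by the number of alignment
    columns, gaps included.  5.0 for identical A/C/G/T sequences; lower
    for diverged ones (values below −2 are possible but not observed for
    biological pairs).
    """
    seq_a = _check_sequence(seq_a, "seq_a")
    seq_b = _check_sequence(seq_b, "seq_b")
    aligner = _global_aligner()
    alignment = aligner.align(seq_a, seq_b)[0]
    return float(alignment.score) / alignment.length


# --- Karlin–Altschul significance for the +5/-4 local-alignment scheme ----

def _lambda_plus5_minus4() -> float:
    # E[exp(lambda * S)] = 1 for a random aligned pair under uniform base
    # composition: (4/16) e^{5l} + (12/16) e^{-4l} = 1, l > 0.
    f = lambda lam: 0.25 * math.exp(5.0 * lam) + 0.75 * math.exp(-4.0 * lam) - 1.0
    return float(brentq(f, 1e-9, 2.0))


_KA_LAMBDA = _lambda_plus5_minus4()
#: Conservative Karlin-Altschul K (upper bound; inflates e-values).
_KA_K = 1.0


def karlin_altschul_evalue(score: float, len_a: int, len_b: int) -> float:
    """Expected number of chance local alignments scoring >= ``score``.

    E = K·m·n·exp(−λS) with λ solved for the +5/−4 match/mismatch scheme at
    uniform base composition and the conservative bound K = 1; the search
    space is the product of the two sequence lengths.
    """
    return _KA_K * len_a * len_b * math.exp(-_KA_LAMBDA * score)


def local_similarity_filter(
    seq_a: str,
    seq_b: str,
    min_coverage: float = 0.5,
    max_evalue: float = 1e-10,
) -> tuple[bool, float, float]:
    """Smith–Waterman pre-filter for a candidate exon pair.

    Returns ``(passed, coverage_frac, evalue)``.  The pair passes iff the
    optimal ungapped local alignment covers strictly more than
    ``min_coverage`` of the shorter sequence and its Karlin–Altschul
    e-value is strictly below ``max_evalue``.  The alignment is ungapped
    because the significance theory behind the e-value is exact only for
    ungapped local scores; near-identical tandem copies align end-to-end
    either way.
    """
    seq_a = _check_sequence(seq_a, "seq_a")
    seq_b = _check_sequence(seq_b, "seq_b")
    aligner = _local_aligner()
    alignment = aligner.align(seq_a, seq_b)[0]
    score = float(alignment.score)
    evalue = karlin_altschul_evalue(score, len(seq_a), len(seq_b))
    # residues of the shorter sequence inside the local alignment
    short_idx = 0 if len(seq_a) <= len(seq_b) else 1
    blocks = alignment.aligned[short_idx]
    span = int(sum(end - start for start, end in blocks))
    coverage = span / min(len(seq_a), len(seq_b))
    passed = (coverage > min_coverage) and (evalue < max_evalue)
    return passed, coverage, evalue


def neighboring_pairs(
    exons: Sequence[ExonRecord], max_gap: int = 5000
) -> list[tuple[ExonRecord, ExonRecord]]:
    """Non-overlapping same-contig exon pairs separated by <= ``max_gap`` bp.

    The gap is measured from the end of the upstream exon to the start of the
    downstream one (0 for abutting exons); overlapping pairs are excluded.
    Each unordered pair is emitted once, upstream exon first.
    """
    by_contig: dict[str, list[ExonRecord]] = {}
    for exon in exons:
        by_contig.setdefault(exon.contig, []).append(exon)
    pairs: list[tuple[ExonRecord, ExonRecord]] = []
    for contig_exons in by_contig.values():
        contig_exons.sort(key=lambda e: (e.start, e.end, e.exon_id))
        for i, a in enumerate(contig_exons):
            for b in contig_exons[i + 1 :]:
                if b.start - a.end > max_gap:
                    break
                if b.start < a.end:  # overlap (b.end > a.start by sort order)
                    continue
                pairs.append((a, b))
    return pairs


def scan_assembly(
    exons: Sequence[ExonRecord],
    max_gap: int = 5000,
    score_threshold: float = 4.8,
    min_coverage: float = 0.5,
    max_evalue: float = 1e-10,
) -> tuple[list[ExonPairScore], dict[str, int], dict[str, int]]:
    """Scan an annotated assembly for nearly identical neighboring exons.

    Pipeline: neighboring pair selection -> local-similarity pre-filter ->
    normalized global score; pairs with norm_score strictly above
    ``score_threshold`` are flagged.  Returns the scored pairs that passed
    the pre-filter plus per-transcript and per-gene counts of distinct
    flagged exons.
    """
    scored: list[ExonPairScore] = []
    exon_index = {e.exon_id: e for e in exons}
    flagged_exons: set[str] = set()
    for a, b in neighboring_pairs(exons, max_gap=max_gap):
        passed, coverage, evalue = local_similarity_filter(
            a.sequence, b.sequence, min_coverage=min_coverage, max_evalue=max_evalue
        )
        if not passed:
            continue
        norm = nw_normalized_score(a.sequence, b.sequence)
        flag = norm > score_threshold
        scored.append(
            ExonPairScore(
                exon_a=a.exon_id,
                exon_b=b.exon_id,
                gap=b.start - a.end,
                coverage_frac=coverage,
                local_significance=evalue,
                norm_score=norm,
                flagged=flag,
            )
        )
        if flag:
            flagged_exons.update((a.exon_id, b.exon_id))
    transcript_counts: dict[str, int] = {}
    gene_counts: dict[str, int] = {}
    for exon_id in flagged_exons:
        exon = exon_index[exon_id]
        if exon.transcript_id:
            transcript_counts[exon.transcript_id] = transcript_counts.get(exon.transcript_id, 0) + 1
        if exon.gene_id:
            gene_counts[exon.gene_id] = gene_counts.get(exon.gene_id, 0) + 1
    return scored, transcript_counts, gene_counts


# --- false chimeric gene detection ---------------------------------------

@dataclass
class ChimerCall:
    """Outcome of the false-chimer test for one gene model."""

    gene_id: str
    is_chimer: bool
    split_coord: int | None = None
    needs_review: bool = False
    reason: str = ""


def detect_false_chimers(
    gene_id: str,
    part_intervals: Mapping[str, tuple[int, int]],
    part_hits: Mapping[str, tuple[str, int]],
) -> ChimerCall:
    """Test whether a gene model is a false fusion of two neighboring genes.

    A predicted gene is called a false chimer when its 5' and 3' parts hit
    two *distinct* reference genes that are *adjacent* in the reference
    gene order (adjacency ranks differing by exactly 1).  ``part_intervals``
    maps part id to its (start, end) block on the query gene (0-based
    half-open); ``part_hits`` maps part id to (reference gene id, reference
    adjacency rank).  The proposed split coordinate is the midpoint of the
    query interval between the two hit blocks.  Overlapping hit blocks make
    the gene unsplittable: it is flagged for manual review instead.
    """
    if set(part_intervals) != set(part_hits) or len(part_intervals) != 2:
        raise ValueError("exactly two parts with matching intervals and hits are required")
    (pa, pb) = sorted(part_intervals, key=lambda p: part_intervals[p])
    (a_start, a_end) = part_intervals[pa]
    (b_start, b_end) = part_intervals[pb]
    (gene_a, rank_a) = part_hits[pa]
    (gene_b, rank_b) = part_hits[pb]
    if gene_a == gene_b:
        return ChimerCall(gene_id, False, reason="both parts hit the same reference gene")
    if abs(rank_a - rank_b) != 1:
        return ChimerCall(gene_id, False, reason="reference hits are not adjacent")
    if b_start < a_end:
        return ChimerCall(
            gene_id, True, split_coord=None, needs_review=True,
            reason="hit blocks overlap; unsplittable",
        )
    return ChimerCall(gene_id, True, split_coord=(a_end + b_start) // 2)
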