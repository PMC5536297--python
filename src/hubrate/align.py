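"""Protein-guided pairwise codon alignment and in-frame segment extraction.

Ortholog CDS pairs are aligned at the protein level (global affine-gap
dynamic programming with BLOSUM62) and the alignment is back-mapped to
codons, so gaps always fall on codon boundaries and the alignment is
in-frame by construction. Downstream rate estimation then keeps only
maximal gapless blocks of at least ``min_segment_nt`` (30 nt), concatenated
5'->3'; pairs whose concatenated blocks fall short of ``min_total_nt``
(300 nt) are rejected.

Codons containing ambiguity characters (N, etc.) are masked — treated like
gap columns during segmentation — because the counting estimators need
unambiguous codons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from .genetics import NUCLEOTIDES, STOP_CODONS, translate_codon, validate_cds

GAP_CODON = "---"


@dataclass
class CodonAlignment:
    """A pairwise codon alignment.

    ``codon_columns`` holds (codon_a, codon_b) with ``---`` for a gap;
    ``segments`` lists the retained gapless blocks as (start_col,
    length_codons) after :func:`extract_inframe`; ``total_nt`` is the
    concatenated retained length; ``retained`` is False for rejected pairs.
    """

    pair_id: str
    codon_columns: list[tuple[str, str]]
    segments: list[tuple[int, int]] = field(default_factory=list)
    total_nt: int = 0
    retained: bool = True

    def concatenated(self) -> tuple[str, str]:
        """The two concatenated retained sequences (gap-free, in frame)."""
        a_parts, b_parts = [], []
        for start, length in self.segments:
            for col in self.codon_columns[start: start + length]:
                a_parts.append(col[0])
                b_parts.append(col[1])
        return "".join(a_parts), "".join(b_parts)


def _translate(cds: str, name: str) -> str:
    aa = []
    for i in range(0, len(cds), 3):
        codon = cds[i: i + 3]
        if set(codon) <= set(NUCLEOTIDES):
            aa.append(translate_codon(codon))
        else:
            aa.append("X")  # ambiguous codon; masked later
    return "".join(aa)


def make_protein_aligner(gap_open: float = -10.0, gap_extend: float = -0.5) -> Align.PairwiseAligner:
    """Global protein aligner with BLOSUM62 and affine gaps."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def codon_align(
    cds_a: str,
    cds_b: str,
    pair_id: str = "pair",
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
) -> CodonAlignment:
    """Align two coding sequences codon-by-codon via their translations.

    Both sequences must be in frame (length divisible by 3) with no internal
    stop codons; a trailing stop is stripped. Gaps in the result occur only
    in whole-codon units.
    """
    cds_a = validate_cds(cds_a, name=f"{pair_id}/a", allow_ambiguity=True)
    cds_b = validate_cds(cds_b, name=f"{pair_id}/b", allow_ambiguity=True)
    prot_a = _translate(cds_a, "a")
    prot_b = _translate(cds_b, "b")
    aligner = make_protein_aligner(gap_open, gap_extend)
    aln = aligner.align(prot_a, prot_b)[0]  # first optimal alignment, deterministic
    codons_a = [cds_a[i: i + 3] for i in range(0, len(cds_a), 3)]
    codons_b = [cds_b[i: i + 3] for i in range(0, len(cds_b), 3)]
    columns: list[tuple[str, str]] = []
    ia = ib = 0
    for ca, cb in zip(aln[0], aln[1]):
        if ca == "-":
            columns.append((GAP_CODON, codons_b[ib]))
            ib += 1
        elif cb == "-":
            columns.append((codons_a[ia], GAP_CODON))
            ia += 1
        else:
            columns.append((codons_a[ia], codons_b[ib]))
            ia += 1
            ib += 1
    assert ia == len(codons_a) and ib == len(codons_b)
    return CodonAlignment(pair_id=pair_id, codon_columns=columns)


def _column_usable(col: tuple[str, str]) -> bool:
    """A column enters a retained segment only if both codons are plain
    ACGT sense codons (no gaps, no ambiguity, no stops)."""
    for codon in col:
        if codon == GAP_CODON or not set(codon) <= set(NUCLEOTIDES):
            return False
        if codon in STOP_CODONS:
            return False
    return True


def extract_inframe(
    aln: CodonAlignment,
    min_segment_nt: int = 30,
    min_total_nt: int = 300,
) -> CodonAlignment:
    """Apply the in-frame segment rule.

    Maximal runs of columns gapless (and unambiguous) in both sequences are
    found; runs shorter than ``min_segment_nt`` are discarded; the survivors
    are concatenated in alignment order. If the concatenated length is below
    ``min_total_nt`` the pair is rejected (``retained=False``) — a normal
    outcome, not an error.
    """
    if min_segment_nt % 3 or min_total_nt % 3:
        raise ValueError("segment thresholds must be whole codons (multiples of 3 nt)")
    segments: list[tuple[int, int]] = []
    run_start = None
    n_cols = len(aln.codon_columns)
    for i in range(n_cols + 1):
        usable = i < n_cols and _column_usable(aln.codon_columns[i])
        if usable and run_start is None:
            run_start = i
        elif not usable and run_start is not None:
            length = i - run_start
            if length * 3 >= min_segment_nt:
                segments.append((run_start, length))
            run_start = None
    total_nt = 3 * sum(length for _, length in segments)
    retained = total_nt >= min_total_nt
    return CodonAlignment(
        pair_id=aln.pair_id,
        codon_columns=aln.codon_columns,
        segments=segments if retained else segments,
        total_nt=total_nt,
        retained=retained,
    )


def align_and_filter(
    cds_a: str,
    cds_b: str,
    pair_id: str = "pair",
    min_segment_nt: int = 30,
    min_total_nt: int = 300,
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
) -> CodonAlignment:
    """codon_align followed by extract_inframe."""
    aln = codon_align(cds_a, cds_b, pair_id=pair_id, gap_open=gap_open, gap_extend=gap_extend)
    return extract_inframe(aln, min_segment_nt=min_segment_nt, min_total_nt=min_total_nt)
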