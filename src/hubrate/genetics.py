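"""Standard genetic-code machinery shared by the dN/dS estimators and the
codon-substitution simulator.

Everything here is specific to the standard (nuclear) genetic code: the 61
sense codons, their single-nucleotide mutational neighborhoods, and the
enumeration of stepwise pathways between codon pairs. These structures are
precomputed once at import so the counting estimators reduce to table
lookups.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

NUCLEOTIDES = "ACGT"
NT_INDEX = {nt: i for i, nt in enumerate(NUCLEOTIDES)}

STOP_CODONS = frozenset(standard_dna_table.stop_codons)
CODON_TO_AA = dict(standard_dna_table.forward_table)

#: the 61 sense codons of the standard code, lexicographic order
SENSE_CODONS = tuple(sorted(CODON_TO_AA))
SENSE_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
N_SENSE = len(SENSE_CODONS)

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


def is_transition(a: str, b: str) -> bool:
    """True if the nucleotide change a->b is a transition (purine<->purine
    or pyrimidine<->pyrimidine)."""
    if a == b:
        raise ValueError("not a change")
    return (a in PURINES and b in PURINES) or (a in PYRIMIDINES and b in PYRIMIDINES)


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a sense codon; '*' for a stop codon."""
    if codon in STOP_CODONS:
        return "*"
    try:
        return CODON_TO_AA[codon]
    except KeyError:
        raise ValueError(f"untranslatable codon {codon!r}") from None


def _build_neighbor_tables():
    """For each sense codon, its 9 single-nucleotide neighbors.

    Returns integer/boolean arrays of shape (61, 9):
      idx   -- index of the neighbor in SENSE_CODONS, or -1 if it is a stop
      is_ts -- change is a transition
      is_syn-- neighbor encodes the same amino acid (False where stop)
    Neighbor order: position-major (pos 0,1,2), then target nucleotide in
    ACGT order, skipping the resident nucleotide.
    """
    idx = np.full((N_SENSE, 9), -1, dtype=np.int64)
    is_ts = np.zeros((N_SENSE, 9), dtype=bool)
    is_syn = np.zeros((N_SENSE, 9), dtype=bool)
    for ci, codon in enumerate(SENSE_CODONS):
        k = 0
        for pos in range(3):
            for nt in NUCLEOTIDES:
                if nt == codon[pos]:
                    continue
                neigh = codon[:pos] + nt + codon[pos + 1:]
                is_ts[ci, k] = is_transition(codon[pos], nt)
                if neigh not in STOP_CODONS:
                    idx[ci, k] = SENSE_INDEX[neigh]
                    is_syn[ci, k] = CODON_TO_AA[neigh] == CODON_TO_AA[codon]
                k += 1
    return idx, is_ts, is_syn


NEIGHBOR_IDX, NEIGHBOR_IS_TS, NEIGHBOR_IS_SYN = _build_neighbor_tables()


def codon_diffs(codon_a: str, codon_b: str) -> tuple[int, ...]:
    """Positions (0-based) at which two codons differ."""
    return tuple(p for p in range(3) if codon_a[p] != codon_b[p])


@lru_cache(maxsize=None)
def pathways(codon_a: str, codon_b: str):
    """All stepwise single-nucleotide pathways from codon_a to codon_b that
    do not pass through a stop codon.

    Each pathway is a tuple of steps; each step is
    (from_codon, to_codon, position, is_syn, is_ts). Endpoints must be sense
    codons. Returns () when every ordering passes through a stop.
    """
    if codon_a in STOP_CODONS or codon_b in STOP_CODONS:
        raise ValueError("pathways defined between sense codons only")
    positions = codon_diffs(codon_a, codon_b)
    out = []
    for order in itertools.permutations(positions):
        cur = codon_a
        steps = []
        ok = True
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                ok = False
                break
            steps.append(
                (
                    cur,
                    nxt,
                    pos,
                    CODON_TO_AA[nxt] == CODON_TO_AA[cur],
                    is_transition(cur[pos], codon_b[pos]),
                )
            )
            cur = nxt
        if ok:
            out.append(tuple(steps))
    return tuple(out)


# fourfold / zerofold degeneracy of each codon position, used by the
# kappa estimator: a position is fourfold degenerate when every nucleotide
# substitution at it is synonymous, zerofold when every one is nonsynonymous
# (stop-codon neighbors disqualify a position from either class).
def _build_degeneracy():
    four = np.zeros((N_SENSE, 3), dtype=bool)
    zero = np.zeros((N_SENSE, 3), dtype=bool)
    for ci, codon in enumerate(SENSE_CODONS):
        for pos in range(3):
            fates = []
            for nt in NUCLEOTIDES:
                if nt == codon[pos]:
                    continue
                neigh = codon[:pos] + nt + codon[pos + 1:]
                if neigh in STOP_CODONS:
                    fates.append("stop")
                elif CODON_TO_AA[neigh] == CODON_TO_AA[codon]:
                    fates.append("syn")
                else:
                    fates.append("non")
            four[ci, pos] = all(f == "syn" for f in fates)
            zero[ci, pos] = all(f == "non" for f in fates)
    return four, zero


FOURFOLD, ZEROFOLD = _build_degeneracy()


def validate_cds(seq: str, name: str = "sequence", allow_ambiguity: bool = False) -> str:
    """Check a CDS string: length divisible by 3, no internal stop codons.

    A single trailing stop codon is stripped. Returns the (possibly
    stripped) upper-case sequence. With ``allow_ambiguity`` codons holding
    non-ACGT characters pass through (they are masked downstream); otherwise
    they raise.
    """
    seq = seq.upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise ValueError(f"{name}: length {len(seq)} not divisible by 3")
    codons = [seq[i: i + 3] for i in range(0, len(seq), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    for j, codon in enumerate(codons):
        if codon in STOP_CODONS:
            raise ValueError(f"{name}: internal stop codon {codon} at codon {j}")
        if not set(codon) <= set(NUCLEOTIDES):
            if not allow_ambiguity:
                raise ValueError(f"{name}: untranslatable codon {codon!r} at codon {j}")
    return "".join(codons)
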