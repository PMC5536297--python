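"""Reciprocal-best-hit (RBH) orthology from tabular similarity-search output.

Putative one-to-one orthologs between a focal taxon and its outgroup are the
pairs (a, b) where b is a's best hit in the forward search, a is b's best
hit in the reverse search, and both hits beat an e-value ceiling (strictly
below 1e-8 by default). "Best" means lowest e-value, ties broken by highest
bit score, then lexicographically smallest subject id, so the pairing is
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class HitRecord:
    """One line of BLAST tabular (outfmt 6) output."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bit_score: float


@dataclass(frozen=True)
class OrthologPair:
    gene_a: str
    gene_b: str
    evalue_ab: float
    evalue_ba: float


def parse_tabular_hits(path) -> list[HitRecord]:
    """Parse a BLAST outfmt-6 TSV into typed records (12 fields per line)."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated fields, got {len(fields)}"
                )
            try:
                rec = HitRecord(
                    query_id=fields[0],
                    subject_id=fields[1],
                    percent_identity=float(fields[2]),
                    alignment_length=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    q_start=int(fields[6]),
                    q_end=int(fields[7]),
                    s_start=int(fields[8]),
                    s_end=int(fields[9]),
                    evalue=float(fields[10]),
                    bit_score=float(fields[11]),
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if rec.evalue < 0:
                raise ValueError(f"{path}:{lineno}: negative e-value")
            records.append(rec)
    return records


def _best_hits(hits: list[HitRecord]) -> dict[str, HitRecord]:
    """Best hit per query: lowest e-value, then highest bit score, then
    lexicographically smallest subject. Self-hits are ignored; only the best
    HSP per (query, subject) pair is considered (implied by the ordering)."""
    best: dict[str, HitRecord] = {}
    for rec in hits:
        if rec.query_id == rec.subject_id:
            continue
        cur = best.get(rec.query_id)
        if cur is None or _hit_key(rec) < _hit_key(cur):
            best[rec.query_id] = rec
    return best


def _hit_key(rec: HitRecord):
    return (rec.evalue, -rec.bit_score, rec.subject_id)


def reciprocal_best_hits(
    hits_ab: list[HitRecord],
    hits_ba: list[HitRecord],
    evalue_max: float = 1e-8,
) -> list[OrthologPair]:
    """Mutual-best pairs with both e-values strictly below ``evalue_max``."""
    best_ab = _best_hits(hits_ab)
    best_ba = _best_hits(hits_ba)
    pairs = []
    for a, fwd in sorted(best_ab.items()):
        b = fwd.subject_id
        rev = best_ba.get(b)
        if rev is None or rev.subject_id != a:
            continue
        if fwd.evalue < evalue_max and rev.evalue < evalue_max:
            pairs.append(
                OrthologPair(gene_a=a, gene_b=b, evalue_ab=fwd.evalue, evalue_ba=rev.evalue)
            )
    return pairs


def write_pairs_tsv(pairs: list[OrthologPair], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tevalue_ab\tevalue_ba\n")
        for p in pairs:
            fh.write(f"{p.gene_a}\t{p.gene_b}\t{p.evalue_ab:g}\t{p.evalue_ba:g}\n")


def read_pairs_tsv(path) -> list[OrthologPair]:
    pairs = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("gene_a\t"):
            raise ValueError(f"{path}: not an ortholog-pair TSV")
        for line in fh:
            a, b, eab, eba = line.rstrip("\n").split("\t")
            pairs.append(OrthologPair(a, b, float(eab), float(eba)))
    return pairs
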