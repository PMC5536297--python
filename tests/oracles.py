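"""Independent brute-force oracles used by the tests.

Deliberately coded from first principles (and from Biopython's codon table
only), without importing the package's own neighbor/pathway machinery, so
they stay an independent check on it.
"""

import itertools

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

STOPS = set(standard_dna_table.stop_codons)
AA = dict(standard_dna_table.forward_table)
SENSE = sorted(AA)


def brute_sites(codon):
    """NG86 site counts by direct neighbor enumeration."""
    syn = tot = 0
    for pos in range(3):
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            neigh = codon[:pos] + nt + codon[pos + 1 :]
            if neigh in STOPS:
                continue
            tot += 1
            if AA[neigh] == AA[codon]:
                syn += 1
    s = 3.0 * syn / tot
    return s, 3.0 - s


def brute_differences(a, b):
    """NG86 difference counts: equal-weight average over orderings of the
    differing positions, dropping orderings that pass through a stop."""
    positions = [p for p in range(3) if a[p] != b[p]]
    if not positions:
        return 0.0, 0.0
    per_path = []
    for order in itertools.permutations(positions):
        cur, sd, nd, ok = a, 0, 0, True
        for pos in order:
            nxt = cur[: pos] + b[pos] + cur[pos + 1 :]
            if nxt in STOPS:
                ok = False
                break
            if AA[nxt] == AA[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            per_path.append((sd, nd))
    if not per_path:
        return None  # caller decides; the package uses a positional fallback
    sd = sum(p[0] for p in per_path) / len(per_path)
    nd = sum(p[1] for p in per_path) / len(per_path)
    return sd, nd


def brute_scale_free_scan(values, betas, n_bins=10):
    """Independent re-implementation of the soft-threshold scan statistic."""
    corr = np.corrcoef(values)
    absr = np.abs(np.clip(corr, -1, 1))
    np.fill_diagonal(absr, 0.0)
    out = []
    for beta in betas:
        k = (absr**beta).sum(axis=1)
        if k.max() == k.min():
            out.append(float("nan"))
            continue
        edges = np.linspace(k.min(), k.max(), n_bins + 1)
        which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
        xs, ys = [], []
        for b in range(n_bins):
            m = which == b
            if m.any() and k[m].mean() > 0:
                xs.append(np.log10(k[m].mean()))
                ys.append(np.log10(m.sum() / k.size))
        slope, intercept = np.polyfit(xs, ys, 1)
        pred = slope * np.asarray(xs) + intercept
        ss_res = ((np.asarray(ys) - pred) ** 2).sum()
        ss_tot = ((np.asarray(ys) - np.mean(ys)) ** 2).sum()
        out.append(float(-np.sign(slope) * (1 - ss_res / ss_tot)))
    return out


def brute_rbh(hits_ab, hits_ba, evalue_max):
    """Exhaustive reciprocal-best-hit enumeration over (query, subject)
    tuples (query, subject, evalue, bit_score)."""

    def best(hits):
        out = {}
        for q, s, e, bits in hits:
            if q == s:
                continue
            cur = out.get(q)
            if cur is None or (e, -bits, s) < (cur[2], -cur[3], cur[1]):
                out[q] = (q, s, e, bits)
        return out

    fwd, rev = best(hits_ab), best(hits_ba)
    pairs = set()
    for a, hit in fwd.items():
        b = hit[1]
        if b in rev and rev[b][1] == a and hit[2] < evalue_max and rev[b][2] < evalue_max:
            pairs.add((a, b))
    return pairs
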