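"""Pairwise dN/dS estimation by counting methods.

Two estimators over gap-free, in-frame codon alignments:

* :func:`ng86_dnds` — the Nei–Gojobori (1986) estimator: synonymous and
  nonsynonymous sites counted per codon with equal mutation rates, pathway
  averaging over difference orderings, and Jukes–Cantor correction for
  multiple hits. Simple and assumption-light; it doubles as the reference
  oracle for the weighted estimator.

* :func:`yn00_dnds` — a Yang–Nielsen (2000)-style estimator: codon
  frequencies from the F3x4 model, a transition/transversion ratio kappa
  estimated from fourfold-degenerate and nondegenerate sites, sites and
  differences weighted by kappa, target-codon frequencies and the current
  dN/dS ratio omega, kappa-aware (K80-style) multiple-hit correction, and
  iteration of the difference weighting until omega stabilizes. In the
  unweighted limit (kappa = 1, uniform codon usage) it collapses to NG86.

Both report S, N (site counts), Sd, Nd (difference counts), pS, pN, dS, dN
and omega = dN/dS (undefined when dS = 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .genetics import (
    FOURFOLD,
    N_SENSE,
    NEIGHBOR_IDX,
    NEIGHBOR_IS_SYN,
    NEIGHBOR_IS_TS,
    NT_INDEX,
    SENSE_CODONS,
    SENSE_INDEX,
    STOP_CODONS,
    ZEROFOLD,
    is_transition,
    pathways,
)


class SaturationError(ValueError):
    """Raised when a difference proportion exceeds the correctable range."""


@dataclass(frozen=True)
class RateEstimate:
    pair_id: str
    method: str
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float
    dN: float
    omega: float  # NaN when dS == 0 or saturated
    kappa: float = float("nan")  # YN00 only
    n_codons: int = 0
    flags: tuple[str, ...] = field(default_factory=tuple)


# ---------------------------------------------------------------- NG86 ----

def ng86_sites(codon: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous site counts for one sense codon.

    Of the nine single-nucleotide neighbors, those that are stop codons are
    excluded and the synonymous fraction is renormalized so s + n = 3.
    """
    try:
        ci = SENSE_INDEX[codon]
    except KeyError:
        raise ValueError(f"{codon!r} is not a sense codon") from None
    valid = NEIGHBOR_IDX[ci] >= 0
    n_valid = int(valid.sum())
    s = 3.0 * NEIGHBOR_IS_SYN[ci, valid].sum() / n_valid
    return s, 3.0 - s


def _positionwise_fallback(codon_a: str, codon_b: str) -> tuple[float, float, float, float]:
    """Classify each differing position by the direct single change in both
    directions (averaged), skipping changes that create stop codons. Used
    only when every full ordering passes through a stop."""
    sd = nd = sd_ts = nd_ts = 0.0
    n_classified = 0
    for pos in range(3):
        if codon_a[pos] == codon_b[pos]:
            continue
        contribs = []
        for src, dst_nt in ((codon_a, codon_b[pos]), (codon_b, codon_a[pos])):
            mutated = src[: pos] + dst_nt + src[pos + 1:]
            if mutated in STOP_CODONS:
                continue
            from .genetics import CODON_TO_AA

            contribs.append(1.0 if CODON_TO_AA[mutated] == CODON_TO_AA[src] else 0.0)
        if not contribs:
            continue
        syn_frac = sum(contribs) / len(contribs)
        ts = 1.0 if is_transition(codon_a[pos], codon_b[pos]) else 0.0
        sd += syn_frac
        nd += 1.0 - syn_frac
        sd_ts += syn_frac * ts
        nd_ts += (1.0 - syn_frac) * ts
        n_classified += 1
    if n_classified == 0:
        raise ValueError(f"no classifiable pathway between {codon_a} and {codon_b}")
    return sd, nd, sd_ts, nd_ts


@lru_cache(maxsize=None)
def _ng86_diff_detail(codon_a: str, codon_b: str) -> tuple[float, float, float, float]:
    """(sd, nd, sd_ts, nd_ts) averaged equally over stop-free pathways."""
    if codon_a == codon_b:
        return 0.0, 0.0, 0.0, 0.0
    paths = pathways(codon_a, codon_b)
    if not paths:
        return _positionwise_fallback(codon_a, codon_b)
    sd = nd = sd_ts = nd_ts = 0.0
    for path in paths:
        for _src, _dst, _pos, syn, ts in path:
            if syn:
                sd += 1.0
                sd_ts += 1.0 if ts else 0.0
            else:
                nd += 1.0
                nd_ts += 1.0 if ts else 0.0
    k = len(paths)
    return sd / k, nd / k, sd_ts / k, nd_ts / k


def ng86_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous difference counts between two sense codons,
    averaged over all stop-free single-step pathway orderings."""
    for c in (codon_a, codon_b):
        if c not in SENSE_INDEX:
            raise ValueError(f"{c!r} is not a sense codon")
    sd, nd, _, _ = _ng86_diff_detail(codon_a, codon_b)
    return sd, nd


def jc_correct(p: float) -> float:
    """Jukes–Cantor multiple-hit correction d = -(3/4) ln(1 - 4p/3)."""
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= 0.75:
        raise SaturationError(f"proportion {p:.4f} >= 3/4; distance saturated")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _codon_indices(seq: str, name: str) -> np.ndarray:
    if len(seq) % 3:
        raise ValueError(f"{name}: length not divisible by 3")
    idx = []
    for i in range(0, len(seq), 3):
        codon = seq[i: i + 3]
        try:
            idx.append(SENSE_INDEX[codon])
        except KeyError:
            raise ValueError(f"{name}: codon {codon!r} at position {i} is not a sense codon")
    return np.asarray(idx, dtype=np.int64)


_SITE_TABLE = None


def _ng86_site_table() -> np.ndarray:
    global _SITE_TABLE
    if _SITE_TABLE is None:
        _SITE_TABLE = np.array([ng86_sites(c)[0] for c in SENSE_CODONS])
    return _SITE_TABLE


def _pair_sequences(aln) -> tuple[str, str, str]:
    """Accept a CodonAlignment (retained) or a (seq_a, seq_b) tuple."""
    if isinstance(aln, tuple):
        return aln[0], aln[1], "pair"
    if not aln.retained:
        raise ValueError(f"{aln.pair_id}: alignment was rejected by the length filter")
    a, b = aln.concatenated()
    return a, b, aln.pair_id


def ng86_dnds(aln) -> RateEstimate:
    """Nei–Gojobori dN/dS for one retained codon alignment.

    S and N are averaged over the two sequences; Sd and Nd are summed over
    columns; pS = Sd/S and pN = Nd/N are Jukes–Cantor corrected. Saturation
    (p >= 3/4) flags the estimate instead of raising.
    """
    seq_a, seq_b, pair_id = _pair_sequences(aln)
    ia = _codon_indices(seq_a, f"{pair_id}/a")
    ib = _codon_indices(seq_b, f"{pair_id}/b")
    if ia.size != ib.size or ia.size < 1:
        raise ValueError(f"{pair_id}: sequences must have equal, nonzero codon counts")
    table = _ng86_site_table()
    S = float((table[ia].sum() + table[ib].sum()) / 2.0)
    N = 3.0 * ia.size - S
    Sd = Nd = 0.0
    for ca, cb in zip(ia, ib):
        if ca == cb:
            continue
        sd, nd = ng86_differences(SENSE_CODONS[ca], SENSE_CODONS[cb])
        Sd += sd
        Nd += nd
    return _finish_estimate(pair_id, "NG86", S, N, Sd, Nd, ia.size)


def _finish_estimate(pair_id, method, S, N, Sd, Nd, n_codons, kappa=float("nan"), flags=()):
    flags = list(flags)
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    try:
        dS = jc_correct(pS)
    except SaturationError:
        dS = float("nan")
        flags.append("dS_saturated")
    try:
        dN = jc_correct(pN)
    except SaturationError:
        dN = float("nan")
        flags.append("dN_saturated")
    omega = dN / dS if (dS and not math.isnan(dS) and not math.isnan(dN) and dS > 0) else float("nan")
    if not math.isnan(dS) and dS == 0:
        flags.append("omega_undefined")
    return RateEstimate(
        pair_id=pair_id, method=method, S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN,
        dS=dS, dN=dN, omega=omega, kappa=kappa, n_codons=int(n_codons), flags=tuple(flags),
    )


# ---------------------------------------------------------------- YN00 ----

def f3x4_frequencies(ia: np.ndarray, ib: np.ndarray) -> np.ndarray:
    """F3x4 codon frequencies over the 61 sense codons, from the pooled
    position-specific nucleotide frequencies of both sequences."""
    counts = np.zeros((3, 4))
    for idx_arr in (ia, ib):
        for ci in idx_arr:
            codon = SENSE_CODONS[ci]
            for pos in range(3):
                counts[pos, NT_INDEX[codon[pos]]] += 1
    # guard: give unseen nucleotides a small pseudo-frequency so no sense
    # codon gets exactly zero probability (zero targets break pathway weights)
    counts += 0.5
    freqs = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            freqs[0, NT_INDEX[c[0]]] * freqs[1, NT_INDEX[c[1]]] * freqs[2, NT_INDEX[c[2]]]
            for c in SENSE_CODONS
        ]
    )
    return pi / pi.sum()


def _k80_components(n_sites: float, n_ts: float, n_tv: float) -> tuple[float, float]:
    """K80 transition distance A and (half) transversion distance B from
    raw counts at a class of nucleotide sites; NaN when saturated/empty."""
    if n_sites <= 0:
        return float("nan"), float("nan")
    P, Q = n_ts / n_sites, n_tv / n_sites
    arg1 = 1.0 - 2.0 * P - Q
    arg2 = 1.0 - 2.0 * Q
    if arg1 <= 0 or arg2 <= 0:
        return float("nan"), float("nan")
    A = -0.5 * math.log(arg1) + 0.25 * math.log(arg2)
    B = -0.25 * math.log(arg2)
    return A, B


def estimate_kappa(ia: np.ndarray, ib: np.ndarray) -> float:
    """Transition/transversion rate ratio from fourfold-degenerate and
    nondegenerate codon positions.

    Positions fourfold-degenerate (or nondegenerate) in *both* codons of a
    column are pooled; transition and transversion distances are averaged
    across the two classes weighted by site counts, and kappa is their
    ratio. NaN when inestimable (no differences, saturation).
    """
    n = {"four": 0.0, "zero": 0.0}
    ts = {"four": 0.0, "zero": 0.0}
    tv = {"four": 0.0, "zero": 0.0}
    for ca, cb in zip(ia, ib):
        codon_a, codon_b = SENSE_CODONS[ca], SENSE_CODONS[cb]
        for pos in range(3):
            if FOURFOLD[ca, pos] and FOURFOLD[cb, pos]:
                cls = "four"
            elif ZEROFOLD[ca, pos] and ZEROFOLD[cb, pos]:
                cls = "zero"
            else:
                continue
            n[cls] += 1
            if codon_a[pos] != codon_b[pos]:
                if is_transition(codon_a[pos], codon_b[pos]):
                    ts[cls] += 1
                else:
                    tv[cls] += 1
    A_sum = B_sum = w_sum = 0.0
    for cls in ("four", "zero"):
        A, B = _k80_components(n[cls], ts[cls], tv[cls])
        if not (math.isnan(A) or math.isnan(B)):
            A_sum += n[cls] * A
            B_sum += n[cls] * B
            w_sum += n[cls]
    if w_sum == 0 or B_sum <= 0:
        return float("nan")
    return (A_sum / w_sum) / (B_sum / w_sum)


def yn00_site_counts(kappa: float, pi: np.ndarray) -> np.ndarray:
    """Per-codon synonymous site counts with mutations weighted by the
    target codon's frequency and kappa for transitions; s + n = 3."""
    valid = NEIGHBOR_IDX >= 0
    w = np.where(valid, pi[np.clip(NEIGHBOR_IDX, 0, N_SENSE - 1)], 0.0)
    w = w * np.where(NEIGHBOR_IS_TS, kappa, 1.0)
    total = w.sum(axis=1)
    syn = (w * NEIGHBOR_IS_SYN).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(total > 0, 3.0 * syn / total, 0.0)
    return s


@lru_cache(maxsize=None)
def _path_step_arrays(ca: int, cb: int):
    """Cached pathway structure between two sense codons: per-path arrays of
    target-codon index, synonymy, transition flag. None when only the
    position-wise fallback applies."""
    paths = pathways(SENSE_CODONS[ca], SENSE_CODONS[cb])
    if not paths:
        return None
    tgt = np.array([[SENSE_INDEX[step[1]] for step in p] for p in paths], dtype=np.int64)
    syn = np.array([[step[3] for step in p] for p in paths], dtype=bool)
    ts = np.array([[step[4] for step in p] for p in paths], dtype=bool)
    return tgt, syn, ts


def _weighted_differences(ca: int, cb: int, kappa: float, pi: np.ndarray, omega: float):
    """(sd, nd, sd_ts, sd_tv, nd_ts, nd_tv) for one codon-pair column with
    pathways weighted by the product of their step rates."""
    arrays = _path_step_arrays(ca, cb)
    if arrays is None:
        sd, nd, sd_ts, nd_ts = _positionwise_fallback(SENSE_CODONS[ca], SENSE_CODONS[cb])
        return sd, nd, sd_ts, sd - sd_ts, nd_ts, nd - nd_ts
    tgt, syn, ts = arrays
    rates = pi[tgt] * np.where(ts, kappa, 1.0) * np.where(syn, 1.0, omega)
    w = rates.prod(axis=1)
    total = w.sum()
    if total <= 0:
        w = np.ones_like(w)
        total = w.sum()
    w = w / total
    sd = float((w[:, None] * syn).sum())
    nd = float((w[:, None] * ~syn).sum())
    sd_ts = float((w[:, None] * (syn & ts)).sum())
    sd_tv = float((w[:, None] * (syn & ~ts)).sum())
    nd_ts = float((w[:, None] * (~syn & ts)).sum())
    nd_tv = float((w[:, None] * (~syn & ~ts)).sum())
    return sd, nd, sd_ts, sd_tv, nd_ts, nd_tv


def _k80_distance(P: float, Q: float) -> float:
    """Total K80 distance from transition/transversion proportions."""
    arg1 = 1.0 - 2.0 * P - Q
    arg2 = 1.0 - 2.0 * Q
    if arg1 <= 0 or arg2 <= 0:
        raise SaturationError("K80 correction saturated")
    return -0.5 * math.log(arg1) - 0.25 * math.log(arg2)


def yn00_dnds(
    aln,
    omega_init: float = 0.5,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> RateEstimate:
    """Yang–Nielsen-style weighted dN/dS for one retained codon alignment.

    Steps: F3x4 codon frequencies; kappa from degenerate-site classes; site
    counts weighted by kappa and target frequencies; pathway-weighted
    difference counts; kappa-aware multiple-hit correction; the difference
    weighting is iterated with the updated omega until |change| < ``tol``.
    """
    seq_a, seq_b, pair_id = _pair_sequences(aln)
    ia = _codon_indices(seq_a, f"{pair_id}/a")
    ib = _codon_indices(seq_b, f"{pair_id}/b")
    if ia.size != ib.size or ia.size < 1:
        raise ValueError(f"{pair_id}: sequences must have equal, nonzero codon counts")
    flags: list[str] = []
    pi = f3x4_frequencies(ia, ib)
    kappa = estimate_kappa(ia, ib)
    kappa_used = kappa
    if math.isnan(kappa):
        kappa_used = 1.0
        flags.append("kappa_fallback")

    site_s = yn00_site_counts(kappa_used, pi)
    S = float((site_s[ia].sum() + site_s[ib].sum()) / 2.0)
    N = 3.0 * ia.size - S

    diff_mask = ia != ib
    pairs, counts = np.unique(
        np.stack([np.minimum(ia[diff_mask], ib[diff_mask]),
                  np.maximum(ia[diff_mask], ib[diff_mask])], axis=1),
        axis=0, return_counts=True,
    ) if diff_mask.any() else (np.zeros((0, 2), dtype=np.int64), np.zeros(0, dtype=np.int64))

    omega = omega_init
    Sd = Nd = 0.0
    dS = dN = 0.0
    converged = pairs.shape[0] == 0
    for _ in range(max_iter):
        Sd = Nd = 0.0
        sd_ts = sd_tv = nd_ts = nd_tv = 0.0
        w_omega = min(max(omega, 1e-4), 99.0) if not math.isnan(omega) else 1.0
        for (ca, cb), cnt in zip(pairs, counts):
            d = _weighted_differences(int(ca), int(cb), kappa_used, pi, w_omega)
            Sd += cnt * d[0]
            Nd += cnt * d[1]
            sd_ts += cnt * d[2]
            sd_tv += cnt * d[3]
            nd_ts += cnt * d[4]
            nd_tv += cnt * d[5]
        try:
            dS = _k80_distance(sd_ts / S, sd_tv / S) if S > 0 else 0.0
        except SaturationError:
            flags.append("dS_saturated")
            dS = float("nan")
            break
        try:
            dN = _k80_distance(nd_ts / N, nd_tv / N) if N > 0 else 0.0
        except SaturationError:
            flags.append("dN_saturated")
            dN = float("nan")
            break
        omega_new = dN / dS if dS > 0 else float("nan")
        if math.isnan(omega_new):
            omega = omega_new
            converged = True
            break
        if abs(omega_new - omega) < tol:
            omega = omega_new
            converged = True
            break
        omega = omega_new
    if not converged and not any(f.endswith("_saturated") for f in flags):
        flags.append("nonconvergent")
    if not math.isnan(dS) and dS == 0:
        flags.append("omega_undefined")
    omega_out = dN / dS if (dS and dS > 0 and not math.isnan(dN)) else float("nan")
    return RateEstimate(
        pair_id=pair_id, method="YN00", S=S, N=N, Sd=Sd, Nd=Nd,
        pS=Sd / S if S > 0 else 0.0, pN=Nd / N if N > 0 else 0.0,
        dS=dS, dN=dN, omega=omega_out, kappa=kappa, n_codons=int(ia.size),
        flags=tuple(flags),
    )


def estimate_rates(aln, method: str = "YN00") -> RateEstimate:
    """Dispatch to the requested estimator."""
    if method.upper() == "NG86":
        return ng86_dnds(aln)
    if method.upper() == "YN00":
        return yn00_dnds(aln)
    raise ValueError(f"unknown rate method {method!r}")
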