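"""Synthetic data with planted structure for every pipeline stage.

Three generators:

* :func:`simulate_expression` — a latent-factor (module eigengene) model of
  a normalized expression matrix. Each module has a standard-normal
  eigengene over samples; gene i loads on its module's eigengene with
  loading lambda_i (hub genes near 1, peripheral genes lower) plus Gaussian
  noise, so within-module correlations are lambda_i * lambda_j and the
  planted expected degree ranking is known exactly.

* :func:`simulate_codon_pair` — two coding sequences diverged from a common
  ancestor under a 61-codon Markov substitution model with target-frequency,
  transition (kappa) and nonsynonymous (omega) weighting, zero rate for
  multi-nucleotide changes, normalized to one expected substitution per
  codon per unit branch length; transition probabilities by matrix
  exponential. This is the validation oracle for the counting estimators.

* :func:`simulate_study` — a joint multi-taxon study: expression matrices
  for focal taxon and outgroup, per-gene omega planted as a noisy decreasing
  function of network degree (noise calibrated by search so the realized
  Kendall association matches ``effect_size``), ortholog CDS pairs evolved
  at those omegas, reciprocal hit tables that recover the true pairing, and
  a truth table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .genetics import N_SENSE, NEIGHBOR_IDX, NEIGHBOR_IS_TS, NEIGHBOR_IS_SYN, SENSE_CODONS
from .rbh import HitRecord
from .stats import kendall_tau_b


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for the synthetic generators.

    Defaults are the package's desk-scale study: module sizes and sample
    counts large enough for stable correlation estimates, CDS lengths and
    divergence in the range where counting estimators are well behaved, and
    an ortholog-pair yield per taxon comparable to the smaller taxa of a
    cross-species microarray compendium.
    """

    n_genes: int = 240
    n_samples: int = 60
    n_modules: int = 4
    hub_fraction: float = 0.1
    within_module_cor: float = 0.7
    noise_sd: float = 1.0
    n_codons: int = 300
    omega_range: tuple[float, float] = (0.05, 0.9)
    effect_size: float = -0.3
    kappa: float = 2.0
    t: float = 0.4
    seed: int = 0

    def __post_init__(self):
        if min(self.n_genes, self.n_samples, self.n_modules, self.n_codons) <= 0:
            raise ValueError("all counts must be positive")
        if not (0 < self.within_module_cor < 1):
            raise ValueError("within_module_cor must be in (0, 1)")
        if self.omega_range[0] > self.omega_range[1] or self.omega_range[0] < 0:
            raise ValueError("omega_range must be ordered and non-negative")
        if not -1.0 <= self.effect_size <= 0.0:
            raise ValueError("effect_size must be in [-1, 0]")


# ------------------------------------------------------------ expression --

def simulate_expression(spec: SimulationSpec, rng=None):
    """Latent-factor expression matrix plus planted per-gene degree.

    Returns (matrix, planted) where ``matrix`` is a genes x samples
    DataFrame (positive intensities: a per-gene baseline offset is added)
    and ``planted`` is a DataFrame with the module label, loading, and the
    planted expected degree score sum_{j != i, same module} lambda_i
    lambda_j, whose ranking the estimated connectivity should recover.
    """
    if spec.n_samples < 4:
        raise ValueError("need at least 4 samples")
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    n = spec.n_genes
    modules = np.arange(n) % spec.n_modules
    n_hubs = max(1, int(round(spec.hub_fraction * n)))
    is_hub = np.zeros(n, dtype=bool)
    # spread hubs across modules
    hub_idx = np.concatenate(
        [np.flatnonzero(modules == m) for m in range(spec.n_modules)]
    )
    per_mod = max(1, n_hubs // spec.n_modules)
    chosen = []
    for m in range(spec.n_modules):
        members = np.flatnonzero(modules == m)
        chosen.extend(members[:per_mod])
    is_hub[np.asarray(chosen[:n_hubs])] = True

    loadings = np.where(
        is_hub,
        rng.uniform(0.88, 0.98, size=n),
        rng.uniform(0.25, spec.within_module_cor, size=n),
    )
    eigengenes = rng.standard_normal((spec.n_modules, spec.n_samples))
    noise = rng.standard_normal((n, spec.n_samples)) * spec.noise_sd
    signal = loadings[:, None] * eigengenes[modules]
    values = signal + np.sqrt(np.clip(1.0 - loadings**2, 0.0, None))[:, None] * noise
    baseline = rng.uniform(6.0, 10.0, size=n)  # intensity-scale offset, keeps means > 0
    values = values + baseline[:, None]

    degree = np.zeros(n)
    for m in range(spec.n_modules):
        members = modules == m
        lam = loadings[members]
        degree[members] = lam * (lam.sum() - lam)

    gene_ids = [f"g{i:05d}" for i in range(n)]
    matrix = pd.DataFrame(
        values, index=pd.Index(gene_ids, name="gene_id"),
        columns=[f"s{j:04d}" for j in range(spec.n_samples)],
    )
    planted = pd.DataFrame(
        {"module": modules, "hub": is_hub, "loading": loadings, "planted_degree": degree},
        index=matrix.index,
    )
    return matrix, planted


# ----------------------------------------------------------- codon model --

def uniform_codon_freqs() -> np.ndarray:
    return np.full(N_SENSE, 1.0 / N_SENSE)


def codon_rate_matrix(omega: float, kappa: float, codon_freqs) -> np.ndarray:
    """61x61 substitution rate matrix: q_ij = pi_j * kappa^[transition] *
    omega^[nonsynonymous] for single-nucleotide changes, zero otherwise,
    scaled to one expected substitution per codon per unit time."""
    pi = np.asarray(codon_freqs, dtype=float)
    if pi.shape != (N_SENSE,):
        raise ValueError(f"codon_freqs must have length {N_SENSE}")
    if abs(pi.sum() - 1.0) > 1e-9:
        raise ValueError("codon frequencies must sum to 1 (tolerance 1e-9)")
    if (pi < 0).any():
        raise ValueError("codon frequencies must be non-negative")
    if omega < 0 or kappa <= 0:
        raise ValueError("need omega >= 0 and kappa > 0")
    Q = np.zeros((N_SENSE, N_SENSE))
    for i in range(N_SENSE):
        for k in range(9):
            j = NEIGHBOR_IDX[i, k]
            if j < 0:
                continue
            rate = pi[j]
            if NEIGHBOR_IS_TS[i, k]:
                rate *= kappa
            if not NEIGHBOR_IS_SYN[i, k]:
                rate *= omega
            Q[i, j] += rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -(pi * np.diag(Q)).sum()
    if scale > 0:
        Q /= scale
    return Q


def _sample_markov(P: np.ndarray, states: np.ndarray, rng) -> np.ndarray:
    cum = np.cumsum(P[states], axis=1)
    u = rng.random(states.size)
    return (u[:, None] > cum).sum(axis=1)


def simulate_codon_pair(
    n_codons: int,
    omega: float,
    t: float,
    kappa: float,
    codon_freqs=None,
    seed=None,
    rng=None,
) -> tuple[str, str]:
    """Two CDS strings diverged by total branch length ``t`` (t/2 per
    lineage; a pairwise estimator only sees the sum)."""
    if t < 0:
        raise ValueError("t must be >= 0")
    pi = uniform_codon_freqs() if codon_freqs is None else np.asarray(codon_freqs, float)
    rng = np.random.default_rng(seed) if rng is None else rng
    ancestor = rng.choice(N_SENSE, size=n_codons, p=pi / pi.sum())
    if t == 0:
        child_a = child_b = ancestor
    else:
        P = expm(codon_rate_matrix(omega, kappa, pi) * (t / 2.0))
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        child_a = _sample_markov(P, ancestor, rng)
        child_b = _sample_markov(P, ancestor, rng)
    to_seq = lambda idx: "".join(SENSE_CODONS[i] for i in idx)
    return to_seq(child_a), to_seq(child_b)


# ------------------------------------------------------------- the study --

def _calibrated_omegas(degree: np.ndarray, spec: SimulationSpec, rng) -> np.ndarray:
    """Assign per-gene omega with Kendall association to the planted degree
    equal to ``effect_size`` within +/- 0.05 (search on the copula mixing
    weight against the realized tau; monotone for fixed noise draws)."""
    n = degree.size
    z_deg = (pd.Series(degree).rank().to_numpy() - (n + 1) / 2.0)
    z_deg = z_deg / z_deg.std()
    eps = rng.standard_normal(n)
    lo, hi = spec.omega_range

    def omega_for(a: float) -> np.ndarray:
        z = -a * z_deg + math.sqrt(max(0.0, 1.0 - a * a)) * eps
        ranks = pd.Series(z).rank().to_numpy() - 1.0
        return lo + (hi - lo) * ranks / max(1, n - 1)

    target = spec.effect_size
    a_lo, a_hi = -1.0, 1.0
    for _ in range(50):
        a_mid = 0.5 * (a_lo + a_hi)
        tau = kendall_tau_b(degree, omega_for(a_mid))
        if abs(tau - target) < 0.005:
            break
        # tau decreases as a increases
        if tau > target:
            a_lo = a_mid
        else:
            a_hi = a_mid
    return omega_for(0.5 * (a_lo + a_hi))


@dataclass
class TaxonStudy:
    """Everything the pipeline needs for one focal-taxon/outgroup pair."""

    taxon: str
    expression: pd.DataFrame  # probe-keyed focal matrix
    probe_map: pd.DataFrame  # probe_id -> gene_id, with multi-probe genes
    expression_outgroup: pd.DataFrame  # gene-keyed outgroup matrix
    cds_focal: dict[str, str]
    cds_outgroup: dict[str, str]
    hits_ab: list[HitRecord]
    hits_ba: list[HitRecord]
    truth: pd.DataFrame = field(repr=False, default=None)


def _hit(q, s, evalue, bits, length) -> HitRecord:
    return HitRecord(
        query_id=q, subject_id=s, percent_identity=90.0, alignment_length=length,
        mismatches=int(0.1 * length), gap_opens=0, q_start=1, q_end=length,
        s_start=1, s_end=length, evalue=evalue, bit_score=bits,
    )


def simulate_taxon(spec: SimulationSpec, taxon: str, seed: int) -> TaxonStudy:
    """One focal taxon with its outgroup: expression with planted hubs,
    orthologous CDS pairs whose omega decreases with planted degree, and
    reciprocal hit tables (true pairs below the e-value ceiling, decoy hits
    above it or outscored)."""
    rng = np.random.default_rng(seed)
    tspec = replace(spec, seed=seed)
    expr, planted = simulate_expression(tspec, rng=rng)
    gene_ids = [f"{taxon}_{g}" for g in expr.index]
    expr.index = pd.Index(gene_ids, name="gene_id")
    planted.index = expr.index

    # outgroup expression: ortholog loadings are a perturbed copy of the
    # focal loadings, so cross-taxon ortholog connectivity correlates
    out_ids = [f"og_{g}" for g in gene_ids]
    modules = planted["module"].to_numpy()
    loadings = np.clip(
        planted["loading"].to_numpy() + rng.normal(0.0, 0.08, len(gene_ids)), 0.1, 0.98
    )
    eigengenes = rng.standard_normal((spec.n_modules, spec.n_samples))
    noise = rng.standard_normal((len(gene_ids), spec.n_samples)) * spec.noise_sd
    out_values = (
        loadings[:, None] * eigengenes[modules]
        + np.sqrt(np.clip(1 - loadings**2, 0, None))[:, None] * noise
        + rng.uniform(6.0, 10.0, len(gene_ids))[:, None]
    )
    expr_out = pd.DataFrame(
        out_values, index=pd.Index(out_ids, name="gene_id"), columns=expr.columns
    )

    # probe map: ~20% of genes carry a duplicate probe
    probe_rows, expr_rows, expr_index = [], [], []
    for gi, gene in enumerate(gene_ids):
        n_probes = 2 if rng.random() < 0.2 else 1
        for p in range(n_probes):
            probe = f"p_{gene}_{p}"
            probe_rows.append((probe, gene))
            expr_index.append(probe)
            jitter = rng.normal(0.0, 0.03, spec.n_samples) if p else 0.0
            expr_rows.append(expr.loc[gene].to_numpy() + jitter)
    probe_map = pd.DataFrame(probe_rows, columns=["probe_id", "gene_id"])
    expr_probes = pd.DataFrame(
        np.asarray(expr_rows), index=pd.Index(expr_index, name="probe_id"),
        columns=expr.columns,
    )

    omegas = _calibrated_omegas(planted["planted_degree"].to_numpy(), spec, rng)

    cds_focal, cds_outgroup = {}, {}
    for gene, out_gene, omega in zip(gene_ids, out_ids, omegas):
        a, b = simulate_codon_pair(
            spec.n_codons, float(omega), spec.t, spec.kappa, rng=rng
        )
        cds_focal[gene] = a
        cds_outgroup[out_gene] = b

    hits_ab, hits_ba = [], []
    length = spec.n_codons * 3
    genes_arr = list(zip(gene_ids, out_ids))
    for i, (gene, out_gene) in enumerate(genes_arr):
        e_true = 10.0 ** (-rng.uniform(30.0, 150.0))
        hits_ab.append(_hit(gene, out_gene, e_true, rng.uniform(400, 900), length))
        hits_ba.append(_hit(out_gene, gene, e_true * rng.uniform(0.5, 2.0), rng.uniform(400, 900), length))
        if rng.random() < 0.3:  # decoy cross-hits, above the ceiling
            j = int(rng.integers(0, len(genes_arr)))
            if j != i:
                e_decoy = 10.0 ** (-rng.uniform(2.0, 7.5))
                hits_ab.append(_hit(gene, genes_arr[j][1], e_decoy, rng.uniform(40, 80), length // 3))
                hits_ba.append(_hit(genes_arr[j][1], gene, e_decoy, rng.uniform(40, 80), length // 3))

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "ortholog_id": out_ids,
            "module": planted["module"].to_numpy(),
            "hub": planted["hub"].to_numpy(),
            "planted_degree": planted["planted_degree"].to_numpy(),
            "omega": omegas,
            "t": spec.t,
            "kappa": spec.kappa,
        }
    ).set_index("gene_id")
    return TaxonStudy(
        taxon=taxon, expression=expr_probes, probe_map=probe_map,
        expression_outgroup=expr_out, cds_focal=cds_focal,
        cds_outgroup=cds_outgroup, hits_ab=hits_ab, hits_ba=hits_ba, truth=truth,
    )


def simulate_study(
    spec: SimulationSpec, taxa: tuple[str, ...] = tuple(f"tax{i + 1}" for i in range(7))
) -> dict[str, TaxonStudy]:
    """A full multi-taxon study (7 focal taxa by default), seeds derived
    from ``spec.seed`` per taxon."""
    root = np.random.default_rng(spec.seed)
    seeds = root.integers(0, 2**31 - 1, size=len(taxa))
    return {taxon: simulate_taxon(spec, taxon, int(seeds[i])) for i, taxon in enumerate(taxa)}


# ------------------------------------------------------------- file I/O ---

def write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i: i + 60] + "\n")


def write_hits_tsv(hits: list[HitRecord], path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.percent_identity:.1f}\t"
                f"{h.alignment_length}\t{h.mismatches}\t{h.gap_opens}\t"
                f"{h.q_start}\t{h.q_end}\t{h.s_start}\t{h.s_end}\t"
                f"{h.evalue:.3g}\t{h.bit_score:.1f}\n"
            )


def write_taxon_files(study: TaxonStudy, outdir) -> dict[str, str]:
    """Write one taxon's inputs in the formats the pipeline reads; returns
    the path map used by the pipeline config."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "probe_map": outdir / "probe_map.tsv",
        "expression_outgroup": outdir / "expression_outgroup.tsv",
        "cds_focal": outdir / "cds_focal.fasta",
        "cds_outgroup": outdir / "cds_outgroup.fasta",
        "hits_ab": outdir / "hits_ab.tsv",
        "hits_ba": outdir / "hits_ba.tsv",
        "truth": outdir / "truth.tsv",
    }
    study.expression.to_csv(paths["expression"], sep="\t", index_label="gene_id")
    study.probe_map.to_csv(paths["probe_map"], sep="\t", header=False, index=False)
    study.expression_outgroup.to_csv(
        paths["expression_outgroup"], sep="\t", index_label="gene_id"
    )
    write_fasta(study.cds_focal, paths["cds_focal"])
    write_fasta(study.cds_outgroup, paths["cds_outgroup"])
    write_hits_tsv(study.hits_ab, paths["hits_ab"])
    write_hits_tsv(study.hits_ba, paths["hits_ba"])
    study.truth.to_csv(paths["truth"], sep="\t")
    return {k: str(v) for k, v in paths.items()}
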