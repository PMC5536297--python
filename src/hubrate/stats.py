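"""Rank-correlation inference layer.

The connectivity-versus-rate association is measured with Kendall's tau-b
(tie-corrected, since connectivity counts and rate estimates are heavily
tied), tested by randomization (the rate vector is permuted, the tau null
distribution rebuilt, two-tailed add-one p-value), corrected across taxa by
Holm's sequential Bonferroni, and combined across taxa by Fisher's combined
probability test; a two-tailed exact sign test asks whether all taxa
sharing the same correlation sign is itself surprising.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

RATE_METRICS = ("dN", "dS", "omega")


def _tie_term(v: np.ndarray) -> float:
    _, counts = np.unique(v, return_counts=True)
    return float((counts * (counts - 1) / 2).sum())


def kendall_tau_b(x, y) -> float:
    """Kendall's tau-b: (C - D) / sqrt((n0 - n1)(n0 - n2)) with the usual
    tie terms n1, n2 for x and y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length 1-D vectors with n >= 2")
    n = x.size
    n0 = n * (n - 1) / 2
    n1, n2 = _tie_term(x), _tie_term(y)
    if n1 == n0 or n2 == n0:
        raise ValueError("tau-b undefined: a vector is constant")
    sx = np.sign(x[:, None] - x[None, :])
    sy = np.sign(y[:, None] - y[None, :])
    c_minus_d = float((sx * sy).sum()) / 2.0
    return c_minus_d / np.sqrt((n0 - n1) * (n0 - n2))


def permutation_pvalue(
    x, y, n_permutations: int = 10000, seed=None, chunk: int = 256
) -> tuple[float, float]:
    """Two-tailed randomization p-value for Kendall's tau.

    y is permuted uniformly ``n_permutations`` times; the p-value is the
    add-one estimate (1 + #{|tau_perm| >= |tau_obs|}) / (1 + n_permutations),
    so it is never zero. Returns (tau_obs, p).

    The permuted statistics are computed from the precomputed sign matrices:
    permuting y permutes rows and columns of its sign matrix, and tie terms
    are permutation-invariant, so only the concordance sum is recomputed.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    tau_obs = kendall_tau_b(x, y)
    n = x.size
    n0 = n * (n - 1) / 2
    denom = np.sqrt((n0 - _tie_term(x)) * (n0 - _tie_term(y)))
    sx = np.sign(x[:, None] - x[None, :]).astype(np.int8)
    sy = np.sign(y[:, None] - y[None, :]).astype(np.int8)
    rng = np.random.default_rng(seed)
    hits = 0
    done = 0
    thresh = abs(tau_obs) - 1e-12  # guard fp noise in |tau_perm| >= |tau_obs|
    while done < n_permutations:
        m = min(chunk, n_permutations - done)
        perms = np.argsort(rng.random((m, n)), axis=1)
        sy_p = sy[perms[:, :, None], perms[:, None, :]]
        np.multiply(sy_p, sx[None, :, :], out=sy_p)
        cmd = sy_p.sum(axis=(1, 2), dtype=np.int64) / 2.0
        taus = cmd / denom
        hits += int((np.abs(taus) >= thresh).sum())
        done += m
    return tau_obs, (1 + hits) / (1 + n_permutations)


def holm_adjust(pvalues, alpha: float = 0.05) -> np.ndarray:
    """Holm step-down (sequential Bonferroni) rejection decisions.

    p-values are sorted ascending; p_(i) is rejected while
    p_(i) <= alpha / (m - i + 1); the first failure stops the procedure.
    Returns booleans in the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if p[idx] <= alpha / (m - rank):
            reject[idx] = True
        else:
            break
    return reject


@dataclass(frozen=True)
class CombinedTestResult:
    statistic: float
    df: int
    p_combined: float


def fisher_combined(pvalues) -> CombinedTestResult:
    """Fisher's combined probability test: -2 sum(ln p) ~ chi2(2m)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    stat = float(-2.0 * np.log(p).sum())
    df = 2 * p.size
    return CombinedTestResult(statistic=stat, df=df, p_combined=float(sps.chi2.sf(stat, df)))


def sign_test(k_same_sign: int, n: int) -> float:
    """Exact two-tailed sign test: p = 2 min(P[X<=k], P[X>=k]) capped at 1,
    X ~ Binomial(n, 1/2)."""
    if n < 1 or not 0 <= k_same_sign <= n:
        raise ValueError("need 0 <= k <= n, n >= 1")
    lower = sps.binom.cdf(k_same_sign, n, 0.5)
    upper = sps.binom.sf(k_same_sign - 1, n, 0.5)
    return float(min(1.0, 2.0 * min(lower, upper)))


@dataclass(frozen=True)
class CorrelationResult:
    taxon_pair: str
    metric: str
    n_pairs: int
    tau: float
    p_perm: float
    significant_raw: bool = False
    significant_holm: bool = False


@dataclass
class TaxonRateData:
    """Joined per-taxon inputs for the correlation stage.

    connectivity: Series gene_id -> k in the focal taxon's network.
    rates: DataFrame indexed by focal gene id with columns dN, dS, omega.
    outgroup_connectivity: optional Series for the outgroup network, used
    for the cross-taxon ortholog-connectivity correlation.
    pairs: optional DataFrame (gene_a focal, gene_b outgroup) mapping
    orthologs; required for the ortholog-connectivity metric.
    """

    connectivity: pd.Series
    rates: pd.DataFrame
    outgroup_connectivity: pd.Series | None = None
    pairs: pd.DataFrame | None = None


def _metric_vectors(data: TaxonRateData, metric: str):
    if metric == "ortholog_connectivity":
        if data.outgroup_connectivity is None or data.pairs is None:
            return None
        sub = data.pairs[
            data.pairs["gene_a"].isin(data.connectivity.index)
            & data.pairs["gene_b"].isin(data.outgroup_connectivity.index)
        ]
        x = data.connectivity.loc[sub["gene_a"]].to_numpy(dtype=float)
        y = data.outgroup_connectivity.loc[sub["gene_b"]].to_numpy(dtype=float)
        return x, y
    genes = data.rates.index.intersection(data.connectivity.index)
    x = data.connectivity.loc[genes].to_numpy(dtype=float)
    y = data.rates.loc[genes, metric].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)  # pairwise deletion (e.g. omega at dS=0)
    return x[ok], y[ok]


def connectivity_rate_analysis(
    datasets: dict[str, TaxonRateData],
    n_permutations: int = 10000,
    alpha: float = 0.05,
    seed=None,
    min_pairs: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The cross-taxon inference table.

    For every taxon pair and metric in {dN, dS, omega} the focal gene's
    connectivity is correlated (tau-b + randomization p) with the ortholog
    pair's rate; the ortholog-connectivity correlation across the two
    networks is added where outgroup connectivity is available. Holm
    adjustment runs across taxa within each metric; Fisher's combined test
    and the sign test on same-sign tau counts summarize each metric.

    Returns (per-taxon results, per-metric combined tests) as DataFrames.
    """
    rng = np.random.default_rng(seed)
    metrics = list(RATE_METRICS) + ["ortholog_connectivity"]
    rows: list[CorrelationResult] = []
    for metric in metrics:
        metric_rows = []
        for taxon_pair, data in datasets.items():
            vecs = _metric_vectors(data, metric)
            if vecs is None:
                continue
            x, y = vecs
            if x.size < min_pairs:
                import warnings

                warnings.warn(
                    f"{taxon_pair}/{metric}: only {x.size} usable pairs; skipped",
                    RuntimeWarning,
                    stacklevel=2,
                )
                continue
            try:
                tau, p = permutation_pvalue(
                    x, y, n_permutations=n_permutations,
                    seed=rng.integers(0, 2**31 - 1),
                )
            except ValueError as exc:  # degenerate (constant) vector
                import warnings

                warnings.warn(
                    f"{taxon_pair}/{metric}: {exc}; skipped", RuntimeWarning, stacklevel=2
                )
                continue
            metric_rows.append(
                CorrelationResult(
                    taxon_pair=taxon_pair, metric=metric, n_pairs=int(x.size),
                    tau=tau, p_perm=p, significant_raw=p < alpha,
                )
            )
        if metric_rows:
            reject = holm_adjust([r.p_perm for r in metric_rows], alpha=alpha)
            metric_rows = [
                CorrelationResult(
                    taxon_pair=r.taxon_pair, metric=r.metric, n_pairs=r.n_pairs,
                    tau=r.tau, p_perm=r.p_perm, significant_raw=r.significant_raw,
                    significant_holm=bool(h),
                )
                for r, h in zip(metric_rows, reject)
            ]
        rows.extend(metric_rows)

    results = pd.DataFrame([vars(r) for r in rows])
    combined_rows = []
    for metric in metrics:
        sub = results[results["metric"] == metric] if len(results) else results
        if len(sub) == 0:
            continue
        fisher = fisher_combined(sub["p_perm"].to_numpy())
        n_neg = int((sub["tau"] < 0).sum())
        combined_rows.append(
            {
                "metric": metric,
                "n_taxa": len(sub),
                "n_negative_tau": n_neg,
                "fisher_statistic": fisher.statistic,
                "fisher_df": fisher.df,
                "fisher_p": fisher.p_combined,
                "sign_test_p": sign_test(n_neg, len(sub)),
                "n_significant_holm": int(sub["significant_holm"].sum()),
            }
        )
    return results, pd.DataFrame(combined_rows)
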