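"""Weighted gene coexpression network construction.

Follows the WGCNA recipe: a Pearson correlation matrix over genes is raised
elementwise (in absolute value) to a soft-thresholding power beta, chosen as
the smallest power at which the weighted degree distribution is
approximately scale-free (signed R^2 of the log-log degree regression above
a cutoff, 0.85 by default). Per-gene connectivity k is then either the
weighted degree or, matching the "tally the connected genes" reading, the
count of partners whose adjacency exceeds a threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def pearson_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Gene-gene Pearson correlation matrix (genes in rows of ``matrix``)."""
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples to correlate")
    values = matrix.to_numpy(dtype=float)
    sds = values.std(axis=1)
    flat = np.flatnonzero(sds == 0)
    if flat.size:
        raise ValueError(f"gene {matrix.index[flat[0]]!r} has zero expression variance")
    corr = np.corrcoef(values)
    np.clip(corr, -1.0, 1.0, out=corr)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=matrix.index, columns=matrix.index)


def adjacency(corr: pd.DataFrame, beta: int) -> pd.DataFrame:
    """Unsigned soft-threshold adjacency a_ij = |r_ij|^beta, zero diagonal."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    adj = np.abs(corr.to_numpy(dtype=float)) ** beta
    np.fill_diagonal(adj, 0.0)
    return pd.DataFrame(adj, index=corr.index, columns=corr.columns)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the scale-free topology fit.

    Weighted degrees are binned into ``n_bins`` equal-width bins; empty bins
    are skipped; log10(frequency) is regressed on log10(mean degree in bin);
    returns -sign(slope) * R^2, so positive values indicate the decreasing
    degree distribution of a scale-free network. NaN when degenerate (all
    degrees equal or fewer than 2 usable bins).
    """
    k = np.asarray(k, dtype=float)
    if k.max() == k.min():
        return float("nan")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if not mask.any():
            continue
        mean_k = k[mask].mean()
        if mean_k <= 0:
            continue
        xs.append(np.log10(mean_k))
        ys.append(np.log10(mask.sum() / k.size))
    if len(xs) < 2:
        return float("nan")
    xs, ys = np.asarray(xs), np.asarray(ys)
    slope, intercept = np.polyfit(xs, ys, 1)
    resid = ys - (slope * xs + intercept)
    ss_tot = ((ys - ys.mean()) ** 2).sum()
    if ss_tot == 0:
        return float("nan")
    r2 = 1.0 - (resid**2).sum() / ss_tot
    return float(-np.sign(slope) * r2)


def soft_threshold_scan(
    matrix: pd.DataFrame,
    candidate_betas=tuple(range(1, 21)),
    n_bins: int = 10,
) -> pd.DataFrame:
    """Scan candidate soft-threshold powers.

    For each beta the weighted connectivity k_i = sum_{j != i} |r_ij|^beta is
    computed, and the scale-free fit statistic plus degree summaries are
    tabulated (one row per beta: beta, signed_r2, mean_k, median_k, max_k).
    """
    candidate_betas = list(candidate_betas)
    if not candidate_betas:
        raise ValueError("candidate_betas is empty")
    if any(b2 <= b1 for b1, b2 in zip(candidate_betas, candidate_betas[1:])):
        raise ValueError("candidate_betas must be strictly increasing")
    corr = pearson_matrix(matrix)
    absr = np.abs(corr.to_numpy(dtype=float))
    np.fill_diagonal(absr, 0.0)
    rows = []
    for beta in candidate_betas:
        k = (absr**beta).sum(axis=1)
        rows.append(
            {
                "beta": beta,
                "signed_r2": scale_free_fit(k, n_bins=n_bins),
                "mean_k": float(k.mean()),
                "median_k": float(np.median(k)),
                "max_k": float(k.max()),
            }
        )
    return pd.DataFrame(rows)


def pick_beta(scan: pd.DataFrame, r2_cutoff: float = 0.85) -> tuple[int, bool]:
    """Smallest beta whose signed R^2 reaches the cutoff.

    Falls back to the beta maximizing signed R^2 (with ``warned=True`` and a
    RuntimeWarning) when no candidate reaches it.
    """
    if len(scan) == 0:
        raise ValueError("empty soft-threshold scan")
    r2 = scan["signed_r2"].to_numpy(dtype=float)
    ok = np.flatnonzero(r2 >= r2_cutoff)
    if ok.size:
        return int(scan["beta"].iloc[ok[0]]), False
    if np.isnan(r2).all():
        raise ValueError("scale-free fit undefined for every candidate beta")
    best = int(np.nanargmax(r2))
    warnings.warn(
        f"no candidate beta reached signed R^2 >= {r2_cutoff}; "
        f"using beta={int(scan['beta'].iloc[best])} with max R^2={r2[best]:.3f}",
        RuntimeWarning,
        stacklevel=2,
    )
    return int(scan["beta"].iloc[best]), True


def connectivity(
    adj: pd.DataFrame, mode: str = "count", adj_threshold: float = 0.1
) -> pd.Series:
    """Per-gene connectivity.

    ``count`` mode tallies partners with adjacency >= ``adj_threshold``
    (the network's "number of genes connected to each gene"); ``weighted``
    mode is the WGCNA weighted degree sum_{j != i} a_ij.
    """
    if mode not in ("count", "weighted"):
        raise ValueError(f"unknown connectivity mode {mode!r}")
    a = adj.to_numpy(dtype=float)
    if mode == "count":
        if not 0.0 <= adj_threshold <= 1.0:
            raise ValueError("adj_threshold must be in [0, 1]")
        a = a.copy()
        np.fill_diagonal(a, -1.0)  # never count self even at threshold 0
        k = (a >= adj_threshold).sum(axis=1).astype(float)
    else:
        k = a.sum(axis=1) - np.diag(a)
    return pd.Series(k, index=adj.index, name="k")


@dataclass
class NetworkResult:
    """A fitted coexpression network: chosen power, adjacency, connectivity."""

    gene_ids: list[str]
    beta: int
    adjacency: pd.DataFrame
    connectivity: pd.Series
    mode: str
    scan: pd.DataFrame = field(repr=False, default=None)
    beta_warned: bool = False


def build_network(
    matrix: pd.DataFrame,
    candidate_betas=tuple(range(1, 21)),
    r2_cutoff: float = 0.85,
    mode: str = "count",
    adj_threshold: float = 0.1,
    n_bins: int = 10,
) -> NetworkResult:
    """Full network stage: scan powers, pick beta, build adjacency, tally k."""
    scan = soft_threshold_scan(matrix, candidate_betas, n_bins=n_bins)
    beta, warned = pick_beta(scan, r2_cutoff=r2_cutoff)
    corr = pearson_matrix(matrix)
    adj = adjacency(corr, beta)
    k = connectivity(adj, mode=mode, adj_threshold=adj_threshold)
    return NetworkResult(
        gene_ids=[str(g) for g in matrix.index],
        beta=beta,
        adjacency=adj,
        connectivity=k,
        mode=mode,
        scan=scan,
        beta_warned=warned,
    )
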