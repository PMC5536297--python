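"""Expression-matrix ingestion and quality filtering.

The analysis starts from an already-normalized gene-by-sample expression
matrix (e.g. RMA-normalized microarray intensities). Two QC steps precede
network construction: (1) when several array probes map to one gene, a
single probe is kept, chosen uniformly at random; (2) genes with too little
expression variability are dropped by a coefficient-of-variation (CV)
filter that retains genes whose CV lies in the upper portion of the
empirical CV distribution (by default, at or above the 5th percentile, i.e.
within the upper 95%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def read_expression_tsv(path) -> pd.DataFrame:
    """Read a TSV expression matrix: first column gene_id, header row of
    sample ids. Returns genes x samples DataFrame (gene_id index)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    validate_expression(df)
    return df


def write_expression_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id")


def validate_expression(matrix: pd.DataFrame) -> None:
    """Enforce the expression-matrix invariants: unique gene ids, unique
    sample ids, all values finite."""
    if matrix.index.duplicated().any():
        dup = matrix.index[matrix.index.duplicated()][0]
        raise ValueError(f"duplicate gene_id {dup!r} in expression matrix")
    if matrix.columns.duplicated().any():
        raise ValueError("duplicate sample ids in expression matrix")
    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("expression matrix contains non-finite values")


def read_probe_map(path) -> pd.DataFrame:
    """Two-column headerless TSV (probe_id, gene_id)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["probe_id", "gene_id"], dtype=str)
    if df["probe_id"].duplicated().any():
        dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise ValueError(f"duplicate probe_id {dup!r} in probe map")
    return df


def dedupe_probes(probe_map: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Keep exactly one probe per gene, chosen uniformly at random.

    Multi-probe genes are common on expression arrays; retaining all probes
    would duplicate rows of the correlation substrate, so one is sampled per
    gene. Reproducible for a fixed ``seed``.
    """
    if len(probe_map) == 0:
        raise ValueError("probe map is empty")
    rng = np.random.default_rng(seed)
    # stable gene order (first appearance), random probe within gene
    out_idx = []
    for _, grp in probe_map.groupby("gene_id", sort=False):
        out_idx.append(rng.choice(grp.index.to_numpy()))
    return probe_map.loc[out_idx].reset_index(drop=True)


@dataclass(frozen=True)
class CVReport:
    gene_id: str
    cv: float
    retained: bool


def compute_cv(matrix: pd.DataFrame) -> pd.Series:
    """Per-gene coefficient of variation: sample sd (n-1 denominator) over
    mean of the gene's row. Requires every row mean > 0 (intensity scale)."""
    validate_expression(matrix)
    values = matrix.to_numpy(dtype=float)
    means = values.mean(axis=1)
    bad = np.flatnonzero(means <= 0)
    if bad.size:
        raise ValueError(
            f"gene {matrix.index[bad[0]]!r} has non-positive mean expression "
            f"({means[bad[0]]:.4g}); CV undefined"
        )
    sds = values.std(axis=1, ddof=1)
    return pd.Series(sds / means, index=matrix.index, name="cv")


def cv_filter(
    matrix: pd.DataFrame, lower_quantile: float = 0.05
) -> tuple[pd.DataFrame, list[CVReport]]:
    """Drop the least-variable genes.

    Genes whose CV is at or above the ``lower_quantile`` quantile of the
    per-gene CV distribution are retained (the quantile uses linear
    interpolation between order statistics). Gene order and sample columns
    are untouched. Returns the filtered matrix and a per-gene report.
    """
    if not 0.0 <= lower_quantile <= 1.0:
        raise ValueError("lower_quantile must be in [0, 1]")
    cv = compute_cv(matrix)
    cutoff = float(np.quantile(cv.to_numpy(), lower_quantile))
    retained = cv >= cutoff
    reports = [
        CVReport(gene_id=str(g), cv=float(c), retained=bool(r))
        for g, c, r in zip(cv.index, cv.to_numpy(), retained.to_numpy())
    ]
    if not retained.any():
        raise ValueError("CV filter removed every gene")
    return matrix.loc[retained], reports


def apply_probe_map(matrix: pd.DataFrame, probe_map: pd.DataFrame) -> pd.DataFrame:
    """Re-key a probe-indexed matrix by gene using a (deduplicated) probe
    map; probes absent from the matrix are dropped."""
    if probe_map["gene_id"].duplicated().any():
        raise ValueError("probe map must be deduplicated (one probe per gene)")
    present = probe_map[probe_map["probe_id"].isin(matrix.index)]
    out = matrix.loc[present["probe_id"]].copy()
    out.index = pd.Index(present["gene_id"], name="gene_id")
    return out
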