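"""End-to-end orchestration: preprocess -> network -> RBH -> codon
alignment -> dN/dS -> correlation statistics, per focal-taxon/outgroup pair,
from a single YAML-able configuration.

Each stage writes plain TSV intermediates under the output directory, plus a
run log recording the seed, parameters, and per-stage record counts, so a
run can be audited and its intermediates reused directly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from . import align as align_mod
from . import molevol, network, preprocess, rbh
from .stats import TaxonRateData, connectivity_rate_analysis

log = logging.getLogger("hubrate")


class PipelineError(RuntimeError):
    pass


@dataclass
class TaxonPaths:
    expression: str
    probe_map: str | None
    cds_focal: str
    cds_outgroup: str
    hits_ab: str
    hits_ba: str
    expression_outgroup: str | None = None


@dataclass
class PipelineConfig:
    taxa: dict[str, TaxonPaths]
    output_dir: str
    lower_quantile: float = 0.05
    candidate_betas: tuple[int, ...] = tuple(range(1, 21))
    r2_cutoff: float = 0.85
    connectivity_mode: str = "count"
    adj_threshold: float = 0.1
    evalue_max: float = 1e-8
    min_segment_nt: int = 30
    min_total_nt: int = 300
    rate_method: str = "YN00"
    n_permutations: int = 10000
    alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        taxa = {
            name: TaxonPaths(**paths) for name, paths in raw.pop("taxa").items()
        }
        if "candidate_betas" in raw:
            raw["candidate_betas"] = tuple(raw["candidate_betas"])
        return cls(taxa=taxa, **raw)

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        raw["candidate_betas"] = list(self.candidate_betas)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def _params_hash(config: "PipelineConfig") -> str:
    raw = asdict(config)
    return hashlib.sha256(
        json.dumps(raw, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def _check_path(path, stage: str, taxon: str):
    if path is None or not Path(path).exists():
        raise PipelineError(f"stage {stage!r} ({taxon}): missing input {path}")
    return Path(path)


def _network_stage(matrix, config: PipelineConfig):
    return network.build_network(
        matrix,
        candidate_betas=config.candidate_betas,
        r2_cutoff=config.r2_cutoff,
        mode=config.connectivity_mode,
        adj_threshold=config.adj_threshold,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage for every configured taxon; returns (and writes) the
    output manifest. Aborts with a diagnostic if a stage yields zero records.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    import numpy as np

    stage_rngs = np.random.default_rng(config.seed)
    dedupe_seed = int(stage_rngs.integers(0, 2**31 - 1))
    stats_seed = int(stage_rngs.integers(0, 2**31 - 1))

    manifest: dict = {
        "seed": config.seed,
        "params_hash": _params_hash(config),
        "taxa": {},
        "outputs": {},
    }
    datasets: dict[str, TaxonRateData] = {}

    for taxon, paths in config.taxa.items():
        tdir = outdir / taxon
        tdir.mkdir(exist_ok=True)
        counts: dict[str, int] = {}

        # ---- preprocess -------------------------------------------------
        expr_path = _check_path(paths.expression, "preprocess", taxon)
        matrix = preprocess.read_expression_tsv(expr_path)
        counts["probes"] = len(matrix)
        if paths.probe_map:
            pmap = preprocess.read_probe_map(_check_path(paths.probe_map, "preprocess", taxon))
            pmap = preprocess.dedupe_probes(pmap, seed=dedupe_seed)
            matrix = preprocess.apply_probe_map(matrix, pmap)
        counts["genes"] = len(matrix)
        matrix, cv_reports = preprocess.cv_filter(matrix, config.lower_quantile)
        counts["genes_cv_retained"] = len(matrix)
        filtered_path = tdir / "expression_filtered.tsv"
        preprocess.write_expression_tsv(matrix, filtered_path)
        pd.DataFrame([vars(r) for r in cv_reports]).to_csv(
            tdir / "cv_report.tsv", sep="\t", index=False
        )

        # ---- network ----------------------------------------------------
        net = _network_stage(matrix, config)
        net.scan.to_csv(tdir / "soft_threshold_scan.tsv", sep="\t", index=False)
        conn = pd.DataFrame(
            {
                "gene_id": net.connectivity.index,
                "k": net.connectivity.to_numpy(),
                "beta": net.beta,
                "mode": net.mode,
            }
        )
        conn.to_csv(tdir / "connectivity.tsv", sep="\t", index=False)
        counts["network_genes"] = len(conn)

        out_conn = None
        if paths.expression_outgroup:
            out_matrix = preprocess.read_expression_tsv(
                _check_path(paths.expression_outgroup, "network", taxon)
            )
            out_matrix, _ = preprocess.cv_filter(out_matrix, config.lower_quantile)
            out_net = _network_stage(out_matrix, config)
            out_conn = out_net.connectivity
            pd.DataFrame(
                {"gene_id": out_conn.index, "k": out_conn.to_numpy(),
                 "beta": out_net.beta, "mode": out_net.mode}
            ).to_csv(tdir / "connectivity_outgroup.tsv", sep="\t", index=False)

        # ---- RBH orthologs ----------------------------------------------
        hits_ab = rbh.parse_tabular_hits(_check_path(paths.hits_ab, "rbh", taxon))
        hits_ba = rbh.parse_tabular_hits(_check_path(paths.hits_ba, "rbh", taxon))
        pairs = rbh.reciprocal_best_hits(hits_ab, hits_ba, evalue_max=config.evalue_max)
        counts["hits_ab"], counts["hits_ba"] = len(hits_ab), len(hits_ba)
        counts["rbh_pairs"] = len(pairs)
        if not pairs:
            raise PipelineError(f"stage 'rbh' ({taxon}): zero reciprocal best hits")
        rbh.write_pairs_tsv(pairs, tdir / "ortholog_pairs.tsv")

        # ---- codon alignment + in-frame filter --------------------------
        cds_a = _read_fasta(_check_path(paths.cds_focal, "align", taxon))
        cds_b = _read_fasta(_check_path(paths.cds_outgroup, "align", taxon))
        aln_dir = tdir / "alignments"
        aln_dir.mkdir(exist_ok=True)
        manifest_rows, retained = [], []
        for pair in pairs:
            if pair.gene_a not in cds_a or pair.gene_b not in cds_b:
                continue
            aln = align_mod.align_and_filter(
                cds_a[pair.gene_a], cds_b[pair.gene_b],
                pair_id=f"{pair.gene_a}|{pair.gene_b}",
                min_segment_nt=config.min_segment_nt,
                min_total_nt=config.min_total_nt,
            )
            manifest_rows.append(
                {
                    "pair_id": aln.pair_id,
                    "gene_a": pair.gene_a,
                    "gene_b": pair.gene_b,
                    "n_segments": len(aln.segments),
                    "total_nt": aln.total_nt,
                    "retained": aln.retained,
                }
            )
            if aln.retained:
                seq_a, seq_b = aln.concatenated()
                with open(aln_dir / f"{pair.gene_a}.fasta", "w") as fh:
                    fh.write(f">{pair.gene_a}\n{seq_a}\n>{pair.gene_b}\n{seq_b}\n")
                retained.append((pair, aln))
        pd.DataFrame(manifest_rows).to_csv(tdir / "alignment_manifest.tsv", sep="\t", index=False)
        counts["alignments_retained"] = len(retained)
        if not retained:
            raise PipelineError(f"stage 'align' ({taxon}): no alignment passed the length filter")

        # ---- rates -------------------------------------------------------
        rate_rows = []
        for pair, aln in retained:
            est = molevol.estimate_rates(aln, method=config.rate_method)
            rate_rows.append(
                {
                    "pair_id": est.pair_id, "gene_a": pair.gene_a, "gene_b": pair.gene_b,
                    "method": est.method, "S": est.S, "N": est.N, "Sd": est.Sd,
                    "Nd": est.Nd, "dN": est.dN, "dS": est.dS, "omega": est.omega,
                    "kappa": est.kappa, "flags": ";".join(est.flags),
                }
            )
        rates = pd.DataFrame(rate_rows)
        rates.to_csv(tdir / "rates.tsv", sep="\t", index=False)
        counts["rate_estimates"] = len(rates)

        datasets[taxon] = TaxonRateData(
            connectivity=net.connectivity,
            rates=rates.set_index("gene_a")[["dN", "dS", "omega"]],
            outgroup_connectivity=out_conn,
            pairs=rates[["gene_a", "gene_b"]],
        )
        manifest["taxa"][taxon] = counts
        log.info("taxon %s: %s", taxon, counts)

    # ---- statistics ------------------------------------------------------
    results, combined = connectivity_rate_analysis(
        datasets,
        n_permutations=config.n_permutations,
        alpha=config.alpha,
        seed=stats_seed,
    )
    results.to_csv(outdir / "correlation_results.tsv", sep="\t", index=False)
    combined.to_csv(outdir / "combined_tests.tsv", sep="\t", index=False)
    manifest["outputs"] = {
        "correlation_results": str(outdir / "correlation_results.tsv"),
        "combined_tests": str(outdir / "combined_tests.tsv"),
    }
    manifest["n_correlations"] = len(results)
    (outdir / "run_log.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
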