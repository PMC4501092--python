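"""End-to-end orchestration: simulate -> preprocess -> indices ->
differential expression -> correlation meta-analysis -> causal filtering ->
locus consistency, with a single config and deterministic seeding.

The headline outputs mirror the study design: genes consistently
deregulated in >= ``de_m`` of T cohorts, genes consistently correlated
with an instability index in >= ``corr_m`` cohorts, their intersection
(the candidate regulators, with matching directionality: overexpressed
genes must correlate positively, underexpressed negatively), the
partial-correlation consensus network, and locus-level rank consistency
for the consensus genes.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import causal as causal_mod
from . import meta as meta_mod
from .indices import (
    ClusterParams,
    cluster_probes,
    compute_zscores,
    full_index_table,
    index_association,
    promoter_methylation,
    summarize_regions,
)
from .io import write_annotation, write_matrix, write_sample_sheet
from .loci import locus_correlations, rank_consistency
from .preprocess import filter_and_impute, preprocess_expression, svd_qc
from .simulate import (
    DriverSpec,
    SimulatedStudy,
    SimulationConfig,
    simulate_pan_cancer,
)

__all__ = ["PipelineConfig", "RunReport", "run_all", "save_study"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Thresholds and study conditions for a full run.

    Defaults: per-cohort alpha 0.05, differential-expression consistency
    at 8 of T cohorts, correlation and causal consistency at 6 of T,
    cluster bounds 1500/500 bp, correlations computed on the
    significant-regions index variant.
    """

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    alpha: float = 0.05
    de_m: int = 8
    corr_m: int = 6
    causal_m: int = 6
    cluster_params: ClusterParams = field(default_factory=ClusterParams)
    index_variant: str = "significant"
    run_qc: bool = True
    outdir: str | None = None

    @property
    def seed(self) -> int:
        return self.sim.seed

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("simulation", {})
        drivers = sim_raw.pop("drivers", None)
        sim = SimulationConfig(**sim_raw)
        if drivers is not None:
            sim.drivers = [DriverSpec(**d) for d in drivers]
        cp = raw.pop("cluster_params", None)
        cfg = cls(sim=sim, **raw)
        if cp is not None:
            cfg.cluster_params = ClusterParams(**cp)
        return cfg

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class RunReport:
    """Everything a run computed, plus per-stage counts and warnings."""

    config: dict
    stage_counts: dict
    index_tables: dict[str, pd.DataFrame]
    index_association: dict[str, dict]
    de_records: dict[str, pd.DataFrame]
    de_consistency: pd.DataFrame
    de_nulls: dict
    corr_records: pd.DataFrame
    corr_consistency: pd.DataFrame
    corr_nulls: dict
    binomial_meta: dict
    candidate_regulators: list[str]
    candidate_directions: dict[str, str]
    causal_records: pd.DataFrame
    consensus: causal_mod.ConsensusNetwork
    meta_network: pd.DataFrame
    locus_reports: dict
    warnings: list[str]

    def summary(self) -> dict:
        """JSON-serialisable headline summary."""
        return {
            "config_seed": self.config["sim"]["seed"],
            "stage_counts": self.stage_counts,
            "candidate_regulators": self.candidate_regulators,
            "candidate_directions": self.candidate_directions,
            "consensus_edges": [
                {"gene": r.gene, "index": r.index, "sign": int(r.sign),
                 "n_support": int(r.n_support)}
                for r in self.consensus.edges.itertuples()
            ],
            "binomial_meta": self.binomial_meta,
            "de_nulls": {k: v for k, v in self.de_nulls.items() if k != "per_cohort"},
            "corr_nulls": {k: v for k, v in self.corr_nulls.items() if k != "per_cohort"},
            "index_association": self.index_association,
            "locus_rank_consistency": {
                key: rep.table.to_dict(orient="records")
                for key, rep in self.locus_reports.items()
            },
            "warnings": self.warnings,
        }


def _candidate_set(
    de_cons: pd.DataFrame, corr_cons: pd.DataFrame, ee_genes: list[str]
) -> tuple[list[str], dict[str, str]]:
    """Genes passing BOTH consistency screens with matching directionality:
    up-regulated genes must correlate positively, down-regulated negatively."""
    match = {"up": "positive", "down": "negative"}
    out, directions = [], {}
    ee = set(ee_genes)
    de_calls = de_cons["call"]
    for gene, sub in corr_cons.groupby("gene"):
        if gene not in ee or gene not in de_calls.index:
            continue
        de_call = de_calls[gene]
        if de_call == "none":
            continue
        if (sub["call"] == match[de_call]).any():
            out.append(gene)
            directions[gene] = de_call
    return sorted(out), directions


def run_all(config: PipelineConfig | None = None, study: SimulatedStudy | None = None) -> RunReport:
    """Execute all stages on a simulated (or supplied) study.

    Rerunning with the same config and seed is bit-identical.  Stage
    failures raise with the stage named; partial outputs already written
    to ``config.outdir`` are retained.
    """
    cfg = config or PipelineConfig()
    warns: list[str] = []
    T = cfg.sim.n_cohorts if study is None else len(study.cohorts)
    for name in ("de_m", "corr_m", "causal_m"):
        if getattr(cfg, name) > T:
            warns.append(f"{name}={getattr(cfg, name)} clamped to {T} cohorts")

    stage = "simulate"
    try:
        if study is None:
            study = simulate_pan_cancer(cfg.sim)
        ee_list = [g for g in study.truth.gene_models
                   if g in set(_ee_universe(study))]

        stage = "cluster"
        clusters = cluster_probes(study.annotation, cfg.cluster_params)

        stage = "per-cohort"
        index_tables, assoc, de_records = {}, {}, {}
        corr_frames, prom_meth, expr_log2, region_beta = {}, {}, {}, {}
        qc_counts = {}
        for cid, cohort in study.cohorts.items():
            expr = preprocess_expression(cohort.expr)
            expr_log2[cid] = expr
            meth = filter_and_impute(cohort.meth)
            if cfg.run_qc:
                qc = svd_qc(expr.data, cohort.sheet)
                qc_counts[cid] = qc.n_significant
            rb = summarize_regions(meth, clusters)
            region_beta[cid] = rb
            _, z = compute_zscores(rb, cohort.sheet)
            idx = full_index_table(z, clusters)
            index_tables[cid] = idx
            assoc[cid] = {
                "all": index_association(idx, "HyperZ", "HypoZ"),
                "significant": index_association(idx, "HyperZ_sig", "HypoZ_sig"),
            }
            de_records[cid] = meta_mod.moderated_t(expr, cohort.sheet)
            corr_frames[cid] = meta_mod.correlate_expr_index(expr, idx, cfg.index_variant)
            prom_meth[cid] = promoter_methylation(rb, clusters)

        stage = "differential-expression meta"
        de_cons = meta_mod.consistency_count(de_records, cfg.alpha, cfg.de_m)
        de_nulls = meta_mod.de_null_probabilities(de_records, cfg.alpha)

        stage = "correlation meta"
        corr_records = pd.concat(corr_frames.values(), ignore_index=True)
        corr_cons = meta_mod.correlation_consistency(corr_records, cfg.alpha, cfg.corr_m)
        corr_nulls = meta_mod.correlation_null_probabilities(corr_records, cfg.alpha)

        stage = "binomial meta-significance"
        pool = len(ee_list)
        ee_de = de_cons.loc[[g for g in ee_list if g in de_cons.index]]
        binom_meta = {}
        for call, p_bar in (("up", de_nulls["p_bar_u"]), ("down", de_nulls["p_bar_d"])):
            tail = meta_mod.binomial_tail(T, min(cfg.de_m, T), p_bar)
            observed = int((ee_de["call"] == call).sum())
            exp_mean, exp_sd = meta_mod.expected_random_count(pool, tail)
            binom_meta[f"de_{call}"] = {
                "observed": observed, "tail_p": tail,
                "expected": exp_mean, "expected_sd": exp_sd,
                "meta_p": meta_mod.meta_significance(observed, pool, tail),
            }
        corr_keys = {("HyperZ", "positive"): "p_bar_uu", ("HyperZ", "negative"): "p_bar_du",
                     ("HypoZ", "positive"): "p_bar_ud", ("HypoZ", "negative"): "p_bar_dd"}
        ee_corr = corr_cons[corr_cons["gene"].isin(ee_list)]
        for (index, call), key in corr_keys.items():
            tail = meta_mod.binomial_tail(T, min(cfg.corr_m, T), corr_nulls[key])
            observed = int(((ee_corr["index"] == index) & (ee_corr["call"] == call)).sum())
            exp_mean, exp_sd = meta_mod.expected_random_count(pool, tail)
            binom_meta[f"corr_{index}_{call}"] = {
                "observed": observed, "tail_p": tail,
                "expected": exp_mean, "expected_sd": exp_sd,
                "meta_p": meta_mod.meta_significance(observed, pool, tail),
            }

        stage = "candidate intersection"
        candidates, directions = _candidate_set(de_cons, corr_cons, ee_list)
        if not candidates:
            warns.append("no candidate regulators pass both screens")

        stage = "causal"
        causal_rows = []
        for cid, cohort in study.cohorts.items():
            idx = index_tables[cid]
            pm = prom_meth[cid]
            expr = expr_log2[cid]
            cancers = [s for s in cohort.sheet.cancers if s in idx.index]
            idx_c = idx.loc[cancers]
            for g in candidates:
                row = pm.loc[g] if g in pm.index else None
                causal_rows.append(
                    causal_mod.single_gene_causal_test(
                        g, expr.data.loc[g], row, idx_c, cohort=cid
                    )
                )
            if candidates:
                K = len(candidates)
                if len(cancers) > 2 * K + 3:
                    causal_rows.append(
                        causal_mod.full_model_causal_test(
                            candidates, expr.data, pm, idx_c, cohort=cid
                        )
                    )
                else:
                    warns.append(
                        f"cohort {cid}: too few cancers for the {K}-gene full model"
                    )
        causal_records = (
            pd.concat(causal_rows, ignore_index=True) if causal_rows else pd.DataFrame(
                columns=["gene", "cohort", "index", "mode", "partial_r", "pvalue"]
            )
        )
        full = causal_records[causal_records["mode"] == "full_model"] if len(causal_records) else causal_records
        consensus = causal_mod.build_consensus(
            full if len(full) else causal_records, cfg.alpha, cfg.causal_m
        )

        stage = "meta network"
        meta_net = (
            meta_mod.expr_expr_meta_network(
                expr_log2,
                {cid: c.sheet for cid, c in study.cohorts.items()},
                candidates,
                cfg.alpha,
            )
            if len(candidates) >= 2
            else pd.DataFrame()
        )

        stage = "locus consistency"
        locus_reports = {}
        cohort_ids = list(study.cohorts)
        reference = cohort_ids[0]
        for r in consensus.edges.itertuples():
            restriction = "cgi" if r.index == "HyperZ" else "opensea"
            tables = {}
            for cid, cohort in study.cohorts.items():
                cancers = cohort.sheet.cancers
                tables[cid] = locus_correlations(
                    region_beta[cid], expr_log2[cid], r.gene, restriction,
                    clusters, cancer_samples=cancers,
                )
            direction = "descending" if r.sign > 0 else "ascending"
            locus_reports[f"{r.gene}:{r.index}"] = rank_consistency(
                tables, reference, direction
            )
    except Exception as exc:  # pragma: no cover - failure path
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report = RunReport(
        config=cfg.echo(),
        stage_counts={
            "n_cohorts": T,
            "n_genes": len(next(iter(de_records.values()))),
            "n_clusters": len(clusters),
            "n_candidates": len(candidates),
            "n_consensus_edges": len(consensus.edges),
            "qc_significant_components": qc_counts,
        },
        index_tables=index_tables,
        index_association=assoc,
        de_records=de_records,
        de_consistency=de_cons,
        de_nulls=de_nulls,
        corr_records=corr_records,
        corr_consistency=corr_cons,
        corr_nulls=corr_nulls,
        binomial_meta=binom_meta,
        candidate_regulators=candidates,
        candidate_directions=directions,
        causal_records=causal_records,
        consensus=consensus,
        meta_network=meta_net,
        locus_reports=locus_reports,
        warnings=warns,
    )
    if cfg.outdir:
        _write_outputs(report, study, Path(cfg.outdir))
    return report


def _ee_universe(study: SimulatedStudy) -> list[str]:
    """EE genes of the study: the first n_ee_genes simulated genes (driver
    genes plus bundled-list symbols)."""
    genes = next(iter(study.cohorts.values())).expr.gene_ids
    return genes[: study.config.n_ee_genes]


def save_study(study: SimulatedStudy, outdir) -> None:
    """Write the per-cohort file set plus ground truth and JSON metadata."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_annotation(study.annotation, out / "probe_annotation.tsv")
    for cid, cohort in study.cohorts.items():
        write_matrix(cohort.expr, out / f"{cid}_expression.tsv")
        write_matrix(cohort.meth, out / f"{cid}_methylation.tsv")
        write_sample_sheet(cohort.sheet, out / f"{cid}_samples.tsv")
    truth = study.truth
    truth.regions.to_csv(out / "truth_regions.tsv", sep="\t")
    pd.concat(truth.latents, names=["cohort_id", "sample_id"]).to_csv(
        out / "truth_latents.tsv", sep="\t"
    )
    pd.Series(truth.gene_models, name="model").rename_axis("gene").to_csv(
        out / "truth_gene_models.tsv", sep="\t"
    )
    meta = dataclasses.asdict(study.config)
    with open(out / "simulation_metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2, default=str)


def _write_outputs(report: RunReport, study: SimulatedStudy, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    for cid, idx in report.index_tables.items():
        idx.to_csv(out / f"{cid}_indices.tsv", sep="\t")
    for cid, de in report.de_records.items():
        de.to_csv(out / f"{cid}_diffexpr.tsv", sep="\t")
    report.de_consistency.to_csv(out / "de_consistency.tsv", sep="\t")
    report.corr_records.to_csv(out / "correlations.tsv", sep="\t", index=False)
    report.corr_consistency.to_csv(out / "correlation_consistency.tsv", sep="\t", index=False)
    report.causal_records.to_csv(out / "causal_records.tsv", sep="\t", index=False)
    report.consensus.edges.to_csv(out / "consensus_edges.tsv", sep="\t", index=False)
    if len(report.meta_network):
        report.meta_network.to_csv(out / "meta_network_edges.tsv", sep="\t", index=False)
    for key, rep in report.locus_reports.items():
        safe = key.replace(":", "_")
        rep.table.to_csv(out / f"rank_consistency_{safe}.tsv", sep="\t", index=False)
    with open(out / "report.json", "w") as fh:
        json.dump(report.summary(), fh, indent=2, default=str)
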